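"""Functional track data structures and builders.

A *track* is a subset of 1-based protein positions, each carrying a weight in
[0, 1] that measures one kind of site functionality:

* ``interaction`` tracks hold per-position ligand binding frequencies over the
  match states of a domain instance (real-valued weights);
* ``domain`` tracks span the whole protein with weight 1 inside the domain
  instance and 0 outside;
* ``conservation`` tracks span the whole protein, weighting each position by
  (non-gap fraction) x (Jensen-Shannon divergence of the alignment column
  against a BLOSUM62 amino-acid background);
* ``natural_variation`` is a one-hot whole-gene encoding handled by
  :mod:`perturbtrack.combine`.

Repeated instances of one domain family are additionally pooled into
*aggregate* tracks; families with ``replace_threshold`` (default 40) or more
instances are represented by their aggregate alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon

from ._blosum import AA_INDEX, AMINO_ACIDS, BLOSUM62_BACKGROUND
from .exceptions import CoordinateError, InputError, MissingAnnotationError

logger = logging.getLogger(__name__)

TRACK_GROUPS = ("interaction", "domain", "conservation", "natural_variation")

_GAP_CHARS = set("-.")


@dataclass
class FunctionalTrack:
    """A weighted set of protein positions of one functionality type.

    Parameters
    ----------
    track_id : str
        Unique identifier within the isoform.
    isoform_id : str
        Protein isoform the positions refer to.
    group : str
        One of ``interaction``, ``domain``, ``conservation``,
        ``natural_variation``.
    positions : array-like of int
        1-based protein positions (the set W); stored sorted and unique.
    weights : array-like of float
        Per-position weights in [0, 1], aligned with ``positions``.
    protein_length : int
        Length L of the protein; every position must lie in [1, L].
    ligand : str, optional
        Ligand label for interaction tracks.
    family_id : str, optional
        Domain family the track derives from; links a domain track to its
        interaction counterpart in the mechanism report.
    min_mutation_count : int, optional
        Calibrated minimum mutation count n* (filled by calibration).
    """

    track_id: str
    isoform_id: str
    group: str
    positions: np.ndarray
    weights: np.ndarray
    protein_length: int
    ligand: Optional[str] = None
    family_id: Optional[str] = None
    min_mutation_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.group not in TRACK_GROUPS:
            raise InputError(f"unknown track group {self.group!r}")
        pos = np.asarray(self.positions, dtype=np.int64)
        wts = np.asarray(self.weights, dtype=float)
        if pos.ndim != 1 or wts.shape != pos.shape:
            raise InputError("positions and weights must be 1-D and aligned")
        if pos.size == 0:
            raise InputError(f"track {self.track_id!r} has no positions")
        order = np.argsort(pos, kind="stable")
        pos, wts = pos[order], wts[order]
        if np.any(np.diff(pos) == 0):
            raise InputError(f"track {self.track_id!r} has duplicate positions")
        if self.protein_length < 1:
            raise InputError("protein_length must be positive")
        if pos[0] < 1 or pos[-1] > self.protein_length:
            raise CoordinateError(
                f"track {self.track_id!r}: positions outside [1, {self.protein_length}]"
            )
        if np.any(wts < 0.0) or np.any(wts > 1.0):
            raise InputError(f"track {self.track_id!r}: weights outside [0, 1]")
        if self.group == "domain" and not np.isin(wts, (0.0, 1.0)).all():
            raise InputError("domain tracks must have 0/1 weights")
        self.positions = pos
        self.weights = wts

    @property
    def is_degenerate(self) -> bool:
        """True when fewer than two distinct weight values exist (zero variance)."""
        return bool(np.ptp(self.weights) == 0.0)

    @property
    def size(self) -> int:
        return int(self.positions.size)

    def weights_at(self, positions: np.ndarray) -> np.ndarray:
        """Weights for positions known to belong to the track."""
        idx = np.searchsorted(self.positions, positions)
        return self.weights[idx]

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Boolean membership mask for arbitrary 1-based positions."""
        positions = np.asarray(positions, dtype=np.int64)
        idx = np.searchsorted(self.positions, positions)
        idx_clipped = np.minimum(idx, self.positions.size - 1)
        return self.positions[idx_clipped] == positions

    @property
    def positive_positions(self) -> np.ndarray:
        return self.positions[self.weights > 0.0]


@dataclass
class DomainInstance:
    """One located instance of a domain family on a protein isoform."""

    family_id: str
    isoform_id: str
    match_state_positions: Sequence[int]
    binding_frequencies: Optional[Mapping[str, Sequence[float]]] = None

    def __post_init__(self) -> None:
        pos = list(self.match_state_positions)
        if not pos:
            raise InputError("domain instance has no match states")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise InputError("match-state positions must be strictly increasing")
        if self.binding_frequencies is not None:
            for ligand, freqs in self.binding_frequencies.items():
                if len(freqs) != len(pos):
                    raise InputError(
                        f"{self.family_id}/{ligand}: binding frequencies do not "
                        "align with match states"
                    )


@dataclass
class ConservationColumn:
    """One alignment column mapped to a protein position."""

    column_index: int
    residue_counts: Dict[str, int]
    gap_count: int = 0
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gap_count < 0 or any(c < 0 for c in self.residue_counts.values()):
            raise InputError("negative counts in conservation column")
        if self.gap_count == 0 and sum(self.residue_counts.values()) == 0:
            raise InputError("empty conservation column")


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence with equal 1/2 mixture weights.

    Symmetric in its arguments and bounded in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = float(jensenshannon(p, q, base=2.0)) ** 2
    # guard against tiny negative round-off and >1 overshoot
    return min(max(d, 0.0), 1.0)


def conservation_weight(
    column: ConservationColumn,
    background: Optional[np.ndarray] = None,
) -> float:
    """Conservation weight = (non-gap fraction) x JSD(column || background).

    The column distribution is the empirical amino-acid frequency over the
    non-gap rows (no pseudo-counts); the default background is the BLOSUM62
    marginal distribution. All-gap columns get weight 0.
    """
    if background is None:
        background = BLOSUM62_BACKGROUND
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or not np.isclose(background.sum(), 1.0):
        raise InputError("background must be a 20-vector summing to 1")
    counts = np.zeros(20, dtype=float)
    for aa, c in column.residue_counts.items():
        aa = aa.upper()
        if aa in AA_INDEX:
            counts[AA_INDEX[aa]] += c
    n_res = counts.sum()
    total = n_res + column.gap_count
    if total == 0:
        raise InputError("empty conservation column")
    if n_res == 0:
        return 0.0
    weight = (n_res / total) * jensen_shannon_divergence(counts / n_res, background)
    return min(max(weight, 0.0), 1.0)


def build_interaction_track(
    instance: DomainInstance,
    ligand: str,
    protein_length: int,
    track_id: Optional[str] = None,
) -> FunctionalTrack:
    """Build an interaction track from one domain instance's binding frequencies.

    Track positions are the instance's match states; weights are the per-state
    binding frequencies for ``ligand``.
    """
    if instance.binding_frequencies is None or ligand not in instance.binding_frequencies:
        raise MissingAnnotationError(
            f"{instance.family_id}: no binding frequencies for ligand {ligand!r}"
        )
    pos = np.asarray(instance.match_state_positions, dtype=np.int64)
    if pos[-1] > protein_length:
        raise CoordinateError(
            f"{instance.family_id}: match state {pos[-1]} exceeds protein "
            f"length {protein_length}"
        )
    track = FunctionalTrack(
        track_id=track_id or f"{instance.family_id}:{ligand}:{pos[0]}",
        isoform_id=instance.isoform_id,
        group="interaction",
        positions=pos,
        weights=np.asarray(instance.binding_frequencies[ligand], dtype=float),
        protein_length=protein_length,
        ligand=ligand,
        family_id=instance.family_id,
    )
    if track.is_degenerate:
        logger.info("interaction track %s is degenerate (constant weights)", track.track_id)
    return track


def build_domain_track(
    instance: DomainInstance,
    protein_length: int,
    track_id: Optional[str] = None,
) -> FunctionalTrack:
    """Build a whole-length 0/1 domain-membership track for one instance."""
    pos = np.asarray(instance.match_state_positions, dtype=np.int64)
    if pos[-1] > protein_length:
        raise CoordinateError(
            f"{instance.family_id}: position {pos[-1]} exceeds protein length "
            f"{protein_length}"
        )
    weights = np.zeros(protein_length, dtype=float)
    weights[pos - 1] = 1.0
    track = FunctionalTrack(
        track_id=track_id or f"{instance.family_id}:domain:{pos[0]}",
        isoform_id=instance.isoform_id,
        group="domain",
        positions=np.arange(1, protein_length + 1, dtype=np.int64),
        weights=weights,
        protein_length=protein_length,
        family_id=instance.family_id,
    )
    if track.is_degenerate:
        logger.info("domain track %s covers the whole protein (degenerate)", track.track_id)
    return track


def _aggregate_weights(
    members: List[FunctionalTrack],
) -> tuple[np.ndarray, np.ndarray]:
    """Union of member positions with the maximum weight at shared positions."""
    agg: Dict[int, float] = {}
    for t in members:
        for p, w in zip(t.positions.tolist(), t.weights.tolist()):
            if agg.get(p, -1.0) < w:
                agg[p] = w
    pos = np.array(sorted(agg), dtype=np.int64)
    return pos, np.array([agg[p] for p in pos], dtype=float)


def build_aggregate_tracks(
    instances: Sequence[DomainInstance],
    protein_length: int,
    *,
    ligand: Optional[str] = None,
    replace_threshold: int = 40,
) -> List[FunctionalTrack]:
    """Emit per-instance and aggregate tracks for a set of domain instances.

    Instances are grouped by family. A family with >= 2 instances contributes
    one aggregate track pooling its instances (maximum weight at overlapping
    positions). A family with >= ``replace_threshold`` instances is represented
    by its aggregate alone; below the threshold both the individual tracks and
    the aggregate are emitted.

    With ``ligand`` set, interaction tracks are built from binding
    frequencies; otherwise whole-length 0/1 domain tracks are built.
    """
    by_family: Dict[str, List[DomainInstance]] = {}
    for inst in instances:
        by_family.setdefault(inst.family_id, []).append(inst)

    out: List[FunctionalTrack] = []
    for family, members in by_family.items():
        if ligand is not None:
            singles = [
                build_interaction_track(
                    m, ligand, protein_length,
                    track_id=f"{family}:{ligand}:{m.match_state_positions[0]}",
                )
                for m in members
            ]
        else:
            singles = [
                build_domain_track(
                    m, protein_length,
                    track_id=f"{family}:domain:{m.match_state_positions[0]}",
                )
                for m in members
            ]
        if len(singles) == 1:
            out.extend(singles)
            continue
        if len(singles) >= 2:
            if ligand is not None:
                member_tracks = singles
            else:
                # aggregate domain membership over instance positions only
                member_tracks = [
                    FunctionalTrack(
                        track_id=f"{family}:span:{m.match_state_positions[0]}",
                        isoform_id=m.isoform_id,
                        group="domain",
                        positions=np.asarray(m.match_state_positions, dtype=np.int64),
                        weights=np.ones(len(m.match_state_positions)),
                        protein_length=protein_length,
                        family_id=family,
                    )
                    for m in members
                ]
            n_member_pos = sum(t.positions.size for t in member_tracks)
            pos, wts = _aggregate_weights(member_tracks)
            if n_member_pos != pos.size:
                logger.info(
                    "family %s: instances overlap; aggregate keeps the maximum "
                    "weight at shared positions", family,
                )
            if ligand is None:
                # domain aggregates span the protein like individual domain tracks
                full = np.zeros(protein_length, dtype=float)
                full[pos - 1] = wts
                pos = np.arange(1, protein_length + 1, dtype=np.int64)
                wts = full
            aggregate = FunctionalTrack(
                track_id=f"{family}:{ligand or 'domain'}:aggregate",
                isoform_id=members[0].isoform_id,
                group="interaction" if ligand is not None else "domain",
                positions=pos,
                weights=wts,
                protein_length=protein_length,
                ligand=ligand,
                family_id=family,
            )
            if len(singles) >= replace_threshold:
                out.append(aggregate)
            else:
                out.extend(singles)
                out.append(aggregate)
    return out


def conservation_track_from_alignment(
    rows: Sequence[str],
    isoform_id: str,
    background: Optional[np.ndarray] = None,
    track_id: Optional[str] = None,
) -> FunctionalTrack:
    """Derive the conservation track from an aligned set of sequences.

    The first row is the reference isoform; alignment columns where the
    reference is a gap are skipped, and the remaining columns map 1:1 onto
    protein positions. Non-standard residue codes are treated as gaps.
    """
    if not rows:
        raise InputError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise InputError("alignment rows have unequal lengths")
    ref = rows[0].upper()
    weights: List[float] = []
    for col in range(width):
        if ref[col] in _GAP_CHARS:
            continue
        counts: Dict[str, int] = {}
        gaps = 0
        for row in rows:
            ch = row[col].upper()
            if ch in AA_INDEX:
                counts[ch] = counts.get(ch, 0) + 1
            else:
                gaps += 1
        column = ConservationColumn(len(weights) + 1, counts, gaps)
        weights.append(conservation_weight(column, background))
    length = len(weights)
    return FunctionalTrack(
        track_id=track_id or "conservation",
        isoform_id=isoform_id,
        group="conservation",
        positions=np.arange(1, length + 1, dtype=np.int64),
        weights=np.asarray(weights, dtype=float),
        protein_length=length,
    )
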