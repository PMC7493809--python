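"""Combining correlated per-track Z scores into gene-level results.

Per-track Z scores are pooled with a weighted Z-transform corrected for the
between-track correlations r_ij:

    Z = sum_i c_i Z_i / sqrt(sum_i c_i^2 + 2 sum_{i<j} c_i c_j r_ij)

The confidence weights c_i split the total confidence equally across the
track groups present (interaction, domain, conservation, natural variation);
within the interaction and domain groups each track's share is proportional
to sqrt(m), m being its count of mutations at positively weighted positions
(configurable to linear in m). By default only tracks that met their
calibrated minimum mutation count and have Z > 0 enter the combination (the
positivity screen can be disabled, e.g. to study the null distribution of
the combined statistic).

The whole-gene (natural variation) statistic uses the one-hot simplification
of the track formulas, down-weighted by a subsample factor s (default
1/sqrt(n), n = total mutation count) so cohort-scale mutation counts do not
swamp the subgene signals; its covariance with all subgene tracks is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .background import NaturalVariationModel
from .engine import TrackStatistics
from .exceptions import CombinationError, InputError
from .tracks import FunctionalTrack

#: Track groups sharing the overall confidence equally when present.
CONFIDENCE_GROUPS = ("interaction", "domain", "conservation", "natural_variation")


@dataclass
class ConfidenceWeights:
    """Per-track confidence weights c_i and their group shares."""

    track_ids: List[str]
    values: np.ndarray
    group_shares: Dict[str, float]

    @property
    def k(self) -> int:
        return len(self.track_ids)


def confidence_weights(
    entries: Sequence[Tuple[FunctionalTrack, TrackStatistics]],
    within_group: str = "sqrt",
) -> ConfidenceWeights:
    """Assign confidence weights to the tracks entering a combination.

    Each group present receives an equal share of the overall confidence
    (absent groups' shares are redistributed); within a group, track i gets a
    share proportional to sqrt(m_i) (``within_group="sqrt"``) or m_i
    (``"linear"``), with m_i the mutations at positively weighted positions.
    """
    if within_group not in ("sqrt", "linear"):
        raise InputError("within_group must be 'sqrt' or 'linear'")
    if not entries:
        raise InputError("no tracks to weight")
    groups = [t.group for t, _ in entries]
    present = [g for g in CONFIDENCE_GROUPS if g in groups]
    share = 1.0 / len(present)
    raw = np.zeros(len(entries), dtype=float)
    for g in present:
        idx = [i for i, grp in enumerate(groups) if grp == g]
        m = np.array([max(entries[i][1].m_positive, 1) for i in idx], dtype=float)
        prop = np.sqrt(m) if within_group == "sqrt" else m
        raw[idx] = share * prop / prop.sum()
    return ConfidenceWeights(
        track_ids=[t.track_id for t, _ in entries],
        values=raw,
        group_shares={g: share for g in present},
    )


def condition_correlation(r: np.ndarray) -> np.ndarray:
    """Symmetrize, unit-diagonalize and clip a correlation matrix.

    Entries are clipped to [-1, 1]; if the clipped matrix still has an
    eigenvalue below -1e-8 it is projected back to the PSD cone by zeroing
    negative eigenvalues (rescaling the diagonal to 1).
    """
    r = np.asarray(r, dtype=float)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    eigvals = np.linalg.eigvalsh(r)
    if eigvals[0] < -1e-8:
        vals, vecs = np.linalg.eigh(r)
        vals = np.clip(vals, 0.0, None)
        r = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.clip(np.diag(r), 1e-12, None))
        r = r / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
    return r


def combine_z(
    z: Sequence[float],
    c: Sequence[float],
    r: np.ndarray,
) -> float:
    """Correlation-corrected weighted Z-transform of per-track Z scores."""
    z = np.asarray(z, dtype=float)
    c = np.asarray(c, dtype=float)
    r = np.asarray(r, dtype=float)
    if z.shape != c.shape or r.shape != (z.size, z.size):
        raise InputError("z, c and r have inconsistent shapes")
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise InputError("correlations must lie in [-1, 1]")
    denom_sq = float(c @ r @ c)
    if denom_sq <= 0.0:
        raise CombinationError(
            f"non-positive combination denominator (c'Rc = {denom_sq:.3e}); "
            f"c = {c.tolist()}, eigmin(R) = {np.linalg.eigvalsh(r)[0]:.3e}"
        )
    return float(np.dot(c, z) / math.sqrt(denom_sq))


def subsample_factor(n_total: int, mode: str = "inv_sqrt_n") -> float:
    """Whole-gene subsample factor s.

    ``inv_sqrt_n`` (default) gives s = 1/sqrt(n); ``none`` disables
    subsampling (s = 1).
    """
    if n_total < 1:
        raise InputError("need at least one mutation")
    if mode == "inv_sqrt_n":
        return 1.0 / math.sqrt(n_total)
    if mode == "none":
        return 1.0
    raise InputError(f"unknown subsample mode {mode!r}")


@dataclass
class WholeGeneStatistics:
    """One-hot whole-gene score statistics under the natural-variation model."""

    gene: str
    lam_gene: float
    s: float
    n_gene: int
    m_positive: int
    sum_f_gene: float
    total_n: int
    total_sum_f: float
    total_sum_f2: float
    score: float
    expected: float
    variance: float
    group: str = "natural_variation"

    @property
    def sd(self) -> float:
        return math.sqrt(max(self.variance, 0.0))

    @property
    def zscore(self) -> Optional[float]:
        if self.variance <= 0.0:
            return None
        return (self.score - self.expected) / self.sd


def whole_gene_statistics(
    gene: str,
    model: NaturalVariationModel,
    sum_f_gene: float,
    n_gene: int,
    total_n: int,
    total_sum_f: float,
    total_sum_f2: float,
    s: Optional[float] = None,
    subsample_mode: str = "inv_sqrt_n",
) -> Optional[WholeGeneStatistics]:
    """Whole-gene score statistics with subsampling.

    S = s * sum_{i in G} f_i, E = s * lam_g * sum_i f_i and
    var = s * lam_g * (1 - s * lam_g) * sum_i f_i^2, the one-hot
    simplification of the track formulas. Returns None when the gene is
    absent from the model universe (subgene tracks still combine).
    """
    lam_g = model.lambda_for(gene)
    if lam_g is None:
        return None
    if s is None:
        s = subsample_factor(total_n, subsample_mode)
    score = s * sum_f_gene
    expected = s * lam_g * total_sum_f
    variance = s * lam_g * (1.0 - s * lam_g) * total_sum_f2
    return WholeGeneStatistics(
        gene=gene,
        lam_gene=lam_g,
        s=s,
        n_gene=n_gene,
        m_positive=n_gene,
        sum_f_gene=sum_f_gene,
        total_n=total_n,
        total_sum_f=total_sum_f,
        total_sum_f2=total_sum_f2,
        score=score,
        expected=expected,
        variance=max(variance, 0.0),
    )


@dataclass
class TrackBreakdown:
    """Reporting row for one mutated track of one isoform."""

    track_id: str
    group: str
    ligand: Optional[str]
    family_id: Optional[str]
    zscore: Optional[float]
    n: int
    m_positive: int
    included: bool
    exclusion_reason: Optional[str] = None


@dataclass
class IsoformResult:
    """Combined score and per-track breakdown for one isoform."""

    isoform: str
    combined_z: Optional[float]
    breakdown: List[TrackBreakdown]
    k: int


@dataclass
class GeneResult:
    """Final per-gene result: the best isoform's combined score."""

    gene: str
    best_isoform: Optional[str]
    combined_z: Optional[float]
    isoforms: Dict[str, IsoformResult]

    @property
    def breakdown(self) -> List[TrackBreakdown]:
        if self.best_isoform is None:
            for iso in sorted(self.isoforms):
                return self.isoforms[iso].breakdown
            return []
        return self.isoforms[self.best_isoform].breakdown


def score_gene(gene: str, isoform_results: Dict[str, IsoformResult]) -> GeneResult:
    """Maximize the combined score over a gene's isoforms.

    Ties (and the choice among scored isoforms) break by lexicographic
    isoform id so output is deterministic.
    """
    if not isoform_results:
        raise InputError("no scored isoforms")
    best_iso: Optional[str] = None
    best_z: Optional[float] = None
    for iso in sorted(isoform_results):
        z = isoform_results[iso].combined_z
        if z is None:
            continue
        if best_z is None or z > best_z:
            best_iso, best_z = iso, z
    return GeneResult(
        gene=gene,
        best_isoform=best_iso,
        combined_z=best_z,
        isoforms=isoform_results,
    )
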