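"""Background mutation models.

Per-position missense probabilities are built from codon structure: a codon's
unnormalized rate is the number of single-nucleotide changes at each of its
three sites that are amino-acid-changing (stops excluded), with changes at C/G
sites up-weighted by the pan-cancer C/G-vs-A/T bias factor ``b`` (default
3.063). Per track, the rates over the track's positions are normalized to sum
to one.

The whole-gene (natural variation) background rests on how often each gene
varies across healthy individuals: per individual, genes are min-ranked by
variant count, the ranks scaled to [0, 1] and floored into 0.01-wide bins;
bins are averaged across individuals and normalized (with a small positive
floor) into a probability distribution over genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import rankdata

from .exceptions import DegenerateTrackError, InputError
from .tracks import FunctionalTrack

logger = logging.getLogger(__name__)

DEFAULT_CG_BIAS = 3.063  # pan-cancer C/G vs A/T relative mutation frequency

_NUCLEOTIDES = "ACGT"
_STOPS = frozenset(standard_dna_table.stop_codons)
_CODON_TO_AA = dict(standard_dna_table.forward_table)


@dataclass(frozen=True)
class CodonProfile:
    """Per-codon missense structure.

    ``bias_factors[d]`` is 1 for an A/T nucleotide at codon site d and ``b``
    for C/G; ``missense_counts[d]`` counts the substitutions at site d that
    change the amino acid without creating a stop.
    """

    codon: str
    bias_factors: tuple
    missense_counts: tuple
    lam: float


@lru_cache(maxsize=None)
def _missense_counts(codon: str) -> tuple:
    aa = _CODON_TO_AA[codon]
    counts = []
    for d in range(3):
        c = 0
        for u in _NUCLEOTIDES:
            if u == codon[d]:
                continue
            mutant = codon[:d] + u + codon[d + 1:]
            if mutant in _STOPS:
                continue
            if _CODON_TO_AA[mutant] != aa:
                c += 1
        counts.append(c)
    return tuple(counts)


def codon_lambda(codon: str, b: float = DEFAULT_CG_BIAS) -> CodonProfile:
    """Unnormalized missense rate of a sense codon.

    Enumerates all 9 single-nucleotide substitutions; nonsense and synonymous
    changes contribute nothing, and each missense change contributes its
    site's bias factor (1 for A/T, ``b`` for C/G).
    """
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(ch not in _NUCLEOTIDES for ch in codon):
        raise InputError(f"not a DNA codon: {codon!r}")
    if codon in _STOPS:
        raise InputError(f"stop codon {codon!r} has no missense rate")
    if b <= 0:
        raise InputError("bias factor b must be positive")
    counts = _missense_counts(codon)
    bias = tuple(1.0 if codon[d] in "AT" else b for d in range(3))
    lam = float(sum(bias[d] * counts[d] for d in range(3)))
    return CodonProfile(codon=codon, bias_factors=bias, missense_counts=counts, lam=lam)


def cds_lambdas(cds: str, b: float = DEFAULT_CG_BIAS) -> np.ndarray:
    """Per-position (per-codon) unnormalized missense rates for a CDS.

    A trailing stop codon is tolerated and dropped; internal stop codons are
    rejected.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise InputError("CDS length is not a multiple of 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    lams = np.empty(len(codons), dtype=float)
    for j, codon in enumerate(codons):
        lams[j] = codon_lambda(codon, b).lam
    return lams


def rescale_for_track(
    lambdas: Optional[np.ndarray],
    track: FunctionalTrack,
) -> np.ndarray:
    """Background probabilities restricted to a track, normalized to sum to 1.

    ``lambdas`` is the full-length per-position rate vector (index j-1 holds
    position j); ``None`` means the uniform background over the track.
    """
    if lambdas is None:
        return np.full(track.size, 1.0 / track.size)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size < track.positions[-1]:
        raise InputError(
            f"lambda vector length {lambdas.size} shorter than track extent "
            f"{track.positions[-1]}"
        )
    if np.any(lambdas < 0):
        raise InputError("negative background rates")
    lam = lambdas[track.positions - 1]
    total = lam.sum()
    if total <= 0:
        raise DegenerateTrackError(
            f"track {track.track_id!r}: background mass is zero over the track"
        )
    return lam / total


@dataclass
class NaturalVariationModel:
    """Per-gene whole-genome background distribution."""

    genes: List[str]
    lam: np.ndarray
    bin_width: float = 0.01
    lambda_floor: float = 1e-4

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        if len(self.genes) != self.lam.size:
            raise InputError("gene list and lambda vector lengths differ")
        self._index: Dict[str, int] = {g: i for i, g in enumerate(self.genes)}

    def lambda_for(self, gene: str) -> Optional[float]:
        i = self._index.get(gene)
        return None if i is None else float(self.lam[i])

    def __contains__(self, gene: str) -> bool:
        return gene in self._index


def build_natural_variation(
    variant_counts: pd.DataFrame,
    bin_width: float = 0.01,
    lambda_floor: float = 1e-4,
    universe: Optional[Sequence[str]] = None,
) -> NaturalVariationModel:
    """Build the whole-gene background from an individual x gene count table.

    Per individual, genes are min-ranked ascending by variant count, ranks are
    scaled as (rank - 1)/(N - 1), floored into ``bin_width`` bins, then
    averaged across individuals; ``lambda_floor`` is added before normalizing
    so no gene gets exactly zero background probability.
    """
    if variant_counts.shape[0] < 1 or variant_counts.shape[1] < 2:
        raise InputError("need at least one individual and two genes")
    if universe is not None:
        universe_set = set(universe)
        missing = [g for g in variant_counts.columns if g not in universe_set]
        if missing:
            logger.warning(
                "%d genes absent from the universe were excluded from the "
                "natural-variation model", len(missing),
            )
            variant_counts = variant_counts.drop(columns=missing)
            if variant_counts.shape[1] < 2:
                raise InputError("fewer than two genes remain after universe filter")
    counts = variant_counts.to_numpy(dtype=float)
    if np.any(counts < 0):
        raise InputError("negative variant counts")
    n_genes = counts.shape[1]
    ranks = rankdata(counts, method="min", axis=1)
    scaled = (ranks - 1.0) / (n_genes - 1.0)
    bins = np.floor(scaled / bin_width + 1e-9) * bin_width
    mean_bins = bins.mean(axis=0) + lambda_floor
    lam = mean_bins / mean_bins.sum()
    return NaturalVariationModel(
        genes=list(variant_counts.columns),
        lam=lam,
        bin_width=bin_width,
        lambda_floor=lambda_floor,
    )
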