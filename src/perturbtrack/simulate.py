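"""Synthetic cohorts with known structure, and the permutation oracle.

The generator emulates every input the pipeline consumes: proteins with
interaction / domain / conservation tracks, coding sequences (for the
codon-level background), somatic mutation tables with subclonal fractions,
and an individual x gene variant-count table for the whole-gene background.
Null genes draw mutation positions from the background; "driver" genes draw
from the background tilted by a multiplicative enrichment factor toward
positions whose interaction-track weight reaches a cutoff. Outputs use the
exact TSV/FASTA dialects of :mod:`perturbtrack.io`, so the full pipeline
runs end-to-end on synthetic data.

The permutation oracle estimates track-score means, standard deviations and
between-track covariances by brute-force position shuffles; it exists to
validate the analytic formulas and is never the scoring path.

Default study conditions: 30 missense mutations per gene, subclonal
fractions uniform on (0.2, 1.0], binding-frequency-like interaction weights
(Beta(0.5, 0.5): a position either contacts the ligand in most co-complex
structures or rarely), mid-spread conservation weights (Beta(2, 2)), two
domain families per protein whose match states also carry the interaction
tracks, and a codon-level background with C/G bias b = 3.063.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as ptio
from .background import DEFAULT_CG_BIAS, build_natural_variation, cds_lambdas
from .engine import MutationRecord
from .exceptions import InputError
from .model import PerturbationModel
from .tracks import FunctionalTrack

_SENSE_CODONS = None
_LIGANDS = ("dna", "rna", "peptide", "ion", "sm")


def _sense_codons() -> List[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from Bio.Data.CodonTable import standard_dna_table

        _SENSE_CODONS = sorted(standard_dna_table.forward_table)
    return _SENSE_CODONS


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic cohort; all are recorded in the output."""

    seed: int = 0
    n_genes: int = 100
    n_drivers: int = 0
    protein_length: Tuple[int, int] = (120, 400)
    n_domain_families: int = 2
    domain_fraction: float = 0.15  # each family instance covers ~this fraction
    interaction_weight_dist: str = "beta-bimodal"  # Beta(0.5, 0.5)
    conservation_weight_dist: str = "beta-mid"  # Beta(2, 2)
    # ligand-binding residues are evolutionarily constrained: each position's
    # conservation weight mixes its interaction weight in with this coefficient
    conservation_coupling: float = 0.5
    background: str = "codon"  # or "uniform"
    b: float = DEFAULT_CG_BIAS
    effect: float = 1.0  # enrichment multiplier; 1 = null
    weight_cutoff: float = 0.5  # tilt positions with interaction weight >= this
    mutations_per_gene: int = 30
    count_mode: str = "fixed"  # or "background": multinomial over genes
    f_range: Tuple[float, float] = (0.2, 1.0)
    n_individuals: int = 20  # for the variant-count table
    driver_prefix: str = "DRV"
    null_prefix: str = "GEN"

    def __post_init__(self) -> None:
        if self.effect < 1.0:
            raise InputError("enrichment effect must be >= 1")
        if self.n_drivers > self.n_genes:
            raise InputError("more drivers than genes")
        if self.count_mode not in ("fixed", "background"):
            raise InputError(f"unknown count_mode {self.count_mode!r}")
        if self.background not in ("codon", "uniform"):
            raise InputError(f"unknown background {self.background!r}")


@dataclass
class SyntheticCohort:
    """Generated tracks, mutations, coding sequences and truth labels."""

    config: SyntheticConfig
    tracks: List[FunctionalTrack]
    mutations: List[MutationRecord]
    truth: Dict[str, bool]  # gene -> is enriched ("driver")
    cds: Dict[str, str]  # isoform -> coding sequence
    variant_counts: pd.DataFrame
    lambdas: Dict[str, np.ndarray]

    def write(self, out_dir: str) -> Dict[str, str]:
        """Write all inputs in the package's file dialects."""
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "tracks": os.path.join(out_dir, "tracks.tsv"),
            "mutations": os.path.join(out_dir, "mutations.tsv"),
            "truth": os.path.join(out_dir, "truth.tsv"),
            "cds": os.path.join(out_dir, "cds.fasta"),
            "variant_counts": os.path.join(out_dir, "variant_counts.tsv"),
            "config": os.path.join(out_dir, "config.tsv"),
        }
        ptio.write_tracks(self.tracks, paths["tracks"])
        ptio.write_mutations(self.mutations, paths["mutations"])
        with open(paths["truth"], "w") as fh:
            fh.write("gene\tis_driver\n")
            for gene in sorted(self.truth):
                fh.write(f"{gene}\t{int(self.truth[gene])}\n")
        with open(paths["cds"], "w") as fh:
            for iso in sorted(self.cds):
                fh.write(f">{iso}\n{self.cds[iso]}\n")
        self.variant_counts.to_csv(paths["variant_counts"], sep="\t")
        with open(paths["config"], "w") as fh:
            for key, value in asdict(self.config).items():
                fh.write(f"{key}\t{value}\n")
        return paths

    def to_model(self, **kwargs) -> PerturbationModel:
        """Build a scoring model over the generated annotation inputs."""
        kwargs.setdefault("lambdas", self.lambdas)
        kwargs.setdefault(
            "natural_variation", build_natural_variation(self.variant_counts)
        )
        return PerturbationModel(self.tracks, **kwargs)

    @property
    def driver_genes(self) -> List[str]:
        return sorted(g for g, d in self.truth.items() if d)


def _weights(rng: np.random.Generator, dist: str, size: int) -> np.ndarray:
    if dist == "beta-bimodal":
        return rng.beta(0.5, 0.5, size=size)
    if dist == "beta-mid":
        return rng.beta(2.0, 2.0, size=size)
    if dist == "uniform":
        return rng.uniform(0.0, 1.0, size=size)
    if dist == "zero-one":
        return rng.integers(0, 2, size=size).astype(float)
    raise InputError(f"unknown weight distribution {dist!r}")


def _gene_annotation(
    rng: np.random.Generator,
    gene: str,
    iso: str,
    cfg: SyntheticConfig,
) -> Tuple[List[FunctionalTrack], str, np.ndarray, np.ndarray]:
    """Tracks, CDS, per-position lambda and interaction-weight maximum."""
    length = int(rng.integers(cfg.protein_length[0], cfg.protein_length[1] + 1))
    codons = rng.choice(_sense_codons(), size=length)
    cds = "".join(codons)
    lam = cds_lambdas(cds, cfg.b) if cfg.background == "codon" else None
    tracks: List[FunctionalTrack] = []
    inter_max = np.zeros(length)
    span = max(int(round(cfg.domain_fraction * length)), 5)
    for fam_idx in range(cfg.n_domain_families):
        family = f"FAM{fam_idx}"
        start = int(rng.integers(1, max(length - span, 2)))
        pos = np.arange(start, min(start + span, length + 1), dtype=np.int64)
        ligand = _LIGANDS[int(rng.integers(len(_LIGANDS)))]
        wts = _weights(rng, cfg.interaction_weight_dist, pos.size)
        tracks.append(
            FunctionalTrack(
                track_id=f"{family}:{ligand}", isoform_id=iso,
                group="interaction", positions=pos, weights=wts,
                protein_length=length, ligand=ligand, family_id=family,
            )
        )
        inter_max[pos - 1] = np.maximum(inter_max[pos - 1], wts)
        dom = np.zeros(length)
        dom[pos - 1] = 1.0
        tracks.append(
            FunctionalTrack(
                track_id=f"{family}:domain", isoform_id=iso, group="domain",
                positions=np.arange(1, length + 1, dtype=np.int64),
                weights=dom, protein_length=length, family_id=family,
            )
        )
    rho = cfg.conservation_coupling
    cons = (1.0 - rho) * _weights(rng, cfg.conservation_weight_dist, length)
    cons = cons + rho * inter_max
    tracks.append(
        FunctionalTrack(
            track_id="conservation", isoform_id=iso, group="conservation",
            positions=np.arange(1, length + 1, dtype=np.int64),
            weights=np.clip(cons, 0.0, 1.0),
            protein_length=length,
        )
    )
    return tracks, cds, lam, inter_max


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; identical seeds give identical output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = []
    for i in range(n):
        prefix = config.driver_prefix if i < config.n_drivers else config.null_prefix
        genes.append(f"{prefix}{i:05d}")
    truth = {g: i < config.n_drivers for i, g in enumerate(genes)}

    tracks: List[FunctionalTrack] = []
    cds: Dict[str, str] = {}
    lambdas: Dict[str, np.ndarray] = {}
    gene_lam: Dict[str, np.ndarray] = {}
    gene_iso: Dict[str, str] = {}
    for gene in genes:
        iso = f"{gene}-1"
        gene_iso[gene] = iso
        g_tracks, g_cds, g_lam, inter_max = _gene_annotation(rng, gene, iso, config)
        tracks.extend(g_tracks)
        cds[iso] = g_cds
        length = len(g_cds) // 3
        if g_lam is None:
            lambdas[iso] = None
            lam = np.full(length, 1.0 / length)
        else:
            lambdas[iso] = g_lam
            lam = g_lam / g_lam.sum()
        if truth[gene] and config.effect > 1.0:
            high = inter_max >= config.weight_cutoff
            if not high.any():
                raise InputError(
                    f"{gene}: enrichment effect requested but no position has "
                    f"interaction weight >= {config.weight_cutoff}"
                )
            lam[high] *= config.effect
            lam /= lam.sum()
        gene_lam[gene] = lam

    # mutation counts per gene
    if config.count_mode == "fixed":
        counts = {g: config.mutations_per_gene for g in genes}
    else:
        # cohort-level multinomial over genes, in proportion to natural
        # gene-level variability (drawn below), expected count preserved
        rates = rng.lognormal(mean=0.0, sigma=0.5, size=n)
        probs = rates / rates.sum()
        total = config.mutations_per_gene * n
        draw = rng.multinomial(total, probs)
        counts = {g: int(c) for g, c in zip(genes, draw)}
        gene_rates = dict(zip(genes, rates))

    mutations: List[MutationRecord] = []
    f_lo, f_hi = config.f_range
    for gene in genes:
        c = counts[gene]
        if c == 0:
            continue
        lam = gene_lam[gene]
        positions = rng.choice(lam.size, size=c, p=lam) + 1
        fs = rng.uniform(f_lo, f_hi, size=c)
        for pos, f in zip(positions.tolist(), fs.tolist()):
            mutations.append(
                MutationRecord(
                    gene=gene, isoform=gene_iso[gene],
                    protein_position=int(pos), mutation_class="missense",
                    f=float(max(f, 1e-9)),
                    sample_id=f"S{rng.integers(10000):05d}",
                    cancer_type="SYNTH",
                )
            )

    # variant-count table for the whole-gene background: per-gene natural
    # variability rates, Poisson counts per individual
    if config.count_mode == "background":
        nat_rates = np.array([gene_rates[g] for g in genes]) * 20.0
    else:
        nat_rates = rng.lognormal(mean=3.0, sigma=0.5, size=n)
    variant_counts = pd.DataFrame(
        rng.poisson(nat_rates, size=(config.n_individuals, n)),
        index=[f"IND{i:04d}" for i in range(config.n_individuals)],
        columns=genes,
    )

    return SyntheticCohort(
        config=config, tracks=tracks, mutations=mutations, truth=truth,
        cds=cds, variant_counts=variant_counts, lambdas=lambdas,
    )


# ---------------------------------------------------------------------------
# permutation oracle


@dataclass
class OracleMoments:
    """Monte-Carlo estimates of E[S_W] and sd[S_W] with standard errors."""

    reps: int
    mean: float
    mean_se: float
    var: float
    var_se: float

    @property
    def sd(self) -> float:
        return float(np.sqrt(max(self.var, 0.0)))


@dataclass
class OracleCovariance:
    """Monte-Carlo estimate of cov[S_V, S_W] with its standard error."""

    reps: int
    cov: float
    cov_se: float
    corr: float


def _draw_positions(
    rng: np.random.Generator,
    lam: np.ndarray,
    shape: Tuple[int, ...],
) -> np.ndarray:
    cdf = np.cumsum(lam)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(shape), side="right")


def oracle_track_moments(
    weights: np.ndarray,
    lam_w: np.ndarray,
    f: np.ndarray,
    reps: int = 20000,
    seed: int = 0,
) -> OracleMoments:
    """Shuffle n mutations within a track's positions and measure (E, sd).

    Each replicate assigns every mutation a position drawn from lambda^W and
    scores S = sum f_i w(pos_i); the estimates come with standard errors
    (for the variance, via the empirical fourth moment) so analytic values
    can be checked within Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    weights = np.asarray(weights, dtype=float)
    f = np.asarray(f, dtype=float)
    idx = _draw_positions(rng, np.asarray(lam_w, dtype=float), (reps, f.size))
    scores = weights[idx] @ f
    mean = float(scores.mean())
    var = float(scores.var(ddof=1))
    centered = scores - mean
    m4 = float(np.mean(centered**4))
    var_se = float(np.sqrt(max(m4 - var**2, 0.0) / reps))
    return OracleMoments(
        reps=reps, mean=mean, mean_se=float(scores.std(ddof=1) / np.sqrt(reps)),
        var=var, var_se=var_se,
    )


def oracle_covariance(
    v_weights: np.ndarray,
    w_weights: np.ndarray,
    lam_x: np.ndarray,
    f_shared: np.ndarray,
    reps: int = 20000,
    seed: int = 0,
) -> OracleCovariance:
    """Empirical covariance of two track scores over their shared mutations.

    The q shared mutations are drawn once per replicate from lambda^X — the
    same mutation lands on one position and scores simultaneously in both
    tracks, which is what makes the covariance estimate valid. Mutations
    outside the overlap are independent across tracks and contribute zero
    covariance, so they are not simulated.
    """
    rng = np.random.default_rng(seed)
    v_weights = np.asarray(v_weights, dtype=float)
    w_weights = np.asarray(w_weights, dtype=float)
    f_shared = np.asarray(f_shared, dtype=float)
    if v_weights.shape != w_weights.shape or v_weights.shape[0] != np.asarray(lam_x).shape[0]:
        raise InputError("overlap weight vectors and lambda^X must align")
    idx = _draw_positions(rng, np.asarray(lam_x, dtype=float), (reps, f_shared.size))
    s_v = v_weights[idx] @ f_shared
    s_w = w_weights[idx] @ f_shared
    dv = s_v - s_v.mean()
    dw = s_w - s_w.mean()
    cov = float(np.dot(dv, dw) / (reps - 1))
    m22 = float(np.mean(dv**2 * dw**2))
    cov_se = float(np.sqrt(max(m22 - cov**2, 0.0) / reps))
    sd_v = float(s_v.std(ddof=1))
    sd_w = float(s_w.std(ddof=1))
    corr = cov / (sd_v * sd_w) if sd_v > 0 and sd_w > 0 else 0.0
    return OracleCovariance(reps=reps, cov=cov, cov_se=cov_se, corr=corr)


def permutation_oracle(
    tracks: Sequence[FunctionalTrack],
    lambdas: Optional[np.ndarray],
    mutations: Sequence[MutationRecord],
    reps: int = 20000,
    seed: int = 0,
):
    """Convenience oracle over observed mutations.

    For a single track, returns :class:`OracleMoments` for the mutations
    falling in it (positions re-drawn from lambda^W). For a pair of tracks,
    returns the :class:`OracleCovariance` conditional on the mutations
    observed in the overlap. More tracks are not supported; validate pairs.
    """
    if reps < 1000:
        raise InputError("oracle needs at least 1000 replicates")
    from .background import rescale_for_track
    from .engine import restrict_mutations

    if len(tracks) == 1:
        t = tracks[0]
        ms = restrict_mutations(t, mutations)
        lam_w = rescale_for_track(lambdas, t)
        return oracle_track_moments(t.weights, lam_w, ms.f, reps=reps, seed=seed)
    if len(tracks) == 2:
        v, w = tracks
        x = np.intersect1d(v.positions, w.positions, assume_unique=True)
        if x.size == 0:
            return OracleCovariance(reps=reps, cov=0.0, cov_se=0.0, corr=0.0)
        if lambdas is None:
            lam_x = np.full(x.size, 1.0 / x.size)
        else:
            lam_x = np.asarray(lambdas, dtype=float)[x - 1]
            lam_x = lam_x / lam_x.sum()
        pos = np.array(
            [m.protein_position for m in mutations if m.mutation_class == "missense"],
            dtype=np.int64,
        )
        f = np.array(
            [m.f for m in mutations if m.mutation_class == "missense"], dtype=float
        )
        mask = np.isin(pos, x)
        f_shared = f[mask]
        if f_shared.size == 0:
            return OracleCovariance(reps=reps, cov=0.0, cov_se=0.0, corr=0.0)
        vx = v.weights_at(x)
        wx = w.weights_at(x)
        return oracle_covariance(vx, wx, lam_x, f_shared, reps=reps, seed=seed)
    raise InputError("permutation_oracle supports one track or a pair")
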