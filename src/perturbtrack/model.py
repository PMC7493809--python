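"""Model/Results interface tying the pipeline together.

:class:`PerturbationModel` holds the fixed annotation side — functional
tracks, per-position backgrounds, the whole-gene natural-variation model and
the combination options. Everything that can be precomputed before any
mutation data arrives (normalized per-track backgrounds, unit moment
constants, minimum-mutation calibrations) lives here. :meth:`fit` scores a
cohort of somatic mutations and returns a :class:`PerturbationResults`
carrying per-gene combined Z scores, the per-track breakdown and summary
tables.

Typical use::

    model = PerturbationModel.from_files("tracks.tsv", cds_path="cds.fasta",
                                         variant_counts_path="counts.tsv")
    results = model.fit(mutations, seed=7)
    print(results.summary())
    ranking = results.ranking()
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import io as ptio
from .background import (
    DEFAULT_CG_BIAS,
    NaturalVariationModel,
    build_natural_variation,
)
from .calibration import (
    DEFAULT_ALPHA,
    DEFAULT_CONSECUTIVE,
    DEFAULT_MAX_N,
    DEFAULT_REPS,
    CalibrationCache,
    CalibrationResult,
    calibrate_min_mutations,
    content_key,
)
from .combine import (
    GeneResult,
    IsoformResult,
    TrackBreakdown,
    WholeGeneStatistics,
    combine_z,
    condition_correlation,
    confidence_weights,
    score_gene,
    subsample_factor,
    whole_gene_statistics,
)
from .engine import (
    MutationRecord,
    TrackProfile,
    TrackStatistics,
    track_covariance,
)
from .exceptions import InputError
from .tracks import FunctionalTrack

logger = logging.getLogger(__name__)

MutationsLike = Union[Sequence[MutationRecord], pd.DataFrame]


@dataclass
class _WholeGeneRef:
    """Duck-typed stand-in so the whole-gene statistic weights like a track."""

    track_id: str
    group: str = "natural_variation"
    ligand: Optional[str] = None
    family_id: Optional[str] = None


def _records_from_frame(df: pd.DataFrame) -> List[MutationRecord]:
    required = {"gene", "isoform", "protein_position", "class"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"mutation frame missing columns {sorted(missing)}")
    records = []
    for row in df.to_dict("records"):
        records.append(
            MutationRecord(
                gene=str(row["gene"]),
                isoform=str(row["isoform"]),
                protein_position=int(row["protein_position"]),
                mutation_class=str(row["class"]),
                f=float(row.get("f", 1.0)),
                sample_id=str(row.get("sample", "")),
                cancer_type=str(row.get("cancer_type", "")),
            )
        )
    return records


class PerturbationModel:
    """Scoring model built from functional tracks and background data.

    Parameters
    ----------
    tracks : sequence of FunctionalTrack
        All subgene tracks, any number of isoforms/genes.
    lambdas : mapping isoform -> ndarray, optional
        Full-length per-position missense rates (e.g. from
        :func:`perturbtrack.background.cds_lambdas`). Isoforms without an
        entry fall back to the uniform background over each track (logged).
    natural_variation : NaturalVariationModel, optional
        Whole-gene background; enables the whole-gene track.
    b : float
        C/G-vs-A/T mutation bias used when backgrounds are built from CDS.
    positive_only : bool
        Restrict the combination to tracks with Z > 0 (the ranking rule).
        Disable to study the null distribution of the combined statistic.
    within_group : {"sqrt", "linear"}
        Within-group confidence proportionality in m.
    subsample_mode : {"inv_sqrt_n", "none"}
        Whole-gene subsample factor rule.
    min_expected_gene_count : float
        Whole-gene track admission rule: require n_total * lambda_gene at
        least this large for the one-hot Bernoulli sum to be treated as
        normal.
    calibrate_tracks : bool
        When True (default), tracks must pass their Shapiro-Wilk
        minimum-mutation calibration to enter the combination; calibration is
        run lazily at fit time (capped at the observed mutation count) unless
        :meth:`calibrate` precomputed it.
    """

    def __init__(
        self,
        tracks: Sequence[FunctionalTrack],
        *,
        lambdas: Optional[Mapping[str, np.ndarray]] = None,
        natural_variation: Optional[NaturalVariationModel] = None,
        b: float = DEFAULT_CG_BIAS,
        positive_only: bool = True,
        within_group: str = "sqrt",
        subsample_mode: str = "inv_sqrt_n",
        min_expected_gene_count: float = 10.0,
        calibrate_tracks: bool = True,
        calibration_reps: int = DEFAULT_REPS,
        calibration_max_n: int = DEFAULT_MAX_N,
        calibration_alpha: float = DEFAULT_ALPHA,
        calibration_cache: Optional[CalibrationCache] = None,
    ):
        self.tracks = list(tracks)
        self.lambdas = dict(lambdas) if lambdas else {}
        self.natural_variation = natural_variation
        self.b = b
        self.positive_only = positive_only
        self.within_group = within_group
        self.subsample_mode = subsample_mode
        self.min_expected_gene_count = min_expected_gene_count
        self.calibrate_tracks = calibrate_tracks
        self.calibration_reps = calibration_reps
        self.calibration_max_n = calibration_max_n
        self.calibration_alpha = calibration_alpha
        self.calibration_cache = calibration_cache or CalibrationCache()

        self._by_isoform: Dict[str, List[FunctionalTrack]] = {}
        for t in self.tracks:
            self._by_isoform.setdefault(t.isoform_id, []).append(t)
        self._profiles: Dict[Tuple[str, str], TrackProfile] = {}
        self._uniform_logged: set = set()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_files(
        cls,
        tracks_path: str,
        *,
        cds_path: Optional[str] = None,
        variant_counts_path: Optional[str] = None,
        b: float = DEFAULT_CG_BIAS,
        **kwargs,
    ) -> "PerturbationModel":
        tracks = ptio.read_tracks(tracks_path)
        lambdas = ptio.read_cds_lambdas(cds_path, b) if cds_path else None
        natvar = None
        if variant_counts_path:
            natvar = build_natural_variation(
                ptio.read_variant_counts(variant_counts_path)
            )
        return cls(tracks, lambdas=lambdas, natural_variation=natvar, b=b, **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        track_frame: pd.DataFrame,
        **kwargs,
    ) -> "PerturbationModel":
        """Build from a frame with the track-file columns (see io.read_tracks)."""
        tracks = []
        for row in track_frame.itertuples(index=False):
            positions, weights = [], []
            for pair in str(row.position_weights).split(";"):
                if pair:
                    p, w = pair.split(":")
                    positions.append(int(p))
                    weights.append(float(w))
            tracks.append(
                FunctionalTrack(
                    track_id=str(row.track_id),
                    isoform_id=str(row.isoform_id),
                    group=str(row.group),
                    positions=np.asarray(positions, dtype=np.int64),
                    weights=np.asarray(weights, dtype=float),
                    protein_length=int(row.protein_length),
                    ligand=None if str(row.ligand) == "." else str(row.ligand),
                    family_id=None if str(row.family_id) == "." else str(row.family_id),
                )
            )
        return cls(tracks, **kwargs)

    # -- precomputation ---------------------------------------------------

    def profile(self, track: FunctionalTrack) -> TrackProfile:
        key = (track.isoform_id, track.track_id)
        prof = self._profiles.get(key)
        if prof is None:
            lam = self.lambdas.get(track.isoform_id)
            if lam is None and self.lambdas and track.isoform_id not in self._uniform_logged:
                logger.info(
                    "isoform %s has no coding sequence; uniform background used",
                    track.isoform_id,
                )
                self._uniform_logged.add(track.isoform_id)
            prof = TrackProfile.build(track, lam)
            self._profiles[key] = prof
        return prof

    def calibrate(self, seed: int = 0, max_n: Optional[int] = None) -> Dict[str, CalibrationResult]:
        """Precompute minimum-mutation calibrations for every track."""
        max_n = max_n or self.calibration_max_n
        out = {}
        for t in self.tracks:
            if t.is_degenerate:
                continue
            out[t.track_id] = self._calibration(self.profile(t), max_n, seed)
        return out

    def _calibration(
        self, prof: TrackProfile, cap: int, seed: int
    ) -> CalibrationResult:
        key = content_key(
            prof.track.weights, prof.lam_w,
            self.calibration_reps, self.calibration_max_n, self.calibration_alpha,
        )
        cached = self.calibration_cache.get(key, cap)
        if cached is not None:
            return cached
        result = calibrate_min_mutations(
            prof.track,
            prof.lam_w,
            reps=self.calibration_reps,
            max_n=min(cap, self.calibration_max_n),
            alpha=self.calibration_alpha,
            seed=seed,
        )
        self.calibration_cache.put(key, result)
        return result

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        mutations: MutationsLike,
        *,
        expression: Optional[ptio.ExpressionTable] = None,
        expression_threshold: float = 0.1,
        seed: int = 0,
    ) -> "PerturbationResults":
        """Score a cohort of somatic mutations.

        Missense mutations drive all statistics; silent/nonsense records are
        retained for reporting only. With ``expression`` given, mutations in
        genes below the TPM threshold in their sample are excluded first.
        """
        if isinstance(mutations, pd.DataFrame):
            records = _records_from_frame(mutations)
        else:
            records = list(mutations)

        expression_report = None
        if expression is not None:
            expression_report = ptio.expression_filter(
                records, expression, expression_threshold
            )
            records = expression_report.kept

        missense = [m for m in records if m.mutation_class == "missense"]
        by_iso: Dict[str, List[MutationRecord]] = {}
        iso_gene: Dict[str, str] = {}
        for m in missense:
            by_iso.setdefault(m.isoform, []).append(m)
            iso_gene.setdefault(m.isoform, m.gene)

        whole_gene = self._whole_gene_statistics(missense)

        iso_results: Dict[str, IsoformResult] = {}
        for iso, muts in by_iso.items():
            iso_results[iso] = self._score_isoform(
                iso, muts, whole_gene.get(iso_gene[iso]), seed
            )

        by_gene: Dict[str, Dict[str, IsoformResult]] = {}
        for iso, res in iso_results.items():
            by_gene.setdefault(iso_gene[iso], {})[iso] = res
        gene_results = {
            gene: score_gene(gene, isoforms) for gene, isoforms in by_gene.items()
        }
        return PerturbationResults(
            model=self,
            gene_results=gene_results,
            mutations=records,
            n_missense=len(missense),
            expression_report=expression_report,
        )

    def _whole_gene_statistics(
        self, missense: Sequence[MutationRecord]
    ) -> Dict[str, WholeGeneStatistics]:
        natvar = self.natural_variation
        if natvar is None or not missense:
            return {}
        in_universe = [m for m in missense if m.gene in natvar]
        if not in_universe:
            return {}
        total_n = len(in_universe)
        f = np.array([m.f for m in in_universe])
        total_sum_f = float(f.sum())
        total_sum_f2 = float(np.square(f).sum())
        s = subsample_factor(total_n, self.subsample_mode)
        per_gene: Dict[str, List[float]] = {}
        for m in in_universe:
            per_gene.setdefault(m.gene, []).append(m.f)
        out = {}
        for gene, fs in per_gene.items():
            stats = whole_gene_statistics(
                gene, natvar, sum_f_gene=float(sum(fs)), n_gene=len(fs),
                total_n=total_n, total_sum_f=total_sum_f,
                total_sum_f2=total_sum_f2, s=s,
            )
            if stats is not None:
                out[gene] = stats
        return out

    def _score_isoform(
        self,
        isoform: str,
        mutations: Sequence[MutationRecord],
        whole_gene: Optional[WholeGeneStatistics],
        seed: int,
    ) -> IsoformResult:
        breakdown: List[TrackBreakdown] = []
        included: List[Tuple[FunctionalTrack, TrackStatistics]] = []
        included_stats: List[TrackStatistics] = []

        for track in self._by_isoform.get(isoform, []):
            if track.is_degenerate:
                continue
            prof = self.profile(track)
            stats = prof.score_batch(mutations)
            if stats.n == 0:
                continue  # breakdown lists mutated tracks only
            z = stats.zscore
            reason = None
            if z is None:
                reason = "degenerate"
            elif self.calibrate_tracks:
                calib = self._calibration(prof, cap=stats.n, seed=seed)
                if calib.never_normal and calib.n_scanned >= self.calibration_max_n:
                    reason = "never_normal"
                elif stats.n < calib.effective_min:
                    reason = "below_min_mutations"
            if reason is None and self.positive_only and z is not None and z <= 0:
                reason = "non_positive_z"
            ok = reason is None
            breakdown.append(
                TrackBreakdown(
                    track_id=track.track_id, group=track.group,
                    ligand=track.ligand, family_id=track.family_id,
                    zscore=z, n=stats.n, m_positive=stats.m_positive,
                    included=ok, exclusion_reason=reason,
                )
            )
            if ok:
                included.append((track, stats))
                included_stats.append(stats)

        wg_entry: Optional[Tuple[_WholeGeneRef, WholeGeneStatistics]] = None
        if whole_gene is not None:
            z = whole_gene.zscore
            reason = None
            expected_count = whole_gene.total_n * whole_gene.lam_gene
            if z is None:
                reason = "degenerate"
            elif expected_count < self.min_expected_gene_count:
                reason = "below_min_mutations"
            elif self.positive_only and z <= 0:
                reason = "non_positive_z"
            ok = reason is None
            breakdown.append(
                TrackBreakdown(
                    track_id=f"whole_gene:{whole_gene.gene}",
                    group="natural_variation", ligand=None, family_id=None,
                    zscore=z, n=whole_gene.n_gene,
                    m_positive=whole_gene.n_gene, included=ok,
                    exclusion_reason=reason,
                )
            )
            if ok:
                wg_entry = (
                    _WholeGeneRef(track_id=f"whole_gene:{whole_gene.gene}"),
                    whole_gene,
                )

        k = len(included) + (1 if wg_entry is not None else 0)
        if k == 0:
            return IsoformResult(isoform=isoform, combined_z=None,
                                 breakdown=breakdown, k=0)

        # correlation matrix: analytic pairwise for subgene tracks, zero rows
        # for the whole-gene statistic
        r = np.eye(k)
        lam = self.lambdas.get(isoform)
        for i in range(len(included)):
            for j in range(i + 1, len(included)):
                ov = track_covariance(
                    included[i][0], included[j][0], lam, mutations,
                    v_stats=included_stats[i], w_stats=included_stats[j],
                )
                r[i, j] = r[j, i] = ov.correlation or 0.0
        r = condition_correlation(r)

        entries: List[Tuple] = list(included)
        if wg_entry is not None:
            entries.append(wg_entry)
        weights = confidence_weights(entries, within_group=self.within_group)
        z_vec = np.array([st.zscore for _, st in entries], dtype=float)
        combined = combine_z(z_vec, weights.values, r)
        return IsoformResult(
            isoform=isoform, combined_z=combined, breakdown=breakdown, k=k
        )


class PerturbationResults:
    """Per-gene combined Z scores with the per-track breakdown.

    Attributes
    ----------
    gene_results : dict gene -> GeneResult
        Best-isoform combined Z and per-track breakdown per gene.
    """

    def __init__(
        self,
        model: PerturbationModel,
        gene_results: Dict[str, GeneResult],
        mutations: Sequence[MutationRecord],
        n_missense: int,
        expression_report=None,
    ):
        self.model = model
        self.gene_results = gene_results
        self.mutations = list(mutations)
        self.n_missense = n_missense
        self.expression_report = expression_report

    # -- access -----------------------------------------------------------

    def __getitem__(self, gene: str) -> GeneResult:
        return self.gene_results[gene]

    def ranking(self, include_unscored: bool = True) -> List[Tuple[str, Optional[float]]]:
        """Genes ordered by combined Z, descending; unscored genes last.

        Ties break lexicographically by gene so the ordering is
        deterministic.
        """
        scored = sorted(
            ((g, r.combined_z) for g, r in self.gene_results.items()
             if r.combined_z is not None),
            key=lambda item: (-item[1], item[0]),
        )
        if not include_unscored:
            return scored
        unscored = sorted(
            (g, None) for g, r in self.gene_results.items() if r.combined_z is None
        )
        return scored + unscored

    def scores(self) -> Dict[str, Optional[float]]:
        return {g: r.combined_z for g, r in self.gene_results.items()}

    def to_frame(self) -> pd.DataFrame:
        """One row per gene: combined Z, best isoform, track counts."""
        rows = []
        for gene, r in sorted(self.gene_results.items()):
            bd = r.breakdown
            rows.append(
                {
                    "gene": gene,
                    "best_isoform": r.best_isoform,
                    "combined_z": r.combined_z,
                    "n_tracks_mutated": len(bd),
                    "n_tracks_included": sum(b.included for b in bd),
                    "top_track": max(
                        (b for b in bd if b.zscore is not None),
                        key=lambda b: b.zscore, default=None,
                    ).track_id if any(b.zscore is not None for b in bd) else None,
                }
            )
        return pd.DataFrame(rows)

    def track_frame(self) -> pd.DataFrame:
        """One row per (gene, track) from each gene's best isoform."""
        rows = []
        for gene, r in sorted(self.gene_results.items()):
            for b in r.breakdown:
                rows.append(
                    {
                        "gene": gene, "track_id": b.track_id, "group": b.group,
                        "ligand": b.ligand, "family_id": b.family_id,
                        "zscore": b.zscore, "n": b.n, "m_positive": b.m_positive,
                        "included": b.included, "reason": b.exclusion_reason,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self, top: int = 15) -> str:
        """Human-readable summary, statsmodels-style."""
        n_genes = len(self.gene_results)
        n_scored = sum(
            1 for r in self.gene_results.values() if r.combined_z is not None
        )
        lines = [
            "Mutational enrichment in weighted functional sites",
            "=" * 58,
            f"Mutations (all classes): {len(self.mutations):>8d}",
            f"Missense scored:         {self.n_missense:>8d}",
            f"Mutated genes:           {n_genes:>8d}",
            f"Genes with combined Z:   {n_scored:>8d}",
            f"Positive-only screen:    {str(self.model.positive_only):>8s}",
            "-" * 58,
            f"{'rank':>4s}  {'gene':<12s} {'combined Z':>10s}  {'best isoform':<14s} {'k':>3s}",
        ]
        for rank, (gene, z) in enumerate(self.ranking(include_unscored=False)[:top], 1):
            r = self.gene_results[gene]
            k = r.isoforms[r.best_isoform].k if r.best_isoform else 0
            lines.append(
                f"{rank:>4d}  {gene:<12s} {z:>10.3f}  {r.best_isoform or '.':<14s} {k:>3d}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def save(self, path: str) -> None:
        ptio.write_results(self, path)
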