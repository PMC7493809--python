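"""Analytic per-track scores, moments, Z scores and between-track covariance.

The score of a track W for n missense mutations with subclonal fractions f_i
landing at positions with track weights z_i is S_W = sum_i f_i z_i. Under the
null that each mutation's position is drawn from the track-normalized
background lambda^W, the per-mutation weight has mean C_E = sum_j lambda_j w_j
and variance C_V = sum_j lambda_j w_j^2 - C_E^2, so

    E[S_W] = C_E * sum_i f_i        var[S_W] = C_V * sum_i f_i^2

and Z_W = (S_W - E[S_W]) / sd[S_W]. C_E and C_V depend only on the track and
its background, so they are precomputed once and scaled by the observed
sum(f) and sum(f^2) at scoring time; the same precompute-and-scale rewrite
applies to the between-track covariance, which conditional on the q mutations
observed in the overlap X = V n W is

    cov[S_V, S_W] = F * (sum_X lam^X v w - (sum_X lam^X v)(sum_X lam^X w))

with F the sum of f^2 over those q mutations and lam^X the background
renormalized over X.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .background import rescale_for_track
from .exceptions import DegenerateTrackError, InputError, UndefinedZError
from .tracks import FunctionalTrack

MUTATION_CLASSES = ("missense", "silent", "nonsense")


@dataclass
class MutationRecord:
    """One somatic mutation at protein resolution."""

    gene: str
    isoform: str
    protein_position: int
    mutation_class: str = "missense"
    f: float = 1.0
    sample_id: str = ""
    cancer_type: str = ""
    codon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.protein_position < 1:
            raise InputError("protein positions are 1-based")
        if not (0.0 < self.f <= 1.0):
            raise InputError(f"subclonal fraction {self.f} outside (0, 1]")
        if self.mutation_class not in MUTATION_CLASSES:
            raise InputError(f"unknown mutation class {self.mutation_class!r}")


@dataclass
class TrackMutationSet:
    """Missense mutations restricted to a track's positions."""

    track: FunctionalTrack
    positions: np.ndarray
    f: np.ndarray

    @property
    def n(self) -> int:
        return int(self.f.size)

    @property
    def sum_f(self) -> float:
        return float(self.f.sum())

    @property
    def sum_f2(self) -> float:
        return float(np.square(self.f).sum())

    @property
    def z(self) -> np.ndarray:
        """Track weight at each mutation's position."""
        return self.track.weights_at(self.positions)

    @property
    def m_positive(self) -> int:
        """Mutations in positively weighted positions (confidence count m)."""
        return int(np.count_nonzero(self.z > 0.0))


@dataclass
class TrackStatistics:
    """Score, analytic moments and Z for one track on one mutation set."""

    track: FunctionalTrack
    c_e: float
    c_v: float
    n: int
    sum_f: float
    sum_f2: float
    m_positive: int
    score: float
    expected: float
    variance: float

    @property
    def sd(self) -> float:
        return math.sqrt(max(self.variance, 0.0))

    @property
    def zscore(self) -> Optional[float]:
        if self.variance <= 0.0:
            return None
        return (self.score - self.expected) / self.sd


@dataclass
class OverlapStatistics:
    """Conditional covariance of two track scores over their overlap X."""

    overlap: np.ndarray
    q: int
    big_f: float
    unit_covariance: float
    covariance: float
    correlation: Optional[float] = None


def restrict_mutations(
    track: FunctionalTrack,
    mutations: Sequence[MutationRecord],
) -> TrackMutationSet:
    """Keep the missense mutations whose positions fall inside the track."""
    pos = np.array(
        [m.protein_position for m in mutations if m.mutation_class == "missense"],
        dtype=np.int64,
    )
    f = np.array(
        [m.f for m in mutations if m.mutation_class == "missense"], dtype=float
    )
    if pos.size:
        mask = track.contains(pos)
        pos, f = pos[mask], f[mask]
    return TrackMutationSet(track=track, positions=pos, f=f)


def track_score(track: FunctionalTrack, mutations: Sequence[MutationRecord]) -> float:
    """S_W = sum_i f_i z_i over missense mutations inside the track."""
    ms = restrict_mutations(track, mutations)
    if ms.n == 0:
        return 0.0
    return float(np.dot(ms.f, ms.z))


def track_moments(track: FunctionalTrack, lam_w: np.ndarray) -> Tuple[float, float]:
    """Unit-mutation constants (C_E, C_V) of a track under lambda^W."""
    lam_w = np.asarray(lam_w, dtype=float)
    if lam_w.shape != track.weights.shape:
        raise InputError("lambda^W does not align with track positions")
    if not np.isclose(lam_w.sum(), 1.0, atol=1e-9):
        raise InputError("lambda^W must be normalized")
    c_e = float(np.dot(lam_w, track.weights))
    c_v = float(np.dot(lam_w, np.square(track.weights)) - c_e**2)
    return c_e, max(c_v, 0.0)


def track_statistics(
    track: FunctionalTrack,
    lam_w: np.ndarray,
    mutations: Sequence[MutationRecord],
) -> TrackStatistics:
    """Precompute-and-scale path: unit constants scaled by sum(f), sum(f^2)."""
    c_e, c_v = track_moments(track, lam_w)
    ms = restrict_mutations(track, mutations)
    score = float(np.dot(ms.f, ms.z)) if ms.n else 0.0
    return TrackStatistics(
        track=track,
        c_e=c_e,
        c_v=c_v,
        n=ms.n,
        sum_f=ms.sum_f,
        sum_f2=ms.sum_f2,
        m_positive=ms.m_positive,
        score=score,
        expected=c_e * ms.sum_f,
        variance=c_v * ms.sum_f2,
    )


def direct_statistics(
    track: FunctionalTrack,
    lam_w: np.ndarray,
    mutations: Sequence[MutationRecord],
) -> TrackStatistics:
    """Direct evaluation summing per-mutation moments (reference path).

    Algebraically identical to :func:`track_statistics`; kept as the slow,
    mutation-by-mutation evaluation the precomputed path must reproduce.
    """
    lam_w = np.asarray(lam_w, dtype=float)
    ms = restrict_mutations(track, mutations)
    e_z = float(np.dot(lam_w, track.weights))
    var_z = float(np.dot(lam_w, np.square(track.weights))) - e_z**2
    expected = 0.0
    variance = 0.0
    score = 0.0
    z = ms.z
    for i in range(ms.n):
        f_i = float(ms.f[i])
        score += f_i * float(z[i])
        expected += f_i * e_z
        variance += f_i**2 * var_z
    return TrackStatistics(
        track=track,
        c_e=e_z,
        c_v=max(var_z, 0.0),
        n=ms.n,
        sum_f=ms.sum_f,
        sum_f2=ms.sum_f2,
        m_positive=ms.m_positive,
        score=score,
        expected=expected,
        variance=max(variance, 0.0),
    )


def track_zscore(stats: TrackStatistics) -> float:
    """Z_W = (S_W - E[S_W]) / sd[S_W]; undefined for zero-variance tracks."""
    z = stats.zscore
    if z is None:
        raise UndefinedZError(
            f"track {stats.track.track_id!r}: zero score variance, Z undefined"
        )
    return z


def overlap_unit_constant(
    v: FunctionalTrack,
    w: FunctionalTrack,
    lambdas: Optional[np.ndarray],
) -> Tuple[np.ndarray, float]:
    """Overlap X = V n W and the unit covariance constant on X.

    The constant is cov of (v-weight, w-weight) for a single position drawn
    from the background renormalized over X; the runtime covariance is this
    constant times F = sum f^2 over the mutations observed in X.
    """
    x = np.intersect1d(v.positions, w.positions, assume_unique=True)
    if x.size == 0:
        return x, 0.0
    if lambdas is None:
        lam_x = np.full(x.size, 1.0 / x.size)
    else:
        lambdas = np.asarray(lambdas, dtype=float)
        lam_x = lambdas[x - 1]
        total = lam_x.sum()
        if total <= 0:
            return x, 0.0
        lam_x = lam_x / total
    vw = v.weights_at(x)
    ww = w.weights_at(x)
    unit = float(np.dot(lam_x, vw * ww) - np.dot(lam_x, vw) * np.dot(lam_x, ww))
    return x, unit


def track_covariance(
    v: FunctionalTrack,
    w: FunctionalTrack,
    lambdas: Optional[np.ndarray],
    mutations: Sequence[MutationRecord],
    v_stats: Optional[TrackStatistics] = None,
    w_stats: Optional[TrackStatistics] = None,
) -> OverlapStatistics:
    """Conditional covariance (and correlation) between two track scores.

    Conditions on the q missense mutations observed at shared positions,
    following the precompute-and-scale rewrite: cov = F * unit constant.
    Disjoint tracks have covariance 0 by construction.
    """
    x, unit = overlap_unit_constant(v, w, lambdas)
    pos = np.array(
        [m.protein_position for m in mutations if m.mutation_class == "missense"],
        dtype=np.int64,
    )
    f = np.array(
        [m.f for m in mutations if m.mutation_class == "missense"], dtype=float
    )
    if x.size and pos.size:
        mask = np.isin(pos, x)
        q = int(mask.sum())
        big_f = float(np.square(f[mask]).sum())
    else:
        q, big_f = 0, 0.0
    cov = big_f * unit
    corr: Optional[float] = None
    if v_stats is not None and w_stats is not None:
        denom = v_stats.sd * w_stats.sd
        if denom > 0:
            corr = float(np.clip(cov / denom, -1.0, 1.0))
    return OverlapStatistics(
        overlap=x, q=q, big_f=big_f, unit_covariance=unit,
        covariance=cov, correlation=corr,
    )


@dataclass
class TrackProfile:
    """A track with its normalized background and precomputed unit constants."""

    track: FunctionalTrack
    lam_w: np.ndarray
    c_e: float
    c_v: float

    @classmethod
    def build(
        cls,
        track: FunctionalTrack,
        lambdas: Optional[np.ndarray] = None,
    ) -> "TrackProfile":
        lam_w = rescale_for_track(lambdas, track)
        c_e, c_v = track_moments(track, lam_w)
        return cls(track=track, lam_w=lam_w, c_e=c_e, c_v=c_v)

    def score_batch(self, mutations: Sequence[MutationRecord]) -> TrackStatistics:
        """Score a mutation set using the precomputed constants."""
        ms = restrict_mutations(self.track, mutations)
        score = float(np.dot(ms.f, ms.z)) if ms.n else 0.0
        return TrackStatistics(
            track=self.track,
            c_e=self.c_e,
            c_v=self.c_v,
            n=ms.n,
            sum_f=ms.sum_f,
            sum_f2=ms.sum_f2,
            m_positive=ms.m_positive,
            score=score,
            expected=self.c_e * ms.sum_f,
            variance=self.c_v * ms.sum_f2,
        )
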