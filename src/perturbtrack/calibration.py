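"""Per-track minimum-mutation calibration.

A track's Z score is only meaningful once the null score distribution is
close enough to normal. For each track we repeatedly draw mutation positions
from the track background (f = 1), accumulate score sums for n = 1, 2, ...,
and Shapiro-Wilk-test the sums at each n. The calibrated minimum n* is the
smallest n at which normality is no longer rejected (p >= alpha, by default
5e-5, with 1000 replicates, probing up to 500 mutations); a run of
``consecutive`` non-rejections (default 3) is required to guard against
single-n noise. Tracks that never pass are flagged never-normal and excluded
from combination.

Results can be cached keyed by a content hash of (weights, lambda^W) so
calibration is done once per distinct track/background pair.
"""

from __future__ import annotations

import hashlib
import warnings
import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.stats import shapiro

from .tracks import FunctionalTrack

DEFAULT_REPS = 1000
DEFAULT_MAX_N = 500
DEFAULT_ALPHA = 5e-5
DEFAULT_CONSECUTIVE = 3


@dataclass
class CalibrationResult:
    """Outcome of the minimum-mutation scan for one track."""

    track_id: str
    min_mutations: Optional[int]
    never_normal: bool
    reps: int
    max_n: int
    alpha: float
    n_scanned: int

    @property
    def effective_min(self) -> int:
        """n* usable in comparisons; never-normal maps beyond the probed range."""
        return self.min_mutations if self.min_mutations is not None else self.max_n + 1


def content_key(
    weights: np.ndarray,
    lam_w: np.ndarray,
    reps: int,
    max_n: int,
    alpha: float,
) -> str:
    """Content hash of (weights, lambda^W, parameters) for caching/seeding."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(weights, dtype=float).tobytes())
    h.update(np.ascontiguousarray(lam_w, dtype=float).tobytes())
    h.update(f"{reps}:{max_n}:{alpha}".encode())
    return h.hexdigest()


def _seed_from_key(key: str, seed: int) -> int:
    h = hashlib.sha256(f"{key}:{seed}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def calibrate_min_mutations(
    track: FunctionalTrack,
    lam_w: np.ndarray,
    reps: int = DEFAULT_REPS,
    max_n: int = DEFAULT_MAX_N,
    alpha: float = DEFAULT_ALPHA,
    consecutive: int = DEFAULT_CONSECUTIVE,
    seed: int = 0,
) -> CalibrationResult:
    """Scan n = 1..max_n for the smallest n with normal-looking null scores.

    Deterministic given ``seed``: the random stream is derived from the seed
    and a content hash of (weights, lambda^W, parameters), so the result does
    not depend on the order tracks are calibrated in.
    """
    lam_w = np.asarray(lam_w, dtype=float)
    weights = track.weights
    result_args = dict(track_id=track.track_id, reps=reps, max_n=max_n, alpha=alpha)
    if track.is_degenerate or np.ptp(weights[lam_w > 0]) == 0.0:
        # constant score under the background: never normal
        return CalibrationResult(
            min_mutations=None, never_normal=True, n_scanned=0, **result_args
        )
    key = content_key(weights, lam_w, reps, max_n, alpha)
    rng = np.random.default_rng(_seed_from_key(key, seed))
    cdf = np.cumsum(lam_w)
    cdf[-1] = 1.0
    sums = np.zeros(reps, dtype=float)
    streak = 0
    for n in range(1, max_n + 1):
        idx = np.searchsorted(cdf, rng.random(reps), side="right")
        sums += weights[idx]
        try:
            with warnings.catch_warnings():
                # near-constant sums at tiny n trip a range warning; they are
                # simply rejections
                warnings.simplefilter("ignore")
                p = shapiro(sums).pvalue
        except Exception:  # degenerate draw (all ties)
            p = 0.0
        if p >= alpha:
            streak += 1
            if streak >= consecutive:
                n_star = n - consecutive + 1
                return CalibrationResult(
                    min_mutations=n_star, never_normal=False, n_scanned=n,
                    **result_args,
                )
        else:
            streak = 0
    return CalibrationResult(
        min_mutations=None, never_normal=True, n_scanned=max_n, **result_args
    )


class CalibrationCache:
    """In-memory calibration cache with an optional JSON sidecar on disk."""

    def __init__(self, path: Optional[str] = None):
        self.path = path
        self._store: Dict[str, dict] = {}
        if path is not None and os.path.exists(path):
            with open(path) as fh:
                self._store = json.load(fh)

    def get(self, key: str, max_n: int) -> Optional[CalibrationResult]:
        entry = self._store.get(key)
        if entry is None:
            return None
        result = CalibrationResult(**entry)
        # a never-normal verdict from a shallower scan does not settle a
        # deeper one
        if result.never_normal and result.n_scanned < max_n:
            return None
        return result

    def put(self, key: str, result: CalibrationResult) -> None:
        self._store[key] = {
            "track_id": result.track_id,
            "min_mutations": result.min_mutations,
            "never_normal": result.never_normal,
            "reps": result.reps,
            "max_n": result.max_n,
            "alpha": result.alpha,
            "n_scanned": result.n_scanned,
        }

    def save(self) -> None:
        if self.path is not None:
            with open(self.path, "w") as fh:
                json.dump(self._store, fh)
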