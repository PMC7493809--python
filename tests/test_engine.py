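"""Per-track scores, analytic moments, Z scores and covariance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from perturbtrack import (
    TrackProfile,
    direct_statistics,
    track_covariance,
    track_moments,
    track_score,
    track_statistics,
    track_zscore,
)
from perturbtrack.combine import condition_correlation
from perturbtrack.exceptions import InputError, UndefinedZError

from conftest import make_mutations, make_track, random_track_fixture


class TestTrackScore:
    def test_weighted_sum(self):
        t = make_track([0.2, 1.0], positions=[5, 9], protein_length=10)
        muts = make_mutations([5, 9], f=[1.0, 0.5])
        assert track_score(t, muts) == pytest.approx(0.7)

    def test_empty_and_outside(self):
        t = make_track([0.2, 1.0], positions=[5, 9], protein_length=10)
        assert track_score(t, []) == 0.0
        assert track_score(t, make_mutations([7])) == 0.0

    def test_non_missense_ignored(self):
        t = make_track([0.2, 1.0], positions=[5, 9], protein_length=10)
        muts = make_mutations([5], cls="silent") + make_mutations([9], cls="nonsense")
        assert track_score(t, muts) == 0.0


class TestTrackMoments:
    def test_two_position_example(self):
        t = make_track([0.2, 1.0])
        c_e, c_v = track_moments(t, np.array([0.5, 0.5]))
        assert c_e == pytest.approx(0.6)
        assert c_v == pytest.approx(0.16)

    def test_constant_weights_degenerate(self):
        t = make_track([0.4, 0.4, 0.4])
        _, c_v = track_moments(t, np.full(3, 1 / 3))
        assert c_v == 0.0

    def test_bernoulli_moments_for_01_weights(self, rng):
        size = 40
        weights = (rng.uniform(size=size) < 0.3).astype(float)
        weights[:2] = [0.0, 1.0]  # ensure both values present
        t = make_track(weights)
        lam = rng.dirichlet(np.ones(size))
        p = lam[weights == 1.0].sum()
        c_e, c_v = track_moments(t, lam)
        assert c_e == pytest.approx(p, abs=1e-12)
        assert c_v == pytest.approx(p * (1 - p), abs=1e-12)


class TestTrackZScore:
    def test_binomial_closed_form_example(self):
        # 10 positions, 3 with weight 1, uniform background, 5 mutations
        # all f=1, observed score 4 -> Z = (4 - 1.5)/sqrt(5 * .3 * .7)
        weights = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        t = make_track(weights)
        stats = track_statistics(t, np.full(10, 0.1),
                                 make_mutations([1, 1, 2, 3, 4]))
        assert stats.score == pytest.approx(4.0)
        assert track_zscore(stats) == pytest.approx(2.5 / math.sqrt(1.05), abs=1e-9)

    def test_zero_when_score_equals_expectation(self):
        t = make_track([0.0, 1.0])
        stats = track_statistics(t, np.array([0.5, 0.5]), make_mutations([1, 2]))
        assert track_zscore(stats) == pytest.approx(0.0)

    def test_undefined_for_degenerate(self):
        t = make_track([0.5, 0.5])
        stats = track_statistics(t, np.array([0.5, 0.5]), make_mutations([1]))
        with pytest.raises(UndefinedZError):
            track_zscore(stats)

    def test_z_invariant_to_common_f_scaling(self, rng):
        t, lam = random_track_fixture(rng)
        pos = rng.choice(t.positions, size=12)
        for c in (1.0, 0.5):
            muts = make_mutations(pos, f=[c] * 12)
            stats = track_statistics(t, lam[t.positions - 1] /
                                     lam[t.positions - 1].sum(), muts)
            if c == 1.0:
                z_full = track_zscore(stats)
            else:
                assert track_zscore(stats) == pytest.approx(z_full, abs=1e-9)

    def test_null_z_is_standard_normal_for_large_n(self, rng):
        """KS sanity check: standardized null scores look standard normal."""
        size, n, reps = 120, 60, 5000
        weights = rng.uniform(0, 1, size)
        t = make_track(weights)
        lam = np.full(size, 1.0 / size)
        c_e, c_v = track_moments(t, lam)
        draws = rng.choice(size, size=(reps, n), p=lam)
        scores = weights[draws].sum(axis=1)
        z = (scores - n * c_e) / math.sqrt(n * c_v)
        assert kstest(z, "norm").pvalue > 0.01


class TestCovariance:
    def test_disjoint_tracks_zero(self):
        v = make_track([0.1, 0.9], positions=[1, 2], protein_length=10)
        w = make_track([0.3, 0.7], positions=[5, 6], protein_length=10)
        ov = track_covariance(v, w, None, make_mutations([1, 5]))
        assert ov.covariance == 0.0 and ov.q == 0

    def test_identical_track_covariance_is_variance(self, rng):
        t, lam = random_track_fixture(rng, max_size=50)
        lam_w = lam[t.positions - 1] / lam[t.positions - 1].sum()
        pos = rng.choice(t.positions, size=20)
        f = rng.uniform(0.2, 1.0, size=20)
        muts = make_mutations(pos, f=f)
        stats = track_statistics(t, lam_w, muts)
        ov = track_covariance(t, t, lam, muts, v_stats=stats, w_stats=stats)
        assert ov.covariance == pytest.approx(stats.variance, rel=1e-12)
        assert ov.correlation == pytest.approx(1.0)

    def test_constant_weights_in_overlap_give_zero(self):
        # W inside V with constant V-weight over the overlap: zero covariance
        v = make_track([0.5, 0.5, 0.5, 0.1], positions=[1, 2, 3, 4])
        w = make_track([0.2, 0.9, 0.4], positions=[1, 2, 3], protein_length=4)
        ov = track_covariance(v, w, None, make_mutations([1, 2, 3]))
        assert ov.covariance == pytest.approx(0.0, abs=1e-15)

    def test_symmetry(self, rng):
        v, lam = random_track_fixture(rng, max_size=60, protein_length=80)
        w, _ = random_track_fixture(rng, max_size=60, protein_length=80)
        muts = make_mutations(rng.integers(1, 81, size=30),
                              f=rng.uniform(0.2, 1, size=30))
        a = track_covariance(v, w, lam, muts).covariance
        b = track_covariance(w, v, lam, muts).covariance
        assert a == pytest.approx(b, rel=1e-12)

    def test_correlation_matrix_psd_on_random_gene(self, rng):
        length = 150
        lam = rng.uniform(0.5, 1.5, length)
        lam /= lam.sum()
        tracks, stats_list = [], []
        muts = make_mutations(rng.integers(1, length + 1, size=40),
                              f=rng.uniform(0.2, 1, size=40))
        for i in range(5):
            t, _ = random_track_fixture(rng, max_size=100, protein_length=length)
            lam_w = lam[t.positions - 1] / lam[t.positions - 1].sum()
            tracks.append(t)
            stats_list.append(track_statistics(t, lam_w, muts))
        k = len(tracks)
        r = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                ov = track_covariance(tracks[i], tracks[j], lam, muts,
                                      v_stats=stats_list[i], w_stats=stats_list[j])
                r[i, j] = r[j, i] = ov.correlation or 0.0
        r = condition_correlation(r)
        assert np.linalg.eigvalsh(r)[0] >= -1e-8


class TestPrecomputeAndScale:
    def test_matches_direct_path(self, rng):
        for _ in range(25):
            t, lam = random_track_fixture(rng)
            n = int(rng.integers(0, 40))
            muts = make_mutations(rng.choice(t.positions, size=n),
                                  f=rng.uniform(0.2, 1.0, size=n))
            prof = TrackProfile.build(t, lam)
            fast = prof.score_batch(muts)
            slow = direct_statistics(t, prof.lam_w, muts)
            assert abs(fast.expected - slow.expected) < 1e-10
            assert abs(fast.variance - slow.variance) < 1e-10
            assert abs(fast.score - slow.score) < 1e-10

    def test_zero_mutations(self, rng):
        t, lam = random_track_fixture(rng)
        prof = TrackProfile.build(t, lam)
        stats = prof.score_batch([])
        assert stats.n == 0 and stats.score == 0.0
        assert stats.expected == 0.0 and stats.variance == 0.0
        assert stats.zscore is None


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=40, deadline=None)
def test_precompute_equivalence_property(seed):
    r = np.random.default_rng(seed)
    size = int(r.integers(2, 80))
    weights = r.uniform(0, 1, size)
    t = make_track(weights, track_id=f"H{seed % 1000}")
    lam = r.uniform(0.05, 1.0, size)
    n = int(r.integers(1, 60))
    muts = make_mutations(r.choice(t.positions, size=n),
                          f=r.uniform(0.01, 1.0, size=n))
    prof = TrackProfile.build(t, lam)
    fast = prof.score_batch(muts)
    slow = direct_statistics(t, prof.lam_w, muts)
    assert abs(fast.expected - slow.expected) < 1e-10
    assert abs(fast.variance - slow.variance) < 1e-10
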