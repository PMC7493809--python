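"""Calibration, confidence weights, Eq.-7-style combination, whole-gene Z."""

import math

import numpy as np
import pandas as pd
import pytest

from perturbtrack import (
    build_natural_variation,
    calibrate_min_mutations,
    combine_z,
    confidence_weights,
    score_gene,
    subsample_factor,
    track_statistics,
    whole_gene_statistics,
)
from perturbtrack.combine import IsoformResult
from perturbtrack.exceptions import CombinationError, InputError

from conftest import make_mutations, make_track


class TestCalibration:
    def test_near_uniform_track_calibrates_quickly(self):
        rng = np.random.default_rng(7)
        weights = rng.uniform(0.3, 0.7, size=100)
        t = make_track(weights)
        res = calibrate_min_mutations(t, np.full(100, 0.01), max_n=50, seed=1)
        assert not res.never_normal
        assert res.min_mutations is not None and res.min_mutations <= 5

    def test_constant_track_never_normal(self):
        t = make_track([0.5] * 10)
        res = calibrate_min_mutations(t, np.full(10, 0.1), seed=1)
        assert res.never_normal and res.min_mutations is None
        assert res.n_scanned == 0

    def test_skewed_01_track_needs_more_mutations(self):
        # Bernoulli(0.001) score sums stay visibly non-normal for a long time
        weights = np.zeros(1000)
        weights[0] = 1.0
        skewed = make_track(weights, track_id="skew")
        res_skew = calibrate_min_mutations(
            skewed, np.full(1000, 0.001), max_n=150, seed=1
        )
        rng = np.random.default_rng(3)
        smooth = make_track(rng.uniform(0.2, 0.8, 100), track_id="smooth")
        res_smooth = calibrate_min_mutations(
            smooth, np.full(100, 0.01), max_n=150, seed=1
        )
        assert res_skew.effective_min > res_smooth.effective_min

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        t = make_track(rng.uniform(0, 1, 50))
        lam = np.full(50, 0.02)
        a = calibrate_min_mutations(t, lam, max_n=30, seed=5)
        b = calibrate_min_mutations(t, lam, max_n=30, seed=5)
        assert a.min_mutations == b.min_mutations


class TestConfidenceWeights:
    def _entry(self, group, m, track_id="T"):
        t = make_track([0.0, 1.0] if group == "domain" else [0.1, 0.9],
                       group=group, track_id=track_id)
        muts = make_mutations([2] * m)
        stats = track_statistics(t, np.array([0.5, 0.5]), muts)
        return (t, stats)

    def test_single_track_gets_full_confidence(self):
        cw = confidence_weights([self._entry("interaction", 3)])
        assert cw.values.tolist() == [1.0]

    def test_sqrt_m_rule_within_group(self):
        entries = [self._entry("interaction", 1, "A"),
                   self._entry("interaction", 4, "B")]
        cw = confidence_weights(entries)
        assert cw.values[1] / cw.values[0] == pytest.approx(2.0)

    def test_linear_rule(self):
        entries = [self._entry("interaction", 1, "A"),
                   self._entry("interaction", 4, "B")]
        cw = confidence_weights(entries, within_group="linear")
        assert cw.values[1] / cw.values[0] == pytest.approx(4.0)

    def test_four_groups_quarter_each(self):
        entries = [self._entry("interaction", 2), self._entry("domain", 2),
                   self._entry("conservation", 2),
                   self._entry("natural_variation", 2)]
        cw = confidence_weights(entries)
        assert np.allclose(cw.values, 0.25)

    def test_absent_groups_redistributed(self):
        entries = [self._entry("interaction", 2), self._entry("conservation", 2)]
        cw = confidence_weights(entries)
        assert np.allclose(cw.values, 0.5)


class TestCombineZ:
    def test_independent_pair(self):
        z = combine_z([1.0, 2.0], [1.0, 1.0], np.eye(2))
        assert z == pytest.approx(3.0 / math.sqrt(2.0))

    def test_perfectly_correlated_pair(self):
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert combine_z([2.0, 2.0], [1.0, 1.0], r) == pytest.approx(2.0)
        assert combine_z([1.0, 3.0], [1.0, 1.0], r) == pytest.approx(2.0)

    def test_identity_correlation_matches_naive(self, rng):
        for _ in range(10):
            k = int(rng.integers(1, 6))
            z = rng.normal(size=k)
            c = rng.uniform(0.1, 1.0, size=k)
            expected = float(np.dot(c, z) / math.sqrt(np.sum(c**2)))
            assert combine_z(z, c, np.eye(k)) == pytest.approx(expected)

    def test_k1_reduces_to_z_for_any_positive_c(self, rng):
        for c in (0.1, 1.0, 7.3):
            assert combine_z([1.7], [c], np.eye(1)) == pytest.approx(1.7)

    def test_pathological_correlation_raises(self):
        r = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(CombinationError):
            combine_z([1.0, 1.0], [1.0, 1.0], r)


class TestWholeGene:
    def _model(self):
        counts = pd.DataFrame([[0, 5, 10]], columns=["g1", "g2", "g3"])
        return build_natural_variation(counts, lambda_floor=0.0)

    def test_worked_example(self):
        # lambda_g = 0.1 is not in the toy model; use direct construction
        from perturbtrack import NaturalVariationModel

        model = NaturalVariationModel(genes=["G", "H"], lam=np.array([0.1, 0.9]))
        stats = whole_gene_statistics(
            "G", model, sum_f_gene=20.0, n_gene=20, total_n=100,
            total_sum_f=100.0, total_sum_f2=100.0, s=1.0,
        )
        assert stats.score == 20.0 and stats.expected == pytest.approx(10.0)
        assert stats.variance == pytest.approx(9.0)
        assert stats.zscore == pytest.approx(10.0 / 3.0)

    def test_expected_count_gives_zero_z(self):
        from perturbtrack import NaturalVariationModel

        model = NaturalVariationModel(genes=["G", "H"], lam=np.array([0.2, 0.8]))
        stats = whole_gene_statistics(
            "G", model, sum_f_gene=20.0, n_gene=20, total_n=100,
            total_sum_f=100.0, total_sum_f2=100.0, s=1.0,
        )
        assert stats.zscore == pytest.approx(0.0)

    def test_z_shrinks_monotonically_with_s(self):
        from perturbtrack import NaturalVariationModel

        model = NaturalVariationModel(genes=["G", "H"], lam=np.array([0.1, 0.9]))
        zs = []
        for s in (1.0, 0.5, 0.1, 0.01):
            stats = whole_gene_statistics(
                "G", model, sum_f_gene=20.0, n_gene=20, total_n=100,
                total_sum_f=100.0, total_sum_f2=100.0, s=s,
            )
            zs.append(stats.zscore)
        assert all(a > b > 0 for a, b in zip(zs, zs[1:]))

    def test_gene_absent_from_universe(self):
        model = self._model()
        assert whole_gene_statistics(
            "nope", model, 1.0, 1, 10, 10.0, 10.0, s=1.0
        ) is None

    def test_subsample_factor(self):
        assert subsample_factor(100) == pytest.approx(0.1)
        assert subsample_factor(100, "none") == 1.0
        with pytest.raises(InputError):
            subsample_factor(0)

    def test_unsubsampled_z_calibrated_under_own_model(self, rng):
        """Counts drawn from the model's own lambda give Z ~ N(0, 1)."""
        n_genes, total = 200, 20000
        counts = pd.DataFrame(rng.poisson(20, size=(10, n_genes)),
                              columns=[f"g{i}" for i in range(n_genes)])
        model = build_natural_variation(counts)
        draw = rng.multinomial(total, model.lam)
        zs = []
        for gene, c in zip(model.genes, draw):
            stats = whole_gene_statistics(
                gene, model, sum_f_gene=float(c), n_gene=int(c), total_n=total,
                total_sum_f=float(total), total_sum_f2=float(total), s=1.0,
            )
            if stats is not None and stats.zscore is not None:
                zs.append(stats.zscore)
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.1
        assert 0.85 < zs.std() < 1.15


class TestScoreGene:
    def _iso(self, iso, z):
        return IsoformResult(isoform=iso, combined_z=z, breakdown=[], k=1)

    def test_max_over_isoforms(self):
        result = score_gene("G", {"a": self._iso("a", 1.2), "b": self._iso("b", 3.4)})
        assert result.combined_z == 3.4 and result.best_isoform == "b"

    def test_single_isoform_identity(self):
        result = score_gene("G", {"a": self._iso("a", 2.2)})
        assert result.combined_z == 2.2

    def test_tie_breaks_lexicographically(self):
        result = score_gene("G", {"b": self._iso("b", 2.0), "a": self._iso("a", 2.0)})
        assert result.best_isoform == "a"

    def test_all_unscored(self):
        result = score_gene("G", {"a": self._iso("a", None)})
        assert result.combined_z is None and result.best_isoform is None
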