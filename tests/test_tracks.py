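"""Track builders, aggregate rules and conservation weighting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perturbtrack import (
    ConservationColumn,
    DomainInstance,
    FunctionalTrack,
    build_aggregate_tracks,
    build_domain_track,
    build_interaction_track,
    conservation_track_from_alignment,
    conservation_weight,
    jensen_shannon_divergence,
)
from perturbtrack._blosum import AMINO_ACIDS, BLOSUM62_BACKGROUND
from perturbtrack.exceptions import (
    CoordinateError,
    InputError,
    MissingAnnotationError,
)

from conftest import make_track


def jsd_oracle(p, q):
    """Hand-written base-2 Jensen-Shannon divergence (independent of scipy)."""
    p = np.asarray(p, float) / np.sum(p)
    q = np.asarray(q, float) / np.sum(q)
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


class TestFunctionalTrack:
    def test_invariants_enforced(self):
        with pytest.raises(CoordinateError):
            make_track([0.5, 0.5], positions=[1, 300], protein_length=200)
        with pytest.raises(InputError):
            make_track([0.5, 1.5])
        with pytest.raises(InputError):
            make_track([0.5, 0.5], positions=[3, 3], protein_length=5)
        with pytest.raises(InputError):
            make_track([0.5, 0.5], group="domain")

    def test_degenerate_flag(self):
        assert make_track([0.3, 0.3, 0.3]).is_degenerate
        assert not make_track([0.3, 0.4]).is_degenerate

    def test_membership_and_lookup(self):
        t = make_track([0.1, 0.9], positions=[5, 9], protein_length=12)
        assert t.contains(np.array([5, 6, 9, 12])).tolist() == [True, False, True, False]
        assert t.weights_at(np.array([9, 5])).tolist() == [0.9, 0.1]


class TestInteractionAndDomainBuilders:
    def test_interaction_transfers_binding_frequencies(self):
        inst = DomainInstance("PF1", "ISO1", [10, 11, 12],
                              {"dna": [0.0, 0.9, 0.3]})
        t = build_interaction_track(inst, "dna", protein_length=20)
        assert t.group == "interaction"
        assert t.positions.tolist() == [10, 11, 12]
        assert t.weights.tolist() == [0.0, 0.9, 0.3]
        assert t.ligand == "dna" and t.family_id == "PF1"

    def test_interaction_constant_weights_flagged_degenerate(self):
        inst = DomainInstance("PF1", "ISO1", [1, 2], {"ion": [0.0, 0.0]})
        assert build_interaction_track(inst, "ion", 5).is_degenerate

    def test_interaction_errors(self):
        inst = DomainInstance("PF1", "ISO1", [10, 300], {"dna": [0.1, 0.2]})
        with pytest.raises(CoordinateError):
            build_interaction_track(inst, "dna", protein_length=200)
        with pytest.raises(MissingAnnotationError):
            build_interaction_track(inst, "rna", protein_length=400)

    def test_domain_track_is_whole_length_01(self):
        inst = DomainInstance("PF2", "ISO1", [3, 4, 5])
        t = build_domain_track(inst, protein_length=6)
        assert t.positions.tolist() == [1, 2, 3, 4, 5, 6]
        assert t.weights.tolist() == [0, 0, 1, 1, 1, 0]

    def test_domain_covering_whole_protein_degenerate(self):
        inst = DomainInstance("PF2", "ISO1", [1, 2, 3])
        assert build_domain_track(inst, protein_length=3).is_degenerate

    def test_two_families_give_independent_tracks(self):
        a = build_domain_track(DomainInstance("PFA", "ISO1", [1, 2]), 10)
        b = build_domain_track(DomainInstance("PFB", "ISO1", [5, 6]), 10)
        assert a.track_id != b.track_id
        assert a.family_id != b.family_id


class TestAggregateTracks:
    def _instances(self, n, family="PFX"):
        out = []
        for i in range(n):
            start = 1 + 10 * i
            out.append(
                DomainInstance(family, "ISO1", [start, start + 1, start + 2],
                               {"ion": [0.2, 0.8, 0.5]})
            )
        return out

    def test_two_instances_emit_individuals_plus_aggregate(self):
        tracks = build_aggregate_tracks(self._instances(2), 500, ligand="ion")
        assert len(tracks) == 3
        agg = [t for t in tracks if t.track_id.endswith("aggregate")]
        assert len(agg) == 1
        assert agg[0].positions.size == 6

    def test_forty_instances_replaced_by_aggregate(self):
        tracks = build_aggregate_tracks(self._instances(40), 500, ligand="ion")
        assert len(tracks) == 1
        assert tracks[0].track_id.endswith("aggregate")

    def test_single_instance_no_aggregate(self):
        tracks = build_aggregate_tracks(self._instances(1), 500, ligand="ion")
        assert len(tracks) == 1
        assert not tracks[0].track_id.endswith("aggregate")

    def test_overlap_resolved_by_maximum_weight(self):
        insts = [
            DomainInstance("PFX", "ISO1", [5, 6], {"ion": [0.1, 0.9]}),
            DomainInstance("PFX", "ISO1", [6, 7], {"ion": [0.4, 0.2]}),
        ]
        tracks = build_aggregate_tracks(insts, 50, ligand="ion")
        agg = next(t for t in tracks if t.track_id.endswith("aggregate"))
        assert agg.positions.tolist() == [5, 6, 7]
        assert agg.weights.tolist() == [0.1, 0.9, 0.2]

    def test_domain_aggregate_spans_protein(self):
        insts = [DomainInstance("PFX", "ISO1", [2, 3]),
                 DomainInstance("PFX", "ISO1", [7, 8])]
        tracks = build_aggregate_tracks(insts, 10)
        agg = next(t for t in tracks if t.track_id.endswith("aggregate"))
        assert agg.positions.size == 10
        assert agg.weights[[1, 2, 6, 7]].tolist() == [1, 1, 1, 1]
        assert agg.weights[[0, 4, 9]].tolist() == [0, 0, 0]


class TestConservation:
    def test_identical_to_background_gives_zero(self):
        counts = {a: int(round(1000 * f)) for a, f in
                  zip(AMINO_ACIDS, BLOSUM62_BACKGROUND)}
        col = ConservationColumn(1, counts, gap_count=0)
        assert conservation_weight(col) < 5e-4  # rounding of counts only

    def test_all_gaps_gives_zero(self):
        col = ConservationColumn(1, {}, gap_count=10)
        assert conservation_weight(col) == 0.0

    def test_point_mass_matches_independent_jsd(self):
        col = ConservationColumn(1, {"W": 50}, gap_count=0)
        point = np.zeros(20)
        point[AMINO_ACIDS.index("W")] = 1.0
        expected = jsd_oracle(point, BLOSUM62_BACKGROUND)
        assert conservation_weight(col) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_non_gap_fraction(self):
        base = {"W": 10}
        weights = [conservation_weight(ConservationColumn(1, base, gap_count=g))
                   for g in (0, 5, 20)]
        assert weights[0] > weights[1] > weights[2]

    def test_errors(self):
        with pytest.raises(InputError):
            ConservationColumn(1, {}, gap_count=0)
        with pytest.raises(InputError):
            ConservationColumn(1, {"A": -1}, gap_count=0)

    def test_track_from_alignment(self):
        rows = ["MW-K", "MW-K", "MA-R"]  # reference gap column dropped
        t = conservation_track_from_alignment(rows, "ISO1")
        assert t.protein_length == 3
        assert t.group == "conservation"
        # invariant column (M) is more conserved than the split K/R column
        assert t.weights[0] > t.weights[2]

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_jsd_matches_oracle_and_is_symmetric(self, seed):
        r = np.random.default_rng(seed)
        p = r.dirichlet(np.ones(20))
        q = r.dirichlet(np.ones(20))
        d = jensen_shannon_divergence(p, q)
        assert d == pytest.approx(jsd_oracle(p, q), abs=1e-9)
        assert d == pytest.approx(jensen_shannon_divergence(q, p), abs=1e-12)
        assert 0.0 <= d <= 1.0

    def test_jsd_zero_iff_equal(self):
        p = np.full(20, 0.05)
        assert jensen_shannon_divergence(p, p) == 0.0
        q = p.copy()
        q[0] += 0.04
        q[1] -= 0.04
        assert jensen_shannon_divergence(p, q) > 0.0


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None)
def test_builders_satisfy_track_invariants_on_random_inputs(seed):
    r = np.random.default_rng(seed)
    length = int(r.integers(20, 200))
    k = int(r.integers(2, min(length, 15)))
    states = np.sort(r.choice(np.arange(1, length + 1), size=k, replace=False))
    freqs = r.uniform(0, 1, size=k)
    inst = DomainInstance("PF", "ISO1", states.tolist(), {"dna": freqs.tolist()})
    for t in (build_interaction_track(inst, "dna", length),
              build_domain_track(inst, length)):
        assert t.positions[0] >= 1 and t.positions[-1] <= length
        assert np.all(np.diff(t.positions) > 0)
        assert np.all((t.weights >= 0) & (t.weights <= 1))
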