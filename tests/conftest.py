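import numpy as np
import pytest

from perturbtrack import FunctionalTrack, MutationRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_track(
    weights,
    positions=None,
    protein_length=None,
    group="interaction",
    track_id="T",
    isoform_id="ISO1",
    **kwargs,
):
    weights = np.asarray(weights, dtype=float)
    if positions is None:
        positions = np.arange(1, weights.size + 1)
    positions = np.asarray(positions, dtype=np.int64)
    if protein_length is None:
        protein_length = int(positions.max())
    return FunctionalTrack(
        track_id=track_id,
        isoform_id=isoform_id,
        group=group,
        positions=positions,
        weights=weights,
        protein_length=protein_length,
        **kwargs,
    )


def make_mutations(positions, f=None, gene="G1", isoform="ISO1", cls="missense"):
    if f is None:
        f = [1.0] * len(positions)
    return [
        MutationRecord(
            gene=gene,
            isoform=isoform,
            protein_position=int(p),
            mutation_class=cls,
            f=float(fi),
            sample_id=f"S{i}",
            cancer_type="TST",
        )
        for i, (p, fi) in enumerate(zip(positions, f))
    ]


def random_track_fixture(rng, max_size=200, group="interaction", protein_length=None):
    """A random non-degenerate track with a random background over it."""
    size = int(rng.integers(5, max_size + 1))
    length = protein_length or int(size + rng.integers(0, 50))
    positions = np.sort(rng.choice(np.arange(1, length + 1), size=size, replace=False))
    weights = rng.uniform(0.0, 1.0, size=size)
    track = make_track(weights, positions=positions, protein_length=length,
                       group=group, track_id=f"R{rng.integers(1 << 30)}")
    lam = rng.uniform(0.1, 1.0, size=length)
    return track, lam / lam.sum()
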