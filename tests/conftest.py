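import numpy as np
import pytest

from nucleoclock.io_fragments import FragmentSet, SampleMeta
from nucleoclock.simulate import CohortSpec, MixtureLink


def make_fragment_set(sample_id="S", **chrom_intervals):
    """FragmentSet from {chrom: [(start, end), ...]} keyword arguments."""
    chroms = {}
    for chrom, pairs in chrom_intervals.items():
        arr = np.asarray(pairs, dtype=np.int64)
        chroms[chrom] = (arr[:, 0], arr[:, 1])
    return FragmentSet(sample_id, chroms)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Cheap cohort spec used by several integration tests."""
    return CohortSpec(
        n_subjects=6,
        genome_length=100_000,
        n_fragments_per_subject=5_000,
        seed=7,
    )


def mono_only_mixture():
    return MixtureLink(w_mono0=1.0, w_di0=0.0, w_tri0=0.0, d_di=0.0, d_tri=0.0)


def tri_only_mixture():
    return MixtureLink(w_mono0=0.0, w_di0=0.0, w_tri0=1.0, d_di=0.0, d_tri=0.0)
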