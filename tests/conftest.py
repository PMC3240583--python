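import numpy as np
import pytest

from clipmotif.kmers import ClipTag
from clipmotif.simulate import SimConfig, generate_dataset


def make_tag(sequence, chrom="chrT", start=0, strand="+", tag_id="t0"):
    """A ClipTag whose interval length matches the sequence (coords arbitrary)."""
    return ClipTag(chrom, start, start + len(sequence), strand, tag_id, sequence)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset shared across tests."""
    cfg = SimConfig(
        genome_length=160_000,
        n_genes=16,
        n_tags=4_000,
        enrichment_factor=10.0,
        duplicate_rate=0.05,
        antisense_rate=0.05,
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
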