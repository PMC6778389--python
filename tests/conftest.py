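import numpy as np
import pytest

import capclust as cc


@pytest.fixture
def genome():
    return cc.GenomeInfo({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def make_dataset(genome):
    """Factory: build a CTSSDataset from per-sample entry dicts.

    ``samples`` maps sample id -> (plus_entries, minus_entries), each a
    {(chrom, pos): count} dict.
    """

    def build(samples, genome_override=None):
        g = genome_override or genome
        plus = {sid: cc.SparseTrack.from_entries("+", p) for sid, (p, _) in samples.items()}
        minus = {sid: cc.SparseTrack.from_entries("-", m) for sid, (_, m) in samples.items()}
        return cc.CTSSDataset(g, list(samples), plus, minus)

    return build


@pytest.fixture
def make_pooled(genome):
    """Factory: wrap plus/minus entry dicts into a PooledTrack."""

    def build(plus_entries, minus_entries, n_samples=1, genome_override=None):
        g = genome_override or genome
        return cc.PooledTrack(
            cc.SparseTrack.from_entries("+", plus_entries),
            cc.SparseTrack.from_entries("-", minus_entries),
            n_samples,
            g,
        )

    return build


def random_sparse_entries(rng, chrom="chr1", span=10_000, density=0.02, max_value=5.0):
    """Random sparse positive float entries on one chromosome."""
    n = rng.binomial(span, density)
    positions = rng.choice(span, size=n, replace=False)
    values = rng.uniform(0.01, max_value, size=n)
    return {(chrom, int(p)): float(v) for p, v in zip(positions, values)}
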