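import numpy as np
import pytest

import capclust as cc
from conftest import random_sparse_entries


class TestLibrarySizes:
    def test_sums_both_strands(self, make_dataset):
        ds = make_dataset({"a": ({("chr1", 1): 5, ("chr1", 2): 3}, {("chr1", 9): 2})})
        assert cc.library_sizes(ds).tolist() == [10.0]

    def test_empty_sample_warns(self, make_dataset):
        ds = make_dataset({"a": ({("chr1", 1): 5}, {}), "b": ({}, {})})
        with pytest.warns(UserWarning, match="zero tags"):
            sizes = cc.library_sizes(ds)
        assert sizes.tolist() == [5.0, 0.0]


class TestNormalizeTpm:
    def test_definition(self, make_dataset):
        big = cc.GenomeInfo({"chr1": 10})
        entries = {("chr1", 0): 4, ("chr1", 1): 2_000_000 - 4}
        ds = make_dataset({"a": (entries, {})}, genome_override=big)
        tpm = cc.normalize_tpm(ds)
        assert tpm.plus["a"].to_dict()[("chr1", 0)] == pytest.approx(2.0)

    def test_per_sample_sum_is_one_million(self, make_dataset):
        rng = np.random.default_rng(0)
        ds = make_dataset(
            {
                "a": (random_sparse_entries(rng), random_sparse_entries(rng)),
                "b": (random_sparse_entries(rng), random_sparse_entries(rng)),
            }
        )
        # counts must be integers for a CTSS dataset; re-quantize
        ds = make_dataset(
            {
                sid: (
                    {k: int(v * 10) + 1 for k, v in ds.plus[sid].to_dict().items()},
                    {k: int(v * 10) + 1 for k, v in ds.minus[sid].to_dict().items()},
                )
                for sid in ds.sample_ids
            }
        )
        tpm = cc.normalize_tpm(ds)
        for sid in tpm.sample_ids:
            assert tpm.sample_total(sid) == pytest.approx(1e6, rel=1e-9)

    def test_same_counts_different_depth_differ(self, make_dataset):
        ds = make_dataset(
            {"a": ({("chr1", 5): 2}, {}), "b": ({("chr1", 5): 2, ("chr1", 9): 2}, {})}
        )
        tpm = cc.normalize_tpm(ds)
        va = tpm.plus["a"].to_dict()[("chr1", 5)]
        vb = tpm.plus["b"].to_dict()[("chr1", 5)]
        assert va == pytest.approx(1e6) and vb == pytest.approx(5e5)

    def test_zero_library_rejected(self, make_dataset):
        ds = make_dataset({"a": ({}, {})})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="zero-size"):
                cc.normalize_tpm(ds)


class TestSupportFilter:
    def three_sample_ds(self, make_dataset, counts):
        return make_dataset(
            {
                f"s{i}": ({("chr1", 100): c} if c else {}, {("chr1", 500): 1})
                for i, c in enumerate(counts)
            }
        )

    def test_single_library_ctss_removed(self, make_dataset):
        ds = self.three_sample_ds(make_dataset, [3, 0, 0])
        out = cc.support_filter_ctss(ds, min_samples=2)
        assert all(out.plus[s].n_entries == 0 for s in out.sample_ids)
        # minus bp present in all samples survives
        assert all(out.minus[s].n_entries == 1 for s in out.sample_ids)

    def test_two_of_three_kept(self, make_dataset):
        ds = self.three_sample_ds(make_dataset, [0, 1, 1])
        out = cc.support_filter_ctss(ds, min_samples=2, min_count=1)
        assert out.plus["s1"].to_dict() == {("chr1", 100): 1}

    def test_k1_c1_is_identity(self, make_dataset):
        ds = self.three_sample_ds(make_dataset, [2, 0, 1])
        out = cc.support_filter_ctss(ds, min_samples=1, min_count=1)
        for sid in ds.sample_ids:
            assert out.plus[sid].to_dict() == ds.plus[sid].to_dict()

    def test_idempotent_on_random_data(self, make_dataset):
        rng = np.random.default_rng(7)
        ds = make_dataset(
            {
                f"s{i}": (
                    {k: int(v) + 1 for k, v in random_sparse_entries(rng, density=0.01).items()},
                    {},
                )
                for i in range(4)
            }
        )
        once = cc.support_filter_ctss(ds, min_samples=2)
        twice = cc.support_filter_ctss(once, min_samples=2)
        for sid in ds.sample_ids:
            assert once.plus[sid].to_dict() == twice.plus[sid].to_dict()


class TestPool:
    def test_sum_of_tpm(self, make_dataset):
        ds = make_dataset({"a": ({("chr1", 7): 1}, {}), "b": ({("chr1", 7): 1}, {})})
        tpm = cc.normalize_tpm(ds)
        pooled = cc.pool(tpm)
        assert pooled.plus.to_dict()[("chr1", 7)] == pytest.approx(2e6)

    def test_unfiltered_total_conserved(self, make_dataset):
        rng = np.random.default_rng(3)
        ds = make_dataset(
            {
                f"s{i}": (
                    {k: int(v) + 1 for k, v in random_sparse_entries(rng).items()},
                    {k: int(v) + 1 for k, v in random_sparse_entries(rng).items()},
                )
                for i in range(3)
            }
        )
        pooled = cc.pool(cc.normalize_tpm(ds))
        assert pooled.total() == pytest.approx(3e6, rel=1e-9)

    def test_raw_counts_rejected(self, make_dataset):
        ds = make_dataset({"a": ({("chr1", 7): 1}, {})})
        with pytest.raises(ValueError, match="TPM"):
            cc.pool(ds)


class _Range:
    def __init__(self, chrom, start, end, strand="+"):
        self.chrom, self.start, self.end, self.strand = chrom, start, end, strand
        self.uid = f"{chrom}:{start}-{end};{strand}"


class TestQuantifyRanges:
    def test_same_strand_sum(self, make_dataset):
        ds = make_dataset({"a": ({("chr1", 10): 3, ("chr1", 11): 4}, {("chr1", 10): 99})})
        m = cc.quantify_ranges(ds, [_Range("chr1", 10, 12)], "same-strand")
        assert m.counts.iloc[0, 0] == 7

    def test_both_strands_over_divergent_pair(self, make_dataset):
        ds = make_dataset({"a": ({("chr1", 10): 10}, {("chr1", 10): 10})})
        r = _Range("chr1", 5, 15, ".")
        m = cc.quantify_ranges(ds, [r], "both-strands")
        assert m.counts.iloc[0, 0] == 20

    def test_unstranded_range_rejected_same_strand(self, make_dataset):
        ds = make_dataset({"a": ({}, {})})
        with pytest.raises(ValueError, match="unstranded"):
            cc.quantify_ranges(ds, [_Range("chr1", 0, 5, ".")], "same-strand")

    def test_partition_recovers_library_sizes(self, make_dataset):
        rng = np.random.default_rng(5)
        ds = make_dataset(
            {
                f"s{i}": (
                    {k: int(v) + 1 for k, v in random_sparse_entries(rng, span=1000).items()},
                    {k: int(v) + 1 for k, v in random_sparse_entries(rng, span=1000).items()},
                )
                for i in range(2)
            }
        )
        ranges = [_Range("chr1", 0, 500, s) for s in "+-"] + [
            _Range("chr1", 500, 100_000, s) for s in "+-"
        ]
        m = cc.quantify_ranges(ds, ranges, "same-strand")
        assert m.counts.sum(axis=0).tolist() == cc.library_sizes(ds).tolist()

    def test_additivity_of_split_ranges(self, make_dataset):
        ds = make_dataset({"a": ({("chr1", i): i + 1 for i in range(20)}, {})})
        whole = cc.quantify_ranges(ds, [_Range("chr1", 0, 20)], "same-strand")
        parts = cc.quantify_ranges(
            ds, [_Range("chr1", 0, 7), _Range("chr1", 7, 20)], "same-strand"
        )
        assert whole.counts.values.sum() == parts.counts.values.sum()


class TestFeatureSupport:
    def make_matrix(self, rows, tpm=None):
        import pandas as pd

        counts = pd.DataFrame(rows).T
        counts.columns = [f"s{i}" for i in range(counts.shape[1])]
        features = pd.DataFrame(
            {"chrom": "chr1", "start": 0, "end": 1, "strand": "+"}, index=counts.index
        )
        m = cc.ExpressionMatrix(features, counts)
        if tpm is not None:
            import pandas as pd

            m.tpm = pd.DataFrame(tpm).T
            m.tpm.columns = counts.columns
        return m

    def test_tpm_threshold_strict(self):
        m = self.make_matrix({"f": [1, 1, 1]}, tpm={"f": [1.2, 0.8, 1.5]})
        assert cc.feature_support(m, 1.0, 2, use_tpm=True, strict=True)["f"]

    def test_tag_threshold_needs_enough_samples(self):
        m = self.make_matrix({"f": [1, 0, 0, 0, 0, 0, 1]})
        assert not cc.feature_support(m, 1, 7, strict=False)["f"]

    def test_all_zero_fails(self):
        m = self.make_matrix({"f": [0, 0, 0]})
        assert not cc.feature_support(m, 0, 1, strict=True)["f"]

    def test_tpm_layer_required(self):
        m = self.make_matrix({"f": [1, 2]})
        with pytest.raises(ValueError, match="TPM"):
            cc.feature_support(m, 1, 1, use_tpm=True)
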