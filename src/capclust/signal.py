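"""Normalization, pooling, sample-support filtering and quantification.

The analysis operates on three unit scales:

* raw tag counts (what the sequencer produced; what DE tools want),
* TPM, tags-per-million: ``count * 1e6 / library_size`` per sample,
* pooled signal: the per-bp SUM of TPM over all samples, per strand.

Library size is always the raw total over both strands of the unfiltered
tracks — sample-support filtering changes which positions are trusted for
clustering, not the sequencing depth.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .tracks import CTSSDataset, PooledTrack, SparseTrack

logger = logging.getLogger(__name__)


class ExpressionMatrix:
    """Feature x sample count matrix with optional TPM layer.

    ``features`` is a DataFrame indexed by feature id with columns
    chrom/start/end/strand (strand "." for unstranded features); ``counts``
    shares that index, one column per sample in dataset order.  The TPM
    layer, when attached, equals counts scaled column-wise by
    ``1e6 / library_size``.
    """

    def __init__(self, features: pd.DataFrame, counts: pd.DataFrame, tpm: pd.DataFrame | None = None):
        if not features.index.equals(counts.index):
            raise ValueError("features and counts must share one index")
        if tpm is not None and (not tpm.index.equals(counts.index) or list(tpm.columns) != list(counts.columns)):
            raise ValueError("TPM layer shape mismatch")
        self.features = features
        self.counts = counts
        self.tpm = tpm

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def add_tpm(self, library_sizes: pd.Series) -> "ExpressionMatrix":
        sizes = library_sizes.reindex(self.counts.columns)
        if sizes.isna().any() or (sizes <= 0).any():
            raise ValueError("library sizes missing or non-positive for some samples")
        self.tpm = self.counts * 1e6 / sizes
        return self

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        return ExpressionMatrix(
            self.features.loc[ids],
            self.counts.loc[ids],
            None if self.tpm is None else self.tpm.loc[ids],
        )

    def to_tsv(self, path, layer: str = "counts") -> None:
        values = self.counts if layer == "counts" else self.tpm
        if values is None:
            raise ValueError(f"layer {layer!r} not present")
        out = pd.concat([self.features, values], axis=1)
        out.to_csv(path, sep="\t", index_label="id")

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.counts.shape[0]} features x {self.counts.shape[1]} samples)"


def library_sizes(dataset: CTSSDataset) -> pd.Series:
    """Raw per-sample tag totals (both strands), in dataset sample order."""
    if dataset.is_tpm and dataset.library_sizes is not None:
        return pd.Series(dataset.library_sizes).reindex(dataset.sample_ids)
    totals = {}
    for sid in dataset.sample_ids:
        totals[sid] = dataset.sample_total(sid)
        if totals[sid] == 0:
            warnings.warn(f"sample {sid!r} has zero tags")
    return pd.Series(totals, dtype=float).reindex(dataset.sample_ids)


def normalize_tpm(dataset: CTSSDataset) -> CTSSDataset:
    """Scale each sample's tracks to tags-per-million.

    Each returned sample's signal sums to 1e6 (up to float tolerance).  Raw
    library sizes are carried on the returned dataset.
    """
    if dataset.is_tpm:
        return dataset
    sizes = library_sizes(dataset)
    if (sizes == 0).any():
        zero = list(sizes[sizes == 0].index)
        raise ValueError(f"cannot TPM-normalize zero-size libraries: {zero}")
    plus = {sid: dataset.plus[sid].scale(1e6 / sizes[sid]) for sid in dataset.sample_ids}
    minus = {sid: dataset.minus[sid].scale(1e6 / sizes[sid]) for sid in dataset.sample_ids}
    return CTSSDataset(
        dataset.genome,
        dataset.sample_ids,
        plus,
        minus,
        groups=dataset.groups,
        is_tpm=True,
        library_sizes=sizes.to_dict(),
    )


def support_filter_ctss(dataset: CTSSDataset, min_samples: int = 2, min_count: float = 1) -> CTSSDataset:
    """Robust-pooling filter: keep a bp (per strand) only with enough support.

    A position survives iff at least ``min_samples`` samples carry signal
    ``>= min_count`` there; positions that fail are removed from every
    sample's track on that strand.  With ``min_samples=2`` this discards
    CTSSs observed in only a single library.  Idempotent.
    """
    if min_samples < 1 or min_count < 1:
        raise ValueError("min_samples and min_count must be >= 1")

    def keep_map(tracks: dict[str, SparseTrack]) -> dict[str, np.ndarray]:
        keep: dict[str, np.ndarray] = {}
        chroms = sorted({c for t in tracks.values() for c in t.chroms})
        for chrom in chroms:
            pos_parts = []
            for t in tracks.values():
                pos, val = t.arrays(chrom)
                pos_parts.append(pos[val >= min_count])
            allpos = np.concatenate(pos_parts) if pos_parts else np.empty(0, dtype=np.int64)
            upos, counts = np.unique(allpos, return_counts=True)
            keep[chrom] = upos[counts >= min_samples]
        return keep

    keep_plus = keep_map(dataset.plus)
    keep_minus = keep_map(dataset.minus)
    plus = {sid: t.filter_positions(keep_plus) for sid, t in dataset.plus.items()}
    minus = {sid: t.filter_positions(keep_minus) for sid, t in dataset.minus.items()}
    return CTSSDataset(
        dataset.genome,
        dataset.sample_ids,
        plus,
        minus,
        groups=dataset.groups,
        is_tpm=dataset.is_tpm,
        library_sizes=dataset.library_sizes,
    )


def pool(tpm_dataset: CTSSDataset) -> PooledTrack:
    """Sum per-sample TPM tracks into one pooled track per strand."""
    if not tpm_dataset.is_tpm:
        raise ValueError("pool() expects a TPM-normalized dataset (see normalize_tpm)")
    plus = SparseTrack.sum_tracks([tpm_dataset.plus[s] for s in tpm_dataset.sample_ids])
    minus = SparseTrack.sum_tracks([tpm_dataset.minus[s] for s in tpm_dataset.sample_ids])
    return PooledTrack(plus, minus, tpm_dataset.n_samples, tpm_dataset.genome)


def quantify_ranges(dataset: CTSSDataset, ranges, strand_mode: str = "same-strand") -> ExpressionMatrix:
    """Count raw tags per range per sample.

    ``ranges`` is a sequence of objects with chrom/start/end/strand
    attributes and a ``uid``; tag-cluster quantification uses
    ``same-strand``, bidirectional (unstranded) clusters use
    ``both-strands``.  Counts are raw so the output can feed standard
    count-based DE tools.
    """
    if strand_mode not in ("same-strand", "both-strands"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if dataset.is_tpm:
        raise ValueError("quantify_ranges expects raw counts, not a TPM dataset")
    ids, rows = [], []
    for r in ranges:
        strand = getattr(r, "strand", ".")
        if strand_mode == "same-strand" and strand not in ("+", "-"):
            raise ValueError(f"unstranded range {getattr(r, 'uid', r)} in same-strand mode")
        ids.append(r.uid)
        rows.append((r.chrom, r.start, r.end, strand))
    features = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"], index=ids)
    if features.index.has_duplicates:
        raise ValueError("duplicate range ids")
    data = np.zeros((len(ids), dataset.n_samples), dtype=np.int64)
    for j, sid in enumerate(dataset.sample_ids):
        for i, r in enumerate(ranges):
            strand = features.iloc[i]["strand"]
            if strand_mode == "same-strand":
                data[i, j] = dataset.track(sid, strand).range_sum(r.chrom, r.start, r.end)
            else:
                data[i, j] = dataset.plus[sid].range_sum(r.chrom, r.start, r.end) + dataset.minus[
                    sid
                ].range_sum(r.chrom, r.start, r.end)
    counts = pd.DataFrame(data, index=ids, columns=dataset.sample_ids)
    return ExpressionMatrix(features, counts)


def feature_support(
    matrix: ExpressionMatrix,
    min_value: float,
    min_samples: int,
    use_tpm: bool = False,
    strict: bool = True,
) -> pd.Series:
    """Boolean per feature: expressed above ``min_value`` in enough samples.

    ``strict=True`` requires value strictly greater than ``min_value``
    (the "> 1 TPM" phrasing); ``strict=False`` uses >= (the ">= 1 tag"
    phrasing).  The sample requirement is always "at least min_samples".
    """
    if min_value < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    layer = matrix.tpm if use_tpm else matrix.counts
    if layer is None:
        raise ValueError("TPM layer requested but not attached (use add_tpm)")
    passing = (layer > min_value) if strict else (layer >= min_value)
    return passing.sum(axis=1) >= min_samples
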