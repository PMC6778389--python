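"""Unidirectional tag-cluster (TC) calling by slice-reduce.

RNA polymerase rarely initiates from a single bp; a promoter produces an
array of nearby CTSSs on one strand.  TCs capture these arrays: positions
whose pooled signal falls below a threshold are discarded (slice), and
surviving same-strand positions closer than a merge distance are joined
into one cluster (reduce).  Each TC records its peak — the bp with the
highest pooled signal, the best single-bp TSS estimate — and its score,
the summed pooled signal of its surviving positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal import ExpressionMatrix, feature_support, library_sizes, normalize_tpm, pool, quantify_ranges
from .tracks import CTSSDataset, PooledTrack


@dataclass
class ClusterConfig:
    """Slice-reduce parameters.

    slice_threshold
        minimum pooled TPM for a CTSS to survive slicing (default 0.1,
        small relative to the downstream >1 TPM cluster filter).
    merge_distance
        maximum number of signal-free bps allowed between consecutive
        surviving CTSSs within one cluster (default 20).
    """

    slice_threshold: float = 0.1
    merge_distance: int = 20

    def __post_init__(self):
        if self.slice_threshold < 0:
            raise ValueError("slice_threshold must be >= 0")
        if self.merge_distance < 0:
            raise ValueError("merge_distance must be >= 0")


@dataclass
class TagCluster:
    """Stranded cluster of nearby CTSSs (0-based half-open span)."""

    chrom: str
    start: int
    end: int
    strand: str
    peak: int
    score: float
    peak_value: float
    category: str | None = None
    gene_id: str | None = None

    def __post_init__(self):
        if not (self.start <= self.peak < self.end):
            raise ValueError("peak must lie within the cluster span")
        if self.peak_value <= 0 or self.score < self.peak_value:
            raise ValueError("require score >= peak_value > 0")

    @property
    def uid(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end};{self.strand}"


def cluster_unidirectional(pooled: PooledTrack, config: ClusterConfig | None = None) -> list[TagCluster]:
    """Call TCs on each strand of the pooled track by slice-reduce.

    Surviving positions with gaps (bps strictly between consecutive
    survivors) of at most ``merge_distance`` form one cluster spanning
    first to last survivor.  Peak ties break to the smallest coordinate;
    the score sums surviving positions only (sub-threshold bps inside the
    span contribute nothing).
    """
    config = config or ClusterConfig()
    clusters: list[TagCluster] = []
    for strand in ("+", "-"):
        track = pooled.strand_track(strand)
        for chrom in track.chroms:
            pos, val = track.arrays(chrom)
            keep = val >= config.slice_threshold
            pos, val = pos[keep], val[keep]
            if pos.size == 0:
                continue
            # gap between consecutive survivors = pos[i+1] - pos[i] - 1
            breaks = np.nonzero(np.diff(pos) - 1 > config.merge_distance)[0] + 1
            for seg_pos, seg_val in zip(np.split(pos, breaks), np.split(val, breaks)):
                peak_idx = int(np.argmax(seg_val))  # argmax takes first on ties
                clusters.append(
                    TagCluster(
                        chrom=chrom,
                        start=int(seg_pos[0]),
                        end=int(seg_pos[-1]) + 1,
                        strand=strand,
                        peak=int(seg_pos[peak_idx]),
                        score=float(seg_val.sum()),
                        peak_value=float(seg_val[peak_idx]),
                    )
                )
    clusters.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
    return clusters


def tc_pipeline(
    dataset: CTSSDataset,
    config: ClusterConfig | None = None,
    min_tpm: float = 1.0,
    min_samples: int = 2,
    strict: bool = True,
) -> tuple[list[TagCluster], ExpressionMatrix]:
    """Pooled-signal TC calling plus per-sample quantification and filtering.

    TCs are called on the pooled TPM signal, quantified same-strand with
    raw counts, and kept only when expressed above ``min_tpm`` (TPM layer)
    in at least ``min_samples`` samples.
    """
    sizes = library_sizes(dataset)
    pooled = pool(normalize_tpm(dataset))
    clusters = cluster_unidirectional(pooled, config)
    matrix = quantify_ranges(dataset, clusters, strand_mode="same-strand").add_tpm(sizes)
    keep = feature_support(matrix, min_value=min_tpm, min_samples=min_samples, use_tpm=True, strict=strict)
    kept_ids = set(keep[keep].index)
    clusters = [c for c in clusters if c.uid in kept_ids]
    return clusters, matrix.subset([c.uid for c in clusters])
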