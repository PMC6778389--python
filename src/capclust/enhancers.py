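"""Bidirectional cluster (BC) calling — enhancer candidate prediction.

Active enhancers transcribe unstable eRNAs divergently: minus-strand
initiation just upstream and plus-strand initiation just downstream of the
enhancer midpoint.  For each candidate midpoint m the pooled signal is
summed over four windowed arms (window w, default 200 bp):

    PU = plus  strand over [m-w, m)      (upstream,   "wrong" side)
    PD = plus  strand over [m, m+w]      (downstream, divergent side)
    MD = minus strand over [m-w, m]      (downstream in minus terms)
    MU = minus strand over (m, m+w]      (upstream,   "wrong" side)

The balance score is the Bhattacharyya coefficient between the observed
arm fractions and the ideal perfectly-divergent distribution
(0, 1/2, 0, 1/2):

    balance(m) = sqrt(fPD / 2) + sqrt(fMD / 2),   f = arms / total

It is 1 exactly when PD = MD and PU = MU = 0, and at most sqrt(1/2) when
either divergent arm is empty — so purely unidirectional signal can never
pass a cutoff above ~0.707.  BCs are called slice-reduce style on the
balance track, exactly like tag clusters are called on the pooled signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal import ExpressionMatrix, feature_support, quantify_ranges
from .tracks import CTSSDataset, PooledTrack

SINGLE_ARM_BOUND = math.sqrt(0.5)


@dataclass
class ArmSums:
    """Windowed strand-specific sums around a candidate midpoint."""

    midpoint: int
    window: int
    pu: float
    pd: float
    md: float
    mu: float

    @property
    def total(self) -> float:
        return self.pu + self.pd + self.md + self.mu


@dataclass
class BalanceConfig:
    """Balance-scoring and BC-merging parameters.

    window
        arm length w in bp (default 200).
    cutoff
        minimum balance score for a midpoint to seed a BC (default 0.95).
    merge_gap
        maximum gap between passing midpoints merged into one BC;
        defaults to ``window``, the natural length scale of one locus.
    """

    window: int = 200
    cutoff: float = 0.95
    merge_gap: int | None = None

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not (0 < self.cutoff <= 1):
            raise ValueError("cutoff must be in (0, 1]")
        if self.merge_gap is None:
            self.merge_gap = self.window
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclass
class BidirectionalCluster:
    """Unstranded divergent-transcription locus (0-based half-open span)."""

    chrom: str
    start: int
    end: int
    maxpos: int
    balance: float
    score: float
    category: str | None = None

    strand = "."  # quantified over both strands

    def __post_init__(self):
        if not (self.start <= self.maxpos < self.end):
            raise ValueError("maxpos must lie within the span")
        if not (0 <= self.balance <= 1 + 1e-12):
            raise ValueError("balance must be in [0, 1]")

    @property
    def uid(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def peak(self) -> int:
        # alias so shared tooling can treat TCs and BCs uniformly
        return self.maxpos


def balance_score(arms: ArmSums) -> float:
    """Bhattacharyya coefficient against the ideal (0, 1/2, 0, 1/2) arms.

    Raises for zero total signal (the score is undefined there; callers
    skip such midpoints).
    """
    total = arms.total
    if total <= 0:
        raise ValueError("balance score undefined for zero windowed signal")
    return math.sqrt(0.5 * (arms.pd / total)) + math.sqrt(0.5 * (arms.md / total))


def arm_sums(pooled: PooledTrack, chrom: str, midpoint: int, window: int = 200) -> ArmSums:
    """Compute the four windowed arm sums at one midpoint."""
    m, w = midpoint, window
    plus, minus = pooled.plus, pooled.minus
    return ArmSums(
        midpoint=m,
        window=w,
        pu=plus.range_sum(chrom, m - w, m),
        pd=plus.range_sum(chrom, m, m + w + 1),
        md=minus.range_sum(chrom, m - w, m + 1),
        mu=minus.range_sum(chrom, m + 1, m + w + 1),
    )


# ---------------------------------------------------------------------------
# interval bookkeeping for candidate midpoints


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int]]:
    order = np.argsort(starts)
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((int(s), int(e)))
    return merged


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        s, e = max(a[i][0], b[j][0]), min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _candidate_midpoints(pooled: PooledTrack, chrom: str, window: int, skip_single_arm: bool) -> np.ndarray:
    """Midpoints worth scoring on one chromosome.

    With ``skip_single_arm`` only midpoints whose PD and MD arms are both
    nonzero are produced — semantics-preserving for cutoffs above
    sqrt(1/2).  Otherwise every midpoint with any windowed signal is
    produced.
    """
    w = window
    length = pooled.genome[chrom]
    ppos, _ = pooled.plus.arrays(chrom)
    mpos, _ = pooled.minus.arrays(chrom)
    if skip_single_arm:
        if ppos.size == 0 or mpos.size == 0:
            return np.empty(0, dtype=np.int64)
        # PD > 0 for m in [p - w, p]; MD > 0 for m in [q, q + w]
        pd_cov = _merge_intervals(ppos - w, ppos + 1)
        md_cov = _merge_intervals(mpos, mpos + w + 1)
        spans = _intersect(pd_cov, md_cov)
    else:
        allpos = np.concatenate([ppos, mpos])
        if allpos.size == 0:
            return np.empty(0, dtype=np.int64)
        spans = _merge_intervals(allpos - w, allpos + w + 1)
    parts = [np.arange(max(0, s), min(length, e), dtype=np.int64) for s, e in spans]
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


def _windowed_arms(pooled: PooledTrack, chrom: str, mids: np.ndarray, window: int):
    """Vectorized (PU, PD, MD, MU) arm sums at many midpoints."""
    w = window
    out = []
    for strand, (lo_off, hi_off_a, hi_off_b) in (
        ("+", (-w, 0, w + 1)),  # PU: [m-w, m), PD: [m, m+w]
        ("-", (-w, 1, w + 1)),  # MD: [m-w, m], MU: (m, m+w]
    ):
        pos, val = pooled.strand_track(strand).arrays(chrom)
        csum = np.concatenate([[0.0], np.cumsum(val)])

        def seg(a, b):
            return csum[np.searchsorted(pos, b, side="left")] - csum[
                np.searchsorted(pos, a, side="left")
            ]

        first = seg(mids + lo_off, mids + hi_off_a)
        second = seg(mids + hi_off_a, mids + hi_off_b)
        out.append((first, second))
    (pu, pd_), (md, mu) = out
    return pu, pd_, md, mu


def balance_track(
    pooled: PooledTrack, config: BalanceConfig | None = None, skip_single_arm: bool = False
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-bp balance scores: chrom -> (positions, balance values).

    By default every midpoint with nonzero windowed signal is scored.
    ``skip_single_arm=True`` scores only midpoints with signal on both
    divergent arms; all skipped midpoints have balance <= sqrt(1/2), so
    this is lossless for any cutoff above that bound.
    """
    config = config or BalanceConfig()
    result: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in sorted(set(pooled.plus.chroms) | set(pooled.minus.chroms)):
        mids = _candidate_midpoints(pooled, chrom, config.window, skip_single_arm)
        if mids.size == 0:
            continue
        pu, pd_, md, mu = _windowed_arms(pooled, chrom, mids, config.window)
        total = pu + pd_ + md + mu
        ok = total > 0
        mids, pd_, md, total = mids[ok], pd_[ok], md[ok], total[ok]
        if mids.size == 0:
            continue
        balance = np.sqrt(0.5 * pd_ / total) + np.sqrt(0.5 * md / total)
        result[chrom] = (mids, balance)
    return result


def cluster_bidirectional(
    pooled: PooledTrack, config: BalanceConfig | None = None
) -> list[BidirectionalCluster]:
    """Call BCs: slice the balance track at the cutoff, reduce nearby runs.

    Midpoints with balance >= cutoff are merged when separated by gaps of
    at most ``merge_gap``; each run becomes a BC spanning first passing bp
    - w to last passing bp + w (clipped to the chromosome), anchored at
    the maximum-balance position (leftmost on ties) and scored as the
    pooled signal over both strands across the span.
    """
    config = config or BalanceConfig()
    skip = config.cutoff > SINGLE_ARM_BOUND
    track = balance_track(pooled, config, skip_single_arm=skip)
    w = config.window
    clusters: list[BidirectionalCluster] = []
    for chrom, (mids, balance) in track.items():
        keep = balance >= config.cutoff
        mids_k, bal_k = mids[keep], balance[keep]
        if mids_k.size == 0:
            continue
        length = pooled.genome[chrom]
        breaks = np.nonzero(np.diff(mids_k) - 1 > config.merge_gap)[0] + 1
        for seg_pos, seg_bal in zip(np.split(mids_k, breaks), np.split(bal_k, breaks)):
            start = max(0, int(seg_pos[0]) - w)
            end = min(length, int(seg_pos[-1]) + w + 1)
            max_idx = int(np.argmax(seg_bal))
            score = pooled.plus.range_sum(chrom, start, end) + pooled.minus.range_sum(chrom, start, end)
            clusters.append(
                BidirectionalCluster(
                    chrom=chrom,
                    start=start,
                    end=end,
                    maxpos=int(seg_pos[max_idx]),
                    balance=float(seg_bal[max_idx]),
                    score=float(score),
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.start, c.end))
    return clusters


def bc_pipeline(
    dataset: CTSSDataset,
    config: BalanceConfig | None = None,
    min_count: float = 1,
    min_samples: int = 1,
) -> tuple[list[BidirectionalCluster], ExpressionMatrix]:
    """BC calling plus both-strand quantification and tag-support filtering.

    Support uses the raw-count layer with >= semantics (">= 1 tag in N
    samples"), matching how enhancer candidates are typically thresholded.
    """
    from .signal import normalize_tpm, pool  # local import avoids cycle at module load

    pooled = pool(normalize_tpm(dataset))
    clusters = cluster_bidirectional(pooled, config)
    matrix = quantify_ranges(dataset, clusters, strand_mode="both-strands")
    keep = feature_support(matrix, min_value=min_count, min_samples=min_samples, use_tpm=False, strict=False)
    kept_ids = set(keep[keep].index)
    clusters = [c for c in clusters if c.uid in kept_ids]
    return clusters, matrix.subset([c.uid for c in clusters])
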