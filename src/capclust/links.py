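"""Enhancer-TSS co-expression links and enhancer stretches.

Linking enhancers to target promoters from expression alone rests on the
assumption that a true enhancer-promoter pair is co-expressed across
samples.  Every (TC, enhancer) pair within a distance window (default
10 kbp, peak to max-balance position) is scored with a rank correlation
across samples — Kendall's tau-b by default, since count matrices are
tie-rich — and p-values are Benjamini-Hochberg adjusted across all tested
pairs.  Positively correlated links are the biologically interpretable
hypothesis set.

Enhancer "stretches" (the super-enhancer analogue for 5'-end data) are
single-linkage chains of enhancer candidates with edge-to-edge gaps below
12.5 kbp; the average pairwise expression correlation of members summarizes
whether a stretch behaves as one coordinated unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signal import ExpressionMatrix


@dataclass
class LinkConfig:
    max_distance: int = 10_000
    method: str = "kendall"  # kendall | pearson | spearman | custom
    fdr: float = 0.05
    custom_fn: Callable[[np.ndarray, np.ndarray], tuple[float, float]] | None = None

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if self.method not in ("kendall", "pearson", "spearman", "custom"):
            raise ValueError(f"unknown correlation method {self.method!r}")
        if self.method == "custom" and self.custom_fn is None:
            raise ValueError("method 'custom' requires custom_fn")


def _corr_fn(config: LinkConfig) -> Callable[[np.ndarray, np.ndarray], tuple[float, float]]:
    if config.method == "kendall":
        return lambda x, y: tuple(stats.kendalltau(x, y))  # tau-b, exact p for small tie-free n
    if config.method == "pearson":
        return lambda x, y: tuple(stats.pearsonr(x, y))
    if config.method == "spearman":
        return lambda x, y: tuple(stats.spearmanr(x, y))
    return config.custom_fn


def candidate_pairs(tcs, enhancers, config: LinkConfig | None = None) -> list[tuple]:
    """All same-chromosome (TC, enhancer) pairs within the distance window.

    Distance is enhancer max-balance position minus TC peak (signed).
    """
    config = config or LinkConfig()
    by_chrom: dict[str, list] = {}
    for tc in tcs:
        by_chrom.setdefault(tc.chrom, []).append(tc)
    pairs = []
    for enh in enhancers:
        for tc in by_chrom.get(enh.chrom, []):
            if abs(enh.maxpos - tc.peak) <= config.max_distance:
                pairs.append((tc, enh))
    return pairs


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate_links(
    pairs,
    tc_matrix: ExpressionMatrix,
    enh_matrix: ExpressionMatrix,
    config: LinkConfig | None = None,
    use_tpm: bool = False,
) -> pd.DataFrame:
    """Correlation, p-value and BH-adjusted p for every candidate pair.

    Returns a table with columns tc_id, enhancer_id, distance, estimate,
    pvalue, padj.  Pairs with a constant expression vector (correlation
    undefined) are dropped with a warning.  BH adjustment runs across all
    computed pairs; filtering to positive links happens downstream.
    """
    config = config or LinkConfig()
    if tc_matrix.sample_ids != enh_matrix.sample_ids:
        raise ValueError("TC and enhancer matrices must share sample order")
    fn = _corr_fn(config)
    tc_layer = tc_matrix.tpm if use_tpm else tc_matrix.counts
    enh_layer = enh_matrix.tpm if use_tpm else enh_matrix.counts
    if tc_layer is None or enh_layer is None:
        raise ValueError("requested TPM layer not attached")
    rows = []
    n_constant = 0
    for tc, enh in pairs:
        x = tc_layer.loc[tc.uid].to_numpy(dtype=float)
        y = enh_layer.loc[enh.uid].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            n_constant += 1
            continue
        est, p = fn(x, y)
        rows.append((tc.uid, enh.uid, int(enh.maxpos - tc.peak), float(est), float(p)))
    if n_constant:
        warnings.warn(f"dropped {n_constant} pair(s) with constant expression")
    links = pd.DataFrame(rows, columns=["tc_id", "enhancer_id", "distance", "estimate", "pvalue"])
    links["padj"] = bh_adjust(links["pvalue"].to_numpy()) if len(links) else []
    return links


def significant_links(links: pd.DataFrame, fdr: float = 0.05, positive_only: bool = True) -> pd.DataFrame:
    """Links passing the FDR level, optionally restricted to estimate > 0."""
    out = links[links["padj"] < fdr]
    if positive_only:
        out = out[out["estimate"] > 0]
    return out


@dataclass
class Stretch:
    """Chain of nearby enhancer candidates ("super enhancer")."""

    chrom: str
    start: int
    end: int
    members: list[str] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def uid(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def find_stretches(enhancers, merge_distance: int = 12_500, min_members: int = 4) -> list[Stretch]:
    """Single-linkage chaining of enhancers with edge-to-edge gaps < merge_distance.

    Chains with at least ``min_members`` members become stretches spanning
    the first member's start to the last member's end.
    """
    if merge_distance <= 0 or min_members < 1:
        raise ValueError("merge_distance must be > 0 and min_members >= 1")
    by_chrom: dict[str, list] = {}
    for enh in enhancers:
        by_chrom.setdefault(enh.chrom, []).append(enh)
    stretches = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda e: (e.start, e.end))
        chain = [members[0]]
        for enh in members[1:]:
            gap = enh.start - chain[-1].end
            if gap < merge_distance:
                chain.append(enh)
            else:
                if len(chain) >= min_members:
                    stretches.append(
                        Stretch(chrom, chain[0].start, chain[-1].end, [e.uid for e in chain])
                    )
                chain = [enh]
        if len(chain) >= min_members:
            stretches.append(Stretch(chrom, chain[0].start, chain[-1].end, [e.uid for e in chain]))
    return stretches


def stretch_correlations(
    stretches: list[Stretch],
    enh_matrix: ExpressionMatrix,
    config: LinkConfig | None = None,
    use_tpm: bool = False,
) -> pd.Series:
    """Average pairwise expression correlation among each stretch's members.

    Concordant members indicate joint activity.  A stretch with a single
    quantified member has no pairs and is reported as NaN.
    """
    config = config or LinkConfig()
    fn = _corr_fn(config)
    layer = enh_matrix.tpm if use_tpm else enh_matrix.counts
    if layer is None:
        raise ValueError("requested TPM layer not attached")
    out = {}
    for st in stretches:
        vals = []
        for a, b in combinations(st.members, 2):
            x = layer.loc[a].to_numpy(dtype=float)
            y = layer.loc[b].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            vals.append(fn(x, y)[0])
        out[st.uid] = float(np.mean(vals)) if vals else float("nan")
    return pd.Series(out, dtype=float)
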