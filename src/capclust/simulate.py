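"""Synthetic multi-sample CTSS datasets with known ground truth.

The generator emulates the signal structure of 5'-end data at the level the
clustering operates on: sparse stranded per-bp counts containing

* sharp TCs — initiation concentrated within a couple of bp of a summit,
* broad TCs — a summit plus a 40-100 bp shoulder of minor CTSSs,
* enhancers — divergent loci emitting minus-strand tags upstream and
  plus-strand tags just downstream of a midpoint, split near 50/50,
* background noise — sparse Poisson singletons, and
* optional transcript models wrapping the planted TCs.

Each feature owns a FIXED set of CTSS positions with fixed weights, drawn
once from the seed; per-sample tag totals are negative-binomial
(overdispersed, like biological replicates) and are distributed over the
positions multinomially.  Real CTSSs recur at the same bp across libraries,
and this is what lets single-library support filtering work; per-sample
random offsets would not survive it.  Designated TC-enhancer pairs share a
latent log-normal activity factor, giving co-expressed links to recover.

Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import Transcript, TranscriptModels
from .tracks import CTSSDataset, GenomeInfo, SparseTrack


@dataclass
class TCSpec:
    chrom: str
    peak: int
    strand: str
    shape: str = "sharp"  # sharp | broad
    mean_expression: float = 50.0

    def __post_init__(self):
        if self.shape not in ("sharp", "broad"):
            raise ValueError(f"unknown TC shape {self.shape!r}")
        if self.mean_expression <= 0:
            raise ValueError("mean_expression must be positive")


@dataclass
class EnhancerSpec:
    chrom: str
    midpoint: int
    mean_expression: float = 50.0
    #: divergent tags fall within this many bp of the midpoint
    max_arm_offset: int = 180

    def __post_init__(self):
        if self.mean_expression <= 0:
            raise ValueError("mean_expression must be positive")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults: 5 samples, mean 50 tags per feature per sample with
    negative-binomial dispersion 0.2, background noise 1e-5 tags per bp
    per strand per sample, latent-activity correlation 0.8 with log-scale
    sd 1.0 for linked pairs.
    """

    seed: int
    n_samples: int = 5
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    tcs: list[TCSpec] = field(default_factory=list)
    enhancers: list[EnhancerSpec] = field(default_factory=list)
    noise_rate: float = 1e-5
    dispersion: float = 0.2
    #: (tc index, enhancer index) pairs sharing a latent activity factor
    linked_pairs: list[tuple[int, int]] = field(default_factory=list)
    latent_rho: float = 0.8
    latent_sigma: float = 1.0
    #: build one transcript per TC; groups of TC indices share a gene
    with_genes: bool = False
    gene_groups: list[list[int]] | None = None

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("need at least one sample")
        if not (0 <= self.latent_rho <= 1):
            raise ValueError("latent_rho must be in [0, 1]")
        genome = GenomeInfo(self.chrom_lengths) if self.chrom_lengths else None
        zones = []
        for i, tc in enumerate(self.tcs):
            if tc.chrom not in genome or not (150 <= tc.peak < genome[tc.chrom] - 150):
                raise ValueError(f"TC {i} outside genome margins")
            zones.append((tc.chrom, tc.peak - 150, tc.peak + 150))
        for i, enh in enumerate(self.enhancers):
            if enh.chrom not in genome or not (250 <= enh.midpoint < genome[enh.chrom] - 250):
                raise ValueError(f"enhancer {i} outside genome margins")
            zones.append((enh.chrom, enh.midpoint - 250, enh.midpoint + 250))
        zones.sort()
        for (c1, s1, e1), (c2, s2, _) in zip(zones, zones[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError("planted features overlap; space them further apart")
        for ti, ei in self.linked_pairs:
            if not (0 <= ti < len(self.tcs) and 0 <= ei < len(self.enhancers)):
                raise ValueError(f"linked pair ({ti}, {ei}) out of range")

    @classmethod
    def random(
        cls,
        seed: int,
        n_samples: int = 5,
        n_sharp: int = 25,
        n_broad: int = 25,
        n_enhancers: int = 20,
        chrom_length: int | None = None,
        spacing: int = 4000,
        mean_expression: float = 50.0,
        noise_rate: float = 1e-5,
        **kwargs,
    ) -> "SimConfig":
        """Place features on a jittered grid along one chromosome."""
        rng = np.random.default_rng(seed)
        n = n_sharp + n_broad + n_enhancers
        if chrom_length is None:
            chrom_length = spacing * (n + 2)
        slots = spacing * (1 + np.arange(n)) + rng.integers(-spacing // 8, spacing // 8, n)
        kinds = ["sharp"] * n_sharp + ["broad"] * n_broad + ["enh"] * n_enhancers
        rng.shuffle(kinds)
        tcs, enhancers = [], []
        for pos, kind in zip(slots.tolist(), kinds):
            if kind == "enh":
                enhancers.append(EnhancerSpec("chr1", pos, mean_expression))
            else:
                strand = "+" if rng.random() < 0.5 else "-"
                tcs.append(TCSpec("chr1", pos, strand, kind, mean_expression))
        return cls(
            seed=seed,
            n_samples=n_samples,
            chrom_lengths={"chr1": int(chrom_length)},
            tcs=tcs,
            enhancers=enhancers,
            noise_rate=noise_rate,
            **kwargs,
        )


def linked_blocks_config(
    seed: int,
    n_samples: int = 50,
    n_blocks: int = 25,
    block_span: int = 25_000,
    pair_distance: int = 3_000,
    mean_expression: float = 50.0,
    latent_rho: float = 0.8,
    latent_sigma: float = 1.0,
    noise_rate: float = 1e-5,
) -> SimConfig:
    """Layout for co-expression link experiments.

    Each block holds a linked TC-enhancer pair ``pair_distance`` apart
    plus an unlinked TC and an unlinked enhancer, all within the usual
    10 kbp pairing window, so candidate pairs split into genuinely
    co-expressed (latent-activity-sharing) and independent ones.  Blocks
    are spaced so pairs never straddle blocks.
    """
    tcs, enhancers, linked = [], [], []
    for b in range(n_blocks):
        base = b * block_span + 2_000
        tcs.append(TCSpec("chr1", base, "+", "sharp", mean_expression))
        enhancers.append(EnhancerSpec("chr1", base + pair_distance, mean_expression))
        linked.append((2 * b, 2 * b))
        tcs.append(TCSpec("chr1", base + 6_000, "-", "sharp", mean_expression))
        enhancers.append(EnhancerSpec("chr1", base + 9_000, mean_expression))
    return SimConfig(
        seed=seed,
        n_samples=n_samples,
        chrom_lengths={"chr1": n_blocks * block_span + 2_000},
        tcs=tcs,
        enhancers=enhancers,
        linked_pairs=linked,
        latent_rho=latent_rho,
        latent_sigma=latent_sigma,
        noise_rate=noise_rate,
    )


@dataclass
class TruthRecord:
    feature_id: str
    kind: str  # tc | enhancer
    chrom: str
    start: int
    end: int
    anchor: int  # true peak (TC) or midpoint (enhancer)
    strand: str
    shape: str | None = None
    gene_id: str | None = None
    partner_id: str | None = None


@dataclass
class SimTruth:
    records: list[TruthRecord]

    @property
    def tcs(self) -> list[TruthRecord]:
        return [r for r in self.records if r.kind == "tc"]

    @property
    def enhancers(self) -> list[TruthRecord]:
        return [r for r in self.records if r.kind == "enhancer"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records]).set_index("feature_id")

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _tc_profile(spec: TCSpec, rng: np.random.Generator):
    """Fixed (positions, weights, start, end) for one planted TC."""
    if spec.shape == "sharp":
        offsets = np.arange(-2, 3)
        weights = np.array([0.02, 0.08, 0.80, 0.08, 0.02])
    else:
        width = int(rng.integers(40, 101))
        half = width // 2
        offsets = np.arange(-half, half + 1)
        shoulder = np.exp(-0.5 * (offsets / (width / 4.0)) ** 2)
        shoulder[half] = 0.0
        shoulder *= 0.7 / shoulder.sum()
        weights = shoulder.copy()
        weights[half] = 0.3  # dominant summit keeps the true peak identifiable
    positions = spec.peak + offsets
    return positions, weights, int(positions[0]), int(positions[-1]) + 1


def _enhancer_profile(spec: EnhancerSpec, rng: np.random.Generator):
    """Fixed divergent CTSS positions/weights for one planted enhancer."""
    def arm():
        # the innermost CTSS sits close to the midpoint (as eRNA TSSs flank
        # the nucleosome-free region), the rest spread over the arm
        k = int(rng.integers(3, 7))
        near = rng.integers(10, 46, size=1)
        far = rng.choice(np.arange(10, spec.max_arm_offset + 1), size=k - 1, replace=False)
        offsets = np.unique(np.concatenate([near, far]))
        w = rng.dirichlet(np.full(offsets.size, 2.0))
        return offsets, w

    plus_off, plus_w = arm()
    minus_off, minus_w = arm()
    plus_pos = spec.midpoint + plus_off
    minus_pos = spec.midpoint - minus_off
    return (plus_pos, plus_w), (minus_pos, minus_w)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_dataset(config: SimConfig) -> tuple[CTSSDataset, TranscriptModels | None, SimTruth]:
    """Generate the dataset, optional gene models and the truth table."""
    rng = np.random.default_rng(config.seed)
    genome = GenomeInfo(config.chrom_lengths)
    sample_ids = [f"sample{j + 1}" for j in range(config.n_samples)]

    # fixed per-feature CTSS profiles
    tc_profiles = [_tc_profile(spec, rng) for spec in config.tcs]
    enh_profiles = [_enhancer_profile(spec, rng) for spec in config.enhancers]

    # latent activity factors (log-normal), shared within linked pairs
    tc_factor = np.ones((len(config.tcs), config.n_samples))
    enh_factor = np.ones((len(config.enhancers), config.n_samples))
    sigma, rho = config.latent_sigma, config.latent_rho
    for ti, ei in config.linked_pairs:
        z = rng.standard_normal(config.n_samples)
        eps = rng.standard_normal(config.n_samples)
        z_enh = rho * z + np.sqrt(1 - rho**2) * eps
        tc_factor[ti] = np.exp(sigma * z - 0.5 * sigma**2)
        enh_factor[ei] = np.exp(sigma * z_enh - 0.5 * sigma**2)

    # accumulate per (sample, strand, chrom) position/count fragments
    frags: dict[tuple[str, str, str], list] = {}

    def add(sample, strand, chrom, positions, counts):
        counts = np.asarray(counts)
        keep = counts > 0
        if keep.any():
            frags.setdefault((sample, strand, chrom), []).append(
                (np.asarray(positions)[keep], counts[keep])
            )

    for i, spec in enumerate(config.tcs):
        positions, weights, _, _ = tc_profiles[i]
        totals = _nb_counts(rng, spec.mean_expression * tc_factor[i], config.dispersion)
        for j, sid in enumerate(sample_ids):
            if totals[j] > 0:
                add(sid, spec.strand, spec.chrom, positions, rng.multinomial(totals[j], weights))

    for i, spec in enumerate(config.enhancers):
        (ppos, pw), (mpos, mw) = enh_profiles[i]
        totals = _nb_counts(rng, spec.mean_expression * enh_factor[i], config.dispersion)
        for j, sid in enumerate(sample_ids):
            if totals[j] == 0:
                continue
            n_plus = rng.binomial(totals[j], 0.5)
            if n_plus > 0:
                add(sid, "+", spec.chrom, ppos, rng.multinomial(n_plus, pw))
            if totals[j] - n_plus > 0:
                add(sid, "-", spec.chrom, mpos, rng.multinomial(totals[j] - n_plus, mw))

    if config.noise_rate > 0:
        for sid in sample_ids:
            for strand in ("+", "-"):
                for chrom, length in genome.items():
                    n = rng.poisson(config.noise_rate * length)
                    if n > 0:
                        pos = rng.integers(0, length, n)
                        upos, cnt = np.unique(pos, return_counts=True)
                        add(sid, strand, chrom, upos, cnt)

    def build_track(sid: str, strand: str) -> SparseTrack:
        track = SparseTrack(strand)
        for (s, st, chrom), parts in frags.items():
            if s != sid or st != strand:
                continue
            allpos = np.concatenate([p for p, _ in parts])
            allcnt = np.concatenate([c for _, c in parts])
            upos, inverse = np.unique(allpos, return_inverse=True)
            summed = np.zeros(upos.size, dtype=np.int64)
            np.add.at(summed, inverse, allcnt)
            track._set(chrom, upos, summed)
        return track

    dataset = CTSSDataset(
        genome,
        sample_ids,
        {sid: build_track(sid, "+") for sid in sample_ids},
        {sid: build_track(sid, "-") for sid in sample_ids},
    )

    # truth table
    records: list[TruthRecord] = []
    partner_of_tc = {ti: ei for ti, ei in config.linked_pairs}
    partner_of_enh = {ei: ti for ti, ei in config.linked_pairs}
    for i, spec in enumerate(config.tcs):
        _, _, start, end = tc_profiles[i]
        records.append(
            TruthRecord(
                feature_id=f"tc{i}",
                kind="tc",
                chrom=spec.chrom,
                start=start,
                end=end,
                anchor=spec.peak,
                strand=spec.strand,
                shape=spec.shape,
                partner_id=f"enh{partner_of_tc[i]}" if i in partner_of_tc else None,
            )
        )
    for i, spec in enumerate(config.enhancers):
        records.append(
            TruthRecord(
                feature_id=f"enh{i}",
                kind="enhancer",
                chrom=spec.chrom,
                start=spec.midpoint - spec.max_arm_offset,
                end=spec.midpoint + spec.max_arm_offset + 1,
                anchor=spec.midpoint,
                strand=".",
                partner_id=f"tc{partner_of_enh[i]}" if i in partner_of_enh else None,
            )
        )

    models = None
    if config.with_genes and config.tcs:
        groups = config.gene_groups or [[i] for i in range(len(config.tcs))]
        seen = [i for grp in groups for i in grp]
        if len(seen) != len(set(seen)):
            raise ValueError("gene_groups must not repeat TC indices")
        transcripts = []
        for g, grp in enumerate(groups):
            gene_id = f"gene{g}"
            for i in grp:
                spec = config.tcs[i]
                if spec.strand == "+":
                    exon = (spec.peak, min(genome[spec.chrom], spec.peak + 500))
                else:
                    exon = (max(0, spec.peak - 499), spec.peak + 1)
                transcripts.append(
                    Transcript(f"tx{i}", gene_id, spec.chrom, spec.strand, [exon])
                )
                records[i].gene_id = gene_id
        models = TranscriptModels(transcripts)

    return dataset, models, SimTruth(records)


def match_to_truth(
    called,
    truth: SimTruth,
    kind: str = "tc",
    anchor_tolerance: int | None = None,
) -> dict[str, str]:
    """Map called-feature uid -> planted feature id (same criteria as
    :func:`evaluate_recovery`); calls matching nothing are absent."""
    if anchor_tolerance is None:
        anchor_tolerance = 5 if kind == "tc" else 50
    records = truth.tcs if kind == "tc" else truth.enhancers
    taken: set[str] = set()
    mapping: dict[str, str] = {}
    for t in records:
        for c in called:
            if c.uid in taken or c.chrom != t.chrom:
                continue
            anchor = c.peak if kind == "tc" else c.maxpos
            if c.start < t.end and t.start < c.end and abs(anchor - t.anchor) <= anchor_tolerance:
                mapping[c.uid] = t.feature_id
                taken.add(c.uid)
                break
    return mapping


def evaluate_recovery(
    called,
    truth: SimTruth,
    kind: str = "tc",
    anchor_tolerance: int | None = None,
) -> dict:
    """Precision/recall of called features against planted truth.

    A call matches a truth record when their intervals overlap and the
    call's anchor (TC peak / BC max-balance position) lies within the
    tolerance of the true anchor: 5 bp for TCs, 50 bp for enhancers —
    stricter than the default merge distances, so matching is unambiguous.
    """
    if anchor_tolerance is None:
        anchor_tolerance = 5 if kind == "tc" else 50
    truth_records = truth.tcs if kind == "tc" else truth.enhancers
    matched_truth: set[str] = set()
    matched_called: set[int] = set()
    distances = []
    for t in truth_records:
        for i, c in enumerate(called):
            if i in matched_called or c.chrom != t.chrom:
                continue
            anchor = c.peak if kind == "tc" else c.maxpos
            if c.start < t.end and t.start < c.end and abs(anchor - t.anchor) <= anchor_tolerance:
                matched_truth.add(t.feature_id)
                matched_called.add(i)
                distances.append(abs(anchor - t.anchor))
                break
    n_called, n_truth = len(called), len(truth_records)
    return {
        "n_called": n_called,
        "n_truth": n_truth,
        "n_matched": len(matched_truth),
        "precision": len(matched_called) / n_called if n_called else float("nan"),
        "recall": len(matched_truth) / n_truth if n_truth else float("nan"),
        "anchor_distances": distances,
    }
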