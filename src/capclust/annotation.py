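"""Hierarchical annotation against transcript models and gene-level analysis.

A de-novo cluster can sit in several transcript contexts at once — an
annotated promoter of one isoform is often inside the 5'UTR or intron of
another isoform of the same gene.  Annotation therefore tests the cluster's
peak position against every transcript and assigns the highest-priority
matching category, on the reasoning that a cluster is more likely to be an
annotated promoter than a novel intragenic one.  The default priority order
is

    promoter > proximal > fiveUTR > threeUTR > CDS > exon > intron
             > antisense > intergenic

with promoter = within +-100 bp of an annotated TSS and proximal = up to
1000 bp upstream of one (both user-modifiable).  Stranded clusters match
same-strand transcripts; "antisense" means the peak overlaps transcripts on
the opposite strand only.  Unstranded bidirectional clusters match either
strand and can never be antisense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .signal import ExpressionMatrix

DEFAULT_CATEGORIES = [
    "promoter",
    "proximal",
    "fiveUTR",
    "threeUTR",
    "CDS",
    "exon",
    "intron",
    "antisense",
    "intergenic",
]


@dataclass
class CategoryConfig:
    categories: list[str] = field(default_factory=lambda: list(DEFAULT_CATEGORIES))
    #: peak within this many bp of an annotated TSS counts as promoter
    promoter_radius: int = 100
    #: upstream distance (bp) for the promoter-proximal zone and for
    #: extending gene spans when assigning TCs to genes
    proximal_distance: int = 1000

    def __post_init__(self):
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("duplicate categories")
        if self.promoter_radius < 0 or self.proximal_distance < 0:
            raise ValueError("distances must be >= 0")
        self._rank = {c: i for i, c in enumerate(self.categories)}

    def rank(self, category: str) -> int:
        return self._rank[category]


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in transcript {self.transcript_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (0-based bp position)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1]

    def _utr(self, side: str) -> list[tuple[int, int]]:
        if not self.cds:
            return []
        cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
        five_left = (self.strand == "+") == (side == "5")
        bound = (self.start, cds_lo) if five_left else (cds_hi, self.end)
        out = []
        for s, e in self.exons:
            lo, hi = max(s, bound[0]), min(e, bound[1])
            if lo < hi:
                out.append((lo, hi))
        return out

    @property
    def utr5(self) -> list[tuple[int, int]]:
        return self._utr("5")

    @property
    def utr3(self) -> list[tuple[int, int]]:
        return self._utr("3")


class TranscriptModels:
    """Indexed transcript/gene structures for annotation queries."""

    def __init__(self, transcripts: list[Transcript]):
        ids = [t.transcript_id for t in transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transcript ids")
        self.transcripts = {t.transcript_id: t for t in transcripts}
        self.genes: dict[str, list[str]] = {}
        for t in transcripts:
            self.genes.setdefault(t.gene_id, []).append(t.transcript_id)

    def gene_transcripts(self, gene_id: str) -> list[Transcript]:
        return [self.transcripts[tid] for tid in self.genes[gene_id]]

    def __len__(self) -> int:
        return len(self.transcripts)

    def write_gtf(self, path) -> None:
        """Write exon/CDS features (1-based inclusive GTF coordinates)."""
        with open(path, "w") as fh:
            for t in self.transcripts.values():
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                for s, e in t.exons:
                    fh.write(f"{t.chrom}\tcapclust\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n")
                for s, e in t.cds:
                    fh.write(f"{t.chrom}\tcapclust\tCDS\t{s + 1}\t{e}\t0\t{t.strand}\t0\t{attrs}\n")


def _feature_ids(feature):
    attrs = feature.attributes
    tid = attrs.get("transcript_id", attrs.get("Parent", [None]))[0]
    gid = attrs.get("gene_id", [None])[0]
    return tid, gid


def load_models(gtf_path) -> TranscriptModels:
    """Load transcript models from GTF/GFF3 (exon and CDS features).

    1-based inclusive file coordinates become 0-based half-open internally.
    Every exon/CDS must carry a transcript id (``transcript_id`` or
    ``Parent``) and a ``gene_id``.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, dict] = {}
    for ftype in ("exon", "CDS"):
        for f in db.features_of_type(ftype):
            tid, gid = _feature_ids(f)
            if tid is None or gid is None:
                raise ValueError(f"{ftype} feature without transcript/gene id: {f}")
            if f.start < 1 or f.end < f.start:
                raise ValueError(f"malformed coordinates in {ftype} {tid}: {f.start}-{f.end}")
            rec = exons.setdefault(tid, {"gene": gid, "chrom": f.seqid, "strand": f.strand, "exon": [], "CDS": []})
            rec[ftype].append((f.start - 1, f.end))
    transcripts = [
        Transcript(tid, rec["gene"], rec["chrom"], rec["strand"], rec["exon"], rec["CDS"])
        for tid, rec in exons.items()
        if rec["exon"]
    ]
    if not transcripts:
        raise ValueError(f"no transcripts with exons found in {gtf_path}")
    return TranscriptModels(transcripts)


# ---------------------------------------------------------------------------
# annotation index


class _Annotator:
    """Point-query interval indexes derived from models + config."""

    def __init__(self, models: TranscriptModels, config: CategoryConfig):
        self.config = config
        self.category_trees: dict[str, IntervalTree] = {}
        self.span_trees: dict[str, IntervalTree] = {}
        self.exon_trees: dict[str, IntervalTree] = {}
        self.tss_zone_trees: dict[str, IntervalTree] = {}
        R, D = config.promoter_radius, config.proximal_distance
        for t in models.transcripts.values():
            cat_regions: list[tuple[str, int, int]] = [("promoter", t.tss - R, t.tss + R + 1)]
            if t.strand == "+":
                cat_regions.append(("proximal", t.tss - D, t.tss))
            else:
                cat_regions.append(("proximal", t.tss + 1, t.tss + D + 1))
            cat_regions += [("fiveUTR", s, e) for s, e in t.utr5]
            cat_regions += [("threeUTR", s, e) for s, e in t.utr3]
            cat_regions += [("CDS", s, e) for s, e in t.cds]
            cat_regions += [("exon", s, e) for s, e in t.exons]
            cat_regions += [("intron", s, e) for s, e in t.introns]
            ctree = self.category_trees.setdefault(t.chrom, IntervalTree())
            for cat, s, e in cat_regions:
                if cat in self.config._rank and s < e:
                    ctree.addi(s, e, (cat, t.strand))
            self.span_trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t.strand)
            etree = self.exon_trees.setdefault(t.chrom, IntervalTree())
            for s, e in t.exons:
                etree.addi(s, e, t.strand)
            # promoter/proximal TSS zone used for enhancer-candidate filtering
            zs = t.tss - D if t.strand == "+" else t.tss - R
            ze = t.tss + R + 1 if t.strand == "+" else t.tss + D + 1
            self.tss_zone_trees.setdefault(t.chrom, IntervalTree()).addi(zs, ze, t.strand)

    def categorize(self, chrom: str, point: int, strand: str) -> str:
        hits = self.category_trees.get(chrom, IntervalTree())[point]
        span_hits = self.span_trees.get(chrom, IntervalTree())[point]
        stranded = strand in ("+", "-")
        candidates = set()
        for iv in hits:
            cat, tx_strand = iv.data
            if not stranded or tx_strand == strand:
                candidates.add(cat)
        if stranded and "antisense" in self.config._rank:
            same = any(iv.data == strand for iv in span_hits)
            opposite = any(iv.data != strand for iv in span_hits)
            if opposite and not same:
                candidates.add("antisense")
        if not candidates:
            return "intergenic"
        return min(candidates, key=self.config.rank)

    def span_overlaps_exon(self, chrom: str, start: int, end: int) -> bool:
        return bool(self.exon_trees.get(chrom, IntervalTree()).overlap(start, end))

    def span_overlaps_tss_zone(self, chrom: str, start: int, end: int) -> bool:
        return bool(self.tss_zone_trees.get(chrom, IntervalTree()).overlap(start, end))


def annotate_clusters(clusters, models: TranscriptModels, config: CategoryConfig | None = None) -> list[str]:
    """Assign one category per cluster (anchored at its peak/maxpos).

    Sets ``cluster.category`` in place and returns the category list in
    cluster order.  Total and deterministic: every cluster gets exactly
    one of the configured categories.
    """
    config = config or CategoryConfig()
    annotator = _Annotator(models, config)
    out = []
    for c in clusters:
        cat = annotator.categorize(c.chrom, c.peak, getattr(c, "strand", "."))
        c.category = cat
        out.append(cat)
    return out


def select_enhancer_candidates(bcs, models: TranscriptModels, config: CategoryConfig | None = None):
    """Filter BCs down to enhancer candidates.

    Bidirectional signal also occurs at divergent gene promoters, so only
    BCs annotated intronic or intergenic are kept, and any BC whose span
    overlaps exonic sequence or the promoter/proximal zone around an
    annotated TSS is dropped (span-based, since exon contamination is a
    property of the whole quantified region, not just the midpoint).
    """
    config = config or CategoryConfig()
    annotator = _Annotator(models, config)
    kept = []
    for bc in bcs:
        category = annotator.categorize(bc.chrom, bc.maxpos, ".")
        if category not in ("intron", "intergenic"):
            continue
        if annotator.span_overlaps_exon(bc.chrom, bc.start, bc.end):
            continue
        if annotator.span_overlaps_tss_zone(bc.chrom, bc.start, bc.end):
            continue
        bc.category = category
        kept.append(bc)
    return kept


# ---------------------------------------------------------------------------
# gene-level analysis


@dataclass
class GeneAssignment:
    """cluster id -> gene id (or None for unassigned)."""

    mapping: dict[str, str | None]

    def assigned(self) -> dict[str, str]:
        return {cid: g for cid, g in self.mapping.items() if g is not None}

    def composition(self, matrix: ExpressionMatrix) -> pd.DataFrame:
        """Per-sample fraction each cluster contributes to its gene's total.

        NaN where the gene total is zero in a sample (fraction undefined)
        or for unassigned clusters.
        """
        frac = pd.DataFrame(np.nan, index=matrix.counts.index, columns=matrix.counts.columns)
        by_gene: dict[str, list[str]] = {}
        for cid, gene in self.assigned().items():
            if cid in matrix.counts.index:
                by_gene.setdefault(gene, []).append(cid)
        for gene, cids in by_gene.items():
            totals = matrix.counts.loc[cids].sum(axis=0)
            ratio = matrix.counts.loc[cids].div(totals.replace(0, np.nan), axis=1)
            frac.loc[cids] = ratio
        return frac


def assign_genes(tcs, models: TranscriptModels, config: CategoryConfig | None = None) -> GeneAssignment:
    """Assign each TC to a gene by peak position, same strand.

    A TC belongs to a gene when its peak lies in the gene's span (union of
    the gene's transcripts, extended upstream by the proximal distance).
    Peaks inside several genes go to the gene whose nearest annotated TSS
    is closest; exact ties leave the TC unassigned.
    """
    config = config or CategoryConfig()
    gene_trees: dict[tuple[str, str], IntervalTree] = {}
    gene_tss: dict[str, list[int]] = {}
    for gene_id, tids in models.genes.items():
        txs = [models.transcripts[tid] for tid in tids]
        gene_tss[gene_id] = [t.tss for t in txs]
        for strand in {t.strand for t in txs}:
            sub = [t for t in txs if t.strand == strand]
            start = min(t.start for t in sub)
            end = max(t.end for t in sub)
            if strand == "+":
                start -= config.proximal_distance
            else:
                end += config.proximal_distance
            chrom = sub[0].chrom
            gene_trees.setdefault((chrom, strand), IntervalTree()).addi(start, end, gene_id)
    mapping: dict[str, str | None] = {}
    for tc in tcs:
        hits = gene_trees.get((tc.chrom, tc.strand), IntervalTree())[tc.peak]
        genes = sorted({iv.data for iv in hits})
        if not genes:
            mapping[tc.uid] = None
        elif len(genes) == 1:
            mapping[tc.uid] = genes[0]
        else:
            dists = {g: min(abs(tc.peak - tss) for tss in gene_tss[g]) for g in genes}
            best = min(dists.values())
            winners = [g for g, d in dists.items() if d == best]
            mapping[tc.uid] = winners[0] if len(winners) == 1 else None
    for tc in tcs:
        tc.gene_id = mapping[tc.uid]
    return GeneAssignment(mapping)


def gene_matrix(tc_matrix: ExpressionMatrix, assignment: GeneAssignment) -> ExpressionMatrix:
    """Sum assigned TC counts per gene (unassigned TCs are excluded)."""
    assigned = assignment.assigned()
    cids = [cid for cid in tc_matrix.counts.index if cid in assigned]
    genes = pd.Series({cid: assigned[cid] for cid in cids})
    counts = tc_matrix.counts.loc[cids].groupby(genes).sum()
    feats = tc_matrix.features.loc[cids]
    features = pd.DataFrame(
        {
            "chrom": feats.groupby(genes)["chrom"].first(),
            "start": feats.groupby(genes)["start"].min(),
            "end": feats.groupby(genes)["end"].max(),
            "strand": feats.groupby(genes)["strand"].first(),
        }
    ).loc[counts.index]
    return ExpressionMatrix(features, counts)


def composition_filter(
    tc_matrix: ExpressionMatrix,
    assignment: GeneAssignment,
    min_fraction: float = 0.1,
    min_samples: int = 0,
) -> list[str]:
    """Drop minor alternative TCs within genes.

    A gene-assigned TC is kept when its share of the gene's expression
    exceeds ``min_fraction`` in strictly more than ``min_samples`` samples
    (undefined fractions — zero gene total — count as failing).
    Unassigned TCs are kept unconditionally.
    """
    frac = assignment.composition(tc_matrix)
    kept = []
    for cid in tc_matrix.counts.index:
        if assignment.mapping.get(cid) is None:
            kept.append(cid)
            continue
        n_pass = int((frac.loc[cid] > min_fraction).sum())
        if n_pass > min_samples:
            kept.append(cid)
    return kept


def multi_tc_summary(assignment: GeneAssignment, kept_ids) -> tuple[pd.DataFrame, dict]:
    """Per-gene TC counts before/after composition filtering.

    Returns the table (gene, n TCs, n surviving TCs) and the fraction of
    genes using more than one TC under each.
    """
    kept = set(kept_ids)
    rows: dict[str, dict] = {}
    for cid, gene in assignment.assigned().items():
        rec = rows.setdefault(gene, {"n_tcs": 0, "n_kept": 0})
        rec["n_tcs"] += 1
        rec["n_kept"] += int(cid in kept)
    table = pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id").sort_index()
    summary = {
        "multi_tc_fraction": float((table["n_tcs"] > 1).mean()) if len(table) else 0.0,
        "multi_tc_fraction_filtered": float((table["n_kept"] > 1).mean()) if len(table) else 0.0,
    }
    return table, summary
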