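"""Tabular/BED export of clusters, links and stretches.

BED output is BED6 with the cluster id as name and ``min(1000,
round(score))`` as the BED score (browser convention); the exact score and
the remaining per-cluster fields travel in companion TSVs.
"""

from __future__ import annotations

import pandas as pd

from .clusters import TagCluster
from .enhancers import BidirectionalCluster
from .links import Stretch


def tc_frame(clusters: list[TagCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.uid,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "peak": c.peak,
                "score": c.score,
                "peak_value": c.peak_value,
                "category": c.category,
                "gene_id": c.gene_id,
            }
            for c in clusters
        ]
    ).set_index("id")


def bc_frame(clusters: list[BidirectionalCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.uid,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "maxpos": c.maxpos,
                "balance": c.balance,
                "score": c.score,
                "category": c.category,
            }
            for c in clusters
        ]
    ).set_index("id")


def write_bed(clusters, path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            score = min(1000, round(c.score))
            strand = getattr(c, "strand", ".")
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.uid}\t{score}\t{strand}\n")


def write_stretches_bed(stretches: list[Stretch], path) -> None:
    with open(path, "w") as fh:
        for st in stretches:
            fh.write(f"{st.chrom}\t{st.start}\t{st.end}\t{st.uid}\t{st.n_members}\t.\n")


def write_links_bedpe(links: pd.DataFrame, tc_features: pd.DataFrame, enh_features: pd.DataFrame, path) -> None:
    """Links as BEDPE (TC span, enhancer span, estimate as the score)."""
    with open(path, "w") as fh:
        for _, row in links.iterrows():
            tc = tc_features.loc[row["tc_id"]]
            enh = enh_features.loc[row["enhancer_id"]]
            fh.write(
                f"{tc['chrom']}\t{tc['start']}\t{tc['end']}"
                f"\t{enh['chrom']}\t{enh['start']}\t{enh['end']}"
                f"\t{row['tc_id']}|{row['enhancer_id']}\t{row['estimate']:.6f}"
                f"\t{tc['strand']}\t.\n"
            )
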