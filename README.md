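# capclust

Analysis of 5'-end transcriptome data — CAGE, PRO-Cap and related assays —
from per-bp CTSS count tracks to TSS candidates, enhancer candidates, gene
expression matrices and enhancer–promoter co-expression links.

5'-end sequencing reduces each RNA to the single base pair where its 5'
end maps, per strand: a CTSS (CAGE-defined TSS) with an associated tag
count. These tracks are the highest-resolution readout of transcription
initiation available, and because active enhancers initiate eRNAs
divergently, the same data also reveals enhancers. `capclust` is for
computational biologists who have per-sample CTSS tracks (BigWig or
bedGraph pairs) and want the full downstream analysis in Python, with
count matrices ready for standard differential-expression tooling.

## What it computes

Let $c_{js}$ be the tag count of sample $s$ at bp $j$ (per strand), and
$N_s = \sum_j c_{js}$ the library size. The **pooled signal** is the
per-bp sum of tags-per-million over samples:

$$p_j = \sum_s 10^6 \, c_{js} / N_s .$$

* **Tag clusters (TCs)** — slice-reduce: discard bps with $p_j$ below a
  threshold (default 0.1), merge surviving same-strand bps separated by at
  most 20 bp. The TC **peak** is the bp with maximal pooled signal.
* **Bidirectional clusters (BCs)** — at every candidate midpoint $m$, sum
  pooled signal over four 200 bp arms: plus-strand upstream/downstream
  (PU, PD) and minus-strand downstream/upstream (MD, MU). The **balance
  score** is the Bhattacharyya coefficient against the ideal perfectly
  divergent distribution $(0, \tfrac12, 0, \tfrac12)$:

  $$B(m) = \sqrt{f_{PD}/2} + \sqrt{f_{MD}/2}, \qquad f = \text{arms}/\text{total},$$

  which equals 1 only for a perfect 50/50 divergent split and is at most
  $\sqrt{1/2} \approx 0.707$ for one-sided signal. Midpoints with
  $B \ge 0.95$ are sliced and reduced into BCs; BCs away from exons and
  annotated promoters are enhancer candidates.
* **Hierarchical annotation** — each cluster peak gets the
  highest-priority matching category: promoter (±100 bp of an annotated
  TSS) > proximal (≤1 kbp upstream) > 5'UTR > 3'UTR > CDS > exon > intron
  > antisense > intergenic.
* **Promoter shape** — the 5–95% interquantile width of the pooled CTSS
  distribution within a TC (≤10 bp = sharp, else broad) and its Shannon
  entropy.
* **Gene-level analysis** — TC counts summed per gene; alternative TSSs
  per gene, with a composition filter removing TCs below 10% of their
  gene's expression.
* **Links and stretches** — Kendall's tau-b between TC and enhancer
  expression for all pairs within 10 kbp, BH-adjusted across pairs;
  enhancer stretches chain candidates with gaps under 12.5 kbp and report
  the members' average pairwise correlation.

A synthetic-data module (`capclust.simulate`) generates multi-sample CTSS
datasets with planted sharp/broad TCs, divergent enhancers, gene models,
co-expression structure and background noise, plus ground-truth tables for
benchmarking every stage.

## Worked example

```python
import capclust as cc

config = cc.SimConfig.random(seed=2, n_sharp=5, n_broad=0, n_enhancers=4)
dataset, _, truth = cc.simulate_dataset(config)
pooled = cc.pool(cc.normalize_tpm(dataset))

arms = cc.arm_sums(pooled, "chr1", truth.enhancers[0].anchor)
print(round(cc.balance_score(arms), 4))

bcs, matrix = cc.bc_pipeline(dataset, min_count=1, min_samples=2)
print(len(bcs))
```

prints

```
0.9985
4
```

The first number is the balance score at a planted enhancer midpoint —
0.9985, essentially the ideal 1.0, because the plus- and minus-strand tags
split almost exactly 50/50 across the divergent arms. The second is the
number of bidirectional clusters called: exactly the 4 planted enhancers,
with none of the 5 planted unidirectional TCs mistaken for an enhancer
(their balance cannot exceed 0.707). `examples/` holds one narrative
script per capability — tag clusters, enhancers, annotation and shape,
gene-level analysis, links and stretches — each printing the quantities it
computes; the outputs above are from `examples/02_call_enhancers.py`.

A thin CLI wraps the same functions for shell use
(`capclust simulate|pool|tcs|enhancers|annotate|shape|genes|links|stretches|all`).

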