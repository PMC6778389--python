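# Methods

## Signal model and units

The atomic observation is a CTSS: a (chromosome, bp, strand) position with
a non-negative integer tag count, per sample. Tracks are stored sparsely
(sorted position/value arrays per chromosome), so memory scales with the
number of covered positions rather than genome length. Coordinates are
0-based half-open throughout; a CTSS is a width-1 interval. GTF input
(1-based inclusive) is converted on load. Minus-strand tracks that encode
counts as negative values are accepted behind a `negative_minus` flag that
takes absolute values; both dialects occur in public data.

Three unit scales are kept deliberately distinct:

* raw counts — what quantification emits, because downstream
  differential-expression tools expect counts;
* TPM — `count * 1e6 / library_size` per sample; library size is always
  the raw both-strand total of the *unfiltered* tracks, since TPM should
  reflect sequencing depth while support filtering is a trust decision
  about individual positions;
* pooled signal — the per-bp **sum** of TPM over samples (not the mean;
  both conventions exist, the sum is used consistently here). Without
  support filtering the pooled total is exactly `n_samples * 1e6`, which
  the tests assert as a conservation law.

Robust pooling (`support_filter_ctss`) keeps a position only if at least
`min_samples` samples have `count >= min_count` there (defaults 2 and 1:
discard CTSSs seen in a single library). The filter is idempotent and
applied before normalization.

## Tag clustering (slice-reduce)

Positions with pooled signal below `slice_threshold` are discarded;
surviving same-strand positions whose gap (bps strictly between
consecutive survivors) is at most `merge_distance` merge into one cluster
spanning first to last survivor. Defaults: threshold 0.1 pooled TPM and
merge distance 20 bp — chosen small relative to the downstream >1 TPM
cluster-level filter and to typical TC widths, and both config-exposed,
since no canonical defaults exist for these two knobs. The cluster score
sums *surviving* positions only (slice-then-reduce semantics: a
sub-threshold bp inside the span contributes nothing). Peak ties break to
the smallest coordinate, making output deterministic.

Cluster-level support (`feature_support`) uses strict `>` for TPM-style
thresholds ("more than 1 TPM") and `>=` for tag-style thresholds ("at
least 1 tag"), selectable via a flag; the sample requirement is always
"at least k samples".

## Bidirectional clustering and the balance score

For midpoint m and window w (default 200 bp) the four arms are
PU = plus over [m−w, m), PD = plus over [m, m+w], MD = minus over
[m−w, m], MU = minus over (m, m+w]. The boundary inclusivities were chosen
so every bp of signal in [m−w, m+w] is counted in exactly one arm per
strand (asserted by a test). The balance score is the Bhattacharyya
coefficient between the observed arm fractions and the ideal
(0, ½, 0, ½): `sqrt(fPD/2) + sqrt(fMD/2)`. Properties relied on: it is 1
iff PD = MD with empty outer arms; it is scale-invariant; and it is
bounded by sqrt(½) whenever either divergent arm is empty. That bound
licenses an exact optimization: for any cutoff above sqrt(½) (the default
0.95 included), midpoints with an empty PD or MD arm are skipped without
scoring; `cluster_bidirectional` enables this automatically and
`balance_track` only on request.

BCs are called slice-reduce style on the balance track: passing midpoints
(balance ≥ cutoff) merge across gaps up to `merge_gap` (default = w, the
length scale of one locus), and each run becomes a BC spanning
[first − w, last + w] clipped to the chromosome — expansion by the scoring
window guarantees both arms' signal lies inside the quantified span. The
max-balance position (leftmost on ties) anchors the BC. BC expression is
quantified over both strands in raw counts.

Enhancer candidates are the BCs annotated intronic or intergenic whose
span neither overlaps exonic sequence nor the promoter/proximal zone
around an annotated TSS (up to 1 kbp upstream plus the promoter radius).
The midpoint category uses the peak like all annotation, but the
exon/promoter filter is span-based, because exon contamination is a
property of the whole quantified region.

## Hierarchical annotation

Each cluster is annotated at its peak (BCs: max-balance position) against
every transcript; the highest-priority matching category wins. Default
order: promoter, proximal, fiveUTR, threeUTR, CDS, exon, intron,
antisense, intergenic; the list and the two distances (promoter ±100 bp,
proximal 1000 bp upstream) are configurable, and the priority order is
exactly the configured list order. Stranded clusters match same-strand
transcripts; antisense means the peak overlaps transcripts only on the
opposite strand; unstranded BCs match either strand and are never
antisense. UTRs are derived as exonic sequence strand-upstream
(5') or -downstream (3') of the CDS extent; transcripts without CDS
contribute plain exons. Annotation is total and deterministic: every
cluster receives exactly one category.

Gene assignment places a TC in a gene when its peak falls in the union of
the gene's same-strand transcript spans extended upstream by the proximal
distance; overlaps of several genes resolve to the gene with the nearest
annotated TSS, and exact ties leave the TC unassigned rather than guess.
Gene matrices sum assigned TC counts (a conservation the tests check).
The composition filter keeps a gene-assigned TC when its share of the
gene's expression exceeds `min_fraction` (default 10%) in strictly more
than `min_samples` samples; a zero gene total makes the share undefined
and counts as failing; unassigned TCs are never composition-filtered.

## Promoter shape

The interquantile width uses first-crossing of the cumulative signal
fraction, scanned left to right in genomic coordinates, with no
interpolation — the data is bp-resolution and first-crossing keeps the
statistic integer-valued and deterministic. Width = highpos − lowpos + 1
with defaults 5% and 95%. Clusters with width ≤ 10 bp are classified
sharp (boundary inclusive; the threshold is configurable). Entropy is the
Shannon entropy in bits of the per-bp signal fractions within the
cluster. Arbitrary user statistics of (cluster, pooled track) plug into
`shape_summary` through the same interface.

## Links and stretches

Candidate pairs are all same-chromosome (TC, enhancer) pairs with
|enhancer maxpos − TC peak| ≤ 10 kbp; distance is anchored peak-to-maxpos
(the two best single-bp estimates) rather than edge-to-edge. The default
correlation is Kendall's tau-b via scipy (tau-b because count matrices
are tie-rich; scipy uses the exact null only for small tie-free n and the
normal approximation otherwise); Pearson, Spearman and arbitrary callables
returning (estimate, p) are accepted. Two-sided p-values are BH-adjusted
(statsmodels) across *all* computed pairs, and positivity of the estimate
is applied as a post-filter, so both "positive links" and "significant
links" counts are available. Pairs with a constant expression vector are
dropped with a warning (their correlation is undefined).

Stretches chain enhancers whose edge-to-edge gap is strictly below
12.5 kbp, single linkage, keeping chains of at least 4 members by
default; each stretch reports the mean tau over all unordered member
pairs (NaN for a single quantified member).

## Synthetic data: what it emulates, what it does not

The generator plants features with *fixed* per-feature CTSS position sets
and weights, drawn once from the seed; per-sample totals are negative
binomial (dispersion 0.2, var = μ + 0.2 μ², realistic biological
overdispersion) distributed multinomially over the positions. Fixed
positions matter: real CTSSs recur at the same bp across libraries, and
single-library support filtering would erase signal placed at per-sample
random offsets.

* Sharp TCs concentrate ≥ 90% of tags within 2 bp of the summit. Broad
  TCs place 30% of mass on a summit and 70% on a Gaussian shoulder of
  width 40–100 bp, so the pooled argmax is a well-defined truth peak
  while the 5–95% width stays far above 10 bp.
* Enhancers emit divergent tags (minus upstream, plus downstream of the
  midpoint), split Binomial(N, ½) between strands, over 3–6 positions per
  arm within 180 bp; each arm's innermost position lies within 45 bp of
  the midpoint, mirroring eRNA initiation flanking the central
  nucleosome-free region and keeping the max-balance position close to
  the true midpoint.
* Designated TC–enhancer pairs share a latent log-normal activity
  (log-scale sd 1.0, correlation ρ = 0.8 by default), inducing the
  co-expression that link prediction recovers. `linked_blocks_config`
  arranges linked and independent features within the 10 kbp pairing
  window so false-positive rates are measurable.
* Background noise is sparse Poisson singletons (default 1e-5 per bp per
  strand per sample).

Default study conditions: 5 samples, mean 50 tags per feature per sample
(50 samples for link experiments). Truth matching uses 5 bp (TC peaks) /
50 bp (enhancer midpoints) tolerances, stricter than the merge distances
so matches are unambiguous.

Not emulated: sequence content (no FASTA), mappability artifacts,
promoter–enhancer distance distributions beyond the block layouts, batch
effects, and depth heterogeneity beyond what the NB draws induce. Passing
recovery tests therefore demonstrates correctness of the clustering,
scoring and linking machinery under clean but realistically dispersed
signal — not robustness to mapping artifacts or annotation errors in
real genomes.

## Numerical choices and degenerate inputs

Balance is computed as fractions first (`sqrt(0.5 * (pd/total))`) to
behave under extreme magnitudes; zero windowed total raises rather than
returning a value. Zero-signal clusters raise in shape statistics.
Zero-size libraries refuse TPM normalization. Empty tracks/cluster lists
flow through every operation as empty results. All tie-breaks
(cluster peaks, BC maxpos) go to the smallest coordinate. Test problem
sizes (10 kbp oracle tracks, 50–100 planted features, 50-sample link
simulations) keep the full suite under a few seconds while exercising
every code path at realistic density.

## Known limitations

* Balance-track candidate enumeration is exact but enumerates every bp
  within a window of signal; for very dense genomes a run-length
  formulation would be faster.
* Gene assignment uses the peak only; a TC straddling two genes is
  attributed entirely to one.
* The Kendall p-value inherits scipy's tie handling (normal
  approximation under ties); for tiny sample counts with heavy ties the
  FDR is approximate.
* The Andersson-style seed-based enhancer pairing method and its 0.6
  balance-cutoff convention are out of scope; cutoffs here refer to the
  Bhattacharyya balance defined above.
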