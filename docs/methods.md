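# Methods

This note records the models, algorithmic conventions, and numerical choices
behind `crosstx`, and what the synthetic fixtures do and do not establish
about real data.

## Probe alignment and the negative set

A probeset on a heterologous hybridization only reports signal when its
probes find near-perfect targets in the sample species' transcriptome.
`probes` implements the defining contract directly: full-length, ungapped,
both-strand Hamming search of 25-mers with at most `k` mismatches
(default 3). The search partitions each probe into `k + 1` contiguous
segments; by pigeonhole an alignment within `k` mismatches must contain one
exact segment, so exact k-mer lookups enumerate all candidate placements,
each verified base by base. The result is provably identical to the naive
sliding-window scan, which the test suite runs as an oracle. `N` bases in
targets match nothing. A probeset is *negative* when none of its probes has
any alignment (a "≥ fraction unaligned" relaxation is available but the
strict rule maximizes background purity). Whether a stranded short-read aligner
would count reverse-strand-only matches is configuration-dependent;
both-strand search is the default here, and the strand-symmetry property
(reverse-complementing the transcriptome preserves the negative set) is
tested.

## Intensity summarization (RMA-lite)

Probe intensities are log2-transformed, quantile-normalized (each column
receives the per-rank cross-column means; within-column ties get the mean of
their rank-assigned values), and summarized per probeset by Tukey two-way
median polish. The polish alternates row- and column-median sweeps with
re-centring, at most 10 sweeps, stopping when the total absolute residual
changes by less than 0.01 between sweeps; probeset expression on an array is
the overall effect plus that array's column effect. No background correction
is applied: the presence-call statistic below is calibrated against negative
probesets processed identically, so an additive background component cancels
by construction. Single-probe probesets pass through unchanged. The additive
decomposition is unique only up to centring constants, so tests compare
effect *differences* and the reconstructed fit.

## Presence p-values (PANP)

Per array, let `u_1 < … < u_m` be the unique expression values of the
negative probesets and `S(u_i)` the fraction of negatives `≥ u_i`. A
probeset's presence p-value is `S` evaluated at its expression: 1 at or
below `u_1`, 0 above `u_m`, linearly interpolated between knots, with tied
values sharing the conservative (larger) p. Step-quantile and interpolated variants
of the empirical survivor function both exist; interpolation is the
documented choice here and gives continuous, monotone p-values whose null
distribution is uniform up to resampling noise. Calls: P at p ≤ 0.02
(the conventional presence threshold for this calling scheme), an optional Marginal band to 0.04, else
Absent. At least 50 negatives are required (configurable); the calibration
experiment uses 10'000 negatives — the realistic cross-species regime, where
most probesets fail to align — against 5'000 null draws and 500 signal
probesets.

## Homologue assignment

PSL records (21 columns, 0-based half-open; the 5-line `psLayout` header is
auto-skipped, and records violating the coordinate/block-sum invariants are
dropped with a warning) are scored as
`matches + repMatches − misMatches − qNumInsert − tNumInsert` — the standard
BLAT score, the only score derivable from PSL alone. Transcript-variant ids
`comp<x>_c<y>_seq<z>` collapse to genes on both sides; per gene pair, scores
and query-side spans (`qEnd − qStart`) are summed over all records. A gene's
homologue is the pair-score argmax among pairs with total aligned length
≥ 100 bp, else none; ties break to the lexicographically smallest partner
for determinism. The direction is parameterized (each query gene gets its
best target by default; `side="target"` swaps the roles), and the aligned
length can be taken target-side by flag, since either summation side is
defensible.

## Counts, expression calls, and normalization

Variant-level counts sum to genes, conserving per-sample totals. A gene is
expressed in a library at ≥ 5 raw reads (before any normalization). TMM
factors follow the conventional scheme: reference column = the one whose
upper quartile of library-scaled counts is nearest the mean upper quartile;
per sample, M- and A-values of library-scaled counts versus the reference
(genes with a zero in either member excluded), doubly trimmed (30% on M, 5%
on A, rank-based with floor(n·trim)+1 bounds), averaged with inverse
delta-method-variance weights `(N−x)/(Nx)` summed over both members; factors
are 2 to that mean, rescaled to geometric mean 1. Because the weights carry
the library sizes, rescaling one column changes the weight mixture slightly:
scale invariance holds only up to those precision weights (tested at 2%),
tightening as counts grow. DESeq-style size factors (median over
all-nonzero genes of count over the gene's geometric mean) serve the
heatmap/display path only.

## Replicate-free differential expression

**NOISeq-sim.** For each of the two libraries, `nss = 5` technical
replicates are simulated: replicate size = round(u·total) with
u ~ Uniform(pnr−v, pnr+v) (pnr = 0.2, v = 0.02), gene counts multinomial on
the library's proportions. Zeros are replaced by k = 0.5; every value is
divided by its own effective (TMM-scaled) library size and put on the scale
of the mean effective library, so replicate and signal statistics are
comparable. All within-sample replicate pairs contribute per-gene
(|M|, D) = (|log2 ratio|, |difference|) points to one pooled noise cloud;
a gene's DE probability is the fraction of noise points it dominates
(non-strict in both coordinates, so ties favour higher probability). Genes
with prob > q = 0.9 *and* up in the focal sample in all three pairwise
contrasts form the enriched set. These internal constants are the cited
algorithm's published defaults, exposed as parameters. Two properties
deserve emphasis: (i) the probability is a pure function of (|M|, D) given
the noise cloud, so exchangeability over genes holds exactly conditional on
the cloud but only approximately across reruns (multinomial sampling is
order-dependent); (ii) simulated replicates carry only technical noise, so
with biological dispersion as high as φ = 0.64 between single libraries a
substantial null fraction (≈ 20% in the calibration experiment) exceeds
q = 0.9 — the known permissiveness of replicate-free NOISeq that motivates
both the three-contrast intersection rule and the stricter exact-test route.

**Exact NB test at fixed dispersion.** Without replicates the dispersion is
fixed at φ = bcv² with bcv = 0.8. Counts are mapped to pseudo-counts at the
geometric-mean library size `N* = √(N1·N2)` (rounded) — a simplification of
the quantile-adjusted pseudo-count machinery of common exact-test
implementations that keeps the test fully enumerable. Conditional on the pseudo-count total `s`, each split
is weighted by `NB(a; s/2, φ)·NB(s−a; s/2, φ)`; the two-sided p sums all
splits whose probability does not exceed the observed one (relative
tolerance 1e-9 for floating-point ties; if every split qualifies the p is
exactly 1). φ = 0 reduces to the conditional Binomial(s, ½) test. Type-I
error at the method's own null is verified by simulation. BH adjustment is
the standard step-up (delegated to statsmodels; note BH is *not* idempotent
— re-adjusting adjusted values changes them — so only order-statistic
monotonicity is asserted). Enrichment requires FDR < 0.05 up-in-focal in all
pairwise comparisons, with a designated pair (the two most similar cell
types) using raw p < 0.001 instead.

## Evidence rules and set algebra

Evidence records per (gene, cell type) combine the number of arrays with a
P call and an RNA-seq expressed flag. Rules are data, not code — a small
AND/OR/parenthesis grammar over `array_P` comparisons and the `rnaseq` flag,
with presets for the doubly-arrayed founder cell ("array_P>=2 OR rnaseq"),
singly-arrayed gametes ("array_P>=1 OR rnaseq"), and the conservative
exclusive-set conjunction ("rnaseq AND array_P>=1"). Cross-species
comparisons are anchored on the partner species' gene ids via the homologue
map; genes without a homologue keep their local id and hence can only appear
in species-exclusive sets — a complementary direct-to-genome
criterion would need the real partner genome and is deliberately out of
scope. Venn regions are computed exactly and must
partition the union (asserted).

## Enrichment

Direct annotations are propagated by the true-path rule (a gene annotated to
a term is annotated to all is_a ancestors; idempotent). Term
overrepresentation is the upper-tail hypergeometric p; `elim` decorrelation
processes terms leaves-to-root and removes the study genes of any term with
p ≤ 0.01 from its ancestors' study overlap before testing them — only the
`significant` column can shrink; `annotated` always reports the true
propagated count. The `weight` decorrelation variant is not implemented;
results are labelled as elim. Family/domain misrepresentation uses the
minimum-likelihood two-sided Fisher test computed in exact integer
arithmetic (products of binomial coefficients), so tie selection and the
final value are exact to the last bit of one float division. The GO universe
is the annotated-gene set by default, the full gene list by preset where an
array-wide universe is wanted. P-values are reported unadjusted, with
p < 0.01 as the conventional reporting filter.

## Heatmap path

Display values are `log2(count / size_factor + 1)` (pseudocount 1, a
documented choice), optionally row-centred/scaled; hierarchical clustering
is complete-linkage on euclidean distances with rows pre-sorted by id so
equal-distance merges are deterministic. Only merge trees and leaf orders
are produced; no rendering.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *data shapes* the pipeline consumes under one
global seed (per-stage substreams keep stages independently reproducible):
transcripts with `comp<x>_c<y>_seq<z>` ids and normal-length variation;
25-mer probes copied from transcripts and mutated at a per-base substitution
rate (every substitution is a guaranteed mismatch, so truth mismatch counts
are exact), plus fully random off-target probesets as true negatives;
log-normal intensity mixtures (background mean 6, SD 1; signal mean 9 — a
+3 SD separation — SD 1 on the log2 scale) with per-probe affinity effects
(SD 0.5, mean 0) for median polish to remove; NB counts with variance
μ + φμ², φ = 0.64, planted cell-type markers at 10% prevalence and 4-fold
elevation, a 15% per-cell-type silencing rate, and log-normal baselines
around 100; a single-rooted random is_a DAG with direct-only annotations;
and single-block PSL records with configurable divergence and half-score
decoys. The array intensity distributions have no
authoritative empirical parameterization — background and signal parameters
are calibration choices of this package, not measurements.

Passing tests therefore establish algorithmic correctness (oracle agreement,
calibration under the generators' assumptions, recovery of planted
structure), not biological validity on real arrays or libraries: real
cross-species hybridizations have sequence-dependent affinity, saturation,
and mismatch-position effects the log-normal mixture ignores; real read
counts have gene-length and GC structure deliberately not modelled (the
analysis applies no length correction); and real homologies are many-to-many
in ways the index-paired truth is not.

## Problem sizes

The default pipeline fixture is 150 genes x 4 cell types, 200 probesets x 11
probes x 5 arrays; calibration experiments use 10'000 negative / 5'000 null
/ 500 signal probesets (presence calls), 2'000 genes (exact-test type-I and
NOISeq recall), 150 gene pairs (homologue recovery), and a 50 kb
transcriptome with 209 probes (aligner oracle). These sizes give stable
Monte-Carlo estimates while keeping a full run in the tens of seconds.

## Known limitations

- The exact NB test's pseudo-count rounding makes p-values mildly
  conservative at very low counts; dispersion is assumed, never estimated.
- NOISeq-sim's noise cloud contains technical variation only (see above);
  its probabilities are not p-values and carry no error-rate guarantee.
- PANP p-values inherit the negative set's resolution: with `m` negatives,
  p-values below `1/m` are only reachable by extrapolating to 0 above the
  negative maximum.
- The `elim`-decorrelated GO p-values are conditional on the processing
  order of equal-depth terms (fixed, topological) and are reported
  unadjusted, as is conventional for decorrelated GO scans.
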