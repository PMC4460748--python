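# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the toolkit. Parameter defaults are the method's
published operating point; the synthetic generators define the study
conditions under which the test suite measures performance.

## Coordinates and interval algebra

All internal coordinates are 1-based inclusive (GFF convention). BED input
(0-based half-open) is converted on read (`start + 1`) and converted back on
write. Overlap is closed-interval intersection: one shared base pair
suffices. Peak-set intersection merges each mark's peaks first (overlapping
or book-ended peaks become one interval), then takes the segment
intersection with a two-pointer sweep; every output base pair is covered by
both marks. The alternative "peaks of A touching B" mode is available
(`intersect_touching`) but is not the default, because the quantity of
interest is the *common enriched territory*, not A's peak boundaries.

## The annotation index

Genes, transcripts and exons are flattened into per-chromosome arrays sorted
by (start, feature id), with a running maximum of interval ends. A query
bisects the starts for the upper bound and the cumulative end-maximum for
the lower bound, then filters the in-between slice. This returns exactly
what a linear scan returns (the test suite asserts equality against a
brute-force oracle on fuzzed genomes) at O(log n + k) per query. Ties are
ordered by (start, id) so output is deterministic.

## seq2gene

Each region is linked to every gene whose span lies within radius *r* of the
region (span-to-span gap, gene strand ignored). Defaults:

| parameter | default | rationale |
|---|---|---|
| radius | 150,000 bp | distal regulatory elements sit on the order of 10⁵ bp from their targets; linking both sides within 150 kb captures them |
| promoter half-width | 2,000 bp | conventional ±2 kb window around the transcript TSS |
| category priority | exonic > promoter > intronic > intergenic | one link per (region, gene) keeps downstream counts unambiguous; the most specific physical relation wins |

Signed distance is 0 when region and gene span overlap, negative when the
gene lies left of the region on the reference strand, positive when right.
Distance is measured span-to-span by default; a TSS-based distance is
available (`query_radius(..., tss_distance=True)`) since which convention an
annotation pipeline uses is a genuine free choice. A nearest-gene-only mode
exists for comparison, but multi-gene linking is the default by design: the
premise of the method is that an element can regulate several genes and
genes in both directions.

## Expression preprocessing

**Probe collapse** keeps, per gene, the probe with the maximal mean
intensity across samples (ties by probe id). This favours the
highest-signal probe rather than averaging probes with different dynamic
ranges.

**Batch adjustment** is the standard parametric empirical-Bayes
location–scale model: per gene, intensities are standardized against a
design of batch indicators plus (when protected) phenotype indicators;
per-batch location effects γ and scale effects δ² are estimated per gene,
shrunk toward normal / inverse-gamma priors whose hyperparameters come from
moments across genes (posterior iterated to relative change < 1e-4), and
removed. Phenotype protection is ON by default: in multi-cohort designs
case/control proportions differ across cohorts, and an unprotected fit
absorbs real group differences into the batch estimates. A batch that
coincides 1:1 with a phenotype group is rejected as inestimable. When the
between-gene variance of the batch effects is numerically zero the unshrunk
estimates are used directly (the priors are degenerate and the posterior
equals the estimate); this also makes a pure location shift removable
exactly. The implementation agrees with the reference R implementation
(`sva::ComBat`, parametric prior) to ~1e-5 on identical input; one test
pins a frozen corner of that reference output.

**IQR filter** keeps ⌈f·G⌉ genes (default f = 0.5) with the largest
interquartile range, computed with linear-interpolation quantiles (R
type 7) — stated because quantile definitions differ across software. Ties
break by gene id. The pipeline always retains the seed gene in addition to
the quota (`always_keep`): a borderline-variable seed must not silently
vanish from its own analysis.

## Per-gene statistics

**Moderated t.** Two-group comparison with pooled per-gene variance s²,
shrunk toward a prior: s̃² = (d₀s₀² + df·s²)/(d₀ + df), t = logFC/(s̃·c),
c = √(1/n₁ + 1/n₂), with df + d₀ degrees of freedom. Hyperparameters come
from moments of log s²: var(log s²) = ψ′(df/2) + ψ′(d₀/2) identifies d₀
(trigamma inversion by Newton iteration); the mean identifies s₀². When the
observed spread of log-variances is at or below sampling variation, d₀ = ∞
(full pooling); `prior_df` can be overridden (0 reproduces the ordinary t
exactly). Genes constant in both groups are flagged and given p = 1 when
logFC = 0. logFC is mean(case) − mean(control) on the log2 scale, and fold
changes are reported as 2^logFC.

**Seed correlation.** Pearson r of each gene with the seed across all
samples; p from the t-transform with n − 2 df; |r| = 1 maps to p = 0.

**FDR.** Benjamini–Hochberg is the default. The Storey variant rescales BH
by π̂₀ = min(1, mean(p > 0.5)/0.5) — a single fixed λ = 0.5 rather than a
λ-grid smoother, trading a little conservatism for determinism; thus
storey-q ≤ BH-q genewise.

**Selection.** Significant DE genes: q < 0.05 and fold change ≥ 2 (up) or
≤ 0.5 (down).

## Biomodule discovery

Both statistics order the gene universe best-first (CE by r, DE by t;
descending for the "up in cases, positively seed-correlated" direction,
ascending for the mirrored direction; ties by gene id). The overlap curve
O(n) = |top-n ∩ top-n| is summarised by

  score = Σ_{n=1..n_max} e^(−βn) · O(n),  β = 1/n_top by default,

i.e. exponential rank weights with e-fold decay at the rank threshold
(n_top = 150 by default): agreement at the very top counts most, agreement
near the threshold still counts. β = 0 recovers the plain area under the
overlap curve. Top and bottom list ends are scored and reported separately
— concordance is typically one-sided, and a two-sided option takes the max.

Significance comes from permuting one list's order uniformly B = 1000 times
(permuting one list is equivalent in distribution to permuting both) with
the add-one estimator p = (1 + #{null ≥ observed})/(B + 1), which cannot
return 0 and is slightly conservative. The permutation stream is seeded and
reproducible. Under independence O(n) ~ Hypergeometric(N, n, n); the mean
n²/N and central 95% band are provided for plotting the chance expectation
against the observed step function.

The biomodule is the intersection of the two top-n_top prefixes. Everything
is rank-based, so the module is invariant to strictly monotone transforms
of either statistic.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ a) on a
background restricted to genes that are both assayed and present somewhere
in the collection; each set's size and the module's size are intersected
with that background before testing. This conditioning is the defence
against inflated significance from genes that could never have been drawn.
Defaults follow the method's operating point: p ≤ 0.001 and count > 5
(a q-value threshold mode is also available, and BH q is always reported).
The odds ratio is a·d/(b·c) on the 2×2 table, with the Haldane–Anscombe
+0.5 correction only when a zero cell occurs; a module identical to a set
within the background is reported as an infinite OR. The hypergeometric
tail equals the one-sided Fisher exact p on the same table; the test suite
cross-checks both code paths.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of (parameters, seed) and attach ground
truth to every dataset.

*Genome*: non-overlapping genes laid left-to-right with exponential gaps;
1–3 transcripts per gene (the first spanning the gene), 1–8 non-overlapping
exons; 31% of genes coding by default. *Peaks*: each planted target gene
receives overlapping peaks for both marks near its TSS (Gaussian offset,
sd 20 kb); background peak pairs are uniform with a configurable
co-occupancy rate. *Expression*: microarray-like Gaussian log2 intensities
(not counts). The seed gene is unit-variance biological signal plus the
case shift; module genes share the seed's biological signal at correlation
ρ and carry the same shift; nulls are independent noise. Defaults mirror
the intended study scale: 28 cases vs 24 controls, a 40-gene module,
ρ = 0.7, 1 log2-unit effect, σ = 1. Batch effects are additive by default
with optional multiplicative scale, assigned round-robin within each
phenotype group so batch and group stay unconfounded.

Two deliberate consequences of this construction, verified in the tests:
the *within-group* correlation of module genes with the seed equals ρ,
while the marginal correlation is (ρ + e²v)/(1 + e²v) (v = case-fraction
variance) because both carry the case shift; and module recovery varies
across replicates mainly through the random case/control imbalance of the
seed's shared signal, which moves all module t-statistics together. In the
default scenario a 50-replicate run gives Jaccard overlap with truth of
roughly 0.4–0.75 (mean ≈ 0.6) at n_top = 150.

The end-to-end chromatin scenario uses a deliberately gene-sparse genome
(mean gap 2 Mb): with realistic human-like spacing nearly every point of
the genome is within 150 kb of some gene, and target *specificity* would be
unmeasurable. Sparse spacing is what makes "false targets from background
peaks" a meaningful rate.

What the generators do **not** emulate: read-level signal and peak-calling
noise, probe-level microarray artefacts, count distributions of RNA-seq,
correlated null genes (co-expression blocks unrelated to the seed), or
dependence between chromatin state and expression. Passing tests therefore
demonstrate correctness of the algorithms and calibration of the tests
under the stated model, not performance on any particular real dataset.

## Problem sizes in the test suite

Oracle-equivalence fuzzing uses genomes of up to 500 genes with hundreds to
a thousand queries; intersection fuzzing up to 1000 peaks per set;
permutation calibration 200 null replicates at N = 500 genes with B = 1000;
module recovery 50 replicates of the default 2000-gene scenario. These
sizes make the whole suite run in well under a minute while leaving the
Monte-Carlo bands tight enough to be informative.

## Known limitations

- GFF3/GTF support targets ordinary gene/transcript/exon annotation with
  `gene_id`/`transcript_id`/`ID`/`Parent` attributes; exotic schema
  features (multi-parent features, discontinuous CDS bookkeeping) are out
  of scope.
- The batch model assumes each batch has ≥ 2 samples and at least partial
  phenotype balance; singleton batches are rejected rather than guessed at.
- Storey's π̂₀ with a single λ is conservative when p-values cluster just
  above 0.5.
- The permutation null treats gene ranks as exchangeable; correlated genes
  make it anti-conservative in principle, which is why the add-one
  estimator and the separate top/bottom reporting are kept conservative.
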