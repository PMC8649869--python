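# Methods

## The problem this package models

In a pooled shRNA dropout (synthetic-lethality) screen, drug-resistant cells
carrying a barcoded hairpin library are cultured under selection; hairpins
targeting genes required for maintained resistance fall out of the
population, and their barcode abundance drops between the reference
(pre-selection) and selected sequencing libraries. Because some genes are
simply required to survive the drug acutely, a parallel arm treats
drug-naive parental cells briefly: hairpins depleting there are subtracted
so that only genes specific to *maintained* resistance remain. Screen hits
are then crossed with expression changes (resistance-associated
up-regulation, knockdown-responsive down-regulation) and tested for gene-set
enrichment. `dropscreen` implements this computation end to end, together
with a generative model that plants known answers so every stage is
testable.

## Screen generative model

Each hairpin *i* targeting gene *g* has

- a baseline abundance drawn log-normal (σ = 1 on the natural-log scale),
  matching the skewed composition of real pooled libraries;
- a knockdown efficacy `e_i ∈ [0, 1]`: a configurable fraction of each
  gene's hairpins (default 0.8) is active with efficacy ~ Beta(5, 2)
  (mean ≈ 0.71); the rest are inert with efficacy exactly 0. Inert hairpins
  are what make the "supported by ≥ n independent hairpins" gene filter
  meaningful; setting them to exactly 0 keeps the per-hairpin closed form
  below exact for testing.

After `w` weeks in an arm where the gene's per-week log2 fitness effect
`s_g ≤ 0` applies, the expected abundance is

    E[a_i] = baseline_i · 2^(s_g · e_i · w)

`s_g` applies in the resistant-selected arm for resistance drivers, in both
the resistant-selected and parental-acute arms for acute-essential genes,
and nowhere for neutral genes. Observed counts are negative-binomial around
the multinomial expectation at the configured depth, with variance
μ + φμ² (φ = 0.05 for screens by default, Poisson at φ = 0).

Arm durations default to 4 weeks of selection in the resistant arm,
mirroring the four-week drug-selection design the pipeline targets, 0 weeks
in the reference. The acute arm's culture duration is not something the
analysis can observe directly; it defaults to the same 4 weeks so that
acute-essential genes deplete detectably in the acute arm — the property
that makes the subtraction rule testable — and is configurable. Default
depth is 2×10⁶ reads/sample with 3 replicates per arm. Planted selection
defaults to s = −0.75/week for both drivers and acute-essential genes, a
strong but sub-total weekly fitness cost under which an average active
hairpin loses ≈ 2.1 log2 units over four weeks.

Infection (MOI), puromycin selection and PCR amplification are deliberately
not modelled mechanistically: the analysis consumes counts, so only their
net effect (baseline composition plus overdispersed counting noise) is
represented. UMIs and amplification bias are out of scope.

## Barcode FASTQ emission and counting

`write_barcode_fastq` emits exactly one read per count unit:
`flank5 + barcode + flank3`, constant Phred+33 quality "I", independent
per-base substitution noise at the configured error rate. This makes
counting an exact inverse at error rate 0.

`count_barcodes` extracts the barcode either at a fixed offset or by
locating the 5′ flank; the locator takes the *leftmost* window within one
substitution of the flank. Leftmost-admissible (rather than
exact-match-anywhere-first) matters: with an error inside the true anchor,
a chance exact occurrence of the flank further into the read must not
capture the barcode position. Barcode matching tolerates 0 or 1 mismatches
(default 1); a read equidistant from two library barcodes is discarded, so
no read is ever double-counted, and assigned + discarded reads always equal
the total. `N` never matches; comparisons are case-insensitive. With
error rate ε and barcode length L, the unrecoverable fraction is bounded by
the binomial probability of ≥ 2 errors in the barcode (≈ C(L,2)ε²) plus
≥ 2 errors in the anchor — about 0.5 % at ε = 0.01, L = 10.

## Depletion scoring and candidate tiers

On CPM-normalized counts, each hairpin's score is

    lfc_i = log2((mean treated + ε) / (mean reference + ε)),  ε = 0.5

A hairpin is *depleted* when `lfc < −1` (strictly; more than 2-fold loss)
and its reference abundance is at least 5 CPM — the floor suppresses calls
driven by low coverage, where the log-ratio of small counts is dominated by
noise. Hairpins depleted in the acute arm have their calls cleared
(shRNA-level subtraction; a gene-level variant clears every hairpin of any
acutely-hit gene). Per gene, the tier is *stringent* when ≥ 4 surviving
hairpins are depleted — i.e. depletion supported by more than three
independent sequences — and *candidate* when ≥ 2. Thresholds are
configurable; lowering the lfc threshold can only shrink the depleted set
(monotonicity, property-tested).

A mean-of-replicates CPM log-ratio was chosen over rank-aggregation scores
because it has an exact element-wise oracle and composes transparently with
the subtraction rule; rank aggregation is a documented possible extension,
not the default.

## Negative-binomial differential expression

Counts are normalized by median-of-ratios size factors (geometric-mean
reference over genes positive in all samples; factors centred to multiply
to 1). Per-gene dispersion is estimated by method of moments within groups,
`φ = (var − mean)/mean²` floored at 0 and pooled by degrees of freedom,
then shrunk toward the across-gene mean raw dispersion:

    φ̂ = (1 − w)·φ_raw + w·φ_common

The default weight is precision-dependent, `w = d₀ / (d₀ + df)` with prior
degrees of freedom d₀ = 20 and df the residual degrees of freedom. At 3 vs 3
replicates (df = 4) the per-gene moment estimate is mostly noise and the
weight leans on the common value (w ≈ 0.83), which is what keeps the test
calibrated — with a light fixed weight the plug-in dispersion makes the
test anticonservative (genes whose sample variance is small by chance are
treated as nearly Poisson). At 8 vs 8 (df = 14) gene-specific signal
carries more weight (w ≈ 0.59). An explicit fixed weight in [0, 1] can be
passed instead.

The test is a likelihood-ratio test of a shared NB mean against free
per-group means at fixed φ̂ (the group sample mean is the NB mean MLE at
fixed dispersion), referred to χ²(1). The LRT was preferred over a Wald
test for stability at low counts. Genes with all-zero counts are dropped
before testing. `log2fc` uses normalized group means with pseudocount 0.5;
BH-adjusted p-values are reported alongside.

The significance filter classes genes as differentially regulated at
raw p < 0.05 (strict) and |log2FC| ≥ 0.58 (inclusive; ≈ 1.5-fold). Raw p is
the default deliberately — it matches the screening-stage convention this
pipeline reproduces — with `use_fdr` switching the filter to the BH-adjusted
values. The ±0.58 boundary is read as inclusive ("minimum" fold change).

Under one-sided planted DE the size factors absorb part of the global
composition shift; the estimable quantity is the planted-vs-background
contrast, which is what the recovery tests measure.

## Integration and enrichment

Candidate calling is a sequence of intersections on case-normalized
(upper-cased, trimmed) gene symbols, each recording its parent sets:
screen-tier genes × differentially regulated genes (both directions by
default, since resistance-associated regulation is not direction-restricted
at this stage; direction is a flag); knockdown-down × resistant-up (direct
target candidates); and the genes down in both of two knockdowns
(co-regulated targets). No alias mapping is attempted. Venn summaries give
exclusive region counts for 2 or 3 sets, which always sum to the union.

Over-representation uses the exact hypergeometric upper tail P[X ≥ k]
(identical to the one-sided Fisher exact test) against an explicit
universe — by default all genes in the expression matrix, not the genome,
the standard background correction for expression-derived queries.
Enrichment significance is P ≤ 0.05, inclusive. The rank-based statistic is
the classic weighted Kolmogorov–Smirnov running sum (weight exponent
p = 1): hits rise by |score|^p normalized over the set, misses fall by
1/(N − m); the enrichment score is the signed extremum, always in [−1, 1].
Its p-value permutes gene labels (set membership over positions) with the
plus-one estimator (1 + exceedances)/(1 + n_perm); a gene-permutation null
fits a pipeline that consumes a single ranked list (no per-sample phenotype
labels survive to this stage), and no NES-style renormalization is
attempted. Permutation tie comparisons carry a 10⁻¹² tolerance so exact
ties are not lost to cumulative-sum rounding.

## Bench-assay closed forms

qPCR fold change is 2^(−ΔΔCt) with amplification efficiency fixed at
perfect doubling (no efficiency correction), invariant to adding a constant
to all four Ct values. ChIP fold enrichment is (IP/input)/(IgG/input),
consuming ratios (the Ct→ratio conversion, which depends on dilution
factors, is left to the caller). Tumor volume is length × width² × 0.52
(mm³), monotone in both calipers; length < width warns (axes likely
swapped) but computes.

## Synthetic RNA-seq and what passing tests show

`simulate_rnaseq` draws NB counts (φ = 0.1 default) around group means
`baseline × 2^effect`, with baselines log-normal (log2 mean 8, σ 1.5) and
effects attached per contrast; groups shared between contrasts express
effects shared between knockdown conditions. The demo pipeline plants
drivers as strongly up-regulated in the resistant contrast (+2 log2,
reflecting the large expression shifts that accompany acquired resistance)
plus ±2 background DE genes, target genes down on knockdown 1, and
co-regulated genes down on both knockdowns.

The generator emulates count structure, library-size differences,
overdispersion and planted effect sharing. It does **not** emulate
GC/length bias, batch effects, outlier samples, correlated genes, or
mapping ambiguity — so passing recovery tests demonstrate the correctness
of the pipeline's logic under its stated noise model, not performance on
real sequencing data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale versions of the study design:
100 genes × 8 hairpins (10 drivers, 5 acute-essential) at depth 2×10⁶ over
20 seeds for screen recovery; 5,000-gene null matrices over 10 seeds and a
200-gene planted cohort (baseline 500, n = 8 per group) over 20 seeds for
DE calibration and power; ~10⁴ reads for the noisy FASTQ round trip. The
planted-effect recovery criterion is evaluated on the cohort aggregate
(mean estimated log2FC within ±0.25 of +1 and ≥ 80 % of planted genes at
p < 0.01 per seed): a single gene at these settings has sd(log2FC) ≈ 0.23,
so a per-gene ±0.25 window could not be met in 18/20 seeds by any unbiased
estimator, while the cohort mean pins the estimator's accuracy tightly.

Other numerical choices: p-values are clipped into (0, 1] (LRT statistics
floored at 0 before χ²); means are floored at 10⁻¹⁰ inside NB
log-likelihoods so zero-count groups contribute finite terms; barcode-space
feasibility (4^L ≥ library size) is checked up front with exact enumeration
of the space when it is small; all generators are pure functions of their
arguments including the seed, and the pipeline report serializes with
sorted keys so reruns are byte-identical.

## Known limitations

- The depletion call has no p-value model; tiers are count-based.
- Exact equivalence with shrinkage-based DE packages is not attempted; the
  dispersion estimator is moment-based with a single common-value prior.
- Single-factor, two-group contrasts only.
- Gene symbols are compared literally after case normalization; no alias
  resolution.
- Headline counts from the motivating screen design (e.g. 1,072 subtracted
  genes, 38 overlay hits, 8 stringent genes, 56 target candidates, 262
  co-regulated genes — the last reported elsewhere as 264, a discrepancy we
  surface rather than reconcile) depend on the original deposited data and
  an unstated depletion criterion; they are not reproducible at desk scale
  and are not targets of this package's tests.
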