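# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `embryolnc`. Module order follows the pipeline.

## Synthetic data (`simdata`)

The generator emulates a stage-structured single-cell FPKM study of human
pre-implantation development: seven consecutive stages (metaphase-II oocyte,
zygote, 2-cell, 4-cell, 8-cell, morula, late blastocyst) with 3, 3, 6, 12,
20, 16 and 30 cells respectively (90 cells), a genome-like annotation, and an
assembly fixture for the transcript-filtering steps. All stochastic draws
flow from one `numpy` Generator seeded by `SimConfig.seed`; identical
configurations produce byte-identical output files.

**Annotation.** Genes (default 400, 30% lncRNA) are placed on 3 chromosomes
with ≥ 20 kb spacing so that no unplanted pair falls inside the 10 kb
neighbor window. Planted neighbor pairs (15 divergent, 15 unidirectional; one
lncRNA + one coding gene each) sit at a 5 kb body gap; divergent pairs are
head-to-head (left gene on '−', right on '+'). Coordinates are 0-based
half-open internally and 1-based inclusive in GTF.

**Expression model.** Per-gene stage means are built on the log₁₀(FPKM+1)
scale, matching the analysis scale of the specificity score:

- *flat* genes: a constant baseline, lognormal across genes (median ≈ 10
  FPKM, sd 0.4 log₁₀ units);
- *stage-specific* genes: 0 FPKM off-stage, 100 FPKM in their stage.
  Stage-restricted transcripts in early embryos (e.g. zygotic-genome-
  activation genes) are essentially silent outside their window, and the
  extreme pattern is what the specificity score is designed to detect;
- *module* genes: baseline plus loading × a Gaussian bump over the stage
  axis (amplitude 2.5 log₁₀ units, peaks spread across stages, loadings
  U(0.7, 1.3)). The amplitude is large enough that module genes survive the
  differential-expression screen even in the 3-cell stages;
- *neighbor-pair* genes: a fixed 30-FPKM baseline plus a shared per-stage
  latent factor (truncated normal, sd 0.8 log₁₀ units). The second member
  loads on the shared factor with weight ρ (default 0.8) and on an
  independent factor with weight √(1−ρ²), so at ρ = 1 and zero noise the
  two log profiles are exactly affine and correlate at 1.0. Truncation of
  the latent keeps baseline + latent positive, preserving that exactness;
- lncRNA mean FPKM is multiplied by `lnc_expression_scale` (0.25), and half
  of the planted stage-specific genes are drawn from lncRNAs
  (`lnc_specific_bias`), reproducing the lower-expressed, more temporally
  specific character of lncRNAs;
- per-cell noise is N(0, 0.2) on the log scale; dropout is
  expression-dependent: a value is zeroed with probability
  `dropout_rate` · logistic((1.0 − mean_log)/0.3), i.e. up to 10% for weakly
  expressed genes and essentially never above ~100 FPKM, as in deep
  full-length single-cell protocols. A flat zero-inflation would make
  strongly expressed genes drop out at the same rate, which such protocols
  do not show, and would make the planted structure unrecoverable in the
  3-cell stages.

**What the generator does not emulate:** read-level sampling, UMI/length
biases, batch effects, doublets, correlated noise between genes beyond the
planted structure, and any particular genome's gene density. Passing the
recovery tests therefore demonstrates correctness of the analysis code under
the stated noise model, not performance on any real dataset.

**Assembly fixture.** Transcripts in five classes (novel lncRNA,
novel-but-coding-like, annotated-overlapping, < 200 bp, single-exon) appear
in two "assembler" sets with identical intron chains (set B terminal exons
extended 50 bp to exercise terminal-end tolerance); single-exon transcripts
appear in set A only. Coverage values come from separated ranges (good
10–50, bad 0.2–2 reads/base) with labels alternating inside each
coding/noncoding category so neither ROC is degenerate.

## Coverage thresholding (`threshold`)

Recovery of an assembled transcript is (overlapping exonic bases)/(reference
exonic length) against its best-matching reference; ≥ 0.75 (inclusive) is
*good*. The candidate set T is the sorted unique observed coverages plus a
below-minimum and an above-maximum sentinel; the sentinels complete the ROC
endpoints at (1, 0) and (0, 1). Sensitivity uses "coverage ≥ t", specificity
"coverage < t", so filtering with `keep if coverage ≥ t*` matches the curve
exactly. Ties in the corner distance break toward the smallest threshold
(most permissive, retaining more transcripts). The combined threshold is the
arithmetic mean of the coding and noncoding optima. Because T contains only
observed values, the optimum under perfect separation is the smallest good
coverage rather than a midpoint inside the gap; the tests assert the
separation property (perfect classification at t*) rather than a particular
in-gap value.

## Novel-lncRNA pipeline (`lncfilter`)

"Assembled by both" means identical (chromosome, strand, intron chain);
terminal exon ends may differ and the first assembler's coordinates are
kept. Single-exon transcripts never match. Annotation overlap is ≥ 1 bp,
exon-vs-exon, strand-agnostic — a transcript entirely inside an annotated
intron survives. Length is summed exonic length with a strict > 200 bp
cut and ≥ 2 exons. The coding-potential consensus defaults to "all four
tools noncoding"; a ≥ 3/4 majority rule is available. Every input transcript
receives exactly one audit entry (kept, or the first eliminating stage), and
stage counts are non-increasing by construction.

## Temporal specificity (`jsspec`)

Entropy uses log base 2, which bounds the Jensen–Shannon divergence against
a point mass by 1 and puts scores on the [0, 1] scale the 0.5 cutoff
presumes. The Jensen–Shannon *distance* is the square root of the
divergence (the metric form); `sqrt=False` exposes the raw divergence for
comparison. Stage pooling is the mean FPKM across a stage's cells (median
available). Unexpressed genes (all-zero stage vector) are flagged and
excluded from score distributions rather than scored 0. Argmax ties resolve
to the earliest stage. Class comparisons: two-sided KS on maximal scores,
two-sided Fisher exact on the specific/non-specific × class table,
Mann–Whitney U on sample-pair Spearman distributions (computed from a rank
transform of the class submatrix; sample pairs with constant ranks are
dropped), and KS on per-gene maxima of log₁₀(FPKM+1).

## Cis-neighbor analysis (`cisneighbor`)

Overlapping gene bodies count as neighbors (gap 0); the 10 kb cut is strict.
Convergent (tail-to-tail) pairs are classified and reported separately from
the two main strata (divergent, unidirectional). Pair correlation is Pearson
on density-normalized stage profiles, with significance flagged at p ≤ 0.05;
undefined correlations (constant profiles) are excluded from summaries. The
null is a seeded uniform sample of distinct coding–coding pairs excluding
true neighbors, capped with a warning if fewer pairs exist than requested.
Effect size is Cohen's d with the pooled (n−1) standard deviation, the
companion of the Student t reported alongside. The per-module
neighbor-fraction summary uses a one-sample t of the neighbor percentages
against 50%, which is algebraically identical to the paired t on the
(neighbor − non-neighbor) split because each row sums to 100%; zero variance
across modules is flagged rather than tested.

## Co-expression networks (`coexpr`)

Differential expression between consecutive stages uses a variance-moderated
pooled t on log₁₀(FPKM+1): per-gene variances are shrunken toward the
across-gene median with prior df 4, and the test df is prior + residual.
With only three cells in the earliest stages an unmoderated two-sample t has
~2 effective df and cannot reach q < 0.01 at any realistic noise level;
moderation is the standard small-sample remedy. BH correction is applied
within each consecutive-stage comparison; fold change is
log₂((mean₂+1)/(mean₁+1)) on stage-mean FPKM (the +1 guards zeros); the
stage-specific flag requires q < 0.01 and |log₂FC| > 1 in at least one
comparison. An externally supplied gene list can bypass the screen.

The signed adjacency ((1+r)/2)^β resolves the ambiguity of "raising a
correlation matrix to a power" for negative r while preserving sign
information. The soft power defaults to 5; `pick_soft_threshold` returns the
smallest candidate whose binned log–log degree-distribution fit reaches
R² ≥ 0.9, falling back to the best fit (warning) or the default when the fit
is degenerate. TOM follows the standard form
TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with unit diagonal.

Module detection is a simplified dynamic cut: average-linkage clustering on
1 − TOM, a static height cut chosen among merge-height quantiles to maximise
the weighted Newman modularity of branches ≥ `min_module_size`, then a
hybrid-like rescue assigning unclustered genes to their best module when
kME ≥ 0.3. Unassigned genes are labelled "grey". Eigengenes are first
principal components of the per-gene standardized module expression, scaled
to unit sample variance and sign-fixed so member genes correlate positively
on average. Modules merge iteratively while any eigengene pair correlates
above 0.85. Labels come from the conventional color vocabulary in
descending size order. Module–trait relations use one-hot stage indicators
plus an ordinal "time" axis (stage index 1..n), Pearson r with Student-t
p-values (n−2 df), flagged at r > 0.6 and p < 10⁻⁴. The hub p-value gate is
exposed but off by default: at 90 samples kME ≥ 0.9 already implies a
vanishing p, and at small synthetic n a fixed 10⁻²² gate would be
unattainable. Interaction filtering keeps rows with ndG ≤ −0.1 (inclusive).

## Preservation and enrichment (`preserve`)

The ortholog map keeps only strict one-to-one pairs (any gene appearing in
two distinct rows is ambiguous and dropped), making the retained map a
bijection. Module overlap is the set-based upper-tail hypergeometric
P(X ≥ k) on the shared universe (genes mapped across species and present in
both analyses); a kME-weighted variant exists in the literature but
publishes the same count + p cells that the set-based test reproduces.
Enrichment uses the same tail test against GMT sets, reported at raw
p ≤ 0.05 and overlap ≥ 5, with BH q-values computed across a module's terms
added for transparency (no correction is applied to the cutoff itself).

## Numerical conventions

- Entropy treats 0·log 0 as 0; the divergence is clamped at ≥ 0 before the
  square root.
- Correlations of constant vectors are undefined: genes are excluded
  (kME), pairs flagged (cis analysis), or the call errors naming the genes
  (network construction).
- 1 − TOM is clamped at ≥ 0 before clustering to absorb floating-point
  noise at TOM = 1.
- Oracle-equivalence tests assert 10⁻¹² absolute agreement; boundary rules
  (recovery 0.75 inclusive, length > 200 strict, gap < 10 kb strict,
  ndG ≤ −0.1 inclusive) are tested exactly.

## Problem sizes

The test suite and acceptance script run the full pipeline on 400-gene ×
90-cell simulations (module recovery over five seeds), a 10,000-pair
correlation null, and a 200-draw × 64-cell overlap-calibration study —
sizes chosen so planted effects are comfortably detectable while the whole
analysis completes in seconds on one core.

## Known limitations

- The tree cut is a modularity-guided static cut with kME rescue, not a
  full reimplementation of the Dynamic Hybrid algorithm; nested modules
  separated only below a single global height are not split. The cut is
  pluggable.
- The moderated-t differential-expression screen is a generic stand-in, not
  a count-model test; with FPKM input and tiny stages its q-values should
  be read as a screening device.
- Scale-free fit on small gene sets is noisy; the default β = 5 is the
  safer choice below a few hundred genes.
- The specificity score depends on the pooling rule (mean vs median) for
  skewed stages; both are exposed.
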