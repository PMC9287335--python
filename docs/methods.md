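# Methods

This note documents the statistical procedures implemented in `mirlink`,
the generative model behind its synthetic cohorts, the defaults and why
they were chosen, and the limits of what the synthetic benchmarks show.

## Correlation analysis

Expression enters the correlation stage as log₂(CPM+1), with CPM computed
without a prior count and features required to exceed 1 CPM in *every*
sample (strict inequality; the filter is deliberately conservative so that
no pair is driven by a handful of zero-inflated libraries). For each
miRNA–mRNA pair the Pearson coefficient is tested two-sided through the
exact transform t = r√((n−2)/(1−r²)) with n−2 degrees of freedom, and BH
adjustment is applied once across the full pair table. Zero-variance
features yield NaN rows that are excluded from the BH family size. The
default significance level on adjusted p-values is 0.05.

The decision to correlate on log₂(CPM+1) rather than raw CPM is a
variance-stabilization choice; the transform is monotone, so the KS-based
shift analyses downstream are unaffected by it, and only the Pearson
coefficients themselves depend on it. TMM factors are *not* applied on
the correlation side: composition bias rescales whole samples and
therefore shifts all log-expression values of a sample equally, which
Pearson correlation across samples largely absorbs; TMM is applied where
it matters, inside the DE chain.

## Target groups and shift tests

Prediction tables carry (miRNA, mRNA, source, score, site type) records
from three source conventions: TargetScan-style context scores (more
negative = stronger predicted repression) with 8mer / 7mer-m8 / 7mer-1a
site classes, miRDB-style 0–100 confidence scores, and miRTarBase-style
validated pairs without scores. Duplicate records per (miRNA, mRNA,
source) collapse to the best score, since site-level exports list one row
per binding site. Score filters are per-source: an absolute context
cut-off for TargetScan, and either an absolute cut-off or a top-fraction
rule for miRDB (the caller picks one); validated pairs are never
score-filtered. The shipped defaults mirror a dual-tool screen: context
< −0.035 with the 5% best miRDB scores for the transcriptome-wide
analysis (restricted to the top 40% highest-expressed mRNAs, ranked by
mean log₂-CPM with a 0.5 prior), miRDB > 85 for single-miRNA analyses,
and the stricter context < −0.366, miRDB > 92.8, r < −0.1 combination for
selecting ontology-analysis input genes.

Shift testing uses the one-sided two-sample Kolmogorov–Smirnov statistic
D⁺ = sup₍ₓ₎ (F_target(x) − F_background(x)) with right-continuous step
ECDFs, where the background is the set of mRNAs (or pairs) with no
prediction from *any* source. The p-value is the asymptotic tail
exp(−2D²·n_eff), n_eff = n_a·n_b/(n_a+n_b), capped at 1. This plain
exponential is accurate at the group sizes these analyses produce
(dozens to thousands); exact small-sample p-values are out of scope, and
the statistic is checked in the tests against a brute-force supremum over
pooled breakpoints. One caveat is inherited from the design rather than
the implementation: pooled all-pairs r values are not independent (pairs
share miRNAs and samples), so the global shift test is approximate and
becomes anti-conservative when few features contribute many pairs. The
null-calibration benchmark therefore uses cohorts of ≥100 miRNAs × 1000
mRNAs, where the dependence is diluted and the test holds its nominal
size.

## Enrichment

Correlation-decile enrichment summarizes each mRNA by its most positive
(or most negative) r across miRNAs, forms the top decile, and contrasts
gene-list membership against the mirrored decile or an equal-size seeded
uniform draw, with a Yates-corrected 2×2 Pearson χ². Over-representation
analysis is the standard upper-tail hypergeometric per term — population
= expressed background, successes = term∩background, draws = input list —
with BH across terms and the GeneRatio (k/n, n = input overlap with the
union of all sets) and Count (k) reporting convention. Gene sets are
user-supplied GMT; the synthetic generator can emit a toy collection with
half its terms enriched for true targets.

## Differential expression

The transfection arm re-implements the voom chain: features kept when
count > 1 in ≥ ¼ of samples (a documented flag switches to the
"count ≥ 1 in strictly more than 25%" reading); TMM normalization factors
with edgeR's defaults (reference sample by upper-quartile proximity,
doubly-trimmed weighted mean of M values, 30%/5% trims, delta-method
weights, geometric-mean-1 rescaling); voom's log₂((count+0.5)/(effective
libsize+1)·10⁶) with a lowess (span 0.5, 3 robustness iterations) trend
of √(residual sd) against average log₂ count, interpolated at each
observation's fitted log-count with constant extrapolation, inverted to
weights sd⁻⁴; a weighted least-squares group-means fit with the explicit
treatment−reference contrast; empirical-Bayes moderation with the prior
(d₀, s₀²) estimated by moment matching on log s² via digamma/trigamma
corrections (trigamma inverted by Newton iteration). Two boundary rules
matter and are tested: when the spread of log-variances does not exceed
sampling noise the prior df is infinite and the common variance is the
arithmetic mean of the residual variances; and the total df of the
moderated t is capped at the pooled residual df so the infinite-prior
branch still uses a proper reference distribution. The implementation
agrees with the reference R chain to ~1e−10 on fixed fixtures (both prior
branches), and TMM factors to 1e−12; those frozen values live in the test
suite.

The down/up asymmetry statistic is a goodness-of-fit χ² (no continuity
correction) of the significant |log₂FC| > 1 counts against a 50:50 split.
Alternative constructions (Yates-corrected, 2×2 against the background)
were considered and rejected as less interpretable; none of them is
canonical, so the construction is documented here as this package's
choice.

## Concordance

Candidates are transcripts that are both DE-significant (BH < 0.05) and
predicted targets of the transfected miRNA. Their patient-cohort r values
are split at the 0.2 and 0.8 linear-interpolation quantiles; the lower
group's logFC mean is tested against the higher group's with a one-sided
Welch t-test (pooled-variance optional). Welch is the default because the
two tails of a truncated candidate set have no reason to share a variance.
The two-stage top-pair selection first keeps the 25 most negatively
correlated candidates, then re-ranks by DE p-value and returns the top 4;
both stage sizes are flags.

## The synthetic cohort generator

The generator is the package's calibration instrument. Per sample s,
library sizes are log-normal, LogNormal(μ_L=ln 10⁷, σ_L=0.3) — tens of
millions of counted reads, typical of bulk sequencing. Per miRNA i a
baseline a_i ~ N(5, 2²) log₂-units and latent abundance z_is = a_i + e_is,
e_is ~ N(0,1); per mRNA j a baseline b_j ~ N(4, 2²) and

    m_js = b_j + Σ_{i:(i,j)∈pairs} β_ij (z_is − a_i) + ε_js,   ε ~ N(0, τ²)

with τ = 1.0 (patient-to-patient biological spread on the log₂ scale).
An intragenic miRNA with host h receives γ·(m_hs − b_h) *before* coupling
terms — the host drives the miRNA, matching the co-transcription
interpretation, with γ = 1 by default. Counts are negative-binomial
(gamma–Poisson) with per-sample means L_s·2^x / Σ 2^x and variance
μ + φμ², φ = 0.1 for patients and φ = 0.05 between cell-line replicates
(transfection), with replicate noise τ_transf = 0.25 — cell-line
triplicates are far tighter than patients.

Couplings: a fraction (default 0.03 of the miRNA×mRNA grid, matching the
~3% density of common predicted pairs in a dual-tool screen of a
well-expressed transcriptome) of pairs carry β < 0, graded by site class
(8mer −0.6, 7mer-m8 −0.4, 7mer-1a −0.2, miRDB-only −0.4, validated −0.5,
in log₂-units per log₂-unit of miRNA deviation) and jittered per pair by
a multiplicative Uniform(0.5, 1.5) factor — site efficacy varies between
pairs even within a class. The same per-pair strength drives the
transfection arm: a mimic at repression depth δ multiplies target means
by 2^(−δ·w_j·|β_j|/mean|β|), w_j ~ Uniform(0.5, 1.5). This shared factor
is what makes patient correlations and transfection fold changes
concordant, as they are for real repression; with independent effect
sizes the concordance analysis would have no signal to find, by
construction. Prediction tables are emitted with score distributions that
make stringent thresholds enrich for true pairs (true: context
U(−0.8,−0.05), miRDB U(80,100); spurious at rate 0.01: context U(−0.3,0),
miRDB U(50,85)), and the annotation stage writes a GTF with intragenic
miRNAs strictly inside their hosts plus a disease gene list (~22% of the
transcriptome) optionally enriched for host genes.

Everything is driven by numpy Generator streams derived from
(seed, stage-index) SeedSequences: identical config and seed give
byte-identical TSV output, and the generator stages (cohort, predictions,
transfection, annotation) are independently reproducible.

What the generator does *not* emulate — and hence what passing benchmarks
do not show: co-regulation networks (all null pairs are independent, so
real data's pervasive correlation structure and its effect on BH-adjusted
counts is absent), batch effects, isomiRs/UMIs, read-level artefacts,
indirect (transcription-factor-mediated) miRNA effects, and saturation or
off-target behaviour of mimic transfection. Benchmarks on this generator
validate the statistical machinery, not the biological error rates of
prediction databases.

## Problem sizes in the shipped benchmarks

The default synthetic transcriptome is 2000 mRNAs — a deliberate
scale-down from a ~6000-gene well-expressed transcriptome that preserves
the multiplicity structure while keeping the all-pairs stage (~322k
pairs at 161 miRNAs) instantaneous. The null-calibration benchmark uses
86 samples with 100 miRNAs × 1000 mRNAs over 20 seeds; recovery
benchmarks use 86-sample cohorts with ≥50 true pairs per site class; the
transfection benchmark embeds ~200 targets at true log₂FC −1 and depth
10⁷. These sizes give each test comfortable power while the whole suite
runs in seconds.

## Known limitations

- The pooled global shift test inherits cross-pair dependence (above).
- The asymptotic KS p-value is approximate below ~10 observations per
  group; groups that small are reported but should be read as
  descriptive.
- The DE chain implements the default voom path only: no quality
  weights, no duplicate-correlation, no robust moderation, no fold-change
  thresholding of the moderated test.
- GO machinery takes gene sets as given: no DAG propagation or term
  redundancy reduction.
- `classify_mirna_loci` is strand-agnostic and requires full interval
  containment; a miRNA straddling a gene boundary is intergenic.
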