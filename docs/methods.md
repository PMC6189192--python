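# Methods

This note documents the models, numerical choices and limitations of the
package; it is the place where genuinely open design decisions are recorded.

## Preprocessing

Probe-level matrices are collapsed to one probe per gene, keeping the probe
with the largest interquartile range across samples. The IQR uses the
linear-interpolation quantile convention (pinned as `preprocess.IQR_METHOD`);
ties between probes are broken by input order. Quantile normalization maps
every column onto the mean order-statistic distribution, with within-column
ties receiving the mean of the order-statistic means they span — the
behaviour of the standard Bioconductor implementation, which the test suite
pins with a frozen 3×2 example. Mean-centering is value − mean per gene, and
is applied **within batch** when a batch map is present: multi-study cohorts
are centered per study before being combined, so study-level offsets cannot
masquerade as biology. Centering and quantile normalization are idempotent,
which the tests assert.

## Signature scoring

The running enrichment score walks the genes of one sample in order of
decreasing expression, adding 1/m at signature members and −1/(n−m)
elsewhere; its prefix minimum/maximum (E−, E+) are the low/high-tail
enrichment statistics. The final prefix value is identically zero, which
guarantees −1 ≤ E− ≤ 0 ≤ E+ ≤ 1. Expression ties are broken by gene
identifier (stable lexicographic order) so results do not depend on input
column order.

Because the statistic depends only on member ranks, the permutation null is
a function of (n, m) alone: it is built once per geometry and shared across
samples, which is numerically identical to permuting each sample's
expression values but removes a factor of n_samples from the cost. For
n ≤ 12 the null can be enumerated exhaustively over all C(n, m) placements,
and the implementation is checked against a brute-force prefix-sum oracle on
exactly those geometries. Empirical p-values use +1 smoothing
(p = (1 + exceedances)/(1 + n_P)), so the floor is 1/(n_P + 1); the default
n_P = 100,000 gives the 10⁻⁵ floor, and lower values are appropriate for
exploratory runs. The reported per-sample score is the extremum of the more
significant tail. Positive subtype calls (P+, R+) require significant
**up**-regulation at α = 0.05 by default; significant down-regulation is a
negative call. α for P/R calls is a parameter; raw p-values drive the calls
and BH-adjusted values are also reported.

Signature members absent from the expression universe are dropped with a
warning (platforms differ) rather than raising.

## TF activity inference

The model G_ik = Σ_j T_ij A_jk is solved per sample by linear least squares
over the genes annotated as targets. An intercept is fitted by default (its
coefficient is estimated but never reported as an activity); the flag is
exposed because the choice is not determined by the model. Collinear design
columns are handled by pivoted QR: a maximal independent column subset is
retained and the remaining coefficients are reported missing (NaN),
propagating to missing p-values and negative calls. On full-rank designs the
solution equals the Moore–Penrose pseudoinverse solution to 1e-8 and leaves
residuals orthogonal to the design — both asserted against independent
oracles in the tests. TFs whose activity is constant across samples (or
entirely non-identifiable) are removed before significance testing.

The permutation null shuffles each sample's expression vector across genes
(n_perm times per sample, default 100) and pools the re-inferred scores over
samples and permutations into one reference vector per TF. Pooling conflates
sample-specific scale differences; mean-centered input mitigates this, and
degenerate permuted fits are retained as legitimate null draws. The K± call
for a designated TF uses p = (1 + #{null ≥ observed})/(1 + n) with a strict
p < α threshold: p exactly at α is a negative call.

## Association analyses

Spearman correlation is computed as the Pearson correlation of midranks,
with a permutation p-value obtained by permuting one vector's sample
assignment; two-sided by default (sidedness is a flag). For the gene- and
TF-wide tables one shared set of score-vector permutations serves every row:
rows are tested marginally, so this is valid and orders of magnitude
faster; rows with zero rank variance are reported missing. BH adjustment is
applied within each table separately. Note that calibration statements about
these tables only apply to genes that are not themselves signature members —
a signature gene's expression mechanically determines the enrichment score,
so its correlation is genuine signal, not a false positive.

Subtype overlap between two labelings uses the one-tailed hypergeometric
upper-tail probability per category pair, with the best and second-best
match reported per category. A TF is labelled *sustaining* (P→P or R→R) by a
conjunction: positive, BH-significant activity–score correlation AND
positive, BH-significant enrichment of its annotated targets against the
corresponding gene-correlation ranking (the running-score machinery applied
to correlation-ranked genes). BH at α = 0.05 within each programme is the
default; raw thresholds are available.

## Survival

Kaplan–Meier, log-rank and Cox proportional-hazards fits delegate to
lifelines behind a contract-checked surface: negative times, single groups,
constant or collinear covariates and missing outcome columns raise before
any model is fit. Ties use the Efron approximation. Stage is coded as a
single ordinal covariate, age as continuous, gender as a binary indicator.
The three standard multivariate models combine the continuous P and R
enrichment scores (jointly and singly) with stage, age and gender for
overall and relapse-free survival. On tie-free two-group data the log-rank
statistic equals the Cox score test at β = 0; the tests verify this against
a hand-written risk-set summation to 1e-6 relative.

## Immune association

Deconvolved immune-cell fractions are consumed as input (any samples ×
cell-types table with fractions in [0, 1]; deconvolution itself is out of
scope). Per cell type, fractions are Spearman-correlated with the designated
TF's activity score (BH across cell types); K+ vs K− fraction distributions
are compared with the two-sided two-sample Kolmogorov–Smirnov test
(asymptotic p-values; optionally within P strata, both pooled and stratified
modes are provided because either is defensible). The sorted-immune-profile
validation uses a one-tailed Welch (unequal-variance) t-test for
myeloid > lymphoid activity; Welch is the default because pooling variances
buys nothing and costs robustness.

## Synthetic cohorts

The generator emulates a multi-study, mean-centered expression cohort:

- **Noise** is i.i.d. Gaussian per gene and sample (`noise_sd`, default 1):
  normalized log-scale intensities are well idealized by Gaussian residuals.
- **Programmes**: dedicated P and R signature gene sets (100 genes each by
  default) are shifted by `effect_size` (default 2 noise-SD units — a strong
  but realistic programme signal) in programme-positive samples. P+ is
  Bernoulli(`frac_P_pos`); with probability `pr_anticorrelation` (default
  0.7) a sample's R status is the complement of its P status, otherwise
  independent — producing the negative P/R coupling real cohorts show.
- **TF activities** are N(0, `activity_sd`) per TF and sample and reach
  expression only through the ternary network (mode × activity added to each
  target), mirroring the fact that TF activity is not TF expression. The
  designated TF (first in the network) is made all-activating; its activity
  is pinned to `effect_size` in the planted K+ samples (a `frac_K_pos` = 0.2
  fraction drawn from within R+ samples) and elevated by a quarter effect in
  the remaining R+ samples, so its activity is *continuously* associated
  with the R programme the way a remodelling-driving activator's would be. A
  bare binary shift proved too weak an association, and coupling K+ to all
  R+ samples pushes the cohort mean so high that per-gene centering absorbs
  half the planted shift; the graded design satisfies both the sensitivity
  and the driver-recovery behaviour the generator is meant to exhibit.
- **Survival** is exponential with hazard multiplied by `hazard_ratio_Rpos`
  (default 2) for R+ samples and independent exponential censoring.
- **Immune fractions**: myeloid cell types follow a noisy logistic transform
  of the designated TF's activity (capped so per-sample sums stay ≤ 1
  without renormalization — renormalizing would induce spurious negative
  correlations in the independent lymphoid columns).
- **Batches** (optional, `n_batches`): per-batch gene-wise offsets that
  per-batch centering removes exactly.

A fully null cohort for calibration is
`SyntheticConfig(effect_size=0, activity_sd=0, hazard_ratio_Rpos=1)`: only
then does the expression carry no planted structure at all, which is the
regime in which positive-call rates must match their nominal level. With
background `activity_sd` > 0 the non-designated TF activities are *genuine*
signal and their detection is power, not miscalibration.

What the generator does **not** emulate: probe-level artefacts, platform
differences, realistic deconvolution mixtures, correlated gene-gene noise,
or non-proportional hazards. Passing recovery tests therefore demonstrate
the correctness of the inferential machinery under the stated model, not
robustness to every property of real cohorts.

## Problem sizes and determinism

The test-suite and demo runs use the default 300-sample, 2000-gene,
50-TF cohort with reduced permutation budgets (1000 signature/Spearman
permutations, 50 expression shuffles per sample for the TF null) — sizes
chosen so the complete validation runs in seconds while keeping p-value
floors (1/1001) far below the α = 0.05 decision points. All randomness flows
from one master seed through named streams (`utils.rng_for`), so any stage
can be rerun in isolation and full pipeline runs are byte-identical given
the same configuration.

## Known limitations

- The least-squares model ignores TF–TF interactions and applies no
  regularization; heavily overlapping target sets reduce identifiability
  (handled, but only by dropping coefficients).
- The pooled TF null assumes samples share a scale; uncentered input
  weakens this.
- Asymptotic KS p-values are approximate for very small groups.
- "Sustaining" is a correlational pattern label, not a causal claim.
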