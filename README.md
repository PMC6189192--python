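# prtf

Stratification of bulk tumour expression cohorts by **proliferation (P)** and
**tissue-remodelling (R)** gene signatures, inference of per-sample
**transcription-factor activity scores** from a signed target network, and
the downstream association machinery that links both to survival and to
immune-cell infiltration. The package is aimed at computational biologists
analysing multi-study microarray/RNA cohorts (colorectal cancer being the
motivating setting) and ships a synthetic-cohort generator with planted
ground truth so every stage can be validated by recovery.

## The methods

**Single-sample signature enrichment.** For sample *k* with *n* genes ranked
by decreasing expression and a signature *L* of *m* genes, the running score

E_ik = Σ_{j≤i} h_{g_jk},  h_g = 1/m if g ∈ L, else −1/(n−m)

has extrema E_k− = min_i E_ik ∈ [−1,0] and E_k+ = max_i E_ik ∈ [0,1]
measuring enrichment in the low/high expression tails. Significance is the
least-bias permutation estimate p_k± = (1 + #exceedances)/(1 + n_P); with the
default n_P = 100,000 the p-value floor is 10⁻⁵. The score on the more
significant tail is reported, and a sample is P+ (or R+) when its signature
is significantly up-regulated (high tail, p+ < α = 0.05). Because the score
is rank-only, the null depends only on (n, m) and is shared across samples.

**TF activity scores.** With T the genes × TFs ternary matrix (T_ij = +1/−1/0
for activation/repression/no annotation, built from a TRRUST-style curated
table after discarding unknown-mode edges), each sample's activity vector
solves G_·k ≈ T A_·k in the least-squares sense. The TF's own transcript
never enters: activity is read off its targets. Pooled permutation of each
sample's expression across genes yields per-TF reference scores; a sample is
**K+** for a designated TF when p = (1 + #{null ≥ obs})/(1 + n) < 0.05.

**Associations.** Spearman correlations (permutation p-values, BH-adjusted)
relate genes and TF activities to the P/R scores; a TF *sustains* a programme
(P→P or R→R) when its activity correlates with the programme's score **and**
its targets are enriched among that programme's correlated genes. Subtype
overlap uses one-tailed hypergeometric tests; survival uses Kaplan–Meier,
log-rank and Cox proportional hazards (Efron ties, Wald tests); immune
fractions (a CIBERSORT-style table, consumed as input) are correlated with
the activity score, with Kolmogorov–Smirnov tail comparisons between K+ and
K− samples.

## Worked example

`examples/` contains one short script per capability. Scoring a 100-sample
synthetic cohort (`python examples/02_signature_scoring.py`) prints:

```
        e_minus  e_plus  p_minus  p_plus  e_reported  tail
sample
S0001     0.000   0.587    1.000   0.001       0.587  high
S0002    -0.372   0.000    0.001   1.000      -0.372   low
S0003     0.000   0.523    1.000   0.001       0.523  high

subtype counts:
pr_label
P-/R+    54
P+/R-    31
P-/R-    10
P+/R+     5

recovery of planted labels: P 1.00, R 1.00
```

S0001's proliferation signature is enriched at the top of its expression
ranking (E+ = 0.587) at the permutation floor p = 0.001, so it is called P+;
S0002's signature sits in the low tail and the sample is P−. On this planted
cohort (signature genes shifted +2 noise-SD in positive samples) the calls
recover the planted labels perfectly, and the P+/R+ double-positives are
rare because the two programmes are generated anti-correlated.

The full pipeline on a generated cohort, from the shell:

```bash
prtf demo --seed 7 --out demo_out
```

writes all stage outputs (signature scores, PR labels, TF activities and
p-values, K calls, gene/TF correlation tables, sustaining-TF list, log-rank
and Cox tables, immune-fraction correlations and KS tests) plus a YAML
manifest under `demo_out/results/`, and a summary reporting, e.g., that the
planted R-driving TF is recovered in the R→R sustaining list and that
myeloid — but not lymphoid — fractions correlate with its activity score.

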