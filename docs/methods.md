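# Methods

## Effect-size model

Each study contributes a two-arm summary (n, mean, SD per arm) on its
platform-native scale. The per-study effect is the standardized mean
difference: Cohen's d = (x̄_case − x̄_control)/s_pooled with
s_pooled² = [(n₁−1)s₁² + (n₂−1)s₂²]/m, m = n₁ + n₂ − 2, corrected to
Hedges' g = J·d, J = 1 − 3/(4m − 1), with sampling variance
var(g) = J²[(1/n₁ + 1/n₂) + d²/(2(n₁+n₂))]. Cohen's d (no correction) is
available behind a flag. Arms with n < 2 are rejected at effect
computation (they may still be loaded).

Pooling is inverse-variance. The common-effect ("fixed") estimator uses
w = 1/v; the random-effects estimator uses the DerSimonian–Laird moment
τ² = max(0, (Q − df)/(Σw − Σw²/Σw)) and weights 1/(v + τ²). CIs are
normal-approximation (z = 1.96) without the Knapp–Hartung adjustment,
matching the STATA-era convention of this literature. Q, τ² and I² are
always computed from the fixed weights, so heterogeneity summaries agree
between models on the same data. Leave-one-out re-estimates τ² in every
iteration. Egger's test is the precision-form regression of g/se on 1/se
with a two-sided t test on the intercept at k − 2 df (statsmodels OLS
underneath); Begg's alternative is not implemented.

### Which model reproduces which published number

The chip-only published values reproduce **exactly** under common-effect
(inverse-variance) weighting of Hedges' g — 25 chips: 0.679
(0.589–0.769) vs published 0.68 (0.59–0.77); tissue subgroup 0.875
(0.764–0.985) vs 0.88 (0.77–0.99); serum 0.288 (0.132–0.444) vs 0.29
(0.13–0.45) — while the accompanying narrative describes random-effects
models. The comprehensive 27-study synthesis instead reproduces under
DerSimonian–Laird: 0.890 (0.556–1.225) vs published 0.89 (0.55–1.22).
The canned analyses in `mirmeta.published` therefore default each
analysis to the model its published number came from; both models are
exposed everywhere.

The adenocarcinoma chip forest is **not exactly reconstructable** from
the shipped tables. The nine datasets whose cancer arms total the stated
350 adenocarcinoma samples give pooled SMDs of 0.689 (fixed) / 0.842
(DL); adding the predominantly squamous GSE51853 (which the dataset
listing carries) gives 0.771 / 1.006, against a published 0.81
(0.59–1.04); the tissue subgroup gives 1.306–1.543 across all supported
configurations against a published 1.55 (1.23–1.88). An exhaustive
subset search over memberships, models and SMD variants finds no
configuration matching all published adenocarcinoma numbers at once: the
published forest evidently used per-dataset adenocarcinoma-only arms
that the NSCLC-wide summary table does not carry. `analysis/02` prints
every configuration; the reported configuration is inverse-variance
Hedges' g over the ten adenocarcinoma-bearing datasets, consistent with
the estimator pinned down by the NSCLC-wide numbers.

## Diagnostic synthesis

Study 2×2 tables are summarized on the logit scale with the usual
within-study variance approximation (1/TP + 1/FN for logit sensitivity,
1/TN + 1/FP for logit specificity). Default continuity handling adds 0.5
to all four cells of a study only when that study has a zero cell;
whole-set and no-correction modes are available.

The default model is the bivariate random-effects model: yᵢ ~ N(μ, Σ + Cᵢ)
with unstructured 2×2 between-study covariance Σ, fitted by Nelder–Mead
maximization of the (restricted) likelihood from two starting points
(σ parametrized in logs, ρ by tanh), non-convergence raising an error.
During development the fit was verified against an independent
mixed-model implementation (R metafor `rma.mv`, struct="UN", REML) to
three decimals on the 15 tissue tables; those estimates are frozen as a
regression test. The SROC is the conditional-mean line
E[logit Se | logit Sp] traced over FPR; the slope is set to zero when the
specificity variance collapses (< 1e−10) to keep the degenerate
all-identical-tables case on the chance diagonal. AUC is the trapezoid
integral on 1000 evenly spaced FPR points, with the curve clamped to
[0, 1].

The Moses–Littenberg alternative regresses D = logit TPR − logit FPR on
S = logit TPR + logit FPR (unweighted, inverse-variance, or sample-size
weights) and back-transforms the fitted line. On the motivating corpus,
the published areas (0.93 tissue, 0.69 serum) reproduce within ±0.03
under the Moses model with sample-size weights and whole-set continuity
correction (0.954 / 0.690); the bivariate model gives 0.844 / 0.611.
The published analysis therefore almost certainly used a
Moses-family tool, and the canned SROC reproduction uses that
configuration, while the bivariate model remains the library default for
new analyses (it is the better-founded model, and the one whose
parameters the tests validate by simulation and external cross-check).

The Youden dichotomizer scans every midpoint between adjacent distinct
observations (plus sentinels beyond the extremes), calling higher
expression positive, and maximizes J = sens + spec − 1 with ties broken
toward higher specificity, then toward the higher cutoff. It is validated
against an exhaustive-classification oracle on all small inputs
(property-based) — not against the corpus 2×2 tables, whose derivation
rule was never published.

## Summary-statistic group tests

Welch t (Welch–Satterthwaite df), pooled-variance t (df = n₁+n₂−2) and
one-way fixed-effects ANOVA (F = MSB/MSW) are computed from per-stratum
n/mean/SD and are exactly the full-data tests applied to any raw sample
with those moments (verified against scipy on moment-matched
reconstructions to 1e−9). The corpus tables mix conventions — the
sequencing cohort's cancer-vs-noncancer row matches the pooled-variance
form, all other two-level rows match Welch — so both are exposed and
none is guessed. Two-sided p-values, no multiplicity correction, matching
the published tables. Paired comparisons (the qPCR cohort's
cancer-vs-paired-normal rows) are out of scope: the within-pair
correlation is unrecoverable from summaries. The comprehensive synthesis
nevertheless treats the qPCR and sequencing cohorts as unpaired two-arm
studies, because that is what the published sample totals (2564/1161)
imply was done.

The binormal AUC Φ(Δmean/√(s₁² + s₂²)) is a summary-statistic stand-in
for single-cohort ROC discrimination. It reproduces the sequencing
cohort's published AUC (0.95) but not the qPCR cohort's published 0.68
(binormal ≈ 0.84): the published per-sample ROC procedure is
unrecoverable from printed summaries, so no claim is attached to it.

## Synthetic-data generator

`simulate_studies` draws per-study true effects θᵢ ~ N(δ + shift, τ²),
then normal within-study samples on a platform-specific (location, scale)
so that the standardized effect is scale-free, exactly as the SMD model
assumes. Serum studies receive an additive effect shift (default −0.6)
emulating the tissue > serum pattern; arm sizes are uniform on
configurable ranges (default 5–100, spanning the corpus); default δ = 0.8
and τ = 0.2 give the strong-but-heterogeneous tissue signal the corpus
shows. Emitted summaries are the exact ddof-1 moments of the emitted
samples. A single seeded `numpy.random.default_rng` drives everything; no
global state.

What the generator does **not** emulate: non-normal and heavy-tailed
expression distributions, probe-level chip artifacts, count noise in
sequencing, paired designs, and correlated sensitivity/specificity
mechanisms beyond the logit-normal one used in the bivariate recovery
test. Passing calibration tests therefore demonstrate correctness of the
estimators under the model's own assumptions, not robustness to real-data
violations of them.

Calibration results (recomputed by `analysis/06` and the test suite): the
DL 95% CI covers δ = 0.8 at τ = 0.2, k = 30 in 95.0% of 500 replicates;
the ≥8-of-12 consensus fraction at vote probability 0.5 matches the exact
binomial tail P(X ≥ 8 | 12, 0.5) = 0.194.

## Data transcription choices

* The chip summary table stores one row per sub-platform (GSE18692 A/B),
  keyed by study id + subset label.
* The source table labels its per-arm location column "median"; the SMD
  arithmetic requires means and the published pooling treated the values
  as means, so they are carried as arm means, recorded in `scale_note`.
* The 2×2 counts were disambiguated from the source layout using
  TP + FN = n_case and FP + TN = n_control; two rows (GSE16512, GSE27486)
  are off by one in the source itself and are transcribed as printed.
* Unknown specimen or disease-subset labels are rejected, never coerced.

## Problem sizes

All corpus analyses run in seconds on one CPU: k ≤ 27 studies for
pooling, k = 15/10 for the SROC fits, 500-replicate calibration runs,
10⁴-gene simulated prediction matrices. The bivariate simulation-recovery
test uses k = 50 studies of ~240 subjects.

## Known limitations

* The adenocarcinoma forest quantities are approximations (see above);
  they are reported under a documented configuration, not tuned to match.
* DL τ² is the only random-effects estimator (no REML/Paule–Mandel), and
  no Knapp–Hartung CI adjustment is offered.
* No HSROC (Rutter–Gatsonis) Bayesian fitting, meta-regression,
  trim-and-fill, or network meta-analysis.
* The vote-count filter expects the 12-platform export format; running
  the prediction algorithms themselves is out of scope.
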