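# Methods

## The design being modelled

A hospital case-control study: 256 patients with angiographic CAD (≥ 50%
stenosis of a major coronary artery) and 49 stenosis-free controls, with
circRNA relative expression measured by qRT-PCR in peripheral blood
mononuclear cells, four binary coronary risk factors from interview
(smoking, drinking, hypertension, diabetes), clinical covariates from
records, and the Gensini score as an angiographic severity measure. The
package implements the statistical chain of such a study end to end; the
crossover additive-interaction analysis is its centrepiece.

## Relative quantification (2^−ΔΔCt)

Triplicate Ct values per channel are averaged; a replicate sample SD above
0.5 cycles (a common qPCR QC convention — the protocol itself specifies
none) sets a flag but never rejects a value. ΔCt = mean Ct(target) − mean
Ct(reference gene); ΔΔCt subtracts a calibrator ΔCt; expression = 2^−ΔΔCt.
Because the calibrator convention is rarely reported, two strategies are
provided: the default **control-group mean ΔCt**, which fixes the control
geometric-mean expression at 1 (consistent with control medians near 1 in
the cohort this emulates), and a **fixed reference sample**. Amplification
efficiency is assumed to be 2 per cycle; Pfaffl-style efficiency correction
and plate effects are out of scope.

## Descriptive layer

Normality is screened per group by Shapiro-Wilk at α = 0.05 (no particular
test is canonical here; Levene/Brown-Forsythe screens are reserved for the
ANOVA stage's variance question). Both groups normal → t-test, pooled or
Welch according to a Levene variance screen, summarised mean ± SD; otherwise
Wilcoxon-Mann-Whitney with the mid-rank normal approximation (exact
enumeration for tie-free groups of ≤ 25), summarised median (IQR). Binary
factors use the two-proportion z test, matching the Z statistics such
baseline tables print for percentages. Spearman matrices are
pairwise-complete with NaN for constant columns or n < 3 pairs.

## ROC evaluation

Thresholds sit at midpoints between consecutive distinct pooled scores, so
tied scores step the curve diagonally in one move and the trapezoidal area
equals the Mann-Whitney probability estimate (wins + half-ties over all
case-control pairs) to machine precision — this identity is property-tested
rather than assumed. Orientation is chosen automatically so AUC ≥ 0.5 and
reported (`lower` for down-regulated markers). The AUC interval defaults to
the Hanley-McNeil variance (the variance actually used by the published
analysis is unstated; DeLong is available), and the p-value tests AUC = 0.5
by normal approximation. Youden-cutoff ties break toward higher specificity
(the cheaper error in a screening setting); the choice is configurable.

## Logistic models

IRLS with step halving guarantees a non-increasing deviance path;
convergence is a coefficient change below 1e−8 within 50 iterations. No
Firth correction is applied (matching a plain maximum-likelihood analysis),
but complete separation is detected (diverging coefficients with saturated
fitted probabilities) and standard errors are suppressed rather than
reported as spuriously finite. On any 2×2 table the fitted univariate OR
equals the cross-product ratio ad/bc — tested to 1e−8 relative error over
1000 random tables. Sex is coded male = 1. Missing covariates are handled
by complete-case filtering with the analysis n reported, mirroring the
varying denominators visible in published per-analysis tables. Expression
enters models untransformed; a z-scoring flag is the natural extension.
Adjustment sets: model 1 = age, sex, BMI, smoking, drinking, diabetes,
hypertension; model 2 adds total cholesterol, triglycerides, Lp(a) and
LDL-C.

## Severity ANOVA

Quartile strata are computed over **all** subjects with a Gensini score
(the published stratum sizes 76/78/76/75 sum to the whole 305-subject
cohort, not the case arm), with linear-interpolation quantiles and boundary
ties assigned to the lower stratum. The classic pooled-variance F is the
default; Welch and Brown-Forsythe variants are selectable because published
reports often cite a robust test while printing a single F. The
summary-statistics route (n, mean, SD) evaluates the identical formula and
is property-tested to agree with the raw-data route exactly. Bonferroni
post-hoc uses pairwise t on the pooled within-group mean square with N − k
degrees of freedom, p multiplied by the number of pairs and capped at 1.

Independent recomputation of the published severity table's F values from
its printed (n, mean, SD) does not recover the printed F under the classic,
Welch, or Brown-Forsythe formulas; those printed F values are therefore
treated as non-reproducible from the published summaries and are not
asserted anywhere.

## Crossover additive interaction

**Dichotomisation.** The published analysis never states how expression was
split into ±; the default is the Youden-optimal ROC cutoff (consistent with
the cutoff analysis such studies report), with median and fixed-threshold
alternatives; the cutoff used is recorded on the table. "+" means
expression above the threshold; the reference cell (−,−) is low expression
with the risk factor absent, which reproduces the published reference rows.

**Crude ORs.** Each cell's OR versus the reference is the cross-product
ratio, with Woolf CI exp(ln OR ± z·√(1/a + 1/b + 1/a₀ + 1/b₀)). The
published ORs are exactly these crude ratios, so the crude pipeline is the
default; a covariate-adjusted mode can be built on the logistic module.
Zero cells raise by default; a Haldane-Anscombe +0.5 correction is
available and always reported.

**Delta-method intervals.** With β = (ln OR10, ln OR01, ln OR11), the
covariance V has V_kk = Σ 1/count over the four cells defining OR_k and
V_kl = 1/a₀ + 1/b₀ (the shared reference cell); a test verifies V against
the observed-information covariance of the saturated four-category logistic
fit. Gradients: ∇RERI = (−OR10, −OR01, OR11); ∇AP = (−OR10/OR11,
−OR01/OR11, (OR10+OR01−1)/OR11); ∇S = (−(OR11−1)OR10/D², −(OR11−1)OR01/D²,
OR11/D) with D = (OR10−1)+(OR01−1). Intervals are estimate ± z·√(gᵀVg),
symmetric on the linear scale — the structure the published intervals show.
The log-scale (Hosmer-Lemeshow) construction for S is available behind
`s_scale="log"`. S is reported as undefined (not an error) when D = 0.

**Critical value.** The default z is the conventional two-decimal quantile
(1.96 at α = 0.05), which reproduces every published Woolf endpoint at
three decimals (one endpoint, 1.848, differs at the third decimal under the
exact quantile 1.959964); the exact quantile is available via `z=`.

**Classification.** Additive interaction is declared only when the RERI
interval excludes 0 and the S interval excludes 1; direction is synergistic
for S > 1, antagonistic for S < 1; undefined S yields "not significant".

### Reconciliation with the published panels

From the printed counts, the pipeline reproduces at three decimals: all six
joint-cell ORs (0.178, 0.235, 0.253, 0.293, 0.316, 0.538) with their Woolf
CIs and per-row p-values, and the interaction point estimates of every
panel, with these known last-digit exceptions, all independently verified
by exact-fraction arithmetic:

| quantity | count-derived | published |
| --- | --- | --- |
| RERI, circRPRD1A × smoking | 0.427 | 0.428 |
| S, circRPRD1A × drinking | 0.904 | 0.905 |
| AP, circRPRD1A × drinking | 0.312 | 0.311 |
| S, circRPRD1A × hypertension | −2.114 | −2.117 |
| AP, circRPRD1A × hypertension | −3.186 | −3.182 |
| AP, circHERPUD2 × drinking | 2.415 | 4.415 |
| RERI, circHERPUD2 × hypertension | −4.005 | −4.008 |
| AP, circHERPUD2 × hypertension | −7.449 | −7.457 |

(The AP = RERI/OR11 identity gives 2.395 for the smoking × circRPRD1A panel
only with the unrounded RERI 0.4274, confirming the count-derived values;
published AP 4.415 for the drinking panel is irreconcilable with the
identity and looks like a +2 transcription slip.)

The published RERI/AP/S **interval half-widths** are *not* derivable from
the printed counts by the delta method above (e.g. RERI half-width for
circRPRD1A × smoking: computed 1.219 vs published 1.638; for circHERPUD2 ×
drinking: computed 0.832 vs published 0.392). The published drinking RERI
standard error (0.200) is smaller than any single variance component of the
counts, so no covariance assignment reproduces it; independence,
sign-flipped covariance and log-scale variants were all tried. A practical
consequence: with count-derived intervals the circHERPUD2 × drinking RERI
interval contains 0, so the pipeline's own classification of that panel is
"not significant", whereas the published intervals yield "significant
antagonistic". The significance rule itself is therefore tested by applying
it to the published intervals (which reproduces every published call), and
the count-derived intervals are reported alongside.

## Synthetic cohort generator

Defaults emulate the validation cohort: 256/49 group sizes; risk-factor
prevalences (smoking 41.3%/35.6%, drinking 28.9%/17.8%, hypertension
63.0%/48.9%, diabetes 20.4%/11.1%); per-group log-normal expression with
μ = ln(median) and σ = ln(q3/q1)/(2·z₀.₇₅) from the published medians and
IQRs (a log-normal matches the median and the quartile *ratio* exactly; it
cannot also match both endpoints when the published quartiles are
asymmetric on the log scale, as for circRPRD1A); covariates as independent
per-group normals (mean ± SD entries) or log-normals (median/IQR entries) —
no correlation structure is claimed; Gensini as log-normal in cases and
half-normal (σ = 3.912, matching the published control upper quartile 4.5)
in controls; sex as Bernoulli from the published M/F counts. A per-variable
MCAR missingness rate (default 0) emulates the incomplete exposure data
implied by the published crossover-cell totals; the real missingness
mechanism is unknown and MCAR is an assumption, not an inference.

Randomness is one integer seed feeding an independent stream per variable
(seed + stable name hash), so adding a variable never perturbs existing
draws and identical seeds give byte-identical cohorts.

The planted-interaction generator draws exposures from group-free marginals
and disease from logit p = β₀ + β_a A + β_b B + β_ab AB; the crossover cell
ORs equal e^{β_a}, e^{β_b}, e^{β_a+β_b+β_ab}, so the implied RERI has the
closed form e^{β_a+β_b+β_ab} − e^{β_a} − e^{β_b} + 1 against which recovery
is tested. Recovery checks use 20,000 subjects for point recovery (within
3 SEs) and 500 replicates of 2,000 subjects for interval coverage (92–97%
band) — sizes chosen to keep Monte-Carlo error well below the tolerances
while the whole suite stays quick.

What the generator does **not** emulate: correlation among covariates or
between expression and covariates, plate/batch effects in Ct values,
non-log-normal expression shapes, informative missingness, and the
selection process of a hospital case series. Passing tests therefore
demonstrate correctness of the estimators and their calibration under the
stated generative model, not robustness to those real-data features.

## Numerical choices and degenerate inputs

- Logistic: tol 1e−8 on coefficient change, max 50 iterations, step
  halving; weights floored at 1e−12 to keep the information matrix finite.
- ROC: degenerate AUC ∈ {0, 1} truncates the CI to [0, 1] and sets a flag;
  identical scores give the diagonal curve and the Youden tie-break returns
  the most specific corner.
- ANOVA: zero within-group variance with equal means gives F = 0, p = 1;
  with unequal means F = ∞, p = 0. Summary route requires SD > 0 and n ≥ 2
  per group.
- Wilcoxon: all-tied data falls back to the mid-rank normal approximation
  (p = 1 at zero shift).
- Crossover: estimability requires every cell to have both a case and a
  control count; otherwise ORs refuse to compute (flag on the table).
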