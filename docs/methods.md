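# Methods

## The activity model

`predcurve` models the probability that a compound is active given its
virtual-screening score with a univariate binomial GLM under the
canonical logit link,

    logit P(A = 1 | Y = y) = β₀ + β₁ y.

The model is deliberately univariate: the predictiveness curve is a
property of *one* score, and adding covariates or flexible calibrators
(splines, isotonic regression) would change what the curve measures.
Regularized or Firth-type fits are likewise out of scope, because they
bias the fitted probabilities away from the maximum-likelihood
calibration that gives the curve its interpretation (at the MLE the mean
fitted probability equals the sample prevalence, so the curve averages
to p).

Fitting is by iteratively reweighted least squares on the
(internally centred) score, with:

| choice | value | why |
|---|---|---|
| max iterations | 100 | standard GLM default |
| convergence | \|Δdeviance\| < 1e-8 | scale-free, matches common GLM software |
| probability clipping | ε = 1e-10 | keeps fitted probabilities strictly inside (0, 1) |
| separation cap | max \|β₀ + β₁y\| ≤ 30 | expit(30) is within 1e-13 of 1; larger coefficients change nothing but overflow risk |

**Separation.** A score that splits actives from inactives perfectly (or
on a quasi-complete boundary) has no finite MLE. Benchmark screens with
very good methods and low prevalence hit this routinely, so it must not
crash the pipeline: separation is detected either when the linear
predictor exceeds the cap or when the coefficient norm doubles over five
consecutive iterations while the deviance collapses toward zero. The fit
is then returned with capped coefficients and `separation_flag` set. The
predictiveness curve of the capped fit approximates the well-defined
limiting object — the step function R(v) = I[(1 − p) < v] — to within
the clipping tolerance.

Score orientation ("higher is better" vs "lower is better", docking
energies being the latter) defaults to `infer`: it is resolved from the
sign of the fitted slope, which treats both conventions uniformly. A
zero slope carries no direction and resolves to `higher_is_better` so
rank-based metrics stay defined.

## The predictiveness curve and its integrals

The empirical curve places the i-th compound (sorted ascending by fitted
probability, stable on ties with input order as secondary key) at
quantile vᵢ = i/n with R(vᵢ) its fitted probability. R is a step
function, constant on each interval ((i−1)/n, i/n], so every integral in
the package is computed as the **exact** Riemann sum over those
intervals — there is no quadrature error and results are exactly
reproducible:

- TG = Σᵢ wᵢ |R(vᵢ) − p| / (2p(1 − p)) with wᵢ the interval width (1/n
  on the uniform grid);
- pTG(v) uses each interval's overlap with (v, 1], so a cut that falls
  inside an interval contributes the fractional mass. This makes the
  identities exact at machine precision: pTG(0) = 2p·TG for every curve,
  and pTG(1 − p) = 1 on the step curve for every prevalence.

p in both denominators is the *sample* prevalence, not the mean fitted
probability; the two coincide at a converged MLE, and sample prevalence
remains well defined when the fit is separated or capped.

Fractions map to compound counts by ceiling: the top x% selects
⌈x·n/100⌉ compounds, guaranteeing a non-empty selection; boundary ties
are resolved by the stable sort order. Tabular reports round prevalence
to 4 decimals, TG/pTG/pAUC to 3, and EF to 2 — the conventional
precisions for benchmark tables.

## Enrichment factor convention

EF_x% = (Hits_x/N_x)/(Hits_t/N_t): the density of actives in the top
x% over the density in the whole dataset, bounded above by 1/p. This is
the standard virtual-screening definition; formulations that put the
selected-subset size in the baseline denominator are inconsistent with
the 1/p bound and are not implemented.

## ROC and partial AUC

ROC vertices come from sweeping the threshold over distinct oriented
scores (scikit-learn's tie-grouped sweep), so tied scores form one
diagonal step and the trapezoidal area equals the Mann–Whitney
probability with ties counted one half. The partial area up to an FPF
cut interpolates the curve linearly at the cut and is reported, by
default, **standardized** as raw/FPF-cut so a perfect method scores 1;
`raw` and `mcclish` normalizations are available and reports label the
convention in use, since published pAUC values are frequently on
incomparable scales. Because an early cut can be specified either as an
FPF bound or as a top fraction of the dataset, both queries are exposed
(`partial_auc` and `partial_auc_top_fraction`); threshold reports use
the FPF actually attained by the selected fraction, and report NaN when
that FPF is zero (the partial area is then degenerate).

Empty selection sides in threshold reports yield NaN for the affected
predictive value (PPV with nothing selected, NPV with nothing rejected):
undefined is reported as undefined, never as 0.

## Threshold finding

The automatic finder is a decision-support heuristic — threshold choice
is ultimately the investigator's — and the manual path
(`translate_threshold`, resolving a value given on any one of the three
scales into a consistent triple with the convention R⁻¹(q) = smallest v
with R(v) ≥ q) is the primary interface.

The heuristic smooths R with a centered moving average (window
max(5, n/100) points), differentiates on the quantile grid, and takes
local maxima of the derivative as candidates, merged within one window
width and ranked by rise rate. The noise floor guards against reading
structure into a quasi-flat curve: the labels are permuted once (seeded),
the model refit, and candidates below twice the permuted curve's maximum
rise rate are discarded. Because the floor needs a refit on permuted
labels, `find_inflexion` accepts the dataset as an optional argument;
without it only exactly-flat curves are guarded. A window of n/100
localizes a clean step to within half a window (±0.005 in v at
n = 10,000).

## The synthetic benchmark

`BinormalSpec` emulates a DUD-like screen: `n_actives` actives with a
fixed number of decoys per active (36, the DUD design ratio, giving
prevalence 1/37 ≈ 0.027) and equal-variance Gaussian scores for the two
classes. Defaults (50 actives, mean gap 2σ) describe a well-separated
screen with population ROC AUC Φ(√2) ≈ 0.92.

Equal variances are chosen deliberately: the true activity-given-score
model is then *exactly* logistic-linear (slope (μₐ − μ_d)/σ², intercept
logit(p) − (μₐ² − μ_d²)/2σ²), so the fitted family contains the truth
and recovering the population TG tests the whole pipeline without
confounding metric error with model misfit. The population TG oracle
integrates E|P(A=1|Y) − p| over the two-component mixture by adaptive
quadrature (split at the density crossing, absolute tolerance 1e-9,
integration limits 15σ beyond the means where the density is ~1e-49).

What the generator does **not** emulate — and therefore what passing
tests do not establish about real screens: multimodal or clipped docking
scores, unequal class variances (which make the true risk non-logistic),
correlated scores across related compounds, and dataset-composition
artifacts of real decoy selection. On real data the logistic model is an
approximation and TG inherits its misfit.

## Problem sizes

The test suite exercises: analytic curves on 10,000-point grids;
identity and oracle-equivalence suites on hundreds of random datasets of
up to 500 compounds; GLM correctness against an independent dense
Newton–Raphson solve (50 datasets, agreement 1e-6) and statsmodels;
parameter recovery over 20 seeds of the 7,400-compound binormal
benchmark (mean TG within ±0.02 of the quadrature oracle, mean AUC
within ±0.02 of the closed form); and the threshold finder on
10,000-compound near-step and flat datasets. The full suite runs in a
few seconds on one CPU.

## Known limitations

- The activity model is strictly logistic-linear in the score; badly
  miscalibrated scores yield a curve whose probabilities should be read
  qualitatively.
- With separation the reported coefficients are capped, not estimates;
  only the induced curve (a near-step) is meaningful.
- The inflexion heuristic ranks candidates by local rise rate only; it
  encodes no misclassification costs, and two nearby rises merge within
  one smoothing window.
- EF and fraction-based metrics depend on the ceiling/tie conventions
  above; other tools' values can differ by one boundary compound.
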