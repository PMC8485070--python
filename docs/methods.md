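# Methods

## Assay model

A cuvette assay adds a fluorogenic substrate proxy to a sediment slurry
(default geometry: 3 g wet sediment in 100 ml borate-buffered saline, 1 ml
reaction volume, 20 mM substrate stocks). Substrate addition defines time
zero; fluorescence is read 3–5 times over ~24 h. The model of one series is

    F(t) = b + m · P(t) + ε,   P(t) = v(S) · t,   v(S) = V_max · S / (K_m + S)

with (m, b) the standard-curve slope/intercept of the released fluorophore
(AMC for peptidase substrates, MUB for glycoside/phosphomonoester
substrates) in the same slurry matrix, and ε homoscedastic Gaussian noise.
Product accumulation is treated as linear over the assay window — initial
rates, no substrate depletion. An optional integrated-rate mode in the
generator (`TruthSpec.depletion`) simulates first-order depletion,
P(t) = S₀(1 − e^{−vt/S₀}), to let tests quantify the downward bias this
assumption would cause; the estimator offers a matching
"initial-linear-window" mode (maximize r² over prefixes of ≥ 3 points) as a
robustness option, with all-points OLS the default.

## Calibration

Standard curves are ordinary least squares of fluorescence on
concentration, fit per fluorophore (matrix-matched, since humic quenching
differs between samples; a global curve is a caller choice by pooling the
input table). Inversion is C = (F − b)/m. Negative back-calculated
concentrations are retained: clipping at zero would bias the subsequent
time regressions upward near the detection limit. Curves require ≥ 3 points
over ≥ 2 distinct non-negative levels; the default synthetic levels
(0–20 µM) bracket the product range a 24-h assay produces.

## Rates, units, detection

v0 is the OLS slope of concentration on time (≥ 3 strictly increasing
timepoints), with its standard error and r². Unit conversion uses
µM ≡ nmol ml⁻¹: the reaction produces v·V_rxn nmol h⁻¹ and contains
m_sed·V_rxn/V_slurry grams of sediment, so the per-gram rate is
v·V_slurry/m_sed (the reaction volume cancels; 0.3 µM h⁻¹ → 10 nmol g⁻¹ h⁻¹
at the default 3 g/100 ml).

The detection limit has three modes: a user-supplied constant (accepted
verbatim, for compatibility with externally derived values such as
4.77×10⁻² / 2.41×10⁻² nmol g⁻¹ h⁻¹); k·SD of ≥ 3 blank rates; or the
noise-based form k·σ_F/(m·T) converted to per-gram units, with k = 3 and T
the assay horizon. The pipeline estimates σ_F from the pooled standard-curve
residuals. "Live significantly above killed" is operationalized as a
one-sided Welch t-test at α = 0.05 on the triplicate rates; zero-variance
ties report p = 1.

## Michaelis–Menten fitting

Saturation designs use 10–11 levels evenly spaced from 0 to 720 or 800 µM.
The default fit target is the live-minus-killed mean rate per level, since
the killed control carries the abiotic and residual-enzyme signal; fitting
live-only is a caller switch. Fitting is damped nonlinear least squares
(trust-region reflective) with V_max⁰ = max(v), K_m⁰ = the substrate level
nearest half-max, bounds V_max ≥ 0, K_m > 0, and standard errors from the
Jacobian-based covariance at the optimum. Non-convergence, a singular
covariance, or an all-non-positive rate vector is reported as a
non-converged fit with a message — never silently returned. Reported fits
require ≥ 5 distinct levels. The K_m-depth trend is an OLS regression of
K_m on depth with a two-sided t-test on the slope.

Single-concentration (400 µM) assays are reported as potential activity at
400 µM without saturation correction; at K_m = 200 µM this is 2/3 of the
true V_max, a factor the synthetic truth makes exact and the tests assert.

## Cell counts and specific activities

Cell counts are interpolated on log10(counts) versus depth with local
polynomials of degree 2 (clamped to n−1), fit independently above and below
the 51.7 mbsf unconformity — the marine and lacustrine deposits are
different regimes and a single global fit would smear the break. No
extrapolation: queries outside a segment's measured span raise, and profile
assembly records a missing value with a warning instead. Cell-specific
activities are v/cells in amol cell⁻¹ h⁻¹ (1 nmol = 10⁹ amol); no
cell-count uncertainty is propagated.

## Retention statistics

Fraction retained is 100·v_killed/v_live, computed per enzyme × depth from
the live and killed triplicate means; pairs with v_live < k_excl·DL
(default k_excl = 3) are excluded as too close to the detection limit for a
ratio to be meaningful, and k_excl = 0 disables exclusion. Summaries are
medians with 25th/75th percentiles under the linear-interpolation quantile
convention, recorded in the output. The omnibus test is tie-corrected
Kruskal–Wallis (chi-square approximation, k−1 df); post hoc comparisons are
Conover–Iman t statistics on mean ranks,

    t_ij = (R̄_i − R̄_j) / sqrt(S² · (N−1−H)/(N−k) · (1/n_i + 1/n_j)),

with S² the pooled tie-aware rank variance and N−k degrees of freedom.
Holm adjustment is the default; unadjusted p-values are also emitted.

## Lifetime bound

The bound chains three relations: E = V_max/(SA/f_s) converts a measured
potential activity into a standing enzyme-carbon concentration via a
literature specific activity SA, with f_s ≥ 1 modelling sorption
suppression of SA in sediments (f_s = 3 triples E); GE·R_c is the community
biomass production rate; and τ ≥ E/(GE·R_c). Defaults: GE = 0.10,
R_c = 0.1 nmol C cm⁻³ day⁻¹ converted per gram with a configurable bulk
density (default 1.0 g cm⁻³), f_s = 1. SA is a distribution — point,
log-uniform (the default shape for a literature range, median at the
geometric mean of the bounds), or log-normal — and GE and R_c are point
masses by default with optional distributions. Monte Carlo (default 10⁵
draws, seeded) propagates the spread; summaries are the median, IQR and
5th/95th percentiles in days, always labelled as lower bounds. Because τ is
a monotone function of each input, the MC median equals the closed form at
the input medians up to MC error ∝ 1/√n, which the tests check.

Temperature scaling is the exponential Q10 form, rate·Q10^(ΔT/10). For a
12 °C offset at Q10 = 2 this is 2^1.2 ≈ 2.30; the commonly quoted "factor
of 2.4" for that offset is not reproducible from the exponential form and
the package reports the exact value.

## Synthetic data: what it emulates, what it does not

The generator mirrors the study layout: twelve enzymes in three classes on
the reference depth grid (4.5–77.9 mbsf), triplicate live/autoclaved series
with 4 timepoints over 24 h, a 400 µM single-concentration design, an
11-level 0–800 µM saturation design at the shallowest depth, activity
profiles peaking near 11 mbsf and vanishing below the unconformity except
for phosphatase, calibration at 1000 RFU µM⁻¹ with intercept 50 RFU,
σ_F = 20 RFU, K_m = 200 µM, retention ρ = 0.5, and cell counts anchored at
4.6×10⁸ cells g⁻¹ near the surface declining log-linearly with an
independent lower segment. Class-specific peak amplitudes (peptidase 22,
glycosylase 16, phosphatase 75 nmol g⁻¹ h⁻¹) match the order of magnitude
of reported maxima.

It does not simulate sorption kinetics, humic quenching dynamics,
heteroscedastic or drifting fluorescence, plate-reader artifacts, or
between-replicate slurry heterogeneity. Passing recovery tests therefore
demonstrates estimator correctness under the stated noise model, not
robustness to every failure mode of real cuvette data.

## Numerical choices and limitations

Determinism: every stochastic component draws from `numpy` generators
seeded from the run seed (sub-streams via `SeedSequence`), and pipeline
CSVs are written with a fixed float format, so rerunning a config is
byte-identical. Problem sizes in the test suite and acceptance script
(200 recovery curves, 2,000 null simulations, 10⁵ MC draws) were chosen to
put Monte-Carlo error well inside the asserted tolerances on a single CPU.
Known limitations: no integrated Michaelis–Menten fitting (the depletion
mode exists only to probe bias), no inhibition or multi-enzyme models, no
error propagation from cell counts, and the retention exclusion threshold
k_excl = 3 is a convention, not an inference.
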