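# sedenz

Analysis pipeline for **potential extracellular enzyme activities in
subsurface sediments**: fluorogenic-assay calibration, initial-rate and
Michaelis–Menten kinetics, depth and cell-specific activity profiles,
autoclave-retention statistics, and Monte-Carlo lower bounds on
extracellular enzyme lifetimes.

Heterotrophic microbes in deeply buried marine sediments depend on
extracellular enzymes to hydrolyze macromolecular organic carbon into
transportable substrates. The measurements this package analyzes are
cuvette assays in which a small fluorogenic substrate proxy (an AMC-linked
peptide or MUB-linked glycoside/phosphomonoester) is added to a sediment
slurry; the appearance of free fluorophore over ~24 h tracks hydrolysis.
The package is aimed at biogeochemists and geomicrobiologists who run such
assays — or want to reason about what they imply for enzyme turnover.

## The core quantities

* **Initial rate.** `v0` is the OLS slope of calibrated product
  concentration on time; with the default slurry geometry (3 g sediment in
  100 ml buffer, 1 ml reactions), µM h⁻¹ converts to per-gram units as
  `v [nmol g⁻¹ h⁻¹] = v [µM h⁻¹] × V_slurry / m_sed`.
* **Saturation kinetics.** `v(S) = V_max·S/(K_m+S)` fit by damped least
  squares to live-minus-killed rates over 10–11 substrate levels
  (0–720/800 µM). Single-concentration assays at 400 µM (20 µl of 20 mM
  stock in 1,000 µl) report potential activity without saturation
  correction.
* **Retention after autoclaving.** `100 × v_killed / v_live` per
  enzyme × depth, compared across enzyme classes with Kruskal–Wallis and
  Conover–Iman rank tests.
* **Lifetime lower bound.** With enzyme concentration
  `E = V_max / (SA / f_s)` (SA a literature specific activity, f_s ≥ 1 a
  sorption-suppression factor) and growth efficiency GE linking biomass
  production to community respiration R_c,

  `τ ≥ E / (GE · R_c)`

  propagated by Monte Carlo over the SA distribution and reported in days.

## Worked example

`examples/05_enzyme_lifetime.py` bounds the lifetime of a peptidase whose
peak potential activity is 14.7 nmol g⁻¹ h⁻¹, with specific activities
log-uniform over 10²–10⁴ mol bonds h⁻¹ (mol enzyme C)⁻¹, GE = 10% and
R_c = 0.1 nmol C cm⁻³ day⁻¹:

```
baseline lower bound on lifetime: median 1.5 days (IQR 0.5-4.6, 5th-95th 0.2-11.7; 100000 draws)
   scenario  median_days  iqr_low_days  iqr_high_days  p5_days  p95_days  n_draws
   baseline     1.466799      0.465497       4.631943 0.184338 11.705724   100000
sorption x3     4.400396      1.396492      13.895830 0.553015 35.117172   100000
    GE 3.7%     3.964320      1.258101      12.518766 0.498212 31.637092   100000
       both    11.892961      3.774304      37.556297 1.494636 94.911275   100000

combined scenario / baseline median ratio: 8.11 (= 3 x 0.10/0.037; every figure is a lower bound)
```

The median is the bound at the geometric mean of the SA range; the spread
is entirely the SA uncertainty. Assuming threefold sorption suppression
and a 3.7% growth efficiency lengthens the bound by exactly
3 × (0.10/0.037) ≈ 8.1. Each `examples/0*.py` script exercises one
capability the same way (rate estimation, saturation fitting, depth
profiles, retention tests, the full pipeline) and prints what the numbers
mean.

The whole pipeline also runs from the shell:

```sh
sedenz --seed 6 --outdir out            # simulate → … → lifetime
sedenz --config run.yaml --stages rates,retention
```

Stages exchange tidy CSVs and write a JSON manifest (config hash, seed,
row counts); reruns with the same config and seed are byte-identical.

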