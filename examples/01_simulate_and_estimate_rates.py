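"""Simulate a single-concentration (400 µM) assay and recover hydrolysis rates.

Generates triplicate live/autoclaved fluorescence series for twelve enzymes
over a study-like depth grid, calibrates fluorescence to product
concentration, and estimates the initial rate v0 per cuvette.
"""

import numpy as np

from sedenz.calibration import fit_standard_curve, fluorescence_to_concentration
from sedenz.kinetics import compute_v0, convert_rate_units, compare_live_killed
from sedenz.synth import default_truth, generate_assay_dataset, generate_standard_curve_data

truth = default_truth(seed=1)
table, _ = generate_assay_dataset(truth, design="vmax")
std = generate_standard_curve_data(truth, levels=[0, 1, 2, 5, 10, 20])

curve = fit_standard_curve(
    std[std.fluorophore == "AMC"][["concentration_uM", "fluorescence"]], "AMC")
print(f"AMC standard curve: slope {curve.slope:.1f} RFU/uM, "
      f"intercept {curve.intercept:.1f} RFU, r^2 {curve.r_squared:.4f}")

sel = table[(table.enzyme == "clostripain") & (table.depth_mbsf == 11.1)]
rates = {}
for trt, g in sel.groupby("treatment"):
    per_rep = []
    for rep, s in g.groupby("replicate"):
        s = s.sort_values("time_h")
        conc = fluorescence_to_concentration(curve, s.fluorescence)
        v = convert_rate_units(compute_v0(s.time_h, conc).v0, truth.geometry)
        per_rep.append(v)
    rates[trt] = np.array(per_rep)
    print(f"clostripain at 11.1 mbsf, {trt}: v0 = {np.mean(per_rep):.2f} "
          f"+/- {np.std(per_rep, ddof=1):.2f} nmol/g/h (triplicate)")

res = compare_live_killed(rates["live"], rates["autoclaved"])
print(f"live > killed? p = {res.p:.2e} -> "
      f"{'significant' if res.significant else 'not significant'}")
print("The killed control retains ~half the live rate: the generator's "
      "autoclave retention fraction is 0.5.")
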