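"""Fit a Michaelis–Menten saturation curve from a simulated 11-level design.

The saturation design spans 0–800 µM; the fit is to live-minus-killed mean
rates per level, and the recovered (V_max, K_m) are compared with the
generating truth. Because the killed control retains half the activity, the
live-minus-killed V_max is half the live V_max.
"""

import pandas as pd

from sedenz.pipeline import Pipeline, RunConfig

cfg = RunConfig(outdir="scratch_example_mm", seed=2)
p = Pipeline(cfg)
p.simulate()
p.calibrate()
p.fit_mm()

mm = pd.read_csv("scratch_example_mm/mm_fits.csv")
row = mm[mm.enzyme == "clostripain"].iloc[0]
print(f"clostripain at {row.depth_mbsf} mbsf: "
      f"V_max = {row.vmax:.2f} +/- {row.vmax_se:.2f} nmol/g/h, "
      f"K_m = {row.km:.0f} +/- {row.km_se:.0f} uM")
print("Truth: K_m = 200 uM; live-minus-killed V_max = 0.5 x 20.2 ~ 10.1 nmol/g/h.")
print(f"At the single-concentration design's 400 uM, the enzyme runs at "
      f"S/(K_m+S) = {400/(row.km+400):.2f} of V_max - the reason "
      "single-concentration 'V_max' assays are reported as potential "
      "activity at 400 uM, not corrected to saturation.")
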