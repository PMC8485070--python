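"""Standard-curve calibration: fluorescence → product concentration.

Fluorogenic assays read relative fluorescence units (RFU); converting to
product concentration requires a standard curve of the free fluorophore
(AMC for peptidase substrates, MUB for glycosylase/phosphatase substrates)
prepared in the same sediment slurry matrix, because humic substances quench
fluorescence differently in each sample. The curve is an ordinary
least-squares line of fluorescence on concentration; its inverse maps a
fluorescence series onto concentration units.

Negative back-calculated concentrations are retained rather than clipped so
downstream rate regressions stay unbiased; detection-limit flagging happens
later, in rate space.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StandardCurve:
    """OLS calibration line fluorescence = intercept + slope * concentration.

    slope is in fluorescence units per µM and must be positive; intercept is
    the matrix background fluorescence.
    """

    fluorophore: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    n: int

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError(f"standard-curve slope must be > 0, got {self.slope}")
        if self.n < 3:
            raise ValueError("standard curve needs at least 3 points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r^2 out of range: {self.r_squared}")

    def to_dict(self) -> dict:
        return asdict(self)


def fit_standard_curve(points: pd.DataFrame, fluorophore: str = "AMC") -> StandardCurve:
    """Fit a standard curve by OLS.

    Parameters
    ----------
    points : DataFrame with columns ``concentration_uM`` and ``fluorescence``
        (a two-column frame in that order is also accepted). At least three
        points over at least two distinct non-negative concentrations.
    fluorophore : label carried on the returned curve.
    """
    if not {"concentration_uM", "fluorescence"} <= set(points.columns):
        if points.shape[1] != 2:
            raise ValueError("expected columns concentration_uM, fluorescence")
        points = points.set_axis(["concentration_uM", "fluorescence"], axis=1)
    conc = np.asarray(points["concentration_uM"], dtype=float)
    fluo = np.asarray(points["fluorescence"], dtype=float)
    if conc.size < 3:
        raise ValueError("need at least 3 standard points")
    if np.any(conc < 0):
        raise ValueError("negative standard concentrations")
    if np.unique(conc).size < 2:
        raise ValueError("singular design: all standard concentrations identical")
    res = stats.linregress(conc, fluo)
    return StandardCurve(
        fluorophore=fluorophore,
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        r_squared=float(res.rvalue**2),
        n=int(conc.size),
    )


def fluorescence_to_concentration(curve: StandardCurve, fluorescence) -> np.ndarray:
    """Invert the standard curve: C = (F - b) / m, in µM.

    Vectorized; values may come out negative under noise and are deliberately
    not clipped.
    """
    if curve.slope <= 0:
        raise ValueError("standard-curve slope must be > 0")
    f = np.asarray(fluorescence, dtype=float)
    return (f - curve.intercept) / curve.slope
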