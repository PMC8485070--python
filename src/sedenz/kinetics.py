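"""Hydrolysis-rate estimation and Michaelis–Menten kinetics.

A potential-activity assay adds a fluorogenic substrate proxy to a sediment
slurry (default geometry: 3 g sediment dispersed in 100 ml buffer, 1 ml
reaction cuvettes) and reads fluorescence 3–5 times over ~24 h. The initial
hydrolysis rate v0 is the OLS slope of calibrated product concentration on
time. Rates are expressed per gram of wet sediment: µM h⁻¹ in the cuvette
times (slurry volume / sediment mass) gives nmol g⁻¹ h⁻¹, because 1 µM in
the 1-ml reaction is 1 nmol ml⁻¹ and each ml of slurry carries
mass/volume grams of sediment.

Live replicates are compared against autoclaved (killed) controls with a
one-sided Welch t-test, saturation designs (10–11 substrate levels) are fit
to v = V_max·S/(K_m+S), and rates can be projected to in-situ temperature
with a Q10 factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class AssayGeometry:
    """Slurry and reaction geometry of the cuvette assay."""

    sediment_mass_g: float = 3.0
    slurry_volume_ml: float = 100.0
    reaction_volume_ml: float = 1.0
    substrate_stock_mM: float = 20.0

    def __post_init__(self):
        for name in ("sediment_mass_g", "slurry_volume_ml",
                     "reaction_volume_ml", "substrate_stock_mM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def sediment_per_reaction_g(self) -> float:
        """Grams of sediment contained in one reaction volume."""
        return self.sediment_mass_g * self.reaction_volume_ml / self.slurry_volume_ml


@dataclass(frozen=True)
class RateEstimate:
    """An initial hydrolysis rate with its regression diagnostics.

    ``v0`` is in nmol g⁻¹ h⁻¹ after unit conversion (µM h⁻¹ before); the
    below-detection flag records whether v0 fell under the detection limit
    used for the run.
    """

    v0: float
    se: float
    n: int
    r_squared: float
    treatment: str = "live"
    below_detection: bool = False
    detection_limit: float = float("nan")

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("rate regression needs >= 3 timepoints")
        if not (self.se >= 0 or np.isnan(self.se)):
            raise ValueError("standard error must be >= 0")


@dataclass(frozen=True)
class MMFit:
    """Michaelis–Menten parameters for one saturation curve."""

    vmax: float
    vmax_se: float
    km: float
    km_se: float
    covariance: tuple = ((float("nan"),) * 2,) * 2
    n_levels: int = 0
    converged: bool = False
    message: str = ""

    def __post_init__(self):
        if self.converged:
            if self.vmax < 0:
                raise ValueError("converged fit with negative V_max")
            if self.km <= 0:
                raise ValueError("converged fit with non-positive K_m")
            if self.n_levels < 5:
                raise ValueError("reported fits require >= 5 concentration levels")

    def predict(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return michaelis_menten(s, self.vmax, self.km)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariance"] = [list(row) for row in self.covariance]
        return d


def michaelis_menten(s, vmax: float, km: float):
    """v(S) = V_max * S / (K_m + S)."""
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def final_substrate_concentration(stock_mM: float, aliquot_ul: float,
                                  total_ul: float) -> float:
    """Final substrate concentration in the cuvette, in µM.

    E.g. 20 µl of a 20 mM stock into a 1,000 µl reaction gives 400 µM, the
    single-concentration potential-activity design.
    """
    if stock_mM <= 0 or total_ul <= 0 or aliquot_ul < 0:
        raise ValueError("volumes and stock concentration must be positive")
    if aliquot_ul > total_ul:
        raise ValueError("aliquot volume exceeds total reaction volume")
    return stock_mM * 1000.0 * aliquot_ul / total_ul


def compute_v0(times_h, conc_uM, treatment: str = "live",
               window: str = "all") -> RateEstimate:
    """Initial rate v0 as the OLS slope of concentration on time (µM h⁻¹).

    Time zero is substrate addition. ``window="all"`` regresses over every
    timepoint; ``window="initial-linear"`` picks the prefix (>= 3 points)
    maximizing r², a guard against late-time curvature from substrate
    depletion.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc_uM, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 timepoints")
    if t.size != c.size:
        raise ValueError("times and concentrations differ in length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if window not in ("all", "initial-linear"):
        raise ValueError(f"unknown window mode {window!r}")

    def _fit(tt, cc):
        res = stats.linregress(tt, cc)
        return res.slope, res.stderr, res.rvalue**2

    if window == "all":
        slope, se, r2 = _fit(t, c)
        n = t.size
    else:
        best = None
        for k in range(3, t.size + 1):
            slope, se, r2 = _fit(t[:k], c[:k])
            if best is None or r2 > best[2]:
                best = (slope, se, r2, k)
        slope, se, r2, n = best
    if np.isnan(r2):  # constant concentration: zero slope, zero spread
        r2 = 0.0
    return RateEstimate(v0=float(slope), se=float(se) if np.isfinite(se) else 0.0,
                        n=int(n), r_squared=float(r2), treatment=treatment)


def convert_rate_units(v_uM_per_h: float, geom: AssayGeometry) -> float:
    """Convert a cuvette rate (µM h⁻¹) to nmol per g sediment per hour.

    µM ≡ nmol ml⁻¹, so the reaction produces v·V_rxn nmol h⁻¹, and the
    reaction holds mass·V_rxn/V_slurry grams of sediment; the reaction
    volume cancels, leaving v · V_slurry / mass.
    """
    if geom.sediment_mass_g <= 0:
        raise ValueError("sediment mass must be positive")
    nmol_per_h = v_uM_per_h * geom.reaction_volume_ml
    return nmol_per_h / geom.sediment_per_reaction_g


def rate_per_g_to_uM(v_nmol_g_h: float, geom: AssayGeometry) -> float:
    """Inverse of :func:`convert_rate_units` (used by the simulator)."""
    return v_nmol_g_h * geom.sediment_per_reaction_g / geom.reaction_volume_ml


def detection_limit(blank_rates=None, *, sigma_f: float | None = None,
                    curve=None, horizon_h: float | None = None,
                    k: float = 3.0, geom: AssayGeometry = AssayGeometry(),
                    override: float | None = None) -> float:
    """Detection limit for a hydrolysis rate, in nmol g⁻¹ h⁻¹.

    Three modes, in precedence order:

    * ``override`` — return a user-supplied constant unchanged (e.g. study
      values 4.77e-2 live / 2.41e-2 killed);
    * empirical — ``k`` times the SD of >= 3 blank rate estimates (already in
      per-gram units);
    * noise-based — the smallest slope resolvable from fluorescence noise,
      k·σ_F/(m·horizon) in µM h⁻¹, converted to per-gram units.
    """
    if override is not None:
        return float(override)
    if blank_rates is not None:
        v = np.asarray([r.v0 if isinstance(r, RateEstimate) else r
                        for r in blank_rates], dtype=float)
        if v.size < 3:
            raise ValueError("empirical mode needs >= 3 blank rates")
        return float(k * v.std(ddof=1))
    if sigma_f is None or curve is None or horizon_h is None:
        raise ValueError("need blank rates, an override, or (sigma_f, curve, horizon)")
    dl_uM_h = k * sigma_f / (curve.slope * horizon_h)
    return convert_rate_units(dl_uM_h, geom)


@dataclass(frozen=True)
class LiveKilledComparison:
    difference: float
    t: float
    p: float
    significant: bool
    alpha: float


def compare_live_killed(live, killed, alpha: float = 0.05) -> LiveKilledComparison:
    """One-sided Welch t-test of mean(live) > mean(killed).

    Accepts RateEstimates or plain rates; degenerate zero-variance inputs
    with equal means are reported as not significant with p = 1.
    """
    lv = np.asarray([r.v0 if isinstance(r, RateEstimate) else r for r in live], float)
    kv = np.asarray([r.v0 if isinstance(r, RateEstimate) else r for r in killed], float)
    if lv.size < 2 or kv.size < 2:
        raise ValueError("need >= 2 replicates per group")
    diff = float(lv.mean() - kv.mean())
    if lv.std(ddof=1) == 0 and kv.std(ddof=1) == 0:
        if diff == 0:
            return LiveKilledComparison(0.0, 0.0, 1.0, False, alpha)
        p = 0.0 if diff > 0 else 1.0
        return LiveKilledComparison(diff, float("inf") * np.sign(diff), p,
                                    diff > 0, alpha)
    t, p = stats.ttest_ind(lv, kv, equal_var=False, alternative="greater")
    return LiveKilledComparison(diff, float(t), float(p), bool(p < alpha), alpha)


def fit_michaelis_menten(curve_data: pd.DataFrame) -> MMFit:
    """Fit v = V_max·S/(K_m+S) to (S, v) pairs by damped least squares.

    Initialization: V_max⁰ = max(v), K_m⁰ = the S whose v is nearest half of
    V_max⁰ (floored away from zero). Standard errors come from the
    Jacobian-based covariance at the optimum. Requires >= 5 distinct
    substrate levels; an all-non-positive rate vector or a failed/singular
    fit is reported as non-converged, never silently returned.
    """
    if not {"substrate_conc_uM", "v"} <= set(curve_data.columns):
        if curve_data.shape[1] != 2:
            raise ValueError("expected columns substrate_conc_uM, v")
        curve_data = curve_data.set_axis(["substrate_conc_uM", "v"], axis=1)
    s = np.asarray(curve_data["substrate_conc_uM"], dtype=float)
    v = np.asarray(curve_data["v"], dtype=float)
    n_levels = np.unique(s).size
    if n_levels < 5:
        raise ValueError("need >= 5 distinct substrate levels")
    if np.all(v <= 0):
        return MMFit(np.nan, np.nan, np.nan, np.nan, n_levels=0,
                     converged=False, message="no signal: all rates <= 0")

    vmax0 = float(v.max())
    half = vmax0 / 2.0
    pos = s[s > 0]
    km0 = float(pos[np.argmin(np.abs(v[s > 0] - half))]) if pos.size else 1.0
    km0 = max(km0, 1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                michaelis_menten, s, v, p0=[vmax0, km0],
                bounds=([0.0, 1e-9], [np.inf, np.inf]), method="trf",
                maxfev=10000,
            )
    except (RuntimeError, ValueError) as exc:
        return MMFit(np.nan, np.nan, np.nan, np.nan, n_levels=0,
                     converged=False, message=f"fit failed: {exc}")
    if not np.all(np.isfinite(pcov)):
        return MMFit(float(popt[0]), np.nan, float(popt[1]), np.nan,
                     n_levels=0, converged=False,
                     message="singular Jacobian: covariance undefined")
    se = np.sqrt(np.diag(pcov))
    return MMFit(vmax=float(popt[0]), vmax_se=float(se[0]),
                 km=float(popt[1]), km_se=float(se[1]),
                 covariance=tuple(tuple(row) for row in pcov),
                 n_levels=int(n_levels), converged=True, message="converged")


def km_depth_trend(fits: pd.DataFrame) -> tuple[float, float, int]:
    """OLS regression of K_m on depth with a two-sided slope test.

    ``fits`` needs columns ``depth_mbsf`` and ``km`` (converged fits only).
    Returns (slope in µM per m, p-value, n).
    """
    if not {"depth_mbsf", "km"} <= set(fits.columns):
        raise ValueError("expected columns depth_mbsf, km")
    d = np.asarray(fits["depth_mbsf"], dtype=float)
    k = np.asarray(fits["km"], dtype=float)
    if d.size < 3:
        raise ValueError("need >= 3 depths with converged fits")
    res = stats.linregress(d, k)
    return float(res.slope), float(res.pvalue), int(d.size)


def temperature_adjust(rate: float, q10: float, dT_C: float) -> float:
    """Scale a rate by Q10^(ΔT/10).

    ΔT is in-situ minus assay temperature, so projecting a 20 °C assay to an
    8 °C sediment uses dT_C = -12.
    """
    if q10 <= 0:
        raise ValueError("Q10 must be positive")
    return rate * q10 ** (dT_C / 10.0)
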