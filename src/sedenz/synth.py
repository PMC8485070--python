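"""Synthetic assay-data generator with known ground truth.

Every downstream stage (calibration, rate estimation, Michaelis–Menten
fitting, retention statistics, lifetime bounds) is testable against the
parameters that generated its inputs. The generator emulates the study
layout: triplicate live/autoclaved cuvette fluorescence series read 3–5
times over ~24 h, a single-concentration (400 µM) potential-activity design
and a 10–11-level saturation design (0–720 or 0–800 µM), enzyme activity
profiles that peak near ~11 mbsf and vanish below the stratigraphic
unconformity at 51.7 mbsf (except phosphatase), and log-linearly declining
cell counts with independent segments above and below the unconformity.

Product accumulation is linear in time by default (no substrate depletion);
an integrated-rate mode simulates first-order depletion so tests can probe
v0-estimation bias. Fluorescence noise is homoscedastic Gaussian.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dists import DistSpec, parse_dist
from .kinetics import AssayGeometry, rate_per_g_to_uM
from .reference import (DEFAULT_DEPTHS_MBSF, UNCONFORMITY_MBSF, enzyme_table)

#: Canonical tidy assay-table columns (one fluorescence reading per row).
ASSAY_COLUMNS = ["sample_id", "depth_mbsf", "enzyme", "enzyme_class",
                 "substrate", "fluorophore", "treatment", "replicate",
                 "substrate_conc_uM", "time_h", "fluorescence"]


@dataclass
class TruthSpec:
    """Ground-truth parameters for one synthetic dataset.

    Parameters
    ----------
    vmax : DataFrame (enzyme, depth_mbsf, vmax_nmol_g_h)
        True maximum potential activities per enzyme × depth.
    enzymes : DataFrame (enzyme, enzyme_class, substrate, fluorophore,
        km_uM, rho) — per-enzyme Michaelis constant and autoclave retention
        fraction ρ (killed/live activity ratio).
    calibration : mapping fluorophore -> (slope m RFU/µM, intercept b RFU).
    sigma_f : fluorescence noise SD (RFU), homoscedastic Gaussian.
    n_replicates, n_timepoints, horizon_h : assay layout; 3 replicates and
        3–5 timepoints over 24 h mirror the cuvette protocol.
    cell_* : log10 cell-count profile parameters, segmented at the
        unconformity (counts in cells per g at a reference depth, plus a
        log10 decline per metre for each segment).
    """

    vmax: pd.DataFrame
    enzymes: pd.DataFrame
    calibration: dict
    sigma_f: float = 20.0
    n_replicates: int = 3
    n_timepoints: int = 4
    horizon_h: float = 24.0
    unconformity_mbsf: float = UNCONFORMITY_MBSF
    geometry: AssayGeometry = field(default_factory=AssayGeometry)
    cell_surface_log10: float = float(np.log10(4.6e8))
    cell_surface_depth: float = 4.35
    cell_decline_above: float = 0.008   # log10 units per metre
    cell_break_log10: float = 7.95      # log10 counts at top of lower segment
    cell_decline_below: float = 0.005
    seed: int = 0
    depletion: bool = False

    def __post_init__(self):
        if (self.vmax["vmax_nmol_g_h"] < 0).any():
            raise ValueError("true V_max must be >= 0")
        if (self.enzymes["km_uM"] <= 0).any():
            raise ValueError("true K_m must be > 0")
        if (self.enzymes["rho"] < 0).any():
            raise ValueError("retention fraction rho must be >= 0")
        if self.sigma_f < 0:
            raise ValueError("sigma_f must be >= 0")
        for fl, (m, b) in self.calibration.items():
            if m <= 0:
                raise ValueError(f"calibration slope for {fl} must be > 0")
        if not 3 <= self.n_timepoints <= 5:
            raise ValueError("n_timepoints must be 3-5")
        if self.horizon_h <= 0:
            raise ValueError("assay horizon must be positive")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")

    def to_json(self) -> str:
        """Serialize the truth record (for the sidecar written next to the
        generated CSV)."""
        d = {
            "vmax": self.vmax.to_dict(orient="records"),
            "enzymes": self.enzymes.to_dict(orient="records"),
            "calibration": {k: list(v) for k, v in self.calibration.items()},
        }
        for key in ("sigma_f", "n_replicates", "n_timepoints", "horizon_h",
                    "unconformity_mbsf", "cell_surface_log10",
                    "cell_surface_depth", "cell_decline_above",
                    "cell_break_log10", "cell_decline_below", "seed",
                    "depletion"):
            d[key] = getattr(self, key)
        d["geometry"] = asdict(self.geometry)
        return json.dumps(d, indent=2, sort_keys=True)


def default_truth(seed: int = 0, rho: float = 0.5, sigma_f: float = 20.0,
                  depths=DEFAULT_DEPTHS_MBSF, enzymes: pd.DataFrame | None = None,
                  km_uM: float = 200.0, deep_phosphatase: bool = True) -> TruthSpec:
    """Study-layout truth: activity peaks near 11 mbsf, decays with depth,
    and is zero below the unconformity for all classes except phosphatase.

    Peak amplitudes are class-specific (peptidases ~22, glycosylases ~16,
    phosphatase ~75 nmol g⁻¹ h⁻¹ at the peak, matching the order of
    magnitude of reported maxima).
    """
    enz = enzyme_table() if enzymes is None else enzymes.copy()
    if "km_uM" not in enz.columns:
        enz["km_uM"] = km_uM
    if "rho" not in enz.columns:
        enz["rho"] = rho
    amp = {"peptidase": 22.0, "glycosylase": 16.0, "phosphatase": 75.0}
    rows = []
    for _, e in enz.iterrows():
        a = amp[e["enzyme_class"]]
        for d in depths:
            if d > UNCONFORMITY_MBSF:
                v = a * 0.03 if (deep_phosphatase and
                                 e["enzyme_class"] == "phosphatase") else 0.0
            else:
                v = a * float(np.exp(-0.5 * ((d - 11.1) / 16.0) ** 2))
            rows.append((e["enzyme"], float(d), v))
    vmax = pd.DataFrame(rows, columns=["enzyme", "depth_mbsf", "vmax_nmol_g_h"])
    calibration = {"AMC": (1000.0, 50.0), "MUB": (1000.0, 50.0)}
    return TruthSpec(vmax=vmax, enzymes=enz, calibration=calibration,
                     sigma_f=sigma_f, seed=seed)


def _series_product_uM(v_uM_h: float, times_h: np.ndarray,
                       s0: float, depletion: bool) -> np.ndarray:
    if not depletion or v_uM_h == 0 or s0 == 0:
        return v_uM_h * times_h
    # First-order depletion proxy: P(t) = S0·(1 - exp(-kt)) with k = v/S0,
    # so dP/dt at t = 0 equals the nominal initial rate v.
    k = v_uM_h / s0
    return s0 * (1.0 - np.exp(-k * times_h))


def generate_assay_dataset(truth: TruthSpec, design: str = "vmax",
                           n_levels: int = 11, s_max_uM: float = 800.0
                           ) -> tuple[pd.DataFrame, TruthSpec]:
    """Simulate the canonical tidy assay table for one design.

    ``design="vmax"`` (alias ``"vmax-single-conc"``): every enzyme × depth ×
    treatment × replicate at a single 400 µM substrate level. ``"saturation"``:
    substrate levels evenly spaced from 0 to ``s_max_uM`` (11 levels 0–800 by
    default; 10 levels 0–720 is the other study layout), at the shallowest
    depth only, as saturation curves are run on the shallowest sample.

    Fluorescence is F(t) = b + m·P(t) + ε with P(t) = v(S)·t,
    v(S) = V_max·S/(K_m+S) scaled by ρ for the autoclaved treatment, and
    ε ~ Normal(0, σ_F). Returns (table, truth) so recovery tests can compare
    against ground truth.
    """
    if design in ("vmax", "vmax-single-conc"):
        levels = np.array([400.0])
        vmax_table = truth.vmax
    elif design == "saturation":
        if truth.horizon_h <= 0:
            raise ValueError("non-positive assay horizon")
        levels = np.linspace(0.0, s_max_uM, n_levels)
        top = truth.vmax["depth_mbsf"].min()
        vmax_table = truth.vmax[truth.vmax["depth_mbsf"] == top]
    else:
        raise ValueError(f"unknown design {design!r}; use 'vmax' or 'saturation'")
    if truth.horizon_h <= 0:
        raise ValueError("non-positive assay horizon")

    rng = np.random.default_rng(truth.seed)
    times = np.linspace(0.0, truth.horizon_h, truth.n_timepoints)
    enz = truth.enzymes.set_index("enzyme")
    rows = []
    for _, vr in vmax_table.iterrows():
        e = enz.loc[vr["enzyme"]]
        m, b = truth.calibration[e["fluorophore"]]
        for treatment in ("live", "autoclaved"):
            scale = float(e["rho"]) if treatment == "autoclaved" else 1.0
            for rep in range(1, truth.n_replicates + 1):
                for s in levels:
                    v_g = vr["vmax_nmol_g_h"] * scale * (
                        s / (e["km_uM"] + s) if s > 0 else 0.0)
                    v_uM = rate_per_g_to_uM(v_g, truth.geometry)
                    p = _series_product_uM(v_uM, times, s, truth.depletion)
                    f = b + m * p
                    if truth.sigma_f > 0:
                        f = f + rng.normal(0.0, truth.sigma_f, size=f.shape)
                    sample_id = f"D{vr['depth_mbsf']:06.2f}"
                    for t, fi in zip(times, f):
                        rows.append((sample_id, vr["depth_mbsf"], vr["enzyme"],
                                     e["enzyme_class"], e["substrate"],
                                     e["fluorophore"], treatment, rep,
                                     float(s), float(t), float(fi)))
    table = pd.DataFrame(rows, columns=ASSAY_COLUMNS)
    return table, truth


def generate_standard_curve_data(truth: TruthSpec, levels,
                                 n_replicates: int | None = None
                                 ) -> pd.DataFrame:
    """Simulate standard-curve readings: F = b + m·C + ε per level, for each
    fluorophore, replicated ``n_replicates`` times (defaults to the assay
    replicate count). Needs >= 3 distinct non-negative levels."""
    levels = np.asarray(levels, dtype=float)
    if np.unique(levels).size < 3:
        raise ValueError("need >= 3 distinct standard levels")
    if np.any(levels < 0):
        raise ValueError("standard levels must be non-negative")
    reps = truth.n_replicates if n_replicates is None else n_replicates
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    rows = []
    for fl, (m, b) in sorted(truth.calibration.items()):
        for c in levels:
            for rep in range(1, reps + 1):
                f = b + m * c
                if truth.sigma_f > 0:
                    f += rng.normal(0.0, truth.sigma_f)
                rows.append((fl, float(c), rep, float(f)))
    return pd.DataFrame(rows, columns=["fluorophore", "concentration_uM",
                                       "replicate", "fluorescence"])


def generate_cell_counts(truth: TruthSpec, depths) -> pd.DataFrame:
    """Simulate a cell-count profile: log10(cells g⁻¹) declines linearly
    with depth, with independent segment parameters above and below the
    unconformity, plus seeded Gaussian noise of 0.05 log10 units (zero when
    ``truth.sigma_f == 0`` so noiseless truths stay fully deterministic)."""
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("empty depth list")
    if np.any(depths <= 0) or np.any(np.diff(depths) < 0):
        raise ValueError("depths must be positive and sorted ascending")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 2]))
    log10n = np.where(
        depths <= truth.unconformity_mbsf,
        truth.cell_surface_log10
        - truth.cell_decline_above * (depths - truth.cell_surface_depth),
        truth.cell_break_log10
        - truth.cell_decline_below * (depths - truth.unconformity_mbsf),
    )
    if truth.sigma_f > 0:
        log10n = log10n + rng.normal(0.0, 0.05, size=log10n.shape)
    return pd.DataFrame({"core": "SYN", "depth_mbsf": depths,
                         "cells_per_g": 10.0 ** log10n})


def generate_specific_activities(n: int, dist, seed: int = 0) -> np.ndarray:
    """Draw ``n`` enzyme specific activities (mol bonds h⁻¹ per mol enzyme C)
    from a distribution spec (point | log-uniform | log-normal)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    d: DistSpec = parse_dist(dist)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    return d.draw(n, rng)
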