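"""Depth profiles: cell-count interpolation and cell-specific activities.

Cell counts in sediment cores are measured near, but rarely exactly at, the
depths where enzyme activities are assayed. Counts are interpolated by
fitting local polynomials to log10(cells g⁻¹) versus depth — separately for
the segments above and below the stratigraphic unconformity, because the
marine and lacustrine deposits have distinct burial histories — and never
extrapolated beyond a segment's measured span. Cell-specific activities are
the per-gram rates divided by interpolated counts, in amol per cell per
hour (1 nmol = 1e9 amol).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import UNCONFORMITY_MBSF

AMOL_PER_NMOL = 1e9


@dataclass
class CellCountProfile:
    """Measured cell counts with segmented polynomial interpolation.

    Fits log10(counts) vs depth per segment; degree (default 2) is clamped
    to n_points - 1 when a segment is short.
    """

    depths: np.ndarray
    counts: np.ndarray
    unconformity_mbsf: float = UNCONFORMITY_MBSF
    degree: int = 2
    segment_fits: dict = field(default_factory=dict, init=False)

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts <= 0):
            raise ValueError("cell counts must be positive")
        if np.any(np.diff(self.depths) < 0):
            raise ValueError("depths must be sorted ascending")
        for name, mask in self._segments().items():
            d = self.depths[mask]
            if d.size >= 2:
                deg = min(self.degree, d.size - 1)
                coef = np.polyfit(d, np.log10(self.counts[mask]), deg)
                self.segment_fits[name] = {
                    "coefficients": coef, "degree": deg,
                    "span": (float(d.min()), float(d.max())), "n": int(d.size),
                }

    def _segments(self) -> dict:
        above = self.depths <= self.unconformity_mbsf
        return {"above": above, "below": ~above}

    @classmethod
    def from_table(cls, table: pd.DataFrame, **kwargs) -> "CellCountProfile":
        t = table.sort_values("depth_mbsf")
        return cls(t["depth_mbsf"].to_numpy(), t["cells_per_g"].to_numpy(),
                   **kwargs)


def interpolate_cell_counts(profile: CellCountProfile, query_depths) -> np.ndarray:
    """Evaluate the segmented log10-polynomial fit at the query depths.

    Each query is served by the segment (above/below the unconformity) it
    falls in; queries outside that segment's measured span, or in a segment
    with fewer than 3 measured points, raise rather than extrapolate.
    """
    q = np.asarray(query_depths, dtype=float)
    out = np.empty_like(q)
    for i, d in enumerate(q.ravel()):
        name = "above" if d <= profile.unconformity_mbsf else "below"
        fit = profile.segment_fits.get(name)
        if fit is None or fit["n"] < 3:
            raise ValueError(
                f"segment '{name}' has fewer than 3 measured points")
        lo, hi = fit["span"]
        if not (lo <= d <= hi):
            raise ValueError(
                f"query depth {d} mbsf outside measured span [{lo}, {hi}] "
                f"of segment '{name}' (no extrapolation)")
        out.ravel()[i] = 10.0 ** np.polyval(fit["coefficients"], d)
    return out


def cell_specific_activity(v_nmol_g_h, cells_per_g) -> np.ndarray:
    """Per-cell rate: v / cells, converted to amol cell⁻¹ h⁻¹."""
    v = np.asarray(v_nmol_g_h, dtype=float)
    c = np.asarray(cells_per_g, dtype=float)
    if np.any(c <= 0):
        raise ValueError("cell counts must be positive")
    return v * AMOL_PER_NMOL / c


def assemble_depth_profile(rates: pd.DataFrame,
                           profile: CellCountProfile) -> pd.DataFrame:
    """Join per-enzyme rate summaries with interpolated cell counts.

    ``rates`` carries one row per enzyme × depth with columns
    ``depth_mbsf, enzyme, enzyme_class, live_v0, live_se, killed_v0,
    killed_se, below_detection``. Depths outside the interpolation span get
    a missing cell count (and specific activity) with a warning rather than
    an extrapolated value.
    """
    if rates.empty:
        return rates.assign(cells_per_g=pd.Series(dtype=float),
                            cell_specific_amol=pd.Series(dtype=float))
    out = rates.copy()
    cells = np.full(len(out), np.nan)
    for i, d in enumerate(out["depth_mbsf"].to_numpy(dtype=float)):
        try:
            cells[i] = interpolate_cell_counts(profile, [d])[0]
        except ValueError as exc:
            warnings.warn(f"no cell count at {d} mbsf: {exc}", stacklevel=2)
    out["cells_per_g"] = cells
    with np.errstate(invalid="ignore"):
        out["cell_specific_amol"] = np.where(
            np.isfinite(cells) & (cells > 0),
            out["live_v0"].to_numpy(dtype=float) * AMOL_PER_NMOL / cells,
            np.nan)
    return out
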