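"""End-to-end pipeline orchestration.

Stages run in canonical order — simulate → calibrate → rates → fit-mm →
profiles → retention → lifetime — against a single config, exchanging tidy
CSV files and writing a JSON run manifest (config echo + hash, seed, row
counts, warnings) so every output is traceable and a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import fit_standard_curve, fluorescence_to_concentration
from .dists import log_uniform, parse_dist, point
from .kinetics import (AssayGeometry, compare_live_killed, compute_v0,
                       convert_rate_units, detection_limit,
                       fit_michaelis_menten, km_depth_trend)
from .lifetime import LifetimeInputs, monte_carlo_lifetime, sensitivity_table
from .profiles import CellCountProfile, assemble_depth_profile
from .reference import ENZYME_CLASSES, FLUOROPHORES, TREATMENTS, UNCONFORMITY_MBSF
from .retention import (conover_iman, fraction_retained, kruskal_wallis,
                        summarize_retention)
from .synth import (ASSAY_COLUMNS, default_truth, generate_assay_dataset,
                    generate_cell_counts, generate_standard_curve_data)

log = logging.getLogger("sedenz")

STAGES = ("simulate", "calibrate", "rates", "fit-mm", "profiles",
          "retention", "lifetime")

_SERIES_KEY = ["sample_id", "enzyme", "treatment", "replicate",
               "substrate_conc_uM"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    outdir: str = "out"
    seed: int = 0
    paths: dict = field(default_factory=dict)
    geometry: AssayGeometry = field(default_factory=AssayGeometry)
    unconformity_mbsf: float = UNCONFORMITY_MBSF
    detection_k: float = 3.0
    detection_override_live: float | None = None
    detection_override_killed: float | None = None
    exclusion_k: float = 3.0
    alpha: float = 0.05
    poly_degree: int = 2
    q10: float = 2.0
    assay_temp_C: float = 20.0
    insitu_temp_C: float = 8.0
    lifetime: dict = field(default_factory=lambda: {
        "enzyme": "clostripain",
        "sa_dist": ["log-uniform", 1e2, 1e4],
        "growth_efficiency": 0.10,
        "rc_nmol_cm3_day": 0.1,
        "bulk_density_g_cm3": 1.0,
        "sorption_factor": 1.0,
        "n_draws": 100_000,
    })

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "geometry" in raw:
            raw["geometry"] = AssayGeometry(**raw["geometry"])
        base = cls()
        lt = dict(base.lifetime)
        lt.update(raw.pop("lifetime", {}))
        raw["lifetime"] = lt
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = asdict(self.geometry)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_assay_table(path) -> pd.DataFrame:
    """Read and validate the canonical tidy assay CSV.

    Checks the schema, the treatment / fluorophore / enzyme-class
    vocabularies, strictly increasing times within each cuvette series, and
    uniqueness of (sample, enzyme, treatment, replicate, concentration,
    time) keys; violations raise with the offending row or series named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"assay table not found: {path}")
    df = pd.read_csv(path)
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["treatment"].isin(TREATMENTS)
    if bad.any():
        raise ValueError(
            f"{path}: row {df.index[bad][0] + 2}: unknown treatment "
            f"{df.loc[bad, 'treatment'].iloc[0]!r}")
    bad = ~df["fluorophore"].isin(FLUOROPHORES)
    if bad.any():
        raise ValueError(
            f"{path}: row {df.index[bad][0] + 2}: unknown fluorophore "
            f"{df.loc[bad, 'fluorophore'].iloc[0]!r}")
    bad = ~df["enzyme_class"].isin(ENZYME_CLASSES)
    if bad.any():
        raise ValueError(
            f"{path}: row {df.index[bad][0] + 2}: unknown enzyme class "
            f"{df.loc[bad, 'enzyme_class'].iloc[0]!r}")
    dup = df.duplicated(subset=_SERIES_KEY + ["time_h"])
    if dup.any():
        key = df.loc[dup, _SERIES_KEY + ["time_h"]].iloc[0].to_dict()
        raise ValueError(f"{path}: duplicate observation key {key}")
    for key, g in df.groupby(_SERIES_KEY, sort=False):
        t = g["time_h"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"{path}: series {dict(zip(_SERIES_KEY, key))}: times must "
                "be strictly increasing")
    return df


def _require(path, stage: str) -> Path:
    p = Path(path) if path else None
    if p is None or not p.exists():
        raise FileNotFoundError(
            f"stage '{stage}' is missing its input {path!r}; run the "
            "producing stage first or point paths at existing files")
    return p


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


class Pipeline:
    """Stage runner bound to one config; see :func:`run_pipeline`."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = {"package": "sedenz", "version": __version__,
                         "seed": config.seed,
                         "config_hash": config.config_hash(),
                         "config": config.to_dict(),
                         "stages": {}, "warnings": []}
        self.paths = dict(config.paths)

    # -- stages ---------------------------------------------------------
    def simulate(self) -> None:
        truth = default_truth(seed=self.cfg.seed)
        vmax_tab, _ = generate_assay_dataset(truth, design="vmax")
        sat_tab, _ = generate_assay_dataset(truth, design="saturation")
        std = generate_standard_curve_data(truth, levels=[0, 1, 2, 5, 10, 20])
        depths = np.unique(truth.vmax["depth_mbsf"])
        grid = np.unique(np.concatenate([
            depths, np.linspace(depths.min(), depths.max(), 40)]))
        cells = generate_cell_counts(truth, np.sort(grid))
        out = {"assay_csv": "assay_vmax.csv",
               "saturation_csv": "assay_saturation.csv",
               "standard_curve_csv": "standard_curves.csv",
               "cell_count_csv": "cell_counts.csv"}
        _write_csv(vmax_tab, self.outdir / out["assay_csv"])
        _write_csv(sat_tab, self.outdir / out["saturation_csv"])
        _write_csv(std, self.outdir / out["standard_curve_csv"])
        _write_csv(cells, self.outdir / out["cell_count_csv"])
        (self.outdir / "truth.json").write_text(truth.to_json())
        for k, v in out.items():
            self.paths[k] = str(self.outdir / v)
        self._record("simulate", {**out, "truth": "truth.json"},
                     rows=len(vmax_tab) + len(sat_tab) + len(std) + len(cells))

    def calibrate(self) -> None:
        path = _require(self.paths.get("standard_curve_csv"), "calibrate")
        std = pd.read_csv(path)
        curves = {}
        for fl, g in std.groupby("fluorophore"):
            curves[fl] = fit_standard_curve(
                g[["concentration_uM", "fluorescence"]], fluorophore=fl)
        payload = {fl: c.to_dict() for fl, c in curves.items()}
        (self.outdir / "calibration.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True))
        self.curves = curves
        self._record("calibrate", {"calibration": "calibration.json"},
                     rows=len(curves))

    def _calibrated_rates(self, table: pd.DataFrame) -> pd.DataFrame:
        """Per-cuvette v0 (nmol g⁻¹ h⁻¹) for every replicate series."""
        rows = []
        for key, g in table.groupby(_SERIES_KEY, sort=False):
            g = g.sort_values("time_h")
            curve = self.curves[g["fluorophore"].iloc[0]]
            conc = fluorescence_to_concentration(curve, g["fluorescence"])
            est = compute_v0(g["time_h"], conc,
                             treatment=g["treatment"].iloc[0])
            rec = dict(zip(_SERIES_KEY, key))
            rec.update(depth_mbsf=g["depth_mbsf"].iloc[0],
                       enzyme_class=g["enzyme_class"].iloc[0],
                       v0_nmol_g_h=convert_rate_units(est.v0, self.cfg.geometry),
                       se_nmol_g_h=convert_rate_units(est.se, self.cfg.geometry),
                       r_squared=est.r_squared, n_timepoints=est.n)
            rows.append(rec)
        return pd.DataFrame(rows)

    def rates(self) -> None:
        if not hasattr(self, "curves"):
            self.calibrate()
        path = _require(self.paths.get("assay_csv"), "rates")
        table = read_assay_table(path)
        per_rep = self._calibrated_rates(table)
        horizon = table["time_h"].max()
        dls = {}
        for trt, override in (("live", self.cfg.detection_override_live),
                              ("autoclaved", self.cfg.detection_override_killed)):
            curve = next(iter(self.curves.values()))
            sigma = _std_residual_sd(pd.read_csv(
                self.paths["standard_curve_csv"]))
            dls[trt] = detection_limit(sigma_f=sigma, curve=curve,
                                       horizon_h=horizon,
                                       k=self.cfg.detection_k,
                                       geom=self.cfg.geometry,
                                       override=override)
        rows = []
        for (depth, enzyme), g in per_rep.groupby(["depth_mbsf", "enzyme"]):
            live = g[g["treatment"] == "live"]["v0_nmol_g_h"].to_numpy()
            killed = g[g["treatment"] == "autoclaved"]["v0_nmol_g_h"].to_numpy()
            cmp_res = compare_live_killed(live, killed, alpha=self.cfg.alpha)
            lv, kv = live.mean(), killed.mean()
            rows.append({
                "depth_mbsf": depth, "enzyme": enzyme,
                "enzyme_class": g["enzyme_class"].iloc[0],
                "live_v0": lv,
                "live_se": live.std(ddof=1) / np.sqrt(live.size),
                "killed_v0": kv,
                "killed_se": killed.std(ddof=1) / np.sqrt(killed.size),
                "difference": cmp_res.difference, "p_value": cmp_res.p,
                "significant": cmp_res.significant,
                "below_detection": bool(lv < dls["live"]),
                "detection_limit": dls["live"],
                "detection_limit_killed": dls["autoclaved"],
            })
        rates = pd.DataFrame(rows).sort_values(
            ["depth_mbsf", "enzyme"]).reset_index(drop=True)
        _write_csv(rates, self.outdir / "rates.csv")
        _write_csv(per_rep, self.outdir / "rates_per_replicate.csv")
        self.paths["rates_csv"] = str(self.outdir / "rates.csv")
        self._record("rates", {"rates": "rates.csv",
                               "per_replicate": "rates_per_replicate.csv"},
                     rows=len(rates))

    def fit_mm(self) -> None:
        if not hasattr(self, "curves"):
            self.calibrate()
        path = _require(self.paths.get("saturation_csv"), "fit-mm")
        table = read_assay_table(path)
        per_rep = self._calibrated_rates(table)
        fits = []
        for (depth, enzyme), g in per_rep.groupby(["depth_mbsf", "enzyme"]):
            # live-minus-killed mean rate per substrate level
            mean = (g.pivot_table(index="substrate_conc_uM",
                                  columns="treatment", values="v0_nmol_g_h",
                                  aggfunc="mean").reset_index())
            if "autoclaved" not in mean or "live" not in mean:
                continue
            data = pd.DataFrame({
                "substrate_conc_uM": mean["substrate_conc_uM"],
                "v": mean["live"] - mean["autoclaved"]})
            fit = fit_michaelis_menten(data)
            fits.append({"depth_mbsf": depth, "enzyme": enzyme,
                         "enzyme_class": g["enzyme_class"].iloc[0],
                         **{k: v for k, v in fit.to_dict().items()
                            if k != "covariance"}})
        mm = pd.DataFrame(fits)
        _write_csv(mm, self.outdir / "mm_fits.csv")
        self.paths["mm_csv"] = str(self.outdir / "mm_fits.csv")
        extra = {}
        conv = mm[mm["converged"] == True]  # noqa: E712
        if conv["depth_mbsf"].nunique() >= 3:
            slope, p, n = km_depth_trend(conv)
            extra = {"km_depth_slope": slope, "km_depth_p": p, "km_depth_n": n}
        self._record("fit-mm", {"mm_fits": "mm_fits.csv", **extra},
                     rows=len(mm))

    def profiles(self) -> None:
        rates_path = _require(self.paths.get("rates_csv"), "profiles")
        cells_path = _require(self.paths.get("cell_count_csv"), "profiles")
        rates = pd.read_csv(rates_path)
        cells = pd.read_csv(cells_path)
        profile = CellCountProfile.from_table(
            cells, unconformity_mbsf=self.cfg.unconformity_mbsf,
            degree=self.cfg.poly_degree)
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            table = assemble_depth_profile(rates, profile)
        for w in wlist:
            self.manifest["warnings"].append(str(w.message))
        _write_csv(table, self.outdir / "depth_profile.csv")
        self.paths["profile_csv"] = str(self.outdir / "depth_profile.csv")
        self._record("profiles", {"depth_profile": "depth_profile.csv"},
                     rows=len(table))

    def retention(self) -> None:
        rates_path = _require(self.paths.get("rates_csv"), "retention")
        rates = pd.read_csv(rates_path)
        records = [
            fraction_retained(r["live_v0"], r["killed_v0"],
                              enzyme=r["enzyme"],
                              enzyme_class=r["enzyme_class"],
                              depth_mbsf=r["depth_mbsf"],
                              dl=r["detection_limit"],
                              exclusion_k=self.cfg.exclusion_k)
            for _, r in rates.iterrows()]
        ret = pd.DataFrame([r.__dict__ for r in records])
        _write_csv(ret, self.outdir / "retention.csv")
        kept = [r for r in records if not r.excluded]
        report = {"n_total": len(records), "n_excluded": len(records) - len(kept),
                  "exclusion_k": self.cfg.exclusion_k}
        if kept:
            report["overall"] = summarize_retention(kept, by="all").to_dict("records")
            report["by_class"] = summarize_retention(kept, by="class").to_dict("records")
            groups = {}
            for r in kept:
                groups.setdefault(r.enzyme_class, []).append(r.fraction_pct)
            if len(groups) >= 2:
                h, dof, p = kruskal_wallis(groups)
                post = conover_iman(groups, h=h, alpha=self.cfg.alpha)
                report["kruskal_wallis"] = {"H": h, "df": dof, "p": p,
                                            "n": sum(map(len, groups.values()))}
                report["conover_iman"] = [pw.__dict__ for pw in post.pairwise]
        (self.outdir / "retention_tests.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        self.paths["retention_csv"] = str(self.outdir / "retention.csv")
        self._record("retention", {"retention": "retention.csv",
                                   "tests": "retention_tests.json"},
                     rows=len(ret))

    def lifetime(self) -> None:
        rates_path = _require(self.paths.get("rates_csv"), "lifetime")
        rates = pd.read_csv(rates_path)
        lt = self.cfg.lifetime
        enzyme = lt.get("enzyme", "clostripain")
        sub = rates[rates["enzyme"] == enzyme]
        if sub.empty:
            raise ValueError(f"lifetime stage: no rates for enzyme {enzyme!r}")
        vmax = float(sub["live_v0"].max())
        sa_csv = self.paths.get("sa_csv")
        if sa_csv and Path(sa_csv).exists():
            sa = pd.read_csv(sa_csv)
            vals = sa.loc[sa["enzyme"] == enzyme, "sa_value"]
            vals = vals if len(vals) else sa["sa_value"]
            sa_dist = (point(float(vals.iloc[0])) if len(vals) == 1 else
                       log_uniform(float(vals.min()), float(vals.max())))
        else:
            sa_dist = parse_dist(lt["sa_dist"])
        inputs = LifetimeInputs(
            vmax_nmol_g_h=vmax, sa_dist=sa_dist,
            growth_efficiency=lt.get("growth_efficiency", 0.10),
            rc_nmol_cm3_day=lt.get("rc_nmol_cm3_day", 0.1),
            bulk_density_g_cm3=lt.get("bulk_density_g_cm3", 1.0),
            sorption_factor=lt.get("sorption_factor", 1.0),
            n_draws=int(lt.get("n_draws", 100_000)), seed=self.cfg.seed)
        scenarios = lt.get("scenarios") or [
            {"label": "baseline"},
            {"label": "sorbed, low GE", "sorption_factor": 3.0,
             "growth_efficiency": 0.037},
        ]
        table = sensitivity_table(inputs, scenarios)
        table.insert(0, "enzyme", enzyme)
        table.insert(1, "vmax_nmol_g_h", vmax)
        _write_csv(table, self.outdir / "lifetime.csv")
        base = monte_carlo_lifetime(inputs)
        (self.outdir / "lifetime.json").write_text(
            json.dumps({"estimate": base.__dict__, "scenarios":
                        table.to_dict("records")}, indent=2, sort_keys=True,
                       default=str))
        self._record("lifetime", {"lifetime": "lifetime.csv",
                                  "summary": "lifetime.json"},
                     rows=len(table))

    # -- bookkeeping ----------------------------------------------------
    def _record(self, stage: str, outputs: dict, rows: int) -> None:
        self.manifest["stages"][stage] = {"outputs": outputs, "rows": rows}
        log.info("stage %-9s done (%d rows)", stage, rows)

    def run(self, stages=STAGES) -> dict:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        order = [s for s in STAGES if s in stages]
        for s in order:
            getattr(self, s.replace("-", "_"))()
        (self.outdir / "run_manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True, default=str))
        return self.manifest


def _std_residual_sd(std: pd.DataFrame) -> float:
    """Pooled residual SD of the standard-curve fits — the fluorescence
    noise estimate feeding the noise-based detection limit."""
    resid = []
    for fl, g in std.groupby("fluorophore"):
        c = fit_standard_curve(g[["concentration_uM", "fluorescence"]],
                               fluorophore=fl)
        resid.append(g["fluorescence"].to_numpy()
                     - (c.intercept + c.slope * g["concentration_uM"].to_numpy()))
    r = np.concatenate(resid)
    return float(r.std(ddof=2)) if r.size > 2 else 0.0


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Execute the requested stages in canonical order; returns the run
    manifest. Missing inputs fail fast naming the stage."""
    return Pipeline(config).run(stages)
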