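"""Autoclave-retention statistics.

Autoclaving a slurry for an hour kills cells; residual substrate hydrolysis
in the killed control measures how much enzyme activity survives — a proxy
for enzyme stability (sorption to mineral surfaces is thought to protect
enzymes from thermal denaturation). The fraction retained is
100·v_killed/v_live per enzyme × depth, excluding pairs whose live rate sits
close to the detection limit (below ``exclusion_k`` × DL, default 3×).

Group differences among enzyme classes (peptidase, glycosylase,
phosphatase) use the tie-corrected Kruskal–Wallis rank test, followed by
Conover–Iman pairwise comparisons (t statistics on mean ranks with the
pooled rank variance scaled by (N-1-H)/(N-k), N-k degrees of freedom),
Holm-adjusted by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import RateEstimate


@dataclass(frozen=True)
class RetentionRecord:
    """Percent activity retained after autoclaving for one enzyme × depth.

    ``fraction_pct`` may exceed 100 (killed > live happens under noise);
    excluded records carry a reason and no usable fraction.
    """

    enzyme: str
    enzyme_class: str
    depth_mbsf: float
    fraction_pct: float
    excluded: bool = False
    reason: str = ""

    def __post_init__(self):
        if not self.excluded and self.fraction_pct < 0:
            raise ValueError("retention fraction must be >= 0")
        if self.excluded and not self.reason:
            raise ValueError("excluded records must carry a reason")


@dataclass(frozen=True)
class GroupTestResult:
    """Omnibus rank test plus pairwise post hoc results."""

    h: float
    df: int
    p: float
    n_total: int
    pairwise: tuple  # of PairwiseResult
    adjustment: str = "holm"

    def __post_init__(self):
        if self.h < 0:
            raise ValueError("H must be >= 0")
        if not 0 <= self.p <= 1:
            raise ValueError("p out of [0, 1]")


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool


def _rate(x) -> float:
    return x.v0 if isinstance(x, RateEstimate) else float(x)


def fraction_retained(live, killed, enzyme: str = "", enzyme_class: str = "",
                      depth_mbsf: float = float("nan"),
                      dl: float = 0.0, exclusion_k: float = 3.0
                      ) -> RetentionRecord:
    """Percent of live activity retained in the killed control.

    The pair is excluded when the live rate is below ``exclusion_k * dl``
    (too close to the detection limit for the ratio to be meaningful) or
    non-positive.
    """
    v_live, v_killed = _rate(live), _rate(killed)
    if v_live <= 0:
        return RetentionRecord(enzyme, enzyme_class, depth_mbsf, float("nan"),
                               excluded=True, reason="live rate <= 0")
    if v_live < exclusion_k * dl:
        return RetentionRecord(enzyme, enzyme_class, depth_mbsf, float("nan"),
                               excluded=True,
                               reason=f"live rate below {exclusion_k}x detection limit")
    return RetentionRecord(enzyme, enzyme_class, depth_mbsf,
                           100.0 * max(v_killed, 0.0) / v_live)


def summarize_retention(records, by: str = "all") -> pd.DataFrame:
    """Median and IQR of retained fractions, grouped by nothing, enzyme
    class, or enzyme.

    Quantiles use the linear-interpolation convention (numpy default),
    recorded in the ``quantile_method`` column. Groups left empty after
    exclusions are omitted with a warning.
    """
    rows = [r for r in records if not r.excluded]
    if not rows:
        raise ValueError("no non-excluded records to summarize")
    df = pd.DataFrame([{"enzyme": r.enzyme, "enzyme_class": r.enzyme_class,
                        "fraction_pct": r.fraction_pct} for r in rows])
    if by == "all":
        groups = [("all", df)]
    elif by == "class":
        groups = list(df.groupby("enzyme_class"))
    elif by == "enzyme":
        groups = list(df.groupby("enzyme"))
    else:
        raise ValueError(f"unknown grouping {by!r}")
    out = []
    for name, g in groups:
        f = g["fraction_pct"].to_numpy()
        q25, q50, q75 = np.quantile(f, [0.25, 0.5, 0.75])  # linear interpolation
        out.append({"group": name, "n": int(f.size), "median_pct": float(q50),
                    "iqr_low_pct": float(q25), "iqr_high_pct": float(q75),
                    "quantile_method": "linear"})
    return pd.DataFrame(out)


def kruskal_wallis(groups: dict) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H across >= 2 groups.

    Returns (H, df, p) with p from the chi-square approximation on k-1
    degrees of freedom. All values identical across all groups gives
    H = 0, p = 1 instead of an error.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs >= 1 value")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need total N >= 3")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), df, float(p)


def conover_iman(groups: dict, h: float | None = None,
                 adjust: str = "holm", alpha: float = 0.05
                 ) -> GroupTestResult:
    """Conover–Iman pairwise comparisons after a Kruskal–Wallis omnibus.

    For groups i, j with mean ranks R̄_i, R̄_j over the pooled ranking of N
    values in k groups:

        t_ij = (R̄_i - R̄_j) / sqrt(S² · (N-1-H)/(N-k) · (1/n_i + 1/n_j))

    with S² the pooled (tie-aware) rank variance
    (Σ r² - N(N+1)²/4)/(N-1), two-sided p from Student's t on N-k df.
    """
    names = list(groups.keys())
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    k = len(arrays)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if h is None:
        h, _, _ = kruskal_wallis(groups)
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrays]
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    mean_ranks = [r.mean() for r in split]
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1)
    dof = n_total - k
    scale = (n_total - 1.0 - h) / dof if dof > 0 else np.nan

    raw = []
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        denom2 = s2 * scale * (1.0 / sizes[i] + 1.0 / sizes[j])
        if denom2 <= 0 or not np.isfinite(denom2):
            t, p = 0.0, 1.0  # all pairs tied / degenerate pooled variance
        else:
            t = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(denom2)
            p = float(2 * stats.t.sf(abs(t), dof))
        raw.append((a, b, float(t), min(p, 1.0)))

    if adjust not in ("holm", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    p_adj = _holm([r[3] for r in raw]) if adjust == "holm" else [r[3] for r in raw]
    pairwise = tuple(
        PairwiseResult(a, b, t, p, pa, bool(pa < alpha))
        for (a, b, t, p), pa in zip(raw, p_adj))
    _, df_omni, p_omni = kruskal_wallis(groups)
    return GroupTestResult(h=float(h), df=df_omni, p=p_omni, n_total=n_total,
                           pairwise=pairwise, adjustment=adjust)


def _holm(pvals) -> list[float]:
    """Holm step-down adjustment."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()
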