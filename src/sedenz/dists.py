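"""Distribution specifications for Monte-Carlo inputs.

Literature compilations of enzyme specific activities span orders of
magnitude, so log-scale families are first-class here: a spec is one of

* ``point(value)`` — a degenerate point mass,
* ``log-uniform(lo, hi)`` — uniform in log space between positive bounds,
* ``log-normal(mu, sigma)`` — ``exp(Normal(mu, sigma))``.

The median of log-uniform(lo, hi) is the geometric mean sqrt(lo*hi), and the
median of log-normal(mu, sigma) is exp(mu); both are used as analytic oracles
for Monte-Carlo medians of monotone transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DistSpec:
    """A validated distribution specification.

    Parameters
    ----------
    kind : {"point", "log-uniform", "log-normal"}
    params : tuple of float
        ``(value,)``, ``(lo, hi)`` or ``(mu, sigma)`` respectively.
    """

    kind: str
    params: tuple

    def __post_init__(self):
        k, p = self.kind, self.params
        if k == "point":
            if len(p) != 1:
                raise ValueError("point takes one parameter")
        elif k == "log-uniform":
            if len(p) != 2:
                raise ValueError("log-uniform takes (lo, hi)")
            lo, hi = p
            if lo <= 0 or hi <= 0:
                raise ValueError("log-uniform bounds must be positive")
            if hi < lo:
                raise ValueError("log-uniform requires lo <= hi")
        elif k == "log-normal":
            if len(p) != 2:
                raise ValueError("log-normal takes (mu, sigma)")
            if p[1] < 0:
                raise ValueError("log-normal sigma must be >= 0")
        else:
            raise ValueError(f"unknown distribution kind: {k!r}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values; reproducible through the supplied generator."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if self.kind == "point":
            return np.full(n, float(self.params[0]))
        if self.kind == "log-uniform":
            lo, hi = self.params
            return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        mu, sigma = self.params
        return np.exp(rng.normal(mu, sigma, size=n))

    def median(self) -> float:
        """Analytic median of the distribution."""
        if self.kind == "point":
            return float(self.params[0])
        if self.kind == "log-uniform":
            lo, hi = self.params
            return float(np.sqrt(lo * hi))
        return float(np.exp(self.params[0]))

    @property
    def is_point(self) -> bool:
        return self.kind == "point"


def point(value: float) -> DistSpec:
    return DistSpec("point", (float(value),))


def log_uniform(lo: float, hi: float) -> DistSpec:
    return DistSpec("log-uniform", (float(lo), float(hi)))


def log_normal(mu: float, sigma: float) -> DistSpec:
    return DistSpec("log-normal", (float(mu), float(sigma)))


def parse_dist(spec) -> DistSpec:
    """Parse a distribution from a DistSpec, mapping, or ``[kind, *params]``
    list as found in config files."""
    if isinstance(spec, DistSpec):
        return spec
    if isinstance(spec, dict):
        return DistSpec(spec["kind"], tuple(float(x) for x in spec["params"]))
    if isinstance(spec, (list, tuple)) and spec:
        return DistSpec(str(spec[0]), tuple(float(x) for x in spec[1:]))
    if isinstance(spec, (int, float)):
        return point(spec)
    raise ValueError(f"cannot parse distribution spec: {spec!r}")
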