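"""Small declarative distribution specs used by the synthetic-log generator.

A :class:`DistSpec` is a serialisable description of a one-dimensional
distribution (family name + parameters) that can be sampled from a
``numpy.random.Generator``.  Waiting times are parameterised by their
*median* in weeks so that profile files read directly against the medians
a service would report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

_FAMILIES = ("lognormal", "fixed", "uniform", "exponential", "poisson_shifted")


@dataclass(frozen=True)
class DistSpec:
    """Declarative spec for a scalar distribution.

    Parameters by family:

    - ``lognormal``: ``median`` (> 0) and ``sigma`` (log-scale SD);
      right-skewed, the default family for waiting times.
    - ``fixed``: ``value`` — a point mass.
    - ``uniform``: ``low`` and ``high``.
    - ``exponential``: ``mean``.
    - ``poisson_shifted``: ``lam`` and integer ``shift`` — counts
      ``shift + Poisson(lam)`` (e.g. number of sessions, at least 1).
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        p = self.params
        if self.family == "lognormal":
            if p.get("median", 0) <= 0 or p.get("sigma", 0) <= 0:
                raise ValueError("lognormal requires median > 0 and sigma > 0")
        elif self.family == "fixed":
            if "value" not in p:
                raise ValueError("fixed requires a value")
        elif self.family == "uniform":
            if p.get("high", -math.inf) < p.get("low", math.inf):
                raise ValueError("uniform requires low <= high")
        elif self.family == "exponential":
            if p.get("mean", 0) <= 0:
                raise ValueError("exponential requires mean > 0")
        elif self.family == "poisson_shifted":
            if p.get("lam", -1) < 0:
                raise ValueError("poisson_shifted requires lam >= 0")

    @property
    def median(self) -> float:
        """Theoretical median of the distribution."""
        p = self.params
        if self.family == "lognormal":
            return float(p["median"])
        if self.family == "fixed":
            return float(p["value"])
        if self.family == "uniform":
            return (float(p["low"]) + float(p["high"])) / 2.0
        if self.family == "exponential":
            return float(p["mean"]) * math.log(2.0)
        # poisson_shifted: no closed form needed here
        return float(p.get("shift", 0)) + float(p["lam"])

    def sample(self, rng: np.random.Generator, size: int | None = None):
        p = self.params
        if self.family == "lognormal":
            return rng.lognormal(math.log(p["median"]), p["sigma"], size)
        if self.family == "fixed":
            v = float(p["value"])
            return v if size is None else np.full(size, v)
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size)
        if self.family == "exponential":
            return rng.exponential(p["mean"], size)
        if self.family == "poisson_shifted":
            return int(p.get("shift", 0)) + rng.poisson(p["lam"], size)
        raise AssertionError(self.family)

    def to_dict(self) -> dict:
        return {"family": self.family, **{k: float(v) for k, v in self.params.items()}}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistSpec":
        d = dict(d)
        family = d.pop("family")
        return cls(family=family, params=d)
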