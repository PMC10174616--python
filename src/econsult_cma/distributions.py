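"""Parametric uncertainty distributions attached to model inputs.

Each model input carries a :class:`DistributionSpec` describing its
second-order uncertainty: beta for transition probabilities, gamma
(shape/rate) for times and attendance costs, normal for staff rates and
the attendance-cost scale variable, lognormal as a configurable
alternative for time inputs, and ``point`` for inputs held fixed.

The gamma family uses the shape/rate convention throughout: a
``gamma(alpha, rate)`` has analytic mean ``alpha / rate`` and standard
deviation ``sqrt(alpha) / rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DomainError

FAMILIES = ("beta", "gamma", "normal", "lognormal", "point")

_REQUIRED_PARAMS = {
    "beta": ("alpha", "beta"),
    "gamma": ("alpha", "rate"),
    "normal": ("mu", "sigma"),
    "lognormal": ("mu_log", "sigma_log"),
    "point": ("value",),
}


@dataclass(frozen=True)
class DistributionSpec:
    """A validated distribution family plus its parameters.

    Parameters
    ----------
    family:
        One of ``beta``, ``gamma``, ``normal``, ``lognormal``, ``point``.
    params:
        Family-specific parameters; see ``_REQUIRED_PARAMS`` for the
        expected keys.
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {FAMILIES}"
            )
        required = _REQUIRED_PARAMS[self.family]
        missing = [k for k in required if k not in self.params]
        if missing:
            raise ConfigurationError(
                f"{self.family} distribution missing parameter(s): {missing}"
            )
        object.__setattr__(
            self, "params", {k: float(self.params[k]) for k in required}
        )
        p = self.params
        if self.family == "beta" and (p["alpha"] <= 0 or p["beta"] <= 0):
            raise DomainError(
                f"beta parameters must be > 0, got alpha={p['alpha']}, "
                f"beta={p['beta']}"
            )
        if self.family == "gamma" and (p["alpha"] <= 0 or p["rate"] <= 0):
            raise DomainError(
                f"gamma shape and rate must be > 0, got alpha={p['alpha']}, "
                f"rate={p['rate']}"
            )
        if self.family == "normal" and p["sigma"] < 0:
            raise DomainError(f"normal sigma must be >= 0, got {p['sigma']}")
        if self.family == "lognormal" and p["sigma_log"] < 0:
            raise DomainError(
                f"lognormal sigma_log must be >= 0, got {p['sigma_log']}"
            )

    # -- analytic moments -------------------------------------------------

    @property
    def mean(self) -> float:
        p = self.params
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "gamma":
            return p["alpha"] / p["rate"]
        if self.family == "normal":
            return p["mu"]
        if self.family == "lognormal":
            return math.exp(p["mu_log"] + p["sigma_log"] ** 2 / 2.0)
        return p["value"]

    @property
    def sd(self) -> float:
        p = self.params
        if self.family == "beta":
            a, b = p["alpha"], p["beta"]
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        if self.family == "gamma":
            return math.sqrt(p["alpha"]) / p["rate"]
        if self.family == "normal":
            return p["sigma"]
        if self.family == "lognormal":
            s2 = p["sigma_log"] ** 2
            return self.mean * math.sqrt(math.expm1(s2))
        return 0.0

    # -- sampling and quantiles -------------------------------------------

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the distribution with the supplied generator.

        The ``point`` family returns its value unconditionally, so a
        degenerate input never consumes random state differently from a
        stochastic one being replaced.
        """
        p = self.params
        if self.family == "beta":
            return rng.beta(p["alpha"], p["beta"], size)
        if self.family == "gamma":
            return rng.gamma(p["alpha"], 1.0 / p["rate"], size)
        if self.family == "normal":
            return rng.normal(p["mu"], p["sigma"], size)
        if self.family == "lognormal":
            return rng.lognormal(p["mu_log"], p["sigma_log"], size)
        value = p["value"]
        return value if size is None else np.full(size, value)

    def ppf(self, q: float) -> float:
        """Quantile function; used for one-way sensitivity bounds."""
        p = self.params
        if self.family == "beta":
            return float(stats.beta.ppf(q, p["alpha"], p["beta"]))
        if self.family == "gamma":
            return float(stats.gamma.ppf(q, p["alpha"], scale=1.0 / p["rate"]))
        if self.family == "normal":
            return float(stats.norm.ppf(q, loc=p["mu"], scale=p["sigma"]))
        if self.family == "lognormal":
            return float(
                stats.lognorm.ppf(
                    q, p["sigma_log"], scale=math.exp(p["mu_log"])
                )
            )
        return p["value"]

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        return cls(family=d["family"], params=dict(d["params"]))


def point(value: float) -> DistributionSpec:
    """Degenerate distribution concentrated at ``value``."""
    return DistributionSpec("point", {"value": value})


def lognormal_from_moments(mean: float, sd: float) -> DistributionSpec:
    """Lognormal with the given arithmetic mean and standard deviation.

    Provided as the configurable alternative family for time inputs; the
    default parameterisation of times is gamma (see
    :func:`econsult_cma.parameters.fit_gamma_by_moments`).
    """
    if mean <= 0:
        raise DomainError(f"lognormal mean must be > 0, got {mean}")
    if sd < 0:
        raise DomainError(f"sd must be >= 0, got {sd}")
    if sd == 0:
        return point(mean)
    sigma2 = math.log1p((sd / mean) ** 2)
    return DistributionSpec(
        "lognormal",
        {"mu_log": math.log(mean) - sigma2 / 2.0, "sigma_log": math.sqrt(sigma2)},
    )
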