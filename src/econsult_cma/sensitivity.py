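"""Uncertainty analysis: one-way (tornado), threshold, and Monte Carlo.

Three complementary views of parameter uncertainty around the base-case
incremental cost (traditional minus eConsult, so positive values favour
the eConsult service):

* **one-way / tornado** — each input in turn is moved to a low and a
  high bound (default: the 2.5th/97.5th percentiles of its uncertainty
  distribution) while all others stay at base case; inputs are ranked
  by the induced span in the incremental cost;
* **threshold** — root-finding on a single input (by default the scale
  variable on the post-eConsult attendance cost) for the value at which
  the incremental cost is zero, i.e. the conclusion would flip;
* **probabilistic (PSA)** — all inputs drawn jointly and independently
  from their distributions for ``n_draws`` Monte Carlo iterations, the
  tree rolled back per draw, and decision uncertainty summarised as the
  fraction of draws in which eConsult costs less.

Sampling uses one seed with a per-parameter substream keyed by a stable
hash of the parameter id, so draws for one parameter do not depend on
how many other parameters exist or the order they are listed in.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distributions import DistributionSpec
from .errors import ConfigurationError, DomainError
from .parameters import Parameter, ParameterTable
from .tree import DecisionTree, rollback

__all__ = [
    "sample",
    "draw_parameter_values",
    "one_way_sa",
    "tornado",
    "threshold_scale",
    "run_psa",
    "TornadoEntry",
    "ThresholdResult",
    "PSAResult",
    "DEFAULT_BOUNDS_QUANTILES",
]

DEFAULT_BOUNDS_QUANTILES = (0.025, 0.975)


def sample(dist: DistributionSpec, rng: np.random.Generator, size: int | None = None):
    """Draw from a distribution spec (thin wrapper over the spec itself)."""
    if not isinstance(dist, DistributionSpec):
        raise ConfigurationError(f"expected a DistributionSpec, got {dist!r}")
    return dist.sample(rng, size)


def _substream(seed: int, pid: str) -> np.random.Generator:
    # stable 32-bit key per parameter id -> adding or reordering parameters
    # never perturbs another parameter's draws
    key = int.from_bytes(
        hashlib.blake2s(pid.encode("utf-8"), digest_size=4).digest(), "big"
    )
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _domain_enforce(param: Parameter, draws: np.ndarray) -> tuple[np.ndarray, int]:
    """Clip draws to the parameter's domain; return (draws, #clipped)."""
    if param.role == "probability":
        clipped = np.clip(draws, 0.0, 1.0)
    else:  # times, costs, rates and the scale variable cannot be negative
        clipped = np.maximum(draws, 0.0)
    return clipped, int(np.count_nonzero(clipped != draws))


def draw_parameter_values(
    table: ParameterTable, n_draws: int, seed: int
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Joint independent draws for every parameter, domain-enforced.

    Returns the draws keyed by parameter id and the per-parameter count
    of draws that had to be clipped to the domain (e.g. negative
    normal draws of the scale variable floored at zero).
    """
    if n_draws < 1:
        raise DomainError(f"n_draws must be >= 1, got {n_draws}")
    values: dict[str, np.ndarray] = {}
    n_clipped: dict[str, int] = {}
    for param in table:
        draws = param.distribution.sample(_substream(seed, param.id), n_draws)
        values[param.id], clipped = _domain_enforce(param, np.asarray(draws, dtype=float))
        if clipped:
            n_clipped[param.id] = clipped
    return values, n_clipped


# ---------------------------------------------------------------------------
# One-way sensitivity analysis


@dataclass(frozen=True)
class TornadoEntry:
    parameter_id: str
    low_input: float
    high_input: float
    incremental_at_low: float
    incremental_at_high: float
    warnings: tuple[str, ...] = ()

    @property
    def span(self) -> float:
        return abs(self.incremental_at_high - self.incremental_at_low)

    def to_dict(self) -> dict:
        return {
            "parameter_id": self.parameter_id,
            "low_input": self.low_input,
            "high_input": self.high_input,
            "incremental_at_low": self.incremental_at_low,
            "incremental_at_high": self.incremental_at_high,
            "span": self.span,
            "warnings": "; ".join(self.warnings),
        }


def _clip_to_domain(param: Parameter, value: float) -> tuple[float, str | None]:
    lo, hi = (0.0, 1.0) if param.role == "probability" else (0.0, np.inf)
    if value < lo or value > hi:
        clipped = float(min(max(value, lo), hi))
        return clipped, (
            f"{param.id}: bound {value:.6g} outside domain [{lo:.6g}, {hi:.6g}], "
            f"clipped to {clipped:.6g}"
        )
    return float(value), None


def one_way_sa(
    tree: DecisionTree,
    parameter_id: str,
    bounds: tuple[float, float] | None = None,
    quantiles: tuple[float, float] = DEFAULT_BOUNDS_QUANTILES,
) -> TornadoEntry:
    """Incremental cost at a low and high value of one input.

    All other inputs stay at base case. ``bounds`` overrides the default
    quantile policy; bounds outside the parameter's domain are clipped
    and the clipping recorded.
    """
    param = tree.parameter_table[parameter_id]
    if bounds is None:
        bounds = (param.distribution.ppf(quantiles[0]), param.distribution.ppf(quantiles[1]))
    warnings = []
    clipped_bounds = []
    for b in bounds:
        v, warning = _clip_to_domain(param, b)
        clipped_bounds.append(v)
        if warning:
            warnings.append(warning)
    base = tree.parameter_table.base_values()
    incs = []
    for v in clipped_bounds:
        values = dict(base)
        values[parameter_id] = v
        incs.append(rollback(tree, values).incremental)
    return TornadoEntry(
        parameter_id=parameter_id,
        low_input=clipped_bounds[0],
        high_input=clipped_bounds[1],
        incremental_at_low=float(incs[0]),
        incremental_at_high=float(incs[1]),
        warnings=tuple(warnings),
    )


def tornado(
    tree: DecisionTree,
    parameter_ids: Sequence[str] | None = None,
    quantiles: tuple[float, float] = DEFAULT_BOUNDS_QUANTILES,
) -> list[TornadoEntry]:
    """One-way analysis over many inputs, sorted by descending span.

    Ties break on parameter id so the ordering is reproducible and
    independent of the order the inputs were listed in.
    """
    if parameter_ids is None:
        parameter_ids = tree.parameter_table.ids
    if not parameter_ids:
        raise ConfigurationError("tornado needs at least one parameter id")
    entries = [one_way_sa(tree, pid, quantiles=quantiles) for pid in parameter_ids]
    return sorted(entries, key=lambda e: (-e.span, e.parameter_id))


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    """Plot-ready tornado table (one row per input, widest span first)."""
    return pd.DataFrame([e.to_dict() for e in entries])


# ---------------------------------------------------------------------------
# Threshold analysis


@dataclass(frozen=True)
class ThresholdResult:
    parameter_id: str
    critical_value: float
    achieved_incremental: float
    closed_form_value: float | None
    bracket: tuple[float, float]
    tolerance: float

    def to_dict(self) -> dict:
        return {
            "parameter_id": self.parameter_id,
            "critical_value": self.critical_value,
            "achieved_incremental": self.achieved_incremental,
            "closed_form_value": self.closed_form_value,
            "bracket": list(self.bracket),
            "tolerance": self.tolerance,
        }


def _bisect(f, lo: float, hi: float, ftol: float) -> float:
    """Bisection run until the function value itself is below ``ftol``
    (or the bracket collapses to floating-point resolution)."""
    flo, fhi = f(lo), f(hi)
    if abs(flo) <= ftol:
        return lo
    if abs(fhi) <= ftol:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fmid = f(mid)
        if abs(fmid) <= ftol or hi - lo <= 4 * np.finfo(float).eps * max(1.0, abs(mid)):
            return mid
        if (flo < 0) != (fmid < 0):
            hi, fhi = mid, fmid
        else:
            lo, flo = mid, fmid
    return 0.5 * (lo + hi)


def threshold_scale(
    tree: DecisionTree,
    parameter_id: str = "attendance_scale",
    bracket: tuple[float, float] = (0.0, 20.0),
    tolerance: float = 1e-6,
) -> ThresholdResult:
    """Value of one input at which the incremental cost is zero.

    Solved by bisection to ``tolerance`` and, when the model is linear
    in the input (it is in the scale variable), cross-checked against
    the closed form from two evaluations; the two must agree within the
    tolerance or the result is rejected.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise DomainError(f"degenerate bracket [{lo}, {hi}]")
    base = tree.parameter_table.base_values()

    def f(x: float) -> float:
        values = dict(base)
        values[parameter_id] = x
        return float(rollback(tree, values).incremental)

    f_lo, f_hi = f(lo), f(hi)
    # linearity probe at three points
    mid = 0.5 * (lo + hi)
    f_mid = f(mid)
    scale = max(abs(f_lo), abs(f_hi), 1.0)
    linear = abs(f_mid - 0.5 * (f_lo + f_hi)) <= 1e-9 * scale
    closed_form = None
    if linear and f_hi != f_lo:
        slope = (f_hi - f_lo) / (hi - lo)
        closed_form = lo - f_lo / slope

    if f_lo == 0.0 or f_hi == 0.0 or (f_lo < 0) != (f_hi < 0):
        critical = _bisect(f, lo, hi, tolerance)
    elif closed_form is not None:
        critical = closed_form
    else:
        raise DomainError(
            f"incremental cost does not change sign over [{lo}, {hi}] and the "
            f"model is not linear in {parameter_id!r}; widen the bracket"
        )
    if closed_form is not None and abs(critical - closed_form) > max(
        tolerance, 1e-9 * abs(closed_form)
    ):
        raise DomainError(
            f"bisection ({critical}) and closed form ({closed_form}) disagree "
            f"beyond tolerance for {parameter_id!r}"
        )
    return ThresholdResult(
        parameter_id=parameter_id,
        critical_value=float(critical),
        achieved_incremental=f(float(critical)),
        closed_form_value=closed_form,
        bracket=(lo, hi),
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAResult:
    """Per-draw arm costs with decision-uncertainty summaries."""

    n_draws: int
    seed: int
    cost_econsult: np.ndarray
    cost_traditional: np.ndarray
    n_clipped: dict[str, int] = field(default_factory=dict)

    @property
    def incremental(self) -> np.ndarray:
        return self.cost_traditional - self.cost_econsult

    @property
    def fraction_econsult_cheaper(self) -> float:
        return float(np.mean(self.incremental > 0.0))

    def summary(self) -> dict:
        inc = self.incremental
        lo, hi = np.percentile(inc, [2.5, 97.5])
        return {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "fraction_econsult_cheaper": self.fraction_econsult_cheaper,
            "incremental_mean": float(inc.mean()),
            "incremental_p2.5": float(lo),
            "incremental_p97.5": float(hi),
            "mean_cost_econsult": float(self.cost_econsult.mean()),
            "mean_cost_traditional": float(self.cost_traditional.mean()),
            "n_clipped": dict(self.n_clipped),
        }

    def to_frame(self) -> pd.DataFrame:
        """One row per draw, CSV-ready (histogram / cost-plane input)."""
        return pd.DataFrame(
            {
                "seed": self.seed,
                "draw": np.arange(self.n_draws),
                "cost_econsult": self.cost_econsult,
                "cost_traditional": self.cost_traditional,
                "incremental": self.incremental,
            }
        )


def run_psa(tree: DecisionTree, n_draws: int = 10_000, seed: int = 0) -> PSAResult:
    """Monte Carlo rollback of the tree under joint parameter uncertainty.

    Every parameter is drawn independently from its distribution (one
    substream per parameter id), draws are clipped to their domains with
    the clip counts reported, and the tree is rolled back per draw.
    Identical seed, identical result.
    """
    values, n_clipped = draw_parameter_values(tree.parameter_table, n_draws, seed)
    result = rollback(tree, values)
    return PSAResult(
        n_draws=n_draws,
        seed=seed,
        cost_econsult=np.asarray(result.cost_econsult, dtype=float),
        cost_traditional=np.asarray(result.cost_traditional, dtype=float),
        n_clipped=n_clipped,
    )
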