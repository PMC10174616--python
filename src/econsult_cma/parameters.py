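"""Model inputs: estimation from activity records and the parameter table.

The cost-minimisation model is driven by a table of named inputs, each
with a base-case value and an uncertainty distribution:

* transition probabilities — estimated from binomial counts, with
  ``beta(successes, failures)`` uncertainty whose analytic mean equals
  the observed proportion;
* handling times and attendance costs — positive quantities with gamma
  uncertainty fitted by moment matching;
* staff rates — per-minute labour costs (salary plus a 30% oncost
  markup) with normal uncertainty, standard deviation taken as 10% of
  the mean;
* the attendance-cost scale variable — a multiplier on the cost of a
  face-to-face attendance that follows an eConsult, 1.0 in the base
  case with normal(1, 0.25) uncertainty.

This module turns raw activity records (an RFA log, an outpatient
attendance extract, a duration audit and staff rates) into such a table,
and ships the published base-case table as a packaged fixture.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .distributions import DistributionSpec, point
from .errors import (
    ConfigurationError,
    DomainError,
    EmptyStratumError,
    UnresolvedParameterError,
)

ROLES = ("probability", "time", "rate", "cost", "scale")

#: Every id the two-arm decision model references.
REQUIRED_PARAMETER_IDS = (
    "p_new_patient",
    "p_dna",
    "p_subsequent_f2f_new",
    "p_subsequent_f2f_review",
    "p_f2f_new",
    "p_f2f_review",
    "p_video_new",
    "p_video_review",
    "t_admin_new",
    "t_admin_review",
    "t_specialist_new_f2f",
    "t_specialist_review_f2f",
    "t_specialist_new_no_f2f",
    "t_specialist_review_no_f2f",
    "rate_admin",
    "rate_specialist",
    "c_f2f_new",
    "c_f2f_review",
    "c_video_new",
    "c_video_review",
    "c_telephone_new",
    "c_telephone_review",
    "attendance_scale",
)


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class CountEstimate:
    """A binomial count pair: ``successes`` out of ``successes + failures``."""

    successes: int
    failures: int

    def __post_init__(self):
        if self.successes < 0 or self.failures < 0:
            raise DomainError("counts must be non-negative")
        if self.successes + self.failures == 0:
            raise EmptyStratumError("count estimate with zero total")

    @property
    def point(self) -> float:
        return self.successes / (self.successes + self.failures)


@dataclass(frozen=True)
class MomentSummary:
    """Sample mean, standard deviation (n-1 denominator) and size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.mean <= 0:
            raise DomainError(f"mean must be > 0, got {self.mean}")
        if self.sd < 0:
            raise DomainError(f"sd must be >= 0, got {self.sd}")
        if self.n < 1:
            raise DomainError(f"n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class StaffRate:
    """Per-minute labour cost for a staff role, oncosts included."""

    role: str
    cost_per_minute: float
    oncost_fraction: float = 0.30

    def __post_init__(self):
        if self.cost_per_minute <= 0:
            raise DomainError("cost_per_minute must be > 0")
        if self.oncost_fraction < 0:
            raise DomainError("oncost_fraction must be >= 0")


@dataclass(frozen=True)
class Parameter:
    """One named model input: base-case value plus uncertainty."""

    id: str
    label: str
    base_value: float
    units: str
    distribution: DistributionSpec
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConfigurationError(
                f"unknown parameter role {self.role!r}; expected one of {ROLES}"
            )
        if self.role == "probability" and not (0.0 <= self.base_value <= 1.0):
            raise DomainError(
                f"probability parameter {self.id!r} has base value "
                f"{self.base_value} outside [0, 1]"
            )
        if self.role in ("time", "cost", "rate") and self.base_value < 0:
            raise DomainError(
                f"{self.role} parameter {self.id!r} has negative base value "
                f"{self.base_value}"
            )

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "label": self.label,
            "base": self.base_value,
            "units": self.units,
            "role": self.role,
            **self.distribution.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Parameter":
        return cls(
            id=d["id"],
            label=d.get("label", d["id"]),
            base_value=float(d["base"]),
            units=d.get("units", ""),
            distribution=DistributionSpec(d["family"], dict(d["params"])),
            role=d["role"],
        )


class ParameterTable:
    """An ordered, validated mapping of parameter id to :class:`Parameter`."""

    def __init__(self, parameters: Iterable[Parameter]):
        self._entries: dict[str, Parameter] = {}
        for p in parameters:
            if p.id in self._entries:
                raise ConfigurationError(f"duplicate parameter id {p.id!r}")
            self._entries[p.id] = p

    def __getitem__(self, pid: str) -> Parameter:
        try:
            return self._entries[pid]
        except KeyError:
            raise UnresolvedParameterError(pid) from None

    def __contains__(self, pid: str) -> bool:
        return pid in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def base_values(self) -> dict[str, float]:
        return {pid: p.base_value for pid, p in self._entries.items()}

    def require(self, ids: Sequence[str] = REQUIRED_PARAMETER_IDS) -> None:
        missing = [pid for pid in ids if pid not in self._entries]
        if missing:
            raise UnresolvedParameterError(missing)

    def replace(self, parameter: Parameter) -> "ParameterTable":
        """Return a copy with one parameter replaced (or added)."""
        entries = dict(self._entries)
        entries[parameter.id] = parameter
        return ParameterTable(entries.values())

    def with_base_value(self, pid: str, value: float) -> "ParameterTable":
        return self.replace(replace(self[pid], base_value=value))

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {"parameters": [p.to_dict() for p in self]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterTable":
        try:
            rows = d["parameters"]
        except (KeyError, TypeError):
            raise ConfigurationError(
                "parameter config must contain a top-level 'parameters' list"
            ) from None
        params = []
        for i, row in enumerate(rows):
            try:
                params.append(Parameter.from_dict(row))
            except (KeyError, TypeError) as exc:
                raise ConfigurationError(
                    f"malformed parameter entry at index {i}: {exc}"
                ) from exc
        return cls(params)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_base_case() -> ParameterTable:
    """Load the packaged base-case parameter table (23 inputs)."""
    ref = importlib.resources.files("econsult_cma") / "data" / "base_case.yaml"
    table = ParameterTable.from_dict(yaml.safe_load(ref.read_text()))
    table.require()
    return table


# ---------------------------------------------------------------------------
# Estimation operations


def estimate_probability(
    successes: int,
    failures: int,
    *,
    id: str = "p",
    label: str | None = None,
) -> Parameter:
    """Probability parameter from a binomial count pair.

    The base value is the observed proportion and the uncertainty is
    ``beta(successes, failures)``, whose analytic mean equals the base
    value exactly. A stratum in which either count is zero has no valid
    beta distribution and is rejected rather than clamped.
    """
    ce = CountEstimate(successes, failures)  # raises on zero total
    dist = DistributionSpec(
        "beta", {"alpha": float(successes), "beta": float(failures)}
    )
    return Parameter(
        id=id,
        label=label or id,
        base_value=ce.point,
        units="proportion",
        distribution=dist,
        role="probability",
    )


def fit_gamma_by_moments(summary: MomentSummary) -> DistributionSpec:
    """Gamma (shape/rate) matching a sample mean and standard deviation.

    ``alpha = (mean/sd)^2`` and ``rate = mean/sd^2``, so the analytic
    mean ``alpha/rate`` and sd ``sqrt(alpha)/rate`` reproduce the
    inputs. A zero sd degenerates to a point mass at the mean.
    """
    if summary.sd == 0:
        return point(summary.mean)
    alpha = (summary.mean / summary.sd) ** 2
    rate = summary.mean / summary.sd**2
    return DistributionSpec("gamma", {"alpha": alpha, "rate": rate})


def derive_staff_rate(
    base_salary_per_minute: float,
    oncost_fraction: float = 0.30,
    sd_fraction: float = 0.10,
    *,
    role: str = "specialist",
    id: str | None = None,
) -> Parameter:
    """Staff-rate parameter: salary plus oncost markup, normal uncertainty.

    The final per-minute cost is ``salary x (1 + oncost_fraction)``; its
    uncertainty is normal with sigma equal to ``sd_fraction`` of the
    mean (a zero sd_fraction degenerates to a point mass).
    """
    if base_salary_per_minute < 0 or oncost_fraction < 0 or sd_fraction < 0:
        raise DomainError("salary, oncost and sd fractions must be non-negative")
    cost = base_salary_per_minute * (1.0 + oncost_fraction)
    if sd_fraction == 0:
        dist = point(cost)
    else:
        dist = DistributionSpec(
            "normal", {"mu": cost, "sigma": sd_fraction * cost}
        )
    return Parameter(
        id=id or f"rate_{role}",
        label=f"Cost for {role} staff",
        base_value=cost,
        units="AUD/min",
        distribution=dist,
        role="rate",
    )


def compute_duration_scale(audited: MomentSummary, funded_minutes: float) -> float:
    """Ratio of audited consultation length to the funded appointment slot.

    Managerial costing assigns attendance costs assuming a fixed slot
    length; when audited consultations run longer, face-to-face costs
    are scaled up by this ratio. Reported truncated to 2 decimals (the
    convention used for the published 41/30 factor).
    """
    if funded_minutes <= 0:
        raise DomainError("funded_minutes must be > 0")
    ratio = audited.mean / funded_minutes
    return math.floor(ratio * 100.0 + 1e-9) / 100.0


def summarize(values: Sequence[float] | np.ndarray) -> MomentSummary:
    """Moment summary of a sample; sd uses the n-1 denominator."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptyStratumError("moment summary of empty sample")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return MomentSummary(mean=float(arr.mean()), sd=sd, n=int(arr.size))


def estimate_time_statistics(
    rfa_log: pd.DataFrame,
    new_review: str,
    subsequent_f2f: bool,
) -> MomentSummary:
    """Per-stratum moments of logged specialist minutes.

    Strata are the cross of patient type (new/review) and whether the
    eConsult led to a subsequent face-to-face attendance.
    """
    mask = (rfa_log["new_review"] == new_review) & (
        rfa_log["subsequent_f2f"].astype(bool) == subsequent_f2f
    )
    sel = rfa_log.loc[mask, "minutes"]
    if sel.empty:
        raise EmptyStratumError(
            f"rfa_log stratum new_review={new_review!r}, "
            f"subsequent_f2f={subsequent_f2f}"
        )
    return summarize(sel.to_numpy())


def build_parameter_table(
    parameters: Iterable[Parameter],
    required: Sequence[str] = REQUIRED_PARAMETER_IDS,
) -> ParameterTable:
    """Assemble and validate a complete parameter table.

    Missing required ids and duplicates are rejected; per-parameter
    domain invariants are enforced by :class:`Parameter` itself.
    """
    table = ParameterTable(parameters)
    table.require(required)
    return table


# ---------------------------------------------------------------------------
# Consistency validation


@dataclass(frozen=True)
class ConsistencyFlag:
    parameter_id: str
    kind: str
    message: str


def gamma_consistency_report(
    table: ParameterTable, tolerance: float = 0.02
) -> list[ConsistencyFlag]:
    """Flag gamma rows whose analytic mean disagrees with the base value.

    A moment-matched gamma has mean equal to the base-case value; rows
    supplied from external sources can disagree (the published table's
    specialist-time rows do). Disagreement beyond ``tolerance``
    (relative) is surfaced, never silently corrected: the base value
    continues to drive the base case while the stated gamma drives the
    probabilistic analysis.
    """
    flags = []
    for p in table:
        if p.distribution.family != "gamma" or p.base_value == 0:
            continue
        rel = abs(p.distribution.mean - p.base_value) / p.base_value
        if rel > tolerance:
            flags.append(
                ConsistencyFlag(
                    parameter_id=p.id,
                    kind="gamma_mean_mismatch",
                    message=(
                        f"gamma mean {p.distribution.mean:.4g} differs from "
                        f"base value {p.base_value:.4g} by {rel:.1%}"
                    ),
                )
            )
    return flags


def make_self_consistent(table: ParameterTable) -> ParameterTable:
    """Re-derive every gamma distribution from its base value and stated sd.

    Returns a table in which each gamma row is moment-matched to
    ``(base_value, sd of the original gamma)``, so analytic means agree
    with base values exactly. Used as the ground truth for synthetic
    data generation.
    """
    out = []
    for p in table:
        if p.distribution.family == "gamma":
            dist = fit_gamma_by_moments(
                MomentSummary(mean=p.base_value, sd=p.distribution.sd, n=1)
            )
            p = replace(p, distribution=dist)
        out.append(p)
    return ParameterTable(out)


# ---------------------------------------------------------------------------
# Raw record readers (CSV dialects shared with the synthetic generator)

RFA_LOG_COLUMNS = ("patient_type", "new_review", "minutes", "subsequent_f2f")
ATTENDANCE_COLUMNS = ("episode_type", "modality", "cost", "attended")
AUDIT_COLUMNS = ("minutes",)
RATES_COLUMNS = ("role", "per_minute", "oncost_fraction")

MODALITIES = ("face_to_face", "video", "telephone")


def _read_csv(path, columns: Sequence[str], name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ConfigurationError(f"cannot read {name} CSV {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{name} CSV {path} missing column(s): {missing}"
        )
    return df


def read_rfa_log(path) -> pd.DataFrame:
    return _read_csv(path, RFA_LOG_COLUMNS, "rfa_log")


def read_attendances(path) -> pd.DataFrame:
    df = _read_csv(path, ATTENDANCE_COLUMNS, "attendances")
    bad = set(df["modality"].unique()) - set(MODALITIES)
    if bad:
        raise ConfigurationError(
            f"attendances CSV {path} has unknown modality value(s): {sorted(bad)}"
        )
    return df


def read_audit(path) -> pd.DataFrame:
    return _read_csv(path, AUDIT_COLUMNS, "audit")


def read_rates(path) -> pd.DataFrame:
    return _read_csv(path, RATES_COLUMNS, "rates")


# ---------------------------------------------------------------------------
# End-to-end estimation from records

_STRATA = ("new", "review")


@dataclass
class EstimationResult:
    """A re-estimated parameter table plus its validation report."""

    table: ParameterTable
    flags: list[ConsistencyFlag] = field(default_factory=list)
    duration_scale: float | None = None


def estimate_parameters(
    rfa_log: pd.DataFrame,
    attendances: pd.DataFrame,
    audit: pd.DataFrame | None = None,
    rates: pd.DataFrame | None = None,
    defaults: ParameterTable | None = None,
    funded_minutes: float = 30.0,
) -> EstimationResult:
    """Re-estimate the full parameter table from raw activity records.

    Transition probabilities come from binomial counts in the RFA log
    and the attendance extract; specialist times and attendance costs
    are gamma-fitted by moments per stratum; staff rates gain the oncost
    markup and 10%-of-mean normal uncertainty. Inputs that activity
    records do not carry (administration handling times, the
    attendance-cost scale variable) are taken from ``defaults`` (the
    packaged base case when omitted). The audit, when given, yields the
    face-to-face duration scale factor, reported for inspection; the
    attendance extract's costs are used as recorded.
    """
    defaults = defaults or load_base_case()
    params: dict[str, Parameter] = {}

    def _prob_from_counts(k: int, rest: int, pid: str, label: str, what: str) -> Parameter:
        # a zero cell has no valid beta distribution; surface it as the
        # empty stratum it reflects rather than a bare domain error
        if k == 0 or rest == 0:
            raise EmptyStratumError(what)
        return estimate_probability(k, rest, id=pid, label=label)

    # -- RFA log: case mix, subsequent-F2F probabilities, specialist times
    n_new = int((rfa_log["new_review"] == "new").sum())
    n_review = int((rfa_log["new_review"] == "review").sum())
    params["p_new_patient"] = _prob_from_counts(
        n_new,
        n_review,
        "p_new_patient",
        "New patient (case mix)",
        "rfa_log new/review case mix",
    )
    for stratum in _STRATA:
        sub = rfa_log[rfa_log["new_review"] == stratum]
        if sub.empty:
            raise EmptyStratumError(f"rfa_log stratum new_review={stratum!r}")
        k = int(sub["subsequent_f2f"].astype(bool).sum())
        params[f"p_subsequent_f2f_{stratum}"] = _prob_from_counts(
            k,
            len(sub) - k,
            f"p_subsequent_f2f_{stratum}",
            f"Subsequent face-to-face attendance, {stratum}",
            f"rfa_log subsequent-F2F outcomes, stratum {stratum!r}",
        )
        for subsequent, suffix in ((True, "f2f"), (False, "no_f2f")):
            pid = f"t_specialist_{stratum}_{suffix}"
            summary = estimate_time_statistics(rfa_log, stratum, subsequent)
            params[pid] = Parameter(
                id=pid,
                label=f"Specialist eConsult time, {stratum}, "
                + ("subsequent F2F" if subsequent else "no subsequent F2F"),
                base_value=summary.mean,
                units="min",
                distribution=fit_gamma_by_moments(summary),
                role="time",
            )

    # -- attendance extract: modality probabilities, DNA, attendance costs
    for stratum in _STRATA:
        sub = attendances[attendances["episode_type"] == stratum]
        if sub.empty:
            raise EmptyStratumError(f"attendances stratum episode_type={stratum!r}")
        f2f = sub[sub["modality"] == "face_to_face"]
        non_f2f = sub[sub["modality"] != "face_to_face"]
        params[f"p_f2f_{stratum}"] = _prob_from_counts(
            len(f2f),
            len(non_f2f),
            f"p_f2f_{stratum}",
            f"Face-to-face attendance, {stratum}",
            f"attendances face-to-face outcomes, stratum {stratum!r}",
        )
        n_video = int((non_f2f["modality"] == "video").sum())
        params[f"p_video_{stratum}"] = _prob_from_counts(
            n_video,
            len(non_f2f) - n_video,
            f"p_video_{stratum}",
            f"Video attendance given not face-to-face, {stratum}",
            f"attendances video/telephone outcomes, stratum {stratum!r}",
        )
        for modality, tag in (
            ("face_to_face", "f2f"),
            ("video", "video"),
            ("telephone", "telephone"),
        ):
            pid = f"c_{tag}_{stratum}"
            rows = sub[sub["modality"] == modality]
            if rows.empty:
                raise EmptyStratumError(
                    f"attendances stratum episode_type={stratum!r}, "
                    f"modality={modality!r}"
                )
            summary = summarize(rows["cost"].to_numpy())
            params[pid] = Parameter(
                id=pid,
                label=f"Outpatient {modality} cost, {stratum}",
                base_value=summary.mean,
                units="AUD",
                distribution=fit_gamma_by_moments(summary),
                role="cost",
            )

    # DNA probability among scheduled face-to-face attendances, pooled
    f2f_all = attendances[attendances["modality"] == "face_to_face"]
    n_dna = int((~f2f_all["attended"].astype(bool)).sum())
    n_attended = len(f2f_all) - n_dna
    if n_dna > 0 and n_attended > 0:
        params["p_dna"] = estimate_probability(
            n_dna, n_attended, id="p_dna", label="DNA, face-to-face attendances"
        )
    else:
        params["p_dna"] = defaults["p_dna"]

    # -- staff rates
    if rates is not None:
        for row in rates.itertuples():
            params[f"rate_{row.role}"] = derive_staff_rate(
                float(row.per_minute),
                float(row.oncost_fraction),
                role=str(row.role),
            )

    # -- everything the records cannot supply comes from the defaults
    for pid in REQUIRED_PARAMETER_IDS:
        if pid not in params:
            params[pid] = defaults[pid]

    table = build_parameter_table(params.values())
    scale = None
    if audit is not None and len(audit):
        scale = compute_duration_scale(
            summarize(audit["minutes"].to_numpy()), funded_minutes
        )
    return EstimationResult(
        table=table, flags=gamma_consistency_report(table), duration_scale=scale
    )
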