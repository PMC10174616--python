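"""Synthetic activity records with the model's distributional structure.

Generates the four raw inputs the estimation pipeline reads — an RFA
log, an outpatient attendance extract, a consultation-duration audit and
staff rates — from a known ground-truth parameter table:

* patient strata by Bernoulli draws on the case-mix probability (review
  eConsult patients arise at their true few-percent rate, so the
  tiny-stratum behaviour of real logs is exercised);
* subsequent-F2F, modality and attended flags by Bernoulli draws on the
  corresponding true probabilities;
* specialist minutes, attendance costs and audited durations from the
  per-stratum gamma distributions (drawn per record, so gamma
  re-fitting is exercised, not just means);
* staff rate rows as the pre-oncost salary consistent with the truth.

The ground truth travels in a JSON sidecar for test harnesses; the
estimation pipeline itself never reads it. What the generator does not
emulate: referral wait times, triage categories, arrival processes, or
any correlation between a patient's time and cost records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .parameters import (
    MomentSummary,
    ParameterTable,
    EstimationResult,
    estimate_parameters,
    fit_gamma_by_moments,
    load_base_case,
    make_self_consistent,
)
from .tree import StructureVariant, CANONICAL, build_base_case_tree, rollback

#: Default audited duration of a new face-to-face consultation (minutes);
#: the funded appointment slot is 30 minutes.
DEFAULT_AUDIT_MEAN = 41.0
DEFAULT_AUDIT_SD = 14.7
DEFAULT_ONCOST = 0.30


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth and sample sizes for one synthetic dataset."""

    truth: ParameterTable
    n_econsult: int = 1000
    n_traditional: int = 1000
    n_audit: int = 94
    seed: int = 0
    audit_mean: float = DEFAULT_AUDIT_MEAN
    audit_sd: float = DEFAULT_AUDIT_SD

    def __post_init__(self):
        if min(self.n_econsult, self.n_traditional, self.n_audit) < 0:
            raise ConfigurationError("sample sizes must be non-negative")
        if self.audit_mean <= 0 or self.audit_sd < 0:
            raise ConfigurationError("audit moments must be positive / non-negative")


def default_config(**overrides) -> GeneratorConfig:
    """Config whose truth is the packaged base case with gamma rows
    re-derived from their base values (so recovery is unbiased)."""
    truth = overrides.pop("truth", make_self_consistent(load_base_case()))
    return GeneratorConfig(truth=truth, **overrides)


@dataclass(frozen=True)
class SyntheticDataset:
    rfa_log: pd.DataFrame
    attendances: pd.DataFrame
    audit: pd.DataFrame
    rates: pd.DataFrame
    truth: ParameterTable

    def write(self, directory) -> dict[str, Path]:
        """Write the CSV files plus the ground-truth JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("rfa_log", self.rfa_log),
            ("attendances", self.attendances),
            ("audit", self.audit),
            ("rates", self.rates),
        ):
            paths[name] = directory / f"{name}.csv"
            df.to_csv(paths[name], index=False)
        paths["truth"] = directory / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth.to_dict(), fh, indent=2)
        return paths


def _bernoulli(rng: np.random.Generator, p: float, n: int) -> np.ndarray:
    return rng.random(n) < p


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Generate one dataset; identical config (incl. seed) → identical data."""
    t = config.truth
    rng = np.random.default_rng(config.seed)
    base = t.base_values()

    # -- RFA log ----------------------------------------------------------
    n = config.n_econsult
    is_new = _bernoulli(rng, base["p_new_patient"], n)
    stratum = np.where(is_new, "new", "review")
    p_sub = np.where(
        is_new, base["p_subsequent_f2f_new"], base["p_subsequent_f2f_review"]
    )
    subsequent = rng.random(n) < p_sub
    minutes = np.empty(n)
    for s, flag, suffix in (
        ("new", True, "f2f"),
        ("new", False, "no_f2f"),
        ("review", True, "f2f"),
        ("review", False, "no_f2f"),
    ):
        mask = (stratum == s) & (subsequent == flag)
        if mask.any():
            dist = t[f"t_specialist_{s}_{suffix}"].distribution
            minutes[mask] = dist.sample(rng, int(mask.sum()))
    rfa_log = pd.DataFrame(
        {
            "patient_type": [f"P{i:06d}" for i in range(n)],
            "new_review": stratum,
            "minutes": np.round(minutes, 2),
            "subsequent_f2f": subsequent.astype(int),
        }
    )

    # -- attendance extract ----------------------------------------------
    m = config.n_traditional
    is_new_a = _bernoulli(rng, base["p_new_patient"], m)
    stratum_a = np.where(is_new_a, "new", "review")
    p_f2f = np.where(is_new_a, base["p_f2f_new"], base["p_f2f_review"])
    f2f = rng.random(m) < p_f2f
    p_video = np.where(is_new_a, base["p_video_new"], base["p_video_review"])
    video = (~f2f) & (rng.random(m) < p_video)
    modality = np.where(f2f, "face_to_face", np.where(video, "video", "telephone"))
    cost = np.empty(m)
    for s in ("new", "review"):
        for mod, tag in (
            ("face_to_face", "f2f"),
            ("video", "video"),
            ("telephone", "telephone"),
        ):
            mask = (stratum_a == s) & (modality == mod)
            if mask.any():
                dist = t[f"c_{tag}_{s}"].distribution
                cost[mask] = dist.sample(rng, int(mask.sum()))
    attended = np.where(f2f, rng.random(m) >= base["p_dna"], True)
    attendances = pd.DataFrame(
        {
            "episode_type": stratum_a,
            "modality": modality,
            "cost": np.round(cost, 2),
            "attended": attended.astype(int),
        }
    )

    # -- duration audit ---------------------------------------------------
    audit_dist = fit_gamma_by_moments(
        MomentSummary(mean=config.audit_mean, sd=config.audit_sd, n=1)
    )
    audit = pd.DataFrame(
        {"minutes": np.round(audit_dist.sample(rng, config.n_audit), 1)}
    )

    # -- staff rates (pre-oncost salary consistent with the truth) --------
    rates = pd.DataFrame(
        {
            "role": ["admin", "specialist"],
            "per_minute": [
                base["rate_admin"] / (1.0 + DEFAULT_ONCOST),
                base["rate_specialist"] / (1.0 + DEFAULT_ONCOST),
            ],
            "oncost_fraction": [DEFAULT_ONCOST, DEFAULT_ONCOST],
        }
    )
    return SyntheticDataset(
        rfa_log=rfa_log,
        attendances=attendances,
        audit=audit,
        rates=rates,
        truth=t,
    )


# ---------------------------------------------------------------------------
# End-to-end recovery


@dataclass(frozen=True)
class RecoveryReport:
    """Truth vs recovered: parameters and the rolled-back incremental."""

    truth_incremental: float
    recovered_incremental: float
    parameters: pd.DataFrame  # id, role, truth, recovered
    estimation: EstimationResult = field(repr=False)

    @property
    def relative_error(self) -> float:
        return abs(self.recovered_incremental - self.truth_incremental) / abs(
            self.truth_incremental
        )


def round_trip_check(
    config: GeneratorConfig, variant: StructureVariant = CANONICAL
) -> RecoveryReport:
    """Generate records, re-estimate every parameter, roll both tables back.

    Inputs that activity records do not carry (administration times, the
    scale variable) are filled from the truth table, mirroring how a real
    re-estimation would source them from configuration rather than logs.
    Empty strata raise, so undersized samples fail loudly.
    """
    ds = generate(config)
    est = estimate_parameters(
        ds.rfa_log, ds.attendances, ds.audit, ds.rates, defaults=config.truth
    )
    truth_rb = rollback(build_base_case_tree(config.truth, variant))
    rec_rb = rollback(build_base_case_tree(est.table, variant))
    rows = [
        {
            "id": p.id,
            "role": p.role,
            "truth": config.truth[p.id].base_value,
            "recovered": p.base_value,
        }
        for p in est.table
        if p.id in config.truth
    ]
    return RecoveryReport(
        truth_incremental=truth_rb.incremental,
        recovered_incremental=rec_rb.incremental,
        parameters=pd.DataFrame(rows),
        estimation=est,
    )
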