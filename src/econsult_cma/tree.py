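"""Two-arm decision tree and probability-weighted rollback.

The model compares two ways of handling the same referral population:

* **eConsult arm** — every request costs administration plus specialist
  handling time (stratum-specific); a fraction of patients subsequently
  needs a face-to-face outpatient attendance, costed at the traditional
  face-to-face attendance cost times the scale variable;
* **traditional arm** — every referral becomes an outpatient attendance,
  face-to-face or (conditionally on not face-to-face) video or
  telephone, each with its own stratum-specific cost.

Both arms branch first on the shared new/review case mix. Scheduled
face-to-face appointments the patient misses (DNA) are costed equal to
attended ones under the hospital's opportunity-cost rule, which makes
the DNA chance nodes payoff-equal; a gross-up variant that rebooks
missed appointments is provided as a documented alternative.

Rollback computes each arm's expected cost per patient as the sum over
root-to-leaf paths of the product of branch probabilities times the
terminal cost. All evaluation broadcasts over numpy arrays, so the same
code serves the deterministic base case and the Monte Carlo analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .errors import ConfigurationError, DomainError, UnresolvedParameterError
from .parameters import ParameterTable, Parameter, estimate_probability

Number = Union[float, np.ndarray]

_PROB_TOL = 1e-9


# ---------------------------------------------------------------------------
# Branch probabilities


@dataclass(frozen=True)
class BranchProb:
    """A branch probability reference.

    ``param`` evaluates to the named parameter, ``complement`` to one
    minus it, and ``residual`` to one minus the sum of the other
    branches of the same chance node (at most one per node).
    """

    kind: str
    pid: str | None = None

    def __post_init__(self):
        if self.kind not in ("param", "complement", "residual"):
            raise ConfigurationError(f"unknown branch-probability kind {self.kind!r}")
        if self.kind != "residual" and not self.pid:
            raise ConfigurationError(f"{self.kind} branch probability needs a parameter id")

    def to_dict(self) -> dict:
        return {"kind": self.kind, **({"pid": self.pid} if self.pid else {})}

    @classmethod
    def from_dict(cls, d: Mapping) -> "BranchProb":
        return cls(kind=d["kind"], pid=d.get("pid"))


def ref(pid: str) -> BranchProb:
    return BranchProb("param", pid)


def complement(pid: str) -> BranchProb:
    return BranchProb("complement", pid)


def residual() -> BranchProb:
    return BranchProb("residual")


# ---------------------------------------------------------------------------
# Cost expressions


@dataclass(frozen=True)
class AttendanceTerm:
    """One attendance-cost term: cost, optionally scaled and grossed up.

    ``scale_id`` multiplies the cost (the post-eConsult scale variable);
    ``dna_id`` divides it by one minus the DNA probability, modelling
    rebooking of missed appointments (gross-up variant only).
    """

    cost_id: str
    scale_id: str | None = None
    dna_id: str | None = None


@dataclass(frozen=True)
class CostExpression:
    """Linear combination of time x rate products and attendance costs."""

    time_terms: tuple[tuple[str, str], ...] = ()
    attendance_terms: tuple[AttendanceTerm, ...] = ()

    def referenced_ids(self) -> set[str]:
        ids = set()
        for tid, rid in self.time_terms:
            ids.update((tid, rid))
        for term in self.attendance_terms:
            ids.add(term.cost_id)
            if term.scale_id:
                ids.add(term.scale_id)
            if term.dna_id:
                ids.add(term.dna_id)
        return ids

    def evaluate(self, values: Mapping[str, Number]) -> Number:
        total: Number = 0.0
        for tid, rid in self.time_terms:
            total = total + values[tid] * values[rid]
        for term in self.attendance_terms:
            cost = values[term.cost_id]
            if term.scale_id is not None:
                cost = cost * values[term.scale_id]
            if term.dna_id is not None:
                cost = cost / (1.0 - values[term.dna_id])
            total = total + cost
        if np.ndim(total) == 0 and total < 0:
            raise DomainError(f"cost expression evaluated to negative value {total}")
        return total

    def to_dict(self) -> dict:
        return {
            "time_terms": [list(t) for t in self.time_terms],
            "attendance_terms": [
                {
                    "cost_id": t.cost_id,
                    "scale_id": t.scale_id,
                    "dna_id": t.dna_id,
                }
                for t in self.attendance_terms
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CostExpression":
        return cls(
            time_terms=tuple((t[0], t[1]) for t in d.get("time_terms", ())),
            attendance_terms=tuple(
                AttendanceTerm(
                    cost_id=t["cost_id"],
                    scale_id=t.get("scale_id"),
                    dna_id=t.get("dna_id"),
                )
                for t in d.get("attendance_terms", ())
            ),
        )


# ---------------------------------------------------------------------------
# Nodes


@dataclass(frozen=True)
class TerminalNode:
    label: str
    cost: CostExpression

    def to_dict(self) -> dict:
        return {"type": "terminal", "label": self.label, "cost": self.cost.to_dict()}


@dataclass(frozen=True)
class ChanceNode:
    label: str
    branches: tuple[tuple[BranchProb, "Node"], ...]

    def __post_init__(self):
        n_residual = sum(1 for p, _ in self.branches if p.kind == "residual")
        if n_residual > 1:
            raise ConfigurationError(
                f"chance node {self.label!r} has more than one residual branch"
            )

    def branch_probabilities(self, values: Mapping[str, Number]) -> list[Number]:
        probs: list[Number] = []
        explicit: Number = 0.0
        for bp, _ in self.branches:
            if bp.kind == "param":
                p = values[bp.pid]
            elif bp.kind == "complement":
                p = 1.0 - values[bp.pid]
            else:
                p = None  # filled below
            probs.append(p)
            if p is not None:
                explicit = explicit + p
        return [1.0 - explicit if p is None else p for p in probs]

    def to_dict(self) -> dict:
        return {
            "type": "chance",
            "label": self.label,
            "branches": [
                {"probability": bp.to_dict(), "child": _node_to_dict(child)}
                for bp, child in self.branches
            ],
        }


Node = Union[TerminalNode, ChanceNode]


def _node_to_dict(node: Node) -> dict:
    return node.to_dict()


def node_from_dict(d: Mapping) -> Node:
    if d["type"] == "terminal":
        return TerminalNode(label=d["label"], cost=CostExpression.from_dict(d["cost"]))
    if d["type"] == "chance":
        return ChanceNode(
            label=d["label"],
            branches=tuple(
                (BranchProb.from_dict(b["probability"]), node_from_dict(b["child"]))
                for b in d["branches"]
            ),
        )
    raise ConfigurationError(f"unknown node type {d.get('type')!r}")


def referenced_ids(node: Node) -> set[str]:
    if isinstance(node, TerminalNode):
        return node.cost.referenced_ids()
    ids = set()
    for bp, child in node.branches:
        if bp.pid:
            ids.add(bp.pid)
        ids.update(referenced_ids(child))
    return ids


# ---------------------------------------------------------------------------
# Structure variants


@dataclass(frozen=True)
class StructureVariant:
    """Documented structural choices the published description leaves open.

    dna:
        ``payoff_equal`` (default) — missed face-to-face appointments
        cost the same as attended ones, modelled as explicit chance
        nodes with equal payoffs; ``gross_up`` — missed appointments are
        rebooked, multiplying face-to-face costs by 1/(1-p_DNA);
        ``omit`` — no DNA nodes (equivalent to payoff_equal by
        construction).
    case_mix:
        ``shared`` (default) — both arms use the eConsult service's
        96.2% new-patient mix, modelling the same referral population;
        ``observed_traditional`` — the traditional arm uses the mix
        observed in the outpatient extract instead.
    modality_split:
        ``conditional`` (default) — the video probability is
        conditional on the attendance not being face-to-face;
        ``unconditional`` — face-to-face, video and telephone split at
        a single three-way node.
    """

    dna: str = "payoff_equal"
    case_mix: str = "shared"
    modality_split: str = "conditional"

    _DNA = ("payoff_equal", "gross_up", "omit")
    _CASE_MIX = ("shared", "observed_traditional")
    _MODALITY = ("conditional", "unconditional")

    def __post_init__(self):
        if self.dna not in self._DNA:
            raise ConfigurationError(f"unknown dna variant {self.dna!r}; expected one of {self._DNA}")
        if self.case_mix not in self._CASE_MIX:
            raise ConfigurationError(
                f"unknown case_mix variant {self.case_mix!r}; expected one of {self._CASE_MIX}"
            )
        if self.modality_split not in self._MODALITY:
            raise ConfigurationError(
                f"unknown modality_split variant {self.modality_split!r}; "
                f"expected one of {self._MODALITY}"
            )

    @property
    def name(self) -> str:
        return f"dna={self.dna},case_mix={self.case_mix},modality={self.modality_split}"

    @classmethod
    def all_variants(cls) -> list["StructureVariant"]:
        return [
            cls(dna=d, case_mix=c, modality_split=m)
            for d in cls._DNA
            for c in cls._CASE_MIX
            for m in cls._MODALITY
        ]


CANONICAL = StructureVariant()

#: Counts of new vs review attendances observed in the outpatient extract,
#: used only by the ``observed_traditional`` case-mix variant.
OBSERVED_TRADITIONAL_MIX = (136, 351)


# ---------------------------------------------------------------------------
# The decision tree


@dataclass(frozen=True)
class RollbackResult:
    cost_econsult: float
    cost_traditional: float
    incremental: float = field(init=False, default=0.0)
    efficiency_fraction: float = field(init=False, default=0.0)

    def __post_init__(self):
        inc = self.cost_traditional - self.cost_econsult
        object.__setattr__(self, "incremental", inc)
        with np.errstate(divide="ignore", invalid="ignore"):
            eff = np.where(
                np.asarray(self.cost_traditional) > 0,
                inc / self.cost_traditional,
                np.nan,
            )
        object.__setattr__(
            self, "efficiency_fraction", float(eff) if np.ndim(eff) == 0 else eff
        )

    def to_dict(self) -> dict:
        return {
            "cost_econsult": float(self.cost_econsult),
            "cost_traditional": float(self.cost_traditional),
            "incremental": float(self.incremental),
            "efficiency_fraction": float(self.efficiency_fraction),
        }


@dataclass(frozen=True)
class DecisionTree:
    econsult: Node
    traditional: Node
    parameter_table: ParameterTable
    variant: StructureVariant = CANONICAL

    def __post_init__(self):
        missing = (
            referenced_ids(self.econsult) | referenced_ids(self.traditional)
        ) - set(self.parameter_table.ids)
        if missing:
            raise UnresolvedParameterError(missing)

    @property
    def arms(self) -> dict[str, Node]:
        return {"econsult": self.econsult, "traditional": self.traditional}

    def to_dict(self) -> dict:
        return {
            "variant": {
                "dna": self.variant.dna,
                "case_mix": self.variant.case_mix,
                "modality_split": self.variant.modality_split,
            },
            "arms": {
                "econsult": _node_to_dict(self.econsult),
                "traditional": _node_to_dict(self.traditional),
            },
            "parameters": self.parameter_table.to_dict()["parameters"],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "DecisionTree":
        return cls(
            econsult=node_from_dict(d["arms"]["econsult"]),
            traditional=node_from_dict(d["arms"]["traditional"]),
            parameter_table=ParameterTable.from_dict({"parameters": d["parameters"]}),
            variant=StructureVariant(**d.get("variant", {})),
        )

    @classmethod
    def from_json(cls, path) -> "DecisionTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Construction


def _dna_wrap(label: str, cost: CostExpression, variant: StructureVariant) -> Node:
    """Attach DNA handling to a face-to-face terminal cost."""
    if variant.dna == "payoff_equal":
        return ChanceNode(
            label=f"{label}: attends?",
            branches=(
                (complement("p_dna"), TerminalNode(f"{label}/attended", cost)),
                (ref("p_dna"), TerminalNode(f"{label}/dna", cost)),
            ),
        )
    if variant.dna == "gross_up":
        grossed = CostExpression(
            time_terms=cost.time_terms,
            attendance_terms=tuple(
                AttendanceTerm(t.cost_id, t.scale_id, "p_dna")
                for t in cost.attendance_terms
            ),
        )
        return TerminalNode(label, grossed)
    return TerminalNode(label, cost)


def _econsult_stratum(stratum: str, variant: StructureVariant) -> Node:
    admin = f"t_admin_{stratum}"
    subsequent_cost = CostExpression(
        time_terms=((admin, "rate_admin"), (f"t_specialist_{stratum}_f2f", "rate_specialist")),
        attendance_terms=(AttendanceTerm(f"c_f2f_{stratum}", scale_id="attendance_scale"),),
    )
    no_subsequent_cost = CostExpression(
        time_terms=((admin, "rate_admin"), (f"t_specialist_{stratum}_no_f2f", "rate_specialist")),
    )
    return ChanceNode(
        label=f"econsult/{stratum}: subsequent F2F?",
        branches=(
            (
                ref(f"p_subsequent_f2f_{stratum}"),
                _dna_wrap(f"econsult/{stratum}/subsequent_f2f", subsequent_cost, variant),
            ),
            (
                complement(f"p_subsequent_f2f_{stratum}"),
                TerminalNode(f"econsult/{stratum}/no_subsequent_f2f", no_subsequent_cost),
            ),
        ),
    )


def _attendance_terminal(stratum: str, modality_tag: str) -> TerminalNode:
    return TerminalNode(
        f"traditional/{stratum}/{modality_tag}",
        CostExpression(attendance_terms=(AttendanceTerm(f"c_{modality_tag}_{stratum}"),)),
    )


def _traditional_stratum(stratum: str, variant: StructureVariant) -> Node:
    f2f_cost = CostExpression(attendance_terms=(AttendanceTerm(f"c_f2f_{stratum}"),))
    f2f_node = _dna_wrap(f"traditional/{stratum}/f2f", f2f_cost, variant)
    video = _attendance_terminal(stratum, "video")
    telephone = _attendance_terminal(stratum, "telephone")
    if variant.modality_split == "conditional":
        non_f2f = ChanceNode(
            label=f"traditional/{stratum}: video or telephone?",
            branches=(
                (ref(f"p_video_{stratum}"), video),
                (complement(f"p_video_{stratum}"), telephone),
            ),
        )
        return ChanceNode(
            label=f"traditional/{stratum}: face-to-face?",
            branches=(
                (ref(f"p_f2f_{stratum}"), f2f_node),
                (complement(f"p_f2f_{stratum}"), non_f2f),
            ),
        )
    return ChanceNode(
        label=f"traditional/{stratum}: modality",
        branches=(
            (ref(f"p_f2f_{stratum}"), f2f_node),
            (ref(f"p_video_{stratum}"), video),
            (residual(), telephone),
        ),
    )


def build_base_case_tree(
    params: ParameterTable, variant: StructureVariant = CANONICAL
) -> DecisionTree:
    """Build the canonical two-arm tree (or a documented variant) over
    a complete parameter table."""
    if not isinstance(variant, StructureVariant):
        raise ConfigurationError(f"variant must be a StructureVariant, got {variant!r}")
    params.require()

    econ = ChanceNode(
        label="econsult: new or review?",
        branches=(
            (ref("p_new_patient"), _econsult_stratum("new", variant)),
            (complement("p_new_patient"), _econsult_stratum("review", variant)),
        ),
    )
    if variant.case_mix == "observed_traditional":
        if "p_new_traditional" not in params:
            n_new, n_review = OBSERVED_TRADITIONAL_MIX
            params = params.replace(
                estimate_probability(
                    n_new,
                    n_review,
                    id="p_new_traditional",
                    label="New patient mix observed in the outpatient extract",
                )
            )
        mix: BranchProb = ref("p_new_traditional")
        mix_c: BranchProb = complement("p_new_traditional")
    else:
        mix, mix_c = ref("p_new_patient"), complement("p_new_patient")
    trad = ChanceNode(
        label="traditional: new or review?",
        branches=(
            (mix, _traditional_stratum("new", variant)),
            (mix_c, _traditional_stratum("review", variant)),
        ),
    )
    return DecisionTree(econsult=econ, traditional=trad, parameter_table=params, variant=variant)


# ---------------------------------------------------------------------------
# Rollback


def _expected(node: Node, values: Mapping[str, Number], check: bool) -> Number:
    if isinstance(node, TerminalNode):
        return node.cost.evaluate(values)
    probs = node.branch_probabilities(values)
    if check:
        total = 0.0
        for p in probs:
            if not (-_PROB_TOL <= p <= 1.0 + _PROB_TOL):
                raise DomainError(
                    f"branch probability {p} outside [0, 1] at node {node.label!r}"
                )
            total += p
        if abs(total - 1.0) > _PROB_TOL:
            raise DomainError(
                f"branch probabilities at node {node.label!r} sum to {total}, not 1"
            )
    out: Number = 0.0
    for p, (_, child) in zip(probs, node.branches):
        out = out + p * _expected(child, values, check)
    return out


def expected_cost(node: Node, values: Mapping[str, Number], check: bool = True) -> Number:
    """Expected cost of one arm under the given parameter values."""
    return _expected(node, values, check)


def rollback(
    tree: DecisionTree, values: Mapping[str, Number] | None = None
) -> RollbackResult:
    """Roll the tree back: expected cost per arm, incremental, efficiency.

    ``values`` defaults to the table's base-case values; arrays
    broadcast, in which case domain checking is skipped (the Monte Carlo
    driver enforces domains before calling).
    """
    if values is None:
        values = tree.parameter_table.base_values()
    check = all(np.ndim(v) == 0 for v in values.values())
    return RollbackResult(
        cost_econsult=expected_cost(tree.econsult, values, check),
        cost_traditional=expected_cost(tree.traditional, values, check),
    )


def evaluate_cost_expression(expr: CostExpression, values: Mapping[str, Number]) -> Number:
    """Evaluate a terminal cost expression against parameter values."""
    return expr.evaluate(values)


# ---------------------------------------------------------------------------
# Path enumeration (inspection / reporting)


@dataclass(frozen=True)
class PathContribution:
    leaf_label: str
    probability: float
    cost: float

    @property
    def contribution(self) -> float:
        return self.probability * self.cost


def enumerate_paths(
    node: Node, values: Mapping[str, float], _prob: float = 1.0
) -> list[PathContribution]:
    """All root-to-leaf paths of one arm with their probabilities and costs."""
    if isinstance(node, TerminalNode):
        return [
            PathContribution(
                leaf_label=node.label,
                probability=float(_prob),
                cost=float(node.cost.evaluate(values)),
            )
        ]
    out: list[PathContribution] = []
    for p, (_, child) in zip(node.branch_probabilities(values), node.branches):
        out.extend(enumerate_paths(child, values, _prob * float(p)))
    return out


def prune_degenerate(node: Node, values: Mapping[str, float]) -> Node:
    """Drop zero-probability branches and collapse single-branch nodes.

    Purely cosmetic for reporting: pruning must not change any
    expectation (tested).
    """
    if isinstance(node, TerminalNode):
        return node
    kept = [
        (bp, prune_degenerate(child, values))
        for p, (bp, child) in zip(node.branch_probabilities(values), node.branches)
        if abs(float(p)) > 0.0
    ]
    if len(kept) == 1 and kept[0][0].kind != "residual":
        # a certain branch: the chance node is vacuous
        bp, child = kept[0]
        probs = ChanceNode(node.label, ((bp, child),)).branch_probabilities(values)
        if abs(float(probs[0]) - 1.0) <= _PROB_TOL:
            return child
    return ChanceNode(node.label, tuple(kept))
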