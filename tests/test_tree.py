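import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from econsult_cma import (
    AttendanceTerm,
    ChanceNode,
    ConfigurationError,
    CostExpression,
    DecisionTree,
    DomainError,
    Parameter,
    ParameterTable,
    StructureVariant,
    TerminalNode,
    UnresolvedParameterError,
    build_base_case_tree,
    complement,
    enumerate_paths,
    evaluate_cost_expression,
    expected_cost,
    point,
    prune_degenerate,
    ref,
    rollback,
)
from conftest import oracle_expected_cost

# Frozen output of the independent path-sum oracle on the packaged
# base case (each leaf's probability product times its cost, summed by
# hand before the rollback implementation existed).
ORACLE_COST_ECONSULT = 203.87391276
ORACLE_COST_TRADITIONAL = 554.43908240476


def _cost_param(pid, value):
    return Parameter(pid, pid, value, "AUD", point(value), "cost")


def _prob_param(pid, value):
    return Parameter(pid, pid, value, "proportion", point(value), "probability")


class TestToyTrees:
    def test_certain_branch_returns_terminal_cost(self):
        table = ParameterTable([_prob_param("p", 1.0), _cost_param("c", 123.0)])
        node = ChanceNode(
            "root",
            (
                (ref("p"), TerminalNode("hit", CostExpression(attendance_terms=(AttendanceTerm("c"),)))),
                (complement("p"), TerminalNode("miss", CostExpression())),
            ),
        )
        assert expected_cost(node, table.base_values()) == 123.0

    def test_even_split_averages_costs(self):
        values = {"p": 0.5, "lo": 100.0, "hi": 300.0}
        node = ChanceNode(
            "root",
            (
                (ref("p"), TerminalNode("lo", CostExpression(attendance_terms=(AttendanceTerm("lo"),)))),
                (complement("p"), TerminalNode("hi", CostExpression(attendance_terms=(AttendanceTerm("hi"),)))),
            ),
        )
        assert expected_cost(node, values) == 200.0

    def test_probability_outside_unit_interval_rejected(self):
        node = ChanceNode(
            "root",
            (
                (ref("p"), TerminalNode("a", CostExpression())),
                (complement("p"), TerminalNode("b", CostExpression())),
            ),
        )
        with pytest.raises(DomainError):
            expected_cost(node, {"p": 1.2})


class TestCostExpression:
    def test_time_times_rate(self):
        expr = CostExpression(time_terms=(("t_admin_new", "rate_admin"),))
        assert evaluate_cost_expression(expr, {"t_admin_new": 20.0, "rate_admin": 0.72}) == pytest.approx(14.40)

    def test_empty_expression_is_free(self):
        assert evaluate_cost_expression(CostExpression(), {}) == 0.0

    def test_scaled_attendance_at_unit_scale(self):
        expr = CostExpression(
            attendance_terms=(AttendanceTerm("c_f2f_new", scale_id="attendance_scale"),)
        )
        values = {"c_f2f_new": 638.50, "attendance_scale": 1.0}
        assert evaluate_cost_expression(expr, values) == pytest.approx(638.50)

    def test_negative_evaluation_rejected(self):
        expr = CostExpression(time_terms=(("t", "r"),))
        with pytest.raises(DomainError):
            evaluate_cost_expression(expr, {"t": -5.0, "r": 1.0})


class TestCanonicalTree:
    def test_structure_has_two_arms_and_enough_leaves(self, canonical_tree):
        values = canonical_tree.parameter_table.base_values()
        n_leaves = sum(
            len(enumerate_paths(arm, values)) for arm in canonical_tree.arms.values()
        )
        assert set(canonical_tree.arms) == {"econsult", "traditional"}
        assert n_leaves >= 10

    def test_rollback_matches_frozen_oracle_values(self, canonical_tree):
        rb = rollback(canonical_tree)
        assert rb.cost_econsult == pytest.approx(ORACLE_COST_ECONSULT, abs=1e-8)
        assert rb.cost_traditional == pytest.approx(ORACLE_COST_TRADITIONAL, abs=1e-8)
        assert rb.incremental == pytest.approx(
            ORACLE_COST_TRADITIONAL - ORACLE_COST_ECONSULT, abs=1e-8
        )
        assert rb.efficiency_fraction == pytest.approx(
            rb.incremental / rb.cost_traditional
        )

    def test_rollback_matches_live_path_enumeration(self, canonical_tree):
        values = canonical_tree.parameter_table.base_values()
        d = canonical_tree.to_dict()
        rb = rollback(canonical_tree)
        assert rb.cost_econsult == pytest.approx(
            oracle_expected_cost(d["arms"]["econsult"], values), rel=1e-12
        )
        assert rb.cost_traditional == pytest.approx(
            oracle_expected_cost(d["arms"]["traditional"], values), rel=1e-12
        )

    def test_econsult_arm_cheaper_at_base_case(self, canonical_tree):
        rb = rollback(canonical_tree)
        assert rb.cost_traditional > rb.cost_econsult

    def test_payoff_equal_dna_nodes_change_nothing(self, base_table):
        with_dna = rollback(build_base_case_tree(base_table, StructureVariant(dna="payoff_equal")))
        without = rollback(build_base_case_tree(base_table, StructureVariant(dna="omit")))
        assert with_dna.cost_econsult == without.cost_econsult
        assert with_dna.cost_traditional == without.cost_traditional

    def test_incremental_is_linear_in_the_scale_variable(self, canonical_tree):
        """Finite differences of the incremental cost with respect to the
        scale variable match the probability-weighted subsequent-attendance
        cost, at any evaluation point."""
        base = canonical_tree.parameter_table.base_values()
        analytic_slope = -(
            base["p_new_patient"] * base["p_subsequent_f2f_new"] * base["c_f2f_new"]
            + (1 - base["p_new_patient"])
            * base["p_subsequent_f2f_review"]
            * base["c_f2f_review"]
        )

        def inc_at(lam):
            values = dict(base)
            values["attendance_scale"] = lam
            return rollback(canonical_tree, values).incremental

        for lo, hi in [(0.0, 1.0), (1.0, 4.0), (2.5, 9.0)]:
            fd = (inc_at(hi) - inc_at(lo)) / (hi - lo)
            assert fd == pytest.approx(analytic_slope, rel=1e-9)

    def test_pruning_zero_probability_branches_keeps_expectation(self, base_table):
        table = base_table.with_base_value("p_video_new", 0.0)
        tree = build_base_case_tree(table)
        values = table.base_values()
        pruned = prune_degenerate(tree.traditional, values)
        assert expected_cost(pruned, values) == pytest.approx(
            expected_cost(tree.traditional, values), rel=1e-12
        )

    def test_unknown_variant_flag_rejected(self, base_table):
        with pytest.raises(ConfigurationError):
            StructureVariant(dna="ignore")
        with pytest.raises(ConfigurationError):
            build_base_case_tree(base_table, variant="canonical")

    def test_unresolved_reference_is_a_named_error(self, base_table):
        params = [p for p in base_table if p.id != "c_video_new"]
        with pytest.raises(UnresolvedParameterError, match="c_video_new"):
            build_base_case_tree(ParameterTable(params))

    def test_json_round_trip_preserves_rollback(self, canonical_tree, tmp_path):
        path = tmp_path / "tree.json"
        canonical_tree.to_json(path)
        again = DecisionTree.from_json(path)
        assert rollback(again).to_dict() == rollback(canonical_tree).to_dict()


class TestVariants:
    def test_observed_case_mix_only_changes_the_traditional_arm(self, base_table):
        rb_shared = rollback(build_base_case_tree(base_table))
        rb_obs = rollback(
            build_base_case_tree(base_table, StructureVariant(case_mix="observed_traditional"))
        )
        assert rb_obs.cost_econsult == pytest.approx(rb_shared.cost_econsult)
        # the outpatient extract is review-heavy, and review attendances
        # are cheaper, so the traditional arm must come out cheaper
        assert rb_obs.cost_traditional < rb_shared.cost_traditional

    def test_gross_up_raises_face_to_face_heavy_costs(self, base_table):
        rb = rollback(build_base_case_tree(base_table))
        rb_g = rollback(build_base_case_tree(base_table, StructureVariant(dna="gross_up")))
        assert rb_g.cost_traditional > rb.cost_traditional
        assert rb_g.cost_econsult > rb.cost_econsult

    def test_residual_modality_split_sums_to_one(self, base_table):
        tree = build_base_case_tree(base_table, StructureVariant(modality_split="unconditional"))
        values = tree.parameter_table.base_values()
        for arm in tree.arms.values():
            total = sum(p.probability for p in enumerate_paths(arm, values))
            assert total == pytest.approx(1.0)


def _random_tree(rng, values, depth=0):
    """Random chance/terminal tree of depth <= 4 with point probabilities."""
    if depth >= 4 or rng.random() < 0.3:
        pid = f"c{len(values)}"
        values[pid] = float(rng.uniform(0, 1000))
        return TerminalNode(pid, CostExpression(attendance_terms=(AttendanceTerm(pid),)))
    n_branches = int(rng.integers(2, 4))
    probs = rng.dirichlet(np.ones(n_branches))
    branches = []
    for i in range(n_branches - 1):
        pid = f"p{len(values)}"
        values[pid] = float(probs[i])
        branches.append((ref(pid), _random_tree(rng, values, depth + 1)))
    from econsult_cma import residual

    branches.append((residual(), _random_tree(rng, values, depth + 1)))
    return ChanceNode(f"n{len(values)}", tuple(branches))


@given(st.integers(0, 10_000))
@settings(max_examples=50, deadline=None)
def test_rollback_agrees_with_path_enumeration_on_random_trees(seed):
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {}
    node = _random_tree(rng, values)
    expected = expected_cost(node, values)
    assert expected == pytest.approx(oracle_expected_cost(node.to_dict(), values), rel=1e-10)
    # path probabilities of a well-formed tree sum to one
    assert sum(p.probability for p in enumerate_paths(node, values)) == pytest.approx(1.0)
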