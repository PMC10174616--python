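import pytest

from econsult_cma import build_base_case_tree, load_base_case


@pytest.fixture(scope="session")
def base_table():
    return load_base_case()


@pytest.fixture(scope="session")
def canonical_tree(base_table):
    return build_base_case_tree(base_table)


def oracle_paths(node_dict, values, prob=1.0):
    """Independent path-enumeration oracle working on the serialised tree.

    Walks the JSON form of an arm, evaluating every cost expression and
    branch probability from scratch, and returns (probability, cost) per
    root-to-leaf path. Shares no evaluation code with the package.
    """
    if node_dict["type"] == "terminal":
        cost = 0.0
        for tid, rid in node_dict["cost"]["time_terms"]:
            cost += values[tid] * values[rid]
        for term in node_dict["cost"]["attendance_terms"]:
            x = values[term["cost_id"]]
            if term.get("scale_id"):
                x *= values[term["scale_id"]]
            if term.get("dna_id"):
                x /= 1.0 - values[term["dna_id"]]
            cost += x
        return [(prob, cost)]
    explicit = 0.0
    probs = []
    for branch in node_dict["branches"]:
        bp = branch["probability"]
        if bp["kind"] == "param":
            p = values[bp["pid"]]
        elif bp["kind"] == "complement":
            p = 1.0 - values[bp["pid"]]
        else:
            p = None
        probs.append(p)
        explicit += 0.0 if p is None else p
    paths = []
    for p, branch in zip(probs, node_dict["branches"]):
        if p is None:
            p = 1.0 - explicit
        paths.extend(oracle_paths(branch["child"], values, prob * p))
    return paths


def oracle_expected_cost(node_dict, values):
    return sum(p * c for p, c in oracle_paths(node_dict, values))
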