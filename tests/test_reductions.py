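"""The hardness gadgets as executable instances, and their inverses."""

from __future__ import annotations

import itertools

import pytest

import karyograph as kg
from karyograph.graph_core import is_chromosome, validate_path, walk_length
from karyograph.reductions import (
    DirectedGraphH,
    PartitionInstance,
    extract_hamiltonian,
    extract_partition,
    figure5_fixture,
    hc_to_chrp,
    partition_to_chrl,
)
from karyograph.wcc import check_wcc


def _has_hamiltonian_cycle(H: DirectedGraphH) -> bool:
    """Independent exhaustive checker over vertex permutations."""
    arcs = set(H.edges)
    if H.n == 1:
        return (1, 1) in arcs
    for perm in itertools.permutations(range(2, H.n + 1)):
        order = (1,) + perm
        if all(
            (order[i], order[(i + 1) % H.n]) in arcs for i in range(H.n)
        ):
            return True
    return False


def test_hc_gadget_structure():
    H = DirectedGraphH(3, ((1, 2), (2, 3), (3, 1)))
    G, params = hc_to_chrp(H)
    assert len(G.vertices) == 18
    assert len(G.E_S) == 9 and len(G.E_R) == 6 and len(G.E_L) == 3
    copies = {e.edge_id: e.copy_number for e in G.E_S}
    assert copies["S:h1:0"] == 1 and copies["S:h1:1"] == 2 and copies["S:h1:2"] == 1
    assert copies["S:h2:0"] == 0 and copies["S:h2:1"] == 1 and copies["S:h2:2"] == 0
    assert all(e.length == 1 for e in G.E_S)
    assert params.n_N == 1 and params.n_T == 0
    assert set(params.lambdas) == {H.n + 3}


def test_hc_four_cycle_zero_cost_single_chromosome():
    H = DirectedGraphH.cycle(4)
    G, params = hc_to_chrp(H)
    res = kg.brute_force_optimum(G, params, lambdas=params.lambdas)
    assert res.cost == 0 and res.certified
    assert len(res.best) == 1
    (witness,) = res.best
    assert is_chromosome(G, witness)
    assert walk_length(G, witness) == H.n + 3
    cycle = extract_hamiltonian(res.best, H, G, params)
    assert cycle is not None and sorted(cycle) == [1, 2, 3, 4]


def test_hc_self_loop_minimal_gadget():
    H = DirectedGraphH(1, ((1, 1),))
    G, params = hc_to_chrp(H)
    res = kg.brute_force_optimum(G, params, lambdas=params.lambdas)
    assert res.cost == 0
    assert walk_length(G, res.best[0]) == 4


def test_hc_sink_vertex_positive_cost():
    # vertex 4 has no outgoing arc: no Hamiltonian cycle exists
    H = DirectedGraphH(4, ((1, 2), (2, 3), (3, 1), (1, 4), (2, 4), (3, 4)))
    G, params = hc_to_chrp(H)
    res = kg.brute_force_optimum(G, params, lambdas=params.lambdas, cost_ceiling=1)
    assert res.best is None and res.cost >= 1
    assert res.zero_certified


def test_extract_hamiltonian_refuses_positive_cost():
    H = DirectedGraphH.cycle(3)
    G, params = hc_to_chrp(H)
    res = kg.brute_force_optimum(G, params, lambdas=params.lambdas)
    # doubling the witness breaks the count expectations: cost > 0
    doubled = res.best + res.best
    assert extract_hamiltonian(doubled, H, G, params) is None


@pytest.mark.parametrize(
    "arcs",
    [
        ((1, 2), (2, 1)),
        ((1, 2), (2, 3), (3, 1)),
        ((1, 2), (2, 3), (3, 2)),
        ((1, 2), (2, 3), (3, 4), (4, 1), (2, 4)),
        ((1, 2), (2, 3), (3, 4), (4, 2)),
        ((1, 3), (3, 2), (2, 4), (4, 1), (1, 2)),
    ],
)
def test_hc_roundtrip_iff_exhaustive_checker(arcs):
    """Gadget optimum is 0 exactly when a Hamiltonian cycle exists, and the
    extracted cycle is valid."""
    n = max(max(a) for a in arcs)
    H = DirectedGraphH(n, tuple(arcs))
    G, params = hc_to_chrp(H)
    expected = _has_hamiltonian_cycle(H)
    res = kg.brute_force_optimum(
        G, params, lambdas=params.lambdas, cost_ceiling=None if expected else 1
    )
    if expected:
        assert res.cost == 0
        cycle = extract_hamiltonian(res.best, H, G, params)
        assert cycle is not None
        assert sorted(cycle) == list(range(1, n + 1))
        arcset = set(H.edges)
        closed = cycle + [cycle[0]]
        assert all((u, v) in arcset for u, v in zip(closed, closed[1:]))
    else:
        assert res.best is None and res.cost >= 1 and res.zero_certified


# ---- PARTITION --------------------------------------------------------------

def _subset_sum_exists(P: PartitionInstance) -> bool:
    if P.total % 2:
        return False
    half = P.total // 2
    return any(
        sum(combo) == half
        for r in range(P.n + 1)
        for combo in itertools.combinations(P.values, r)
    )


def test_partition_gadget_structure_and_invariant():
    for values in [(1, 1), (2, 1, 1), (3, 1)]:
        P = PartitionInstance(values)
        G, params, v_w, req = partition_to_chrl(P)
        scale = 2 if P.total % 2 else 1
        total = sum(e.length * e.copy_number for e in G.edges.values())
        assert total == 10 * (P.n + 2) * P.total * scale
        assert params.n_N == P.n + 2 and params.n_T == 0
        assert check_wcc(G, v_w).satisfied
        # every adjacency edge (aberrant and reference) is required
        assert all(G.edge(eid).required for eid in req)


def test_partition_even_pair_zero_cost_and_roundtrip():
    P = PartitionInstance((1, 1))
    G, params, v_w, req = partition_to_chrl(P)
    res = kg.brute_force_optimum(
        G, params, lambdas=params.lambdas, v_w=v_w, required=req
    )
    assert res.cost == 0 and res.certified
    lengths = sorted(walk_length(G, c) for c in res.best)
    assert lengths == [10 * P.total] * (P.n + 2)
    subset = extract_partition(res.best, P, G, params)
    assert subset is not None
    assert 2 * sum(P.values[i - 1] for i in subset) == P.total


def test_partition_2_1_1_roundtrip():
    P = PartitionInstance((2, 1, 1))
    G, params, v_w, req = partition_to_chrl(P)
    res = kg.brute_force_optimum(
        G, params, lambdas=params.lambdas, v_w=v_w, required=req
    )
    assert res.cost == 0
    subset = extract_partition(res.best, P, G, params)
    assert subset is not None
    assert sum(P.values[i - 1] for i in subset) == 2


def test_partition_odd_total_positive_cost():
    P = PartitionInstance((1, 1, 1))
    G, params, v_w, req = partition_to_chrl(P)
    res = kg.brute_force_optimum(
        G, params, lambdas=params.lambdas, v_w=v_w, required=req, cost_ceiling=1
    )
    assert res.best is None and res.cost >= 1
    assert res.zero_certified


def test_partition_zero_cost_iff_subset_exists():
    for values in [(1, 1), (1, 2), (2, 1, 1), (1, 1, 2)]:
        P = PartitionInstance(values)
        G, params, v_w, req = partition_to_chrl(P)
        expected = _subset_sum_exists(P)
        res = kg.brute_force_optimum(
            G, params, lambdas=params.lambdas, v_w=v_w, required=req,
            cost_ceiling=None if expected else 1,
        )
        assert (res.cost == 0) == expected


def test_extract_partition_refuses_positive_cost():
    P = PartitionInstance((1, 1))
    G, params, v_w, req = partition_to_chrl(P)
    res = kg.brute_force_optimum(
        G, params, lambdas=params.lambdas, v_w=v_w, required=req
    )
    assert extract_partition(res.best[:-1], P, G, params) is None


def test_gadget_witnesses_are_direction_valid():
    """The machine-checked reading of the gadget edge tuples: the witness
    chromosomes validate under the direction rule."""
    H = DirectedGraphH.cycle(4)
    G, params = hc_to_chrp(H)
    res = kg.brute_force_optimum(G, params, lambdas=params.lambdas)
    for c in res.best:
        assert validate_path(G, c)[0]
    P = PartitionInstance((1, 1))
    G2, p2, vw2, req2 = partition_to_chrl(P)
    res2 = kg.brute_force_optimum(G2, p2, lambdas=p2.lambdas, v_w=vw2, required=req2)
    for c in res2.best:
        assert validate_path(G2, c)[0]


# ---- the solution-multiplicity fixture --------------------------------------

def test_figure5_satisfies_wcc():
    G, params, v_w, req = figure5_fixture()
    assert check_wcc(G, v_w).satisfied


def test_figure5_pipeline_zero_cost():
    G, params, v_w, req = figure5_fixture()
    rep = kg.solve_chrw(G, params, v_w)
    assert rep.W_C == 0
    assert rep.W_f == rep.W_0


def test_figure5_has_exactly_two_optimal_multisets():
    G, params, v_w, req = figure5_fixture()
    res = kg.brute_force_optimum(G, params, v_w=v_w, required=req, all_optima=True)
    assert res.cost == 0
    assert len(res.optima) == 2
    expected = {
        (
            ("S:chr1:0", "L:000", "S:chr2:1", "L:001", "S:chr1:2"),
            ("S:chr2:0", "R:chr2:1", "S:chr2:1", "R:chr2:2", "S:chr2:2"),
        ),
        (
            ("S:chr1:0", "L:000", "S:chr2:1", "R:chr2:2", "S:chr2:2"),
            ("S:chr1:2", "L:001", "S:chr2:1", "R:chr2:1", "S:chr2:0"),
        ),
    }
    got = {
        tuple(sorted(tuple(s.edge_id for s in c.steps) for c in ms))
        for ms in res.optima
    }
    assert got == {tuple(sorted(ms)) for ms in expected}
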