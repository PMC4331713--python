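"""Min-cost integer circulations on the circular chromosome graph, and an
exact brute-force oracle over chromosome multisets.

The chromosome-multiset optimization is converted into a flow problem by
extending the chromosome graph with two terminal vertices:

* ``v_N`` collects chromosome starts and ends through terminal edges
  ``e_t(v)`` (one per split vertex), turning every chromosome into part of
  one big cycle;
* ``v_T`` routes endpoints that sit at internal breakpoints (truncations);
* a self-loop ``e_N`` at ``v_N`` with cost weight ``Q_N`` counts
  chromosomes, and ``e_T`` between ``v_N`` and ``v_T`` with weight ``Q_T``
  counts truncation endpoints;
* every segment edge (and ``e_N``, ``e_T``) gets a reverse partner with both
  end directions negated, the same cost weight, and upper bound ``n(e)``, so
  that *deficits* (fewer visits than the expected copy number) can be paid
  for without violating the lower bound ``l(e) = n(e)``.

An integer circulation is an edge flow ``f`` with ``l(e) <= f(e) <= u(e)``
and signed balance ``sum_e a(v,e) f(e) = 0`` at every vertex, where
``a(v,e)`` counts +1/-1 per ``+``/``-`` end of ``e`` at ``v`` (a self-loop
with two ``+`` ends contributes +2).  With ``W_0 = Q_N n_N + Q_T n_T +
sum |e| n(e)``, the minimum circulation cost satisfies
``min W(f) = min W(C) + W_0``.

The solver backend is scipy's HiGHS mixed-integer optimizer.  The bidirected
constraint matrix is not totally unimodular, so the integer program is
solved as such rather than trusting LP rounding; all data are small integers
and results are re-verified exactly in integer arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .graph_core import (
    KIND_D,
    KIND_L,
    KIND_N,
    KIND_R,
    KIND_S,
    MINUS,
    PLUS,
    V3,
    V5,
    VM,
    VN,
    VT,
    BidirectedEdge,
    ChromosomeGraph,
    CostParams,
    GraphError,
    Step,
    Vertex,
    Walk,
    canonical_multiset_key,
    canonical_walk,
    is_chromosome,
    lambda_feasible,
    walk_vertices,
    walk_visits,
)
from .wcc import check_wcc

__all__ = [
    "incidence",
    "CircularChromosomeGraph",
    "Circulation",
    "CirculationInfeasible",
    "build_circular_graph",
    "is_circulation",
    "solve_min_cost_circulation",
    "canonical_flow",
    "flow_cost",
    "lemma1_edge_budget",
    "BruteForceResult",
    "brute_force_optimum",
]

VN_KEY = ("#N", 0, "#")
VT_KEY = ("#T", 0, "#")
EID_N = "N"
EID_T = "T"


def incidence(v, e: BidirectedEdge) -> int:
    """Signed incidence a(v,e): +1 per '+'-end and -1 per '-'-end of e at v."""
    vkey = v.key if isinstance(v, Vertex) else tuple(v)
    a = 0
    for i in (0, 1):
        if e.end(i).key == vkey:
            a += 1 if e.dir(i) == PLUS else -1
    return a


def lemma1_edge_budget(G: ChromosomeGraph, params: CostParams) -> int:
    """Upper bound U(4|V|+1)(|E|+1) on the edge count of an optimal multiset."""
    U = params.effective_U(G)
    return U * (4 * len(G.vertices) + 1) * (len(G.edges) + 1)


class CircularChromosomeGraph(ChromosomeGraph):
    """Chromosome graph extended with terminal vertices/edges and flow bounds."""

    def __init__(self) -> None:
        super().__init__()
        self.params: Optional[CostParams] = None
        self.V_W: frozenset = frozenset()
        self.W_0: int = 0
        self.partner: dict[str, str] = {}  # e <-> its reverse partner
        self.base_edge_ids: frozenset[str] = frozenset()

    @property
    def v_N(self) -> Vertex:
        return self.vertices[VN_KEY]

    @property
    def v_T(self) -> Vertex:
        return self.vertices[VT_KEY]

    @property
    def E_N(self) -> list[BidirectedEdge]:
        return self.edges_of_kind(KIND_N)

    @property
    def E_D(self) -> list[BidirectedEdge]:
        return self.edges_of_kind(KIND_D)

    @staticmethod
    def terminal_edge_id(vkey: tuple) -> str:
        return f"t:{vkey[0]}:{vkey[1]}:{vkey[2]}"


class CirculationInfeasible(RuntimeError):
    """No integer circulation satisfies the bounds and balance constraints."""


def _neg(d: str) -> str:
    return MINUS if d == PLUS else PLUS


def build_circular_graph(
    G: ChromosomeGraph,
    params: CostParams,
    V_W: Iterable,
    required: Optional[Iterable[str]] = None,
    check: bool = True,
    upper_override: Optional[int] = None,
) -> CircularChromosomeGraph:
    """Construct the circular chromosome graph with bounds and cost weights.

    ``V_W`` are the marked chromosome-end vertices; ``required`` optionally
    names additional adjacency edges to force (edges already flagged required
    stay required).  The input graph is copied, never mutated.  Unspecified
    upper bounds default to the solution-size budget ``U(4|V|+1)(|E|+1)``
    (``upper_override`` substitutes a smaller cap, e.g. for exhaustive
    enumeration tests).

    Raises :class:`~karyograph.graph_core.GraphError` when the instance fails
    the weakly connected constraint; repair it first (``wcc.repair_wcc``).
    """
    vkeys = frozenset(v.key if isinstance(v, Vertex) else tuple(v) for v in V_W)
    unknown = vkeys - set(G.vertices)
    if unknown:
        raise GraphError(f"V_W references unknown vertices: {sorted(unknown)}")
    base = G.copy()
    if required is not None:
        for eid in required:
            e = base.edge(eid)
            if e.kind not in (KIND_L, KIND_R):
                raise GraphError(f"only E_L/E_R edges can be required, not {eid}")
            e.required = True
    if check:
        report = check_wcc(base, vkeys)
        if not report.satisfied:
            raise GraphError(
                "instance violates the weakly connected constraint "
                f"({len(report.bad_components)} unanchored component(s)); "
                "run wcc.repair_wcc first"
            )

    B = upper_override if upper_override is not None else lemma1_edge_budget(base, params)

    Gc = CircularChromosomeGraph()
    Gc.params = params
    Gc.V_W = vkeys
    for v in base.vertices.values():
        Gc.add_vertex(v)
    v_N = Gc.add_vertex(Vertex("#N", 0, "#", VN))
    v_T = Gc.add_vertex(Vertex("#T", 0, "#", VT))
    Gc.chrom_order = list(base.chrom_order)
    Gc.n_breaks = dict(base.n_breaks)

    # base edges, with flow bounds
    for eid in sorted(base.edges):
        e = base.edges[eid]
        if e.kind == KIND_S:
            lo: int = e.copy_number
        else:  # E_L / E_R: force only the required ones
            lo = 1 if e.required else 0
        Gc.add_edge(
            BidirectedEdge(
                edge_id=e.edge_id, end1=e.end1, dir1=e.dir1, end2=e.end2,
                dir2=e.dir2, kind=e.kind, copy_number=e.copy_number,
                length=e.length, required=e.required, lower=lo, upper=B,
            )
        )
    Gc.base_edge_ids = frozenset(base.edges)

    # terminal edges e_t(v): chromosome starts/ends splice through v_N,
    # truncation endpoints through v_T
    for vkey in sorted(base.vertices):
        v = base.vertices[vkey]
        if v.klass == V5:
            term, tdir = v_N, PLUS
        elif v.klass == V3:
            term, tdir = v_N, MINUS
        elif v.klass == VM:
            term = v_T
            tdir = MINUS if v.side == PLUS else PLUS
        else:  # pragma: no cover - base graphs hold only V5/V3/VM
            raise GraphError(f"unexpected vertex class {v.klass} in base graph")
        Gc.add_edge(
            BidirectedEdge(
                edge_id=Gc.terminal_edge_id(vkey), end1=term, dir1=MINUS,
                end2=v, dir2=tdir, kind=KIND_N, copy_number=0, length=0,
                lower=1 if vkey in vkeys else 0, upper=B,
            )
        )

    Gc.add_edge(
        BidirectedEdge(
            edge_id=EID_T, end1=v_N, dir1=MINUS, end2=v_T, dir2=PLUS,
            kind=KIND_N, copy_number=params.n_T, length=params.Q_T,
            lower=params.n_T, upper=B,
        )
    )
    Gc.add_edge(
        BidirectedEdge(
            edge_id=EID_N, end1=v_N, dir1=PLUS, end2=v_N, dir2=PLUS,
            kind=KIND_N, copy_number=params.n_N, length=params.Q_N,
            lower=params.n_N, upper=B,
        )
    )

    # reverse partners for segment edges and the two counting edges
    for eid in sorted(Gc.base_edge_ids) + [EID_N, EID_T]:
        e = Gc.edge(eid)
        if eid not in (EID_N, EID_T) and e.kind != KIND_S:
            continue
        did = f"D:{eid}"
        Gc.add_edge(
            BidirectedEdge(
                edge_id=did,
                end1=e.end1, dir1=_neg(e.dir1),
                end2=e.end2, dir2=_neg(e.dir2),
                kind=KIND_D, copy_number=0, length=e.length,
                lower=0, upper=e.copy_number,
            )
        )
        Gc.partner[eid] = did
        Gc.partner[did] = eid

    Gc.W_0 = (
        params.Q_N * params.n_N
        + params.Q_T * params.n_T
        + sum(e.length * e.copy_number for e in base.edges.values())
    )
    return Gc


@dataclass
class Circulation:
    """Integer edge flow with its cost W(f) = sum cost_weight(e) * f(e)."""

    flows: dict[str, int]
    W: int

    def __getitem__(self, edge_id: str) -> int:
        return self.flows.get(edge_id, 0)


def flow_cost(Gc: CircularChromosomeGraph, flows: dict[str, int]) -> int:
    return sum(Gc.edge(eid).length * f for eid, f in flows.items())


def is_circulation(
    Gc: CircularChromosomeGraph,
    flows: dict[str, int],
    check_bounds: bool = True,
) -> tuple[bool, Optional[str]]:
    """Verify per-edge bounds and signed vertex balance; name the first
    violated constraint.  ``check_bounds=False`` verifies balance and
    nonnegativity only (canonicalized flows deliberately dip below the
    segment lower bounds)."""
    for eid in sorted(Gc.edges):
        e = Gc.edges[eid]
        f = flows.get(eid, 0)
        if f < 0:
            return False, f"f({eid}) = {f} < 0"
        if check_bounds:
            if f < e.lower:
                return False, f"f({eid}) = {f} < l = {e.lower}"
            if e.upper is not None and f > e.upper:
                return False, f"f({eid}) = {f} > u = {e.upper}"
    for vkey in sorted(Gc.vertices):
        bal = 0
        for eid, end_idx in Gc.incident(vkey):
            e = Gc.edges[eid]
            bal += (1 if e.dir(end_idx) == PLUS else -1) * flows.get(eid, 0)
        if bal != 0:
            return False, f"balance at {Gc.vertices[vkey]!r} is {bal}, not 0"
    return True, None


def solve_min_cost_circulation(
    Gc: CircularChromosomeGraph,
    seed: Optional[int] = None,
    tie_break: bool = True,
) -> Circulation:
    """Exact minimum-cost integer circulation via HiGHS branch-and-bound.

    A second solve with the optimal cost pinned minimizes total flow (with
    tiny edge-rank preferences) so that ties among co-optimal circulations
    resolve deterministically and without gratuitous circling flow.  ``seed``
    is accepted for interface symmetry; the backend is deterministic.

    Raises :class:`CirculationInfeasible` when no integer flow satisfies the
    bounds and balance constraints (e.g. a required edge whose balance
    cannot close).
    """
    del seed  # deterministic backend
    eids = sorted(Gc.edges)
    idx = {eid: i for i, eid in enumerate(eids)}
    n = len(eids)
    lo = np.array([Gc.edges[e].lower for e in eids], dtype=float)
    up = np.array(
        [math.inf if Gc.edges[e].upper is None else Gc.edges[e].upper for e in eids],
        dtype=float,
    )
    weights = np.array([Gc.edges[e].length for e in eids], dtype=float)

    rows, cols, vals = [], [], []
    vkeys = sorted(Gc.vertices)
    for r, vkey in enumerate(vkeys):
        for eid, end_idx in Gc.incident(vkey):
            rows.append(r)
            cols.append(idx[eid])
            vals.append(1.0 if Gc.edges[eid].dir(end_idx) == PLUS else -1.0)
    A = sparse.coo_matrix((vals, (rows, cols)), shape=(len(vkeys), n)).tocsr()
    balance = LinearConstraint(A, 0.0, 0.0)

    res = milp(
        c=weights,
        constraints=[balance],
        integrality=np.ones(n),
        bounds=Bounds(lo, up),
    )
    if res.status != 0 or res.x is None:
        raise CirculationInfeasible(
            f"no feasible integer circulation (solver status {res.status}: "
            f"{res.message})"
        )
    flows = _round_exact(res.x)
    W = int(sum(int(weights[i]) * flows[i] for i in range(n)))

    if tie_break:
        pin = LinearConstraint(sparse.csr_matrix(weights), W, W)
        rank = np.array([1.0 + i / (10.0 * n) for i in range(n)])
        res2 = milp(
            c=rank,
            constraints=[balance, pin],
            integrality=np.ones(n),
            bounds=Bounds(lo, up),
        )
        if res2.status == 0 and res2.x is not None:
            flows = _round_exact(res2.x)

    fmap = {eids[i]: flows[i] for i in range(n)}
    ok, why = is_circulation(Gc, fmap)
    if not ok:  # pragma: no cover - guards solver numerics
        raise CirculationInfeasible(f"solver returned a non-circulation: {why}")
    return Circulation(flows=fmap, W=flow_cost(Gc, fmap))


def _round_exact(x: np.ndarray) -> list[int]:
    out = []
    for xi in x:
        r = round(float(xi))
        if abs(xi - r) > 1e-6:  # pragma: no cover - integral data
            raise CirculationInfeasible(f"non-integral solver value {xi}")
        out.append(int(r))
    return out


def canonical_flow(
    Gc: CircularChromosomeGraph, C: Sequence[Walk]
) -> dict[str, int]:
    """The explicit feasible circulation certifying W(f) = W(C) + W_0.

    Segment deficits ride the reverse partners; every chromosome start/end
    consumes one terminal edge; ``e_N``/``e_T`` absorb count surpluses and
    their partners absorb count deficits.
    """
    params = Gc.params
    assert params is not None
    m: dict[str, int] = {}
    tr = 0
    end_count: dict[tuple, int] = {}
    for c in C:
        if not is_chromosome(Gc, c):
            raise GraphError("canonical_flow needs a multiset of chromosomes")
        verts = walk_vertices(Gc, c)
        for endpoint in (verts[0], verts[-1]):
            end_count[endpoint.key] = end_count.get(endpoint.key, 0) + 1
            if endpoint.klass == VM:
                tr += 1
        for eid, k in walk_visits(c).items():
            m[eid] = m.get(eid, 0) + k
    size = len(C)

    flows: dict[str, int] = {eid: 0 for eid in Gc.edges}
    for eid in Gc.base_edge_ids:
        e = Gc.edge(eid)
        mc = m.get(eid, 0)
        if e.kind == KIND_S:
            flows[eid] = max(e.copy_number, mc)
            flows[f"D:{eid}"] = max(0, e.copy_number - mc)
        else:
            flows[eid] = mc
    for vkey in sorted(set(Gc.vertices) - {VN_KEY, VT_KEY}):
        flows[Gc.terminal_edge_id(vkey)] = end_count.get(vkey, 0)
    flows[EID_N] = max(params.n_N, size)
    flows["D:" + EID_N] = max(0, params.n_N - size)
    flows[EID_T] = max(params.n_T, tr)
    flows["D:" + EID_T] = max(0, params.n_T - tr)
    return flows


# ---------------------------------------------------------------------------
# exhaustive oracle: branch-and-bound over chromosome multisets
# ---------------------------------------------------------------------------

@dataclass
class BruteForceResult:
    """Outcome of the exhaustive multiset search.

    ``certified`` -- the returned cost is provably the optimum.
    ``zero_certified`` -- weaker: "the optimum is zero iff the returned cost
    is zero" is proven (the zero-cost phase ran with rigorous visit caps).
    Full certification can be lost around zero-length segments, whose
    cost-free revisits force heuristic visit caps in the positive-cost phase,
    or with a user-supplied cost function (no admissible bound available).
    """

    cost: int
    best: Optional[tuple[Walk, ...]]
    optima: tuple[tuple[Walk, ...], ...] = ()
    certified: bool = True
    zero_certified: bool = True
    nodes: int = 0
    flags: tuple[str, ...] = ()


def _zero_length_caps(
    G: ChromosomeGraph, params: CostParams
) -> tuple[dict[str, float], bool]:
    """Fixpoint upper bounds on edge visits in any zero-cost multiset.

    In a zero-cost solution the visit count of every positive-length segment
    equals its copy number, at most ``n_T`` endpoints sit at internal
    breakpoints, and each visit of an edge consumes one traversal incidence
    at each of its end vertices.  Iterating

        bound(e) = min over ends v of (sum of other edge-end bounds at v
                                       + endpoint allowance at v)

    downward from infinity therefore yields rigorous caps whenever the
    zero-length edges are anchored by pinned neighbours.  Returns bounds for
    every edge plus a flag saying whether all zero-length segment bounds came
    out finite.
    """
    INF = math.inf
    bound: dict[str, float] = {}
    for eid, e in G.edges.items():
        if e.kind == KIND_S and e.length > 0:
            bound[eid] = e.copy_number
        else:
            bound[eid] = INF

    def allowance(v: Vertex) -> int:
        return params.n_T if v.klass == VM else 2 * params.n_N

    changed = True
    while changed:
        changed = False
        for eid in sorted(G.edges):
            e = G.edges[eid]
            if e.kind == KIND_S and e.length > 0:
                continue  # pinned
            best = bound[eid]
            for i in (0, 1):
                v = e.end(i)
                total: float = allowance(v)
                for oid, end_idx in G.incident(v.key):
                    if oid == eid and end_idx == i:
                        continue  # this very end; a self-loop's other end counts
                    total += bound[oid]
                best = min(best, total)
            if best < bound[eid]:
                bound[eid] = best
                changed = True

    all_finite = all(
        not math.isinf(bound[e.edge_id])
        for e in G.edges.values()
        if e.kind == KIND_S and e.length == 0
    )
    return bound, all_finite


def _greedy_feasible(
    G: ChromosomeGraph, v_w: frozenset, required: frozenset[str]
) -> list[Walk]:
    """A cheap feasible multiset seeding the branch-and-bound incumbent: one
    segment-adjacency-segment sandwich per required edge, plus a
    single-segment chromosome per uncovered end-marker vertex."""
    out: list[Walk] = []
    covered_ends: set = set()

    def s_edge_at(vkey: tuple) -> str:
        for eid, _ in G.incident(vkey):
            if G.edges[eid].kind == KIND_S:
                return eid
        raise GraphError(f"no segment edge at {vkey}")

    for eid in sorted(required):
        e = G.edge(eid)
        sa = s_edge_at(e.end1.key)
        sb = s_edge_at(e.end2.key)
        ea, eb = G.edge(sa), G.edge(sb)
        # enter S_a at its far end so it exits at e.end1, then e, then S_b
        sa_fwd = ea.end2.key == e.end1.key
        sb_fwd = eb.end1.key == e.end2.key
        start = ea.end1 if sa_fwd else ea.end2
        steps = (Step(sa, sa_fwd), Step(eid, True), Step(sb, sb_fwd))
        w = Walk(start=start.key, steps=steps)
        out.append(w)
        verts = walk_vertices(G, w)
        covered_ends.update((verts[0].key, verts[-1].key))
    for vkey in sorted(v_w - covered_ends):
        sid = s_edge_at(vkey)
        e = G.edge(sid)
        out.append(Walk(start=e.end1.key, steps=(Step(sid, True),)))
    return out


def _summarize(G: ChromosomeGraph, C: Sequence[Walk]) -> tuple[int, int, dict]:
    m: dict[str, int] = {}
    tr = 0
    for c in C:
        verts = walk_vertices(G, c)
        for endpoint in (verts[0], verts[-1]):
            if endpoint.klass == VM:
                tr += 1
        for eid, k in walk_visits(c).items():
            m[eid] = m.get(eid, 0) + k
    return len(C), tr, m


def brute_force_optimum(
    G: ChromosomeGraph,
    params: CostParams,
    edge_budget: Optional[int] = None,
    lambdas: Optional[Sequence[int]] = None,
    cost_fn: Optional[Callable[[int, int, dict[str, int]], int]] = None,
    v_w: Iterable = (),
    required: Optional[Iterable[str]] = None,
    all_optima: bool = False,
    excess_cap: int = 3,
    cost_ceiling: Optional[int] = None,
) -> BruteForceResult:
    """Exact optimum over chromosome multisets by depth-first enumeration.

    With ``cost_ceiling`` the search stops once the optimum is proven to be
    at least the ceiling: the result then has ``best=None`` and ``cost`` is a
    certified lower bound (useful to separate zero from positive optima
    without paying for the exact positive value).

    Solves the full NP-complete problem (with per-chromosome length caps when
    ``lambdas`` is given) on tiny graphs.  Chromosomes are grown step by
    step; multisets are generated in canonical order (each member in
    canonical orientation, members sorted) to kill reversal and permutation
    symmetry; branches are cut with the admissible bound made of
    irreversible cost -- chromosome-count surplus, truncation surplus, and
    positive-length visit surpluses -- against the best solution found.

    The search runs in two phases.  Phase one decides, with rigorous visit
    caps, whether a zero-cost multiset exists (then it is optimal: W >= 0).
    Phase two, entered only for positive optima, seeds an incumbent with a
    cheap feasible multiset and searches below it.

    Optional side constraints mirror the polynomial pipeline: ``required``
    adjacency edges must be visited, and every ``v_w`` vertex must be a
    chromosome endpoint.  ``cost_fn(size, tr, m) -> int`` substitutes any
    monotone cost honoring the abstract cost family (then only cap/budget
    pruning applies and the result carries a flag).  With ``all_optima``
    every optimal multiset (up to member reversal and order) is collected.
    """
    if lambdas is not None:
        params = CostParams(
            n_N=params.n_N, n_T=params.n_T, Q_N=params.Q_N, Q_T=params.Q_T,
            U=params.U, lambdas=tuple(lambdas),
        )
    v_w_keys = frozenset(v.key if isinstance(v, Vertex) else tuple(v) for v in v_w)
    req: frozenset[str] = frozenset(
        required
        if required is not None
        else (e.edge_id for e in G.edges.values() if e.required)
    )
    budget = edge_budget if edge_budget is not None else lemma1_edge_budget(G, params)
    if budget > lemma1_edge_budget(G, params):
        raise ValueError("edge_budget exceeds the solution-size bound")

    default_cost = cost_fn is None

    def evaluate(size: int, tr: int, m: dict[str, int]) -> int:
        if default_cost:
            w = params.Q_N * abs(size - params.n_N) + params.Q_T * abs(tr - params.n_T)
            for e in G.E_S:
                w += e.length * abs(m.get(e.edge_id, 0) - e.copy_number)
            return w
        return cost_fn(size, tr, m)

    caps, caps_rigorous = _zero_length_caps(G, params)
    caps_rigorous = caps_rigorous and default_cost
    # keep phase 1 finite: zero-length segments with no rigorous anchor get a
    # fallback cap (certification is then withheld); adjacency-edge bounds
    # stay as computed (infinite ones fall back to the global capacity cap)
    phase1_caps = {
        eid: (
            b
            if not math.isinf(b)
            or not (G.edges[eid].kind == KIND_S and G.edges[eid].length == 0)
            else G.edges[eid].copy_number + excess_cap
        )
        for eid, b in caps.items()
    }

    # ---- phase 1: is there a zero-cost solution? --------------------------
    engine = _MultisetSearch(
        G, params, evaluate, default_cost, req, v_w_keys, budget,
        zero_caps=phase1_caps, excess_cap=excess_cap,
        static_caps=not default_cost, rigorous=caps_rigorous,
    )
    r1 = engine.run(incumbent=1, collect=all_optima)
    zero_certified = caps_rigorous and not r1.capped
    if r1.best is not None:
        flags = () if zero_certified or not all_optima else ("zero-length-caps-heuristic",)
        return BruteForceResult(
            cost=0, best=r1.best, optima=r1.optima if all_optima else (),
            certified=True,  # W(C) >= 0 always, so a found 0 is optimal
            zero_certified=True,
            nodes=r1.nodes, flags=flags,
        )

    # ---- phase 2: optimum is positive -------------------------------------
    # iterative deepening on the incumbent: a run pruned at level k is an
    # exhaustive search of all completions costing < k, so the first level
    # that returns a solution returns the global optimum
    heuristic_caps = {
        eid: (b if not math.isinf(b) else G.edges[eid].copy_number) + excess_cap
        for eid, b in caps.items()
        if G.edges[eid].kind == KIND_S and G.edges[eid].length == 0
    }
    seed = _greedy_feasible(G, v_w_keys, req)
    seed_state: Optional[tuple] = None
    if params.lambdas is None or lambda_feasible(G, seed, params):
        seed_state = (tuple(seed), evaluate(*_summarize(G, seed)))

    engine2 = _MultisetSearch(
        G, params, evaluate, default_cost, req, v_w_keys, budget,
        zero_caps=heuristic_caps, excess_cap=excess_cap,
        static_caps=not default_cost, rigorous=False,
    )
    # a conservative finite cost ceiling (any feasible multiset costs less)
    n_l = len(params.lambdas) if params.lambdas is not None else 0
    ceiling = (
        params.Q_N * (params.n_N + n_l + 1)
        + params.Q_T * (params.n_T + 2 * (n_l + 1))
        + sum(e.length * e.copy_number for e in G.edges.values())
        + (n_l + params.n_N) * max(
            [params.lambdas and max(params.lambdas) or 0]
            + [e.length for e in G.E_S]
        )
        + 1
    )
    if cost_ceiling is not None and cost_ceiling <= 1:
        # phase 1 already proved the optimum positive, i.e. >= 1
        return BruteForceResult(
            cost=1, best=None, certified=zero_certified,
            zero_certified=zero_certified, nodes=r1.nodes,
            flags=("cost-ceiling",),
        )
    level = 2
    r2 = None
    while True:
        cap = level
        if seed_state is not None:
            cap = min(cap, seed_state[1] + 1)
        if cost_ceiling is not None:
            cap = min(cap, cost_ceiling)
        use_seed = seed_state if (seed_state and cap == seed_state[1] + 1) else None
        r2 = engine2.run(incumbent=cap, seed=use_seed, collect=all_optima)
        if r2.best is not None:
            break
        if cost_ceiling is not None and cap == cost_ceiling:
            # exhaustive below the ceiling: the optimum is >= cost_ceiling
            return BruteForceResult(
                cost=cost_ceiling, best=None,
                certified=zero_certified and not r2.capped,
                zero_certified=zero_certified,
                nodes=r1.nodes + r2.nodes,
                flags=("cost-ceiling",) + (("visit-caps-pruned",) if r2.capped else ()),
            )
        if level > ceiling:
            raise GraphError(
                "brute force found no feasible multiset within the cost ceiling"
            )
        level *= 2
    if r2.best is None:  # pragma: no cover - a feasible multiset always exists
        raise GraphError("brute force found no feasible multiset within budget")
    flags = []
    if r2.budget_hit:
        flags.append("budget-limited")
    if r2.capped:
        flags.append("visit-caps-pruned")
    if not default_cost:
        flags.append("custom-cost-no-bound-pruning")
    return BruteForceResult(
        cost=r2.best_cost,
        best=r2.best,
        optima=r2.optima if all_optima else (),
        certified=default_cost and zero_certified and not (r2.budget_hit or r2.capped),
        zero_certified=zero_certified,
        nodes=r1.nodes + r2.nodes,
        flags=tuple(flags),
    )


@dataclass
class _SearchOutcome:
    best: Optional[tuple[Walk, ...]]
    best_cost: int
    optima: tuple
    nodes: int
    budget_hit: bool
    capped: bool


class _MultisetSearch:
    """Depth-first enumeration of chromosome multisets.

    ``zero_caps`` bounds visits of zero-length segment edges (rigorous in the
    zero-cost phase, heuristic with slack otherwise); ``static_caps`` adds
    n(e)+excess caps on all segments (needed when no admissible cost bound is
    available).  ``rigorous`` marks cap prunes as sound rather than
    certification-breaking.
    """

    def __init__(
        self,
        G: ChromosomeGraph,
        params: CostParams,
        evaluate: Callable[[int, int, dict[str, int]], int],
        default_cost: bool,
        required: frozenset[str],
        v_w: frozenset,
        budget: int,
        zero_caps: dict[str, float],
        excess_cap: int,
        static_caps: bool,
        rigorous: bool,
    ) -> None:
        self.G = G
        self.params = params
        self.evaluate = evaluate
        self.default_cost = default_cost
        self.required = required
        self.v_w = v_w
        self.budget = budget
        self.zero_caps = zero_caps
        self.excess_cap = excess_cap
        self.static_caps = static_caps
        self.rigorous = rigorous
        self.s_edges = [e.edge_id for e in G.E_S]
        self.lengths = {eid: e.length for eid, e in G.edges.items()}
        self.copy_n = {
            eid: (e.copy_number if e.kind == KIND_S else 0)
            for eid, e in G.edges.items()
        }
        # adjacency edges are always sandwiched between segment visits, so
        # total segment capacity bounds each adjacency edge's visits
        def s_capacity(eid: str) -> int:
            if self.lengths[eid] == 0:
                b = zero_caps.get(eid, math.inf)
                return int(b) if not math.isinf(b) else self.copy_n[eid] + excess_cap
            return self.copy_n[eid] + excess_cap
        self.lr_cap = sum(s_capacity(eid) for eid in self.s_edges)
        self.max_lambda = max(params.lambdas) if params.lambdas is not None else None

    # admissible lower bound on the final cost of any completion
    def _lb(self, n_chroms: int, tr: int, m: dict[str, int]) -> int:
        if not self.default_cost:
            return 0
        p = self.params
        lb = p.Q_N * max(0, n_chroms - p.n_N)
        lb += p.Q_T * max(0, tr - p.n_T)
        for eid, cnt in m.items():
            excess = cnt - self.copy_n[eid]
            if excess > 0 and self.lengths[eid] > 0:
                lb += self.lengths[eid] * excess
        return lb

    def run(
        self,
        incumbent: Optional[int],
        seed: Optional[tuple[tuple[Walk, ...], int]] = None,
        collect: bool = False,
    ) -> _SearchOutcome:
        self.best: Optional[tuple[Walk, ...]] = None
        self.best_cost: float = math.inf if incumbent is None else incumbent
        self.collect = collect
        self.optima: dict[tuple, tuple[Walk, ...]] = {}
        if seed is not None:
            self.best = seed[0]
            self.best_cost = seed[1]
            if collect:
                self.optima[canonical_multiset_key(self.G, seed[0])] = seed[0]
        self.nodes = 0
        self.budget_hit = False
        self.capped = False

        m: dict[str, int] = {eid: 0 for eid in self.G.edges}
        self._chromosomes: list[Walk] = []
        self._ends_used: dict[tuple, int] = {}
        self._lengths: list[int] = []
        self._search_between(m, tr=0, total_edges=0)
        return _SearchOutcome(
            best=self.best,
            best_cost=int(self.best_cost) if self.best is not None else -1,
            optima=tuple(self.optima[k] for k in sorted(self.optima)),
            nodes=self.nodes,
            budget_hit=self.budget_hit,
            capped=self.capped,
        )

    def _prune_at(self) -> float:
        # when collecting, keep branches that can tie the incumbent
        return self.best_cost + (1 if self.collect else 0)

    def _feasible_completion(self, m: dict[str, int]) -> bool:
        if any(m.get(eid, 0) < 1 for eid in self.required):
            return False
        for vkey in self.v_w:
            if self._ends_used.get(vkey, 0) < 1:
                return False
        if self.params.lambdas is not None:
            caps = sorted(self.params.lambdas, reverse=True)
            lens = sorted(self._lengths, reverse=True)
            if len(lens) > len(caps):
                return False
            if any(ln > cap for ln, cap in zip(lens, caps)):
                return False
        return True

    # ---- decision point between chromosomes -------------------------------
    def _search_between(self, m: dict[str, int], tr: int, total_edges: int) -> None:
        G = self.G
        self.nodes += 1

        # option A: stop here and score the completed multiset
        if self._feasible_completion(m):
            final = self.evaluate(len(self._chromosomes), tr, m)
            if final < self.best_cost:
                self.best_cost = final
                self.best = tuple(self._chromosomes)
                if self.collect:
                    self.optima = {canonical_multiset_key(G, self.best): self.best}
            elif self.collect and self.best is not None and final == self.best_cost:
                key = canonical_multiset_key(G, tuple(self._chromosomes))
                self.optima.setdefault(key, tuple(self._chromosomes))

        # option B: grow another chromosome
        if self._lb(len(self._chromosomes) + 1, tr, m) >= self._prune_at():
            return
        if total_edges >= self.budget:
            self.budget_hit = True
            return
        prev_key = (
            canonical_walk(G, self._chromosomes[-1]).steps
            if self._chromosomes
            else None
        )
        for sid in self.s_edges:
            e = G.edges[sid]
            for forward in (True, False):
                start = e.end(0 if forward else 1)
                steps = [Step(sid, forward)]
                self._extend(
                    m, tr, total_edges, prev_key, start,
                    steps,
                    cur=e.end(1 if forward else 0),
                    exit_dir=e.dir(1 if forward else 0),
                    chrom_len=e.length,
                )

    # ---- grow one chromosome ----------------------------------------------
    def _extend(
        self,
        m: dict[str, int],
        tr: int,
        total_edges: int,
        prev_key,
        start_vertex: Vertex,
        steps: list[Step],
        cur: Vertex,
        exit_dir: str,
        chrom_len: int,
    ) -> None:
        G = self.G
        self.nodes += 1
        eid = steps[-1].edge_id  # the step this call is responsible for
        m[eid] += 1
        try:
            if not self._visit_ok(m, eid):
                return
            if self.max_lambda is not None and chrom_len > self.max_lambda:
                return
            if total_edges + len(steps) > self.budget:
                self.budget_hit = True
                return
            start_tr = 1 if start_vertex.klass == VM else 0
            if self._lb(len(self._chromosomes) + 1, tr + start_tr, m) >= self._prune_at():
                return

            # option A: end the chromosome here (last edge must be a segment)
            if G.edges[eid].kind == KIND_S:
                walk = Walk(start=start_vertex.key, steps=tuple(steps))
                ckey = canonical_walk(G, walk).steps
                if walk.steps == ckey and (prev_key is None or ckey >= prev_key):
                    end_tr = 1 if cur.klass == VM else 0
                    self._chromosomes.append(walk)
                    for k in (start_vertex.key, cur.key):
                        self._ends_used[k] = self._ends_used.get(k, 0) + 1
                    self._lengths.append(chrom_len)
                    self._search_between(
                        m, tr + start_tr + end_tr, total_edges + len(steps)
                    )
                    self._lengths.pop()
                    for k in (start_vertex.key, cur.key):
                        self._ends_used[k] -= 1
                    self._chromosomes.pop()

            # option B: keep walking
            need = MINUS if exit_dir == PLUS else PLUS
            for nid, end_idx in G.incident(cur.key):
                e = G.edges[nid]
                if e.is_self_loop():
                    ends = [i for i in (0, 1) if e.dir(i) == need]
                    if not ends:
                        continue
                    i = ends[0]
                else:
                    if e.dir(end_idx) != need:
                        continue
                    i = end_idx
                steps.append(Step(nid, i == 0))
                self._extend(
                    m, tr, total_edges, prev_key, start_vertex, steps,
                    cur=e.end(1 - i),
                    exit_dir=e.dir(1 - i),
                    chrom_len=chrom_len + e.length,
                )
                steps.pop()
        finally:
            m[eid] -= 1

    def _visit_ok(self, m: dict[str, int], eid: str) -> bool:
        e = self.G.edges[eid]
        cnt = m[eid]
        if e.kind == KIND_S:
            if e.length == 0:
                cap = self.zero_caps.get(eid, math.inf)
                if self.static_caps:
                    cap = min(cap, e.copy_number + self.excess_cap)
                if cnt > cap:
                    if not self.rigorous:
                        self.capped = True
                    return False
            elif self.static_caps and cnt > e.copy_number + self.excess_cap:
                self.capped = True
                return False
        else:  # adjacency edges: sandwiched between segments, capacity-bounded
            if cnt > min(self.lr_cap, self.zero_caps.get(eid, math.inf)):
                if not self.rigorous:
                    self.capped = True
                return False
        return True
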