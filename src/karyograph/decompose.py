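"""From an optimal circulation to chromosomes.

The converse half of the flow correspondence: an optimal circulation on the
circular chromosome graph is (1) *canonicalized* -- reverse-partner flow is
subtracted from its forward edge, leaving a balanced nonnegative flow with
zero reverse flow; (2) decomposed into direction-valid cycles whose visit
counts equal the flow exactly; (3) merged into a single cycle through shared
vertices (possible because the weakly connected constraint puts all support
edges in one component); and (4) cut at the terminal vertices: removing
``v_N``, ``v_T`` and the terminal edges splits the big cycle into exactly
``f(e_N)`` paths, each of which starts and ends with a segment edge -- a
chromosome.  The identity ``W(f) = W(C) + W_0`` then holds exactly.

Because several chromosome multisets can realize the same circulation, the
splicing/cutting choices are surfaced: ``enumerate_extractions`` lists every
multiset whose visit counts reproduce the canonical flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .circulation import (
    EID_N,
    EID_T,
    VN_KEY,
    VT_KEY,
    CircularChromosomeGraph,
    Circulation,
    build_circular_graph,
    is_circulation,
    lemma1_edge_budget,
    solve_min_cost_circulation,
)
from .graph_core import (
    KIND_N,
    KIND_S,
    MINUS,
    PLUS,
    VM,
    ChromosomeGraph,
    CostParams,
    GraphError,
    Step,
    Vertex,
    Walk,
    canonical_multiset_key,
    canonical_walk,
    cost as solution_cost,
    is_chromosome,
    validate_path,
    walk_length,
    walk_vertices,
    walk_visits,
)
from .sv_io import SolutionReport
from .wcc import check_wcc, default_E_W, repair_wcc

logger = logging.getLogger(__name__)

__all__ = [
    "canonicalize",
    "decompose_into_cycles",
    "merge_cycles",
    "extract_chromosomes",
    "enumerate_extractions",
    "solve_chrw",
]


def canonicalize(Gc: CircularChromosomeGraph, flows: dict[str, int]) -> dict[str, int]:
    """Subtract reverse-partner flow pairwise; reverse flows become zero.

    Equal flow on an edge and its direction-negated partner cancels at every
    vertex, so the result is again balanced (though it may dip below the
    segment lower bounds -- it is a decomposition object, not a feasible
    circulation).  Raises if any reverse flow exceeds its forward flow, which
    cannot happen at an optimum.
    """
    out = dict(flows)
    for eid, did in Gc.partner.items():
        if eid.startswith("D:"):
            continue
        fe, fd = out.get(eid, 0), out.get(did, 0)
        if fd > fe:
            raise GraphError(
                f"non-canonical circulation: f({did}) = {fd} > f({eid}) = {fe}"
            )
        out[eid] = fe - fd
        out[did] = 0
    return out


def decompose_into_cycles(
    Gc: CircularChromosomeGraph, flows: dict[str, int]
) -> list[Walk]:
    """Express a balanced nonnegative integer flow as cycles with
    multiplicity, conserving visit counts exactly (m(R,e) = f(e)).

    Walks extend greedily (smallest edge id first); whenever a
    (vertex, pending-direction) state repeats, the enclosed steps form a
    direction-valid cycle, which is removed.  Runs in time proportional to
    the total flow.
    """
    ok, why = is_circulation(Gc, flows, check_bounds=False)
    if not ok:
        raise GraphError(f"cannot decompose: {why}")
    rem = {eid: f for eid, f in flows.items() if f > 0}
    cycles: list[Walk] = []

    def take(eid: str) -> None:
        rem[eid] -= 1
        if rem[eid] == 0:
            del rem[eid]

    while rem:
        eid0 = min(rem)
        e0 = Gc.edge(eid0)
        # states[i] = (vertex, direction the i-th step presents there)
        steps: list[Step] = [Step(eid0, True)]
        states: list[tuple[tuple, str]] = [(e0.end1.key, e0.dir1)]
        take(eid0)
        cur, exit_dir = e0.end2.key, e0.dir2
        while True:
            state = (cur, MINUS if exit_dir == PLUS else PLUS)
            if state in states:
                j = states.index(state)
                cyc_steps = tuple(steps[j:])
                cycles.append(Walk(start=states[j][0], steps=cyc_steps))
                del steps[j:]
                del states[j:]
                if not steps:
                    break
                last = Gc.edge(steps[-1].edge_id)
                i_exit = 1 if steps[-1].forward else 0
                cur, exit_dir = last.end(i_exit).key, last.dir(i_exit)
                continue
            need = state[1]
            chosen = None
            for nid, end_idx in Gc.incident(cur):
                if nid not in rem:
                    continue
                e = Gc.edges[nid]
                if e.is_self_loop():
                    ends = [i for i in (0, 1) if e.dir(i) == need]
                    if not ends:
                        continue
                    chosen = (nid, ends[0])
                else:
                    if e.dir(end_idx) != need:
                        continue
                    chosen = (nid, end_idx)
                break
            if chosen is None:  # pragma: no cover - balance guarantees a move
                raise GraphError(
                    f"flow admits no continuation at {cur} needing '{need}'"
                )
            nid, i = chosen
            e = Gc.edges[nid]
            steps.append(Step(nid, i == 0))
            states.append(state)
            take(nid)
            cur, exit_dir = e.end(1 - i).key, e.dir(1 - i)
    return cycles


def _e_plus(Gc: CircularChromosomeGraph) -> frozenset[str]:
    return frozenset(
        e.edge_id
        for e in Gc.edges.values()
        if e.lower >= 1 or e.copy_number >= 1
    )


def _rotate_to(Gc: CircularChromosomeGraph, cycle: Walk, vkey: tuple) -> Walk:
    verts = [v.key for v in walk_vertices(Gc, cycle)]
    i = verts.index(vkey)  # first occurrence; verts[-1] == verts[0]
    if i == 0:
        return cycle
    steps = cycle.steps[i:] + cycle.steps[:i]
    return Walk(start=vkey, steps=steps)


def _junction_dirs(Gc: CircularChromosomeGraph, w: Walk) -> tuple[str, str]:
    """(direction the first step presents at the start vertex,
    direction the last step presents at the start vertex)."""
    first = Gc.edge(w.steps[0].edge_id)
    last = Gc.edge(w.steps[-1].edge_id)
    d_first = first.dir(0 if w.steps[0].forward else 1)
    d_last = last.dir(1 if w.steps[-1].forward else 0)
    return d_first, d_last


def _reverse(Gc: CircularChromosomeGraph, w: Walk) -> Walk:
    verts = walk_vertices(Gc, w)
    return Walk(
        start=verts[-1].key,
        steps=tuple(Step(s.edge_id, not s.forward) for s in reversed(w.steps)),
    )


def merge_cycles(
    Gc: CircularChromosomeGraph, cycles: Sequence[Walk]
) -> tuple[Optional[Walk], list[Walk]]:
    """Splice all support-bearing cycles into one through shared vertices.

    At a shared vertex one cycle is inserted into the other, reversed when
    needed so the direction rule holds at both junctions.  Cycles carrying no
    support edge (lower bound or copy number >= 1) cannot occur at an
    optimum (they could be dropped to reduce W(f)); they are discarded and
    returned for logging.  Support cycles in more than one weakly connected
    component contradict the WCC precondition and raise.
    """
    eplus = _e_plus(Gc)
    keep = [c for c in cycles if any(s.edge_id in eplus for s in c.steps)]
    discarded = [c for c in cycles if not any(s.edge_id in eplus for s in c.steps)]
    for c in discarded:
        logger.warning("discarding support-free cycle of %d edges", len(c.steps))
    if not keep:
        return None, discarded
    pool = sorted(keep, key=lambda c: (min(s.edge_id for s in c.steps), c.steps))
    merged = pool.pop(0)
    while pool:
        mverts = {v.key for v in walk_vertices(Gc, merged)}
        hit = None
        for k, cand in enumerate(pool):
            shared = [v.key for v in walk_vertices(Gc, cand) if v.key in mverts]
            if shared:
                hit = (k, shared[0])
                break
        if hit is None:
            raise GraphError(
                "support cycles span multiple weakly connected components; "
                "the WCC precondition was violated"
            )
        k, vkey = hit
        other = _rotate_to(Gc, pool.pop(k), vkey)
        merged = _rotate_to(Gc, merged, vkey)
        d_first_m, d_last_m = _junction_dirs(Gc, merged)
        d_first_o, _ = _junction_dirs(Gc, other)
        if d_first_o != (MINUS if d_last_m == PLUS else PLUS):
            other = _reverse(Gc, other)
        merged = Walk(start=merged.start, steps=merged.steps + other.steps)
    ok, why = validate_path(Gc, merged)
    if not ok:  # pragma: no cover - construction is direction-correct
        raise GraphError(f"merged cycle violates the direction rule: {why}")
    return merged, discarded


def extract_chromosomes(
    Gc: CircularChromosomeGraph, merged: Optional[Walk]
) -> list[Walk]:
    """Cut the merged cycle at the terminal machinery.

    Dropping ``v_N``/``v_T`` and all terminal edges splits the cycle into
    maximal runs of base-graph edges; the terminal-edge directions force
    every run to start and end with a segment edge, i.e. to be a chromosome.
    """
    if merged is None or not merged.steps:
        return []
    term = {e.edge_id for e in Gc.E_N}
    if not any(s.edge_id in term for s in merged.steps):
        raise GraphError(
            "merged cycle visits no terminal edge; cannot cut into chromosomes"
        )
    # rotate so the cycle starts on a terminal edge
    first_term = next(i for i, s in enumerate(merged.steps) if s.edge_id in term)
    steps = merged.steps[first_term:] + merged.steps[:first_term]
    verts = walk_vertices(
        Gc, Walk(start=walk_vertices(Gc, merged)[first_term].key, steps=steps)
    )
    out: list[Walk] = []
    run: list[Step] = []
    run_start: Optional[tuple] = None
    for i, s in enumerate(steps):
        if s.edge_id in term:
            if run:
                out.append(Walk(start=run_start, steps=tuple(run)))
                run = []
            run_start = verts[i + 1].key
        else:
            run.append(s)
    if run:
        out.append(Walk(start=run_start, steps=tuple(run)))
    for c in out:
        if (
            Gc.edge(c.steps[0].edge_id).kind != KIND_S
            or Gc.edge(c.steps[-1].edge_id).kind != KIND_S
        ):  # pragma: no cover - direction bookkeeping guards this
            raise GraphError("extracted path is not bounded by segment edges")
    return [canonical_walk(Gc, c) for c in out]


def enumerate_extractions(
    Gc: CircularChromosomeGraph,
    canonical: dict[str, int],
    limit: Optional[int] = None,
) -> list[tuple[Walk, ...]]:
    """All chromosome multisets realizing a canonicalized circulation.

    A multiset realizes the flow when the visit count of every base edge
    equals its flow, chromosome endpoints consume the terminal-edge flows
    ``f(e_t(v))`` exactly, and the number of chromosomes is ``f(e_N)``.
    Multisets are deduplicated up to member reversal and order.  This is the
    source of solution multiplicity: one circulation, several karyotypes.
    """
    rem = {eid: canonical.get(eid, 0) for eid in Gc.base_edge_ids}
    ends = {
        vkey: canonical.get(Gc.terminal_edge_id(vkey), 0)
        for vkey in Gc.vertices
        if vkey not in (VN_KEY, VT_KEY)
    }
    n_chrom = canonical.get(EID_N, 0)
    found: dict[tuple, tuple[Walk, ...]] = {}
    chroms: list[Walk] = []
    s_edges = [e.edge_id for e in Gc.E_S]

    def search_between(prev_key) -> None:
        if limit is not None and len(found) >= limit:
            return
        if not any(rem.values()):
            if len(chroms) == n_chrom and not any(ends.values()):
                key = canonical_multiset_key(Gc, tuple(chroms))
                found.setdefault(key, tuple(chroms))
            return
        if len(chroms) >= n_chrom:
            return
        for sid in s_edges:
            if rem.get(sid, 0) < 1:
                continue
            e = Gc.edges[sid]
            for forward in (True, False):
                start = e.end(0 if forward else 1)
                if ends.get(start.key, 0) < 1:
                    continue
                ends[start.key] -= 1
                rem[sid] -= 1
                extend(
                    prev_key, start,
                    [Step(sid, forward)],
                    cur=e.end(1 if forward else 0),
                    exit_dir=e.dir(1 if forward else 0),
                )
                rem[sid] += 1
                ends[start.key] += 1

    def extend(prev_key, start_v: Vertex, steps: list[Step], cur: Vertex, exit_dir: str) -> None:
        if limit is not None and len(found) >= limit:
            return
        if Gc.edges[steps[-1].edge_id].kind == KIND_S and ends.get(cur.key, 0) >= 1:
            walk = Walk(start=start_v.key, steps=tuple(steps))
            ckey = canonical_walk(Gc, walk).steps
            if walk.steps == ckey and (prev_key is None or ckey >= prev_key):
                ends[cur.key] -= 1
                chroms.append(walk)
                search_between(ckey)
                chroms.pop()
                ends[cur.key] += 1
        need = MINUS if exit_dir == PLUS else PLUS
        for nid, end_idx in Gc.incident(cur.key):
            if rem.get(nid, 0) < 1:
                continue
            e = Gc.edges[nid]
            if e.is_self_loop():
                cands = [i for i in (0, 1) if e.dir(i) == need]
                if not cands:
                    continue
                i = cands[0]
            else:
                if e.dir(end_idx) != need:
                    continue
                i = end_idx
            rem[nid] -= 1
            steps.append(Step(nid, i == 0))
            extend(prev_key, start_v, steps, e.end(1 - i), e.dir(1 - i))
            steps.pop()
            rem[nid] += 1

    search_between(None)
    return [found[k] for k in sorted(found)]


# ---------------------------------------------------------------------------
# the end-to-end polynomial pipeline
# ---------------------------------------------------------------------------

def _walk_components(
    G: ChromosomeGraph,
    walk: Walk,
    coords: Optional[dict[str, tuple[str, int, int]]],
) -> list[tuple[str, int, int, str]]:
    """Oriented reference components of a chromosome (segment edges only).

    Forward traversal of a segment edge (left split vertex to right) is the
    ``+`` orientation.  Without genomic coordinates, breakpoint ordinals
    stand in for positions.
    """
    out = []
    for s in walk.steps:
        e = G.edge(s.edge_id)
        if e.kind != KIND_S:
            continue
        if coords is not None and s.edge_id in coords:
            chrom, start, end = coords[s.edge_id]
        else:
            parts = s.edge_id.split(":")
            chrom, j = ":".join(parts[1:-1]), parts[-1]
            start, end = int(j), int(j) + 1
        out.append((chrom, start, end, "+" if s.forward else "-"))
    return out


def solve_chrw(
    G: ChromosomeGraph,
    params: CostParams,
    V_W: Iterable,
    required: Optional[Iterable[str]] = None,
    repair: Optional[str] = None,
    all_optima: bool = False,
    seed: Optional[int] = None,
    segment_coords: Optional[dict[str, tuple[str, int, int]]] = None,
) -> SolutionReport:
    """The polynomial pipeline: circular graph, min-cost circulation,
    canonicalize, decompose, merge, extract; verify W(f) = W(C) + W_0.

    ``repair`` (``augment``/``drop``/``error``) fixes instances violating the
    weakly connected constraint before solving; without it a violating
    instance raises.  With ``all_optima`` the report's diagnostics carry
    every chromosome multiset realizing the optimal circulation.
    """
    work = G.copy()
    if required is not None:
        for eid in required:
            work.edge(eid).required = True
    v_w = frozenset(v.key if isinstance(v, Vertex) else tuple(v) for v in V_W)
    repair_log: list[str] = []
    if repair is not None:
        _, repair_log = repair_wcc(work, v_w, mode=repair)
    Gc = build_circular_graph(work, params, v_w)
    circ = solve_min_cost_circulation(Gc, seed=seed)
    canon = canonicalize(Gc, circ.flows)
    cycles = decompose_into_cycles(Gc, canon)
    merged, dropped = merge_cycles(Gc, cycles)
    C = extract_chromosomes(Gc, merged)

    for c in C:
        if not is_chromosome(Gc, c):  # pragma: no cover - validated upstream
            raise GraphError("pipeline produced a non-chromosome")
    if len(C) != canon.get(EID_N, 0):  # pragma: no cover
        raise GraphError("chromosome count disagrees with f(e_N)")

    W_C = solution_cost(work, C, params)
    if circ.W != W_C + Gc.W_0:  # pragma: no cover - the core exact identity
        raise GraphError(
            f"flow/chromosome cost identity violated: W(f)={circ.W}, "
            f"W(C)={W_C}, W_0={Gc.W_0}"
        )

    m: dict[str, int] = {}
    tr = 0
    for c in C:
        verts = walk_vertices(work, c)
        tr += sum(1 for v in (verts[0], verts[-1]) if v.klass == VM)
        for eid, k in walk_visits(c).items():
            m[eid] = m.get(eid, 0) + k
    residuals = [
        (e.edge_id, m.get(e.edge_id, 0), e.copy_number) for e in work.E_S
    ]
    diagnostics: dict = {
        "repair": repair_log,
        "discarded_cycles": len(dropped),
        "edge_budget": lemma1_edge_budget(work, params),
        "total_edges": sum(len(c.steps) for c in C),
    }
    optima = None
    if all_optima:
        optima = enumerate_extractions(Gc, canon)
        diagnostics["n_optimal_extractions"] = len(optima)
        diagnostics["optimal_extractions"] = [
            [_walk_components(work, c, segment_coords) for c in multiset]
            for multiset in optima
        ]

    return SolutionReport(
        chromosomes=[_walk_components(work, c, segment_coords) for c in C],
        lengths=[walk_length(work, c) for c in C],
        W_C=W_C,
        W_f=circ.W,
        W_0=Gc.W_0,
        n_chromosomes=len(C),
        truncations=tr,
        residuals=residuals,
        circulation=circ.flows,
        walks=C,
        diagnostics=diagnostics,
        optima=optima,
    )
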