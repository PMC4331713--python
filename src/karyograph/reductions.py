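"""Executable gadgets for the two hardness proofs, plus the
solution-multiplicity fixture.

These constructions double as exact test instances: the Hamiltonian-cycle
gadget has a zero-cost chromosome multiset iff the source digraph has a
Hamiltonian cycle, and the PARTITION gadget has a zero-cost length-bounded
multiset iff the integer multiset admits an equal-sum bipartition.  The
extraction helpers invert the reductions, turning zero-cost witnesses back
into combinatorial certificates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .graph_core import (
    KIND_L,
    KIND_R,
    MINUS,
    PLUS,
    BidirectedEdge,
    ChromosomeGraph,
    CostParams,
    GraphError,
    Step,
    Walk,
    cost as solution_cost,
    reverse_walk,
    walk_visits,
)
from .sv_io import _add_reference_chromosome

__all__ = [
    "DirectedGraphH",
    "PartitionInstance",
    "hc_to_chrp",
    "extract_hamiltonian",
    "partition_to_chrl",
    "extract_partition",
    "figure5_fixture",
]


@dataclass(frozen=True)
class DirectedGraphH:
    """A simple directed graph, the Hamiltonian-cycle instance."""

    n: int
    edges: tuple[tuple[int, int], ...]  # 1-based vertex pairs

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one vertex")
        for u, v in self.edges:
            if not (1 <= u <= self.n and 1 <= v <= self.n):
                raise ValueError(f"edge ({u},{v}) out of range")

    @staticmethod
    def cycle(n: int) -> "DirectedGraphH":
        return DirectedGraphH(n, tuple((i, i % n + 1) for i in range(1, n + 1)))


@dataclass(frozen=True)
class PartitionInstance:
    """Positive integers s(1..n); sought: a subset summing to half the total."""

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.values or any(v < 1 for v in self.values):
            raise ValueError("PARTITION needs positive integers")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def total(self) -> int:
        return sum(self.values)


def _hc_chrom(i: int) -> str:
    return f"h{i}"


def hc_to_chrp(H: DirectedGraphH) -> tuple[ChromosomeGraph, CostParams]:
    """The Hamiltonian-cycle gadget.

    Per digraph vertex: a three-segment mini-chromosome of unit-length
    segments with copy numbers (1,2,1) for vertex 1 and (0,1,0) otherwise.
    Per digraph arc (i', i): one aberrant edge from the downstream split
    vertex of i' 's middle segment into the upstream split vertex of i 's
    middle segment, so that traversing the aberrant edge corresponds to
    following the arc.  A single chromosome (n_N = 1, n_T = 0) can realize
    all copy numbers exactly iff it threads every middle segment once --
    i.e. iff the digraph has a Hamiltonian cycle; its length is then
    |V'| + 3 <= lambda.
    """
    G = ChromosomeGraph()
    for i in range(1, H.n + 1):
        copies = (1, 2, 1) if i == 1 else (0, 1, 0)
        _add_reference_chromosome(
            G, _hc_chrom(i), 2, [(cn, 1) for cn in copies]
        )
    for k, (src, dst) in enumerate(H.edges):
        G.add_edge(
            BidirectedEdge(
                edge_id=f"L:{k:03d}",
                end1=G.vertices[(_hc_chrom(src), 2, PLUS)], dir1=MINUS,
                end2=G.vertices[(_hc_chrom(dst), 1, MINUS)], dir2=PLUS,
                kind=KIND_L, copy_number=0, length=0,
            )
        )
    params = CostParams(
        n_N=1, n_T=0, Q_N=10, Q_T=10,
        lambdas=tuple([H.n + 3] * (H.n + 3)),
    )
    return G, params


def _orient_start(G: ChromosomeGraph, walk: Walk, first_edge: str) -> Optional[Walk]:
    if walk.steps and walk.steps[0].edge_id == first_edge:
        return walk
    rev = reverse_walk(G, walk)
    if rev.steps and rev.steps[0].edge_id == first_edge:
        return rev
    return None


def extract_hamiltonian(
    C: Sequence[Walk], H: DirectedGraphH, G: ChromosomeGraph,
    params: Optional[CostParams] = None,
) -> Optional[list[int]]:
    """Read a Hamiltonian cycle off a zero-cost gadget solution.

    The middle segments appear in the single chromosome in the order the
    cycle visits the digraph vertices (vertex 1 first and last).  Returns the
    vertex order, or None when the multiset is not a zero-cost witness.
    """
    if params is not None and solution_cost(G, C, params) > 0:
        return None
    if len(C) != 1:
        return None
    walk = _orient_start(G, C[0], f"S:{_hc_chrom(1)}:0")
    if walk is None:
        return None
    seq = []
    for s in walk.steps:
        parts = s.edge_id.split(":")
        if parts[0] == "S" and parts[2] == "1":
            seq.append(int(parts[1][1:]))
    if len(seq) != H.n + 1 or seq[0] != 1 or seq[-1] != 1:
        return None
    if sorted(seq[:-1]) != list(range(1, H.n + 1)):
        return None
    arcs = set(H.edges)
    for u, v in zip(seq, seq[1:]):
        if (u, v) not in arcs:
            return None
    return seq[:-1]


def _pt_chrom(i: int) -> str:
    return f"p{i}"


def partition_to_chrl(
    P: PartitionInstance,
) -> tuple[ChromosomeGraph, CostParams, list[tuple], list[str]]:
    """The PARTITION gadget: (graph, params, V_W, required edge ids).

    Per integer s(i): a block whose middle segment has length s(i) and copy
    number 2; a hub block (index n+1) whose zero-length middle segment is a
    routing station with copy number n+2.  Aberrant edges let the two hub
    chromosomes collect disjoint sets of middle segments; the uniform length
    cap 10*S_total forces the two collections to sum to S_total/2 each.  All
    adjacency edges are required and every natural chromosome end is a
    marker, so the instance satisfies the weakly connected constraint.  When
    S_total is odd, every length, cap and penalty is doubled so the hub
    segment length 9*S_total/2 stays integral (the reduction is preserved
    exactly).
    """
    n, S = P.n, P.total
    scale = 2 if S % 2 else 1
    G = ChromosomeGraph()
    for i in range(1, n + 1):
        s = P.values[i - 1]
        _add_reference_chromosome(
            G, _pt_chrom(i), 2,
            [(1, 9 * S * scale), (2, s * scale), (1, (S - s) * scale)],
        )
    _add_reference_chromosome(
        G, _pt_chrom(n + 1), 2,
        [(2, 9 * S * scale // 2), (n + 2, 0), (2, 5 * S * scale)],
    )
    hub = _pt_chrom(n + 1)
    k = 0
    for i in range(1, n + 1):
        ch = _pt_chrom(i)
        G.add_edge(
            BidirectedEdge(
                edge_id=f"L:{k:03d}",
                end1=G.vertices[(ch, 1, MINUS)], dir1=PLUS,
                end2=G.vertices[(hub, 2, PLUS)], dir2=MINUS,
                kind=KIND_L, copy_number=0, length=0, required=True,
            )
        )
        k += 1
        G.add_edge(
            BidirectedEdge(
                edge_id=f"L:{k:03d}",
                end1=G.vertices[(ch, 2, PLUS)], dir1=MINUS,
                end2=G.vertices[(hub, 1, MINUS)], dir2=PLUS,
                kind=KIND_L, copy_number=0, length=0, required=True,
            )
        )
        k += 1
    required = []
    for e in G.edges.values():
        if e.kind == KIND_L:
            required.append(e.edge_id)
        elif e.kind == KIND_R:
            e.required = True
            required.append(e.edge_id)
    params = CostParams(
        n_N=n + 2, n_T=0,
        Q_N=100 * S * scale, Q_T=100 * S * scale,
        lambdas=tuple([10 * S * scale] * (2 * (n + 2))),
    )
    v_w = sorted(
        v.key for v in G.vertices.values() if v.klass in ("V5", "V3")
    )
    return G, params, v_w, sorted(required)


def _find_pattern(walk: Walk, pattern: Sequence[str]) -> Optional[int]:
    ids = [s.edge_id for s in walk.steps]
    for i in range(len(ids) - len(pattern) + 1):
        if ids[i : i + len(pattern)] == list(pattern):
            return i
    return None


def extract_partition(
    C: Sequence[Walk],
    P: PartitionInstance,
    G: ChromosomeGraph,
    params: Optional[CostParams] = None,
) -> Optional[set[int]]:
    """Recover an equal-sum subset from a zero-cost gadget solution.

    First normalizes the multiset: whenever the chromosome opening block i
    does not also close it, the closing tail lives on another chromosome and
    the two are rerouted at the (unique-copy-surplus) middle segment -- the
    swap preserves all visit counts and both lengths.  After normalization
    the block chromosomes are canonical and the subset is read off one hub
    chromosome's middle-segment visits.
    """
    if params is not None and solution_cost(G, C, params) > 0:
        return None
    n = P.n
    work = list(C)
    for i in range(1, n + 1):
        ch = _pt_chrom(i)
        open_pat = [f"S:{ch}:0", f"R:{ch}:1", f"S:{ch}:1"]
        close_pat = [f"S:{ch}:1", f"R:{ch}:2", f"S:{ch}:2"]
        a_idx = next(
            (k for k, c in enumerate(work)
             if any(s.edge_id == f"S:{ch}:0" for s in c.steps)),
            None,
        )
        if a_idx is None:
            return None
        ca = _orient_start(G, work[a_idx], f"S:{ch}:0")
        if ca is None or _find_pattern(ca, open_pat) != 0:
            return None
        if [s.edge_id for s in ca.steps[3:5]] == close_pat[1:]:
            work[a_idx] = ca
            continue  # already canonical: S0 R1 S1 R2 S2
        b_idx = next(
            (k for k, c in enumerate(work)
             if k != a_idx and any(s.edge_id == f"S:{ch}:2" for s in c.steps)),
            None,
        )
        if b_idx is None:
            return None
        cb = work[b_idx]  # orient cb to end with S2
        if cb.steps[-1].edge_id != f"S:{ch}:2":
            cb = reverse_walk(G, cb)
        if cb.steps[-1].edge_id != f"S:{ch}:2":
            return None
        j = _find_pattern(cb, close_pat)
        if j is None or j + 3 != len(cb.steps):
            return None
        # reroute: ca = S0 R1 S1 | p1 ; cb = p2 | S1 R2 S2
        p1 = ca.steps[3:]
        p2 = cb.steps[:j]
        new_a = Walk(start=ca.start, steps=ca.steps[:3] + tuple(cb.steps[j + 1 :]))
        new_b = Walk(start=cb.start, steps=p2 + (cb.steps[j],) + p1)
        work[a_idx] = new_a
        work[b_idx] = new_b
    hub0 = f"S:{_pt_chrom(n + 1)}:0"
    hubs = [c for c in work if any(s.edge_id == hub0 for s in c.steps)]
    if not hubs:
        return None
    visits = walk_visits(hubs[0])
    subset = {
        i for i in range(1, n + 1) if visits.get(f"S:{_pt_chrom(i)}:1", 0) > 0
    }
    if 2 * sum(P.values[i - 1] for i in subset) != P.total:
        return None
    return subset


def figure5_fixture() -> tuple[ChromosomeGraph, CostParams, list[tuple], list[str]]:
    """A small two-chromosome instance whose optimal circulation admits
    exactly two chromosome multisets: the aberrant edges and the reference
    route through the second chromosome's middle segment can be assigned to
    either karyotype.  Returns (graph, params, V_W, required edge ids)."""
    G = ChromosomeGraph()
    _add_reference_chromosome(G, "chr1", 2, [(1, 10), (0, 10), (1, 10)])
    _add_reference_chromosome(G, "chr2", 2, [(1, 10), (2, 10), (1, 10)])
    G.add_edge(
        BidirectedEdge(
            edge_id="L:000",
            end1=G.vertices[("chr1", 1, PLUS)], dir1=MINUS,
            end2=G.vertices[("chr2", 1, MINUS)], dir2=PLUS,
            kind=KIND_L, copy_number=0, length=0, required=True,
        )
    )
    G.add_edge(
        BidirectedEdge(
            edge_id="L:001",
            end1=G.vertices[("chr2", 2, PLUS)], dir1=MINUS,
            end2=G.vertices[("chr1", 2, MINUS)], dir2=PLUS,
            kind=KIND_L, copy_number=0, length=0, required=True,
        )
    )
    required = ["L:000", "L:001", "R:chr2:1", "R:chr2:2"]
    for eid in ("R:chr2:1", "R:chr2:2"):
        G.edge(eid).required = True
    params = CostParams(n_N=2, n_T=0, Q_N=100, Q_T=100)
    v_w = [
        ("chr1", 0, MINUS), ("chr1", 3, PLUS),
        ("chr2", 0, MINUS), ("chr2", 3, PLUS),
    ]
    return G, params, v_w, required
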