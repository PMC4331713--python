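"""Bidirected chromosome-graph domain types and the solution cost function.

A *chromosome graph* models a rearranged (target) genome against a reference.
Every reference breakpoint ``j`` of reference chromosome ``i`` is split into
two vertices ``v(i,j,-)`` / ``v(i,j,+)``; a chromosome start is the single
vertex ``v(i,0,-)`` (class ``V5``) and a chromosome end is ``v(i,n_i+1,+)``
(class ``V3``).  Edges come in three classes:

* ``S`` -- reference segments between consecutive breakpoints, carrying an
  experimentally estimated copy number ``n(e)`` and a base-pair length ``|e|``;
* ``R`` -- reference adjacencies across a breakpoint (the "keep reading the
  reference" edges);
* ``L`` -- aberrant adjacencies observed in the target genome.

Each edge end carries its own ``+``/``-`` direction (a bidirected graph).  A
walk must leave every interior vertex with the direction opposite to the one
it entered with; this single rule is what prevents two adjacency edges from
being glued back-to-back without an intervening segment.  A *chromosome* is a
direction-valid walk whose first and last edges are segment (``S``) edges.

A candidate target genome is a multiset ``C`` of chromosomes.  Its cost

    W(C) = Q_N * | |C| - n_N |  +  Q_T * | Tr(C) - n_T |
           + sum_{e in E_S} |e| * | m(C,e) - n(e) |

penalizes deviations from the observed chromosome count ``n_N``, truncation
count ``n_T`` (chromosome endpoints at internal breakpoints), and per-segment
copy numbers.  All quantities are exact integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Optional, Sequence

__all__ = [
    "PLUS",
    "MINUS",
    "Vertex",
    "BidirectedEdge",
    "Step",
    "Walk",
    "ChromosomeGraph",
    "ChromosomeSet",
    "CostParams",
    "PathViolation",
    "validate_path",
    "is_chromosome",
    "reverse_walk",
    "canonical_walk",
    "canonical_multiset_key",
    "walk_length",
    "walk_visits",
    "walk_vertices",
    "solution_summary",
    "cost",
    "lambda_feasible",
]

PLUS = "+"
MINUS = "-"

# vertex classes
V5 = "V5"
V3 = "V3"
VM = "VM"
VN = "VN"
VT = "VT"

# edge kinds
KIND_S = "S"
KIND_L = "L"
KIND_R = "R"
KIND_N = "N"  # terminal edges of the circular graph
KIND_D = "D"  # reverse-partner edges of the circular graph


def _opp(d: str) -> str:
    return MINUS if d == PLUS else PLUS


@dataclass(frozen=True, order=True)
class Vertex:
    """A split breakpoint vertex (or a terminal vertex of the circular graph).

    ``chrom`` is the reference chromosome name (or a novel-insertion id);
    ``index`` is the breakpoint ordinal ``j`` (0 = chromosome start,
    ``n_i + 1`` = chromosome end); ``side`` is which half of the split the
    vertex is.
    """

    chrom: str
    index: int
    side: str  # "-" or "+" ("" for VN/VT)
    klass: str = VM

    @property
    def key(self) -> tuple:
        return (self.chrom, self.index, self.side)

    def __repr__(self) -> str:  # compact, used in violation messages
        if self.klass in (VN, VT):
            return f"v[{self.klass}]"
        return f"v[{self.chrom},{self.index},{self.side}]"


@dataclass(eq=False)
class BidirectedEdge:
    """An edge with an independent ``+``/``-`` direction at each end.

    ``length`` doubles as the unit cost weight in the circulation objective
    (for the terminal edges ``e_N``/``e_T`` it holds ``Q_N``/``Q_T``).
    ``lower``/``upper`` are flow bounds used only on circular graphs.
    """

    edge_id: str
    end1: Vertex
    dir1: str
    end2: Vertex
    dir2: str
    kind: str
    copy_number: int = 0
    length: int = 0
    required: bool = False
    lower: int = 0
    upper: Optional[int] = None

    def __hash__(self) -> int:
        return id(self)

    @property
    def ends(self) -> tuple[Vertex, Vertex]:
        return (self.end1, self.end2)

    @property
    def dirs(self) -> tuple[str, str]:
        return (self.dir1, self.dir2)

    def end(self, i: int) -> Vertex:
        return self.end1 if i == 0 else self.end2

    def dir(self, i: int) -> str:
        return self.dir1 if i == 0 else self.dir2

    def is_self_loop(self) -> bool:
        return self.end1.key == self.end2.key

    def __repr__(self) -> str:
        return (
            f"<{self.dir1}{self.end1!r},{self.dir2}{self.end2!r},"
            f"{self.copy_number},{self.length}>#{self.edge_id}"
        )


class Step(NamedTuple):
    """One traversal step: an edge and the end it was entered through.

    ``forward`` means the edge was entered at ``end1`` and exited at ``end2``.
    """

    edge_id: str
    forward: bool


@dataclass(frozen=True)
class Walk:
    """An alternating vertex/edge sequence, stored as a start vertex key plus
    traversal steps.  Immutable and hashable, so walks can live in multisets.
    """

    start: tuple  # vertex key
    steps: tuple[Step, ...] = ()

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def edge_ids(self) -> tuple[str, ...]:
        return tuple(s.edge_id for s in self.steps)


Path = Walk  # a chromosome is a Walk whose first/last edges are S-edges


class GraphError(ValueError):
    """Raised for structurally invalid graphs or unknown references."""


@dataclass(frozen=True)
class PathViolation:
    position: int
    reason: str

    def __str__(self) -> str:
        return f"at step {self.position}: {self.reason}"


class ChromosomeGraph:
    """Container for vertices and bidirected edges, partitioned by edge kind.

    Maintains per-reference-chromosome breakpoint counts ``n_i`` and an
    incidence index for walk validation and flow decomposition.
    """

    def __init__(self) -> None:
        self.vertices: dict[tuple, Vertex] = {}
        self.edges: dict[str, BidirectedEdge] = {}
        self.chrom_order: list[str] = []
        self.n_breaks: dict[str, int] = {}
        self._incident: dict[tuple, list[tuple[str, int]]] = {}

    # -- construction -----------------------------------------------------
    def add_vertex(self, v: Vertex) -> Vertex:
        existing = self.vertices.get(v.key)
        if existing is not None:
            if existing != v:
                raise GraphError(f"conflicting vertex redefinition at {v.key}")
            return existing
        self.vertices[v.key] = v
        self._incident[v.key] = []
        return v

    def add_edge(self, e: BidirectedEdge) -> BidirectedEdge:
        if e.edge_id in self.edges:
            raise GraphError(f"duplicate edge id {e.edge_id!r}")
        for end in e.ends:
            if end.key not in self.vertices:
                raise GraphError(f"edge {e.edge_id!r} references unknown vertex {end!r}")
        self.edges[e.edge_id] = e
        self._incident[e.end1.key].append((e.edge_id, 0))
        self._incident[e.end2.key].append((e.edge_id, 1))
        return e

    def register_chromosome(self, chrom: str, n_breakpoints: int) -> None:
        if chrom in self.n_breaks:
            raise GraphError(f"chromosome {chrom!r} registered twice")
        self.chrom_order.append(chrom)
        self.n_breaks[chrom] = n_breakpoints

    # -- accessors --------------------------------------------------------
    def edge(self, edge_id: str) -> BidirectedEdge:
        try:
            return self.edges[edge_id]
        except KeyError:
            raise GraphError(f"unknown edge id {edge_id!r}") from None

    def incident(self, vkey: tuple) -> list[tuple[str, int]]:
        """Edge ends at a vertex as (edge_id, end_index), sorted by edge id."""
        return sorted(self._incident.get(vkey, ()))

    def edges_of_kind(self, *kinds: str) -> list[BidirectedEdge]:
        return [self.edges[k] for k in sorted(self.edges) if self.edges[k].kind in kinds]

    @property
    def E_S(self) -> list[BidirectedEdge]:
        return self.edges_of_kind(KIND_S)

    @property
    def E_L(self) -> list[BidirectedEdge]:
        return self.edges_of_kind(KIND_L)

    @property
    def E_R(self) -> list[BidirectedEdge]:
        return self.edges_of_kind(KIND_R)

    @property
    def N_C(self) -> int:
        return len(self.chrom_order)

    @property
    def N_A(self) -> int:
        return len(self.edges_of_kind(KIND_L))

    def copy(self) -> "ChromosomeGraph":
        g = ChromosomeGraph()
        for v in self.vertices.values():
            g.add_vertex(v)
        for eid in sorted(self.edges):
            e = self.edges[eid]
            g.add_edge(
                BidirectedEdge(
                    edge_id=e.edge_id, end1=e.end1, dir1=e.dir1, end2=e.end2,
                    dir2=e.dir2, kind=e.kind, copy_number=e.copy_number,
                    length=e.length, required=e.required, lower=e.lower,
                    upper=e.upper,
                )
            )
        g.chrom_order = list(self.chrom_order)
        g.n_breaks = dict(self.n_breaks)
        return g

    def __repr__(self) -> str:
        return (
            f"ChromosomeGraph(|V|={len(self.vertices)}, "
            f"|E_S|={len(self.E_S)}, |E_L|={len(self.E_L)}, |E_R|={len(self.E_R)})"
        )


ChromosomeSet = tuple  # multiset of Walk, stored as a tuple


# ---------------------------------------------------------------------------
# walk mechanics
# ---------------------------------------------------------------------------

def walk_vertices(G: ChromosomeGraph, walk: Walk) -> list[Vertex]:
    """The alternating vertex sequence v_1 .. v_{l+1} of a walk."""
    if walk.start not in G.vertices:
        raise GraphError(f"unknown start vertex {walk.start}")
    seq = [G.vertices[walk.start]]
    cur = walk.start
    for step in walk.steps:
        e = G.edge(step.edge_id)
        entry = e.end1 if step.forward else e.end2
        exit_ = e.end2 if step.forward else e.end1
        if entry.key != cur:
            raise GraphError(
                f"step {step.edge_id} entered at {entry!r}, walk is at {cur}"
            )
        seq.append(exit_)
        cur = exit_.key
    return seq


def _step_entry_dir(e: BidirectedEdge, step: Step) -> str:
    return e.dir1 if step.forward else e.dir2


def _step_exit_dir(e: BidirectedEdge, step: Step) -> str:
    return e.dir2 if step.forward else e.dir1


def validate_path(
    G: ChromosomeGraph, walk: Walk
) -> tuple[bool, Optional[PathViolation]]:
    """Check the bidirected direction-alternation rule along a walk.

    Returns ``(True, None)`` for a valid path, otherwise ``(False, violation)``
    naming the first offending step.  Unknown vertices or edges raise
    :class:`GraphError`.
    """
    if walk.start not in G.vertices:
        raise GraphError(f"unknown start vertex {walk.start}")
    cur = walk.start
    prev_exit_dir: Optional[str] = None
    for pos, step in enumerate(walk.steps):
        e = G.edge(step.edge_id)
        entry = e.end1 if step.forward else e.end2
        if entry.key != cur:
            return False, PathViolation(
                pos, f"edge {step.edge_id} does not attach to {cur} at its entry end"
            )
        entry_dir = _step_entry_dir(e, step)
        if prev_exit_dir is not None and entry_dir != _opp(prev_exit_dir):
            return False, PathViolation(
                pos,
                f"direction rule violated at {cur}: left previous edge with "
                f"'{prev_exit_dir}', entered {step.edge_id} with '{entry_dir}'",
            )
        prev_exit_dir = _step_exit_dir(e, step)
        cur = (e.end2 if step.forward else e.end1).key
    return True, None


def is_chromosome(G: ChromosomeGraph, walk: Walk) -> bool:
    """True iff the walk is a valid path whose first and last edges are S-edges."""
    ok, violation = validate_path(G, walk)
    if not ok:
        raise GraphError(f"not a valid path: {violation}")
    if not walk.steps:
        return False
    first = G.edge(walk.steps[0].edge_id)
    last = G.edge(walk.steps[-1].edge_id)
    return first.kind == KIND_S and last.kind == KIND_S


def is_cycle(G: ChromosomeGraph, walk: Walk) -> bool:
    """A cycle returns to its start vertex and closes with opposite directions."""
    ok, _ = validate_path(G, walk)
    if not ok or not walk.steps:
        return False
    verts = walk_vertices(G, walk)
    if verts[0].key != verts[-1].key:
        return False
    first = G.edge(walk.steps[0].edge_id)
    last = G.edge(walk.steps[-1].edge_id)
    return _step_entry_dir(first, walk.steps[0]) == _opp(
        _step_exit_dir(last, walk.steps[-1])
    )


def reverse_walk(G: ChromosomeGraph, walk: Walk) -> Walk:
    """The same walk traversed from the other end (DNA strands are unordered)."""
    verts = walk_vertices(G, walk)
    steps = tuple(Step(s.edge_id, not s.forward) for s in reversed(walk.steps))
    return Walk(start=verts[-1].key, steps=steps)


def canonical_walk(G: ChromosomeGraph, walk: Walk) -> Walk:
    """Canonical orientation: the lexicographically smaller of the two step
    sequences of the walk and its reversal, comparing edge ids and preferring
    forward traversal on ties."""
    rev = reverse_walk(G, walk)
    key = lambda w: tuple((s.edge_id, not s.forward) for s in w.steps)
    return min(walk, rev, key=key)


def canonical_multiset_key(G: ChromosomeGraph, C: Iterable[Walk]) -> tuple:
    """Order-free, orientation-free key identifying a chromosome multiset."""
    return tuple(sorted(canonical_walk(G, c).steps for c in C))


def walk_length(G: ChromosomeGraph, walk: Walk) -> int:
    return sum(G.edge(s.edge_id).length for s in walk.steps)


def walk_visits(walk: Walk) -> dict[str, int]:
    m: dict[str, int] = {}
    for s in walk.steps:
        m[s.edge_id] = m.get(s.edge_id, 0) + 1
    return m


# ---------------------------------------------------------------------------
# solution summaries and cost
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostParams:
    """Experimental expectations and penalty weights.

    ``n_N``  -- observed number of chromosomes in the target genome (>= 1).
    ``n_T``  -- observed number of chromosomal truncations.
    ``Q_N``, ``Q_T`` -- penalty per unit deviation in chromosome / truncation
    count; tuned so that count errors outweigh plausible segment-length noise.
    ``U``    -- strict upper bound on n_N, n_T and every copy number; only
    used for the solution-size budget (defaults to one above the largest
    observed value when omitted).
    ``lambdas`` -- optional per-chromosome length caps (ignored by the
    polynomial pipeline, enforced by the length-constrained brute force).
    """

    n_N: int
    n_T: int = 0
    Q_N: int = 1
    Q_T: int = 1
    U: Optional[int] = None
    lambdas: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.n_N < 1:
            raise ValueError("n_N must be >= 1")
        if self.n_T < 0:
            raise ValueError("n_T must be >= 0")
        if self.Q_N <= 0 or self.Q_T <= 0:
            raise ValueError("Q_N and Q_T must be positive")
        if self.lambdas is not None:
            object.__setattr__(self, "lambdas", tuple(int(x) for x in self.lambdas))
            if len(self.lambdas) < self.n_N:
                raise ValueError("need at least n_N length caps (N_L >= n_N)")

    @property
    def N_L(self) -> Optional[int]:
        return None if self.lambdas is None else len(self.lambdas)

    def effective_U(self, G: ChromosomeGraph) -> int:
        if self.U is not None:
            return self.U
        biggest = max([self.n_N, self.n_T] + [e.copy_number for e in G.E_S], default=0)
        return biggest + 1


def solution_summary(
    G: ChromosomeGraph, C: Sequence[Walk]
) -> tuple[int, int, dict[str, int]]:
    """(|C|, Tr(C), m(C,.)) for a multiset of chromosomes.

    ``Tr`` counts endpoint *incidences* in V_M: a chromosome with both ends at
    internal breakpoints contributes 2.  Unvisited edges get m = 0.
    """
    m: dict[str, int] = {e.edge_id: 0 for e in G.edges.values()}
    tr = 0
    for c in C:
        if not is_chromosome(G, c):
            raise GraphError(f"member is not a chromosome: {c}")
        verts = walk_vertices(G, c)
        for endpoint in (verts[0], verts[-1]):
            if endpoint.klass == VM:
                tr += 1
        for s in c.steps:
            m[s.edge_id] += 1
    return len(C), tr, m


def cost(
    G: ChromosomeGraph,
    C: Sequence[Walk],
    params: CostParams,
    summary: Optional[tuple[int, int, Mapping[str, int]]] = None,
) -> int:
    """W(C): count penalties plus length-weighted copy-number deviations.

    Only segment edges contribute to the third term; adjacency edges have
    zero length and zero copy number by construction.
    """
    if summary is None:
        size, tr, m = solution_summary(G, C)
    else:
        size, tr, m = summary
    w = params.Q_N * abs(size - params.n_N) + params.Q_T * abs(tr - params.n_T)
    for e in G.E_S:
        w += e.length * abs(m.get(e.edge_id, 0) - e.copy_number)
    return w


def lambda_feasible(
    G: ChromosomeGraph,
    C: Sequence[Walk],
    params: CostParams,
    lengths: Optional[Sequence[int]] = None,
) -> bool:
    """Can chromosomes be injectively assigned to length caps?

    Feasibility is decided by comparing lengths and caps sorted in descending
    order (an exchange argument shows this is equivalent to the existence of
    an injective assignment with each |c| <= lambda).  With no caps configured
    every multiset is feasible.
    """
    if params.lambdas is None:
        return True
    if lengths is None:
        lengths = [walk_length(G, c) for c in C]
    if len(lengths) > len(params.lambdas):
        return False
    caps = sorted(params.lambdas, reverse=True)
    for ln, cap in zip(sorted(lengths, reverse=True), caps):
        if ln > cap:
            return False
    return True
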