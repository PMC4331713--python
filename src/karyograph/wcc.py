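"""Weakly connected components and the weakly connected constraint (WCC).

The polynomial-time pipeline needs every flow-bearing part of the graph to be
reachable from a known chromosome end: after decomposing a circulation into
cycles, the cycles are merged through shared vertices, which is only possible
when all support edges live in one weakly connected component anchored at a
marked end vertex.

``V_W`` is the set of vertices known to be chromosome ends in the target
genome (natural reference ends that survive, plus detected truncation
points).  ``E_W`` is the support edge set: segment edges with copy number
>= 1 plus adjacency edges marked *required*.  The instance satisfies WCC when
every component of the ``E_W``-induced subgraph (directions ignored) contains
a ``V_W`` vertex.

Components are computed over the *edge-induced* subgraph: vertices touching
no ``E_W`` edge cannot host flow and are vacuously good.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .graph_core import (
    KIND_L,
    KIND_R,
    KIND_S,
    ChromosomeGraph,
    Vertex,
)

__all__ = [
    "WccComponent",
    "WccReport",
    "default_E_W",
    "weakly_connected_components",
    "check_wcc",
    "repair_wcc",
]


def _vkeys(V_W: Iterable) -> frozenset:
    keys = set()
    for v in V_W:
        keys.add(v.key if isinstance(v, Vertex) else tuple(v))
    return frozenset(keys)


def default_E_W(G: ChromosomeGraph) -> frozenset[str]:
    """E_W = {e in E_S | n(e) >= 1} + {required e in E_L + E_R}."""
    out = set()
    for e in G.edges.values():
        if e.kind == KIND_S and e.copy_number >= 1:
            out.add(e.edge_id)
        elif e.kind in (KIND_L, KIND_R) and e.required:
            out.add(e.edge_id)
    return frozenset(out)


@dataclass(frozen=True)
class WccComponent:
    vertices: frozenset
    edge_ids: frozenset
    good: bool


@dataclass(frozen=True)
class WccReport:
    components: tuple[WccComponent, ...]
    satisfied: bool

    @property
    def bad_components(self) -> tuple[WccComponent, ...]:
        return tuple(c for c in self.components if not c.good)

    def to_dict(self) -> dict:
        return {
            "satisfied": self.satisfied,
            "n_components": len(self.components),
            "components": [
                {
                    "good": c.good,
                    "vertices": sorted(map(list, c.vertices)),
                    "edges": sorted(c.edge_ids),
                }
                for c in self.components
            ],
        }


def _undirected_view(G: ChromosomeGraph, edge_ids: Iterable[str]) -> nx.MultiGraph:
    g = nx.MultiGraph()
    for eid in sorted(edge_ids):
        e = G.edge(eid)
        g.add_edge(e.end1.key, e.end2.key, key=eid)
    return g


def weakly_connected_components(
    G: ChromosomeGraph, edge_ids: Iterable[str]
) -> list[tuple[frozenset, frozenset]]:
    """Maximal components of the edge-induced subgraph, directions ignored.

    Returns (vertex-key set, edge-id set) pairs, sorted by smallest edge id
    so the partition is independent of iteration order.
    """
    edge_ids = set(edge_ids)
    unknown = edge_ids - set(G.edges)
    if unknown:
        raise ValueError(f"unknown edge ids in E': {sorted(unknown)}")
    g = _undirected_view(G, edge_ids)
    comps = []
    for nodes in nx.connected_components(g):
        eids = frozenset(
            k for u, v, k in g.subgraph(nodes).edges(keys=True)
        )
        comps.append((frozenset(nodes), eids))
    comps.sort(key=lambda c: min(c[1]))
    return comps


def check_wcc(
    G: ChromosomeGraph,
    V_W: Iterable,
    E_W: Optional[Iterable[str]] = None,
) -> WccReport:
    """Is every edge-bearing support component anchored at a V_W vertex?"""
    vkeys = _vkeys(V_W)
    if E_W is None:
        E_W = default_E_W(G)
    comps = []
    satisfied = True
    for verts, eids in weakly_connected_components(G, E_W):
        good = bool(verts & vkeys)
        satisfied = satisfied and good
        comps.append(WccComponent(verts, eids, good))
    return WccReport(tuple(comps), satisfied)


def _bfs_to_good(
    G: ChromosomeGraph, sources: list, targets: set
) -> Optional[list[str]]:
    """Shortest undirected edge path (by edge count) from any source vertex to
    any target vertex, over the full graph.  Deterministic: sources and
    neighbor edges are expanded in sorted order."""
    parent: dict = {s: None for s in sources}
    frontier = list(sources)
    while frontier:
        nxt = []
        for u in frontier:
            for eid, end_idx in G.incident(u):
                e = G.edge(eid)
                w = e.end(1 - end_idx).key
                if w in parent:
                    continue
                parent[w] = (u, eid)
                if w in targets:
                    path = []
                    cur = w
                    while parent[cur] is not None:
                        cur, peid = parent[cur]
                        path.append(peid)
                    path.reverse()
                    return path
                nxt.append(w)
        frontier = sorted(nxt)
    return None


def repair_wcc(
    G: ChromosomeGraph,
    V_W: Iterable,
    E_W: Optional[Iterable[str]] = None,
    mode: str = "augment",
) -> tuple[frozenset[str], list[str]]:
    """Modify the instance in place until it satisfies WCC.

    ``augment`` connects each bad component to a good one along a shortest
    undirected path, marking traversed segment edges as present (n(e) >= 1)
    and traversed adjacency edges as required -- the algorithmic stand-in for
    experimentally confirming those edges.  ``drop`` clears copy numbers and
    required flags on every edge of each bad component.  ``error`` raises.

    Returns the repaired E_W and a human-readable change log.  If a bad
    component has no undirected path to a good one, augmentation falls back
    to dropping it (with a log entry).
    """
    if mode not in ("augment", "drop", "error"):
        raise ValueError(f"unknown repair mode {mode!r}")
    vkeys = _vkeys(V_W)
    ew = set(default_E_W(G) if E_W is None else E_W)
    log: list[str] = []

    def drop_component(comp: WccComponent) -> None:
        for eid in sorted(comp.edge_ids):
            e = G.edge(eid)
            if e.kind == KIND_S:
                if e.copy_number != 0:
                    log.append(f"drop: set n({eid}) = 0")
                e.copy_number = 0
            else:
                if e.required:
                    log.append(f"drop: cleared required flag on {eid}")
                e.required = False
            ew.discard(eid)

    while True:
        report = check_wcc(G, vkeys, ew)
        if report.satisfied:
            return frozenset(ew), log
        if mode == "error":
            raise ValueError(
                f"WCC violated: {len(report.bad_components)} bad component(s)"
            )
        bad = report.bad_components[0]
        if mode == "drop":
            drop_component(bad)
            continue
        good_vertices = set()
        for comp in report.components:
            if comp.good:
                good_vertices |= comp.vertices
        good_vertices |= vkeys  # V_W vertices outside any support component
        path = _bfs_to_good(G, sorted(bad.vertices), good_vertices)
        if path is None:
            log.append("augment: no connecting path; falling back to drop")
            drop_component(bad)
            continue
        for eid in path:
            e = G.edge(eid)
            if e.kind == KIND_S:
                if e.copy_number < 1:
                    log.append(f"augment: set n({eid}) = 1")
                    e.copy_number = 1
            else:
                if not e.required:
                    log.append(f"augment: marked {eid} required")
                    e.required = True
            ew.add(eid)
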