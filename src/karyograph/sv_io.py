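"""Parsing of SV datasets, graph construction, and solution output.

Input files (all plain text):

* segments TSV: ``chrom  start  end  copy_number`` -- 0-based half-open
  reference intervals with integer copy numbers, tiling each reference
  chromosome contiguously;
* adjacencies TSV (BEDPE-flavoured): ``chrom1 pos1 side1 chrom2 pos2 side2
  required support`` -- one aberrant junction per row, each breakend given by
  a between-base position and a side (``R``: the segment to the right of the
  position takes part in the junction, ``L``: the segment to the left);
* config YAML/JSON: ``n_N, n_T, Q_N, Q_T, U, lambdas, end_markers,
  required_reference_adjacencies, novel_insertions``.

Breakpoints are unified across sources (interior segment boundaries,
adjacency positions, end markers, required reference adjacencies); segments
are auto-split at new breakpoints and inherit their copy number.  The breakend
side fixes graph attachment: ``R`` at position p attaches to the ``-`` split
vertex with direction ``+``, ``L`` to the ``+`` split vertex with direction
``-`` (the segment that "stretches toward" the next breakpoint).

Outputs: an AGP v2.1 file describing each reconstructed chromosome as
ordered, oriented reference components, a JSON report, and a TSV circulation
dump.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from .graph_core import (
    KIND_L,
    KIND_R,
    KIND_S,
    MINUS,
    PLUS,
    V3,
    V5,
    VM,
    BidirectedEdge,
    ChromosomeGraph,
    CostParams,
    GraphError,
    Vertex,
    Walk,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Breakend",
    "NovelInsertion",
    "SVDataset",
    "SolutionReport",
    "read_sv_dataset",
    "build_prototype_graph",
    "build_chromosome_graph",
    "attach_novel_insertions",
    "write_solution",
    "parse_agp",
    "graph_to_dict",
    "graph_from_dict",
]

SIDE_R = "R"  # junction uses the segment to the right of pos
SIDE_L = "L"  # junction uses the segment to the left of pos

NOVEL_PREFIX = "ins:"


@dataclass(frozen=True, order=True)
class Breakend:
    """One side of a junction: a between-base position plus the side of the
    participating segment."""

    chrom: str
    pos: int
    side: str

    def __post_init__(self) -> None:
        if self.side not in (SIDE_R, SIDE_L):
            raise ValueError(f"breakend side must be R or L, not {self.side!r}")


@dataclass(frozen=True)
class Adjacency:
    bnd1: Breakend
    bnd2: Breakend
    required: bool = False
    support: int = 0


@dataclass(frozen=True)
class NovelInsertion:
    """A fragment absent from the reference, modelled as its own mini
    chromosome (named ``ins:<id>``) connected to the main graph by aberrant
    adjacencies."""

    insertion_id: str
    length: int
    copy_number: int = 1
    breakpoints: tuple[int, ...] = ()
    adjacencies: tuple[Adjacency, ...] = ()
    copy_numbers: Optional[tuple[int, ...]] = None  # per internal segment
    required_breakpoints: tuple[int, ...] = ()  # internal ref-adjacencies to force

    @property
    def chrom(self) -> str:
        return NOVEL_PREFIX + self.insertion_id

    def segment_copy_numbers(self) -> list[int]:
        n_segs = len(self.breakpoints) + 1
        if self.copy_numbers is not None:
            if len(self.copy_numbers) != n_segs:
                raise GraphError(
                    f"novel insertion {self.insertion_id}: expected {n_segs} "
                    "per-segment copy numbers"
                )
            return list(self.copy_numbers)
        return [self.copy_number] * n_segs


@dataclass
class SVDataset:
    """Unified SV input: tiled segments, resolved adjacencies, config.

    After construction, every chromosome holds sorted breakpoint positions
    ``bp[chrom]`` strictly inside its extent, per-segment copy numbers and
    the adjacency/marker attachments resolved to breakpoint indices.
    """

    extents: dict[str, tuple[int, int]]
    breakpoints: dict[str, list[int]]
    copy_numbers: dict[str, list[int]]  # per chrom: n_i + 1 values
    adjacencies: list[Adjacency]
    params: CostParams
    end_markers: tuple[Breakend, ...] = ()
    required_ref_adjacencies: tuple[tuple[str, int], ...] = ()
    novel_insertions: tuple[NovelInsertion, ...] = ()

    # -- resolved views ---------------------------------------------------
    def chrom_order(self) -> list[str]:
        return sorted(self.extents)

    def n_breakpoints(self, chrom: str) -> int:
        return len(self.breakpoints[chrom])

    def positions(self, chrom: str) -> list[int]:
        """Boundary positions [start, bp_1, ..., bp_n, end]."""
        s, e = self.extents[chrom]
        return [s] + list(self.breakpoints[chrom]) + [e]

    def breakpoint_index(self, chrom: str, pos: int) -> int:
        """Index j of a boundary position (0 = start, n_i + 1 = end)."""
        try:
            return self.positions(chrom).index(pos)
        except ValueError:
            raise GraphError(
                f"position {chrom}:{pos} is not a breakpoint or chromosome end"
            ) from None

    def segment_coords(self) -> dict[str, tuple[str, int, int]]:
        """Reference interval of every segment edge, keyed by edge id."""
        coords = {}
        for chrom in self.chrom_order():
            pos = self.positions(chrom)
            for j in range(len(pos) - 1):
                coords[f"S:{chrom}:{j}"] = (chrom, pos[j], pos[j + 1])
        for ins in self.novel_insertions:
            pos = [0] + list(ins.breakpoints) + [ins.length]
            for j in range(len(pos) - 1):
                coords[f"S:{ins.chrom}:{j}"] = (ins.chrom, pos[j], pos[j + 1])
        return coords

    def attachment(self, bnd: Breakend) -> tuple[tuple, str]:
        """Graph attachment of a breakend: (vertex key, edge direction).

        ``R`` means the rightward segment participates: the adjacency edge
        attaches to the ``-`` split vertex with direction ``+``; ``L``
        attaches to the ``+`` split vertex with direction ``-``.
        """
        if bnd.chrom.startswith(NOVEL_PREFIX):
            ins = self._novel(bnd.chrom)
            pos = [0] + list(ins.breakpoints) + [ins.length]
            j = pos.index(bnd.pos) if bnd.pos in pos else None
            if j is None:
                raise GraphError(f"unknown novel-fragment position {bnd}")
        else:
            j = self.breakpoint_index(bnd.chrom, bnd.pos)
        if bnd.side == SIDE_R:
            return (bnd.chrom, j, MINUS), PLUS
        return (bnd.chrom, j, PLUS), MINUS

    def _novel(self, chrom: str) -> NovelInsertion:
        for ins in self.novel_insertions:
            if ins.chrom == chrom:
                return ins
        raise GraphError(f"unknown novel insertion {chrom!r}")

    def end_marker_vertices(self) -> list[tuple]:
        """V_W: vertex keys of the marked target-chromosome ends."""
        out = []
        for bnd in self.end_markers:
            vkey, _ = self.attachment(bnd)
            out.append(vkey)
        return sorted(set(out))

    def total_content(self) -> int:
        """sum over segments of length * copy_number (genome content)."""
        total = 0
        for chrom in self.chrom_order():
            pos = self.positions(chrom)
            for j, cn in enumerate(self.copy_numbers[chrom]):
                total += (pos[j + 1] - pos[j]) * cn
        return total


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _load_config(path_or_dict: Union[str, Path, dict]) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    text = Path(path_or_dict).read_text()
    if str(path_or_dict).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _parse_novel(raw: dict) -> NovelInsertion:
    adjacencies = []
    ins_id = str(raw["id"])
    for a in raw.get("adjacencies", ()):
        adjacencies.append(
            Adjacency(
                bnd1=Breakend(NOVEL_PREFIX + ins_id, int(a["frag_pos"]), a["frag_side"]),
                bnd2=Breakend(str(a["chrom"]), int(a["pos"]), a["side"]),
                required=bool(a.get("required", True)),
                support=int(a.get("support", 0)),
            )
        )
    cns = raw.get("copy_numbers")
    return NovelInsertion(
        insertion_id=ins_id,
        length=int(raw["length"]),
        copy_number=int(raw.get("copy_number", 1)),
        breakpoints=tuple(int(b) for b in raw.get("breakpoints", ())),
        adjacencies=tuple(adjacencies),
        copy_numbers=tuple(int(x) for x in cns) if cns else None,
        required_breakpoints=tuple(
            int(b) for b in raw.get("required_breakpoints", ())
        ),
    )


def read_sv_dataset(
    segments: Union[str, Path, pd.DataFrame],
    adjacencies: Union[str, Path, pd.DataFrame, None],
    config: Union[str, Path, dict],
) -> SVDataset:
    """Read and unify the three inputs into an :class:`SVDataset`.

    Breakpoints are the union of interior segment boundaries, adjacency
    positions, end-marker positions and required-reference-adjacency
    positions; segments are auto-split at new breakpoints with inherited
    copy numbers.  Overlapping or gapped segment tilings and adjacency
    positions outside the covered intervals are errors.
    """
    if not isinstance(segments, pd.DataFrame):
        segments = pd.read_csv(segments, sep="\t")
    if adjacencies is None:
        adjacencies = pd.DataFrame(
            columns="chrom1 pos1 side1 chrom2 pos2 side2 required support".split()
        )
    elif not isinstance(adjacencies, pd.DataFrame):
        adjacencies = pd.read_csv(adjacencies, sep="\t")
    cfg = _load_config(config)

    lambdas = cfg.get("lambdas") or None
    params = CostParams(
        n_N=int(cfg["n_N"]),
        n_T=int(cfg.get("n_T", 0)),
        Q_N=int(cfg.get("Q_N", 1)),
        Q_T=int(cfg.get("Q_T", 1)),
        U=(int(cfg["U"]) if cfg.get("U") is not None else None),
        lambdas=tuple(int(x) for x in lambdas) if lambdas else None,
    )
    end_markers = tuple(
        Breakend(str(m["chrom"]), int(m["pos"]), str(m["side"]))
        for m in cfg.get("end_markers", ())
    )
    req_ref = tuple(
        (str(r["chrom"]), int(r["pos"]))
        for r in cfg.get("required_reference_adjacencies", ())
    )
    novel = tuple(_parse_novel(raw) for raw in cfg.get("novel_insertions", ()))

    # raw per-chromosome tilings
    raw: dict[str, list[tuple[int, int, int]]] = {}
    for row in segments.itertuples(index=False):
        chrom, start, end, cn = str(row.chrom), int(row.start), int(row.end), int(row.copy_number)
        if end <= start:
            raise GraphError(f"empty segment {chrom}:{start}-{end}")
        if cn < 0:
            raise GraphError(f"negative copy number on {chrom}:{start}-{end}")
        raw.setdefault(chrom, []).append((start, end, cn))
    extents: dict[str, tuple[int, int]] = {}
    for chrom, segs in raw.items():
        segs.sort()
        for (s1, e1, _), (s2, e2, _) in zip(segs, segs[1:]):
            if s2 < e1:
                raise GraphError(f"overlapping segments on {chrom} at {s2}")
            if s2 > e1:
                raise GraphError(f"gap in segment tiling on {chrom} at {e1}")
        extents[chrom] = (segs[0][0], segs[-1][1])

    adj_list: list[Adjacency] = []
    collapsed: dict[tuple, Adjacency] = {}
    for row in adjacencies.itertuples(index=False):
        b1 = Breakend(str(row.chrom1), int(row.pos1), str(row.side1))
        b2 = Breakend(str(row.chrom2), int(row.pos2), str(row.side2))
        a = Adjacency(
            *sorted((b1, b2)),
            required=bool(int(getattr(row, "required", 0))),
            support=int(getattr(row, "support", 0)),
        )
        key = (a.bnd1, a.bnd2)
        if key in collapsed:  # duplicates collapse; support accumulates
            prev = collapsed[key]
            collapsed[key] = Adjacency(
                a.bnd1, a.bnd2, prev.required or a.required,
                prev.support + a.support,
            )
        else:
            collapsed[key] = a
    for ins in novel:
        for a in ins.adjacencies:
            collapsed[(a.bnd1, a.bnd2)] = a
    adj_list = [collapsed[k] for k in sorted(collapsed)]

    # unified breakpoints
    bp: dict[str, set[int]] = {chrom: set() for chrom in extents}
    for chrom, segs in raw.items():
        for _, end, _ in segs[:-1]:
            bp[chrom].add(end)
    def note_position(chrom: str, pos: int) -> None:
        if chrom.startswith(NOVEL_PREFIX):
            return
        if chrom not in extents:
            raise GraphError(f"position on unknown chromosome {chrom!r}")
        s, e = extents[chrom]
        if not (s <= pos <= e):
            raise GraphError(f"position {chrom}:{pos} outside covered interval [{s},{e}]")
        if s < pos < e:
            bp[chrom].add(pos)

    for a in adj_list:
        for b in (a.bnd1, a.bnd2):
            if not b.chrom.startswith(NOVEL_PREFIX):
                note_position(b.chrom, b.pos)
    for m in end_markers:
        if not m.chrom.startswith(NOVEL_PREFIX):
            note_position(m.chrom, m.pos)
    for chrom, pos in req_ref:
        note_position(chrom, pos)
        s, e = extents[chrom]
        if not (s < pos < e):
            raise GraphError(
                f"required reference adjacency {chrom}:{pos} is not internal"
            )

    breakpoints = {chrom: sorted(ps) for chrom, ps in bp.items()}

    # auto-split: copy number of each unified segment inherited from the raw
    # segment that covers it
    copy_numbers: dict[str, list[int]] = {}
    for chrom in extents:
        pos = [extents[chrom][0]] + breakpoints[chrom] + [extents[chrom][1]]
        cns = []
        for j in range(len(pos) - 1):
            mid_start = pos[j]
            cn = None
            for s, e, c in raw[chrom]:
                if s <= mid_start < e:
                    cn = c
                    break
            assert cn is not None
            cns.append(cn)
        copy_numbers[chrom] = cns

    return SVDataset(
        extents=extents,
        breakpoints=breakpoints,
        copy_numbers=copy_numbers,
        adjacencies=adj_list,
        params=params,
        end_markers=end_markers,
        required_ref_adjacencies=req_ref,
        novel_insertions=novel,
    )


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

@dataclass
class PrototypeGraph:
    """Undirected precursor of the chromosome graph: one vertex per boundary
    position, segment edges, and one aberrant-adjacency edge per junction."""

    chrom_order: list[str]
    n_breaks: dict[str, int]
    segments: dict[tuple[str, int], tuple[int, int]]  # (chrom, j) -> (n, length)
    adjacencies: list[tuple[str, tuple, tuple, bool, int]]
    # each adjacency: (edge_id, (chrom, j, side), (chrom, j, side), required, support)

    @property
    def n_vertices(self) -> int:
        return sum(self.n_breaks[c] + 2 for c in self.chrom_order)

    @property
    def n_segment_edges(self) -> int:
        return len(self.segments)

    @property
    def n_adjacency_edges(self) -> int:
        return len(self.adjacencies)


def build_prototype_graph(ds: SVDataset) -> PrototypeGraph:
    """Vertices at every boundary position, segment edges between consecutive
    boundaries, one adjacency edge per aberrant junction (reference
    chromosomes only; novel fragments are attached to the split graph)."""
    chroms = ds.chrom_order()
    segments = {}
    for chrom in chroms:
        pos = ds.positions(chrom)
        for j, cn in enumerate(ds.copy_numbers[chrom]):
            segments[(chrom, j)] = (cn, pos[j + 1] - pos[j])
    adjacencies = []
    for k, a in enumerate(ds.adjacencies):
        if a.bnd1.chrom.startswith(NOVEL_PREFIX) or a.bnd2.chrom.startswith(NOVEL_PREFIX):
            continue  # handled by attach_novel_insertions
        att1 = (a.bnd1.chrom, ds.breakpoint_index(a.bnd1.chrom, a.bnd1.pos), a.bnd1.side)
        att2 = (a.bnd2.chrom, ds.breakpoint_index(a.bnd2.chrom, a.bnd2.pos), a.bnd2.side)
        adjacencies.append((f"L:{k:03d}", att1, att2, a.required, a.support))
    return PrototypeGraph(
        chrom_order=chroms,
        n_breaks={c: ds.n_breakpoints(c) for c in chroms},
        segments=segments,
        adjacencies=adjacencies,
    )


def _add_reference_chromosome(
    G: ChromosomeGraph,
    chrom: str,
    n: int,
    seg_info: Sequence[tuple[int, int]],
) -> None:
    """Split vertices, segment edges and reference-adjacency edges for one
    (reference or novel) chromosome with n internal breakpoints."""
    G.register_chromosome(chrom, n)
    verts: dict[tuple, Vertex] = {}
    verts[(chrom, 0, MINUS)] = G.add_vertex(Vertex(chrom, 0, MINUS, V5))
    for j in range(1, n + 1):
        verts[(chrom, j, PLUS)] = G.add_vertex(Vertex(chrom, j, PLUS, VM))
        verts[(chrom, j, MINUS)] = G.add_vertex(Vertex(chrom, j, MINUS, VM))
    verts[(chrom, n + 1, PLUS)] = G.add_vertex(Vertex(chrom, n + 1, PLUS, V3))
    for j in range(n + 1):
        cn, length = seg_info[j]
        G.add_edge(
            BidirectedEdge(
                edge_id=f"S:{chrom}:{j}",
                end1=verts[(chrom, j, MINUS)], dir1=MINUS,
                end2=verts[(chrom, j + 1, PLUS)], dir2=PLUS,
                kind=KIND_S, copy_number=cn, length=length,
            )
        )
    for j in range(1, n + 1):
        G.add_edge(
            BidirectedEdge(
                edge_id=f"R:{chrom}:{j}",
                end1=verts[(chrom, j, PLUS)], dir1=MINUS,
                end2=verts[(chrom, j, MINUS)], dir2=PLUS,
                kind=KIND_R, copy_number=0, length=0,
            )
        )


def _attachment_vertex(att: tuple) -> tuple[tuple, str]:
    chrom, j, side = att
    if side == SIDE_R:
        return (chrom, j, MINUS), PLUS
    return (chrom, j, PLUS), MINUS


def build_chromosome_graph(proto: PrototypeGraph) -> ChromosomeGraph:
    """Split every internal vertex in two and orient edge ends.

    Segment edge j runs ``-`` at the left split vertex to ``+`` at the right
    one; reference adjacencies run ``-`` at the ``+`` vertex to ``+`` at the
    ``-`` vertex; aberrant adjacencies attach according to their breakend
    side.  Traversal entering a split pair through one side must leave
    through the other, which is exactly the direction-alternation rule.
    """
    G = ChromosomeGraph()
    for chrom in proto.chrom_order:
        n = proto.n_breaks[chrom]
        _add_reference_chromosome(
            G, chrom, n, [proto.segments[(chrom, j)] for j in range(n + 1)]
        )
    for edge_id, att1, att2, required, support in proto.adjacencies:
        (v1, d1), (v2, d2) = _attachment_vertex(att1), _attachment_vertex(att2)
        G.add_edge(
            BidirectedEdge(
                edge_id=edge_id,
                end1=G.vertices[v1], dir1=d1,
                end2=G.vertices[v2], dir2=d2,
                kind=KIND_L, copy_number=0, length=0, required=required,
            )
        )
    return G


def mark_required_reference_adjacencies(G: ChromosomeGraph, ds: SVDataset) -> None:
    for chrom, pos in ds.required_ref_adjacencies:
        j = ds.breakpoint_index(chrom, pos)
        G.edge(f"R:{chrom}:{j}").required = True


def attach_novel_insertions(G: ChromosomeGraph, ds: SVDataset) -> ChromosomeGraph:
    """Add each novel fragment as a chromosome-like component linked to the
    main graph by aberrant-adjacency edges.

    The fragment contributes a segment edge of its stated length (split at
    internal breakpoints, with reference-adjacency edges between the parts)
    and one aberrant edge per declared junction.  A fragment with no
    junction is attached as an isolated component with a warning -- it will
    surface in the weakly-connected check.
    """
    if not ds.novel_insertions:
        return G
    G = G.copy()
    next_l = sum(1 for e in G.edges.values() if e.kind == KIND_L)
    # fragments first (a junction may join two novel fragments), edges second
    for ins in ds.novel_insertions:
        pos = [0] + list(ins.breakpoints) + [ins.length]
        cns = ins.segment_copy_numbers()
        seg_info = [(cns[j], pos[j + 1] - pos[j]) for j in range(len(pos) - 1)]
        _add_reference_chromosome(G, ins.chrom, len(ins.breakpoints), seg_info)
        for bp in ins.required_breakpoints:
            j = pos.index(bp)
            G.edge(f"R:{ins.chrom}:{j}").required = True
        if not ins.adjacencies:
            logger.warning(
                "novel insertion %s has no connecting adjacency; it forms an "
                "isolated component", ins.insertion_id,
            )
    for ins in ds.novel_insertions:
        for a in ins.adjacencies:
            (v1, d1) = ds.attachment(a.bnd1)
            (v2, d2) = ds.attachment(a.bnd2)
            G.add_edge(
                BidirectedEdge(
                    edge_id=f"L:{next_l:03d}",
                    end1=G.vertices[v1], dir1=d1,
                    end2=G.vertices[v2], dir2=d2,
                    kind=KIND_L, copy_number=0, length=0, required=a.required,
                )
            )
            next_l += 1
    return G


def build_graph(ds: SVDataset) -> ChromosomeGraph:
    """Dataset -> chromosome graph (prototype, split, flags, insertions)."""
    G = build_chromosome_graph(build_prototype_graph(ds))
    mark_required_reference_adjacencies(G, ds)
    return attach_novel_insertions(G, ds)


# ---------------------------------------------------------------------------
# solution output
# ---------------------------------------------------------------------------

@dataclass
class SolutionReport:
    """Everything the pipeline knows about a solved instance."""

    chromosomes: list[list[tuple[str, int, int, str]]]  # oriented components
    lengths: list[int]
    W_C: int
    W_f: int
    W_0: int
    n_chromosomes: int
    truncations: int
    residuals: list[tuple[str, int, int]]  # (segment edge, m(C,e), n(e))
    circulation: dict[str, int]
    walks: list[Walk]
    diagnostics: dict
    optima: Optional[list] = None  # alternative optimal multisets (walks)

    def to_dict(self) -> dict:
        return {
            "chromosomes": [
                [list(comp) for comp in chrom] for chrom in self.chromosomes
            ],
            "lengths": self.lengths,
            "W_C": self.W_C,
            "W_f": self.W_f,
            "W_0": self.W_0,
            "n_chromosomes": self.n_chromosomes,
            "truncations": self.truncations,
            "residuals": [list(r) for r in self.residuals],
            "diagnostics": self.diagnostics,
        }


def write_solution(report: SolutionReport, out_prefix: Union[str, Path]) -> dict[str, Path]:
    """Write AGP v2.1, a JSON report, and a circulation TSV.

    AGP rows are 1-based inclusive; each reconstructed chromosome becomes an
    object named ``karyotype_<k>`` whose components are oriented reference
    segments.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    agp_path = out_prefix.with_suffix(".agp")
    json_path = out_prefix.with_suffix(".json")
    tsv_path = Path(str(out_prefix) + ".circulation.tsv")

    lines = ["##agp-version\t2.1"]
    for k, chrom in enumerate(report.chromosomes, start=1):
        obj = f"karyotype_{k}"
        obj_pos = 0
        for part, (ref, start, end, orient) in enumerate(chrom, start=1):
            length = end - start
            lines.append(
                "\t".join(
                    [
                        obj,
                        str(obj_pos + 1),
                        str(obj_pos + length),
                        str(part),
                        "W",
                        ref,
                        str(start + 1),
                        str(end),
                        orient,
                    ]
                )
            )
            obj_pos += length
    agp_path.write_text("\n".join(lines) + "\n")

    json_path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")

    rows = ["edge_id\tkind\tf"]
    for eid in sorted(report.circulation):
        kind = eid.split(":", 1)[0]
        kind = {"S": "S", "R": "R", "L": "L", "t": "N", "N": "N", "T": "N", "D": "D"}.get(
            kind, "?"
        )
        rows.append(f"{eid}\t{kind}\t{report.circulation[eid]}")
    tsv_path.write_text("\n".join(rows) + "\n")
    return {"agp": agp_path, "json": json_path, "circulation": tsv_path}


def graph_to_dict(
    G: ChromosomeGraph,
    params: Optional[CostParams] = None,
    v_w: Iterable = (),
) -> dict:
    """JSON-serializable dump of a chromosome graph (with optional problem
    parameters and end markers).  Covers graphs that have no genomic
    coordinates, e.g. gadgets with zero-length segments."""
    d: dict = {
        "chromosomes": [
            {"name": c, "n_breakpoints": G.n_breaks[c]} for c in G.chrom_order
        ],
        "edges": [
            {
                "edge_id": e.edge_id,
                "end1": list(e.end1.key), "dir1": e.dir1,
                "end2": list(e.end2.key), "dir2": e.dir2,
                "kind": e.kind,
                "copy_number": e.copy_number,
                "length": e.length,
                "required": e.required,
            }
            for eid in sorted(G.edges)
            for e in [G.edges[eid]]
        ],
        "V_W": [list(v.key if isinstance(v, Vertex) else tuple(v)) for v in v_w],
    }
    if params is not None:
        d["params"] = {
            "n_N": params.n_N, "n_T": params.n_T,
            "Q_N": params.Q_N, "Q_T": params.Q_T,
            "U": params.U,
            "lambdas": list(params.lambdas) if params.lambdas else None,
        }
    return d


def graph_from_dict(d: dict) -> tuple[ChromosomeGraph, Optional[CostParams], list[tuple]]:
    """Inverse of :func:`graph_to_dict`."""
    G = ChromosomeGraph()
    for c in d["chromosomes"]:
        chrom, n = c["name"], int(c["n_breakpoints"])
        _add_reference_chromosome(G, chrom, n, [(0, 0)] * (n + 1))
    # re-adding edges: drop the placeholder S/R edges and rebuild from dump
    G.edges.clear()
    G._incident = {k: [] for k in G.vertices}
    for e in d["edges"]:
        k1, k2 = tuple(e["end1"]), tuple(e["end2"])
        G.add_edge(
            BidirectedEdge(
                edge_id=e["edge_id"],
                end1=G.vertices[k1], dir1=e["dir1"],
                end2=G.vertices[k2], dir2=e["dir2"],
                kind=e["kind"],
                copy_number=int(e["copy_number"]),
                length=int(e["length"]),
                required=bool(e["required"]),
            )
        )
    params = None
    if d.get("params"):
        p = d["params"]
        params = CostParams(
            n_N=int(p["n_N"]), n_T=int(p["n_T"]),
            Q_N=int(p["Q_N"]), Q_T=int(p["Q_T"]),
            U=(int(p["U"]) if p.get("U") is not None else None),
            lambdas=tuple(p["lambdas"]) if p.get("lambdas") else None,
        )
    v_w = [tuple(v) for v in d.get("V_W", ())]
    return G, params, v_w


def parse_agp(path: Union[str, Path]) -> dict[str, list[tuple[str, int, int, str]]]:
    """Read back an AGP file into 0-based half-open oriented components."""
    objects: dict[str, list] = {}
    expected_next: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        obj, obj_beg, obj_end, _part, comp_type = fields[:5]
        if comp_type != "W":
            raise GraphError(f"unsupported AGP component type {comp_type!r}")
        ref, comp_beg, comp_end, orient = fields[5:9]
        obj_beg, obj_end = int(obj_beg), int(obj_end)
        comp_beg, comp_end = int(comp_beg), int(comp_end)
        if obj_end - obj_beg != comp_end - comp_beg:
            raise GraphError(f"AGP length mismatch in object {obj}")
        nxt = expected_next.get(obj, 1)
        if obj_beg != nxt:
            raise GraphError(f"AGP object {obj} is not contiguous at {obj_beg}")
        expected_next[obj] = obj_end + 1
        objects.setdefault(obj, []).append((ref, comp_beg - 1, comp_end, orient))
    return objects
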