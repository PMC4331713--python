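"""Simulated rearranged genomes with known truth.

The generator applies a sequence of rearrangement operations (deletion,
tandem duplication, inversion, reciprocal translocation, truncation, novel
insertion) to a toy reference and records the resulting target chromosomes
as ordered, oriented reference intervals.  From that truth it derives
exactly the four kinds of observable the inference consumes: aberrant
adjacencies, per-segment copy numbers, the chromosome/truncation counts, and
chromosome lengths -- plus the end markers and required edges that make the
instance satisfy the weakly connected constraint by construction.

In noise-free mode the truth chromosomes themselves have cost zero, so the
pipeline optimum must be zero too.  The optional noise model drops or
invents adjacencies and perturbs copy numbers by one -- the minimal error
modes of real SV callers; calibrating realistic error rates is out of
scope, and read-level effects (mappability, coverage dispersion) are not
emulated at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .graph_core import (
    MINUS,
    PLUS,
    ChromosomeGraph,
    CostParams,
    GraphError,
    Step,
    Walk,
    canonical_multiset_key,
    walk_visits,
    walk_vertices,
)
from .sv_io import (
    NOVEL_PREFIX,
    SIDE_L,
    SIDE_R,
    Breakend,
    SVDataset,
    read_sv_dataset,
)

__all__ = [
    "RearrangementOp",
    "SimulationTruth",
    "NoiseModel",
    "simulate_genome",
    "emit_tables",
    "emit_sv_dataset",
    "truth_walks",
    "evaluate_recovery",
    "write_dataset_files",
]

Interval = tuple[str, int, int, str]  # (source chrom, start, end, strand)

OP_KINDS = (
    "deletion",
    "tandem_duplication",
    "inversion",
    "translocation",
    "truncation",
    "novel_insertion",
)

# relative frequencies of the operations; the four canonical rearrangement
# classes dominate, with occasional truncations and novel insertions
DEFAULT_OP_WEIGHTS = {
    "deletion": 1.0,
    "tandem_duplication": 1.0,
    "inversion": 1.0,
    "translocation": 1.0,
    "truncation": 0.5,
    "novel_insertion": 0.5,
}


@dataclass(frozen=True)
class RearrangementOp:
    kind: str
    params: dict


@dataclass
class SimulationTruth:
    reference: dict[str, int]  # chromosome name -> length
    novel: dict[str, int]  # novel fragment name (ins:*) -> length
    ops: list[RearrangementOp]
    target: list[list[Interval]]
    seed: int

    def chromosome_lengths(self) -> list[int]:
        return [sum(e - s for _, s, e, _ in chrom) for chrom in self.target]

    def source_length(self, chrom: str) -> int:
        if chrom.startswith(NOVEL_PREFIX):
            return self.novel[chrom]
        return self.reference[chrom]


@dataclass(frozen=True)
class NoiseModel:
    """Minimal caller-error model: independent adjacency drop-out, false
    adjacencies, and +-1 copy-number perturbation per segment."""

    p_drop_adjacency: float = 0.0
    n_false_adjacencies: int = 0
    p_perturb_copy: float = 0.0


def _split_at(intervals: list[Interval], pos: int) -> tuple[list[Interval], list[Interval]]:
    """Cut an interval list at target-coordinate pos."""
    left: list[Interval] = []
    right: list[Interval] = []
    acc = 0
    for iv in intervals:
        chrom, s, e, strand = iv
        ln = e - s
        if acc + ln <= pos:
            left.append(iv)
        elif acc >= pos:
            right.append(iv)
        else:
            cut = pos - acc
            if strand == "+":
                left.append((chrom, s, s + cut, "+"))
                right.append((chrom, s + cut, e, "+"))
            else:
                left.append((chrom, e - cut, e, "-"))
                right.append((chrom, s, e - cut, "-"))
        acc += ln
    return left, right


def _length(intervals: Sequence[Interval]) -> int:
    return sum(e - s for _, s, e, _ in intervals)


def _invert(intervals: list[Interval]) -> list[Interval]:
    return [
        (chrom, s, e, "-" if strand == "+" else "+")
        for chrom, s, e, strand in reversed(intervals)
    ]


def simulate_genome(
    ref_spec: Union[dict[str, int], Sequence[tuple[str, int]]],
    n_ops: int,
    seed: int,
    op_weights: Optional[dict[str, float]] = None,
    min_piece: int = 1,
) -> SimulationTruth:
    """Apply ``n_ops`` sampled rearrangements to the reference; fully
    reproducible from ``seed``.  Degenerate draws (pieces too small to cut)
    are resampled with bounded retries."""
    reference = dict(ref_spec)
    rng = np.random.default_rng(seed)
    weights = dict(DEFAULT_OP_WEIGHTS)
    if op_weights:
        weights.update(op_weights)
    kinds = [k for k in OP_KINDS if weights.get(k, 0) > 0]
    probs = np.array([weights[k] for k in kinds], dtype=float)
    probs /= probs.sum()

    target: list[list[Interval]] = [
        [(name, 0, length, "+")] for name, length in reference.items()
    ]
    novel: dict[str, int] = {}
    ops: list[RearrangementOp] = []

    def pick_chrom(min_len: int = 1) -> Optional[int]:
        lens = np.array([_length(c) for c in target], dtype=float)
        ok = lens >= min_len
        if not ok.any():
            return None
        p = lens * ok
        return int(rng.choice(len(target), p=p / p.sum()))

    applied = 0
    attempts = 0
    while applied < n_ops and attempts < 50 * max(1, n_ops):
        attempts += 1
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        if kind in ("deletion", "tandem_duplication", "inversion"):
            ci = pick_chrom(min_len=2 * min_piece + 1)
            if ci is None:
                continue
            L = _length(target[ci])
            a = int(rng.integers(min_piece if kind == "deletion" else 0, L - min_piece))
            b = int(rng.integers(a + min_piece, L + (0 if kind == "deletion" else 1)))
            if kind == "deletion" and (a == 0 and b == L):
                continue  # keep chromosomes nonempty
            left, rest = _split_at(target[ci], a)
            mid, right = _split_at(rest, b - a)
            if kind == "deletion":
                if not left and not right:
                    continue
                target[ci] = left + right
            elif kind == "tandem_duplication":
                target[ci] = left + mid + mid + right
            else:
                target[ci] = left + _invert(mid) + right
            ops.append(RearrangementOp(kind, {"chrom_index": ci, "start": a, "end": b}))
        elif kind == "translocation":
            if len(target) < 2:
                continue
            ci, cj = rng.choice(len(target), size=2, replace=False)
            ci, cj = int(ci), int(cj)
            La, Lb = _length(target[ci]), _length(target[cj])
            if La < 2 * min_piece or Lb < 2 * min_piece:
                continue
            a = int(rng.integers(min_piece, La - min_piece + 1))
            b = int(rng.integers(min_piece, Lb - min_piece + 1))
            head_a, tail_a = _split_at(target[ci], a)
            head_b, tail_b = _split_at(target[cj], b)
            target[ci] = head_a + tail_b
            target[cj] = head_b + tail_a
            ops.append(RearrangementOp(kind, {"chroms": (ci, cj), "pos": (a, b)}))
        elif kind == "truncation":
            ci = pick_chrom(min_len=2 * min_piece)
            if ci is None:
                continue
            L = _length(target[ci])
            cut = int(rng.integers(min_piece, L - min_piece + 1))
            left, right = _split_at(target[ci], cut)
            keep_left = bool(rng.integers(0, 2))
            target[ci] = left if keep_left else right
            ops.append(
                RearrangementOp(kind, {"chrom_index": ci, "pos": cut, "keep_left": keep_left})
            )
        else:  # novel_insertion
            ci = pick_chrom()
            if ci is None:
                continue
            L = _length(target[ci])
            pos = int(rng.integers(0, L + 1))
            ins_len = int(rng.integers(2, 8)) * 10
            name = f"{NOVEL_PREFIX}n{len(novel) + 1}"
            novel[name] = ins_len
            left, right = _split_at(target[ci], pos)
            target[ci] = left + [(name, 0, ins_len, "+")] + right
            ops.append(RearrangementOp(kind, {"chrom_index": ci, "pos": pos, "name": name}))
        applied += 1

    # merge abutting co-linear intervals so truth is in normal form
    target = [_normalize(chrom) for chrom in target]
    return SimulationTruth(
        reference=reference, novel=novel, ops=ops, target=target, seed=seed
    )


def _normalize(intervals: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for iv in intervals:
        if out:
            c, s, e, st = out[-1]
            c2, s2, e2, st2 = iv
            if c == c2 and st == st2 == "+" and e == s2:
                out[-1] = (c, s, e2, "+")
                continue
            if c == c2 and st == st2 == "-" and s == e2:
                out[-1] = (c, s2, e, "-")
                continue
        out.append(iv)
    return out


# ---------------------------------------------------------------------------
# deriving the observable SV data from the truth
# ---------------------------------------------------------------------------

def _junction_breakends(a: Interval, b: Interval) -> tuple[Breakend, Breakend]:
    """Breakends of the junction between consecutive target intervals."""
    ca, sa, ea, sta = a
    cb, sb, eb, stb = b
    bnd_a = Breakend(ca, ea, SIDE_L) if sta == "+" else Breakend(ca, sa, SIDE_R)
    bnd_b = Breakend(cb, sb, SIDE_R) if stb == "+" else Breakend(cb, eb, SIDE_L)
    return bnd_a, bnd_b


def _is_reference_adjacency(a: Interval, b: Interval) -> Optional[tuple[str, int]]:
    """(chrom, breakpoint position) when the junction just continues the
    reference, else None."""
    ca, sa, ea, sta = a
    cb, sb, eb, stb = b
    if ca == cb and sta == stb == "+" and ea == sb:
        return (ca, ea)
    if ca == cb and sta == stb == "-" and sa == eb:
        return (ca, sa)
    return None


def _chrom_end_markers(chrom: list[Interval]) -> tuple[Breakend, Breakend]:
    c0, s0, e0, st0 = chrom[0]
    cl, sl, el, stl = chrom[-1]
    start = Breakend(c0, s0, SIDE_R) if st0 == "+" else Breakend(c0, e0, SIDE_L)
    end = Breakend(cl, el, SIDE_L) if stl == "+" else Breakend(cl, sl, SIDE_R)
    return start, end


def emit_tables(
    truth: SimulationTruth,
    noise: Optional[NoiseModel] = None,
    noise_seed: Optional[int] = None,
    Q: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Observable SV data for a simulated genome, as the three input tables
    (segments, adjacencies, config).

    Segments carry true copy numbers over the unified breakpoint tiling;
    every true aberrant junction becomes a required adjacency; reference
    adjacencies the truth actually crosses become required too (that is what
    anchors every supported component at an end marker, so the noise-free
    instance satisfies the weakly connected constraint by construction); the
    config carries the true chromosome count, truncation count and lengths.
    """
    rng = np.random.default_rng(
        truth.seed + 1 if noise_seed is None else noise_seed
    )
    noise = noise or NoiseModel()

    # copy numbers over the unified tiling
    cuts: dict[str, set[int]] = {c: set() for c in truth.reference}
    for name in truth.novel:
        cuts[name] = set()
    for chrom in truth.target:
        for c, s, e, _ in chrom:
            L = truth.source_length(c)
            for p in (s, e):
                if 0 < p < L:
                    cuts[c].add(p)
    coverage: dict[tuple[str, int, int], int] = {}
    segments_rows = []
    seg_tiling: dict[str, list[tuple[int, int]]] = {}
    for c in sorted(cuts):
        bounds = [0] + sorted(cuts[c]) + [truth.source_length(c)]
        seg_tiling[c] = list(zip(bounds, bounds[1:]))
        for s, e in seg_tiling[c]:
            coverage[(c, s, e)] = 0
    for chrom in truth.target:
        for c, s, e, _ in chrom:
            for ts, te in seg_tiling[c]:
                if s <= ts and te <= e:
                    coverage[(c, ts, te)] += 1

    # junctions
    aberrant: list[tuple[Breakend, Breakend]] = []
    used_ref: set[tuple[str, int]] = set()
    for chrom in truth.target:
        for a, b in zip(chrom, chrom[1:]):
            ref = _is_reference_adjacency(a, b)
            if ref is not None:
                used_ref.add(ref)
            else:
                aberrant.append(_junction_breakends(a, b))
        # reference adjacencies crossed inside an interval (breakpoints cut
        # by other intervals) anchor the tiling too
        for c, s, e, _ in chrom:
            for p in cuts[c]:
                if s < p < e:
                    used_ref.add((c, p))

    markers: list[Breakend] = []
    n_T = 0
    for chrom in truth.target:
        for bnd in _chrom_end_markers(chrom):
            markers.append(bnd)
            L = truth.source_length(bnd.chrom)
            internal = not (
                (bnd.side == SIDE_R and bnd.pos == 0)
                or (bnd.side == SIDE_L and bnd.pos == L)
            )
            if internal:
                n_T += 1

    # ---- noise ------------------------------------------------------------
    if noise.p_drop_adjacency > 0:
        aberrant = [
            j for j in aberrant if rng.random() >= noise.p_drop_adjacency
        ]
    for _ in range(noise.n_false_adjacencies):
        chroms = sorted(truth.reference)
        c1, c2 = rng.choice(chroms), rng.choice(chroms)
        p1 = int(rng.integers(1, truth.reference[str(c1)]))
        p2 = int(rng.integers(1, truth.reference[str(c2)]))
        aberrant.append(
            (
                Breakend(str(c1), p1, SIDE_L if rng.random() < 0.5 else SIDE_R),
                Breakend(str(c2), p2, SIDE_L if rng.random() < 0.5 else SIDE_R),
            )
        )

    for c in sorted(truth.reference):
        for ts, te in seg_tiling[c]:
            if noise.p_perturb_copy > 0 and rng.random() < noise.p_perturb_copy:
                delta = 1 if rng.random() < 0.5 else -1
                coverage[(c, ts, te)] = max(0, coverage[(c, ts, te)] + delta)

    # ---- assemble tables --------------------------------------------------
    for c in sorted(truth.reference):
        for ts, te in seg_tiling[c]:
            segments_rows.append((c, ts, te, coverage[(c, ts, te)]))
    segments = pd.DataFrame(
        segments_rows, columns=["chrom", "start", "end", "copy_number"]
    )

    adj_rows = []
    novel_adjacencies: dict[str, list[dict]] = {name: [] for name in truth.novel}
    for b1, b2 in aberrant:
        if b1.chrom.startswith(NOVEL_PREFIX) or b2.chrom.startswith(NOVEL_PREFIX):
            frag, other = (b1, b2) if b1.chrom.startswith(NOVEL_PREFIX) else (b2, b1)
            novel_adjacencies[frag.chrom].append(
                {
                    "frag_pos": frag.pos, "frag_side": frag.side,
                    "chrom": other.chrom, "pos": other.pos, "side": other.side,
                    "required": True, "support": 1,
                }
            )
        else:
            adj_rows.append(
                (b1.chrom, b1.pos, b1.side, b2.chrom, b2.pos, b2.side, 1, 1)
            )
    adjacencies = pd.DataFrame(
        adj_rows,
        columns="chrom1 pos1 side1 chrom2 pos2 side2 required support".split(),
    )

    lengths = truth.chromosome_lengths()
    config = {
        "n_N": len(truth.target),
        "n_T": n_T,
        "Q_N": Q,
        "Q_T": Q,
        "lambdas": sorted(lengths, reverse=True),
        "end_markers": [
            {"chrom": m.chrom, "pos": m.pos, "side": m.side} for m in markers
        ],
        "required_reference_adjacencies": [
            {"chrom": c, "pos": p}
            for c, p in sorted(used_ref)
            if not c.startswith(NOVEL_PREFIX)
        ],
        "novel_insertions": [
            {
                "id": name[len(NOVEL_PREFIX):],
                "length": truth.novel[name],
                "breakpoints": sorted(cuts[name]),
                "copy_numbers": [coverage[(name, s, e)] for s, e in seg_tiling[name]],
                "required_breakpoints": sorted(
                    p for c, p in used_ref if c == name
                ),
                "adjacencies": novel_adjacencies[name],
            }
            for name in sorted(truth.novel)
        ],
    }
    return segments, adjacencies, config


def emit_sv_dataset(
    truth: SimulationTruth,
    noise: Optional[NoiseModel] = None,
    noise_seed: Optional[int] = None,
    Q: int = 100,
) -> SVDataset:
    """Parsed :class:`SVDataset` view of :func:`emit_tables`."""
    segments, adjacencies, config = emit_tables(truth, noise, noise_seed, Q)
    return read_sv_dataset(segments, adjacencies, config)


def write_dataset_files(ds_inputs: tuple, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write (segments_df, adjacencies_df, config_dict) as the three
    standard input files."""
    segments, adjacencies, config = ds_inputs
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "segments": out / "segments.tsv",
        "adjacencies": out / "adjacencies.tsv",
        "config": out / "config.yaml",
    }
    segments.to_csv(paths["segments"], sep="\t", index=False)
    adjacencies.to_csv(paths["adjacencies"], sep="\t", index=False)
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=False))
    return paths


# ---------------------------------------------------------------------------
# truth as walks, and recovery scoring
# ---------------------------------------------------------------------------

def truth_walks(truth: SimulationTruth, ds: SVDataset, G: ChromosomeGraph) -> list[Walk]:
    """The true target chromosomes as walks on the chromosome graph.

    Each oriented reference interval expands to its segment edges joined by
    reference adjacencies; aberrant junctions map to the aberrant edge
    connecting the two breakend attachment vertices.
    """

    def seg_steps(iv: Interval) -> list[Step]:
        c, s, e, strand = iv
        if c.startswith(NOVEL_PREFIX):
            ins = next(i for i in ds.novel_insertions if i.chrom == c)
            pos = [0] + list(ins.breakpoints) + [ins.length]
        else:
            pos = ds.positions(c)
        j1, j2 = pos.index(s), pos.index(e)
        steps = []
        if strand == "+":
            for j in range(j1, j2):
                if j > j1:
                    steps.append(Step(f"R:{c}:{j}", True))
                steps.append(Step(f"S:{c}:{j}", True))
        else:
            for j in range(j2 - 1, j1 - 1, -1):
                if j < j2 - 1:
                    steps.append(Step(f"R:{c}:{j + 1}", False))
                steps.append(Step(f"S:{c}:{j}", False))
        return steps

    def find_l_edge(v1: tuple, v2: tuple) -> Step:
        for e in G.E_L:
            keys = (e.end1.key, e.end2.key)
            if keys == (v1, v2):
                return Step(e.edge_id, True)
            if keys == (v2, v1):
                return Step(e.edge_id, False)
        raise GraphError(f"no aberrant edge between {v1} and {v2}")

    walks = []
    for chrom in truth.target:
        steps: list[Step] = []
        for k, iv in enumerate(chrom):
            if k > 0:
                prev = chrom[k - 1]
                ref = _is_reference_adjacency(prev, iv)
                if ref is not None:
                    c, p = ref
                    j = ds.breakpoint_index(c, p)
                    forward = prev[3] == "+"
                    steps.append(Step(f"R:{c}:{j}", forward))
                else:
                    b1, b2 = _junction_breakends(prev, iv)
                    v1, _ = ds.attachment(b1)
                    v2, _ = ds.attachment(b2)
                    steps.append(find_l_edge(v1, v2))
            steps.extend(seg_steps(iv))
        first = G.edge(steps[0].edge_id)
        start = first.end1 if steps[0].forward else first.end2
        walks.append(Walk(start=start.key, steps=tuple(steps)))
    return walks


def evaluate_recovery(
    G: ChromosomeGraph,
    C: Sequence[Walk],
    truth_C: Sequence[Walk],
    params: CostParams,
) -> dict:
    """Compare a reconstruction against the truth chromosomes.

    Exact multiset match is reported but not required by downstream checks:
    co-optimal karyotypes are a structural feature of the problem, so the
    operative criterion is matching the (zero) cost and the per-segment
    visit counts.
    """
    from .graph_core import cost as solution_cost, solution_summary

    size, tr, m = solution_summary(G, C)
    t_size, t_tr, t_m = solution_summary(G, truth_C)
    residuals = {
        e.edge_id: m.get(e.edge_id, 0) - t_m.get(e.edge_id, 0) for e in G.E_S
    }
    return {
        "exact_match": canonical_multiset_key(G, C) == canonical_multiset_key(G, truth_C),
        "size_delta": size - t_size,
        "tr_delta": tr - t_tr,
        "max_abs_visit_residual": max((abs(r) for r in residuals.values()), default=0),
        "W": solution_cost(G, C, params),
        "W_truth": solution_cost(G, truth_C, params),
    }
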