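"""Dataset parsing, breakpoint unification, graph construction and output."""

from __future__ import annotations

import pandas as pd
import pytest

import karyograph as kg
from karyograph.graph_core import MINUS, PLUS, GraphError
from karyograph.sv_io import (
    attach_novel_insertions,
    build_chromosome_graph,
    build_prototype_graph,
    graph_from_dict,
    graph_to_dict,
    parse_agp,
    read_sv_dataset,
    write_solution,
)
from karyograph.synthetic import emit_tables, simulate_genome, write_dataset_files

from conftest import one_segment_dataset, simulated_instance


def _cfg(n_N=1, **extra):
    base = {"n_N": n_N, "n_T": 0, "Q_N": 10, "Q_T": 10}
    base.update(extra)
    return base


def test_single_segment_dataset(trivial_ds):
    assert trivial_ds.chrom_order() == ["chr1"]
    assert trivial_ds.n_breakpoints("chr1") == 0
    assert trivial_ds.copy_numbers["chr1"] == [1]


def test_auto_split_at_adjacency_position():
    seg = pd.DataFrame(
        [("chr1", 0, 1000, 2)], columns=["chrom", "start", "end", "copy_number"]
    )
    adj = pd.DataFrame(
        [("chr1", 400, "L", "chr1", 400, "R", 1, 5)],
        columns="chrom1 pos1 side1 chrom2 pos2 side2 required support".split(),
    )
    ds = read_sv_dataset(seg, adj, _cfg())
    assert ds.breakpoints["chr1"] == [400]
    assert ds.copy_numbers["chr1"] == [2, 2]  # inherited on both halves


def test_splitting_preserves_total_content():
    seg = pd.DataFrame(
        [("chr1", 0, 1000, 2)], columns=["chrom", "start", "end", "copy_number"]
    )
    before = read_sv_dataset(seg, None, _cfg()).total_content()
    adj = pd.DataFrame(
        [("chr1", 123, "L", "chr1", 777, "R", 0, 1)],
        columns="chrom1 pos1 side1 chrom2 pos2 side2 required support".split(),
    )
    after = read_sv_dataset(seg, adj, _cfg()).total_content()
    assert before == after == 2000


def test_overlap_gap_and_out_of_range_errors():
    bad_overlap = pd.DataFrame(
        [("chr1", 0, 500, 1), ("chr1", 400, 1000, 1)],
        columns=["chrom", "start", "end", "copy_number"],
    )
    with pytest.raises(GraphError, match="overlap"):
        read_sv_dataset(bad_overlap, None, _cfg())
    gapped = pd.DataFrame(
        [("chr1", 0, 400, 1), ("chr1", 500, 1000, 1)],
        columns=["chrom", "start", "end", "copy_number"],
    )
    with pytest.raises(GraphError, match="gap"):
        read_sv_dataset(gapped, None, _cfg())
    seg = pd.DataFrame(
        [("chr1", 0, 1000, 1)], columns=["chrom", "start", "end", "copy_number"]
    )
    adj = pd.DataFrame(
        [("chr1", 1500, "L", "chr1", 400, "R", 0, 1)],
        columns="chrom1 pos1 side1 chrom2 pos2 side2 required support".split(),
    )
    with pytest.raises(GraphError, match="outside"):
        read_sv_dataset(seg, adj, _cfg())
    with pytest.raises(ValueError, match="n_N"):
        read_sv_dataset(seg, None, _cfg(n_N=0))


def test_duplicate_adjacencies_collapse_with_summed_support():
    seg = pd.DataFrame(
        [("chr1", 0, 1000, 1)], columns=["chrom", "start", "end", "copy_number"]
    )
    adj = pd.DataFrame(
        [
            ("chr1", 400, "L", "chr1", 600, "R", 0, 3),
            ("chr1", 600, "R", "chr1", 400, "L", 1, 4),
        ],
        columns="chrom1 pos1 side1 chrom2 pos2 side2 required support".split(),
    )
    ds = read_sv_dataset(seg, adj, _cfg())
    assert len(ds.adjacencies) == 1
    a = ds.adjacencies[0]
    assert a.support == 7 and a.required


def test_prototype_graph_counts():
    # two chromosomes, two breakpoints each, two adjacencies
    seg = pd.DataFrame(
        [("a", 0, 30, 1), ("b", 0, 30, 1)],
        columns=["chrom", "start", "end", "copy_number"],
    )
    adj = pd.DataFrame(
        [
            ("a", 10, "L", "b", 10, "R", 0, 1),
            ("a", 20, "L", "b", 20, "R", 0, 1),
        ],
        columns="chrom1 pos1 side1 chrom2 pos2 side2 required support".split(),
    )
    ds = read_sv_dataset(seg, adj, _cfg(n_N=2))
    proto = build_prototype_graph(ds)
    assert proto.n_vertices == 8
    assert proto.n_segment_edges == 6
    assert proto.n_adjacency_edges == 2
    # trivial case
    proto0 = build_prototype_graph(one_segment_dataset())
    assert (proto0.n_vertices, proto0.n_segment_edges, proto0.n_adjacency_edges) == (2, 1, 0)


@pytest.mark.parametrize("seed", range(5))
def test_prototype_counts_match_direct_enumeration(seed):
    truth, ds, G, _ = simulated_instance(seed, op_weights={"novel_insertion": 0})
    proto = build_prototype_graph(ds)
    n = {c: ds.n_breakpoints(c) for c in ds.chrom_order()}
    assert proto.n_vertices == sum(ni + 2 for ni in n.values())
    assert proto.n_segment_edges == sum(ni + 1 for ni in n.values())
    assert proto.n_adjacency_edges == len(
        [a for a in ds.adjacencies]
    )


def test_split_graph_structure_and_attachment_sides():
    seg = pd.DataFrame(
        [("a", 0, 30, 1), ("b", 0, 30, 1)],
        columns=["chrom", "start", "end", "copy_number"],
    )
    adj = pd.DataFrame(
        [("a", 10, "R", "b", 10, "L", 0, 1)],
        columns="chrom1 pos1 side1 chrom2 pos2 side2 required support".split(),
    )
    ds = read_sv_dataset(seg, adj, _cfg(n_N=2))
    G = build_chromosome_graph(build_prototype_graph(ds))
    e = G.edge("L:000")
    ends = {(end.key, d) for end, d in zip(e.ends, e.dirs)}
    # R side -> '-' split vertex with '+' direction; L side -> '+' with '-'
    assert (("a", 1, MINUS), PLUS) in ends
    assert (("b", 1, PLUS), MINUS) in ends
    # segment edges run '-' at the left split vertex, '+' at the right
    s = G.edge("S:a:0")
    assert (s.end1.key, s.dir1) == (("a", 0, MINUS), MINUS)
    assert (s.end2.key, s.dir2) == (("a", 1, PLUS), PLUS)
    # reference adjacencies run '-' at the '+' vertex, '+' at the '-' vertex
    r = G.edge("R:a:1")
    assert (r.end1.key, r.dir1) == (("a", 1, PLUS), MINUS)
    assert (r.end2.key, r.dir2) == (("a", 1, MINUS), PLUS)


def test_no_breakpoints_means_no_split_and_no_reference_adjacencies(trivial_ds):
    G = kg.build_graph(trivial_ds)
    assert len(G.E_R) == 0
    assert all(v.klass in ("V5", "V3") for v in G.vertices.values())


def test_novel_insertion_edge_deltas():
    cfg = _cfg(
        end_markers=[
            {"chrom": "chr1", "pos": 0, "side": "R"},
            {"chrom": "chr1", "pos": 1000, "side": "L"},
        ],
        novel_insertions=[
            {
                "id": "x",
                "length": 500,
                "adjacencies": [
                    {"frag_pos": 0, "frag_side": "R", "chrom": "chr1", "pos": 400, "side": "L"},
                    {"frag_pos": 500, "frag_side": "L", "chrom": "chr1", "pos": 400, "side": "R"},
                ],
            }
        ],
    )
    seg = pd.DataFrame(
        [("chr1", 0, 1000, 1)], columns=["chrom", "start", "end", "copy_number"]
    )
    ds = read_sv_dataset(seg, None, cfg)
    G0 = build_chromosome_graph(build_prototype_graph(ds))
    G = attach_novel_insertions(G0, ds)
    assert len(G.E_S) - len(G0.E_S) == 1
    assert len(G.E_L) - len(G0.E_L) == 2
    # no insertions: unchanged
    assert attach_novel_insertions(G0, one_segment_dataset()) is G0


def test_novel_insertion_with_internal_breakpoint():
    cfg = _cfg(
        novel_insertions=[
            {
                "id": "y",
                "length": 500,
                "breakpoints": [200],
                "adjacencies": [
                    {"frag_pos": 0, "frag_side": "R", "chrom": "chr1", "pos": 400, "side": "L"}
                ],
            }
        ]
    )
    seg = pd.DataFrame(
        [("chr1", 0, 1000, 1)], columns=["chrom", "start", "end", "copy_number"]
    )
    ds = read_sv_dataset(seg, None, cfg)
    G0 = build_chromosome_graph(build_prototype_graph(ds))
    G = attach_novel_insertions(G0, ds)
    assert len(G.E_S) - len(G0.E_S) == 2
    assert len(G.E_R) - len(G0.E_R) == 1
    assert len(G.E_L) - len(G0.E_L) == 1


def test_read_build_is_deterministic(tmp_path):
    truth = simulate_genome({"chr1": 60, "chr2": 40}, n_ops=4, seed=11)
    tables = emit_tables(truth)
    paths = write_dataset_files(tables, tmp_path)
    ds1 = kg.read_sv_dataset(paths["segments"], paths["adjacencies"], paths["config"])
    ds2 = kg.read_sv_dataset(paths["segments"], paths["adjacencies"], paths["config"])
    g1, g2 = kg.build_graph(ds1), kg.build_graph(ds2)
    assert sorted(g1.edges) == sorted(g2.edges)
    for eid in g1.edges:
        a, b = g1.edge(eid), g2.edge(eid)
        assert (a.end1.key, a.dir1, a.end2.key, a.dir2, a.copy_number, a.length) == (
            b.end1.key, b.dir1, b.end2.key, b.dir2, b.copy_number, b.length
        )


def test_file_round_trip_reproduces_dataset(tmp_path):
    truth = simulate_genome({"chr1": 60, "chr2": 40}, n_ops=4, seed=5)
    seg, adj, cfg = emit_tables(truth)
    from_memory = read_sv_dataset(seg, adj, cfg)
    paths = write_dataset_files((seg, adj, cfg), tmp_path)
    from_files = kg.read_sv_dataset(
        paths["segments"], paths["adjacencies"], paths["config"]
    )
    assert from_memory.extents == from_files.extents
    assert from_memory.breakpoints == from_files.breakpoints
    assert from_memory.copy_numbers == from_files.copy_numbers
    assert from_memory.adjacencies == from_files.adjacencies
    assert from_memory.end_markers == from_files.end_markers
    assert from_memory.params == from_files.params


def test_write_solution_and_agp_round_trip(tmp_path, trivial_ds):
    G = kg.build_graph(trivial_ds)
    report = kg.solve_chrw(
        G, trivial_ds.params, trivial_ds.end_marker_vertices(),
        segment_coords=trivial_ds.segment_coords(),
    )
    paths = write_solution(report, tmp_path / "sol")
    assert all(p.exists() for p in paths.values())
    objects = parse_agp(paths["agp"])
    assert list(objects.values()) == [c for c in report.chromosomes]
    # circulation dump has one row per edge
    rows = paths["circulation"].read_text().strip().splitlines()
    assert len(rows) - 1 == len(report.circulation)


def test_agp_reports_reversed_orientation(tmp_path):
    # inversion of the right half of a chromosome
    truth = simulate_genome({"chr1": 100}, n_ops=0, seed=0)
    truth.target[0] = [("chr1", 0, 50, "+"), ("chr1", 50, 100, "-")]
    ds = kg.emit_sv_dataset(truth)
    G = kg.build_graph(ds)
    report = kg.solve_chrw(
        G, ds.params, ds.end_marker_vertices(), segment_coords=ds.segment_coords()
    )
    paths = write_solution(report, tmp_path / "inv")
    orientations = {
        comp[3] for obj in parse_agp(paths["agp"]).values() for comp in obj
    }
    assert orientations == {"+", "-"}


def test_graph_json_round_trip():
    from karyograph.reductions import partition_to_chrl, PartitionInstance

    G, params, v_w, req = partition_to_chrl(PartitionInstance((1, 2)))
    d = graph_to_dict(G, params, v_w)
    G2, params2, v_w2 = graph_from_dict(d)
    assert sorted(G2.edges) == sorted(G.edges)
    for eid in G.edges:
        a, b = G.edge(eid), G2.edge(eid)
        assert (a.end1.key, a.dir1, a.end2.key, a.dir2) == (
            b.end1.key, b.dir1, b.end2.key, b.dir2
        )
        assert (a.copy_number, a.length, a.required) == (
            b.copy_number, b.length, b.required
        )
    assert params2 == params
    assert sorted(v_w2) == sorted(v_w)
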