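"""Shared fixtures: tiny instances, random-instance factories, oracles."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import karyograph as kg
from karyograph.sv_io import read_sv_dataset
from karyograph.synthetic import emit_tables, simulate_genome
from karyograph.wcc import check_wcc, repair_wcc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def one_segment_dataset(copy_number: int = 1, length: int = 1000, n_N: int = 1):
    seg = pd.DataFrame(
        [("chr1", 0, length, copy_number)],
        columns=["chrom", "start", "end", "copy_number"],
    )
    cfg = {
        "n_N": n_N,
        "n_T": 0,
        "Q_N": 10,
        "Q_T": 10,
        "end_markers": [
            {"chrom": "chr1", "pos": 0, "side": "R"},
            {"chrom": "chr1", "pos": length, "side": "L"},
        ],
    }
    return read_sv_dataset(seg, None, cfg)


@pytest.fixture
def trivial_ds():
    return one_segment_dataset()


@pytest.fixture
def trivial_graph(trivial_ds):
    return kg.build_graph(trivial_ds)


def simulated_instance(seed: int, n_ops: int = 3, ref=None, **sim_kwargs):
    """Noise-free simulated instance: (truth, dataset, graph, V_W)."""
    truth = simulate_genome(
        ref or {"chr1": 50, "chr2": 40}, n_ops=n_ops, seed=seed, **sim_kwargs
    )
    ds = kg.emit_sv_dataset(truth)
    G = kg.build_graph(ds)
    return truth, ds, G, ds.end_marker_vertices()


def perturbed_instance(seed: int):
    """Tiny WCC-satisfying instance with at most one injected error, plus the
    matching parameters with length caps removed (the polynomial problem has
    no length restriction).  Returns (graph, params, V_W)."""
    rng = np.random.default_rng(seed)
    truth = simulate_genome(
        {"chr1": 12, "chr2": 10},
        n_ops=int(rng.integers(1, 3)),
        seed=seed,
        op_weights={"novel_insertion": 0, "truncation": 0.3},
        min_piece=2,
    )
    seg, adj, cfg = emit_tables(truth, Q=4)
    mode = seed % 3
    if mode == 1 and len(adj):
        adj = adj.drop(index=int(rng.integers(len(adj)))).reset_index(drop=True)
    elif mode == 2:
        i = int(rng.integers(len(seg)))
        delta = 1 if rng.random() < 0.5 else -1
        seg.loc[i, "copy_number"] = max(0, int(seg.loc[i, "copy_number"]) + delta)
    ds = read_sv_dataset(seg, adj, cfg)
    G = kg.build_graph(ds)
    v_w = ds.end_marker_vertices()
    if not check_wcc(G, v_w).satisfied:
        repair_wcc(G, v_w, mode="augment")
    params = dataclasses.replace(ds.params, lambdas=None)
    return G, params, v_w
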