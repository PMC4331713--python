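# karyograph

Reconstruct the **global structure of chromosomes** — how segments of a
reference genome are extracted, ordered and oriented in an unknown target
genome — from structural-variation (SV) data: aberrant adjacencies, segment
copy numbers, and the experimentally observed number, truncation count and
lengths of chromosomes.

Individual SV calls (a deletion here, a translocation there) do not say what
the rearranged chromosomes actually look like. `karyograph` is aimed at
people analysing complex rearrangements — cancer karyotypes, chromothripsis,
chromoplexy — who have SV calls and copy-number profiles and want whole
ordered chromosome reconstructions, plus at researchers studying the
combinatorics of the reconstruction problem itself (the NP-completeness
gadgets are shipped as executable instances).

## The model

The reference genome is encoded as a **bidirected chromosome graph**
`G = (V, E)`. Every breakpoint is split into two vertices `v⁻/v⁺`; edges come
in three classes and carry an independent `+`/`−` direction at each end:

* `E_S` — reference segments, with copy number `n(e)` and length `|e|`;
* `E_R` — reference adjacencies across each breakpoint;
* `E_L` — aberrant adjacencies observed in the target.

A **chromosome** is a walk that leaves every vertex with the direction
opposite to the one it entered with (this forbids gluing two adjacencies
back-to-back) and whose first and last edges are segments. For a candidate
multiset `C` of chromosomes, with `m(C,e)` the visit counts and `Tr(C)` the
number of chromosome ends at internal breakpoints, the cost is

```
W(C) = Q_N·| |C| − n_N | + Q_T·| Tr(C) − n_T | + Σ_{e∈E_S} |e|·| m(C,e) − n(e) |
```

Minimising `W(C)` is NP-complete in general (reductions from Hamiltonian
Cycle and, with per-chromosome length caps λᵢ, from PARTITION — both shipped
in `karyograph.reductions`). Under the **weakly connected constraint** (every
support component of the graph contains a marked chromosome-end vertex) the
problem without length caps is solved exactly in polynomial time: the graph
is extended with terminal vertices `v_N`, `v_T`, counting edges `e_N`, `e_T`
and reverse-partner edges, a minimum-cost integer **circulation** `f` is
computed (HiGHS, exact integer arithmetic throughout), and the identity

```
W(f) = W(C) + W_0,    W_0 = Q_N·n_N + Q_T·n_T + Σ |e|·n(e)
```

converts the optimal flow back into an optimal chromosome multiset via flow
decomposition, cycle merging and extraction. Because several karyotypes can
realize the same optimal circulation, `--all-optima` enumerates them all
instead of hiding the ambiguity.

## Worked example

Simulate a small rearranged genome (two 100 bp reference chromosomes, three
random operations) and reconstruct it:

```bash
$ karyograph simulate --seed 11 --chromosomes 2 --length 100 --ops 3 --out sim
$ cat sim/segments.tsv
chrom   start   end     copy_number
chr1    0       25      1
chr1    25      99      0
chr1    99      100     1
chr2    0       100     1
$ cat sim/adjacencies.tsv
chrom1  pos1  side1  chrom2  pos2  side2  required  support
chr1    25    L      chr1    99    R      1         1
```

The copy-number drop over `chr1:25–99` together with the adjacency joining
`chr1:25` (left side) to `chr1:99` (right side) is the signature of a
deletion. Solving:

```bash
$ karyograph solve sim/segments.tsv sim/adjacencies.tsv sim/config.yaml --out solution
{
  "W_C": 0,
  "W_f": 326,
  "W_0": 326,
  "n_chromosomes": 2,
  "truncations": 0,
  ...
}
$ cat solution.agp
##agp-version   2.1
karyotype_1     1       25      1       W       chr1    1       25      +
karyotype_1     26      26      2       W       chr1    100     100     +
karyotype_2     1       100     1       W       chr2    1       100     +
```

`W_C = 0` means the reconstruction explains every observation exactly: the
flow cost `W_f` equals the constant `W_0` (326 = Q_N·2 + Q_T·0 + Σ|e|n(e) =
200 + 126), so the chromosome cost is zero. The AGP file spells out the
karyotype: the first reconstructed chromosome is `chr1[0,25)` joined to
`chr1[99,100)` — the deletion — and `chr2` is intact.

The same pipeline is available as a library:

```python
import karyograph as kg
ds = kg.read_sv_dataset("sim/segments.tsv", "sim/adjacencies.tsv", "sim/config.yaml")
G = kg.build_graph(ds)
report = kg.solve_chrw(G, ds.params, ds.end_marker_vertices(),
                       segment_coords=ds.segment_coords())
report.W_C          # 0
report.chromosomes  # [[('chr1', 0, 25, '+'), ('chr1', 99, 100, '+')], ...]
```

Other entry points: `check-wcc` (+ `--repair augment|drop`), `brute-force`
(exact exhaustive oracle for tiny instances, with `--lambdas` for the
length-constrained problem and `--all-optima`), `reduce-hc` /
`reduce-partition` (emit the hardness gadgets as solvable instances),
`validate`.

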