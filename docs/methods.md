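# Methods

## The reconstruction model

`karyograph` treats karyotype reconstruction as combinatorial optimisation
on a bidirected graph. Vertices are split reference breakpoints (`v⁻`/`v⁺`
per breakpoint, a single `v⁻` at each reference chromosome start, a single
`v⁺` at each end). Segment edges (`E_S`) carry an estimated copy number
`n(e)` and a base-pair length `|e|`; reference-adjacency edges (`E_R`) and
aberrant-adjacency edges (`E_L`) carry neither. Each edge end has its own
`+`/`−` direction, and a walk must leave every vertex with the direction
opposite to its entry direction. The direction assignment makes segment
edges the only edges with a `−` end at `v⁻` vertices and the only edges with
a `+` end at `v⁺` vertices, so adjacency edges can never be traversed
back-to-back: every junction is realized by genomic sequence, which is the
biological point of the construction.

A target genome is a multiset `C` of *chromosomes* (direction-valid walks
bounded by segment edges). Its cost penalizes disagreement with the three
observables — chromosome count `n_N`, truncation count `n_T` (chromosome
ends at internal breakpoints, observed as copy-number drops without an
adjacency), and per-segment copy numbers — with the count penalties weighted
by constants `Q_N`, `Q_T` and the copy-number penalties weighted by segment
length. All quantities are integers; there is no floating point anywhere in
the cost algebra, so every reported identity is exact, not approximate.

Conventions chosen where the formulation leaves room:

* a chromosome and its reversal are the same object (DNA strands are
  unordered); the canonical form is the lexicographically smaller edge-id
  sequence, preferring forward traversal on ties;
* `Tr(C)` counts endpoint *incidences*: a chromosome with both ends at
  internal breakpoints contributes 2;
* per-chromosome length caps λᵢ are matched to chromosomes by sorted
  pointwise comparison, which by an exchange argument equals the existence
  of an injective assignment;
* zero copy number is legal (a segment absent from the target).

One consequence of using the concrete cost `|e|·|m−n|` is that zero-length
segment edges contribute nothing for any visit count, so a zero total cost
pins visit counts only on positive-length segments. The PARTITION gadget
(below) is the one place where zero-length segments appear; its argument
survives because the per-chromosome length budget pins the routing
indirectly.

## The polynomial pipeline (circulation route)

The pipeline solves the problem without length caps, for instances that
satisfy the **weakly connected constraint (WCC)**: every component of the
support subgraph (segments with `n(e) ≥ 1` plus *required* adjacency edges)
must contain a marked chromosome-end vertex (`V_W`). Components with no
support edge are vacuously good — an unused split vertex cannot host flow,
and only support edges matter for the cycle-merging argument below.

Construction of the circular graph: a terminal vertex `v_N` receives one
terminal edge per natural chromosome end, a second terminal vertex `v_T`
receives one per internal split vertex (routing truncation endpoints), the
self-loop `e_N` at `v_N` (cost weight `Q_N`, both ends `+`, incidence ±2
handled explicitly) counts chromosomes, and `e_T` (weight `Q_T`) counts
truncations. Every segment edge and both counting edges get a
direction-negated *reverse partner* with upper bound `n(e)` and the same
cost weight, which is how visit deficits are paid for while the forward edge
keeps its lower bound `l(e) = n(e)`. Required adjacency edges get `l = 1`;
the lower bound is applied to required edges only, not to all adjacency
edges — otherwise the required-edge machinery would be vacuous and most real
instances infeasible. Terminal edges at `V_W` vertices get `l = 1` (a marked
end must be used). Unspecified upper bounds use the solution-size budget
`U(4|V|+1)(|E|+1)`, with `U` one above the largest observed count when not
configured; an override exists so tests can enumerate the integer box
exhaustively.

The minimum-cost integer circulation is found with scipy's HiGHS
mixed-integer optimizer. The constraint matrix of a bidirected flow is not
totally unimodular, so the integer program is solved as such rather than
rounding an LP; inputs are small integers and the returned flow is
re-verified exactly (bounds and signed balances) in integer arithmetic. Ties
among co-optimal circulations are broken by a second solve that pins the
optimal cost and minimises total flow with small edge-rank preferences; the
backend is deterministic, so repeated runs give identical circulations. A
fully lexicographic tie-break would need one solve per edge and was not
worth the cost at these instance sizes.

Conversion back to chromosomes follows the constructive correspondence:

1. **canonicalize** — subtract each reverse-partner flow from its forward
   edge (balanced again by symmetry; the result may dip below segment lower
   bounds, it is a decomposition object, not a feasible circulation);
2. **decompose** — walk the positive flow, smallest edge id first, splicing
   out a cycle whenever a (vertex, pending-direction) state repeats; visit
   counts equal the flow exactly and the time is linear in total flow;
3. **merge** — splice all support-bearing cycles into one at shared
   vertices, reversing the incoming cycle when the junction directions
   clash (the direction-rule validator, not the prose argument, is the
   arbiter of this step — every merged cycle is re-validated); support-free
   cycles cannot occur at an optimum and are discarded with a warning if a
   non-optimal flow is ever decomposed;
4. **extract** — delete `v_N`, `v_T` and the terminal edges; the terminal
   direction assignments force every remaining run to start and end with a
   segment edge, and the number of runs equals `f(e_N)`.

The identity `W(f) = W(C) + W_0` with
`W_0 = Q_N n_N + Q_T n_T + Σ|e|n(e)` is asserted inside the pipeline on
every solve; a violation is an internal error, never a warning.

Because one optimal circulation can be cut into chromosomes in several ways,
`enumerate_extractions` lists every multiset whose visit counts, endpoint
usage and chromosome count reproduce the canonical flow. The two-chromosome
multiplicity fixture (`figure5_fixture`) has exactly two.

Instances that fail WCC can be repaired before solving: `augment` adds a
shortest undirected path (ties broken by edge id; both the path rule and the
target choice are this package's determinism choice, the formulation itself
does not prescribe one) from each unanchored component to an anchored one,
marking traversed segments present and adjacencies required; `drop` zeroes
the offending component's copy numbers and required flags; `error` refuses.

## The exhaustive oracle (brute-force route)

`brute_force_optimum` solves the full NP-complete problem — including length
caps and, optionally, any monotone cost function — on tiny graphs, by
depth-first enumeration of chromosome multisets with three layers of
control:

* **symmetry** — members are generated in canonical orientation and in
  nondecreasing canonical order, so each multiset is visited once;
* **admissible pruning** — the bound built from irreversible cost
  (chromosome-count surplus, truncation surplus, positive-length visit
  surpluses) cuts branches against the best solution found;
* **visit caps** — zero-length segments admit cost-free revisits, so a
  fixpoint computation bounds their visits in any zero-cost solution: the
  visit count of an edge is limited by the traversal incidences its end
  vertices can supply (pinned positive-length neighbours, endpoint
  allowances `n_T` at internal vertices and `2 n_N` elsewhere), iterated to
  convergence. When the fixpoint is finite the caps are rigorous; otherwise
  a slack fallback is used and the result carries a flag instead of a
  certificate.

The search runs in two phases. Phase one decides whether a zero-cost
multiset exists (a found zero is optimal outright, since the cost is
nonnegative). Phase two, entered only for positive optima, iteratively
deepens the incumbent (2, 4, 8, …): a run pruned at level *k* is an
exhaustive search of all completions costing less than *k*, so the first
level that returns a solution returns the global optimum. A cheap feasible
seed (one segment–adjacency–segment sandwich per required edge plus one
single-segment chromosome per uncovered end marker) caps the deepening when
it satisfies the length constraints. Callers that only need to separate
zero from positive optima (the odd-total PARTITION instance, where the
exact positive optimum is expensive and irrelevant) pass a `cost_ceiling`;
the result then carries a certified lower bound with `best=None` rather
than an exact value.

The oracle accepts the same side constraints the pipeline enforces
(required edges, mandatory end-marker usage) so that the two routes solve
the same problem; the cross-check of pipeline optima against oracle optima
on random instances is the package's strongest correctness evidence, and
the two routes share no solver code.

## The reduction gadgets

The Hamiltonian-cycle gadget builds, per digraph vertex, a three-segment
mini-chromosome of unit lengths with copy numbers (1,2,1) for the first
vertex and (0,1,0) otherwise, and one aberrant edge per arc; with
`n_N = 1`, `n_T = 0`, `λ = |V'|+3`, a zero-cost solution exists iff the
digraph has a Hamiltonian cycle, and `extract_hamiltonian` reads the vertex
order back off the single witness chromosome (trying both orientations,
since a reversed chromosome is the same object but a reversed directed
cycle is not necessarily a cycle of the digraph). The penalty constants,
which the zero/positive dichotomy does not depend on, are set to 10.

The PARTITION gadget encodes each integer `s(i)` as a block whose middle
segment has length `s(i)` and copy number 2, plus a hub block whose
zero-length middle segment (copy `n+2`) routes collection; all adjacency
edges are required, every natural chromosome end is a marker (so WCC holds
by construction), `λᵢ = 10·S_Σ`, `Q_N = Q_T = 100·S_Σ`, `n_N = n+2`. When
`S_Σ` is odd every length, cap and penalty is doubled so the hub segment
length `9·S_Σ/2` stays integral — a uniform scaling that preserves the
reduction exactly. `extract_partition` first normalizes a zero-cost witness
(when the chromosome opening block *i* does not also close it, the closing
tail lives on another chromosome and the two are rerouted at the
copy-two middle segment; the swap preserves all visit counts and both
lengths), then reads the subset off a hub chromosome. The number of cap
slots is set to `2(n+2)`; the formulation treats the cap list as unbounded,
and doubling the natural chromosome count leaves ample room without
admitting solutions the cost could ever prefer (each surplus chromosome
costs `Q_N = 100·S_Σ`).

## The synthetic-data generator

`simulate_genome` applies a seeded sequence of operations — deletion, tandem
duplication, inversion, reciprocal translocation, truncation, novel
insertion, with default relative weights 1:1:1:1:0.5:0.5 (the four canonical
rearrangement classes dominate; truncations and insertions are rarer events
in the data model this emulates) — to a toy reference, tracking target
chromosomes as ordered, oriented reference intervals. `emit_tables` derives
the observables exactly: unified breakpoints, per-segment coverage counts,
one breakend pair per non-reference junction, end markers, `n_N`, `n_T` and
true lengths (the cap list is exactly the true lengths; the count penalties
default to `Q = 100`). Every true aberrant junction is marked required, and
every reference adjacency the truth crosses — between intervals *and inside
them*, at breakpoints cut by other intervals — is marked required too; this
is what makes noise-free emission satisfy WCC by construction, so the truth
multiset always has cost zero and the pipeline optimum must be zero as
well.

What the generator does *not* emulate: read-level effects (coverage
dispersion, mappability, breakend position uncertainty — input positions
are exact by design, fuzzy breakend clustering is out of scope), subclonal
mixtures, and realistic error rates. The optional noise model (independent
adjacency drop-out, invented adjacencies, ±1 copy perturbation) exists to
create instances whose optimum is *not* zero for the oracle cross-check,
not to mimic a particular caller. Passing tests therefore demonstrate the
algorithmic correctness of the reconstruction machinery on its own terms,
not calling performance on real sequencing data.

Because co-optimal karyotypes are a structural feature of the problem,
recovery is scored as "pipeline optimum equals the truth's (zero) cost and
per-segment visit counts match"; exact multiset identity is reported but
not required.

## Problem sizes and degenerate inputs

The shipped checks run the pipeline on 100 simulated genomes (two reference
chromosomes of 50/40 bp, three operations each), cross-check pipeline
against oracle on 30 perturbed instances of two chromosomes (12/10 bp, at
most one injected error), and run the gadgets at |V'| = 4 and s = (1,1) /
(1,1,1); the whole suite completes in well under a minute. The oracle is
exponential by nature and is meant for graphs of this scale only.

Degenerate inputs: empty adjacency tables are fine (the reference itself is
a valid instance); a segment with copy 0 and no support edges raises no WCC
complaint; an all-zero instance solves to the empty multiset with cost
`W_0`; infeasible bound combinations (e.g. a required edge whose balance
cannot close) surface as a structured infeasibility error from the solver,
not as a silent wrong answer.

## Known limitations

* Exactness of the circulation rests on HiGHS branch-and-bound over small
  integer data; pathological instances with enormous coefficients could in
  principle hit numerical tolerances, which is why every returned flow is
  re-verified in integer arithmetic (and rejected, not repaired, on
  failure).
* `enumerate_extractions` enumerates the karyotypes of one optimal
  circulation; distinct co-optimal circulations (rare under the total-flow
  tie-break, but possible) would contribute further karyotypes that only
  the brute-force `all_optima` route reports.
* Choosing among co-optimal karyotypes requires evidence outside this data
  model (long-range mates, FISH) and is deliberately out of scope.
* The brute force loses its optimality certificate around zero-length
  segments when the fixpoint caps do not close, and with user-supplied cost
  functions (no admissible bound); both cases are flagged on the result
  rather than guessed.
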