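# Methods

## Model

An evidence network is an undirected simple graph: vertices are
treatments, and an edge joins two treatments compared head-to-head in
at least one randomized trial. A multi-arm trial with k arms
contributes the complete subgraph on its arms (k(k−1)/2 edges).
Repeated comparisons of the same pair collapse to a single edge:
connectedness and distance depend only on whether a pair was ever
compared, so the adjacency matrix stays 0/1 and reproduces published
matrices exactly. Self-comparisons are rejected as input errors;
single-arm studies contribute an (isolated) vertex but no edges.

Three quantities are derived from the adjacency matrix A:

1. **Walk counts.** (A^k)_ij is the number of k-step walks between i
   and j, and C_l = Σ_{k≤l} A^k counts walks of length at most l.
   These grow exponentially in k, so they are computed in
   arbitrary-precision integer arithmetic (numpy object arrays holding
   Python ints); a fixed-width implementation would wrap silently well
   within realistic k for dense networks.
2. **Indirect connection matrix.** I(C_{n−1}), the elementwise
   indicator of C_{n−1}, is 1 exactly where two treatments are joined
   by some walk (no shortest path exceeds n−1 steps). It is the
   transitive closure of adjacency; all off-diagonal entries equal to 1
   is the connectedness test.
3. **Distance matrix.** D = A + Σ_{i=2..n−1} i·(I(C_i) − I(C_{i−1})):
   a pair entering the reachable set at step i lies at shortest-path
   distance exactly i.

## Numerical route and termination

The reachability chain is never computed through the integer powers.
Instead the boolean recurrence R_1 = I(A), R_i = I(R_{i−1} + R_{i−1}A)
— which equals I(C_i) — runs on bit matrices, so the computation is
exact at any n and costs one boolean matrix product per step. The
iteration stops at the first i with R_i = R_{i−1}: all later increments
of the distance sum vanish, so the result is identical and the loop
usually ends far before n−1 on sparse networks. The test suite verifies
on random graphs that this route coincides with the literal
indicator-of-power-sums route.

Two conventions required a decision:

- **Diagonal of D.** The distance formula, read literally, puts
  nonzero entries on the diagonal (any vertex with an edge acquires a
  closed 2-walk, so I(C_2) − I(C_1) is 1 there). Every published
  presentation of D has a zero diagonal, and the distance from a
  treatment to itself is zero by definition. The implementation seeds
  the running reachable set with the identity (distance 0 to self), so
  diagonal entries are never treated as newly reached and D keeps its
  zero diagonal while all off-diagonal entries follow the formula.
- **Diagonal of I(C_{n−1}).** Defined with ones on the diagonal. For
  an *isolated* vertex the literal computation gives 0 (no walk from a
  vertex to itself without edges); the implementation forces 1 for
  every vertex, reading the diagonal as "each treatment is trivially
  comparable with itself". The built-in networks contain no isolated
  vertices, so either reading reproduces all published matrices; the
  choice only shows in degenerate inputs.

**Unconnected pairs** are coded 0 in D by default, matching the
published convention and making printed matrices reproduce bit-exactly;
this conflates "self" with "not comparable", so
`unconnected_code="missing"` keeps −1 sentinels instead, and the writer
can render unconnected cells as blank (the usual published layout) or
`inf`. The stabilization property I(C_l) = I(C_{n−1}) for l ≥ n−1 is a
statement about connectivity, i.e. about off-diagonal entries: the
diagonal itself keeps changing at small l (closed walks appear only at
even lengths), so the property tests force the diagonal before
comparing.

**Edge cases.** n = 0 gives empty matrices and a vacuously connected
network (with a warning); n = 1 is connected; n = 2 makes the distance
sum empty so D = A, as implemented.

## Component collection

Components are the equivalence classes of the indirect connection
relation, read off I(C_{n−1}) row by row. Ordering is deterministic:
components sorted by their smallest original label index, labels inside
a component keeping their original relative order. This exactly
reproduces the header orderings of the published block-collected
tables. `block_sort` applies the resulting permutation to rows and
columns; off-block entries are necessarily the unconnected code, so
sorting preserves the multiset of entries and is idempotent.

## Input dialects

The three readers (arm-level long table; wide one-row-per-study
`t1..tK` matrix; plain edge list) all reduce to the same study-records
→ pairwise-edges construction, so equivalent inputs yield identical
networks — a tested invariant. Wide-format missing markers are `NA`,
`.` and the empty cell (R and Stata dialects differ); the exact column
naming of the wide treatment-matrix layout is not standardized, so any
columns matching `t<number>` are accepted and other columns are
ignored. Treatment codes are always strings, even when numeric, to
avoid silent reordering and leading-zero loss. Delimiters are sniffed
(comma/tab) with an explicit override.

## Built-in networks and the random generator

Four example networks ship with the package. The two small ones are
stored as edge lists; the two larger ones are stored as their published
block-collected distance tables (plain TSV text embedded in the
module), from which the edge set is recovered as the distance-1 cells —
exact, because a pair is at distance 1 precisely when directly
compared. The tables double as cell-for-cell reference surfaces in the
tests: the recovered edges must regenerate every printed cell. Of note,
the 23-treatment network's printed table contains exactly 24 distance-1
cells, and those 24 edges regenerate the table perfectly, so 24 is the
edge count this package reports for it.

The random generator emulates the *combinatorial* structure of evidence
networks — planted component sizes, tree-sparse to complete density —
for oracle testing: each component gets a uniform random spanning tree
(random Prüfer sequence), guaranteeing the declared component structure
exactly, then independent extra within-component edges with probability
`edge_density`. It is deterministic given its seed. It does not emulate
anything clinical (no outcome data, no trial sizes, no degree
distributions of real treatment networks), so passing tests certify the
graph algorithms, not any statistical property of real NMA data sets.
Oracle tests run at n ≤ 12 across 200 seeds and densities from 0 to 1,
where brute-force BFS and an independent component routine are cheap
and exhaustive enough to hit empty, tree, cyclic and complete regimes.

## Command-line behavior

Disconnection is a warning — a distinct exit status (2) and a stderr
message — not a failure, because analysing the largest component of a
disconnected network is legitimate practice; `--strict` upgrades it to
exit 1 for pipelines that must not proceed. Input errors exit 1.
Reports go to stdout, diagnostics to stderr; repeated runs are
byte-identical.

## Limitations

- Connectivity only: no effect synthesis, no inconsistency or
  node-splitting assessment, no evidence weighting by variance or risk
  of bias, no contribution matrix, no network plotting.
- The distance matrix measures steps, not evidential strength: a
  one-step comparison from one small trial counts the same as one from
  ten large trials.
- With loops in the network, the shortest path is only an approximate
  measure of the assumptions an actual pooled indirect estimate uses,
  since estimation draws on all walks, not only the shortest.
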