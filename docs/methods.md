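# Methods

This note records the model behind `coreclust`, the parameter choices and
their rationale, the numerical conventions, and the known limitations of the
approach — in particular where the centralization objective carries no
signal. Everything stated here is computed by the test suite or the CLI; no
numbers are quoted that the repository does not reproduce.

## Model and assumptions

The input is a simple undirected graph. Self-loops are dropped on read,
parallel edges collapse, and directed input is symmetrized. Edge weights are
ignored throughout: betweenness, modularity, the K function and the cut
scores are all defined on the unweighted topology.

The working hypothesis of the method is that a community is organized around
a **core**: a node that brokers much of the shortest-path traffic of its
region (high betweenness) while its own neighborhood is sparsely
interconnected (its neighbors depend on it rather than on each other).
Clusters are then grown outward from cores, instead of being carved out by a
global objective such as modularity. The greedy-modularity baseline
(`fast_newman`) exists precisely so the two philosophies can be compared on
the same graph with the same cut scores.

## Quantities

**Normalized betweenness.** `C_B(x)` is shortest-path betweenness with the
undirected normalization `2 / ((n-1)(n-2))`, computed by Brandes'
accumulation. For `n < 3` the normalization is undefined and every node
scores 0. The implementation is cross-checked in the test suite against a
brute-force all-pairs geodesic-counting oracle on 100 random graphs with
`n <= 12` at absolute tolerance 1e-9.

**Core influence.** With `k_x` the degree of `x` and `E_x` the number of
edges among the neighbors of `x`,

```
C_A(x) = C_B(x) / ( 2 * max(E_x, 1) / (k_x * (k_x - 1)) )
```

Nodes of degree < 2 score 0 (no neighbor pair exists). `E_x` is floored at 1
so that a node whose neighborhood contains no edges at all — maximally
dependent neighbors, the strongest core signal — gets the largest finite
amplification `k(k-1)/2` instead of a division by zero. The floor only
matters when `E_x = 0` and changes no value elsewhere.

**Centralization.** For a profile of core-influence values with maximum
`C_A*`,

```
C_A^g = sum_x (C_A* - C_A(x)) / ((n-1) * max_x (C_A* - C_A(x)))
```

A uniform profile (including a single-node profile) has centralization 0; a
one-hot profile has centralization 1. The quantity is permutation- and
scale-invariant and lies in `[0, 1]`; these are verified as derandomized
property tests (`tests/test_invariants.py`). Because floating-point summation
is order-dependent, permutation invariance holds to 1e-12, not bit-for-bit.

**K function.** For node `i` in cluster `q`, with `m_i` edges from `i` into
`q`, `d_i` the degree of `i`, `d_q` the total degree of `q`'s members, `d`
the total degree of the graph and `m` its edge count,

```
K(i) = m_i / ( (d_i/d) * ((d_q - d_i)/(d - d_i)) * m )
```

This compares the actual attachment of `i` to `q` against the expectation
under degree-preserving random wiring. When the whole connected graph is one
cluster, `K(i) = d/m = 2` identically — the analytic anchor the test suite
asserts. Degenerate denominators (`d_i = d`, or `d_q = d_i`, or an edgeless
graph) return 0 rather than raising: a node that *is* the cluster's entire
degree carries no evidence of over-attachment.

## The clustering procedure

1. Compute `C_A` for every node. The **candidate core list** is the top
   `ceil(0.2 n)` nodes ordered by `C_A` descending, then degree descending,
   then label ascending (deterministic tie-breaks).
2. Nodes carry one of three states: **P** (assigned to a cluster), **Q**
   (unassigned), **R** (contested between clusters). The states partition the
   node set at all times; `cluster(..., validate=True)` asserts this after
   every event.
3. Each candidate in order: if still Q, it founds a cluster and absorbs its
   Q-neighbors as members; neighbors already in *other* clusters become
   contested (R). If the candidate is already P, it may still found its own
   cluster when its K value against its current cluster falls inside the
   closed interval `[1.96, 2.71]` — it is attached no more strongly than a
   random-wiring anchor value of 2 would explain, so it plausibly heads its
   own community.
4. Contested nodes are resolved one at a time: the node joins the
   neighboring cluster that maximizes the summed per-cluster centralization
   of the affected clusters after the tentative move. Ties are broken by
   more edges into the cluster, then by smaller cluster id. A node with no
   P-neighbor defers until a later sweep.
5. Frontier sweeps repeat absorption/resolution until no state changes. If Q
   nodes remain when sweeps stall (disconnected components with no candidate
   core), the best remaining Q node by the candidate ordering founds a new
   cluster and sweeping resumes. An edgeless graph therefore yields all
   singletons, while every connected component receives at least one cluster.
6. A final refinement pass re-runs contested-style resolution over boundary
   nodes to a fixed point, capped at `max_iter` (default 100) passes. The
   objective is not monotone under single-node moves, so a two-node
   oscillation is possible; the cap terminates it and a warning is recorded
   in the run report rather than raising.

### Parameter defaults and rationale

| Parameter | Default | Rationale |
|---|---|---|
| candidate fraction | 0.20 | top quintile by `C_A`; `ceil` so small graphs still get one candidate |
| K interval | `[1.96, 2.71]` (closed) | brackets the whole-graph anchor `K = 2`; closed so the anchor value itself qualifies |
| `max_iter` | 100 | refinement cap; reached only under objective oscillation |
| ordering key | `"ca"` | candidates ranked by core influence; betweenness and degree act only as tie-breaks |

Cluster ids are founding-order integers starting at 1. All orderings that
could be ambiguous are given explicit deterministic tie-breaks, so two runs
on the same input are byte-identical (asserted in the CLI tests).

## Baseline: greedy modularity (Fast–Newman)

Agglomerative merging from singletons; at each step the connected community
pair with the largest

```
dQ = m_ij/m - 2 * (d_i/2m) * (d_j/2m)
```

is merged (ties: lexicographically smallest id pair), `Q` is recorded after
every merge including the singleton start, and the returned partition is the
state at the peak of the trace. The incremental bookkeeping is tested
against from-scratch modularity recomputation at every step, and the peak
`Q` against an exhaustive merge-sequence search on small reference graphs.
Greedy agglomeration is not guaranteed to reach the global maximum over all
merge sequences on arbitrary graphs — the exhaustive-oracle equality is
asserted only on the designated reference graphs, where it holds.

## Evaluation

For a cluster `S` with `n_S` members, `m_S` internal edges and `c_S`
boundary edges: conductance `c_S / (2 m_S + c_S)` and expansion `c_S / n_S`,
with the `0/0` case (no incident edges) scored 0. Lower is better for both.
The NCP-style profile keeps the minimum of each score per cluster size;
`compare` aligns two profiles on common sizes and reports strict-win
fractions. An edge-end conservation law — `sum_S (2 m_S + c_S) = 2m` for any
complete partition — is asserted over random partitions of random graphs.

## Synthetic benchmarks

`planted_partition` wraps the standard planted-partition generator
(`b` blocks of `s` nodes, within-block edge probability `p_in`, between-block
`p_out`, zero-padded string labels, ground truth by block index). NMI uses
the `2I / (H_A + H_B)` normalization with the conventions: both partitions
single-cluster → 1; exactly one partition with zero entropy → 0. It is
cross-checked against scikit-learn's implementation.

What the generator does emulate: assortative block structure with tunable
contrast, the regime where recovery difficulty is controlled by
`p_in - p_out`. What it does not emulate: degree heterogeneity (all nodes
have the same expected degree), overlapping communities, or hub-and-spoke
topologies — precisely the structures where a betweenness-based core score
is most informative.

## Numerical conventions

- Betweenness, modularity and `dQ` are accumulated in double precision; the
  `dQ` tie-break key rounds to 14 decimals before comparing so that
  symmetric pairs with analytically equal gains tie deterministically.
- The contested-resolution objective rounds the summed centralization to 12
  decimals before comparison, so analytically tied moves fall through to the
  discrete tie-breaks (edges into cluster, then cluster id) instead of being
  decided by float noise.
- Seeds passed through the synthetic generator and the CLI are reduced
  modulo 2^31 before reaching the underlying RNGs.
- Oracle comparisons use absolute tolerances: 1e-9 for betweenness, 1e-12
  for modularity traces; property tests use 1e-12.

## Limitations

**The centralization objective is blind to flat core-influence profiles.**
On a planted-partition graph every node is statistically identical: the
`C_A` values are (block-)exchangeable, so the per-cluster centralization of
a tentative assignment contains no information about which block a contested
node came from. Consequently, contested resolution on such graphs is driven
almost entirely by the discrete tie-breaks, and recovery of planted blocks
in the noisy regime is poor — substantially below what greedy modularity
achieves on the same graphs. This is a property of the objective, not of the
implementation: the analytic identities, conservation laws, state-machine
invariants and exact recovery in the disjoint-clique regime all hold. The
method's comparative advantage is expected on graphs with genuine core
structure (strong brokers with sparse neighborhoods), not on
degree-homogeneous block models.

**Other known limits.** The final refinement objective is not monotone, so
refinement may hit the iteration cap instead of a fixed point (reported, not
raised). The greedy baseline may miss the global modularity maximum on
general graphs. All computations are for unweighted simple graphs; weights
present in the input are discarded.
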