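# Methods

## Model and conventions

The dynamical object is the synchronous strict-threshold Boolean network:
node `i` is active at `t+1` iff its signed input sum `Σ_j A_ji x_j(t)` is
strictly positive. The tie (sum = 0) always maps to inactive; this is not
configurable, and it makes the all-off state a fixed point of every signed
network. States are packed into integers LSB-first (`s = Σ_i x_i 2^i`), so
the reflection `¬x` is the arithmetic complement `(2^n − 1) − s`, and all
decoded tuples read `(node0, node1, …)`. Truth-table networks
(`BooleanFunctionNetwork`) use the same encoding with per-node input lists;
the symmetry definitions depend only on the map `τ`, so every metric works
identically for both model classes.

"Cycle length" counts fixed points as cycles of length 1. A finite
functional graph always contains a cycle, so the maximum cycle length of
any network is ≥ 1 and every state belongs to exactly one basin; basin
sizes therefore sum to `2^n`, which the attractor finder asserts by
construction and the tests check independently.

## Attractor detection

`find_attractors` walks `τ` iteratively from every unvisited state, marking
the current path; closing onto the path identifies a new cycle, closing
onto finished territory inherits its basin label. This is linear in `2^n`
with no recursion. The same three-colour walk, compiled with numba,
powers the batch kernel used by surveys and the GA; the incremental
input-sum trick (state `x` reuses the sums of `x` with its lowest bit
cleared) makes a full 128-state transition table cost ~7 additions per
state, so 10^6 seven-node networks are evaluated in a few seconds.

Transition tables are materialized only up to a cap (default `n = 22`, a
~4M-entry table); beyond it the package refuses exhaustive computation and
offers the sampled symmetry estimators instead. Exact attractor detection
for larger `n` (SAT- or sampling-based) is out of scope.

## Symmetry metrics

The fully-symmetric fraction counts states with `τ(¬x) = ¬τ(x)`; the
partial symmetry ratio `p_sr` counts symmetric bits,
`f(x)_i ≠ f(¬x)_i`, averaged over all `2^n · n` state-bits. Exact values
come from one sweep of the transition table (the bit count is a popcount of
`succ[x] XOR succ[¬x]`). The per-state indicator takes equal values at `x`
and `¬x`, and no Boolean state is its own complement, so the state space
splits into mirror pairs — a property the tests exploit as an internal
consistency check. `p_sr ≥` full fraction always, with equality at 1.

Above the cap, both metrics are estimated from `m` uniform random states
(default 10^4): per-state and per-bit indicators are unbiased, and a
normal-approximation binomial 95% half-width is attached (`m · n`
Bernoulli draws for `p_sr`). Sampling treats the per-bit draws as
independent, which slightly understates the half-width when a node's
function makes bits strongly dependent; for screening purposes this is
immaterial. Batch screens over model files report both metrics plus the
method used, so either reading of a "symmetry ratio" (whole transitions vs
bits) is available.

## Motif census

Canonical form of a triad is the lexicographically smallest row-major
flattening over the 6 simultaneous row/column permutations, with trit
order `−1 < 0 < 1`; ids are 9-character `-0+` strings. The full table of
19683 canonicalizations is precomputed vectorially at import, making
population scans a table lookup. Exhaustive enumeration gives 3411 classes,
confirmed by Burnside's lemma ((3^9 + 3·3^5 + 2·3^3)/6). Connectivity
uses the convention that a node with no incoming or outgoing edge to the
other two (self-loops ignored) disconnects the triad: 127 classes are
disconnected, leaving 3284 — the universe network scans count against.
Disconnected triads encountered in a scan are excluded from counts but
included in `triples_scanned`, so rates are comparable across populations.

Suppressed-motif detection compares a target census against a baseline:
motifs with baseline count ≥ `min_support` (default 50) and frequency
ratio below `ratio_threshold` (default 0.05) are flagged. Both thresholds
are exposed; the defaults operationalize "almost completely absent" and, on
evolved-vs-random 7-node populations with a well-powered baseline census
(≥5000 networks), reproducibly yield a suppressed set of around thirty
motifs.

Gluing stamps uniformly random motifs from a set onto uniformly random
ordered node triples (the random ordering realizes a uniform relabeling of
the class), overwriting previous entries, until the nonzero fraction first
reaches the target density or a stamp budget (default `50·n²`) runs out;
budget exhaustion is reported rather than raised, since some motif sets
(e.g. the empty triad) cannot reach any positive density.

## Pareto GA

Genomes are the `n²` trits of `W` row-major. Objectives: maximize the
longest cycle, minimize the nonzero-edge count (raw count rather than a
normalized density — integer-valued and monotone in density). The
optimizer is NSGA-II-style: vectorized non-dominated sorting, crowding
distance, binary tournament on (rank, crowding), uniform crossover at rate
0.7, per-locus mutation at rate `1/n²` to a uniformly chosen *different*
trit, and elitist μ+λ truncation. Extreme points of the first front carry
infinite crowding distance, so the best-cycle individual always survives
and the best cycle length is non-decreasing — an invariant under test.
Runs are reproducible from a seed; history records best cycle, front size
and the 2-D hypervolume against the reference point (cycle 0, edges
`n²+1`).

Population size 100 and 200 generations at `n = 7` are the default study
conditions; a single run takes well under a second, and twenty replicates
give a front population of ~200 networks whose motif census is compared
against density-matched random baselines.

## Random ensembles and surveys

"Uniform" networks draw each entry i.i.d. uniform on `{−1, 0, 1}` (so the
expected density is 2/3); the density-conditioned generator places an exact
number of nonzero entries with a chosen inhibitory fraction, and is used
both for density sweeps and for density-matched baselines (edge counts
drawn from the population being matched). Kauffman NK networks assign every
node `K` distinct uniform inputs and a fair-coin truth table; for such
tables each bit transitions symmetrically with probability exactly 1/2
(the patterns of `x` and `¬x` index independent table entries), so the
ensemble's expected symmetry ratio is 50% — the property the screen's null
baseline is checked against.

Circuit statistics enumerate simple directed cycles of the interaction
graph (networkx), counting self-loops as length-1 circuits; a circuit's
sign is the product of its edge signs. Enumeration is guarded to small `n`
(≤ 12) since the circuit count grows super-exponentially. The survey's
"mean circuit length" is the unweighted mean over enumerated circuits.

Survey defaults are scaled for interactive use: 10^4 networks per survey
(configurable upward), 3·10^4 for the correlation checks in the tests, and
10^6 for the rare-event sweep, which measures that a 7-node uniform
network attains a maximal cycle of length 19 on the order of once per
million draws.

## Numerical and design notes

- Two-sample z-tests use the unpooled normal statistic; t-tests are
  Welch's. Zero-variance degenerate inputs return (0, p=1) on equal means
  and (±inf, p=0) otherwise rather than NaN.
- The `.bnet` dialect is BoolNet's: optional `targets, factors` header,
  `#` comments, `!`/`&`/`|` with AND over OR precedence, constants 0/1.
  Compilation enumerates truth tables exhaustively and is capped at 16
  inputs per node. Conversion of threshold networks to `.bnet` writes one
  minterm per activating regulator pattern — exact but exponential in
  in-degree, intended for small models and round-trip testing.
- Exhaustive enumeration shows that demanding full reflection symmetry of
  *every* maximal-cycle network holds at `n = 3` but not at `n = 2` (8
  networks attain the maximum, one is fully symmetric). The symmetric
  extremal network is exactly the minimum-edge one at both sizes, which is
  the form the extremal-symmetry test asserts; the package treats the
  sparse extremal representatives as the meaningful witnesses, consistent
  with the cycle-versus-density trade-off perspective used throughout.

## What the synthetic conditions do and do not show

All experiments are self-generating: random ensembles, evolved populations,
glued networks, and programmatically written `.bnet` fixtures. They
exercise the full pipeline end to end, but small uniform ensembles are not
biological models: real regulatory networks are sparse (mean in-degree
~2–5), have heavy-tailed structure, and their Boolean reductions carry
modeller choices. Passing tests therefore validate the machinery and the
ensemble-level claims (density/cycle trends, motif suppression, symmetry
enrichment under evolution), not any statement about a particular
biological repository; the screen over user-supplied `.bnet` files is the
intended route to such data.
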