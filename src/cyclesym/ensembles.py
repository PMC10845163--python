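"""Random network ensembles and cycle-length surveys.

Generators
----------
``random_uniform``     i.i.d. uniform trits per matrix entry — the baseline
                       ensemble for cycle-length distributions.
``random_density``     exactly ``edge_count`` nonzero entries placed
                       uniformly, each inhibitory with a given probability —
                       the density-conditioned ensemble.
``kauffman``           NK-style random Boolean network: K distinct random
                       inputs per node and i.i.d. fair-coin truth tables —
                       the null model for the biological symmetry screen.

Surveys draw many networks, measure the longest attractor cycle plus
structural covariates (edge counts by sign, self-loops by sign, simple
directed circuits), and aggregate by a chosen grouping, mirroring the
density / edge-mix / circuit / self-loop analyses of the random-sampling
study.  ``compare_populations`` supplies the two-sample z and t tests used
when contrasting populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import BooleanFunctionNetwork, SignedNetwork
from .state_space import batch_max_cycle_length

__all__ = [
    "random_uniform",
    "random_uniform_batch",
    "random_density",
    "kauffman",
    "CircuitStats",
    "circuit_stats",
    "cycle_length_survey",
    "compare_populations",
]


def random_uniform(n: int, rng: np.random.Generator) -> SignedNetwork:
    """A network with each of the n^2 trits i.i.d. uniform on {-1, 0, 1}."""
    return SignedNetwork(rng.integers(-1, 2, size=(n, n), dtype=np.int8))


def random_uniform_batch(n: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """(size, n, n) batch of i.i.d. uniform trit matrices."""
    return rng.integers(-1, 2, size=(size, n, n), dtype=np.int8)


def random_density(
    n: int,
    edge_count: int,
    inhibitory_fraction: float,
    rng: np.random.Generator,
) -> SignedNetwork:
    """A network with exactly ``edge_count`` uniformly placed nonzero
    entries, each -1 with probability ``inhibitory_fraction`` else +1."""
    if not 0 <= edge_count <= n * n:
        raise ValueError("edge_count must be in [0, n^2]")
    W = np.zeros(n * n, dtype=np.int8)
    pos = rng.choice(n * n, size=edge_count, replace=False)
    signs = np.where(rng.random(edge_count) < inhibitory_fraction, -1, 1)
    W[pos] = signs
    return SignedNetwork(W.reshape(n, n))


def kauffman(n: int, K: int, rng: np.random.Generator) -> BooleanFunctionNetwork:
    """Kauffman NK random Boolean network: every node gets K distinct inputs
    chosen uniformly and a uniformly random truth table of 2^K fair bits."""
    if not 1 <= K <= n:
        raise ValueError("need 1 <= K <= n")
    inputs = [tuple(int(j) for j in rng.choice(n, size=K, replace=False))
              for _ in range(n)]
    tables = [rng.integers(0, 2, size=1 << K, dtype=np.uint8) for _ in range(n)]
    return BooleanFunctionNetwork(n=n, inputs=tuple(inputs), tables=tuple(tables))


@dataclass(frozen=True)
class CircuitStats:
    """Simple directed circuits of the interaction graph (self-loops are
    length-1 circuits); a circuit is excitatory when the product of its
    edge signs is +1, inhibitory when -1."""

    circuit_count: int
    mean_length: float          # nan when there is no circuit
    excitatory: int
    inhibitory: int
    self_excitation: int        # +1 diagonal entries
    self_inhibition: int        # -1 diagonal entries


def circuit_stats(net: SignedNetwork, n_cap: int = 12) -> CircuitStats:
    """Enumerate the simple directed circuits of W's nonzero pattern."""
    if net.n > n_cap:
        raise ValueError(f"circuit enumeration capped at n={n_cap}")
    G = nx.DiGraph()
    G.add_nodes_from(range(net.n))
    for i, j in zip(*np.nonzero(net.W)):
        G.add_edge(int(i), int(j), sign=int(net.W[i, j]))
    lengths, exc, inh = [], 0, 0
    for cyc in nx.simple_cycles(G):
        lengths.append(len(cyc))
        sign = 1
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            sign *= G.edges[a, b]["sign"]
        if sign > 0:
            exc += 1
        else:
            inh += 1
    diag = np.diag(net.W)
    return CircuitStats(
        circuit_count=len(lengths),
        mean_length=float(np.mean(lengths)) if lengths else float("nan"),
        excitatory=exc,
        inhibitory=inh,
        self_excitation=int((diag == 1).sum()),
        self_inhibition=int((diag == -1).sum()),
    )


_GROUPINGS = ("density", "edge_mix", "circuit_length", "self_loops")


def cycle_length_survey(
    n: int,
    samples: int,
    rng: np.random.Generator,
    group_by: str = "density",
    generator=None,
    chunk: int = 50_000,
) -> pd.DataFrame:
    """Sample networks, measure longest cycle lengths, aggregate by a grouping.

    ``group_by`` is one of ``density`` (nonzero-entry count), ``edge_mix``
    ((excitatory, inhibitory) counts), ``circuit_length`` (mean simple-circuit
    length, rounded to 1 decimal), or ``self_loops`` ((self-excitation,
    self-inhibition) counts).  The default generator is the uniform ensemble;
    pass ``generator(rng) -> SignedNetwork`` to survey another one.

    Returns a DataFrame with columns ``group``, ``mean_cycle``, ``max_cycle``,
    ``count``.
    """
    if samples < 1:
        raise ValueError("samples must be >= 1")
    if group_by not in _GROUPINGS:
        raise ValueError(f"group_by must be one of {_GROUPINGS}")
    groups: list = []
    cycles: list = []
    done = 0
    while done < samples:
        b = min(chunk, samples - done)
        if generator is None:
            W = random_uniform_batch(n, b, rng)
        else:
            W = np.stack([generator(rng).W for _ in range(b)])
        cyc = batch_max_cycle_length(W)
        cycles.append(cyc)
        if group_by == "density":
            g = np.count_nonzero(W.reshape(b, -1), axis=1)
            groups.extend(int(x) for x in g)
        elif group_by == "edge_mix":
            flat = W.reshape(b, -1)
            groups.extend(zip((flat == 1).sum(axis=1).tolist(),
                              (flat == -1).sum(axis=1).tolist()))
        elif group_by == "self_loops":
            diag = W[:, np.arange(n), np.arange(n)]
            groups.extend(zip((diag == 1).sum(axis=1).tolist(),
                              (diag == -1).sum(axis=1).tolist()))
        else:  # circuit_length
            for w in W:
                cs = circuit_stats(SignedNetwork(w))
                groups.append(round(cs.mean_length, 1)
                              if cs.circuit_count else 0.0)
        done += b
    df = pd.DataFrame({"group": groups, "cycle": np.concatenate(cycles)})
    out = (df.groupby("group")["cycle"]
             .agg(mean_cycle="mean", max_cycle="max", count="size")
             .reset_index()
             .rename(columns={"group": "group"}))
    return out


def compare_populations(values_a, values_b, test: str = "z",
                        alternative: str = "two-sided"):
    """Two-sample location test between populations of measurements.

    ``test="z"`` uses the unpooled normal z statistic; ``test="t"`` Welch's
    t.  Returns ``(statistic, p_value)``.  With zero variance in both
    samples the statistic is 0 and p 1.0 when the means agree, and
    ±inf / 0.0 when they differ (degenerate separation).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    if test != "z":
        raise ValueError("test must be 'z' or 't'")
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    se = np.sqrt(va / a.size + vb / b.size)
    diff = a.mean() - b.mean()
    if se == 0:
        if diff == 0:
            return 0.0, 1.0
        z = float(np.inf if diff > 0 else -np.inf)
    else:
        z = float(diff / se)
    if alternative == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        raise ValueError("alternative must be two-sided/greater/less")
    return z, float(p)
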