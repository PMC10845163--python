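"""Pareto genetic algorithm: maximize cycle length, minimize edge count.

Networks are encoded as genomes of n^2 trits (the row-major flattening of
W).  Fitness is bi-objective: the longest attractor cycle length (to be
maximized) against the number of nonzero interactions (to be minimized) —
long dynamical repertoires at low wiring cost.  The optimizer is a standard
non-dominated-sorting GA with crowding-distance diversity preservation
(NSGA-II style): binary tournament parent selection on (rank, crowding),
uniform crossover, per-locus trit mutation to a uniformly chosen different
value, and elitist mu+lambda survivor selection.  Runs are fully
reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import SignedNetwork
from .state_space import batch_max_cycle_length

__all__ = [
    "Objectives",
    "ParetoFront",
    "GAConfig",
    "dominates",
    "genome_to_network",
    "network_to_genome",
    "evaluate",
    "evolve",
]


@dataclass(frozen=True)
class Objectives:
    """One individual's fitness: cycle_len is maximized, edges minimized."""

    cycle_len: int
    edges: int


def dominates(a: Objectives, b: Objectives) -> bool:
    """Pareto dominance: a at least as good on both objectives, strictly
    better on one."""
    ge = a.cycle_len >= b.cycle_len and a.edges <= b.edges
    strict = a.cycle_len > b.cycle_len or a.edges < b.edges
    return ge and strict


def genome_to_network(genome: np.ndarray) -> SignedNetwork:
    g = np.asarray(genome, dtype=np.int8)
    n = int(round(np.sqrt(g.size)))
    if n * n != g.size:
        raise ValueError(f"genome length {g.size} is not a perfect square")
    return SignedNetwork(g.reshape(n, n))


def network_to_genome(net: SignedNetwork) -> np.ndarray:
    return net.W.reshape(-1).copy()


def evaluate(genome: np.ndarray) -> Objectives:
    """Decode and score one genome."""
    net = genome_to_network(genome)
    return Objectives(cycle_len=int(batch_max_cycle_length(net.W[None])[0]),
                      edges=net.edge_count)


@dataclass(frozen=True)
class GAConfig:
    n: int = 7
    pop_size: int = 100
    generations: int = 200
    crossover_rate: float = 0.7
    mutation_rate: float | None = None   # default 1/n^2 per locus
    tournament_size: int = 2

    def __post_init__(self):
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.mutation_rate is None:
            object.__setattr__(self, "mutation_rate", 1.0 / self.n**2)


@dataclass
class ParetoFront:
    """Final non-dominated set plus per-generation statistics."""

    n: int
    genomes: np.ndarray        # (F, n*n) trits
    objectives: list           # list of Objectives, parallel to genomes
    history: pd.DataFrame      # generation, best_cycle, front_size, hypervolume

    @property
    def members(self):
        return list(zip(self.genomes, self.objectives))

    def networks(self):
        return [genome_to_network(g) for g in self.genomes]

    def to_json(self, indent: int | None = None) -> str:
        payload = {
            "n": self.n,
            "members": [
                {"genome": [int(t) for t in g],
                 "cycle_len": o.cycle_len, "edges": o.edges}
                for g, o in zip(self.genomes, self.objectives)
            ],
            "history": self.history.to_dict(orient="list"),
        }
        return json.dumps(payload, indent=indent)


def _front_ranks(cycle: np.ndarray, edges: np.ndarray):
    """Non-dominated sorting: rank 0 is the Pareto front.  Vectorized
    pairwise dominance; fronts are peeled iteratively."""
    P = cycle.size
    ge = (cycle[:, None] >= cycle[None, :]) & (edges[:, None] <= edges[None, :])
    strict = (cycle[:, None] > cycle[None, :]) | (edges[:, None] < edges[None, :])
    dom = ge & strict  # dom[i, j]: i dominates j
    rank = np.full(P, -1, dtype=np.int64)
    remaining = np.ones(P, dtype=bool)
    r = 0
    while remaining.any():
        n_dom = (dom & remaining[:, None]).sum(axis=0)
        front = remaining & (n_dom == 0)
        rank[front] = r
        remaining &= ~front
        r += 1
    return rank


def _crowding(cycle: np.ndarray, edges: np.ndarray, rank: np.ndarray):
    P = cycle.size
    crowd = np.zeros(P)
    for r in np.unique(rank):
        idx = np.flatnonzero(rank == r)
        if idx.size <= 2:
            crowd[idx] = np.inf
            continue
        for obj in (cycle[idx].astype(float), edges[idx].astype(float)):
            order = np.argsort(obj, kind="stable")
            span = obj[order[-1]] - obj[order[0]]
            crowd[idx[order[0]]] = crowd[idx[order[-1]]] = np.inf
            if span > 0:
                gaps = (obj[order[2:]] - obj[order[:-2]]) / span
                crowd[idx[order[1:-1]]] += gaps
    return crowd


def _hypervolume(cycle: np.ndarray, edges: np.ndarray, n: int) -> float:
    """2-D hypervolume of the front w.r.t. the reference point
    (cycle_len=0, edges=n^2+1)."""
    rank = _front_ranks(cycle, edges)
    idx = np.flatnonzero(rank == 0)
    pts = sorted({(int(edges[i]), int(cycle[i])) for i in idx})
    hv = 0.0
    e_ref = n * n + 1
    for k, (e, c) in enumerate(pts):
        e_next = pts[k + 1][0] if k + 1 < len(pts) else e_ref
        hv += c * (e_next - e)
    return hv


def _select_survivors(cycle, edges, mu):
    rank = _front_ranks(cycle, edges)
    crowd = _crowding(cycle, edges, rank)
    # lexicographic (rank asc, crowding desc); stable for reproducibility
    order = np.lexsort((-crowd, rank))
    return order[:mu]


def evolve(
    n: int = 7,
    pop_size: int = 100,
    generations: int = 200,
    crossover_rate: float = 0.7,
    mutation_rate: float | None = None,
    seed: int | np.random.Generator = 0,
    init_genomes: np.ndarray | None = None,
) -> ParetoFront:
    """Run the Pareto GA and return the final front with run statistics.

    The initial population is uniform random trit genomes unless
    ``init_genomes`` is given.  Each generation produces ``pop_size``
    offspring by tournament selection, uniform crossover and per-locus
    mutation, then keeps the best ``pop_size`` of parents+offspring by
    (non-domination rank, crowding distance).
    """
    cfg = GAConfig(n=n, pop_size=pop_size, generations=generations,
                   crossover_rate=crossover_rate, mutation_rate=mutation_rate)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    L = n * n
    if init_genomes is None:
        pop = rng.integers(-1, 2, size=(pop_size, L), dtype=np.int8)
    else:
        pop = np.asarray(init_genomes, dtype=np.int8).copy()
        if pop.shape != (pop_size, L):
            raise ValueError("init_genomes must have shape (pop_size, n*n)")
    cycle = batch_max_cycle_length(pop.reshape(-1, n, n))
    edges = np.count_nonzero(pop, axis=1).astype(np.int64)

    hist = []
    for gen in range(cfg.generations):
        rank = _front_ranks(cycle, edges)
        crowd = _crowding(cycle, edges, rank)
        # binary tournament on (rank, crowding)
        cand = rng.integers(0, pop_size, size=(2 * pop_size, cfg.tournament_size))
        best = cand[:, 0]
        for t in range(1, cfg.tournament_size):
            ch = cand[:, t]
            better = (rank[ch] < rank[best]) | (
                (rank[ch] == rank[best]) & (crowd[ch] > crowd[best]))
            best = np.where(better, ch, best)
        p1, p2 = best[:pop_size], best[pop_size:]
        children = pop[p1].copy()
        cross = rng.random(pop_size) < cfg.crossover_rate
        swap_mask = rng.random((pop_size, L)) < 0.5
        take2 = cross[:, None] & swap_mask
        children[take2] = pop[p2][take2]
        # per-locus mutation to a uniformly chosen *different* trit
        mut = rng.random((pop_size, L)) < cfg.mutation_rate
        shift = rng.integers(1, 3, size=(pop_size, L), dtype=np.int8)
        mutated = ((children + 1 + shift) % 3 - 1).astype(np.int8)
        children[mut] = mutated[mut]

        ch_cycle = batch_max_cycle_length(children.reshape(-1, n, n))
        ch_edges = np.count_nonzero(children, axis=1).astype(np.int64)
        all_pop = np.concatenate([pop, children])
        all_cycle = np.concatenate([cycle, ch_cycle])
        all_edges = np.concatenate([edges, ch_edges])
        keep = _select_survivors(all_cycle, all_edges, pop_size)
        pop, cycle, edges = all_pop[keep], all_cycle[keep], all_edges[keep]
        hist.append((gen + 1, int(cycle.max()),
                     int((_front_ranks(cycle, edges) == 0).sum()),
                     _hypervolume(cycle, edges, n)))

    rank = _front_ranks(cycle, edges)
    idx = np.flatnonzero(rank == 0)
    # drop exact duplicate genomes; distinct genomes with equal objectives stay
    genomes = pop[idx]
    _, uniq = np.unique(genomes, axis=0, return_index=True)
    idx = idx[np.sort(uniq)]
    history = pd.DataFrame(hist, columns=[
        "generation", "best_cycle", "front_size", "hypervolume"])
    return ParetoFront(
        n=n,
        genomes=pop[idx],
        objectives=[Objectives(int(cycle[i]), int(edges[i])) for i in idx],
        history=history,
    )
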