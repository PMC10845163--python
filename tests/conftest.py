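import numpy as np
import pytest

from cyclesym import SignedNetwork
from cyclesym.evolution import evolve


@pytest.fixture
def mutual_excitation():
    """Two mutually exciting, self-inhibiting nodes: the smallest network
    with a period-2 attractor."""
    return SignedNetwork([[-1, 1], [1, -1]])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_attractors(net):
    """Independent attractor oracle: iterate the single-step update from
    every start state until a state repeats; the tail of each trajectory is
    the attractor cycle, and each start contributes one basin count.

    Returns (set of cycles as frozensets of states, dict cycle -> basin size).
    """
    N = 1 << net.n
    basins: dict[frozenset, int] = {}
    cycles_states: dict[frozenset, tuple] = {}
    for s0 in range(N):
        seen = {}
        s = s0
        t = 0
        while s not in seen:
            seen[s] = t
            s = net.step(s)
            t += 1
        # s is the first repeated state; the cycle is everything from its
        # first occurrence onward
        start = seen[s]
        cycle = tuple(st for st, when in sorted(seen.items(), key=lambda kv: kv[1])
                      if when >= start)
        key = frozenset(cycle)
        cycles_states[key] = cycle
        basins[key] = basins.get(key, 0) + 1
    return cycles_states, basins


@pytest.fixture(scope="session")
def evolved_fronts():
    """Twenty replicate Pareto-GA runs at the study scale (n=7, population
    100, 200 generations), shared by the evolution-based checks."""
    return [evolve(n=7, pop_size=100, generations=200, seed=s)
            for s in range(20)]
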