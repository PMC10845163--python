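"""Exhaustive state-space analysis: transition maps, attractors, basins.

The synchronous dynamics of an ``n``-node network form a functional graph
τ on the ``2**n`` states; every connected component of that graph contains
exactly one directed cycle (an attractor — a fixed point counts as a
length-1 cycle) and the component is the cycle's basin.  This module
materializes τ as a table, extracts all cycles with exact basin sizes in
linear time, and measures the effect of single-edge perturbations on the
longest cycle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _fast
from .network import BooleanFunctionNetwork, SignedNetwork, decode_state

__all__ = [
    "DEFAULT_STATE_SPACE_CAP",
    "CapacityError",
    "TransitionMap",
    "AttractorSet",
    "build_transition_map",
    "find_attractors",
    "max_cycle_length",
    "batch_max_cycle_length",
    "edge_perturbation_decrement",
]

#: Largest n for which the full 2**n transition table is materialized.
DEFAULT_STATE_SPACE_CAP = 22


class CapacityError(ValueError):
    """Raised when an exhaustive computation would exceed the state-space cap;
    use the sampled estimators in :mod:`cyclesym.symmetry` instead."""


def _check_cap(n: int, cap: int) -> None:
    if n > cap:
        raise CapacityError(
            f"n={n} exceeds the state-space cap ({cap}): the full 2^n table "
            "is not materialized; use sampled_symmetry for large networks")


@dataclass(frozen=True)
class TransitionMap:
    """The functional graph τ as a table: ``successor[s]`` = τ(s)."""

    n: int
    successor: np.ndarray

    def __post_init__(self):
        succ = np.asarray(self.successor, dtype=np.int64)
        N = 1 << self.n
        if succ.shape != (N,):
            raise ValueError(f"successor must have length 2**n = {N}")
        if succ.size and (succ.min() < 0 or succ.max() >= N):
            raise ValueError("successor entries must lie in [0, 2**n)")
        object.__setattr__(self, "successor", succ)
        self.successor.setflags(write=False)


@dataclass(frozen=True)
class AttractorSet:
    """All attractor cycles of a transition map with exact basin sizes."""

    n: int
    cycles: tuple            # tuple of tuples of integer states
    basin_sizes: tuple       # one basin size per cycle; sums to 2**n

    @property
    def max_cycle_length(self) -> int:
        return max(len(c) for c in self.cycles)

    @property
    def fixed_points(self) -> tuple:
        return tuple(c[0] for c in self.cycles if len(c) == 1)

    def to_json(self, indent: int | None = None) -> str:
        payload = {
            "n": self.n,
            "cycles": [
                {
                    "length": len(c),
                    "states": list(c),
                    "states_bits": [list(decode_state(s, self.n)) for s in c],
                    "basin_size": b,
                }
                for c, b in zip(self.cycles, self.basin_sizes)
            ],
            "max_cycle_length": self.max_cycle_length,
        }
        return json.dumps(payload, indent=indent)


def build_transition_map(net, cap: int = DEFAULT_STATE_SPACE_CAP) -> TransitionMap:
    """Materialize τ over all ``2**n`` states (vectorized over states)."""
    n = net.n
    _check_cap(n, cap)
    N = 1 << n
    states = np.arange(N, dtype=np.uint64)
    X = ((states[:, None] >> np.arange(n, dtype=np.uint64)) & 1).astype(np.uint8)
    Y = net.step_bits(X)
    powers = (np.uint64(1) << np.arange(n, dtype=np.uint64))
    succ = (Y.astype(np.uint64) @ powers).astype(np.int64)
    return TransitionMap(n=n, successor=succ)


def find_attractors(tmap: TransitionMap) -> AttractorSet:
    """Every cycle of τ plus exact basin sizes, by iterative path colouring.

    Linear in the number of states: each state is walked once while
    unvisited, and basin labels propagate backwards along finished paths.
    """
    succ = tmap.successor
    N = succ.size
    basin_of = np.full(N, -1, dtype=np.int64)  # cycle index per state
    on_path = np.zeros(N, dtype=bool)
    cycles: list[tuple] = []
    path: list[int] = []
    for start in range(N):
        if basin_of[start] >= 0:
            continue
        v = start
        path.clear()
        while basin_of[v] < 0 and not on_path[v]:
            on_path[v] = True
            path.append(v)
            v = int(succ[v])
        if on_path[v]:
            # closed a brand-new cycle starting at v
            i = path.index(v)
            cyc = tuple(path[i:])
            label = len(cycles)
            cycles.append(cyc)
            for s in cyc:
                basin_of[s] = label
        label = basin_of[v]
        for s in path:
            basin_of[s] = label
            on_path[s] = False
    counts = np.bincount(basin_of, minlength=len(cycles))
    return AttractorSet(n=tmap.n, cycles=tuple(cycles),
                        basin_sizes=tuple(int(c) for c in counts))


def max_cycle_length(net, cap: int = DEFAULT_STATE_SPACE_CAP) -> int:
    """Length of the longest attractor cycle (>= 1; fixed points count)."""
    if isinstance(net, SignedNetwork):
        _check_cap(net.n, cap)
        succ = _fast.succ_tables(net.W[None, :, :])
        return int(_fast.max_cycle_lengths(succ)[0])
    tmap = build_transition_map(net, cap=cap)
    return int(_fast.max_cycle_lengths(tmap.successor[None, :].astype(np.int32))[0])


def batch_max_cycle_length(W_batch: np.ndarray) -> np.ndarray:
    """Longest-cycle length for each of a (B, n, n) batch of trit matrices."""
    W_batch = np.ascontiguousarray(np.asarray(W_batch, dtype=np.int8))
    succ = _fast.succ_tables(W_batch)
    return _fast.max_cycle_lengths(succ)


def edge_perturbation_decrement(
    net: SignedNetwork,
    trials: int,
    rng: np.random.Generator,
    nonzero_only: bool = False,
    cap: int = DEFAULT_STATE_SPACE_CAP,
):
    """Distribution of the drop in longest cycle length under single-edge edits.

    Each trial picks one matrix position uniformly (over all n^2 entries, or
    over the nonzero ones with ``nonzero_only``), changes its trit to one of
    the two other values uniformly, and records
    ``original_max_cycle - perturbed_max_cycle``.

    Returns ``(decrements, mean)`` where ``decrements`` is an int array of
    length ``trials``.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    n = net.n
    _check_cap(n, cap)
    base = max_cycle_length(net, cap=cap)
    if nonzero_only:
        pos = np.argwhere(net.W != 0)
        if pos.size == 0:
            raise ValueError("nonzero_only requested but the network has no edges")
        picks = pos[rng.integers(0, len(pos), size=trials)]
    else:
        flat = rng.integers(0, n * n, size=trials)
        picks = np.column_stack((flat // n, flat % n))
    W_batch = np.repeat(net.W[None, :, :], trials, axis=0).astype(np.int8)
    for t, (i, j) in enumerate(picks):
        old = int(net.W[i, j])
        others = [v for v in (-1, 0, 1) if v != old]
        W_batch[t, i, j] = others[rng.integers(0, 2)]
    perturbed = batch_max_cycle_length(W_batch)
    decs = base - perturbed
    return decs, float(decs.mean())
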