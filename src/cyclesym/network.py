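"""Core network types and the synchronous update rule.

Two model classes share one dynamics interface:

* :class:`SignedNetwork` — an ``n x n`` matrix of trits ``W`` with
  ``W[i, j]`` the sign of the directed edge *i -> j* (+1 excitatory,
  -1 inhibitory, 0 absent).  A node activates at the next step iff its
  signed input sum is strictly positive; a tie (sum = 0) deactivates it.
* :class:`BooleanFunctionNetwork` — per-node truth tables over an ordered
  input list, the general Boolean-network form used for ``.bnet`` models
  and Kauffman random ensembles.

States are encoded as integers, LSB-first: bit ``i`` of the integer is the
state of node ``i``, so the state ``s`` equals ``sum_i x_i * 2**i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SignedNetwork",
    "BooleanFunctionNetwork",
    "encode_state",
    "decode_state",
    "negate",
    "step",
    "trajectory",
]

TRITS = (-1, 0, 1)


def encode_state(bits) -> int:
    """Pack a sequence of 0/1 node states (node 0 first) into an integer."""
    s = 0
    for i, b in enumerate(bits):
        if b not in (0, 1):
            raise ValueError(f"state bits must be 0/1, got {b!r}")
        s |= int(b) << i
    return s


def decode_state(s: int, n: int) -> tuple[int, ...]:
    """Unpack an integer state into the tuple (x_0, x_1, ..., x_{n-1})."""
    _check_state(s, n)
    return tuple((s >> i) & 1 for i in range(n))


def negate(s: int, n: int) -> int:
    """Bitwise complement within ``n`` bits: the NOT-gate reflection ¬s."""
    _check_state(s, n)
    return ((1 << n) - 1) - s


def _check_state(s: int, n: int) -> None:
    if not 0 <= s < (1 << n):
        raise ValueError(f"state {s} out of range for n={n}")


@dataclass(frozen=True)
class SignedNetwork:
    """Signed threshold network: trit interaction matrix plus the update rule.

    Parameters
    ----------
    W : array-like of shape (n, n)
        ``W[i, j]`` in {-1, 0, 1} is the sign of the edge from node ``i``
        to node ``j``.  The diagonal holds self-loops.
    """

    W: np.ndarray

    def __post_init__(self):
        W = np.asarray(self.W, dtype=np.int8)
        if W.ndim != 2 or W.shape[0] != W.shape[1] or W.shape[0] < 1:
            raise ValueError(f"W must be a square n>=1 matrix, got shape {W.shape}")
        if not np.isin(W, TRITS).all():
            raise ValueError("W entries must be trits in {-1, 0, 1}")
        object.__setattr__(self, "W", W)
        self.W.setflags(write=False)

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def edge_count(self) -> int:
        """Number of nonzero interactions (self-loops included)."""
        return int(np.count_nonzero(self.W))

    @property
    def density(self) -> float:
        return self.edge_count / self.n**2

    def step(self, s: int) -> int:
        """One synchronous update: bit i of the result is 1 iff the signed
        input sum ``sum_j W[j, i] * x_j`` is strictly positive."""
        _check_state(s, self.n)
        x = np.fromiter(((s >> i) & 1 for i in range(self.n)), dtype=np.int64,
                        count=self.n)
        sums = x @ self.W
        out = 0
        for i in range(self.n):
            if sums[i] > 0:
                out |= 1 << i
        return out

    def step_bits(self, X: np.ndarray) -> np.ndarray:
        """Vectorized update of a batch of states given as an (m, n) 0/1 array."""
        return (X.astype(np.int64) @ self.W > 0).astype(np.uint8)

    def relabel(self, perm) -> "SignedNetwork":
        """Apply a node permutation to rows and columns simultaneously."""
        p = np.asarray(perm)
        return SignedNetwork(self.W[np.ix_(p, p)])


@dataclass(frozen=True)
class BooleanFunctionNetwork:
    """General synchronous Boolean network given by per-node truth tables.

    ``inputs[i]`` is the ordered list of input node indices of node ``i``
    (length ``k_i``); ``tables[i]`` is a length ``2**k_i`` 0/1 array whose
    entry at index ``sum_j x_{inputs[i][j]} * 2**j`` is the node's next
    state.  Constant nodes have ``k_i = 0`` and a single-entry table.
    """

    n: int
    inputs: tuple = field(default=())
    tables: tuple = field(default=())
    names: tuple = field(default=())

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(self.inputs) != self.n or len(self.tables) != self.n:
            raise ValueError("inputs and tables must each have one entry per node")
        inputs = tuple(tuple(int(j) for j in inp) for inp in self.inputs)
        tables = tuple(np.asarray(t, dtype=np.uint8) for t in self.tables)
        for i, (inp, tab) in enumerate(zip(inputs, tables)):
            if any(not 0 <= j < self.n for j in inp):
                raise ValueError(f"node {i}: input index out of range")
            if tab.size != 1 << len(inp):
                raise ValueError(
                    f"node {i}: table length {tab.size} != 2**{len(inp)}")
            if not np.isin(tab, (0, 1)).all():
                raise ValueError(f"node {i}: table entries must be 0/1")
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "tables", tables)
        names = tuple(self.names) if self.names else tuple(
            f"v{i}" for i in range(self.n))
        if len(names) != self.n:
            raise ValueError("names must have one entry per node")
        object.__setattr__(self, "names", names)

    @property
    def mean_in_degree(self) -> float:
        return sum(len(inp) for inp in self.inputs) / self.n

    def step(self, s: int) -> int:
        _check_state(s, self.n)
        out = 0
        for i in range(self.n):
            idx = 0
            for j, src in enumerate(self.inputs[i]):
                idx |= ((s >> src) & 1) << j
            if self.tables[i][idx]:
                out |= 1 << i
        return out

    def step_bits(self, X: np.ndarray) -> np.ndarray:
        """Vectorized update of an (m, n) 0/1 state array."""
        m = X.shape[0]
        out = np.empty((m, self.n), dtype=np.uint8)
        for i in range(self.n):
            idx = np.zeros(m, dtype=np.int64)
            for j, src in enumerate(self.inputs[i]):
                idx |= X[:, src].astype(np.int64) << j
            out[:, i] = self.tables[i][idx]
        return out


Network = SignedNetwork | BooleanFunctionNetwork


def step(net: Network, s: int) -> int:
    """Successor τ(s) of integer state ``s`` under one synchronous update."""
    return net.step(s)


def trajectory(net: Network, s0: int, t_max: int):
    """Iterate τ from ``s0`` for at most ``t_max`` steps.

    Returns ``(states, repeated)`` where ``states`` starts with ``s0`` and
    stops either after ``t_max`` steps or one step after the first revisited
    state (the repeat is included); ``repeated`` says which happened.
    """
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    _check_state(s0, net.n)
    states = [s0]
    seen = {s0}
    for _ in range(t_max):
        nxt = net.step(states[-1])
        states.append(nxt)
        if nxt in seen:
            return states, True
        seen.add(nxt)
    return states, False
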