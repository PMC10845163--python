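"""3-node signed motif census, suppressed-motif detection, and gluing.

A *3-motif* is the induced signed subgraph on three nodes — a 3x3 trit
matrix considered up to simultaneous row/column permutation.  Its canonical
form is the lexicographically smallest row-major flattening over the six
node permutations, with trit order -1 < 0 < 1; canonical ids are written as
9-character strings over ``-0+`` (row-major).

Of the 3^9 = 19683 labeled matrices there are 3411 permutation classes
(Burnside: (19683 + 3*243 + 2*27)/6).  A class is *connected* when every
node has at least one inter-node edge, incoming or outgoing (self-loops do
not confer connectivity); 127 classes fail this, leaving 3284 connected
classes — the universe used for network scans.

*Suppressed motifs* are classes strongly under-represented in a target
population (cycle-optimized evolved networks) relative to a baseline
(density-matched random networks).  ``glue_network`` builds networks by
stamping motifs from a given set onto random node triples until a target
edge density is reached, the construction used to show that suppressed
motifs actively destroy long cycles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import SignedNetwork

__all__ = [
    "Motif",
    "MotifCensus",
    "canonical_form",
    "matrix_to_id",
    "id_to_matrix",
    "enumerate_motif_classes",
    "scan_network",
    "motif_enrichment",
    "glue_network",
    "GlueResult",
]

_PERMS = list(itertools.permutations(range(3)))
_WEIGHTS = 3 ** np.arange(8, -1, -1, dtype=np.int64)  # first entry most significant
_CHARS = "-0+"


def _build_tables():
    """Canonical raw index and connectivity for all 19683 labeled matrices."""
    idx = np.arange(3**9, dtype=np.int64)
    digits = (idx[:, None] // _WEIGHTS[None, :]) % 3  # (19683, 9), row-major
    canon = np.full(3**9, np.iinfo(np.int64).max, dtype=np.int64)
    for perm in _PERMS:
        flat_map = [3 * perm[a] + perm[b] for a in range(3) for b in range(3)]
        vals = digits[:, flat_map] @ _WEIGHTS
        np.minimum(canon, vals, out=canon)
    mats = digits.reshape(-1, 3, 3) - 1
    off = ~np.eye(3, dtype=bool)
    isolated = np.zeros(3**9, dtype=bool)
    for a in range(3):
        row = mats[:, a, :][:, off[a]]
        col = mats[:, :, a][:, off[:, a]]
        isolated |= (row == 0).all(axis=1) & (col == 0).all(axis=1)
    return canon, ~isolated


_CANON, _CONNECTED = _build_tables()


def _raw_index(M: np.ndarray) -> int:
    return int((M.reshape(9) + 1) @ _WEIGHTS)


def _index_to_matrix(idx: int) -> np.ndarray:
    digits = (idx // _WEIGHTS) % 3
    return (digits - 1).reshape(3, 3).astype(np.int8)


def matrix_to_id(M: np.ndarray) -> str:
    """Row-major 9-character ``-0+`` string of a 3x3 trit matrix."""
    return "".join(_CHARS[d + 1] for d in np.asarray(M, dtype=int).reshape(9))


def id_to_matrix(motif_id: str) -> np.ndarray:
    if len(motif_id) != 9 or any(c not in _CHARS for c in motif_id):
        raise ValueError(f"malformed motif id {motif_id!r}")
    return np.array([_CHARS.index(c) - 1 for c in motif_id],
                    dtype=np.int8).reshape(3, 3)


def canonical_form(M) -> str:
    """Canonical id of a 3x3 trit matrix: the lexicographic minimum of the
    row-major flattening over the 6 simultaneous row/column permutations."""
    M = np.asarray(M, dtype=np.int8)
    if M.shape != (3, 3) or not np.isin(M, (-1, 0, 1)).all():
        raise ValueError("motif must be a 3x3 matrix of trits in {-1, 0, 1}")
    return matrix_to_id(_index_to_matrix(int(_CANON[_raw_index(M)])))


def is_connected_motif(M) -> bool:
    """True when every node touches the other two by some edge (self-loops
    ignored)."""
    M = np.asarray(M, dtype=np.int8)
    return bool(_CONNECTED[_raw_index(M)])


@dataclass(frozen=True)
class Motif:
    """A 3-node signed motif held in canonical form."""

    canonical_id: str

    @classmethod
    def from_matrix(cls, M) -> "Motif":
        return cls(canonical_form(M))

    @property
    def matrix(self) -> np.ndarray:
        return id_to_matrix(self.canonical_id)

    @property
    def connected(self) -> bool:
        return is_connected_motif(self.matrix)


def enumerate_motif_classes(connected_only: bool = False) -> set[str]:
    """All distinct motif classes by exhaustive enumeration of the 19683
    labeled matrices; with ``connected_only`` the 127 classes containing a
    node with no inter-node edge are discarded."""
    canon_ids = np.unique(_CANON)
    if connected_only:
        canon_ids = canon_ids[_CONNECTED[canon_ids]]
    return {matrix_to_id(_index_to_matrix(int(i))) for i in canon_ids}


@dataclass
class MotifCensus:
    """Counts of connected motif classes over node triples.

    ``counts`` maps canonical id -> count; ``triples_scanned`` includes
    triples whose induced motif was disconnected (those are scanned but not
    counted, keeping rates on the 3284-class universe).
    """

    counts: dict = field(default_factory=dict)
    triples_scanned: int = 0

    def add(self, other: "MotifCensus") -> "MotifCensus":
        merged = dict(self.counts)
        for k, v in other.counts.items():
            merged[k] = merged.get(k, 0) + v
        return MotifCensus(counts=merged,
                           triples_scanned=self.triples_scanned + other.triples_scanned)

    def rate(self, motif_id: str) -> float:
        if self.triples_scanned == 0:
            return 0.0
        return self.counts.get(motif_id, 0) / self.triples_scanned

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, v, v / self.triples_scanned)
                for k, v in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["canonical_id", "count", "rate"])


def scan_network(net: SignedNetwork) -> MotifCensus:
    """Census of the C(n,3) induced triads of one network (connected classes
    only)."""
    n = net.n
    if n < 3:
        raise ValueError("motif scan needs n >= 3")
    triples = np.array(list(itertools.combinations(range(n), 3)))
    sub = net.W[triples[:, :, None], triples[:, None, :]]  # (T, 3, 3)
    raw = (sub.reshape(-1, 9).astype(np.int64) + 1) @ _WEIGHTS
    counts: dict[str, int] = {}
    for r in raw:
        if _CONNECTED[r]:
            cid = matrix_to_id(_index_to_matrix(int(_CANON[r])))
            counts[cid] = counts.get(cid, 0) + 1
    return MotifCensus(counts=counts, triples_scanned=len(triples))


def scan_population(nets) -> MotifCensus:
    """Pooled census over a population of networks."""
    total = MotifCensus()
    for net in nets:
        total = total.add(scan_network(net))
    return total


def motif_enrichment(
    target: MotifCensus,
    baseline: MotifCensus,
    ratio_threshold: float = 0.05,
    min_support: int = 50,
):
    """Per-motif frequency ratios target/baseline and the suppressed set.

    Only motifs with baseline count >= ``min_support`` are assessed; rates
    are normalized by each census's ``triples_scanned``.  A motif whose
    ratio falls below ``ratio_threshold`` is flagged suppressed.

    Returns ``(report, suppressed)``: a DataFrame with one row per assessed
    motif and the set of suppressed canonical ids.
    """
    if baseline.triples_scanned == 0 or not baseline.counts:
        raise ValueError("baseline census is empty")
    rows = []
    suppressed = set()
    for motif_id, b_count in sorted(baseline.counts.items()):
        if b_count < min_support:
            continue
        b_rate = b_count / baseline.triples_scanned
        t_count = target.counts.get(motif_id, 0)
        t_rate = t_count / target.triples_scanned if target.triples_scanned else 0.0
        ratio = t_rate / b_rate
        flag = ratio < ratio_threshold
        if flag:
            suppressed.add(motif_id)
        rows.append((motif_id, t_count, b_count, t_rate, b_rate, ratio, flag))
    report = pd.DataFrame(rows, columns=[
        "canonical_id", "target_count", "baseline_count",
        "target_rate", "baseline_rate", "ratio", "suppressed"])
    return report, suppressed


@dataclass(frozen=True)
class GlueResult:
    network: SignedNetwork
    stamps: int
    reached_density: bool


def glue_network(
    n: int,
    motif_ids,
    target_density: float,
    rng: np.random.Generator,
    stamp_budget: int | None = None,
) -> GlueResult:
    """Build a network by stamping motifs onto random node triples.

    Starting from the empty matrix, each stamp draws a uniformly random
    ordered triple of distinct nodes and a uniformly random motif from
    ``motif_ids`` and overwrites the induced 3x3 submatrix with the motif's
    canonical matrix (the random ordering of the triple realizes a uniform
    relabeling of the class).  Stamping stops when the fraction of nonzero
    entries first reaches ``target_density`` or the stamp budget
    (default ``50 * n**2``) is exhausted; ``reached_density`` reports which.
    """
    if n < 3:
        raise ValueError("gluing needs n >= 3")
    if not 0 < target_density <= 1:
        raise ValueError("target_density must be in (0, 1]")
    motif_list = sorted(set(motif_ids))
    if not motif_list:
        raise ValueError("motif set must be nonempty")
    mats = [id_to_matrix(m) for m in motif_list]
    if stamp_budget is None:
        stamp_budget = 50 * n * n
    W = np.zeros((n, n), dtype=np.int8)
    target_edges = target_density * n * n
    stamps = 0
    while np.count_nonzero(W) < target_edges and stamps < stamp_budget:
        triple = rng.choice(n, size=3, replace=False)
        M = mats[rng.integers(0, len(mats))]
        W[np.ix_(triple, triple)] = M
        stamps += 1
    reached = np.count_nonzero(W) >= target_edges
    return GlueResult(network=SignedNetwork(W), stamps=stamps,
                      reached_density=bool(reached))
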