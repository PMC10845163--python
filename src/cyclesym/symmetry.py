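"""Dynamical reflection-symmetry metrics.

A synchronous Boolean network has *dynamical reflection symmetry* at a state
x when complementing the state commutes with the update: τ(¬x) = ¬τ(x),
with ¬ the bitwise NOT.  Two metrics quantify how much of the state space
respects this reflection:

* the **fully symmetric fraction** — the fraction of states x whose entire
  transition is mirrored, τ(¬x) = ¬τ(x);
* the **partial symmetry ratio** ``p_sr`` — the fraction of individual bits
  that transition symmetrically,

  .. math:: p_{sr} = \\frac{1}{2^n n} \\sum_x \\sum_i
            \\theta(|f(x)_i - f(\\neg x)_i|),

  where θ(z)=1 for z>0 and 0 otherwise: bit i of state x counts as
  symmetric when ``f(x)_i != f(¬x)_i``.

Both are computed exactly by sweeping the full ``2**n`` table when n is
below the state-space cap, and by uniform Monte-Carlo state sampling with a
binomial confidence half-width otherwise (biological-scale models reach
hundreds of nodes, where 2^n is unreachable).  No state is its own
complement, so every state pairs with a distinct mirror partner.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .state_space import DEFAULT_STATE_SPACE_CAP, build_transition_map

__all__ = [
    "SymmetryReport",
    "full_symmetric_fraction",
    "partial_symmetry_ratio",
    "sampled_symmetry",
    "symmetry_report",
]

_POPCOUNT8 = np.array([bin(i).count("1") for i in range(256)], dtype=np.int64)


def _popcount(a: np.ndarray) -> np.ndarray:
    a = a.astype(np.uint64)
    out = np.zeros(a.shape, dtype=np.int64)
    for shift in range(0, 64, 8):
        out += _POPCOUNT8[((a >> np.uint64(shift)) & np.uint64(0xFF)).astype(np.int64)]
    return out


@dataclass(frozen=True)
class SymmetryReport:
    """Reflection-symmetry metrics for one network."""

    n: int
    full_sym_count: float        # states x with tau(¬x) = ¬tau(x) (estimate if sampled)
    full_sym_fraction: float
    p_sr: float
    method: str                  # "exact" | "sampled"
    sample_count: int | None = None
    ci_halfwidth_full: float | None = None
    ci_halfwidth_psr: float | None = None

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps(asdict(self), indent=indent)


def full_symmetric_fraction(net, cap: int = DEFAULT_STATE_SPACE_CAP):
    """Exact count and fraction of fully symmetric states.

    Returns ``(count, fraction)`` with ``count`` the number of states x
    (out of 2**n) satisfying τ(¬x) = ¬τ(x).
    """
    tmap = build_transition_map(net, cap=cap)
    succ = tmap.successor
    mask = (1 << net.n) - 1
    sym = succ[::-1] == mask - succ  # index ¬x = mask - x
    count = int(sym.sum())
    return count, count / (mask + 1)


def partial_symmetry_ratio(net, cap: int = DEFAULT_STATE_SPACE_CAP) -> float:
    """Exact partial symmetry ratio: mean over states and bits of the
    indicator that bit i transitions symmetrically (f(x)_i != f(¬x)_i)."""
    tmap = build_transition_map(net, cap=cap)
    succ = tmap.successor
    mask = (1 << net.n) - 1
    # bit i of succ[x] XOR succ[¬x] is set exactly when f(x)_i != f(¬x)_i
    diff_bits = _popcount(np.bitwise_xor(succ, succ[::-1]))
    return float(diff_bits.sum()) / ((mask + 1) * net.n)


def symmetry_report(net, cap: int = DEFAULT_STATE_SPACE_CAP,
                    m: int = 10_000,
                    rng: np.random.Generator | None = None) -> SymmetryReport:
    """Exact metrics when ``2**n`` is materializable, sampled otherwise."""
    if net.n <= cap:
        count, frac = full_symmetric_fraction(net, cap=cap)
        return SymmetryReport(n=net.n, full_sym_count=count,
                              full_sym_fraction=frac,
                              p_sr=partial_symmetry_ratio(net, cap=cap),
                              method="exact")
    if rng is None:
        rng = np.random.default_rng()
    return sampled_symmetry(net, m=m, rng=rng)


def sampled_symmetry(net, m: int, rng: np.random.Generator) -> SymmetryReport:
    """Monte-Carlo estimates of both symmetry metrics from ``m`` uniform states.

    Draws states as independent fair-coin bit vectors, evaluates f(x) and
    f(¬x) in vectorized batches, and returns unbiased estimates with a
    normal-approximation binomial 95% confidence half-width.  Works for any
    network size.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    n = net.n
    X = rng.integers(0, 2, size=(m, n), dtype=np.int8).astype(np.uint8)
    FX = net.step_bits(X)
    FNX = net.step_bits(1 - X)
    # bit i symmetric  <=>  f(x)_i != f(¬x)_i
    sym_bits = FX != FNX
    full_sym = sym_bits.all(axis=1)
    p_full = float(full_sym.mean())
    p_sr = float(sym_bits.mean())
    hw_full = 1.96 * np.sqrt(p_full * (1 - p_full) / m)
    hw_psr = 1.96 * np.sqrt(p_sr * (1 - p_sr) / (m * n))
    return SymmetryReport(
        n=n,
        full_sym_count=p_full * (2.0**n),
        full_sym_fraction=p_full,
        p_sr=p_sr,
        method="sampled",
        sample_count=m,
        ci_halfwidth_full=float(hw_full),
        ci_halfwidth_psr=float(hw_psr),
    )
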