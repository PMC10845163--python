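"""Readers/writers for network formats and the batch symmetry screen.

Signed networks travel as TSV trit matrices (rows = source node) or as
JSON ``{"n": ..., "W": [[...]]}``; Boolean-function models as ``.bnet``
files.  ``screen_models`` runs the reflection-symmetry screen over a
directory of model files and returns one row per model — the workflow used
to compare repositories of biological Boolean models against random
baselines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bnet import compile_model, read_bnet
from .network import SignedNetwork
from .state_space import DEFAULT_STATE_SPACE_CAP
from .symmetry import symmetry_report

__all__ = [
    "read_network_tsv",
    "write_network_tsv",
    "read_network_json",
    "write_network_json",
    "load_network",
    "read_motif_ids",
    "write_motif_ids",
    "screen_models",
]


def read_network_tsv(path) -> SignedNetwork:
    W = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return SignedNetwork(W)


def write_network_tsv(net: SignedNetwork, path) -> None:
    np.savetxt(path, net.W, fmt="%d", delimiter="\t")


def read_network_json(path) -> SignedNetwork:
    with open(path) as fh:
        payload = json.load(fh)
    W = np.asarray(payload["W"])
    if payload.get("n") not in (None, W.shape[0]):
        raise ValueError(f"{path}: declared n={payload['n']} does not match "
                         f"matrix shape {W.shape}")
    return SignedNetwork(W)


def write_network_json(net: SignedNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump({"n": net.n, "W": net.W.tolist()}, fh)


_LOADERS = {".tsv": read_network_tsv, ".txt": read_network_tsv,
            ".json": read_network_json}


def load_network(path):
    """Load a model by extension: TSV/JSON trit matrix -> SignedNetwork,
    ``.bnet`` -> compiled BooleanFunctionNetwork."""
    p = Path(path)
    if p.suffix == ".bnet":
        return compile_model(read_bnet(p))
    try:
        return _LOADERS[p.suffix](p)
    except KeyError:
        raise ValueError(f"unsupported network format {p.suffix!r}") from None


def read_motif_ids(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_motif_ids(ids, path) -> None:
    with open(path, "w") as fh:
        for motif_id in sorted(ids):
            fh.write(motif_id + "\n")


def screen_models(
    paths,
    cap: int = DEFAULT_STATE_SPACE_CAP,
    m: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Symmetry screen over model files (``.bnet``/TSV/JSON).

    For each model, computes both reflection-symmetry metrics — exactly
    when ``2**n`` fits under ``cap``, by ``m``-state sampling otherwise —
    and reports name, size, mean in-degree, the metrics, the method used,
    and the sampling confidence half-width.
    """
    paths = sorted(Path(p) for p in paths)
    rng = np.random.default_rng(seed)
    rows = []
    for p in paths:
        net = load_network(p)
        rep = symmetry_report(net, cap=cap, m=m, rng=rng)
        if isinstance(net, SignedNetwork):
            mean_k = float(np.count_nonzero(net.W, axis=0).mean())
        else:
            mean_k = net.mean_in_degree
        rows.append({
            "model": p.stem,
            "n": net.n,
            "mean_in_degree": mean_k,
            "full_sym_fraction": rep.full_sym_fraction,
            "p_sr": rep.p_sr,
            "method": rep.method,
            "sample_count": rep.sample_count,
            "ci_halfwidth_psr": rep.ci_halfwidth_psr,
        })
    return pd.DataFrame(rows)
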