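"""Graph-theoretic summaries of binary directed networks and raw GC matrices.

Characteristic path length L averages the directed shortest-path lengths
m_ij over ordered node pairs (j != i, then over i); causal density CD is the
mean directed GC over the n(n-1) ordered pairs; causal flow of a node is its
outgoing minus incoming total influence (out-degree minus in-degree on binary
networks).

Unreachable pairs: printed L values below 1 are only possible if unreachable
pairs contribute less than 1, so the default rule counts them as 0; the
exclude-unreachable and harmonic-mean alternatives are available and every
result carries the reachable-pair fraction.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TrialDesign
from .network import BinaryDirectedNetwork, ROIPairSet, WindowGrid

__all__ = [
    "UNREACHABLE",
    "PathLengthResult",
    "CausalDensityResult",
    "shortest_paths",
    "characteristic_path_length",
    "causal_density",
    "causal_flow",
    "metric_series",
]

#: Marker for unreachable ordered pairs in the shortest-path matrix.
UNREACHABLE = -1


def shortest_paths(adjacency: np.ndarray) -> np.ndarray:
    """Directed unweighted shortest-path matrix by BFS from every node.

    ``adjacency`` is a square 0/1 matrix. Returns an int matrix with
    ``UNREACHABLE`` (-1) for unreachable ordered pairs; the diagonal is 0 by
    convention and excluded from all summaries.
    """
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    n = a.shape[0]
    succ = [np.flatnonzero(a[i]) for i in range(n)]
    dist = np.full((n, n), UNREACHABLE, dtype=int)
    for s in range(n):
        dist[s, s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in succ[u]:
                if dist[s, v] == UNREACHABLE:
                    dist[s, v] = dist[s, u] + 1
                    q.append(v)
    return dist


@dataclass
class PathLengthResult:
    """Characteristic path length with per-node averages and reachability."""

    length: float
    per_node: np.ndarray
    dist: np.ndarray
    reachable_fraction: float
    rule: str


def characteristic_path_length(dist: np.ndarray, unreachable_rule: str = "zero") -> PathLengthResult:
    """L = (1/n) sum_i L_i with L_i = sum_{j != i} m_ij / (n - 1).

    ``unreachable_rule``: 'zero' (default — unreachable pairs contribute 0,
    allowing L < 1 on sparse networks), 'exclude' (average only over reachable
    pairs), or 'harmonic' (average of 1/m, unreachable -> 0, inverted; the
    global-efficiency flavor).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    reach = (d > 0) & off
    reachable_fraction = float(reach.sum()) / (n * (n - 1))
    if unreachable_rule == "zero":
        vals = np.where(reach, d, 0.0)
        per_node = vals.sum(axis=1) / (n - 1)
        length = float(per_node.mean())
    elif unreachable_rule == "exclude":
        per_node = np.array([
            d[i, reach[i]].mean() if reach[i].any() else 0.0 for i in range(n)
        ])
        length = float(d[reach].mean()) if reach.any() else 0.0
    elif unreachable_rule == "harmonic":
        inv = np.where(reach, 1.0 / np.where(reach, d, 1.0), 0.0)
        per_node = inv.sum(axis=1) / (n - 1)
        mean_inv = float(per_node.mean())
        length = 1.0 / mean_inv if mean_inv > 0 else float("inf")
    else:
        raise ValueError(f"unknown unreachable rule {unreachable_rule!r}")
    return PathLengthResult(
        length=length,
        per_node=per_node,
        dist=np.asarray(dist),
        reachable_fraction=reachable_fraction,
        rule=unreachable_rule,
    )


@dataclass
class CausalDensityResult:
    """Mean directed GC over ordered node pairs."""

    cd: float
    n_nodes: int
    n_missing: int
    estimator: str = "bivariate"


def causal_density(gc_matrix: np.ndarray, estimator: str = "bivariate") -> CausalDensityResult:
    """CD = mean of the n(n-1) off-diagonal directed GC values.

    NaN entries (flagged/unusable pairs) are excluded and counted; a matrix
    with no usable off-diagonal value raises.
    """
    g = np.asarray(gc_matrix, dtype=float)
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError("gc_matrix must be square")
    n = g.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = g[off]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("all pairwise GC values missing")
    return CausalDensityResult(
        cd=float(vals[finite].mean()),
        n_nodes=n,
        n_missing=int((~finite).sum()),
        estimator=estimator,
    )


def causal_flow(matrix: np.ndarray, node: int | None = None) -> np.ndarray | float:
    """flow(i) = sum of outgoing minus sum of incoming values at node i.

    Works on weighted GC matrices and binary adjacencies alike (out-degree
    minus in-degree in the binary case). NaN entries are treated as absent.
    Flows sum to zero over all nodes (conservation).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    clean = np.where(np.isfinite(m), m, 0.0)
    np.fill_diagonal(clean, 0.0)
    flows = clean.sum(axis=1) - clean.sum(axis=0)
    if node is None:
        return flows
    if not 0 <= node < m.shape[0]:
        raise ValueError(f"unknown node index {node}")
    return float(flows[node])


def _pair_matrix(df: pd.DataFrame, nodes: tuple[str, ...]) -> np.ndarray:
    """Mean-GC node matrix from long rows (source, target, gc); NaN where absent."""
    idx = {lbl: i for i, lbl in enumerate(nodes)}
    m = np.full((len(nodes), len(nodes)), np.nan)
    agg = df.groupby(["source", "target"], observed=True)["gc"].mean()
    for (s, t), v in agg.items():
        m[idx[s], idx[t]] = v
    return m


def metric_series(
    networks: dict[tuple[str, str], BinaryDirectedNetwork],
    gc_table: pd.DataFrame,
    grid: WindowGrid,
    design: TrialDesign,
    unreachable_rule: str = "zero",
) -> pd.DataFrame:
    """Tidy per-window metric series for every (group, band).

    Emits, per task window: the group-level characteristic path length ``L``
    (from the binary network) and causal flow per node, plus causal density
    ``CD`` — at group level (mean GC matrix over all the group's trials) and
    per subject (the observation unit for the group ANOVA). Columns:
    group, band, window, phase, metric, node, subject, value.
    """
    phases = grid.phase_labels(design)
    rows: list[tuple] = []
    task = gc_table[gc_table["segment"] == "task"]
    for (group, band), net in networks.items():
        if net.adjacency.shape[0] != grid.n_windows:
            raise ValueError("network stack and window grid are misaligned")
        gdf = task[(task["group"] == group) & (task["band"] == band)]
        nodes = net.pairs.nodes
        for w in range(grid.n_windows):
            adj, _ = net.as_node_adjacency(w)
            pl = characteristic_path_length(shortest_paths(adj), unreachable_rule)
            rows.append((group, band, w, phases[w], "L", None, None, pl.length))
            for lbl, fl in zip(nodes, causal_flow(adj)):
                rows.append((group, band, w, phases[w], "flow", lbl, None, float(fl)))
        wdf = gdf.groupby("window", observed=True)
        for w, sub in wdf:
            cd = causal_density(_pair_matrix(sub, nodes))
            rows.append((group, band, int(w), phases[int(w)], "CD", None, None, cd.cd))
        for (subject, w), sub in gdf.groupby(["subject", "window"], observed=True):
            try:
                cd = causal_density(_pair_matrix(sub, nodes))
            except ValueError:
                continue
            rows.append((group, band, int(w), phases[int(w)], "CD_subject", None, subject, cd.cd))
    return pd.DataFrame(
        rows,
        columns=["group", "band", "window", "phase", "metric", "node", "subject", "value"],
    )
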