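"""Sliding-window GC tables and baseline-referenced binary directed networks.

The task segment is tiled by 90 nonoverlapping 100 ms windows (defaults); the
baseline segment yields same-length baseline windows (10 at defaults). For
every (trial, window, ordered pair, band) the band-averaged bivariate spectral
GC is tabulated; per pair, task windows are contrasted against the pooled
baseline values with a cluster-based permutation test, and windows whose
clusters beat the permutation null become 1-entries of the binary directed
network ("significantly above baseline").
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .design import DEFAULT_BANDS, FrequencyBand, SourceTimeSeries, TrialDesign
from .preprocess import prepare_window
from .synth import Cohort
from .vargc import default_grid_hz, pair_band_gc

__all__ = [
    "WindowGrid",
    "ROIPairSet",
    "BinaryDirectedNetwork",
    "ClusterTestResult",
    "slice_windows",
    "window_gc_table",
    "cluster_permutation_test",
    "binarize_networks",
]


@dataclass(frozen=True)
class WindowGrid:
    """Nonoverlapping contiguous windows tiling the task segment exactly."""

    window_ms: float = 100.0
    n_windows: int = 90

    def validate(self, design: TrialDesign) -> None:
        if abs(self.window_ms * self.n_windows - design.task_duration) > 1e-9:
            raise ValueError(
                f"{self.n_windows} x {self.window_ms} ms windows do not tile the "
                f"{design.task_duration} ms task segment"
            )
        n = self.window_ms * design.sampling_rate / 1000.0
        if abs(n - round(n)) > 1e-9:
            compatible = [int(1000 * k / self.window_ms) for k in range(1, 61)]
            raise ValueError(
                f"{self.window_ms} ms is not an integer sample count at fs="
                f"{design.sampling_rate}; compatible rates include {compatible[:5]}..."
            )

    def samples_per_window(self, design: TrialDesign) -> int:
        self.validate(design)
        return int(round(self.window_ms * design.sampling_rate / 1000.0))

    def n_baseline_windows(self, design: TrialDesign) -> int:
        return design.n_baseline_samples // self.samples_per_window(design)

    def window_phase(self, design: TrialDesign, window: int) -> str:
        """Phase label of a task window (by its start time)."""
        return design.phase_of(window * self.window_ms)

    def phase_labels(self, design: TrialDesign) -> list[str]:
        return [self.window_phase(design, w) for w in range(self.n_windows)]


@dataclass(frozen=True)
class ROIPairSet:
    """Ordered (source, target) node pairs forming the analyzed network."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate ordered pairs forbidden")
        for s, t in self.pairs:
            if s == t:
                raise ValueError(f"self-pair ({s},{t}) forbidden")
        object.__setattr__(self, "pairs", tuple((s, t) for s, t in self.pairs))

    @classmethod
    def frontal_to_parietal(cls, design: TrialDesign) -> "ROIPairSet":
        """All frontal->parietal ordered pairs (40 at the default 8x5 layout)."""
        return cls(tuple((f, p) for f in design.frontal_nodes for p in design.parietal_nodes))

    def validate(self, design: TrialDesign) -> None:
        known = set(design.nodes)
        for s, t in self.pairs:
            if s not in known or t not in known:
                raise ValueError(f"pair ({s},{t}) references a node absent from the design")

    @property
    def nodes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s, t in self.pairs:
            for lbl in (s, t):
                if lbl not in seen:
                    seen.append(lbl)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.pairs)


def slice_windows(
    trial: SourceTimeSeries, grid: WindowGrid
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Slice one trial into task windows and same-length baseline windows.

    Returns ``(task_windows, baseline_windows)``; concatenating the task
    windows reproduces the task segment exactly (partition property).
    """
    design = trial.design
    spw = grid.samples_per_window(design)
    nb = design.n_baseline_samples
    task = trial.task
    if task.shape[1] != spw * grid.n_windows:
        raise ValueError("grid does not tile the task segment")
    task_windows = [task[:, w * spw : (w + 1) * spw] for w in range(grid.n_windows)]
    n_base = nb // spw
    base = trial.baseline
    baseline_windows = [base[:, w * spw : (w + 1) * spw] for w in range(n_base)]
    return task_windows, baseline_windows


def _iter_trial_pair_gc(
    trial: SourceTimeSeries,
    grid: WindowGrid,
    pairs: ROIPairSet,
    bands: dict[str, FrequencyBand],
    p_max: int,
    freqs_hz: np.ndarray,
    gate_rule: str,
):
    """Yield rows (segment, window, source, target, band, gc, order, flags)."""
    design = trial.design
    fs = design.sampling_rate
    node_idx = {lbl: i for i, lbl in enumerate(design.nodes)}
    # unordered pair -> list of requested ordered orientations
    unordered: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for s, t in pairs.pairs:
        unordered.setdefault(tuple(sorted((s, t))), []).append((s, t))

    band_masks = {name: band.contains(freqs_hz) for name, band in bands.items()}
    task_windows, baseline_windows = slice_windows(trial, grid)
    segments = [("task", task_windows), ("baseline", baseline_windows)]
    for segment, windows in segments:
        for w, window in enumerate(windows):
            for (a, b), orientations in unordered.items():
                sub = window[[node_idx[a], node_idx[b]], :]
                prepared, report = prepare_window(sub, rule=gate_rule)
                flags = []
                if report.insufficient:
                    flags.append("insufficient")
                if report.degenerate:
                    flags.append("degenerate")
                if report.differenced:
                    flags.append("differenced")
                if report.differenced and not report.passed:
                    flags.append("still_nonstationary")
                usable = not (report.insufficient or report.degenerate)
                if usable:
                    # prepared rows [a, b]; pair_band_gc treats row0 as target,
                    # row1 as source, so res[band] = (f_{b->a}, f_{a->b})
                    res, order = pair_band_gc(
                        prepared, fs, freqs_hz=freqs_hz, bands=bands, p_max=p_max,
                        band_masks=band_masks,
                    )
                else:
                    res, order = {name: (float("nan"), float("nan")) for name in bands}, 0
                flag_str = ";".join(flags)
                for band_name in bands:
                    f_b_to_a, f_a_to_b = res[band_name]
                    for s, t in orientations:
                        gc = f_a_to_b if (s, t) == (a, b) else f_b_to_a
                        yield (segment, w, s, t, band_name, gc, order, flag_str)


def window_gc_table(
    cohort: Cohort,
    grid: WindowGrid,
    pairs: ROIPairSet,
    bands: dict[str, FrequencyBand] | None = None,
    p_max: int = 3,
    n_freqs: int = 128,
    gate_rule: str = "both",
    include_reverse: bool = False,
) -> pd.DataFrame:
    """Long-format band-averaged GC table for a whole cohort.

    One row per (group, subject, trial, segment, window, source, target, band);
    baseline windows carry ``segment == 'baseline'``. Unusable windows appear
    with NaN gc and a non-empty ``flags`` string — never as silent zeros.
    ``include_reverse`` adds the reversed orientation of every pair (computed
    from the same bivariate fit at no extra cost).
    """
    bands = bands or DEFAULT_BANDS
    pairs.validate(cohort.design)
    use_pairs = pairs
    if include_reverse:
        rev = [(t, s) for s, t in pairs.pairs if (t, s) not in pairs.pairs]
        use_pairs = ROIPairSet(pairs.pairs + tuple(rev))
    freqs_hz = default_grid_hz(cohort.design.sampling_rate, n_freqs)
    rows = []
    for group, subject, trial in cohort.iter_trials():
        tid = trial.meta.get("trial", -1)
        for rec in _iter_trial_pair_gc(trial, grid, use_pairs, bands, p_max, freqs_hz, gate_rule):
            rows.append((group, subject, tid) + rec)
    return pd.DataFrame(
        rows,
        columns=[
            "group", "subject", "trial", "segment", "window",
            "source", "target", "band", "gc", "var_order", "flags",
        ],
    )


def conditional_gc_table(
    cohort: Cohort,
    grid: WindowGrid,
    pairs: ROIPairSet,
    p: int = 2,
    gate_rule: str = "both",
) -> pd.DataFrame:
    """Time-domain *conditional* GC per window for every ordered pair.

    The alternative causal-density estimator: for each window the full VAR on
    the pair-induced node set is contrasted with the VAR omitting the source's
    lags (log-ratio of the target's residual variances), so each edge is
    conditioned on the remaining network. Broadband by construction (no
    spectral decomposition); rows carry ``band == 'broadband'``.
    """
    from .vargc import conditional_time_domain_gc

    pairs.validate(cohort.design)
    nodes = pairs.nodes
    node_idx = {lbl: i for i, lbl in enumerate(cohort.design.nodes)}
    sel = [node_idx[lbl] for lbl in nodes]
    local = {lbl: i for i, lbl in enumerate(nodes)}
    rows = []
    for group, subject, trial in cohort.iter_trials():
        tid = trial.meta.get("trial", -1)
        task_windows, baseline_windows = slice_windows(trial, grid)
        for segment, windows in (("task", task_windows), ("baseline", baseline_windows)):
            for w, window in enumerate(windows):
                prepared, report = prepare_window(window[sel, :], rule=gate_rule)
                usable = not (report.insufficient or report.degenerate)
                for s, t in pairs.pairs:
                    if usable:
                        try:
                            gc = conditional_time_domain_gc(prepared, p, local[t], local[s])
                        except (ValueError, np.linalg.LinAlgError):
                            gc = float("nan")
                    else:
                        gc = float("nan")
                    rows.append(
                        (group, subject, tid, segment, w, s, t, "broadband", gc, p,
                         "differenced" if report.differenced else "")
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "subject", "trial", "segment", "window",
            "source", "target", "band", "gc", "var_order", "flags",
        ],
    )


# ---------------------------------------------------------------------------
# cluster-based permutation against baseline
# ---------------------------------------------------------------------------

@dataclass
class ClusterTestResult:
    """Per-window significance mask for one pair/band with cluster provenance."""

    mask: np.ndarray                  # (n_windows,) bool
    t_stats: np.ndarray               # (n_windows,)
    clusters: list[tuple[int, int, float, float]]  # (start, stop, mass, p)
    threshold: float
    n_perm: int
    alpha: float
    warning: str = ""


def _welch_t_vs_pool(task: np.ndarray, pool_mean: float, pool_var: float, n_pool: int) -> np.ndarray:
    """Welch t per task window (columns of ``task``) against a pooled sample."""
    n1 = np.sum(np.isfinite(task), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.nanmean(np.where(np.isfinite(task), task, np.nan), axis=0)
        v1 = np.nanvar(task, axis=0, ddof=1)
        denom = np.sqrt(v1 / n1 + pool_var / n_pool)
        t = (m1 - pool_mean) / denom
    t[~np.isfinite(t)] = 0.0
    return t


def _clusters_from(t: np.ndarray, thresh: float) -> list[tuple[int, int, float]]:
    above = t > thresh
    out = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            out.append((start, i, float(t[start:i].sum())))
            start = None
    if start is not None:
        out.append((start, len(above), float(t[start:].sum())))
    return out


def cluster_permutation_test(
    task_values: np.ndarray,
    baseline_values: np.ndarray,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    cluster_alpha: float = 0.05,
) -> ClusterTestResult:
    """Cluster-based permutation contrast of task windows against baseline.

    Parameters
    ----------
    task_values :
        (n_trials, n_task_windows) per-window GC values.
    baseline_values :
        (n_trials, n_baseline_windows) baseline GC values; pooled across
        trials and windows for the pointwise contrast.
    n_perm, alpha :
        Number of label permutations (>= 100) and cluster significance level.
    cluster_alpha :
        Pointwise cluster-forming level; threshold is the one-sided Student t
        quantile at ``1 - cluster_alpha``.

    Per window, a Welch t contrasts the task values (across trials) with the
    pooled baseline values; contiguous supra-threshold windows form clusters
    whose t-mass is compared with the max-cluster-mass permutation null
    obtained by shuffling the task/baseline window labels within each trial.
    One-sided (task above baseline), matching the edge semantics.
    """
    task = np.atleast_2d(np.asarray(task_values, dtype=float))
    base = np.atleast_2d(np.asarray(baseline_values, dtype=float))
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if base.size == 0:
        raise ValueError("baseline pool is empty")
    if task.shape[0] != base.shape[0]:
        raise ValueError("task and baseline must have matching trial counts")
    n_trials, n_w = task.shape
    n_bw = base.shape[1]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    finite_base = base[np.isfinite(base)]
    finite_task = task[np.isfinite(task)]
    if finite_base.size < 2 or finite_task.size < 2 or (np.var(finite_base) == 0 and np.var(finite_task) == 0):
        return ClusterTestResult(
            mask=np.zeros(n_w, dtype=bool),
            t_stats=np.zeros(n_w),
            clusters=[],
            threshold=float("nan"),
            n_perm=n_perm,
            alpha=alpha,
            warning="zero-variance or insufficient data",
        )

    df = max(min(n_trials, finite_base.size) - 1, 1)
    thresh = float(sstats.t.ppf(1 - cluster_alpha, df))

    def stats_for(task_m: np.ndarray, base_m: np.ndarray) -> np.ndarray:
        pool = base_m[np.isfinite(base_m)]
        return _welch_t_vs_pool(task_m, float(pool.mean()), float(pool.var(ddof=1)), pool.size)

    t_obs = stats_for(task, base)
    obs_clusters = _clusters_from(t_obs, thresh)

    combined = np.concatenate([task, base], axis=1)  # (n_trials, n_w + n_bw)
    max_mass = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permuted(combined, axis=1)
        masses = _clusters_from(stats_for(perm[:, :n_w], perm[:, n_w:]), thresh)
        max_mass[i] = max((m for _, _, m in masses), default=0.0)

    mask = np.zeros(n_w, dtype=bool)
    clusters = []
    for start, stop, mass in obs_clusters:
        p = (1.0 + float(np.sum(max_mass >= mass))) / (1.0 + n_perm)
        clusters.append((start, stop, mass, p))
        if p < alpha:
            mask[start:stop] = True
    return ClusterTestResult(
        mask=mask, t_stats=t_obs, clusters=clusters, threshold=thresh,
        n_perm=n_perm, alpha=alpha,
    )


@dataclass
class BinaryDirectedNetwork:
    """Per-window 0/1 adjacency stack over the ordered pair set for one band."""

    band: str
    group: str
    pairs: ROIPairSet
    adjacency: np.ndarray            # (n_windows, n_pairs) uint8
    alpha: float
    n_perm: int
    cluster_rule: str = "contiguous-windows, one-sided t mass"
    coverage: dict[str, int] = field(default_factory=dict)

    def window_matrix(self, window: int) -> dict[tuple[str, str], int]:
        return {pair: int(v) for pair, v in zip(self.pairs.pairs, self.adjacency[window])}

    def as_node_adjacency(self, window: int) -> tuple[np.ndarray, tuple[str, ...]]:
        """Square 0/1 node-by-node adjacency induced by the pair set."""
        nodes = self.pairs.nodes
        idx = {lbl: i for i, lbl in enumerate(nodes)}
        a = np.zeros((len(nodes), len(nodes)), dtype=np.uint8)
        for (s, t), v in zip(self.pairs.pairs, self.adjacency[window]):
            a[idx[s], idx[t]] = v
        return a, nodes


def binarize_networks(
    gc_table: pd.DataFrame,
    grid_n_windows: int,
    pairs: ROIPairSet,
    bands: Iterable[str] = ("theta", "gamma"),
    alpha: float = 0.05,
    n_perm: int = 200,
    seed: int = 0,
    groups: Sequence[str] | None = None,
) -> dict[tuple[str, str], BinaryDirectedNetwork]:
    """Binary directed networks per (group, band) from a cohort GC table.

    Trials are pooled per group (one adjacency stack per group); for each pair
    the cluster permutation contrast against baseline marks significant
    windows. Missing (flagged) values stay missing for the contrast — they are
    counted in ``coverage`` and never imputed. Raises if the table lacks any
    requested pair.
    """
    out: dict[tuple[str, str], BinaryDirectedNetwork] = {}
    groups = tuple(groups) if groups is not None else tuple(pd.unique(gc_table["group"]))
    ss = np.random.SeedSequence(seed)
    group_rngs = {
        (g, b): np.random.default_rng(child)
        for (g, b), child in zip(
            [(g, b) for g in groups for b in bands],
            ss.spawn(len(groups) * len(tuple(bands))),
        )
    }
    for group in groups:
        gdf = gc_table[gc_table["group"] == group]
        for band in bands:
            bdf = gdf[gdf["band"] == band]
            adjacency = np.zeros((grid_n_windows, len(pairs)), dtype=np.uint8)
            missing = 0
            for j, (s, t) in enumerate(pairs.pairs):
                pdf = bdf[(bdf["source"] == s) & (bdf["target"] == t)]
                if pdf.empty:
                    raise ValueError(f"GC table has no rows for pair ({s},{t}) in band {band}")
                task = (
                    pdf[pdf["segment"] == "task"]
                    .pivot_table(index=["subject", "trial"], columns="window", values="gc", dropna=False)
                    .to_numpy()
                )
                base = (
                    pdf[pdf["segment"] == "baseline"]
                    .pivot_table(index=["subject", "trial"], columns="window", values="gc", dropna=False)
                    .to_numpy()
                )
                missing += int(np.sum(~np.isfinite(task)) + np.sum(~np.isfinite(base)))
                res = cluster_permutation_test(
                    task, base, n_perm=n_perm, alpha=alpha, seed=group_rngs[(group, band)]
                )
                adjacency[:, j] = res.mask.astype(np.uint8)
            out[(group, band)] = BinaryDirectedNetwork(
                band=band,
                group=group,
                pairs=pairs,
                adjacency=adjacency,
                alpha=alpha,
                n_perm=n_perm,
                coverage={"missing_values": missing},
            )
    return out
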