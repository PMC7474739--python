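"""Group comparison of metric series: per-window ANOVA and phase/band tables.

Per analysis window, a one-way ANOVA compares the groups' subject-level metric
values; contiguous significant spans (>= 2 windows by default) reproduce the
shaded significance regions of the metric time-course figures. Phase-level
summary tables give mean +/- SD per phase x band x group with a theta-vs-gamma
comparison and the conventional significance stars.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "WindowComparison",
    "per_window_anova",
    "significance_stars",
    "phase_band_table",
    "format_phase_table",
]


def significance_stars(p: float) -> str:
    """Conventional star coding: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class WindowComparison:
    """Per-window one-way ANOVA results for one (band, metric)."""

    f_stats: np.ndarray
    p_values: np.ndarray
    mask: np.ndarray                     # p < alpha after configured correction
    spans: list[tuple[int, int]]         # contiguous significant spans
    alpha: float
    correction: str
    degenerate: np.ndarray | None = None


def _contiguous_spans(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    spans = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                spans.append((start, i))
            start = None
    if start is not None and len(mask) - start >= min_len:
        spans.append((start, len(mask)))
    return spans


def per_window_anova(
    values_by_group: dict[str, np.ndarray],
    alpha: float = 0.05,
    correction: str = "none",
    min_span: int = 2,
) -> WindowComparison:
    """One-way ANOVA per window across groups of subject-level values.

    Parameters
    ----------
    values_by_group :
        group label -> (n_subjects, n_windows) array; NaN entries (missing
        subjects) are dropped per window.
    correction :
        'none' (default; the mask is the uncorrected p < alpha decision) or
        'bh' (Benjamini-Hochberg across windows).
    min_span :
        Minimum length of the reported contiguous significant spans (the mask
        itself is not span-filtered).

    Zero within-group variance windows: if the group means are also equal the
    window is an exact tie (p = 1); otherwise it is flagged degenerate and its
    p is 0 (means differ with zero noise).
    """
    groups = [np.atleast_2d(np.asarray(v, dtype=float)) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n_w = groups[0].shape[1]
    if any(g.shape[1] != n_w for g in groups):
        raise ValueError("groups disagree on window count")
    f_stats = np.full(n_w, np.nan)
    p_values = np.full(n_w, np.nan)
    degenerate = np.zeros(n_w, dtype=bool)
    for w in range(n_w):
        samples = [g[:, w][np.isfinite(g[:, w])] for g in groups]
        if any(s.size < 2 for s in samples):
            continue
        if all(np.var(s) == 0 for s in samples):
            means = [s.mean() for s in samples]
            if np.ptp(means) == 0:
                f_stats[w], p_values[w] = 0.0, 1.0
            else:
                f_stats[w], p_values[w] = np.inf, 0.0
                degenerate[w] = True
            continue
        f, p = sstats.f_oneway(*samples)
        f_stats[w], p_values[w] = float(f), float(p)
    if correction == "none":
        padj = p_values
    elif correction == "bh":
        padj = np.full(n_w, np.nan)
        ok = np.isfinite(p_values)
        if ok.any():
            padj[ok] = sstats.false_discovery_control(p_values[ok], method="bh")
    else:
        raise ValueError(f"unknown correction {correction!r}")
    mask = np.where(np.isfinite(padj), padj < alpha, False)
    return WindowComparison(
        f_stats=f_stats,
        p_values=p_values,
        mask=mask,
        spans=_contiguous_spans(mask, min_span),
        alpha=alpha,
        correction=correction,
        degenerate=degenerate,
    )


def phase_band_table(
    series: pd.DataFrame,
    metric: str = "CD",
    bands: Sequence[str] = ("theta", "gamma"),
    compare: tuple[str, str] = ("theta", "gamma"),
) -> pd.DataFrame:
    """Phase-level mean +/- SD per group and band, with a band comparison.

    ``series`` is the tidy metric-series frame (columns group, band, window,
    phase, metric, value). The observation unit is the window-level group
    value; SD is over windows within the phase. Per (group, phase), the two
    bands named in ``compare`` are contrasted by Welch two-sample t on the
    window values; stars follow the conventional thresholds. Degenerate
    contrasts (zero variance in both bands) get p = NaN and a 'degenerate'
    note.
    """
    df = series[series["metric"] == metric]
    if df.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    rows = []
    for group, gdf in df.groupby("group", observed=True):
        gdf = gdf.sort_values("window")  # chronological phase order
        for phase, pdf in gdf.groupby("phase", sort=False, observed=True):
            if pdf.empty:
                raise ValueError(f"empty phase {phase!r}")
            cells = {}
            for band in bands:
                v = pdf[pdf["band"] == band]["value"].to_numpy(dtype=float)
                v = v[np.isfinite(v)]
                cells[band] = v
            a, b = (cells.get(c, np.array([])) for c in compare)
            if a.size >= 2 and b.size >= 2 and (np.var(a) > 0 or np.var(b) > 0):
                t, p = sstats.ttest_ind(a, b, equal_var=False)
                p = float(p)
                note = ""
            else:
                p, note = float("nan"), "degenerate"
            for band in bands:
                v = cells[band]
                rows.append(
                    {
                        "group": group,
                        "phase": phase,
                        "metric": metric,
                        "band": band,
                        "mean": float(v.mean()) if v.size else float("nan"),
                        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                        "n_windows": int(v.size),
                        "comparison": f"{compare[0]} vs {compare[1]}",
                        "p": p,
                        "stars": significance_stars(p),
                        "note": note,
                    }
                )
    return pd.DataFrame(rows)


def format_phase_table(table: pd.DataFrame, metric: str | None = None) -> str:
    """Render a phase/band summary as an aligned text table."""
    df = table if metric is None else table[table["metric"] == metric]
    lines = []
    for group, gdf in df.groupby("group", observed=True):
        lines.append(f"[{group}]")
        bands = list(dict.fromkeys(gdf["band"]))
        header = f"{'phase':<22}" + "".join(f"{b:>18}" for b in bands) + f"{'p':>10}"
        lines.append(header)
        for phase, pdf in gdf.groupby("phase", sort=False, observed=True):
            cells = []
            for b in bands:
                row = pdf[pdf["band"] == b]
                if row.empty:
                    cells.append(f"{'-':>18}")
                else:
                    r = row.iloc[0]
                    cells.append(f"{r['mean']:.3f} ± {r['sd']:.3f}".rjust(18))
            r0 = pdf.iloc[0]
            ptxt = r0["stars"] if r0["stars"] else (f"{r0['p']:.3f}" if np.isfinite(r0["p"]) else "n/a")
            lines.append(f"{phase:<22}" + "".join(cells) + f"{ptxt:>10}")
        lines.append("")
    return "\n".join(lines)
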