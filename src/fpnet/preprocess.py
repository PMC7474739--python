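"""Signal conditioning and the per-window stationarity protocol.

Pipeline order (fixed): zero-phase bandpass and baseline correction on the
whole trial, then — per analysis window — linear detrend/demean, a joint
ADF+KPSS stationarity gate, and at most one first-order difference for windows
that fail the gate.

The gate decisions are computed with direct OLS formulas (a fixed-lag
augmented Dickey-Fuller regression and the KPSS level statistic) against the
standard 5% critical values, because the pipeline gates very large numbers of
short windows; unit tests cross-check the decisions against the statsmodels
implementations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .design import SourceTimeSeries

__all__ = [
    "StationarityReport",
    "bandpass_filter",
    "baseline_correct",
    "detrend_demean",
    "adf_tstat",
    "kpss_stat",
    "stationarity_gate",
    "difference_once",
    "prepare_window",
]

#: Minimum window length for the stationarity regressions.
MIN_GATE_SAMPLES = 20

# MacKinnon 5% critical value for the ADF 't' with constant is ~-2.86 for
# large n and around -2.92 at n=50; computed once per length via statsmodels.
_adf_crit_cache: dict[int, float] = {}


def _adf_crit_5pct(nobs: int) -> float:
    if nobs not in _adf_crit_cache:
        from statsmodels.tsa.adfvalues import mackinnoncrit

        _adf_crit_cache[nobs] = float(mackinnoncrit(N=1, regression="c", nobs=nobs)[1])
    return _adf_crit_cache[nobs]


#: KPSS 5% critical value, level-stationarity null ('c').
KPSS_CRIT_5PCT = 0.463


# ---------------------------------------------------------------------------
# whole-trial conditioning
# ---------------------------------------------------------------------------

def bandpass_filter(ts: SourceTimeSeries, low: float, high: float, order: int = 4) -> SourceTimeSeries:
    """Zero-phase (forward-backward) Butterworth bandpass.

    Forward-backward filtering keeps the filter's group delay from introducing
    a spurious direction-dependent lag between nodes, which matters because
    everything downstream measures directed lead/lag structure.
    """
    nyq = ts.design.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band [{low}, {high}] Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=ts.design.sampling_rate, output="sos")
    return ts.with_data(signal.sosfiltfilt(sos, ts.data, axis=1))


def baseline_correct(ts: SourceTimeSeries, baseline_window_ms: tuple[float, float] | None = None) -> SourceTimeSeries:
    """Subtract each node's mean over the baseline window from the whole trial."""
    if baseline_window_ms is None:
        baseline_window_ms = (0.0, ts.design.baseline_duration)
    lo, hi = baseline_window_ms
    i0 = ts.design.ms_to_samples(lo)
    i1 = ts.design.ms_to_samples(hi)
    if not (0 <= i0 < i1 <= ts.design.n_samples):
        raise ValueError(f"baseline window {baseline_window_ms} ms outside trial or empty")
    mean = ts.data[:, i0:i1].mean(axis=1, keepdims=True)
    return ts.with_data(ts.data - mean)


# ---------------------------------------------------------------------------
# per-window protocol
# ---------------------------------------------------------------------------

def detrend_demean(window: np.ndarray) -> np.ndarray:
    """Remove each node's best-fit line (slope and intercept).

    Direct least-squares projection (equivalent to a linear detrend); written
    out because the batch pipeline calls this for every analysis window.
    """
    window = np.asarray(window, dtype=float)
    n = window.shape[-1]
    if n < 3:
        raise ValueError("window must have at least 3 samples")
    tc = np.arange(n, dtype=float)
    tc -= tc.mean()
    centered = window - window.mean(axis=-1, keepdims=True)
    slope = (centered @ tc) / (tc @ tc)
    return centered - np.multiply.outer(slope, tc)


def adf_tstat(x: np.ndarray, lag: int = 1) -> float:
    """Fixed-lag augmented Dickey-Fuller t-statistic (regression with constant).

    Regresses ``diff(x)[t]`` on ``[1, x[t-1], diff(x)[t-1..t-lag]]`` and returns
    the t-statistic of the level coefficient. Returns ``nan`` for degenerate
    (zero-variance) input.
    """
    x = np.asarray(x, dtype=float)
    dx = np.diff(x)
    n = dx.size - lag
    if n < 4 or np.ptp(x) == 0:
        return float("nan")
    y = dx[lag:]
    cols = [np.ones(n), x[lag:-1]]
    for k in range(1, lag + 1):
        cols.append(dx[lag - k : -k])
    z = np.column_stack(cols)
    g = z.T @ z
    rhs = np.empty((z.shape[1], 2))
    rhs[:, 0] = z.T @ y
    rhs[:, 1] = 0.0
    rhs[1, 1] = 1.0  # second column solves for (G^{-1})_{.,1}
    try:
        sol = np.linalg.solve(g, rhs)
    except np.linalg.LinAlgError:
        return float("nan")
    beta = sol[:, 0]
    ginv11 = sol[1, 1]
    resid = y - z @ beta
    dof = n - z.shape[1]
    if dof <= 0:
        return float("nan")
    s2 = float(resid @ resid) / dof
    se = np.sqrt(s2 * ginv11)
    if se == 0 or not np.isfinite(se):
        return float("nan")
    return float(beta[1] / se)


def kpss_stat(x: np.ndarray, nlags: int | None = None) -> float:
    """KPSS level-stationarity statistic with Bartlett long-run variance."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.ptp(x) == 0:
        return float("nan")
    e = x - x.mean()
    s = np.cumsum(e)
    if nlags is None:
        nlags = int(np.ceil(4.0 * (n / 100.0) ** 0.25))
    lrv = float(e @ e) / n
    for k in range(1, nlags + 1):
        w = 1.0 - k / (nlags + 1.0)
        lrv += 2.0 * w * float(e[k:] @ e[:-k]) / n
    if lrv <= 0:
        return float("nan")
    return float(s @ s) / (n * n * lrv)


@dataclass
class StationarityReport:
    """Joint ADF/KPSS gate decision for one window.

    ``adf_pass[i]`` — node i rejects the unit-root null; ``kpss_pass[i]`` —
    node i fails to reject level stationarity. The window passes overall iff
    every node passes the configured rule. ``insufficient`` marks windows too
    short for the regressions (treated as non-stationary).
    """

    adf_pass: np.ndarray
    kpss_pass: np.ndarray
    passed: bool
    differenced: bool = False
    insufficient: bool = False
    degenerate: bool = False


def stationarity_gate(
    window: np.ndarray,
    adf_level_crit: float | None = None,
    kpss_crit: float = KPSS_CRIT_5PCT,
    adf_lag: int = 1,
    rule: str = "both",
) -> StationarityReport:
    """Gate one (nodes x samples) window on joint ADF + KPSS decisions.

    ``rule='both'`` (default) requires ADF to reject a unit root AND KPSS not
    to reject stationarity, per node; ``rule='either'`` accepts a node if
    either test is favorable. Degenerate (constant) nodes fail the gate.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite values")
    n_nodes, n_samp = window.shape
    if n_samp < MIN_GATE_SAMPLES:
        false = np.zeros(n_nodes, dtype=bool)
        return StationarityReport(false, false.copy(), passed=False, insufficient=True)
    crit = adf_level_crit if adf_level_crit is not None else _adf_crit_5pct(n_samp - 1 - adf_lag)
    adf_pass = np.zeros(n_nodes, dtype=bool)
    kpss_pass = np.zeros(n_nodes, dtype=bool)
    degenerate = False
    for i in range(n_nodes):
        t = adf_tstat(window[i], lag=adf_lag)
        k = kpss_stat(window[i])
        if np.isnan(t) or np.isnan(k):
            degenerate = True
            continue
        adf_pass[i] = t < crit
        kpss_pass[i] = k < kpss_crit
    if rule == "both":
        node_ok = adf_pass & kpss_pass
    elif rule == "either":
        node_ok = adf_pass | kpss_pass
    else:
        raise ValueError(f"unknown gate rule {rule!r}")
    return StationarityReport(
        adf_pass, kpss_pass, passed=bool(node_ok.all()) and not degenerate, degenerate=degenerate
    )


def difference_once(window: np.ndarray) -> np.ndarray:
    """First-order difference along time; output is one sample shorter."""
    window = np.asarray(window, dtype=float)
    if window.shape[-1] < 2:
        raise ValueError("window must have at least 2 samples to difference")
    return np.diff(window, axis=-1)


def prepare_window(
    window: np.ndarray,
    rule: str = "both",
    adf_lag: int = 1,
) -> tuple[np.ndarray, StationarityReport]:
    """Apply the full per-window protocol: detrend/demean, gate, difference.

    Differencing is applied at most once; windows that remain non-stationary
    afterwards are returned with ``passed=False`` and ``differenced=True`` so
    callers can flag (not silently drop or impute) them.
    """
    w = detrend_demean(window)
    report = stationarity_gate(w, rule=rule, adf_lag=adf_lag)
    if report.passed or report.insufficient:
        return w, report
    w2 = detrend_demean(difference_once(w))
    report2 = stationarity_gate(w2, rule=rule, adf_lag=adf_lag)
    report2.differenced = True
    return w2, report2
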