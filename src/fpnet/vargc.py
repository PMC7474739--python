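"""Vector-autoregressive model fitting and frequency-domain Granger causality.

For a stationary VAR(p) process x_t = sum_k A_k x_{t-k} + e_t with residual
covariance Sigma, the transfer function is

    H(w) = (I - sum_{k=1..p} A_k exp(-i k w))^{-1}

and the cross-power spectral density factorizes as S(w) = H(w) Sigma H*(w).
The (Geweke) spectral Granger causality from source Y to target X is

    f_{Y->X}(w) = -ln(1 - H_XY(w) Sigma_{Y|X} H_XY*(w) / S_XX(w))

with the partial residual covariance
Sigma_{Y|X} = Sigma_YY - Sigma_YX Sigma_XX^{-1} Sigma_XY removing the
instantaneous residual correlation. Values are in nats; band summaries are
arithmetic means of f over the grid frequencies inside the band. The
time-domain measure ln(var_restricted / var_full) is provided both as the
classical statistic and as an independent oracle for the spectral integral
identity (mean of f over the full grid equals the time-domain value).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DEFAULT_BANDS, FrequencyBand

__all__ = [
    "VARModel",
    "SpectralMatrices",
    "SpectralGCResult",
    "default_grid_hz",
    "fit_var",
    "select_order_bic",
    "transfer_function",
    "cpsd",
    "spectral_gc_pair",
    "band_average",
    "time_domain_gc",
    "conditional_time_domain_gc",
    "pair_band_gc",
]

#: Grid points in (0, Nyquist]; 128 is ample for band means over 4-60 Hz.
DEFAULT_N_FREQS = 128

#: f-values below this are treated as exact zeros (finite-sample jitter).
NEG_CLIP_TOL = -1e-10

#: Condition-number ceiling for the transfer-function inversion.
COND_LIMIT = 1e12


def default_grid_hz(fs: float, n_freqs: int = DEFAULT_N_FREQS) -> np.ndarray:
    """Equally spaced frequency grid over (0, Nyquist] in Hz."""
    return np.linspace(0.0, fs / 2.0, n_freqs + 1)[1:]


@dataclass
class VARModel:
    """Least-squares fitted VAR(p)."""

    order: int
    coefs: np.ndarray          # (p, n, n)
    sigma: np.ndarray          # (n, n) residual covariance (dof-corrected)
    n_samples: int             # effective observations used in the regression
    loglik: float
    bic: float
    spectral_radius: float

    @property
    def n_nodes(self) -> int:
        return self.coefs.shape[1]


def _lagged(x: np.ndarray, p: int, t0: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Build response Y (T_eff, n) and regressor Z (T_eff, n*p) matrices.

    ``x`` is (n_nodes, T); regression starts at ``t0`` (default p) so a common
    sample can be enforced across candidate orders. Z columns are ordered
    lag-major: [x_{t-1} all nodes, x_{t-2} all nodes, ...].
    """
    n, t_len = x.shape
    t0 = p if t0 is None else max(t0, p)
    y = x[:, t0:].T
    z = np.empty((t_len - t0, n * p))
    for k in range(1, p + 1):
        z[:, (k - 1) * n : k * n] = x[:, t0 - k : t_len - k].T
    return y, z


def _companion_radius(coefs: np.ndarray) -> float:
    p, n, _ = coefs.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(coefs), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def fit_var(window: np.ndarray, p: int) -> VARModel:
    """Fit a VAR(p) by multivariate least squares (no intercept).

    Windows are demeaned upstream, so no intercept is estimated. The residual
    covariance uses the degrees-of-freedom-corrected denominator
    ``T_eff - n*p``; the BIC stored on the model uses the ML covariance.
    Raises ``np.linalg.LinAlgError`` on a singular regressor moment matrix
    (degenerate window).
    """
    x = np.atleast_2d(np.asarray(window, dtype=float))
    n, t_len = x.shape
    t_eff = t_len - p
    if t_eff <= n * p + 1:
        raise ValueError(f"window too short ({t_len} samples) for VAR({p}) on {n} nodes")
    y, z = _lagged(x, p)
    g = z.T @ z
    beta = np.linalg.solve(g, z.T @ y)  # (n*p, n)
    resid = y - z @ beta
    rss = resid.T @ resid
    dof = t_eff - n * p
    sigma = rss / dof
    sigma_ml = rss / t_eff
    sign, logdet = np.linalg.slogdet(sigma_ml)
    if sign <= 0:
        logdet = -np.inf if sign == 0 else float("nan")
    loglik = -0.5 * t_eff * (n * np.log(2 * np.pi) + logdet + n)
    bic = logdet + np.log(t_eff) / t_eff * p * n * n
    coefs = beta.T.reshape(n, p, n).transpose(1, 0, 2)
    return VARModel(
        order=p,
        coefs=coefs,
        sigma=sigma,
        n_samples=t_eff,
        loglik=float(loglik),
        bic=float(bic),
        spectral_radius=_companion_radius(coefs),
    )


def select_order_bic(window: np.ndarray, p_max: int = 3) -> int:
    """BIC order selection over 1..p_max on a common estimation sample.

    All candidates are fitted on observations ``t >= p_max`` so their BIC
    values are comparable; ties break toward the smaller order. If the window
    cannot support ``p_max``, the ceiling is lowered; if even p=1 is
    infeasible, ``ValueError`` is raised (window unusable).
    """
    x = np.atleast_2d(np.asarray(window, dtype=float))
    n, t_len = x.shape
    while p_max > 1 and t_len - p_max <= n * p_max + 1:
        p_max -= 1
    if t_len - 1 <= n + 1:
        raise ValueError("window too short for any VAR order")
    best_p, best_bic = 1, np.inf
    for p in range(1, p_max + 1):
        y, z = _lagged(x, p, t0=p_max)
        t_eff = y.shape[0]
        try:
            beta = np.linalg.solve(z.T @ z, z.T @ y)
        except np.linalg.LinAlgError:
            continue
        resid = y - z @ beta
        sign, logdet = np.linalg.slogdet(resid.T @ resid / t_eff)
        if sign <= 0:
            continue
        bic = logdet + np.log(t_eff) / t_eff * p * n * n
        if bic < best_bic - 1e-12:
            best_p, best_bic = p, bic
    return best_p


@dataclass
class SpectralMatrices:
    """Transfer function and CPSD evaluated on a frequency grid."""

    freqs_hz: np.ndarray        # (F,)
    h: np.ndarray               # (F, n, n) complex
    s: np.ndarray | None = None  # (F, n, n) complex Hermitian
    mask: np.ndarray | None = None  # (F,) True where the grid point is valid


def transfer_function(model: VARModel, freqs_hz: np.ndarray, fs: float) -> SpectralMatrices:
    """H(w) = (I - sum_k A_k exp(-i k w))^{-1} on the given Hz grid.

    Grid points where the characteristic matrix is ill-conditioned
    (condition number above 1e12) are masked rather than extrapolated.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    w = 2.0 * np.pi * freqs_hz / fs  # radians per sample
    p, n, _ = model.coefs.shape
    phases = np.exp(-1j * np.outer(w, np.arange(1, p + 1)))  # (F, p)
    a = np.tensordot(phases, model.coefs, axes=(1, 0))  # (F, n, n)
    m = np.eye(n)[None, :, :] - a
    mask = np.linalg.cond(m) < COND_LIMIT
    h = np.full_like(m, np.nan)
    if mask.any():
        h[mask] = np.linalg.inv(m[mask])
    return SpectralMatrices(freqs_hz=freqs_hz, h=h, mask=mask)


def cpsd(model: VARModel, freqs_hz: np.ndarray, fs: float) -> SpectralMatrices:
    """Cross-power spectral density S(w) = H(w) Sigma H*(w)."""
    sm = transfer_function(model, freqs_hz, fs)
    s = sm.h @ model.sigma @ np.conj(np.swapaxes(sm.h, -1, -2))
    # enforce exact Hermitian symmetry against roundoff
    sm.s = 0.5 * (s + np.conj(np.swapaxes(s, -1, -2)))
    return sm


@dataclass
class SpectralGCResult:
    """Both directions of the bivariate spectral GC for one node pair."""

    source: str
    target: str
    freqs_hz: np.ndarray
    f_source_to_target: np.ndarray
    f_target_to_source: np.ndarray
    partial_cov_source: float      # Sigma_{Y|X} used for source->target
    partial_cov_target: float
    mask: np.ndarray
    n_clipped: int = 0
    band_averages: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def usable(self) -> bool:
        return bool(self.mask.any())


def _geweke_direction(h: np.ndarray, s: np.ndarray, sigma: np.ndarray, tgt: int, src: int) -> tuple[np.ndarray, float, int]:
    """f_{src->tgt}(w) over the grid, with the partial covariance used."""
    sig_cond = sigma[src, src] - sigma[src, tgt] * sigma[tgt, src] / sigma[tgt, tgt]
    sxx = np.real(s[:, tgt, tgt])
    hxy2 = np.abs(h[:, tgt, src]) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sxx > 0, hxy2 * sig_cond / sxx, np.nan)
        f = -np.log(1.0 - ratio)
    n_clipped = int(np.sum((f < 0) & (f >= NEG_CLIP_TOL)))
    f = np.where(f < 0, np.where(f >= NEG_CLIP_TOL, 0.0, np.nan), f)
    return f, float(sig_cond), n_clipped


def spectral_gc_pair(
    model: VARModel,
    freqs_hz: np.ndarray,
    fs: float,
    source: str = "Y",
    target: str = "X",
    source_idx: int = 1,
    target_idx: int = 0,
    bands: dict[str, FrequencyBand] | None = None,
) -> SpectralGCResult:
    """Spectral Granger causality for a bivariate VAR, both directions.

    ``model`` must be the 2-node VAR fitted on the pair; the two directional
    spectra are computed from the same fit, so swapping source/target labels
    swaps the results exactly. Grid points with non-positive target spectrum
    or an ill-conditioned inversion are masked (NaN), never zero-filled.
    """
    if model.n_nodes != 2:
        raise ValueError("spectral_gc_pair expects the bivariate VAR of the pair")
    sm = cpsd(model, freqs_hz, fs)
    f_st, pc_s, nc1 = _geweke_direction(sm.h, sm.s, model.sigma, target_idx, source_idx)
    f_ts, pc_t, nc2 = _geweke_direction(sm.h, sm.s, model.sigma, source_idx, target_idx)
    mask = sm.mask & np.isfinite(f_st) & np.isfinite(f_ts)
    res = SpectralGCResult(
        source=source,
        target=target,
        freqs_hz=np.asarray(freqs_hz, dtype=float),
        f_source_to_target=f_st,
        f_target_to_source=f_ts,
        partial_cov_source=pc_s,
        partial_cov_target=pc_t,
        mask=mask,
        n_clipped=nc1 + nc2,
    )
    if bands:
        res.band_averages = {
            name: {
                "source_to_target": band_average(res, band, direction="source_to_target"),
                "target_to_source": band_average(res, band, direction="target_to_source"),
            }
            for name, band in bands.items()
        }
    return res


def band_average(result: SpectralGCResult, band: FrequencyBand, direction: str = "source_to_target") -> float:
    """Arithmetic mean of f over grid points with Hz value in [low, high)."""
    sel = band.contains(result.freqs_hz) & result.mask
    if not sel.any():
        raise ValueError(f"band {band.name} [{band.low}, {band.high}) contains no usable grid point")
    f = result.f_source_to_target if direction == "source_to_target" else result.f_target_to_source
    return float(np.mean(f[sel]))


def time_domain_gc(window: np.ndarray, p: int, target_idx: int = 0, source_idx: int = 1) -> float:
    """Classical time-domain GC: ln(restricted var / full var) for the target.

    Restricted model: target regressed on its own p lags only. Full model: the
    bivariate VAR(p). Both use the ML residual variance on the same sample.
    Degenerate (zero-variance) source series contribute nothing and yield 0.
    """
    x = np.atleast_2d(np.asarray(window, dtype=float))
    pair = x[[target_idx, source_idx], :]
    y, z = _lagged(pair, p)
    t_eff = y.shape[0]
    yt = y[:, 0]
    # full: both nodes' lags; restricted: target's own lags (columns 0, 2, ...)
    own_cols = [k * 2 for k in range(p)]

    def rvar(cols: list[int]) -> float:
        zz = z[:, cols]
        g = zz.T @ zz
        try:
            beta = np.linalg.solve(g, zz.T @ yt)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(zz, yt, rcond=None)[0]
        r = yt - zz @ beta
        return float(r @ r) / t_eff

    v_full = rvar(list(range(2 * p)))
    v_restr = rvar(own_cols)
    if v_full <= 0:
        return 0.0
    return max(0.0, float(np.log(v_restr / v_full)))


def conditional_time_domain_gc(window: np.ndarray, p: int, target_idx: int, source_idx: int) -> float:
    """Conditional GC of source->target given all remaining nodes.

    Log-ratio of the target's residual variance between the full VAR on all
    nodes and the VAR omitting the source's lags. This is the optional
    alternative edge/density estimator conditioning on the rest of the
    network.
    """
    x = np.atleast_2d(np.asarray(window, dtype=float))
    n = x.shape[0]
    y, z = _lagged(x, p)
    t_eff = y.shape[0]
    yt = y[:, target_idx]
    keep = [k * n + j for k in range(p) for j in range(n) if j != source_idx]

    def rvar(cols) -> float:
        zz = z[:, cols]
        beta = np.linalg.lstsq(zz, yt, rcond=None)[0]
        r = yt - zz @ beta
        return float(r @ r) / t_eff

    v_full = rvar(list(range(n * p)))
    v_restr = rvar(keep)
    if v_full <= 0:
        return 0.0
    return max(0.0, float(np.log(v_restr / v_full)))


def _pair_f_spectra(
    coefs: np.ndarray, sigma: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Both directional f-spectra for a 2-node VAR via the analytic 2x2 inverse.

    Same mathematics as :func:`spectral_gc_pair` (and cross-checked against it
    in tests) but hand-inlined because the batch pipeline evaluates it for
    every window and pair. Returns ``(f_1to0, f_0to1, valid_mask)``.
    """
    p = coefs.shape[0]
    phases = np.exp(-1j * np.outer(w, np.arange(1, p + 1)))  # (F, p)
    m00 = 1.0 - phases @ coefs[:, 0, 0]
    m01 = -(phases @ coefs[:, 0, 1])
    m10 = -(phases @ coefs[:, 1, 0])
    m11 = 1.0 - phases @ coefs[:, 1, 1]
    det = m00 * m11 - m01 * m10
    mask = np.abs(det) > 1e-12
    inv_det = np.where(mask, det, 1.0) ** -1
    h00, h01 = m11 * inv_det, -m01 * inv_det
    h10, h11 = -m10 * inv_det, m00 * inv_det
    s00, s01, s11 = sigma[0, 0], sigma[0, 1], sigma[1, 1]
    sxx = (np.abs(h00) ** 2) * s00 + 2.0 * np.real(h00 * np.conj(h01)) * s01 + (np.abs(h01) ** 2) * s11
    syy = (np.abs(h10) ** 2) * s00 + 2.0 * np.real(h10 * np.conj(h11)) * s01 + (np.abs(h11) ** 2) * s11
    sig_1_given_0 = s11 - s01 * s01 / s00
    sig_0_given_1 = s00 - s01 * s01 / s11
    with np.errstate(divide="ignore", invalid="ignore"):
        f10 = -np.log(1.0 - (np.abs(h01) ** 2) * sig_1_given_0 / sxx)
        f01 = -np.log(1.0 - (np.abs(h10) ** 2) * sig_0_given_1 / syy)
    for f in (f10, f01):
        bad = f < 0
        f[bad & (f >= NEG_CLIP_TOL)] = 0.0
        f[bad & (f < NEG_CLIP_TOL)] = np.nan
    mask &= np.isfinite(f10) & np.isfinite(f01) & (sxx > 0) & (syy > 0)
    return f10, f01, mask


def pair_band_gc(
    window_pair: np.ndarray,
    fs: float,
    freqs_hz: np.ndarray | None = None,
    bands: dict[str, FrequencyBand] | None = None,
    p_max: int = 3,
    band_masks: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, tuple[float, float]], int]:
    """Band-averaged bivariate spectral GC for one prepared 2-row window.

    Fast path used by the batch pipeline: BIC order selection (same criterion
    as :func:`select_order_bic`, inlined via Gram submatrices), VAR fit, both
    GC directions, band means; tests pin it against the generic
    ``select_order_bic`` + ``fit_var`` + ``spectral_gc_pair`` route. Row 0 is
    treated as target, row 1 as source: returns
    ``({band: (f_row1->row0, f_row0->row1)}, selected_order)``; band values
    are NaN when the window is unusable. ``band_masks`` may carry precomputed
    grid-membership masks.
    """
    bands = bands or DEFAULT_BANDS
    freqs_hz = default_grid_hz(fs) if freqs_hz is None else freqs_hz
    if band_masks is None:
        band_masks = {name: band.contains(freqs_hz) for name, band in bands.items()}
    nanres = {name: (float("nan"), float("nan")) for name in bands}

    x = np.atleast_2d(np.asarray(window_pair, dtype=float))
    t_len = x.shape[1]
    while p_max > 1 and t_len - p_max <= 2 * p_max + 1:
        p_max -= 1
    if t_len - 1 <= 3:
        return nanres, 0
    # order selection on the common sample t >= p_max, via Gram submatrices
    y, z = _lagged(x, p_max)
    t_sel = y.shape[0]
    g = z.T @ z
    c = z.T @ y
    yy = y.T @ y
    best_p, best_bic = 1, np.inf
    log_t = np.log(t_sel)
    for p in range(1, p_max + 1):
        k = 2 * p
        try:
            beta = np.linalg.solve(g[:k, :k], c[:k])
        except np.linalg.LinAlgError:
            continue
        rss = yy - c[:k].T @ beta
        det = rss[0, 0] * rss[1, 1] - rss[0, 1] * rss[1, 0]
        if det <= 0:
            continue
        bic = np.log(det / (t_sel * t_sel)) + log_t / t_sel * p * 4
        if bic < best_bic - 1e-12:
            best_p, best_bic = p, bic
    p = best_p
    # final fit at the selected order on its full sample t >= p
    y, z = _lagged(x, p)
    t_eff = y.shape[0]
    try:
        beta = np.linalg.solve(z.T @ z, z.T @ y)
    except np.linalg.LinAlgError:
        return nanres, p
    resid = y - z @ beta
    dof = t_eff - 2 * p
    if dof <= 0:
        return nanres, p
    sigma = resid.T @ resid / dof
    if not np.all(np.isfinite(beta)) or sigma[0, 0] <= 0 or sigma[1, 1] <= 0:
        return nanres, p
    coefs = beta.T.reshape(2, p, 2).transpose(1, 0, 2)
    w = 2.0 * np.pi * freqs_hz / fs
    f10, f01, mask = _pair_f_spectra(coefs, sigma, w)
    if not mask.any():
        return nanres, p
    out = {}
    for name in bands:
        sel = band_masks[name] & mask
        if not sel.any():
            out[name] = (float("nan"), float("nan"))
        else:
            out[name] = (float(f10[sel].mean()), float(f01[sel].mean()))
    return out, p
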