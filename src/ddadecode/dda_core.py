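"""Delay differential analysis: sparse nonlinear model fits as features.

The model fitted to every (standardized) window is

    du/dt = a1*u(t - tau1) + a2*u(t - tau2) + a3*u(t - tau1)**2,

with integer sample delays and a unit sample step, so coefficients are in
per-sample units and invariant to the sampling rate once windows are
standardized.  The derivative is estimated by a 3-point center difference.
The least-squares coefficients (a1, a2, a3) and the RMS residual rho of
each fit are the features; they summarize the local dynamics of the window
rather than its spectral content.

Fit modes
---------
* single-trial (ST): each window of each channel fitted independently;
* cross-trial/cross-channel (CT): one coefficient set fitted jointly to a
  group of windows by pooling their regression rows;
* dynamical-ergodicity score E = rho_CT - mean(rho_ST): the penalty paid
  for forcing one model onto all members of the group, near zero when the
  group shares one dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal_io import FeatureMatrix, TrialSet
from .windowing import WindowSet, WindowSpec, window_tensor

__all__ = [
    "DelayPair",
    "DDAFit",
    "estimate_derivative",
    "build_design",
    "fit_st",
    "fit_ct",
    "ergodicity_score",
    "extract_features",
    "features_from_windows",
]

logger = logging.getLogger(__name__)

_QUANTITIES = ("a1", "a2", "a3", "rho")


@dataclass(frozen=True, order=True)
class DelayPair:
    """Ordered integer delays (tau1, tau2) in samples; tau1 != tau2.

    The pair is ordered because only the tau1 term enters the model
    quadratically, so (3, 7) and (7, 3) are different model structures.
    """

    tau1: int
    tau2: int

    def __post_init__(self) -> None:
        if self.tau1 < 1 or self.tau2 < 1:
            raise ValueError("delays must be >= 1 sample")
        if self.tau1 == self.tau2:
            raise ValueError("tau1 and tau2 must differ")

    @property
    def tmax(self) -> int:
        return max(self.tau1, self.tau2)


@dataclass(frozen=True)
class DDAFit:
    """Least-squares fit of one window (ST) or window group (CT)."""

    a1: float
    a2: float
    a3: float
    rho: float
    n_rows: int

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3])

    @property
    def is_degenerate(self) -> bool:
        return not np.isfinite([self.a1, self.a2, self.a3, self.rho]).all()


def estimate_derivative(u: np.ndarray) -> np.ndarray:
    """Center-difference derivative, unit sample step.

    Returns du[n] = (u[n+1] - u[n-1]) / 2 for the interior points
    n = 1 .. N-2 (length N-2); the endpoints are excluded.
    """
    u = np.asarray(u, dtype=float)
    if u.size < 3:
        raise ValueError("need at least 3 samples")
    return (u[2:] - u[:-2]) / 2.0


def build_design(u: np.ndarray, d: DelayPair) -> tuple[np.ndarray, np.ndarray]:
    """Regression system for one window.

    Rows are indexed by n = tmax .. N-2; columns are
    [u[n-tau1], u[n-tau2], u[n-tau1]^2]; the target is the center-difference
    derivative at n.  n_rows = N - 1 - tmax.
    """
    u = np.asarray(u, dtype=float)
    N = u.size
    if N <= d.tmax + 2:
        raise ValueError(f"window of {N} samples too short for delays {d}")
    n = np.arange(d.tmax, N - 1)
    x1 = u[n - d.tau1]
    X = np.stack([x1, u[n - d.tau2], x1 * x1], axis=-1)
    y = (u[n + 1] - u[n - 1]) / 2.0
    return X, y


def _solve_batch(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares over a batch of designs: X (B, R, 3), y (B, R).

    QR-based solve; rank-deficient designs fall back to the minimum-norm
    pseudo-inverse solution (condition number logged).  Non-finite designs
    (degenerate windows) yield NaN coefficients and residual.
    """
    B = X.shape[0]
    coef = np.full((B, 3), np.nan)
    rho = np.full(B, np.nan)
    finite = np.isfinite(X).all(axis=(1, 2)) & np.isfinite(y).all(axis=1)
    if not finite.any():
        return coef, rho
    Xf, yf = X[finite], y[finite]
    Q, R = np.linalg.qr(Xf)
    diag = np.abs(np.diagonal(R, axis1=-2, axis2=-1))
    good = diag.min(axis=1) > 1e-12 * np.maximum(diag.max(axis=1), np.finfo(float).tiny)
    qty = np.einsum("bri,br->bi", Q, yf)
    c = np.empty((Xf.shape[0], 3))
    if good.any():
        c[good] = np.linalg.solve(R[good], qty[good][..., None])[..., 0]
    for i in np.nonzero(~good)[0]:
        c[i] = np.linalg.pinv(Xf[i]) @ yf[i]
        logger.debug("rank-deficient design, cond=%.3g; pseudo-inverse used",
                     np.linalg.cond(Xf[i]))
    resid = np.einsum("bri,bi->br", Xf, c) - yf
    coef[finite] = c
    rho[finite] = np.sqrt(np.mean(resid * resid, axis=1))
    return coef, rho


def fit_st(u: np.ndarray, d: DelayPair) -> DDAFit:
    """Single-trial fit of one window.

    The window is expected to be standardized (zero mean, unit variance);
    a constant or non-finite window produces a NaN-flagged fit.
    """
    u = np.asarray(u, dtype=float)
    if np.isfinite(u).all() and u.std() <= 1e-12 * max(1.0, abs(u.mean())):
        u = np.full_like(u, np.nan)
    X, y = build_design(u, d)
    coef, rho = _solve_batch(X[None], y[None])
    return DDAFit(*coef[0], rho=float(rho[0]), n_rows=X.shape[0])


def fit_ct(windows: list[np.ndarray], d: DelayPair) -> DDAFit:
    """Cross-trial/cross-channel fit: one coefficient set for all windows.

    The regression rows of every window are pooled (stacked vertically) and
    solved jointly; rho is the RMS residual over all pooled rows.  A single
    window reduces to :func:`fit_st`.
    """
    if not windows:
        raise ValueError("need at least one window")
    systems = [build_design(np.asarray(w, dtype=float), d) for w in windows]
    X = np.concatenate([s[0] for s in systems], axis=0)
    y = np.concatenate([s[1] for s in systems], axis=0)
    coef, rho = _solve_batch(X[None], y[None])
    return DDAFit(*coef[0], rho=float(rho[0]), n_rows=X.shape[0])


def ergodicity_score(st_fits: list[DDAFit], ct_fit: DDAFit) -> float:
    """Dynamical-similarity score E = rho_CT - mean(rho_ST).

    Nonnegative up to numerical tolerance (the pooled fit cannot beat the
    per-window fits in RMS); small when the windows share one dynamics.
    NaN-flagged inputs give NaN.
    """
    rhos = np.array([f.rho for f in st_fits])
    if ct_fit.is_degenerate or not np.isfinite(rhos).all():
        return float("nan")
    return float(ct_fit.rho - rhos.mean())


def _tensor_design(W: np.ndarray, d: DelayPair) -> tuple[np.ndarray, np.ndarray]:
    """Design for a window tensor (..., L) -> X (..., R, 3), y (..., R)."""
    L = W.shape[-1]
    if L <= d.tmax + 2:
        raise ValueError(f"window of {L} samples too short for delays {d}")
    n = np.arange(d.tmax, L - 1)
    x1 = W[..., n - d.tau1]
    X = np.stack([x1, W[..., n - d.tau2], x1 * x1], axis=-1)
    y = (W[..., n + 1] - W[..., n - 1]) / 2.0
    return X, y


def features_from_windows(ws: WindowSet, triples, d: DelayPair) -> FeatureMatrix:
    """Per-trial DDA feature vectors from a standardized window tensor.

    For each channel triple and trial: ST statistics per channel (mean and
    population SD across windows of a1, a2, a3, rho -> 8 features), the same
    8 for the joint CT fit over the triple's channels per window, and 2 for
    the ergodicity score E — 34 features per triple in sliding mode.  With a
    single window per trial the raw values replace the mean/SD pairs
    (3*4 + 4 + 1 = 17 features per triple).  NaN-flagged windows are
    excluded from the aggregation; a trial whose windows are all degenerate
    yields a NaN row.
    """
    W = ws.windows
    n_trials, n_ch, n_win, L = W.shape
    X, y = _tensor_design(W, d)
    R = X.shape[-2]
    st_coef, st_rho = _solve_batch(X.reshape(-1, R, 3), y.reshape(-1, R))
    st_coef = st_coef.reshape(n_trials, n_ch, n_win, 3)
    st_rho = st_rho.reshape(n_trials, n_ch, n_win)

    single = n_win == 1
    cols: list[np.ndarray] = []
    names: list[str] = []

    def add(name: str, per_window: np.ndarray) -> None:
        # per_window: (n_trials, n_win) -> aggregate across windows
        if single:
            cols.append(per_window[:, 0])
            names.append(f"{name}.val")
        else:
            n_bad = int(np.isnan(per_window).sum())
            if n_bad:
                logger.debug("%s: %d degenerate windows excluded", name, n_bad)
            all_nan = np.isnan(per_window).all(axis=1)
            pw = per_window.copy()
            pw[all_nan] = 0.0  # placeholder; masked back to NaN below
            m = np.nanmean(pw, axis=1)
            s = np.nanstd(pw, axis=1)
            m[all_nan] = np.nan
            s[all_nan] = np.nan
            cols.append(m)
            names.append(f"{name}.mean")
            cols.append(s)
            names.append(f"{name}.std")

    for ti, trip in enumerate(triples):
        for c in trip:
            ch_name = ws.channel_names[c] if ws.channel_names else f"ch{c}"
            vals = {
                "a1": st_coef[:, c, :, 0],
                "a2": st_coef[:, c, :, 1],
                "a3": st_coef[:, c, :, 2],
                "rho": st_rho[:, c, :],
            }
            for q in _QUANTITIES:
                add(f"T{ti}.{ch_name}.{q}", vals[q])
        # CT: pool the triple's channels row-wise per window index
        Xct = np.concatenate([X[:, c] for c in trip], axis=-2)  # (trials, n_win, 3R, 3)
        yct = np.concatenate([y[:, c] for c in trip], axis=-1)
        ct_coef, ct_rho = _solve_batch(Xct.reshape(-1, 3 * R, 3), yct.reshape(-1, 3 * R))
        ct_coef = ct_coef.reshape(n_trials, n_win, 3)
        ct_rho = ct_rho.reshape(n_trials, n_win)
        ct_vals = {
            "a1": ct_coef[:, :, 0],
            "a2": ct_coef[:, :, 1],
            "a3": ct_coef[:, :, 2],
            "rho": ct_rho,
        }
        for q in _QUANTITIES:
            add(f"T{ti}.CT.{q}", ct_vals[q])
        e = ct_rho - st_rho[:, list(trip), :].mean(axis=1)
        add(f"T{ti}.E", e)

    values = np.stack(cols, axis=1)
    bad_rows = np.isnan(values).any(axis=1)
    if bad_rows.any():
        logger.warning("%d trials have NaN features (degenerate windows)", bad_rows.sum())
    return FeatureMatrix(
        values=values,
        feature_names=names,
        labels=ws.labels,
        subjects=ws.subjects,
    )


def extract_features(
    trialset: TrialSet, triples, d: DelayPair, wspec: WindowSpec
) -> FeatureMatrix:
    """Windowize a trial set and extract its DDA feature matrix."""
    W = window_tensor(trialset.data, trialset.fs, wspec)
    ws = WindowSet(
        windows=W,
        labels=trialset.labels,
        subjects=trialset.subjects,
        channel_names=list(trialset.channel_names),
    )
    return features_from_windows(ws, triples, d)
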