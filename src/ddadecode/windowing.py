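"""Trial segmentation into analysis windows, and per-window normalization.

Windows are half-open ``[start, stop)`` sample intervals with 0-based
indexing.  Millisecond-to-sample conversions use round-half-away-from-zero;
an incomplete trailing window is dropped, never padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WindowSpec", "WindowSet", "make_windows", "standardize_window", "window_tensor"]


def _round_half_away(x: float) -> int:
    """Round half away from zero (1.5 -> 2, 2.5 -> 3)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


@dataclass(frozen=True)
class WindowSpec:
    """Windowing scheme: one window per trial, or sliding windows.

    Parameters
    ----------
    mode : {"single", "sliding"}
        ``single`` uses the whole trial as one window; ``sliding`` tiles
        the trial with overlapping fixed-length windows.
    win_len_ms : float
        Window length in milliseconds (sliding mode only).
    overlap : float
        Fractional overlap between consecutive windows, ``0 <= overlap < 1``.
    """

    mode: str = "sliding"
    win_len_ms: float = 700.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("single", "sliding"):
            raise ValueError(f"unknown window mode {self.mode!r}")
        if self.mode == "sliding":
            if self.win_len_ms <= 0:
                raise ValueError("win_len_ms must be positive")
            if not 0.0 <= self.overlap < 1.0:
                raise ValueError("overlap must be in [0, 1)")


def make_windows(trial_len: int, fs: float, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open sample intervals covering one trial.

    In sliding mode the window length is ``round(win_len_ms * fs / 1000)``
    samples and the step is ``round(win_len * (1 - overlap))`` samples;
    e.g. a 4 s trial at 1024 Hz with 700 ms / 50% overlap yields 10 windows
    of 717 samples stepped by 359.
    """
    if spec.mode == "single":
        if trial_len < 1:
            raise ValueError("empty trial")
        return [(0, trial_len)]
    win = _round_half_away(spec.win_len_ms * fs / 1000.0)
    if win < 1:
        raise ValueError("window shorter than one sample")
    if win > trial_len:
        raise ValueError(f"window of {win} samples exceeds trial of {trial_len} samples")
    step = max(1, _round_half_away(win * (1.0 - spec.overlap)))
    starts = range(0, trial_len - win + 1, step)
    return [(s, s + win) for s in starts]


def standardize_window(u: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance scaling (population SD).

    A zero-variance window is degenerate: it is returned as all-NaN so the
    flag propagates into NaN-coded model fits rather than silently biasing
    aggregates.
    """
    u = np.asarray(u, dtype=float)
    sd = u.std()
    # relative tolerance: a numerically-constant window (sd at rounding
    # level of its mean) is as degenerate as an exactly constant one
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(u.mean())):
        return np.full_like(u, np.nan)
    return (u - u.mean()) / sd


@dataclass
class WindowSet:
    """Standardized windows of a set of trials (or pseudo-trials).

    ``windows`` has shape (n_trials, n_channels, n_windows, win_len); every
    window is individually standardized, degenerate windows are NaN-coded.
    """

    windows: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]


def window_tensor(data: np.ndarray, fs: float, spec: WindowSpec) -> np.ndarray:
    """Cut (trials, channels, samples) into standardized windows.

    Returns an array (trials, channels, n_windows, win_len).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected (trials, channels, samples)")
    bounds = make_windows(data.shape[2], fs, spec)
    segs = np.stack([data[:, :, a:b] for a, b in bounds], axis=2)
    mean = segs.mean(axis=-1, keepdims=True)
    sd = segs.std(axis=-1, keepdims=True)
    ok = sd > 1e-12 * np.maximum(1.0, np.abs(mean))
    out = np.where(ok, (segs - mean) / np.where(ok, sd, 1.0), np.nan)
    return out
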