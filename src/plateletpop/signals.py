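"""Fluorescence signal synthesis and first-spike detection.

The mean fluorescence of an analysis annulus is modeled as the average of a
single *basic response curve* — a smooth growth-and-decay intensity function
representing the ensemble-average calcium response of cells after
activation — shifted in time by each cell's activation time:

    I_a(t) = baseline + (1 / N_a) * sum_{i in a} f(t - TA_i)

with f = 0 before activation.  The basic curve itself is obtained by a
polynomial least-squares fit to the (baseline-subtracted) mean trace of the
annulus nearest to the stimulation spot, where the diffusion delay is
negligible.

Single-cell traces are handled separately: the first calcium spike after the
flash is located with standard peak detection, with the prominence threshold
expressed in robust units of the pre-flash noise (1.4826 x median absolute
deviation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .population import ActivationResult

__all__ = [
    "BasicResponseCurve",
    "TraceSet",
    "fit_basic_curve",
    "synthesize_area_signal",
    "normalize_trace",
    "detect_first_spike",
    "detect_first_spikes",
]

#: Default polynomial degree and support (s) of the basic response curve.
DEFAULT_DEGREE = 5
DEFAULT_T_MAX = 120.0
#: Default peak-prominence multiplier, in robust pre-flash noise units.
DEFAULT_MIN_PROMINENCE = 8.0


@dataclass(frozen=True)
class BasicResponseCurve:
    """Polynomial growth-and-decay intensity response of an activated cell.

    ``coef`` are ordinary polynomial coefficients (lowest order first) in
    time since activation, valid on [0, t_max]; evaluation is zero before
    activation, clamped at >= 0, and holds the end value beyond t_max.
    """

    coef: np.ndarray
    t_max: float
    baseline: float = 0.0
    residual_rms: float = float("nan")

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError(f"t_max must be positive, got {self.t_max}")
        object.__setattr__(self, "coef", np.asarray(self.coef, dtype=float))

    def __call__(self, dt) -> np.ndarray:
        """Evaluate at time-since-activation ``dt`` (s)."""
        dt = np.asarray(dt, dtype=float)
        clipped = np.clip(dt, 0.0, self.t_max)
        val = np.polynomial.polynomial.polyval(clipped, self.coef)
        out = np.where(dt < 0, 0.0, np.maximum(val, 0.0))
        return out if out.ndim else float(out)

    def sampled(self, step: float, horizon: float) -> np.ndarray:
        """Evaluate on the regular grid 0, step, ..., >= horizon."""
        n = int(np.ceil(horizon / step)) + 1
        return self(np.arange(n) * step)


@dataclass(frozen=True)
class TraceSet:
    """Uniformly sampled intensity traces, per cell or per area.

    ``values`` has shape (n_traces, n_frames); ``columns`` names the traces
    (cell ids or ``area_k`` labels).
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "per-cell"  # "per-cell" | "per-area"
    columns: Optional[list] = None

    def __post_init__(self) -> None:
        steps = np.diff(self.times)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace time grid must be uniform")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])

    def to_frame(self) -> pd.DataFrame:
        cols = self.columns or list(range(self.values.shape[0]))
        df = pd.DataFrame(self.values.T, columns=[str(c) for c in cols])
        df.insert(0, "time_s", self.times)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str = "per-cell") -> "TraceSet":
        cols = [c for c in df.columns if c != "time_s"]
        return cls(
            times=df["time_s"].to_numpy(float),
            values=df[cols].to_numpy(float).T,
            kind=kind,
            columns=cols,
        )


def fit_basic_curve(
    times,
    values,
    degree: int = DEFAULT_DEGREE,
    t_max: float = DEFAULT_T_MAX,
    baseline: float = 0.0,
) -> BasicResponseCurve:
    """Least-squares polynomial fit of a post-flash mean trace.

    Parameters
    ----------
    times : array
        Time since the flash (s); frames outside [0, t_max] are ignored.
    values : array
        Mean intensity of the nearest annulus (same length as ``times``).
    degree : int
        Polynomial degree (>= 2).
    baseline : float
        Resting intensity subtracted before fitting; stored on the curve so
        synthesized signals can add it back.
    """
    if degree < 2:
        raise ValueError(f"degree must be >= 2, got {degree}")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = (times >= 0) & (times <= t_max)
    if np.count_nonzero(mask) <= degree:
        raise ValueError("trace does not cover [0, t_max] densely enough")
    t, v = times[mask], values[mask] - baseline
    if np.ptp(v) == 0:
        warnings.warn("degenerate (constant) trace; returning a flat curve")
        return BasicResponseCurve(
            coef=np.array([v[0]]), t_max=t_max, baseline=baseline, residual_rms=0.0
        )
    series = np.polynomial.Polynomial.fit(t, v, degree)
    coef = series.convert().coef
    rms = float(np.sqrt(np.mean((np.polynomial.polynomial.polyval(t, coef) - v) ** 2)))
    return BasicResponseCurve(coef=coef, t_max=t_max, baseline=baseline, residual_rms=rms)


def _synthesize_exact(
    ta: np.ndarray, curve: BasicResponseCurve, time_grid: np.ndarray
) -> np.ndarray:
    """Mean of curve(t - ta_i) over cells, exact per-cell evaluation."""
    total = np.zeros_like(time_grid)
    chunk = max(1, int(4e6 // max(time_grid.size, 1)))
    for start in range(0, ta.size, chunk):
        dt = time_grid[None, :] - ta[start : start + chunk, None]
        total += curve(dt).sum(axis=0)
    return total / ta.size


def _synthesize_binned(
    ta: np.ndarray,
    curve: BasicResponseCurve,
    time_grid: np.ndarray,
    oversample: int,
) -> np.ndarray:
    """Mean of curve(t - ta_i) via linear deposition on an oversampled grid.

    Activation times are split with linear weights between the two
    neighbouring fine-grid bins (grid step = frame period / oversample), so
    the result is the exact sum with the curve replaced by its piecewise
    linear interpolant — continuous in ta, with O(step^2) error.
    Requires a uniform time grid starting at 0.
    """
    step = (time_grid[1] - time_grid[0]) / oversample
    pos = ta / step
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    n_fine = time_grid.size * oversample + 1
    weights = np.zeros(n_fine + 1)
    np.add.at(weights, np.minimum(lo, n_fine), 1.0 - frac)
    np.add.at(weights, np.minimum(lo + 1, n_fine), frac)
    kernel = curve.sampled(step, float(time_grid[-1]))
    conv = np.convolve(weights[:n_fine], kernel)
    return conv[:: oversample][: time_grid.size] / ta.size


def synthesize_area_signal(
    act: ActivationResult,
    areas: np.ndarray,
    curve: BasicResponseCurve,
    time_grid,
    area_indices: Optional[Sequence[int]] = None,
    baseline: Optional[float] = None,
    method: str = "exact",
    oversample: int = 4,
) -> pd.DataFrame:
    """Per-annulus mean intensity from activation times and a basic curve.

    I_a(t) = baseline + (1/N_a) * sum_{i in a, TA_i <= t} curve(t - TA_i);
    never-activated cells contribute baseline only but stay in N_a.  With
    ``method="binned"`` the sum is computed by fast convolution on an
    oversampled frame grid (see :func:`_synthesize_binned`); "exact"
    evaluates the polynomial per cell and frame.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if baseline is None:
        baseline = curve.baseline
    if area_indices is None:
        area_indices = sorted(k for k in np.unique(areas) if k > 0)
    if method == "binned" and (time_grid[0] != 0.0 or time_grid.size < 2):
        method = "exact"
    out = {"time_s": time_grid}
    for k in area_indices:
        ta_k = act.ta[areas == k]
        n_k = ta_k.size
        if n_k == 0:
            warnings.warn(f"area {k} holds no cells; returning baseline only")
            out[f"area_{k}"] = np.full_like(time_grid, baseline)
            continue
        active = ta_k[~np.isnan(ta_k)]
        if active.size == 0:
            out[f"area_{k}"] = np.full_like(time_grid, baseline)
            continue
        if method == "binned":
            mean_resp = _synthesize_binned(active, curve, time_grid, oversample)
        elif method == "exact":
            mean_resp = _synthesize_exact(active, curve, time_grid)
        else:
            raise ValueError(f"unknown method {method!r}")
        out[f"area_{k}"] = baseline + mean_resp * (active.size / n_k)
    return pd.DataFrame(out)


def normalize_trace(df: pd.DataFrame, flash_time: float) -> pd.DataFrame:
    """Divide each series by its own pre-flash mean (self-normalization).

    After normalization the pre-flash mean of every column is exactly 1,
    matching how recorded intensities are reduced before model comparison.
    Idempotent up to floating point.
    """
    pre = df["time_s"] < flash_time
    if not pre.any():
        raise ValueError("empty pre-flash window")
    out = df.copy()
    for col in df.columns:
        if col == "time_s":
            continue
        m = df.loc[pre, col].mean()
        if m == 0:
            raise ValueError(f"zero pre-flash mean in column {col!r}")
        out[col] = df[col] / m
    return out


def _robust_noise_scale(pre: np.ndarray) -> float:
    """1.4826 x MAD of the pre-flash frames (Gaussian-consistent sigma)."""
    return 1.4826 * float(np.median(np.abs(pre - np.median(pre))))


def detect_first_spike(
    values,
    times,
    flash_time: float,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> Optional[float]:
    """Time of the first qualifying calcium spike after the flash, or None.

    A qualifying spike is a local maximum whose prominence exceeds
    ``min_prominence`` times the robust pre-flash noise scale.  Peaks before
    ``flash_time`` are ignored.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.size < 3:
        raise ValueError("trace shorter than 3 frames")
    if not (times[0] <= flash_time <= times[-1]):
        raise ValueError("flash_time outside the trace")
    noise = _robust_noise_scale(values[times < flash_time])
    threshold = max(min_prominence * noise, 1e-12)
    peaks, _ = find_peaks(values, prominence=threshold)
    for idx in peaks:
        if times[idx] > flash_time:
            return float(times[idx])
    return None


def detect_first_spikes(
    traces: TraceSet,
    flash_time: float,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> np.ndarray:
    """First-spike time per cell of a TraceSet; NaN where none qualifies."""
    out = np.full(traces.values.shape[0], np.nan)
    for i, row in enumerate(traces.values):
        t = detect_first_spike(row, traces.times, flash_time, min_prominence)
        if t is not None:
            out[i] = t
    return out
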