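"""FRAP curve normalization, bleach correction and recovery metrics.

Fluorescence recovery after photobleaching measures ensemble mobility: a
circular region is bleached in a single step and the mean ROI intensity
F(t) is followed over time.  Curves are scaled per cell as

    F_norm(t) = (F(t) - F(0)) / (<F_pre> - F(0))

with t = 0 at the first post-bleach frame and <F_pre> the mean pre-bleach
intensity, so the normalized curve starts at 0 and recovers toward the
mobile fraction.  A constant background cancels in this linear transform.
Residual acquisition photobleaching is corrected by dividing by a single
exponential decay whose rate is averaged over fits to control-ROI series.
Cells in which less than 40% of the initial intensity was removed by the
bleach step are excluded by QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FRAPCurve",
    "BleachCorrection",
    "normalize_frap",
    "fit_bleach",
    "bleach_correct",
    "qc_bleach_depth",
    "recovery_metrics",
]


@dataclass
class FRAPCurve:
    """A normalized single-cell recovery curve (t = 0 at first post frame)."""

    times: np.ndarray  # s, starting at 0
    values: np.ndarray  # normalized intensity; values[0] == 0 by construction
    f_pre: float
    f0: float
    bleach_depth: float  # 1 - F(0)/<F_pre>
    correction: dict = field(default_factory=dict)


@dataclass
class BleachCorrection:
    """Average single-exponential acquisition-bleach model over a cell set."""

    rate: float  # s^-1, averaged over control-ROI fits
    rates: np.ndarray
    n_used: int
    n_dropped: int

    def apply(self, series: np.ndarray, times: np.ndarray) -> np.ndarray:
        """Divide a raw series by the normalized decay exp(-rate * (t - t0))."""
        times = np.asarray(times, float)
        return np.asarray(series, float) / np.exp(-self.rate * (times - times[0]))


def normalize_frap(
    series: np.ndarray,
    n_pre: int,
    times: np.ndarray | None = None,
    dt: float = 1.0,
) -> FRAPCurve:
    """Normalize a bleach-ROI intensity series.

    ``series`` holds ``n_pre`` pre-bleach frames followed by the
    post-bleach frames; ``F(0)`` is the first post-bleach value and
    ``<F_pre>`` the mean of the pre-bleach frames.
    """
    series = np.asarray(series, float)
    if n_pre < 1:
        raise ValueError("need at least one pre-bleach frame")
    if len(series) <= n_pre:
        raise ValueError("post-bleach series is empty")
    f_pre = float(series[:n_pre].mean())
    post = series[n_pre:]
    f0 = float(post[0])
    denom = f_pre - f0
    if denom == 0:
        raise ValueError("degenerate normalization: <F_pre> equals F(0)")
    if times is None:
        t_post = dt * np.arange(len(post))
    else:
        times = np.asarray(times, float)
        t_post = times[n_pre:] - times[n_pre]
    values = (post - f0) / denom
    depth = 1.0 - f0 / f_pre if f_pre != 0 else float("nan")
    return FRAPCurve(t_post, values, f_pre, f0, depth)


def _exp_model(t, a, k):
    return a * np.exp(-k * t)


def fit_bleach(series: np.ndarray, times: np.ndarray) -> tuple[float, float]:
    """Fit A*exp(-k t) to one control-ROI series; returns (A, k)."""
    series = np.asarray(series, float)
    times = np.asarray(times, float)
    if len(series) < 4:
        raise ValueError("control series needs at least 4 points")
    t = times - times[0]
    a0 = float(series[0]) if series[0] > 0 else float(series.mean())
    span = max(t[-1], 1e-9)
    tail = max(float(series[-1]), 1e-12)
    k0 = max(math.log(max(a0, 1e-12) / tail) / span, 0.0)
    popt, _ = curve_fit(_exp_model, t, series, p0=[a0, k0], maxfev=10_000)
    return float(popt[0]), float(popt[1])


def bleach_correct(
    control_series: list[np.ndarray],
    times: list[np.ndarray] | np.ndarray,
) -> BleachCorrection:
    """Average single-exponential fits over a set of control-ROI series.

    Non-converging fits are dropped (and counted); if all series fail no
    correction is applied (rate 0) and the result is flagged through
    ``n_used == 0``.
    """
    if isinstance(times, np.ndarray) and np.ndim(times[0]) == 0:
        times = [times] * len(control_series)
    rates = []
    n_dropped = 0
    for s, t in zip(control_series, times):
        try:
            _, k = fit_bleach(s, t)
            rates.append(k)
        except (RuntimeError, ValueError):
            n_dropped += 1
    if rates:
        rate = float(np.mean(rates))
    else:
        rate = 0.0
    return BleachCorrection(rate, np.array(rates), len(rates), n_dropped)


def qc_bleach_depth(
    pre_mean: float, f0: float, threshold: float = 0.40
) -> bool:
    """Accept a cell iff the bleach step removed >= ``threshold`` of the
    pre-bleach intensity (the boundary case is accepted)."""
    if not (np.isfinite(pre_mean) and np.isfinite(f0)):
        raise ValueError("intensities must be finite")
    if pre_mean <= 0:
        raise ValueError("pre-bleach mean must be positive")
    return (1.0 - f0 / pre_mean) >= threshold


def recovery_metrics(curve: FRAPCurve, t_probe: float = 48.0) -> dict:
    """Recovery readouts of one normalized curve.

    ``recovery_at_t_probe`` is the normalized value linearly interpolated
    at ``t_probe`` seconds (NaN if the curve ends earlier); ``plateau`` is
    the mean of the final 10% of points.
    """
    t, v = curve.times, curve.values
    if t[-1] >= t_probe:
        recovery = float(np.interp(t_probe, t, v))
    else:
        recovery = float("nan")
    n_tail = max(1, int(round(0.1 * len(v))))
    return {
        "recovery_at_t_probe": recovery,
        "t_probe_s": t_probe,
        "plateau": float(v[-n_tail:].mean()),
    }
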