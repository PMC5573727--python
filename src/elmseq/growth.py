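"""Early and late growth-curve slopes from plate-reader time series.

The growth index is the 430/560 nm absorbance ratio sampled over time.
Two summary slopes are computed from pairwise slopes between time points a
fixed number of measurements apart, summarized as the maximum over sliding
windows of the within-window median:

* early slope — gap of 3 measurements, restricted to the 10-30 h interval
  (growth proper);
* late slope — gap of 4 measurements over the whole curve (metabolic
  activity).
"""

from __future__ import annotations

import numpy as np

DEFAULT_WINDOW = 30
EARLY_INTERVAL = (10.0, 30.0)


def pairwise_slopes(times, values, gap: int) -> np.ndarray:
    """(value[i] - value[i+gap]) / (time[i] - time[i+gap]) for all i."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("times and values must be matching 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if len(t) <= gap:
        raise ValueError(f"need more than {gap} time points")
    return (v[:-gap] - v[gap:]) / (t[:-gap] - t[gap:])


def max_median_slope(slopes: np.ndarray, window: int = DEFAULT_WINDOW,
                     step: int = 1) -> float:
    """Max over sliding windows of the median slope.

    Windows of ``window`` consecutive slopes advance by ``step``;
    incomplete trailing windows are dropped. A series shorter than one
    window forms a single window.
    """
    s = np.asarray(slopes, dtype=float)
    if s.size == 0:
        raise ValueError("no slopes to summarize")
    if s.size <= window:
        return float(np.median(s))
    starts = range(0, s.size - window + 1, step)
    return float(max(np.median(s[i:i + window]) for i in starts))


def early_slope(times, values, gap: int = 3, window: int = DEFAULT_WINDOW,
                interval: tuple[float, float] = EARLY_INTERVAL,
                step: int = 1) -> float:
    """Growth slope over the early (10-30 h by default) interval."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    mask = (t >= interval[0]) & (t <= interval[1])
    if mask.sum() <= gap:
        raise ValueError(
            f"too few points in interval {interval}: {int(mask.sum())}"
        )
    return max_median_slope(pairwise_slopes(t[mask], v[mask], gap),
                            window=window, step=step)


def late_slope(times, values, gap: int = 4, window: int = DEFAULT_WINDOW,
               step: int = 1) -> float:
    """Whole-curve slope with a gap of 4 measurements."""
    return max_median_slope(pairwise_slopes(times, values, gap),
                            window=window, step=step)
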