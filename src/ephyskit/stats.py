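"""Windowed statistics, rise-time analytics, stability selection and MPFA
summary statistics.

MPFA (multiple-probability fluctuation analysis) summarizes evoked-response
amplitudes per release-probability condition as a mean peak current I_p, a
variance sigma_I^2 and the standard error of that variance.  The variance
error comes from h-statistics - the unbiased estimators of population
central moments - via the unbiased estimate of Var(s^2):

    Var(s^2) = (1/n) * (mu4_hat - s^4_hat * (n - 3)/(n - 1))

where mu4_hat is the unbiased fourth central moment and s^4_hat the
unbiased estimate of sigma^4.  These errors weight the variance-mean fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import spearmanr

from .trace import SweepSet, Trace, WindowSpec


@dataclass
class StatsResult:
    measure: str
    values: np.ndarray               # one value per sweep, NaN on failure
    times: np.ndarray | None         # extremum time for min/max, else None
    window: WindowSpec
    baseline_window: WindowSpec | None
    baselines: np.ndarray | None


@dataclass
class MPFAPoint:
    label: str
    i_p: float           # mean peak current, pA
    sigma2: float        # variance, pA^2
    var_err: float       # SD of the variance estimate, pA^2
    n: int               # trials
    background_var: float = 0.0


# ---------------------------------------------------------------------------
# windowed measures
# ---------------------------------------------------------------------------

def window_measure(sweepset: SweepSet, measure: str, window: WindowSpec,
                   baseline_window: WindowSpec | None = None) -> StatsResult:
    """Per-sweep avg/min/max of (trace - baseline mean) over a window."""
    if measure not in ("avg", "min", "max"):
        raise ValueError(f"unknown measure {measure!r}")
    values = np.full(len(sweepset), np.nan)
    times = np.full(len(sweepset), np.nan)
    bases = np.full(len(sweepset), np.nan)
    for k, tr in enumerate(sweepset):
        idx = tr.window_indices(window)
        if idx.size == 0:
            continue
        base = 0.0
        if baseline_window is not None:
            bidx = tr.window_indices(baseline_window)
            if bidx.size == 0:
                continue
            base = float(tr.samples[bidx].mean())
        bases[k] = base
        seg = tr.samples[idx] - base
        if measure == "avg":
            values[k] = seg.mean()
        elif measure == "min":
            j = int(np.argmin(seg))
            values[k] = seg[j]
            times[k] = tr.t_start + idx[j] * tr.dt
        else:
            j = int(np.argmax(seg))
            values[k] = seg[j]
            times[k] = tr.t_start + idx[j] * tr.dt
    return StatsResult(measure, values,
                       times if measure in ("min", "max") else None,
                       window, baseline_window, bases)


def peak_window(sweepset: SweepSet, search: WindowSpec, width: float = 0.1,
                polarity: str = "neg") -> WindowSpec:
    """A narrow window centered on the extremum of the set average.

    The default 0.1-ms width is the convention for measuring peak amplitudes
    in MPFA: average the selected sweeps, locate the polarity extremum in
    the search window and center the measurement window there.
    """
    from .trace import average
    mean, _ = average(sweepset)
    idx = mean.window_indices(search)
    seg = mean.samples[idx]
    j = int(np.argmin(seg)) if polarity == "neg" else int(np.argmax(seg))
    t_peak = mean.t_start + idx[j] * mean.dt
    return WindowSpec(t_peak - width / 2.0, t_peak + width / 2.0)


def rise_time(trace: Trace, p_low: float, p_high: float,
              baseline_window: WindowSpec, peak_window: WindowSpec
              ) -> tuple[float, float, float]:
    """Fractional rise time, e.g. 10-90% or 20-80%.

    The peak is the polarity extremum in ``peak_window`` relative to the
    baseline mean; t_low/t_high are the last linearly interpolated crossings
    of baseline + p*(peak - baseline) before the peak.  Returns
    (t_low, t_high, rt); NaNs when a crossing cannot be found.
    """
    if not 0 < p_low < p_high < 1:
        raise ValueError("need 0 < p_low < p_high < 1")
    bidx = trace.window_indices(baseline_window)
    pidx = trace.window_indices(peak_window)
    if bidx.size == 0 or pidx.size == 0:
        return (np.nan, np.nan, np.nan)
    base = float(trace.samples[bidx].mean())
    seg = trace.samples[pidx] - base
    j = int(np.argmax(np.abs(seg)))
    peak = seg[j]
    i_peak = pidx[j]
    sign = np.sign(peak) if peak != 0 else 1.0
    y = sign * (trace.samples - base)   # peak-positive view
    target_peak = sign * peak

    def last_crossing(frac: float) -> float:
        level = frac * target_peak
        for i in range(i_peak, 0, -1):
            if y[i - 1] < level <= y[i]:
                f = (level - y[i - 1]) / (y[i] - y[i - 1])
                return trace.t_start + (i - 1 + f) * trace.dt
        return np.nan

    t_low = last_crossing(p_low)
    t_high = last_crossing(p_high)
    if np.isnan(t_low) or np.isnan(t_high):
        return (np.nan, np.nan, np.nan)
    return (t_low, t_high, t_high - t_low)


def rt_slope(trace: Trace, p_low: float, p_high: float,
             baseline_window: WindowSpec, peak_window: WindowSpec) -> float:
    """Slope (signal units per ms) between the two rise-time crossings.

    slope = (p_high - p_low) * (peak - baseline) / rt, baseline-relative;
    it scales with amplitude where the rise time does not, which is what
    makes it useful as a second classification criterion.
    """
    bidx = trace.window_indices(baseline_window)
    pidx = trace.window_indices(peak_window)
    if bidx.size == 0 or pidx.size == 0:
        return np.nan
    base = float(trace.samples[bidx].mean())
    seg = trace.samples[pidx] - base
    peak = seg[int(np.argmax(np.abs(seg)))]
    t_low, t_high, rt = rise_time(trace, p_low, p_high, baseline_window,
                                  peak_window)
    if not np.isfinite(rt) or rt == 0:
        return np.nan
    return (p_high - p_low) * peak / rt


# ---------------------------------------------------------------------------
# stability and set construction
# ---------------------------------------------------------------------------

def stability_range(values, alpha: float = 0.05, min_len: int = 10
                    ) -> tuple[int, int, float, float]:
    """Longest stable suffix of a per-sweep measure series.

    Scans the start index i upward and returns the first window [i, n) whose
    Spearman rank correlation with sweep index has two-sided p >= alpha,
    i.e. no detectable monotonic trend.  Returns (i_begin, i_end, rho, p).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < min_len:
        raise ValueError(f"need at least {min_len} values, got {n}")
    for i in range(0, n - min_len + 1):
        seg = v[i:]
        rho, p = spearmanr(np.arange(seg.size), seg)
        if np.isnan(p):
            continue
        if p >= alpha:
            return i, n, float(rho), float(p)
    raise ValueError("no stable region: every suffix window shows a trend")


_OPS = {">": np.greater, "<": np.less, ">=": np.greater_equal,
        "<=": np.less_equal}


def classify_inequality(values, op: str, threshold: float) -> np.ndarray:
    """Boolean set membership from a per-sweep inequality (NaN -> False)."""
    if op not in _OPS:
        raise ValueError(f"unknown operator {op!r}; use one of {sorted(_OPS)}")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    v = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = _OPS[op](v, threshold)
    mask = np.where(np.isfinite(v), mask, False)
    if v.size and not np.isfinite(v).any():
        warnings.warn("all values are NaN; classification is empty")
    return mask


# ---------------------------------------------------------------------------
# h-statistics and MPFA summary
# ---------------------------------------------------------------------------

def h_moment4(x) -> float:
    """Unbiased (h-statistic) estimate of the fourth central moment."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("fourth-moment h-statistic needs n >= 4")
    d = x - x.mean()
    m2 = np.mean(d * d)
    m4 = np.mean(d ** 4)
    return n * ((n * n - 2 * n + 3) * m4 - 3 * (2 * n - 3) * m2 * m2) \
        / ((n - 1) * (n - 2) * (n - 3))


def h_sigma4(x) -> float:
    """Unbiased estimate of sigma^4 (the square of the population variance)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("sigma^4 h-statistic needs n >= 4")
    d = x - x.mean()
    m2 = np.mean(d * d)
    m4 = np.mean(d ** 4)
    return n * ((n * n - 3 * n + 3) * m2 * m2 - (n - 1) * m4) \
        / ((n - 1) * (n - 2) * (n - 3))


def var_of_variance(x) -> float:
    """Unbiased estimate of Var(s^2) from the h-statistics."""
    x = np.asarray(x, dtype=float)
    n = x.size
    v = (h_moment4(x) - h_sigma4(x) * (n - 3) / (n - 1)) / n
    return max(float(v), 0.0)


def mpfa_stats(peaks, backgrounds, label: str = "",
               subtract_background: bool = True) -> MPFAPoint:
    """Summarize one probability condition for the variance-mean relation.

    I_p is the mean of the per-trial peak measures; sigma2 the unbiased
    variance of the peaks minus (optionally) the unbiased variance of the
    background measures; var_err the h-statistic SD of the peak variance.
    """
    peaks = np.asarray(peaks, dtype=float)
    backgrounds = np.asarray(backgrounds, dtype=float)
    if peaks.size < 4 or backgrounds.size < 4:
        raise ValueError("mpfa_stats needs n >= 4 peaks and backgrounds")
    i_p = float(peaks.mean())
    bg_var = float(backgrounds.var(ddof=1))
    sigma2 = float(peaks.var(ddof=1))
    if subtract_background:
        sigma2 -= bg_var
    if sigma2 < 0:
        warnings.warn(f"negative corrected variance ({sigma2:g} pA^2) floored at 0")
        sigma2 = 0.0
    # floor keeps var_err > 0 even for degenerate zero-variance conditions
    # (e.g. P = 1 with no quantal variability), so weights stay finite
    var_err = max(float(np.sqrt(var_of_variance(peaks))), 1e-12)
    return MPFAPoint(label, i_p, sigma2, var_err, peaks.size, bg_var)


def spillover_subtract(point: MPFAPoint, ip_s: float, sigma2_s: float
                       ) -> MPFAPoint:
    """Remove externally estimated spillover mean/variance from a point."""
    sigma2 = point.sigma2 - sigma2_s
    if sigma2 < 0:
        warnings.warn("spillover-corrected variance < 0; floored at 0")
        sigma2 = 0.0
    return replace(point, i_p=point.i_p - ip_s, sigma2=sigma2,
                   label=f"{point.label}-spillover_corrected")
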