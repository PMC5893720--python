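"""Spontaneous synaptic event detection.

Two detectors are provided:

* a sliding-baseline threshold search: a stepwise scan for a sample that
  deviates from a local baseline (the mean over a short window ending a
  fixed forward offset before the test point) by more than a level, given
  either in absolute signal units or as a multiple of the rolling baseline
  standard deviation;
* template matching in the Clements & Bekkers sense: a unit template is
  least-squares fitted (scale + offset) to the data at every position and
  the detection criterion is scale / residual SD.

Both return :class:`EventRecord` lists that can be reviewed, exported, and
extracted into per-event sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, find_peaks

from .trace import SweepSet, Trace, lowpass


@dataclass(frozen=True)
class DetectionConfig:
    polarity: str = "neg"             # "neg" | "pos"
    level_mode: str = "absolute"      # "absolute" | "n_stdv"
    level: float = 6.0                # pA, or SD multiples in n_stdv mode
    baseline_win: float = 5.0         # b, ms
    forward_offset: float = 2.5       # Delta t_f, ms
    onset_win: float = 2.0            # ms, backward search for the onset
    peak_win: float = 2.0             # ms, forward search for the peak
    require_onset: bool = True
    require_peak: bool = True
    min_separation: float = 1.0       # ms
    lowpass_fc: float | None = None   # kHz, detection-time filter (None = off)
    onset_fraction: float = 0.10      # onset = last point within this fraction
                                      # of the event amplitude from baseline

    def __post_init__(self) -> None:
        if self.polarity not in ("neg", "pos"):
            raise ValueError("polarity must be 'neg' or 'pos'")
        if self.level_mode not in ("absolute", "n_stdv"):
            raise ValueError("level_mode must be 'absolute' or 'n_stdv'")
        if not (self.baseline_win > 0 and self.forward_offset > 0 and self.level > 0):
            raise ValueError("baseline_win, forward_offset and level must be > 0")


@dataclass(frozen=True)
class TemplateConfig:
    template: np.ndarray              # unit amplitude, baseline 0
    level: float = -3.0               # criterion level (negative for neg events)
    polarity: str = "neg"
    min_separation: float = 1.0       # ms

    def __post_init__(self) -> None:
        w = np.asarray(self.template, dtype=float)
        if w.size < 3:
            raise ValueError("template needs at least 3 samples")
        if np.ptp(w) == 0:
            raise ValueError("template is constant")
        object.__setattr__(self, "template", w)


@dataclass
class EventRecord:
    sweep: int
    t_cross: float
    t_onset: float | None
    t_peak: float | None
    peak_amp: float | None
    baseline: float
    accepted: bool = True
    reason: str = ""


def _sliding_mean_sd(y: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Trailing-window mean and SD ending at each index (window [i-w+1, i])."""
    c1 = np.cumsum(np.insert(y, 0, 0.0))
    c2 = np.cumsum(np.insert(y * y, 0, 0.0))
    mean = np.full_like(y, np.nan)
    sd = np.full_like(y, np.nan)
    i = np.arange(w - 1, y.size)
    s1 = c1[i + 1] - c1[i + 1 - w]
    s2 = c2[i + 1] - c2[i + 1 - w]
    mean[i] = s1 / w
    var = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
    sd[i] = np.sqrt(var)
    return mean, sd


def detect_threshold(trace: Trace, config: DetectionConfig,
                     sweep: int = 0) -> list[EventRecord]:
    """Sliding-baseline threshold event search on one trace."""
    work = lowpass(trace, config.lowpass_fc) if config.lowpass_fc else trace
    y = work.samples
    dt = work.dt
    w = max(int(round(config.baseline_win / dt)), 1)
    off = max(int(round(config.forward_offset / dt)), 1)
    if trace.n <= w + off:
        raise ValueError("trace shorter than baseline window + forward offset")

    mean, sd = _sliding_mean_sd(y, w)
    # baseline for test index i is the window ending at i - off
    base = np.full_like(y, np.nan)
    base[off:] = mean[:-off]
    base_sd = np.full_like(y, np.nan)
    base_sd[off:] = sd[:-off]

    sign = -1.0 if config.polarity == "neg" else 1.0
    dev = sign * (y - base)
    thr = config.level if config.level_mode == "absolute" else config.level * base_sd
    candidates = np.nonzero(dev > thr)[0]

    onset_n = max(int(round(config.onset_win / dt)), 1)
    peak_n = max(int(round(config.peak_win / dt)), 1)
    sep_n = max(int(round(config.min_separation / dt)), 1)

    events: list[EventRecord] = []
    pos = 0
    ci = 0
    while ci < candidates.size:
        i = candidates[ci]
        if i < pos:
            ci += 1
            continue
        b = float(base[i])
        # provisional peak: polarity extremum within the peak window after the crossing
        seg = slice(i, min(i + peak_n + 1, trace.n))
        rel = sign * (y[seg] - b)
        j = i + int(np.argmax(rel))
        amp = float(rel.max())
        peak_ok = j > i or rel[0] == amp  # extremum found in window
        # peak must be a genuine local extremum, not the window edge still rising
        if j == seg.stop - 1 and j < trace.n - 1 and sign * (y[j + 1] - b) > amp:
            peak_ok = False
        # onset: last pre-crossing sample within onset_fraction*amp of baseline
        t_onset = None
        k0 = max(i - onset_n, 0)
        pre = sign * (y[k0:i + 1] - b)
        within = np.nonzero(pre <= config.onset_fraction * amp)[0]
        if within.size:
            t_onset = work.t_start + (k0 + within[-1]) * dt
        t_peak = work.t_start + j * dt if peak_ok else None
        peak_amp = float(y[j] - b) if peak_ok else None

        accepted = True
        reason = ""
        if config.require_onset and t_onset is None:
            accepted, reason = False, "no onset"
        if config.require_peak and not peak_ok:
            accepted, reason = False, (reason + "; " if reason else "") + "no peak"
        events.append(EventRecord(sweep, work.t_start + i * dt, t_onset, t_peak,
                                  peak_amp, b, accepted, reason))
        pos = (j if peak_ok else i) + sep_n
        ci += 1
    return events


def detect_template(trace: Trace, config: TemplateConfig,
                    sweep: int = 0) -> tuple[Trace, list[EventRecord]]:
    """Template-matching detection; returns (criterion trace, events).

    At each offset k the data segment d is fitted as d ~ s*w + c by least
    squares; the detection criterion is DC(k) = s / sigma_res with
    sigma_res = sqrt(SSE / (K - 1)).  Events are the local extrema of DC
    beyond the criterion level.
    """
    w = config.template
    K = w.size
    y = trace.samples
    if K >= y.size:
        raise ValueError("template must be shorter than the trace")
    n_off = y.size - K + 1

    sw = float(w.sum())
    sww = float((w * w).sum())
    ones = np.ones(K)
    sd_ = fftconvolve(y, ones[::-1], mode="valid")          # sum d
    sdd = fftconvolve(y * y, ones[::-1], mode="valid")      # sum d^2
    swd = fftconvolve(y, w[::-1], mode="valid")             # sum w d

    denom = K * sww - sw * sw
    s = (K * swd - sw * sd_) / denom
    c = (sd_ - s * sw) / K
    sse = (sdd + s * s * sww + K * c * c
           + 2.0 * s * c * sw - 2.0 * s * swd - 2.0 * c * sd_)
    sse = np.maximum(sse, 0.0)
    sigma = np.sqrt(sse / (K - 1))
    dc = s / np.maximum(sigma, 1e-12)

    criterion = Trace(dc, dt=trace.dt, t_start=trace.t_start, units="",
                      label="detection_criterion")

    sign = -1.0 if config.polarity == "neg" else 1.0
    sep_n = max(int(round(config.min_separation / trace.dt)), 1)
    peaks, _ = find_peaks(sign * dc, height=abs(config.level), distance=sep_n)

    events: list[EventRecord] = []
    for k in peaks:
        seg = slice(k, min(k + K, y.size))
        rel = sign * (y[seg] - c[k])
        j = k + int(np.argmax(rel))
        events.append(EventRecord(sweep,
                                  trace.t_start + k * trace.dt,
                                  None,
                                  trace.t_start + j * trace.dt,
                                  float(y[j] - c[k]),
                                  float(c[k])))
    return criterion, events


def events_to_waves(trace: Trace, events: list[EventRecord], pre_ms: float,
                    post_ms: float) -> tuple[SweepSet, int]:
    """Copy each accepted event into its own sweep.

    Each sweep spans the half-open window [t_cross - pre, t_cross + post)
    with t = 0 at the window start.  Events whose window would run off the
    trace edge are dropped; the count of dropped events is returned.
    """
    n_pre = int(round(pre_ms / trace.dt))
    n_post = int(round(post_ms / trace.dt))
    traces = []
    dropped = 0
    for ev in sorted((e for e in events if e.accepted), key=lambda e: e.t_cross):
        i = trace.index_at(ev.t_cross)
        if i - n_pre < 0 or i + n_post > trace.n:
            dropped += 1
            continue
        traces.append(Trace(trace.samples[i - n_pre:i + n_post].copy(),
                            dt=trace.dt, t_start=0.0, units=trace.units,
                            label=f"Event{len(traces)}"))
    return SweepSet(traces, prefix="Event0"), dropped


def review_set(events: list[EventRecord], index: int, accept: bool,
               reason: str = "") -> tuple[list[EventRecord], int, int]:
    """Accept/reject one event; returns (events, n_accepted, n_rejected)."""
    if not 0 <= index < len(events):
        raise IndexError(f"event index {index} out of range 0..{len(events) - 1}")
    events = list(events)
    events[index] = replace_event(events[index], accepted=accept, reason=reason)
    n_acc = sum(e.accepted for e in events)
    return events, n_acc, len(events) - n_acc


def replace_event(ev: EventRecord, **kw) -> EventRecord:
    d = ev.__dict__ | kw
    return EventRecord(**d)


def template_from_events(sweepset: SweepSet, length_ms: float,
                         baseline_ms: float = 0.2) -> np.ndarray:
    """Average of extracted events, normalized to baseline 0 / peak 1.

    The average is truncated to ``length_ms`` and its first ``baseline_ms``
    is taken as the zero level; a unit-amplitude template for
    :func:`detect_template`.
    """
    from .trace import average
    mean, _ = average(sweepset)
    n = int(round(length_ms / mean.dt))
    y = mean.samples[:n].copy()
    nb = max(int(round(baseline_ms / mean.dt)), 1)
    y -= y[:nb].mean()
    j = int(np.argmax(np.abs(y)))
    if y[j] == 0:
        raise ValueError("event average is flat; cannot build a template")
    # divide by the signed peak so the template peaks at +1; matching it to
    # negative-going data then yields a negative scale and a negative DC
    return y / y[j]
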