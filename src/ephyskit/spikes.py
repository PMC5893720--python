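"""Threshold spike detection and spike-train summaries.

A spike is an upward level crossing of the membrane potential; the detector
re-arms only after the trace falls back below the level, so one action
potential yields one spike.  Crossing times are linearly interpolated to
sub-sample precision (at 20 us sampling the interpolation matters for ISI
statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import SweepSet, Trace, WindowSpec, histogram


@dataclass
class SpikeRaster:
    spike_times: list[np.ndarray]   # per-sweep, ms, strictly increasing
    level: float                    # detection level, mV
    window: WindowSpec

    @property
    def n_sweeps(self) -> int:
        return len(self.spike_times)

    @property
    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.spike_times))


def _detect_one(trace: Trace, level: float, window: WindowSpec) -> np.ndarray:
    idx = trace.window_indices(window)
    if idx.size == 0:
        raise ValueError(f"spike window [{window.xbgn}, {window.xend}] ms is "
                         f"outside the trace")
    y = trace.samples
    i0, i1 = max(idx[0], 1), idx[-1]
    # an upward crossing needs the previous sample strictly below the level,
    # which is exactly the fall-below-level re-arm condition
    i = np.arange(i0, i1 + 1)
    cross = i[(y[i - 1] < level) & (y[i] >= level)]
    frac = (level - y[cross - 1]) / (y[cross] - y[cross - 1])
    return trace.t_start + (cross - 1 + frac) * trace.dt


def detect_spikes(sweepset: SweepSet, level: float,
                  window: WindowSpec) -> SpikeRaster:
    """Detect upward level crossings in every sweep of a set."""
    return SpikeRaster([_detect_one(tr, level, window) for tr in sweepset],
                       level, window)


def mean_rate(raster: SpikeRaster, window: WindowSpec | None = None
              ) -> np.ndarray:
    """Per-sweep mean firing rate (Hz) over the window."""
    win = window or raster.window
    dur_s = (win.xend - win.xbgn) / 1000.0
    if dur_s <= 0:
        raise ValueError("zero-length window")
    return np.array([np.sum((t >= win.xbgn) & (t <= win.xend)) / dur_s
                     for t in raster.spike_times])


def fi_relation(raster: SpikeRaster, amplitudes,
                window: WindowSpec | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """FI relation: (stimulus amplitude, firing rate) pairs sorted by amplitude."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.size != raster.n_sweeps:
        raise ValueError(f"{amplitudes.size} amplitudes for "
                         f"{raster.n_sweeps} sweeps")
    rates = mean_rate(raster, window)
    order = np.argsort(amplitudes)
    return amplitudes[order], rates[order]


def isi_histogram(raster: SpikeRaster, bin_width: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Inter-spike-interval histogram pooled across sweeps (ms bins)."""
    isis = np.concatenate([np.diff(t) for t in raster.spike_times]
                          or [np.array([])])
    return histogram(isis, bin_width)


def psth(raster: SpikeRaster, bin_width: float, t0: float = 0.0
         ) -> tuple[np.ndarray, np.ndarray]:
    """Peristimulus time histogram in spikes/s per sweep.

    Counts are pooled across sweeps relative to ``t0`` and normalized by
    (number of sweeps * bin width), so summing bins * bin width * sweeps
    recovers the total spike count.
    """
    pooled = np.concatenate([t - t0 for t in raster.spike_times]
                            or [np.array([])])
    centers, counts = histogram(pooled, bin_width)
    rate = counts / (raster.n_sweeps * bin_width / 1000.0) if raster.n_sweeps \
        else counts.astype(float)
    return centers, rate


def spikes_to_waves(sweepset: SweepSet, raster: SpikeRaster, pre_ms: float,
                    post_ms: float) -> tuple[SweepSet, int]:
    """Copy each detected spike into its own aligned sweep.

    Each sweep spans [t_spike - pre, t_spike + post); spikes too close to
    the sweep edges are dropped and counted.
    """
    traces = []
    dropped = 0
    for tr, times in zip(sweepset, raster.spike_times):
        n_pre = int(round(pre_ms / tr.dt))
        n_post = int(round(post_ms / tr.dt))
        for ts in times:
            i = tr.index_at(ts)
            if i - n_pre < 0 or i + n_post > tr.n:
                dropped += 1
                continue
            traces.append(Trace(tr.samples[i - n_pre:i + n_post].copy(),
                                dt=tr.dt, t_start=0.0, units=tr.units,
                                label=f"Spike0_{len(traces)}"))
    return SweepSet(traces, prefix="Spike0"), dropped
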