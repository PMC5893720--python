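"""Seeded generators of ground-truth-annotated synthetic recordings.

These emulate the data the analysis stages consume - continuous
voltage-clamp records with embedded EPSCs, current-clamp sweeps with action
potentials, and binomial variance-mean samples - with every generated
feature recorded so detector/fitter output can be scored against truth.
All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import sample_site_amplitudes
from .stats import MPFAPoint, mpfa_stats
from .trace import Trace
from .waveforms import SynExpParams, synexp_eval, synexp_unit_peak


@dataclass
class GroundTruth:
    event_times: np.ndarray
    amplitudes: np.ndarray
    noise_sd: float
    seed: int
    params: dict = field(default_factory=dict)


def synth_event_trace(n_events: int,
                      amp_mean: float = -20.0,
                      amp_sd: float = 0.0,
                      kinetics: SynExpParams | None = None,
                      times: np.ndarray | None = None,
                      min_gap: float = 50.0,
                      noise_sd: float = 2.0,
                      drift_per_s: float = 0.0,
                      duration_ms: float = 2000.0,
                      dt: float = 0.02,
                      seed: int = 0,
                      filtered_noise: bool = False
                      ) -> tuple[Trace, GroundTruth]:
    """Continuous record: baseline 0 + noise (+ drift) + known EPSCs.

    Events use a unit-peak synaptic waveform scaled by per-event amplitudes
    (Gaussian around ``amp_mean``).  Event times are either supplied or
    drawn uniformly with a minimum gap.  ``filtered_noise`` applies a
    single-pole smoothing to the noise for a colored-noise variant.
    """
    rng = np.random.default_rng(seed)
    kin = kinetics or SynExpParams()
    unit, t_peak = synexp_unit_peak(kin)
    n = int(round(duration_ms / dt))
    t = dt * np.arange(n)

    if times is None:
        lo, hi = 2.0 * min_gap, duration_ms - 2.0 * min_gap
        free = (hi - lo) - max(n_events - 1, 0) * min_gap
        if n_events > 0 and free < 0:
            raise ValueError("event density too high for the requested gap")
        # uniform order statistics in the free space, then re-insert the gaps
        times = lo + np.sort(rng.uniform(0.0, free, size=n_events)) \
            + min_gap * np.arange(n_events)
    else:
        times = np.sort(np.asarray(times, dtype=float))

    amps = amp_mean + amp_sd * rng.standard_normal(n_events) if n_events \
        else np.array([])
    y = np.zeros(n)
    for tk, a in zip(times, amps):
        i0 = max(int((tk - kin.t0) / dt) - 2, 0)
        i1 = min(int((tk + 12.0 * max(kin.tau_d1, kin.tau_d2)) / dt), n)
        y[i0:i1] += a * synexp_eval(unit, t[i0:i1] - tk)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=n)
        if filtered_noise:
            alpha = 0.5
            for i in range(1, n):
                noise[i] = alpha * noise[i - 1] + (1 - alpha) * noise[i]
            noise *= noise_sd / noise.std()
        y += noise
    if drift_per_s:
        y += drift_per_s * t / 1000.0
    truth = GroundTruth(times, amps, noise_sd, seed,
                        {"kinetics": unit, "peak_delay": t_peak - unit.t0})
    return Trace(y, dt=dt, units="pA", label="C_Record"), truth


def default_ap_template(dt: float = 0.02) -> np.ndarray:
    """A simple ~2 ms action-potential shape peaking at +30 mV (relative)."""
    t = dt * np.arange(int(round(3.0 / dt)))
    rise = np.exp(-((t - 0.8) / 0.15) ** 2)
    ahp = -0.15 * np.exp(-((t - 1.6) / 0.5) ** 2)
    return 100.0 * (rise + ahp)  # mV above rest; rest -70 -> peak +30


def synth_vm_trace(spike_times,
                   ap_template: np.ndarray | None = None,
                   resting_mv: float = -70.0,
                   noise_sd: float = 0.5,
                   duration_ms: float = 1000.0,
                   dt: float = 0.02,
                   seed: int = 0) -> tuple[Trace, GroundTruth]:
    """Current-clamp sweep: resting potential + inserted APs + noise."""
    rng = np.random.default_rng(seed)
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    tmpl = ap_template if ap_template is not None else default_ap_template(dt)
    if resting_mv + tmpl.max() <= 0.0:
        raise ValueError("AP template must cross 0 mV above rest")
    width_ms = tmpl.size * dt
    if spike_times.size > 1 and np.diff(spike_times).min() < width_ms:
        raise ValueError("overlapping action potentials")
    n = int(round(duration_ms / dt))
    y = np.full(n, resting_mv)
    for tk in spike_times:
        i0 = int(round(tk / dt))
        i1 = min(i0 + tmpl.size, n)
        y[i0:i1] += tmpl[:i1 - i0]
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    truth = GroundTruth(spike_times, np.full(spike_times.size, tmpl.max()),
                        noise_sd, seed, {"resting_mv": resting_mv})
    return Trace(y, dt=dt, units="mV", label="Sim_Vmem"), truth


def synth_mpfa_dataset(n_sites: int = 5,
                       p_values=(0.1, 0.3, 0.5, 0.8, 1.0),
                       q_p: float = -20.0,
                       cv_qi: float = 0.0,
                       cv_qii: float = 0.0,
                       n_per_condition: int = 150,
                       background_sd: float = 1.0,
                       precision: float = 0.01,
                       seed: int = 0
                       ) -> tuple[list[MPFAPoint], dict]:
    """Direct binomial variance-mean samples, bypassing waveform kinetics.

    Per trial the peak measure is the sum over released sites of the site
    amplitude jittered by cv_qi, plus Gaussian background noise; fast
    ground truth for variance-mean fitting tests.
    """
    rng = np.random.default_rng(seed)
    sites = sample_site_amplitudes(n_sites, q_p, cv_qii, precision, rng) \
        if cv_qii > 0 else None
    amps = sites.amplitudes if sites is not None \
        else np.full(n_sites, q_p, dtype=float)
    points = []
    for p in p_values:
        release = rng.random((n_per_condition, n_sites)) < p
        jitter = 1.0 + cv_qi * rng.standard_normal((n_per_condition, n_sites))
        peaks = (release * amps * jitter).sum(axis=1)
        peaks = peaks + rng.normal(0.0, background_sd, size=n_per_condition)
        bgs = rng.normal(0.0, background_sd, size=n_per_condition)
        points.append(mpfa_stats(peaks, bgs, label=f"P={p}"))
    truth = {"n_sites": n_sites, "q_p": q_p, "cv_qi": cv_qi,
             "cv_qii": cv_qii, "site_amplitudes": amps, "seed": seed}
    return points, truth
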