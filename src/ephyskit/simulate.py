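"""Generative models: stochastic multinomial quantal release, the R*P
short-term-plasticity model, and a conductance-driven integrate-and-fire
neuron.

Quantal release model
---------------------
A synapse with N independent release sites.  On each trial, site i releases
with probability P (a uniform draw on [0, 1] compared against P); a success
contributes its site amplitude Q_p,i jittered by a within-site amplitude CV
(CV_QS) and shifted by a Gaussian latency (SD sigma_QL), riding on a
unit-peak synaptic waveform.  Site amplitudes are drawn once per simulation
so that their sample mean and CV match the targets (Q_p, CV_QII) to a
stated precision; the latency jitter additionally induces an amplitude CV
(CV_QL) through the peak-measurement window, so the composite within-site
CV is CV_QI = sqrt(CV_QS^2 + CV_QL^2).

R*P short-term plasticity
-------------------------
Event-driven depression/facilitation: the response to an event is
G_max * R * P; immediately after, R -> R - R*P (resource depletion) and
P -> P + Delta*(1 - P) (facilitation); between events both relax
exponentially to R_inf, P_inf with time constants tau_R, tau_P.

Integrate-and-fire
------------------
C_m dV/dt = g_leak (E_leak - V) + sum_i g_i(t) (E_i - V) + I_inj(t),
integrated by exponential Euler (exact for conductances held constant over
a step), with threshold/peak/reset spiking and an absolute refractory
period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stats import MPFAPoint, mpfa_stats, peak_window, window_measure
from .trace import SweepSet, Trace, WindowSpec
from .waveforms import SynExpParams, synexp_eval, synexp_unit_peak


def composite_cv_qi(cv_qs: float, cv_ql: float) -> float:
    """Composite within-site quantal CV: sqrt(CV_QS^2 + CV_QL^2)."""
    return math.hypot(cv_qs, cv_ql)


# ---------------------------------------------------------------------------
# quantal release
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantalSimConfig:
    n_sites: int = 5
    p_release: float = 0.5
    q_p: float = -20.0            # quantal peak amplitude, pA
    cv_qs: float = 0.3            # within-site amplitude CV
    sigma_ql: float = 0.08        # latency SD, ms
    cv_qii: float = 0.3           # across-site CV of Q_p
    precision: float = 0.01       # relative tolerance for the site-amplitude set
    n_trials: int = 150
    waveform: SynExpParams = field(default_factory=SynExpParams)
    stim_time: float = 2.0        # ms
    dt: float = 0.01              # ms
    sweep_ms: float = 12.0
    noise_sd: float = 0.0         # pA
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_release <= 1.0:
            raise ValueError("p_release must be in [0, 1]")
        if min(self.cv_qs, self.cv_qii) < 0 or self.sigma_ql < 0:
            raise ValueError("CVs and sigma_ql must be >= 0")
        if not self.precision > 0:
            raise ValueError("precision must be > 0")


@dataclass
class SiteAmplitudeSet:
    amplitudes: np.ndarray
    mean: float
    cv: float
    iterations: int


def sample_site_amplitudes(n_sites: int, q_p: float, cv_qii: float,
                           precision: float,
                           rng: np.random.Generator,
                           max_iter: int = 1_000_000) -> SiteAmplitudeSet:
    """Draw per-site quantal amplitudes whose mean and CV hit their targets.

    Sets of ``n_sites`` values are drawn from Gaussian(q_p, |q_p|*cv_qii)
    until both |mean/q_p - 1| and |CV/cv_qii - 1| fall within ``precision``.
    Values whose sign differs from q_p are resampled.  With cv_qii = 0 all
    sites are exactly q_p.
    """
    if cv_qii == 0:
        amps = np.full(n_sites, q_p, dtype=float)
        return SiteAmplitudeSet(amps, q_p, 0.0, 1)
    if n_sites < 2:
        raise ValueError("need n_sites >= 2 when cv_qii > 0")
    sd = abs(q_p) * cv_qii
    best = None
    best_err = np.inf
    for it in range(1, max_iter + 1):
        amps = rng.normal(q_p, sd, size=n_sites)
        bad = np.sign(amps) != np.sign(q_p)
        while bad.any():
            amps[bad] = rng.normal(q_p, sd, size=int(bad.sum()))
            bad = np.sign(amps) != np.sign(q_p)
        mean = amps.mean()
        cv = amps.std(ddof=1) / abs(mean)
        err = max(abs(mean / q_p - 1.0), abs(cv / cv_qii - 1.0))
        if err < best_err:
            best, best_err = (amps, mean, cv, it), err
        if abs(mean / q_p - 1.0) <= precision and \
                abs(cv / cv_qii - 1.0) <= precision:
            return SiteAmplitudeSet(amps, float(mean), float(cv), it)
    amps, mean, cv, it = best
    raise RuntimeError(
        f"site-amplitude sampling did not reach precision {precision} in "
        f"{max_iter} iterations; closest achieved mean={mean:g}, cv={cv:g}")


def simulate_quantal(config: QuantalSimConfig,
                     rng: np.random.Generator | None = None,
                     site_set: SiteAmplitudeSet | None = None
                     ) -> tuple[SweepSet, pd.DataFrame, SiteAmplitudeSet]:
    """Monte Carlo simulation of multinomial quantal release.

    Returns the simulated EPSC sweeps, a ground-truth release table
    (trial, site, amplitude, latency) and the site-amplitude set used.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if site_set is None:
        site_set = sample_site_amplitudes(config.n_sites, config.q_p,
                                          config.cv_qii, config.precision, rng)
    unit, _ = synexp_unit_peak(config.waveform)
    n = int(round(config.sweep_ms / config.dt))
    t = config.dt * np.arange(n)

    release = rng.random((config.n_trials, config.n_sites)) < config.p_release
    amp_jit = rng.normal(0.0, config.cv_qs,
                         size=(config.n_trials, config.n_sites))
    latency = rng.normal(0.0, config.sigma_ql,
                         size=(config.n_trials, config.n_sites))

    traces = []
    rows = []
    for k in range(config.n_trials):
        y = np.zeros(n)
        for i in np.nonzero(release[k])[0]:
            amp = site_set.amplitudes[i] * (1.0 + amp_jit[k, i])
            lat = latency[k, i]
            y += amp * synexp_eval(unit, t - config.stim_time - lat)
            rows.append((k, i, amp, lat))
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, size=n)
        traces.append(Trace(y, dt=config.dt, units="pA", label=f"EPSC{k}"))
    table = pd.DataFrame(rows, columns=["trial", "site", "amplitude",
                                        "latency"])
    return SweepSet(traces, prefix="EPSC"), table, site_set


def mpfa_from_sim(base_config: QuantalSimConfig,
                  p_values=(0.1, 0.3, 0.5, 0.8, 1.0),
                  cv_qi: float | None = None,
                  seed: int | None = None,
                  peak_width: float = 0.1):
    """Full simulated MPFA protocol: simulate, measure, summarize, fit.

    One site-amplitude set and one simulation per release probability
    (fresh seeds per condition, shared waveform and site statistics).
    Per-trial peaks are the mean current in a ``peak_width`` window centered
    on the peak of the grand average across all conditions; the background
    measure uses a window of the same width before the stimulus.  The
    variance-mean relation is fitted with CV_QI fixed at
    sqrt(CV_QS^2 + CV_QL^2) (CV_QL = 0.2 for the standard latency SD) and
    CV_QII fixed at its configured value.

    Returns (points, FitResult, per-condition sweep sets).
    """
    from .fitting import VarianceMeanModel

    seed = base_config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    site_rng = np.random.default_rng(ss.spawn(1)[0])
    site_set = sample_site_amplitudes(base_config.n_sites, base_config.q_p,
                                      base_config.cv_qii,
                                      base_config.precision, site_rng)

    condition_sets = []
    for p, child in zip(p_values, ss.spawn(len(p_values))):
        cfg = replace(base_config, p_release=p)
        sweeps, _, _ = simulate_quantal(cfg, np.random.default_rng(child),
                                        site_set=site_set)
        condition_sets.append(sweeps)

    # one shared measurement window from the grand average of all trials
    pooled = SweepSet([tr for s in condition_sets for tr in s], prefix="all")
    polarity = "neg" if base_config.q_p < 0 else "pos"
    search = WindowSpec(base_config.stim_time,
                        min(base_config.stim_time + 5.0,
                            base_config.sweep_ms - base_config.dt))
    pw = peak_window(pooled, search, width=peak_width, polarity=polarity)
    bg_end = base_config.stim_time - 2.0 * base_config.sigma_ql - 3.0 * base_config.dt
    bw = WindowSpec(bg_end - peak_width, bg_end)

    points: list[MPFAPoint] = []
    for p, sweeps in zip(p_values, condition_sets):
        peaks = window_measure(sweeps, "avg", pw).values
        bgs = window_measure(sweeps, "avg", bw).values
        points.append(mpfa_stats(peaks, bgs, label=f"P={p}"))

    if cv_qi is None:
        cv_qi = composite_cv_qi(base_config.cv_qs,
                                0.2 if base_config.sigma_ql else 0.0)
    model = VarianceMeanModel(points, cv_qi=cv_qi, cv_qii=base_config.cv_qii)
    return points, model.fit(), condition_sets


# ---------------------------------------------------------------------------
# R*P short-term plasticity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RPParams:
    r_inf: float = 1.0
    p_inf: float = 0.14
    delta: float = 0.0            # facilitation increment in [0, 1]
    tau_r: float = 131.0          # ms
    tau_p: float = 100.0          # ms
    g_max: SynExpParams = field(default_factory=SynExpParams)
    label: str = "direct"

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("Delta must be in [0, 1]")
        if not (self.tau_r > 0 and self.tau_p > 0):
            raise ValueError("tau_R and tau_P must be > 0")
        if not 0.0 <= self.p_inf <= 1.0:
            raise ValueError("P_inf must be in [0, 1]")


def rp_event_values(event_times, params: RPParams
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact event-driven evolution of (R, P, R*P) at each event time.

    Starts at (R_inf, P_inf); at each event records the pre-update values,
    then applies R -> R - R*P and P -> P + Delta*(1 - P); between events
    both relax with closed-form exponentials.
    """
    times = np.asarray(event_times, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("event times must be strictly increasing")
    r, p = params.r_inf, params.p_inf
    t_prev = None
    rs = np.empty(times.size)
    ps = np.empty(times.size)
    for k, tk in enumerate(times):
        if t_prev is not None:
            dtk = tk - t_prev
            r = params.r_inf + (r - params.r_inf) * math.exp(-dtk / params.tau_r)
            p = params.p_inf + (p - params.p_inf) * math.exp(-dtk / params.tau_p)
        rs[k] = r
        ps[k] = p
        r = r - r * p
        p = p + params.delta * (1.0 - p)
        t_prev = tk
    return rs, ps, rs * ps


def rp_regular_train_fixed_point(interval: float, params: RPParams) -> float:
    """Closed-form steady-state R for a regular train with Delta = 0.

    R* = (1 - e) / (1 - (1 - P_inf) e) with e = exp(-T/tau_R); the oracle
    for the iterated event-driven update.
    """
    e = math.exp(-interval / params.tau_r)
    return (1.0 - e) / (1.0 - (1.0 - params.p_inf) * e)


def stp_conductance_train(event_trains, direct: RPParams,
                          spillover: RPParams | None, dt: float,
                          length_ms: float) -> Trace:
    """Sum of plasticity-scaled conductance waveforms over input trains.

    Each input train drives its own R*P state (independently for the direct
    and spillover components); every event adds (R*P at the event) times the
    component's unit G_max waveform at the event time.  All inputs and
    components sum into one conductance trace (nS).
    """
    if isinstance(event_trains, np.ndarray) or (
            event_trains and np.isscalar(event_trains[0])):
        event_trains = [np.asarray(event_trains, dtype=float)]
    n = int(round(length_ms / dt))
    t = dt * np.arange(n)
    total = np.zeros(n)
    components = [direct] + ([spillover] if spillover is not None else [])
    for comp in components:
        for train in event_trains:
            train = np.asarray(train, dtype=float)
            _, _, rp = rp_event_values(train, comp)
            for tk, scale in zip(train, rp):
                total += scale * synexp_eval(comp.g_max, t - tk)
    return Trace(total, dt=dt, units="nS", label="G_train")


# ---------------------------------------------------------------------------
# integrate-and-fire
# ---------------------------------------------------------------------------

@dataclass
class IAFParams:
    c_m: float = 3.0              # pF
    g_leak: float = 1.0           # nS
    e_leak: float = -75.0         # mV
    v_thresh: float = -40.0       # mV
    v_peak: float = 20.0          # mV (cosmetic, one sample)
    v_reset: float = -65.0        # mV
    t_refrac: float = 2.0         # ms
    synapses: list[tuple[Trace, float]] = field(default_factory=list)
    i_inj: Trace | None = None    # pA
    dt: float = 0.02              # ms (used when no input traces are given)
    duration_ms: float = 100.0
    v_init: float | None = None

    def __post_init__(self) -> None:
        if not self.v_reset < self.v_thresh < self.v_peak:
            raise ValueError("need V_reset < V_thresh < V_peak")
        if not (self.c_m > 0 and self.g_leak > 0):
            raise ValueError("C_m and g_leak must be > 0")


def iaf_simulate(params: IAFParams) -> tuple[Trace, np.ndarray]:
    """Integrate the conductance-driven leaky integrate-and-fire neuron.

    Exponential-Euler update per step (exact for inputs held constant over
    the step).  Units: pF, nS, mV, pA, ms are mutually consistent
    (tau = C/g in ms, I/g in mV).  Returns the voltage trace and spike
    times; the spike sample is drawn at V_peak, then the membrane is held
    at V_reset for the refractory period.
    """
    inputs = [g for g, _ in params.synapses]
    if params.i_inj is not None:
        inputs.append(params.i_inj)
    if inputs:
        dt = inputs[0].dt
        n = inputs[0].n
        for tr in inputs:
            if abs(tr.dt - dt) > 1e-12 or tr.n != n:
                raise ValueError("all input traces must share dt and length")
    else:
        dt = params.dt
        n = int(round(params.duration_ms / params.dt))

    g_syn = np.zeros((len(params.synapses), n))
    e_syn = np.zeros(len(params.synapses))
    for j, (g, e_rev) in enumerate(params.synapses):
        g_syn[j] = g.samples
        e_syn[j] = e_rev
    i_inj = params.i_inj.samples if params.i_inj is not None else np.zeros(n)

    g_tot = params.g_leak + g_syn.sum(axis=0)
    drive = params.g_leak * params.e_leak + (g_syn * e_syn[:, None]).sum(axis=0) \
        + i_inj
    # represent each step [k-1, k] by its endpoint-average conductance/drive:
    # still exponential Euler, but second-order accurate for smooth inputs
    if n > 1:
        g_tot = 0.5 * (g_tot[:-1] + g_tot[1:])
        drive = 0.5 * (drive[:-1] + drive[1:])
    v_inf = drive / g_tot
    decay = np.exp(-g_tot * dt / params.c_m)

    v = np.empty(n)
    v[0] = params.e_leak if params.v_init is None else params.v_init
    refrac_steps = int(round(params.t_refrac / dt))
    spikes = []
    hold_until = -1
    vk = v[0]
    for k in range(1, n):
        if k <= hold_until:
            v[k] = params.v_reset
            vk = params.v_reset
            continue
        v_prev = vk
        vk = v_inf[k - 1] + (vk - v_inf[k - 1]) * decay[k - 1]
        if not np.isfinite(vk):
            raise FloatingPointError(f"non-finite membrane potential at step {k}")
        if vk >= params.v_thresh:
            # sub-sample crossing time by linear interpolation over the step
            frac = (params.v_thresh - v_prev) / (vk - v_prev) \
                if vk > v_prev else 1.0
            spikes.append((k - 1 + frac) * dt)
            v[k] = params.v_peak
            vk = params.v_reset
            hold_until = k + refrac_steps
        else:
            v[k] = vk
    return Trace(v, dt=dt, units="mV", label="Sim_Vmem"), np.array(spikes)
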