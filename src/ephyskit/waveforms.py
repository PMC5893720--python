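"""Deterministic stimulus and synaptic waveform construction.

The synaptic waveform family used throughout the package is the
multi-exponential "SynExp" function

    Y(t) = [1 - exp(-(t - t0)/tau_r)]^n
           * [a_d1 exp(-(t - t0)/tau_d1) + a_d2 exp(-(t - t0)/tau_d2)]

for t >= t0 and Y = 0 before onset.  It describes an EPSC/EPSG with a
sigmoid-like rise (tau_r, exponent n) and a double-exponential decay.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .trace import SweepSet, Trace


@dataclass(frozen=True)
class SynExpParams:
    """Parameters of the SynExp synaptic waveform (times in ms)."""

    t0: float = 0.0
    tau_r: float = 0.116
    n: float = 1.0
    a_d1: float = 86.72
    tau_d1: float = 0.36
    a_d2: float = 13.28
    tau_d2: float = 2.034

    def __post_init__(self) -> None:
        if not (self.tau_r > 0 and self.tau_d1 > 0):
            raise ValueError("tau_r and tau_d1 must be > 0")
        if self.a_d2 != 0 and not self.tau_d2 > 0:
            raise ValueError("tau_d2 must be > 0 when a_d2 != 0")
        if self.n < 1:
            raise ValueError("rise exponent n must be >= 1")


def synexp_eval(params: SynExpParams, t) -> np.ndarray:
    """Evaluate the SynExp waveform at times ``t`` (ms); 0 before onset."""
    t = np.asarray(t, dtype=float)
    s = t - params.t0
    out = np.zeros_like(s)
    m = s > 0
    sm = s[m]
    rise = (1.0 - np.exp(-sm / params.tau_r)) ** params.n
    decay = params.a_d1 * np.exp(-sm / params.tau_d1)
    if params.a_d2 != 0:
        decay = decay + params.a_d2 * np.exp(-sm / params.tau_d2)
    out[m] = rise * decay
    return out


def synexp_peak_time(params: SynExpParams, tol: float = 1e-6) -> float:
    """Time of the waveform's absolute-value peak (golden-section search)."""
    horizon = params.t0 + 10.0 * max(params.tau_d1,
                                     params.tau_d2 if params.a_d2 else 0.0,
                                     params.tau_r)
    res = minimize_scalar(lambda t: -abs(float(synexp_eval(params, [t])[0])),
                          bounds=(params.t0, horizon), method="bounded",
                          options={"xatol": tol})
    return float(res.x)


def synexp_unit_peak(params: SynExpParams, tol: float = 1e-6
                     ) -> tuple[SynExpParams, float]:
    """Rescale a_d1/a_d2 by a common factor so that max|Y| = 1.

    Returns the rescaled parameters and the peak time.  Needed so per-site
    quantal amplitudes can scale a unit-peak waveform.
    """
    t_peak = synexp_peak_time(params, tol)
    peak = float(synexp_eval(params, [t_peak])[0])
    if peak == 0.0:
        raise ValueError("degenerate waveform: peak is zero")
    scale = 1.0 / abs(peak)
    return replace(params, a_d1=params.a_d1 * scale,
                   a_d2=params.a_d2 * scale), t_peak


@dataclass(frozen=True)
class PulseSpec:
    """Square-pulse stimulus: sweep k gets amplitude amp + k*delta."""

    shape: str = "square"
    amp: float = 0.0
    delta: float = 0.0
    onset: float = 0.0
    width: float = 1.0
    applies_to: object = "all"  # "all" or list of sweep indices

    def __post_init__(self) -> None:
        if self.shape != "square":
            raise ValueError(f"unsupported shape {self.shape!r}")
        if not self.width > 0:
            raise ValueError("width must be > 0")


def parse_pulse_config(text: str) -> PulseSpec:
    """Parse a semicolon-delimited pulse configuration string.

    Accepts the notation used by acquisition protocols, e.g.
    ``"wave = all;pulse = square;amp = 0,delta = 5;onset = 50;width = 1,000;"``.
    Thousands separators inside numbers are stripped; ``delta`` may ride in
    the same field as ``amp``.
    """
    fields: dict[str, str] = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        # a chunk may hold "amp = 0,delta = 5": split on commas that precede a key
        parts = [chunk]
        if "=" in chunk:
            import re
            parts = re.split(r",(?=\s*[A-Za-z])", chunk)
        for part in parts:
            if "=" not in part:
                raise ValueError(f"cannot parse pulse token {part!r}")
            key, _, val = part.partition("=")
            fields[key.strip().lower()] = val.strip()

    def num(key: str, default: float | None = None) -> float:
        if key not in fields:
            if default is None:
                raise ValueError(f"missing pulse key {key!r}")
            return default
        return float(fields[key].replace(",", ""))

    known = {"wave", "pulse", "amp", "delta", "onset", "width"}
    unknown = set(fields) - known
    if unknown:
        raise ValueError(f"unknown pulse key(s): {sorted(unknown)}")
    shape = fields.get("pulse", "square")
    if shape != "square":
        raise ValueError(f"unsupported shape {shape!r}")
    wave = fields.get("wave", "all")
    applies_to = "all" if wave == "all" else [int(w) for w in wave.split(",")]
    return PulseSpec(shape=shape, amp=num("amp"), delta=num("delta", 0.0),
                     onset=num("onset", 0.0), width=num("width"),
                     applies_to=applies_to)


def make_pulse_sweeps(spec: PulseSpec, n_sweeps: int, dt: float,
                      length_ms: float, units: str = "pA") -> SweepSet:
    """Generate square-pulse command sweeps; sweep k has amp + k*delta."""
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if spec.onset + spec.width > length_ms:
        raise ValueError(f"pulse [{spec.onset}, {spec.onset + spec.width}] ms "
                         f"exceeds sweep length {length_ms} ms")
    n = int(round(length_ms / dt))
    t = dt * np.arange(n)
    on = (t >= spec.onset) & (t < spec.onset + spec.width)
    which = range(n_sweeps) if spec.applies_to == "all" else spec.applies_to
    traces = []
    for k in range(n_sweeps):
        y = np.zeros(n)
        if k in which or spec.applies_to == "all":
            y[on] = spec.amp + k * spec.delta
        traces.append(Trace(y, dt=dt, units=units, label=f"pulse{k}"))
    return SweepSet(traces, prefix="Pulse")


@dataclass(frozen=True)
class TrainSpec:
    """Poisson event train with a refractory dead time between events."""

    rate: float          # mean rate f, Hz
    t_max: float         # ms
    dead_time: float = 1.0  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("rate must be > 0")
        if self.dead_time < 0:
            raise ValueError("dead time must be >= 0")
        if self.rate * self.dead_time / 1000.0 >= 1.0:
            raise ValueError("infeasible rate: f * dead_time >= 1")


def poisson_times(spec: TrainSpec, rng: np.random.Generator | None = None
                  ) -> np.ndarray:
    """Event times (ms) of a dead-time-corrected Poisson train.

    Intervals are dead_time + Exp(1/lambda') with
    lambda' = f / (1 - f*dead_time/1000), so the asymptotic mean rate equals
    the requested f despite the refractory gap.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lam = spec.rate / (1.0 - spec.rate * spec.dead_time / 1000.0)  # Hz
    mean_gap_ms = 1000.0 / lam
    # draw in blocks until we pass t_max
    times = []
    t = 0.0
    while t <= spec.t_max:
        gaps = spec.dead_time + rng.exponential(mean_gap_ms, size=256)
        for g in gaps:
            t += g
            if t > spec.t_max:
                break
            times.append(t)
    return np.array(times)
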