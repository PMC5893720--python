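"""Sweep/trace containers and the basic wave transforms.

A :class:`Trace` is one uniformly sampled record (a "sweep" or "wave"):
current in pA, voltage in mV or conductance in nS, with the sample interval
``dt`` in milliseconds.  Sample ``i`` sits at ``t_start + i*dt`` (0-based) and
analysis windows are closed intervals ``[xbgn, xend]`` on sample times.

Every transform returns a new object and appends exactly one provenance note,
so a trace carries an append-only record of what was done to it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d


@dataclass(frozen=True)
class ProvenanceNote:
    timestamp: str
    operation: str
    params: str

    @classmethod
    def now(cls, operation: str, params: str = "") -> "ProvenanceNote":
        return cls(datetime.now(timezone.utc).isoformat(), operation, params)


@dataclass(frozen=True)
class WindowSpec:
    """Closed time window [xbgn, xend] in ms."""

    xbgn: float
    xend: float

    def __post_init__(self) -> None:
        if not self.xbgn < self.xend:
            raise ValueError(f"window requires xbgn < xend, got [{self.xbgn}, {self.xend}]")


@dataclass
class Trace:
    samples: np.ndarray
    dt: float
    t_start: float = 0.0
    units: str = "pA"
    label: str = ""
    notes: list[ProvenanceNote] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a 1-D array of length >= 1")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def t_end(self) -> float:
        return self.t_start + (self.n - 1) * self.dt

    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n)

    def index_at(self, t: float) -> int:
        """Nearest sample index for time t (clipped to the trace)."""
        i = int(round((t - self.t_start) / self.dt))
        return min(max(i, 0), self.n - 1)

    def window_indices(self, window: WindowSpec) -> np.ndarray:
        """Indices of samples with time in the closed window."""
        t = self.times()
        eps = 1e-9 * self.dt
        idx = np.nonzero((t >= window.xbgn - eps) & (t <= window.xend + eps))[0]
        return idx

    def _derive(self, samples: np.ndarray, op: str, params: str = "",
                **changes) -> "Trace":
        new = replace(self, samples=np.asarray(samples, dtype=float),
                      notes=list(self.notes) + [ProvenanceNote.now(op, params)],
                      **changes)
        return new


@dataclass
class SweepSet:
    """Ordered traces sharing a wave prefix and channel.

    ``sets`` maps a set name to a boolean membership array, one flag per
    sweep.  The special set ``SetX`` marks sweeps excluded from every
    selection (e.g. recordings corrupted by noise).  ``groups`` optionally
    assigns each sweep to a disjoint group, by default in a repeating cycle
    as used for protocols acquired in a repeating sequence.
    """

    traces: list[Trace]
    prefix: str = "Record"
    channel: str = "A"
    sets: dict[str, np.ndarray] = field(default_factory=dict)
    groups: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {k: np.asarray(v, dtype=bool) for k, v in self.sets.items()}
        for name, mem in self.sets.items():
            if mem.size != len(self.traces):
                raise ValueError(
                    f"set {name!r} has {mem.size} flags for {len(self.traces)} sweeps")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def __getitem__(self, i: int) -> Trace:
        return self.traces[i]

    def define_set(self, name: str, membership: Iterable[bool]) -> None:
        mem = np.asarray(list(membership), dtype=bool)
        if mem.size != len(self.traces):
            raise ValueError(f"membership length {mem.size} != {len(self.traces)} sweeps")
        self.sets[name] = mem

    def assign_groups_cyclic(self, n_groups: int) -> None:
        self.groups = {i: i % n_groups for i in range(len(self.traces))}

    # -- selection ------------------------------------------------------
    def select(self, set_expr: str = "All") -> "SweepSet":
        """Return a view of the sweeps matching a set-algebra expression.

        The expression may combine defined set names with OR/AND/NOT and
        parentheses (e.g. ``"Fast OR Fast2"``); ``"All"`` selects every
        sweep.  SetX members are always excluded.
        """
        mask = _eval_set_expr(set_expr, self)
        if "SetX" in self.sets:
            mask = mask & ~self.sets["SetX"]
        idx = np.nonzero(mask)[0]
        return self.subset(idx)

    def subset(self, indices: Sequence[int]) -> "SweepSet":
        idx = list(indices)
        sets = {k: v[idx] for k, v in self.sets.items()}
        groups = {j: self.groups[i] for j, i in enumerate(idx) if i in self.groups}
        return SweepSet([self.traces[i] for i in idx], self.prefix, self.channel,
                        sets, groups)


_TOKEN = re.compile(r"\s*(\(|\)|OR|AND|NOT|[A-Za-z_]\w*)\s*")


def _eval_set_expr(expr: str, ss: SweepSet) -> np.ndarray:
    tokens: list[str] = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if not m:
            raise ValueError(f"cannot parse set expression at {expr[pos:]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    out = _parse_or(tokens, ss)
    if tokens:
        raise ValueError(f"trailing tokens in set expression: {tokens}")
    return out


def _parse_or(tokens: list[str], ss: SweepSet) -> np.ndarray:
    left = _parse_and(tokens, ss)
    while tokens and tokens[0] == "OR":
        tokens.pop(0)
        left = left | _parse_and(tokens, ss)
    return left


def _parse_and(tokens: list[str], ss: SweepSet) -> np.ndarray:
    left = _parse_unary(tokens, ss)
    while tokens and tokens[0] == "AND":
        tokens.pop(0)
        left = left & _parse_unary(tokens, ss)
    return left


def _parse_unary(tokens: list[str], ss: SweepSet) -> np.ndarray:
    if not tokens:
        raise ValueError("unexpected end of set expression")
    tok = tokens.pop(0)
    if tok == "NOT":
        return ~_parse_unary(tokens, ss)
    if tok == "(":
        val = _parse_or(tokens, ss)
        if not tokens or tokens.pop(0) != ")":
            raise ValueError("unbalanced parentheses in set expression")
        return val
    if tok == "All":
        return np.ones(len(ss.traces), dtype=bool)
    if tok in ss.sets:
        return ss.sets[tok].copy()
    raise ValueError(f"unknown set name {tok!r}")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def baseline_subtract(trace: Trace, window: WindowSpec) -> Trace:
    """Subtract the mean over a baseline window from the whole trace."""
    idx = trace.window_indices(window)
    if idx.size == 0:
        raise ValueError(f"baseline window [{window.xbgn}, {window.xend}] ms does "
                         f"not intersect trace [{trace.t_start}, {trace.t_end}] ms")
    base = float(trace.samples[idx].mean())
    return trace._derive(trace.samples - base, "baseline_subtract",
                         f"window=[{window.xbgn},{window.xend}] mean={base:g}")


def smooth_binomial(trace: Trace, n_passes: int) -> Trace:
    """Binomial smoothing: n passes of the (1, 2, 1)/4 kernel.

    Edges are handled by reflection, so length and DC level are preserved.
    """
    if n_passes < 0:
        raise ValueError("n_passes must be >= 0")
    y = trace.samples.copy()
    k = np.array([0.25, 0.5, 0.25])
    for _ in range(n_passes):
        padded = np.concatenate([y[1:2], y, y[-2:-1]])
        y = np.convolve(padded, k, mode="valid")
    return trace._derive(y, "smooth_binomial", f"n_passes={n_passes}")


def lowpass(trace: Trace, f_c: float) -> Trace:
    """Zero-phase Gaussian low-pass filter with -3 dB point at ``f_c`` (kHz)."""
    nyquist = 0.5 / trace.dt  # kHz, since dt is in ms
    if not 0 < f_c < nyquist:
        raise ValueError(f"f_c must be in (0, {nyquist:g}) kHz, got {f_c}")
    # amplitude response exp(-(2 pi f)^2 sigma_t^2 / 2) = 1/sqrt(2) at f_c
    sigma_t = np.sqrt(np.log(2.0)) / (2.0 * np.pi * f_c)  # ms
    y = gaussian_filter1d(trace.samples, sigma=sigma_t / trace.dt, mode="reflect")
    return trace._derive(y, "lowpass", f"f_c={f_c} kHz")


def align(sweepset: SweepSet, offsets: Sequence[float]) -> SweepSet:
    """Shift each sweep's time axis so its reference time lands at zero.

    ``offsets`` gives the reference time of each sweep (e.g. a fitted onset
    t0); the sweep's ``t_start`` is shifted by ``-offset``.  Samples are
    untouched.
    """
    offsets = np.asarray(list(offsets), dtype=float)
    if offsets.size != len(sweepset):
        raise ValueError(f"{offsets.size} offsets for {len(sweepset)} sweeps")
    traces = [tr._derive(tr.samples, "align", f"offset={off:g}",
                         t_start=tr.t_start - float(off))
              for tr, off in zip(sweepset, offsets)]
    return replace(sweepset, traces=traces)


def interpolate_common(sweepset: SweepSet, dt_target: float) -> SweepSet:
    """Linearly resample all sweeps onto one grid over their common time span."""
    if not dt_target > 0:
        raise ValueError("dt_target must be > 0")
    t0 = max(tr.t_start for tr in sweepset)
    t1 = min(tr.t_end for tr in sweepset)
    if t1 < t0:
        raise ValueError("sweeps have no common time range to interpolate")
    n = int(np.floor((t1 - t0) / dt_target)) + 1
    grid = t0 + dt_target * np.arange(n)
    traces = [tr._derive(np.interp(grid, tr.times(), tr.samples),
                         "interpolate_common", f"dt={dt_target}",
                         dt=dt_target, t_start=t0)
              for tr in sweepset]
    return replace(sweepset, traces=traces)


def _check_common_grid(sweepset: SweepSet) -> None:
    tr0 = sweepset[0]
    for tr in sweepset:
        if tr.n != tr0.n or abs(tr.dt - tr0.dt) > 1e-12 or \
                abs(tr.t_start - tr0.t_start) > 1e-9 * tr0.dt:
            raise ValueError("sweeps are not on a common grid; "
                             "run interpolate_common first")


def average(sweepset: SweepSet) -> tuple[Trace, Trace]:
    """Pointwise mean and sample standard deviation of the sweeps."""
    if len(sweepset) < 1:
        raise ValueError("average needs at least one sweep")
    _check_common_grid(sweepset)
    stack = np.stack([tr.samples for tr in sweepset])
    mean = stack.mean(axis=0)
    stdv = stack.std(axis=0, ddof=1) if len(sweepset) > 1 else np.zeros_like(mean)
    tr0 = sweepset[0]
    params = f"n={len(sweepset)} prefix={sweepset.prefix}"
    mean_tr = tr0._derive(mean, "average", params,
                          label=f"Avg_{sweepset.prefix}_{sweepset.channel}0")
    stdv_tr = tr0._derive(stdv, "average_stdv", params,
                          label=f"Stdv_Avg_{sweepset.prefix}_{sweepset.channel}0")
    return mean_tr, stdv_tr


_UNIT_DIV = {("pA", "mV"): ("nS", 1000.0)}  # pA / mV = nS after x1000


def pointwise_combine(trace: Trace, other, op: str) -> Trace:
    """Elementwise arithmetic against another trace or a scalar.

    op is one of subtract | divide | multiply | assign.  Dividing a current
    (pA) by a voltage (mV) yields a conductance trace in nS.
    """
    if isinstance(other, Trace):
        if other.n != trace.n:
            raise ValueError(f"shape mismatch: {trace.n} vs {other.n} samples")
        rhs = other.samples
        rhs_units = other.units
    else:
        rhs = float(other)
        rhs_units = None
    units = trace.units
    scale = 1.0
    if op == "subtract":
        out = trace.samples - rhs
    elif op == "multiply":
        out = trace.samples * rhs
    elif op == "divide":
        if np.any(np.asarray(rhs) == 0):
            raise ZeroDivisionError("divisor contains zeros")
        out = trace.samples / rhs
        if rhs_units is not None and (trace.units, rhs_units) in _UNIT_DIV:
            units, scale = _UNIT_DIV[(trace.units, rhs_units)]
            out = out * scale
    elif op == "assign":
        out = np.full_like(trace.samples, rhs) if np.isscalar(rhs) else np.array(rhs)
    else:
        raise ValueError(f"unknown op {op!r}")
    return trace._derive(out, "pointwise_combine", f"op={op}", units=units)


def clip_segments(trace: Trace, intervals: Sequence[WindowSpec]) -> Trace:
    """Replace samples in each interval by a line between its boundary samples.

    Used to remove stimulus artifacts before averaging or fitting.
    """
    iv = sorted(intervals, key=lambda w: w.xbgn)
    for a, b in zip(iv, iv[1:]):
        if b.xbgn <= a.xend:
            raise ValueError("clip intervals overlap")
    y = trace.samples.copy()
    for w in iv:
        idx = trace.window_indices(w)
        if idx.size == 0:
            continue
        i0, i1 = idx[0], idx[-1]
        if i0 - 1 < 0 or i1 + 1 >= trace.n:
            raise ValueError(f"clip interval [{w.xbgn}, {w.xend}] touches the trace edge")
        left, right = y[i0 - 1], y[i1 + 1]
        y[i0:i1 + 1] = np.interp(np.arange(i0, i1 + 1), [i0 - 1, i1 + 1], [left, right])
    return trace._derive(y, "clip_segments", f"n_intervals={len(iv)}")


def concatenate(sweepset: SweepSet) -> Trace:
    """Join sweeps end-to-end into one continuous trace."""
    if len(sweepset) < 1:
        raise ValueError("concatenate needs at least one sweep")
    tr0 = sweepset[0]
    for tr in sweepset:
        if abs(tr.dt - tr0.dt) > 1e-12:
            raise ValueError("dt mismatch between sweeps")
        if tr.units != tr0.units:
            raise ValueError("unit mismatch between sweeps")
    samples = np.concatenate([tr.samples for tr in sweepset])
    return tr0._derive(samples, "concatenate", f"n={len(sweepset)}",
                       label=f"C_{sweepset.prefix}")


def histogram(values, bin_width: float, origin: float = 0.0
              ) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-width histogram with edges at origin + k*bin_width.

    Bins are left-closed, right-open.  Returns (bin centers, counts); counts
    sum to the number of finite input values.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.array([]), np.array([], dtype=int)
    k_lo = int(np.floor((v.min() - origin) / bin_width))
    k_hi = int(np.floor((v.max() - origin) / bin_width)) + 1
    edges = origin + bin_width * np.arange(k_lo, k_hi + 1)
    counts, _ = np.histogram(v, bins=edges)
    # np.histogram closes the last bin on the right; push exact top-edge hits up
    top = v == edges[-1]
    if top.any():  # pragma: no cover - guarded by edge construction
        counts[-1] -= top.sum()
    centers = edges[:-1] + bin_width / 2.0
    return centers, counts


def normalize(trace: Trace, window: WindowSpec | None = None) -> Trace:
    """Scale to [0, 1] via (x - min)/(max - min) over a window (convention)."""
    idx = trace.window_indices(window) if window is not None else np.arange(trace.n)
    lo, hi = trace.samples[idx].min(), trace.samples[idx].max()
    if hi == lo:
        raise ValueError("cannot normalize a constant trace")
    return trace._derive((trace.samples - lo) / (hi - lo), "normalize",
                         f"min={lo:g} max={hi:g}", units="")


def differentiate(trace: Trace) -> Trace:
    """Central-difference derivative (convention), units per ms."""
    dy = np.gradient(trace.samples, trace.dt)
    return trace._derive(dy, "differentiate", "", units=f"{trace.units}/ms")
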