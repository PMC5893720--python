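"""Weighted nonlinear least-squares models for synaptic waveforms and the
multinomial variance-mean relation.

Each model follows a Model/Results pattern: construct the model from data,
call :meth:`fit` and receive a :class:`FitResult` with estimates, standard
errors, residual sum of squares, the fitted curve and a ``summary()`` table.
Parameters can be held fixed at their initial values (e.g. fixing the
quantal CVs in the variance-mean fit, or the slow decay amplitude at zero).

The variance-mean (MPFA) model is the multinomial relation

    sigma_I^2 = [Q_p I_p - I_p^2 / N] (1 + CV_QII^2) + Q_p I_p CV_QI^2

linking the variance of evoked peak currents to their mean across release-
probability conditions; N is the number of functional release sites and
Q_p the quantal peak amplitude.  With the CVs fixed the relation is linear
in (Q_p, 1/N), so the weighted fit has a closed-form solution that is used
as the optimizer's starting point (and as an independent cross-check in the
test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .stats import MPFAPoint
from .trace import Trace, WindowSpec
from .waveforms import SynExpParams, synexp_eval


@dataclass
class FitResult:
    model: str
    params: dict[str, float]
    bse: dict[str, float]
    rss: float
    n_points: int
    fitted: np.ndarray
    converged: bool
    n_iter: int
    held: dict[str, float] = field(default_factory=dict)
    x: np.ndarray | None = None

    @property
    def dof(self) -> int:
        return self.n_points - (len(self.params) - len(self.held))

    def summary(self) -> str:
        lines = [f"{self.model} fit: {self.n_points} points, "
                 f"RSS = {self.rss:.6g}, "
                 f"{'converged' if self.converged else 'NOT converged'} "
                 f"({self.n_iter} iterations)",
                 f"{'parameter':>12} {'estimate':>14} {'std err':>12}"]
        for name, val in self.params.items():
            if name in self.held:
                lines.append(f"{name:>12} {val:>14.6g} {'(held)':>12}")
            else:
                lines.append(f"{name:>12} {val:>14.6g} {self.bse[name]:>12.4g}")
        return "\n".join(lines)


class _LSQModel:
    """Shared machinery: named parameters, holds, trust-region optimization."""

    param_names: tuple[str, ...] = ()
    model_name = "model"

    def _predict(self, params: dict[str, float]) -> np.ndarray:
        raise NotImplementedError

    def _observed(self) -> np.ndarray:
        raise NotImplementedError

    def _weights_sd(self) -> np.ndarray | None:
        return None  # per-point sigma; residuals are divided by it

    def _initial(self) -> dict[str, float]:
        raise NotImplementedError

    def _bounds(self) -> dict[str, tuple[float, float]]:
        return {}

    def fit(self, start: dict[str, float] | None = None,
            hold: dict[str, float] | None = None,
            max_iter: int = 200, tol: float = 1e-8) -> FitResult:
        hold = dict(hold or {})
        init = self._initial()
        init.update(start or {})
        init.update(hold)
        free = [p for p in self.param_names if p not in hold]
        if not free:
            raise ValueError("no free parameters")
        bounds = self._bounds()
        lo = np.array([bounds.get(p, (-np.inf, np.inf))[0] for p in free])
        hi = np.array([bounds.get(p, (-np.inf, np.inf))[1] for p in free])
        y = self._observed()
        sd = self._weights_sd()

        def unpack(x: np.ndarray) -> dict[str, float]:
            d = dict(init)
            d.update(zip(free, x))
            return d

        def resid(x: np.ndarray) -> np.ndarray:
            r = self._predict(unpack(x)) - y
            if sd is not None:
                r = r / sd
            return np.where(np.isfinite(r), r, 1e6)

        x0 = np.clip(np.array([init[p] for p in free], dtype=float), lo, hi)
        sol = least_squares(resid, x0, bounds=(lo, hi), x_scale="jac",
                            xtol=tol, ftol=tol, gtol=tol,
                            max_nfev=max_iter * max(len(free), 1) * 4)
        est = unpack(sol.x)
        r = resid(sol.x)
        rss = float(np.sum((self._predict(est) - y) ** 2))
        # covariance of the free parameters from the whitened Jacobian
        bse = {p: 0.0 for p in self.param_names}
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj)
            if sd is None:
                dof = max(y.size - len(free), 1)
                cov = cov * float(r @ r) / dof
            for p, v in zip(free, np.sqrt(np.maximum(np.diag(cov), 0.0))):
                bse[p] = float(v)
        except np.linalg.LinAlgError:
            pass
        return FitResult(self.model_name, {p: float(est[p]) for p in self.param_names},
                         bse, rss, y.size, self._predict(est),
                         bool(sol.success), int(sol.nfev), hold, sol.x)


# ---------------------------------------------------------------------------
# SynExp EPSC waveform
# ---------------------------------------------------------------------------

class SynExpModel(_LSQModel):
    """Fit the SynExp synaptic waveform to a trace segment.

    Parameters: t0, tau_r, n, a_d1, tau_d1, a_d2, tau_d2.  The window
    should contain the onset, peak and initial decay.  Hold ``a_d2=0`` to
    fit a single decay component.
    """

    param_names = ("t0", "tau_r", "n", "a_d1", "tau_d1", "a_d2", "tau_d2")
    model_name = "synexp"

    def __init__(self, trace: Trace, window: WindowSpec | None = None):
        self.trace = trace
        idx = trace.window_indices(window) if window is not None \
            else np.arange(trace.n)
        if idx.size < 8:
            raise ValueError("fit window holds fewer than 8 samples")
        self.t = trace.t_start + idx * trace.dt
        self.y = trace.samples[idx]

    def _observed(self) -> np.ndarray:
        return self.y

    def _predict(self, p: dict[str, float]) -> np.ndarray:
        if p["tau_r"] <= 0 or p["tau_d1"] <= 0 or p["n"] < 1 or \
                (p["a_d2"] != 0 and p["tau_d2"] <= 0):
            return np.full_like(self.t, np.inf)
        s = self.t - p["t0"]
        out = np.zeros_like(s)
        m = s > 0
        rise = (1.0 - np.exp(-s[m] / p["tau_r"])) ** p["n"]
        decay = p["a_d1"] * np.exp(-s[m] / p["tau_d1"])
        if p["a_d2"] != 0:
            decay = decay + p["a_d2"] * np.exp(-s[m] / p["tau_d2"])
        out[m] = rise * decay
        return out

    def _initial(self) -> dict[str, float]:
        t, y = self.t, self.y
        j = int(np.argmax(np.abs(y)))
        peak = y[j]
        sign = np.sign(peak) if peak != 0 else 1.0
        yy = sign * y
        # onset guess: last 20% crossing before the peak
        lvl = 0.2 * yy[j]
        before = np.nonzero(yy[:j + 1] < lvl)[0]
        i0 = before[-1] if before.size else 0
        t0 = t[i0]
        tau_r = max((t[j] - t0) / 2.0, self.trace.dt)
        # decay: log-linear fit over the post-peak tail
        tail = slice(j, len(t))
        pos = yy[tail] > 0.05 * yy[j]
        if pos.sum() >= 3:
            tt = t[tail][pos] - t[j]
            ly = np.log(yy[tail][pos])
            slope, icept = np.polyfit(tt, ly, 1)
            tau_d1 = -1.0 / slope if slope < 0 else (t[-1] - t[j])
            a_d1 = sign * np.exp(icept)
        else:
            tau_d1 = max(t[-1] - t[j], self.trace.dt)
            a_d1 = peak
        return {"t0": t0, "tau_r": tau_r, "n": 1.0, "a_d1": a_d1,
                "tau_d1": max(tau_d1, self.trace.dt), "a_d2": 0.1 * a_d1,
                "tau_d2": 5.0 * max(tau_d1, self.trace.dt)}

    def _bounds(self) -> dict[str, tuple[float, float]]:
        eps = 1e-6
        return {"tau_r": (eps, np.inf), "n": (1.0, np.inf),
                "tau_d1": (eps, np.inf), "tau_d2": (eps, np.inf)}

    def result_params(self, res: FitResult) -> SynExpParams:
        return SynExpParams(**{k: res.params[k] for k in self.param_names})


# ---------------------------------------------------------------------------
# multinomial variance-mean relation (MPFA)
# ---------------------------------------------------------------------------

def multinomial_variance(i_p, n_sites: float, q_p: float,
                         cv_qi: float = 0.0, cv_qii: float = 0.0) -> np.ndarray:
    """Multinomial variance-mean relation sigma_I^2(I_p)."""
    i_p = np.asarray(i_p, dtype=float)
    return (q_p * i_p - i_p ** 2 / n_sites) * (1.0 + cv_qii ** 2) \
        + q_p * i_p * cv_qi ** 2


class VarianceMeanModel(_LSQModel):
    """Weighted fit of the multinomial relation to MPFA points.

    ``points`` is a list of :class:`MPFAPoint`; weights are 1/var_err^2.
    CV_QI and CV_QII are normally held at predetermined values.
    """

    param_names = ("N", "Q_p", "CV_QI", "CV_QII")
    model_name = "multinomial variance-mean"

    def __init__(self, points: list[MPFAPoint] | None = None, *,
                 i_p=None, sigma2=None, var_err=None,
                 cv_qi: float = 0.0, cv_qii: float = 0.0):
        if points is not None:
            i_p = [p.i_p for p in points]
            sigma2 = [p.sigma2 for p in points]
            var_err = [p.var_err for p in points]
        self.i_p = np.asarray(i_p, dtype=float)
        self.sigma2 = np.asarray(sigma2, dtype=float)
        if var_err is None:
            self.var_err = None
        else:
            ve = np.asarray(var_err, dtype=float)
            # a degenerate (zero-variance) condition would otherwise get
            # unbounded weight; floor its error at 1e-3 of the median error
            pos = ve[ve > 1e-9]
            ve = np.maximum(ve, 1e-3 * np.median(pos)) if pos.size else None
            self.var_err = ve
        self.cv_qi = cv_qi
        self.cv_qii = cv_qii
        if self.i_p.size < 2:
            raise ValueError("need at least 2 variance-mean points")
        if np.ptp(self.i_p) == 0:
            raise ValueError("all I_p are equal: design is singular")

    def _observed(self) -> np.ndarray:
        return self.sigma2

    def _weights_sd(self) -> np.ndarray | None:
        return self.var_err

    def _predict(self, p: dict[str, float]) -> np.ndarray:
        if p["N"] == 0:
            return np.full_like(self.i_p, np.inf)
        return multinomial_variance(self.i_p, p["N"], p["Q_p"],
                                    p["CV_QI"], p["CV_QII"])

    def closed_form(self) -> tuple[float, float]:
        """Exact weighted solution with the CVs fixed.

        With CVs fixed the relation is theta1*I_p + theta2*I_p^2 with
        theta1 = Q_p (1 + CV_QII^2 + CV_QI^2), theta2 = -(1 + CV_QII^2)/N:
        a weighted parabola through the origin.
        """
        w = np.ones_like(self.i_p) if self.var_err is None \
            else 1.0 / self.var_err ** 2
        X = np.column_stack([self.i_p, self.i_p ** 2])
        A = X.T @ (w[:, None] * X)
        b = X.T @ (w * self.sigma2)
        theta = np.linalg.solve(A, b)
        kii = 1.0 + self.cv_qii ** 2
        q_p = theta[0] / (kii + self.cv_qi ** 2)
        n_sites = -kii / theta[1]
        return n_sites, q_p

    def _initial(self) -> dict[str, float]:
        n_sites, q_p = self.closed_form()
        if not np.isfinite(n_sites) or n_sites <= 0:
            n_sites = 2.0 * np.max(np.abs(self.i_p)) / max(abs(q_p), 1e-9)
        return {"N": n_sites, "Q_p": q_p, "CV_QI": self.cv_qi,
                "CV_QII": self.cv_qii}

    def _bounds(self) -> dict[str, tuple[float, float]]:
        return {"N": (1e-6, np.inf)}

    def fit(self, start=None, hold=None, **kw) -> FitResult:
        if hold is None:
            hold = {"CV_QI": self.cv_qi, "CV_QII": self.cv_qii}
        return super().fit(start=start, hold=hold, **kw)


# ---------------------------------------------------------------------------
# Gaussian (histogram) model
# ---------------------------------------------------------------------------

class GaussianModel(_LSQModel):
    """Gaussian fit to a histogram (e.g. a rise-time distribution)."""

    param_names = ("amp", "center", "sd")
    model_name = "gaussian"

    def __init__(self, centers, counts):
        self.centers = np.asarray(centers, dtype=float)
        self.counts = np.asarray(counts, dtype=float)
        if self.centers.size < 4:
            raise ValueError("need at least 4 bins")

    @classmethod
    def from_values(cls, values, bin_width: float, origin: float = 0.0):
        from .trace import histogram
        centers, counts = histogram(values, bin_width, origin)
        return cls(centers, counts)

    def _observed(self) -> np.ndarray:
        return self.counts

    def _predict(self, p: dict[str, float]) -> np.ndarray:
        if p["sd"] <= 0:
            return np.full_like(self.centers, np.inf)
        z = (self.centers - p["center"]) / p["sd"]
        return p["amp"] * np.exp(-0.5 * z * z)

    def _initial(self) -> dict[str, float]:
        w = np.maximum(self.counts, 0.0)
        tot = w.sum()
        if tot <= 0:
            return {"amp": 1.0, "center": float(self.centers.mean()),
                    "sd": float(np.ptp(self.centers)) / 4 or 1.0}
        mu = float((w * self.centers).sum() / tot)
        sd = float(np.sqrt((w * (self.centers - mu) ** 2).sum() / tot)) or \
            float(np.ptp(self.centers)) / 4
        return {"amp": float(w.max()), "center": mu, "sd": sd}

    def _bounds(self) -> dict[str, tuple[float, float]]:
        return {"sd": (1e-12, np.inf)}

    @staticmethod
    def upper_cut(res: FitResult, n_sd: float = 5.0) -> float:
        """center + n_sd * SD: the slow/fast dividing line convention."""
        return res.params["center"] + n_sd * res.params["sd"]


# ---------------------------------------------------------------------------
# double exponential decay
# ---------------------------------------------------------------------------

class DoubleExpModel(_LSQModel):
    """a1 exp(-t/tau1) + a2 exp(-t/tau2) (+ optional offset) on a decay segment.

    Times are measured from the start of the fit window.  Used e.g. to fit
    the final decay of an averaged stimulus artifact before subtracting it.
    """

    param_names = ("a1", "tau1", "a2", "tau2", "offset")
    model_name = "doubleexp"

    def __init__(self, trace: Trace, window: WindowSpec | None = None):
        idx = trace.window_indices(window) if window is not None \
            else np.arange(trace.n)
        if idx.size < 6:
            raise ValueError("fit window holds fewer than 6 samples")
        self.t = (idx - idx[0]) * trace.dt
        self.y = trace.samples[idx]
        self.t_abs0 = trace.t_start + idx[0] * trace.dt

    def _observed(self) -> np.ndarray:
        return self.y

    def _predict(self, p: dict[str, float]) -> np.ndarray:
        if p["tau1"] <= 0 or (p["a2"] != 0 and p["tau2"] <= 0):
            return np.full_like(self.t, np.inf)
        out = p["a1"] * np.exp(-self.t / p["tau1"]) + p["offset"]
        if p["a2"] != 0:
            out = out + p["a2"] * np.exp(-self.t / p["tau2"])
        return out

    def _initial(self) -> dict[str, float]:
        y = self.y
        sign = np.sign(y[0] - y[-1]) or 1.0
        yy = sign * (y - y[-1])
        pos = yy > max(1e-12, 0.01 * np.max(yy))
        if pos.sum() >= 3:
            slope, icept = np.polyfit(self.t[pos], np.log(yy[pos]), 1)
            tau = -1.0 / slope if slope < 0 else self.t[-1] or 1.0
            a = sign * np.exp(icept)
        else:
            tau = self.t[-1] or 1.0
            a = y[0] - y[-1]
        return {"a1": 0.7 * a, "tau1": 0.5 * tau, "a2": 0.3 * a,
                "tau2": 2.0 * tau, "offset": float(y[-1])}

    def _bounds(self) -> dict[str, tuple[float, float]]:
        return {"tau1": (1e-9, np.inf), "tau2": (1e-9, np.inf)}

    def fit(self, start=None, hold=None, **kw) -> FitResult:
        if hold is None:
            hold = {"offset": 0.0}
        return super().fit(start=start, hold=hold, **kw)


# convenience wrappers --------------------------------------------------------

def fit_synexp(trace: Trace, window: WindowSpec | None = None,
               hold: dict[str, float] | None = None, **kw) -> FitResult:
    return SynExpModel(trace, window).fit(hold=hold, **kw)


def fit_multinomial(points: list[MPFAPoint], cv_qi: float = 0.0,
                    cv_qii: float = 0.0, **kw) -> FitResult:
    return VarianceMeanModel(points, cv_qi=cv_qi, cv_qii=cv_qii).fit(**kw)


def fit_gaussian(centers, counts, **kw) -> FitResult:
    return GaussianModel(centers, counts).fit(**kw)


def fit_doubleexp(trace: Trace, window: WindowSpec | None = None,
                  hold: dict[str, float] | None = None, **kw) -> FitResult:
    return DoubleExpModel(trace, window).fit(hold=hold, **kw)
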