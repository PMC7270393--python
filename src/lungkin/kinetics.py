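"""One- and two-tissue compartment models for lung TACs.

Model of the measured PET signal in a lung region driven by the arterial
plasma input Cp and whole-blood curve Cwb::

    C_model(t) = (1 - Vb) * C_tissue(t) + Vb * Cwb(t - delta)

with the tissue response the convolution of the (time-shifted) plasma curve
with the compartmental impulse response:

* 1TCM:  h(t) = K1 * exp(-k2 t),                 V_T = K1/k2
* 2TCM:  h(t) = A1 exp(-a1 t) + A2 exp(-a2 t),    V_T = K1/k2 * (1 + k3/k4)

where a1, a2 are the standard roots of the two-tissue system.  The
convolution is evaluated analytically for a piecewise-linear input on its
1-s grid, and the model TAC is returned as exact frame averages.

The (1 - Vb) factor is the volume-conserving convention; a pure-additive
variant (``convention="additive"``) is available.  The time shift delta
(positive = tissue clock lags the blood clock) applies to both the plasma
input driving the tissue and the whole-blood term.

Fits are weighted nonlinear least squares with a deterministic multi-start
grid; model comparison uses AIC and the one-tailed (right) F test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .core import FrameSchedule, TimeActivityCurve
from .input_function import InputFunction

__all__ = [
    "KineticParameters",
    "KineticResults",
    "ModelComparison",
    "OneTissueModel",
    "TwoTissueModel",
    "exp_conv",
    "frame_average",
    "solve_model_tac",
    "compare_models",
]

C11_LAMBDA_PER_MIN = np.log(2.0) / 20.4  # 11C decay constant, 1/min


@dataclass(frozen=True)
class KineticParameters:
    """Compartmental rate constants plus blood volume and input time shift.

    k1 in ml/cm3/min; k2, k3, k4 in 1/min; vb a fraction in [0, 1);
    delta_s the blood-to-tissue time shift in seconds.
    """

    k1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    vb: float = 0.0
    delta_s: float = 0.0

    def __post_init__(self):
        if self.k1 < 0:
            raise ValueError("K1 must be >= 0")
        if self.k2 <= 0:
            raise ValueError("k2 must be > 0")
        if self.k3 < 0 or self.k4 < 0:
            raise ValueError("k3 and k4 must be >= 0")
        if not 0 <= self.vb < 1:
            raise ValueError("Vb must lie in [0, 1)")

    @property
    def is_two_tissue(self) -> bool:
        return self.k3 > 0 or self.k4 > 0

    @property
    def vt(self) -> float:
        """Total distribution volume (ml/cm3) by the model formula."""
        if self.k3 > 0 and self.k4 == 0:
            return np.nan  # irreversible trapping: V_T undefined
        if self.k3 > 0:
            return self.k1 / self.k2 * (1.0 + self.k3 / self.k4)
        return self.k1 / self.k2


def exp_conv(values: np.ndarray, dt_min: float, theta_per_min: float) -> np.ndarray:
    """Convolution y(t) = int_0^t values(s) exp(-theta (t - s)) ds for a
    piecewise-linear ``values`` on a uniform grid, evaluated exactly at the
    grid points (time unit: minutes).

    The recursion y_i = E y_{i-1} + c_i with E = exp(-theta dt) is exact for
    linear interpolation of the input within each step; it is solved with a
    first-order IIR filter.  theta = 0 reduces to the running integral.
    """
    v = np.asarray(values, dtype=float)
    th = float(theta_per_min) * dt_min  # dimensionless theta*dt
    dv = np.diff(v)
    if th < 1e-4:
        # series in theta*dt to avoid cancellation; th=0 is the trapezoid rule
        g1 = dt_min * (1.0 - th / 2.0 + th * th / 6.0)          # (1-E)/theta
        g2 = dt_min * (0.5 - th / 6.0 + th * th / 24.0)         # (th-(1-E))/(theta^2 dt)
        E = np.exp(-th)
    else:
        E = np.exp(-th)
        one_m_E = -np.expm1(-th)
        g1 = one_m_E / theta_per_min
        g2 = (th - one_m_E) / (theta_per_min * th)
    c = np.empty_like(v)
    c[0] = 0.0
    c[1:] = v[:-1] * g1 + dv * g2
    return lfilter([1.0], [1.0, -E], c)


def frame_average(curve: np.ndarray, t_s: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each acquisition frame (trapezoid)."""
    integral = np.concatenate([[0.0], np.cumsum((curve[1:] + curve[:-1]) * 0.5 * np.diff(t_s))])
    lo = np.interp(schedule.frame_start, t_s, integral)
    hi = np.interp(schedule.frame_end_s, t_s, integral)
    return (hi - lo) / schedule.frame_duration


def _two_tissue_impulse(p: KineticParameters):
    """Amplitudes and rates of the bi-exponential 2TC impulse response."""
    s = p.k2 + p.k3 + p.k4
    disc = s * s - 4.0 * p.k2 * p.k4
    sq = np.sqrt(max(disc, 0.0))
    if sq < 1e-12 * max(s, 1e-12):  # repeated root: nudge apart
        sq = 1e-9 * max(s, 1e-9)
    a1 = 0.5 * (s - sq)
    a2 = 0.5 * (s + sq)
    A1 = p.k1 * (p.k3 + p.k4 - a1) / (a2 - a1)
    A2 = p.k1 * (a2 - p.k3 - p.k4) / (a2 - a1)
    return A1, a1, A2, a2


def solve_model_tac(
    params: KineticParameters,
    input_fn: InputFunction,
    schedule: FrameSchedule,
    convention: str = "volume",
) -> np.ndarray:
    """Frame-averaged model TAC for the given parameters and input."""
    if convention not in ("volume", "additive"):
        raise ValueError("convention must be 'volume' or 'additive'")
    t = input_fn.t_s
    if t[-1] < schedule.total_duration_s - 1e-9:
        raise ValueError("input-function grid does not cover the frame schedule")
    cp = input_fn.plasma_at(t, params.delta_s)
    wb = input_fn.whole_blood_at(t, params.delta_s)
    dt_min = 1.0 / 60.0
    if params.is_two_tissue:
        A1, a1, A2, a2 = _two_tissue_impulse(params)
        ctis = A1 * exp_conv(cp, dt_min, a1) + A2 * exp_conv(cp, dt_min, a2)
    else:
        ctis = params.k1 * exp_conv(cp, dt_min, params.k2)
    if convention == "volume":
        model = (1.0 - params.vb) * ctis + params.vb * wb
    else:
        model = ctis + params.vb * wb
    return frame_average(model, t, schedule)


@dataclass
class KineticResults:
    """Fit results for one TAC and one compartment model."""

    model_id: str
    params: KineticParameters
    vt: float
    rss: float
    n: int
    p: int
    se: dict = field(default_factory=dict)
    converged: bool = True
    fittedvalues: np.ndarray | None = None
    resid: np.ndarray | None = None
    tac: TimeActivityCurve | None = None
    convention: str = "volume"

    @property
    def aic(self) -> float:
        """Gaussian-RSS AIC: n ln(RSS/n) + 2p (no small-sample correction)."""
        return self.n * np.log(self.rss / self.n) + 2 * self.p if self.rss > 0 else -np.inf

    @property
    def aicc(self) -> float:
        corr = 2 * self.p * (self.p + 1) / max(self.n - self.p - 1, 1)
        return self.aic + corr

    @property
    def rel_se(self) -> dict:
        return {
            k: (v / abs(getattr(self.params, k)) if getattr(self.params, k) != 0 else np.inf)
            for k, v in self.se.items()
        }

    @property
    def non_identifiable(self) -> list[str]:
        """Parameters whose relative standard error exceeds 50% (or is
        undefined): surfaced, not hidden, because poorly identified k3/k4
        are expected for lung data best described by a single compartment."""
        out = []
        for k, r in self.rel_se.items():
            if not np.isfinite(r) or r > 0.5:
                out.append(k)
        return out

    def summary(self) -> str:
        lines = [
            f"{self.model_id} fit  (n frames = {self.n}, free parameters = {self.p})",
            "-" * 58,
            f"{'parameter':<10}{'estimate':>14}{'std err':>14}{'rel se':>12}",
        ]
        for name in ("k1", "k2", "k3", "k4", "vb", "delta_s"):
            val = getattr(self.params, name)
            if name in ("k3", "k4") and self.model_id == "1TCM":
                continue
            se = self.se.get(name, np.nan)
            rse = self.rel_se.get(name, np.nan)
            lines.append(f"{name:<10}{val:>14.5g}{se:>14.3g}{rse:>12.2%}")
        lines += [
            "-" * 58,
            f"V_T = {self.vt:.4g} ml/cm3    RSS = {self.rss:.4g}    AIC = {self.aic:.2f}",
        ]
        if self.non_identifiable:
            lines.append(f"non-identifiable (rel SE > 50%): {', '.join(self.non_identifiable)}")
        if not self.converged:
            lines.append("WARNING: optimizer did not report convergence")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Measured frames and fitted model curve against time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.tac.mid_times_min
        ax.plot(t, self.tac.values, "o", label="measured", ms=4)
        ax.plot(t, self.fittedvalues, "-", label=f"{self.model_id} fit")
        ax.set_xlabel("time (min)")
        ax.set_ylabel(f"activity ({self.tac.units})")
        ax.legend()
        return ax


class _CompartmentModelBase:
    """Shared machinery of the 1TC and 2TC weighted least-squares fits."""

    model_id = ""
    _rate_names: tuple = ()

    def __init__(
        self,
        tac: TimeActivityCurve,
        input_fn: InputFunction,
        weights="uniform",
        convention: str = "volume",
        fit_vb: bool = True,
        fit_delta: bool = True,
        delta_bound_s: float = 30.0,
        fixed: dict | None = None,
    ):
        self.tac = tac
        self.input_fn = input_fn
        self.convention = convention
        self.fit_vb = fit_vb
        self.fit_delta = fit_delta
        self.delta_bound_s = float(delta_bound_s)
        self.fixed = dict(fixed or {})
        self.weights = self._build_weights(weights)

    def _build_weights(self, weights) -> np.ndarray:
        sched = self.tac.schedule
        if weights is None or weights == "uniform":
            w = np.ones(sched.n_frames)
        elif weights == "duration-decay":
            # frame-duration / decay heuristic: w ~ duration * exp(-lambda t)
            w = sched.frame_duration / 60.0 * np.exp(-C11_LAMBDA_PER_MIN * sched.mid_times_min)
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != (sched.n_frames,):
                raise ValueError("weights length must equal the number of frames")
        return w / w.mean()

    # --- free-parameter bookkeeping -------------------------------------
    def _free_names(self) -> list[str]:
        names = list(self._rate_names)
        if self.fit_vb:
            names.append("vb")
        if self.fit_delta:
            names.append("delta_s")
        return [n for n in names if n not in self.fixed]

    def _bounds(self, names):
        lo, hi = [], []
        table = {
            "k1": (1e-6, 2.0),
            "k2": (1e-6, 5.0),
            "k3": (0.0, 2.0),
            "k4": (1e-6, 2.0),
            "vb": (0.0, 0.95),
            "delta_s": (-self.delta_bound_s, self.delta_bound_s),
        }
        for n in names:
            b = table[n]
            lo.append(b[0])
            hi.append(b[1])
        return np.array(lo), np.array(hi)

    def _make_params(self, names, x) -> KineticParameters:
        kw = {"k3": 0.0, "k4": 0.0, "vb": 0.0, "delta_s": 0.0}
        kw.update(self.fixed)
        kw.update(dict(zip(names, x)))
        return KineticParameters(**kw)

    def _start_grid(self) -> list[dict]:
        raise NotImplementedError

    def fit(self, xtol: float = 1e-12, ftol: float = 1e-12, max_nfev: int = 400) -> KineticResults:
        """Weighted least squares from a deterministic multi-start grid;
        the best final cost wins (no random restarts, for reproducibility)."""
        names = self._free_names()
        lo, hi = self._bounds(names)
        y = self.tac.values
        sw = np.sqrt(self.weights)

        def resid(x):
            model = solve_model_tac(
                self._make_params(names, x), self.input_fn, self.tac.schedule, self.convention
            )
            return sw * (model - y)

        best = None
        any_success = False
        for start in self._start_grid():
            x0 = np.clip(np.array([start[n] for n in names]), lo, hi)
            try:
                sol = least_squares(
                    resid, x0, bounds=(lo, hi), xtol=xtol, ftol=ftol, gtol=1e-14,
                    max_nfev=max_nfev,
                )
            except Exception:
                continue
            any_success = any_success or sol.success
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError(f"{self.model_id}: no start converged")

        params = self._make_params(names, best.x)
        fitted = solve_model_tac(params, self.input_fn, self.tac.schedule, self.convention)
        r = y - fitted
        rss = float(np.sum(self.weights * r * r))
        n, p = y.size, len(names)
        se = self._standard_errors(best, names, rss, n, p)
        return KineticResults(
            model_id=self.model_id, params=params, vt=params.vt, rss=rss, n=n, p=p,
            se=se, converged=bool(any_success), fittedvalues=fitted, resid=r,
            tac=self.tac, convention=self.convention,
        )

    @staticmethod
    def _standard_errors(sol, names, rss, n, p) -> dict:
        if n <= p:
            return {k: np.inf for k in names}
        try:
            JTJ = sol.jac.T @ sol.jac
            cov = rss / (n - p) * np.linalg.pinv(JTJ)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except Exception:
            se = np.full(len(names), np.inf)
        return dict(zip(names, se))


class OneTissueModel(_CompartmentModelBase):
    """One-tissue compartment model fitted to a lung TAC.

    Free parameters: K1, k2, Vb, delta (Vb and delta can be fixed via
    ``fixed={'vb': ..., 'delta_s': ...}``).  V_T = K1/k2.
    """

    model_id = "1TCM"
    _rate_names = ("k1", "k2")

    def _start_grid(self):
        return [
            {"k1": k1, "k2": k2, "vb": 0.1, "delta_s": 0.0}
            for k1 in (0.01, 0.03, 0.05)
            for k2 in (0.005, 0.015, 0.05)
        ]


class TwoTissueModel(_CompartmentModelBase):
    """Two-tissue compartment model; V_T = K1/k2 (1 + k3/k4).

    k3/k4 identifiability diagnostics (relative standard errors) are
    attached to the results; for lung TACs adequately described by one
    compartment, large k3/k4 uncertainties are the expected outcome.
    """

    model_id = "2TCM"
    _rate_names = ("k1", "k2", "k3", "k4")

    def _start_grid(self):
        return [
            {"k1": k1, "k2": k2, "k3": 0.01, "k4": 0.01, "vb": 0.1, "delta_s": 0.0}
            for k1 in (0.01, 0.03, 0.05)
            for k2 in (0.005, 0.015, 0.05)
        ]


@dataclass
class ModelComparison:
    """AIC + one-tailed (right) F-test comparison of two nested fits."""

    aic: dict
    f_stat: float
    f_pvalue: float
    preferred: str
    tie: bool = False
    note: str = ""

    def summary(self) -> str:
        ids = list(self.aic)
        out = [
            f"model comparison: {ids[0]} vs {ids[1]}",
            *(f"  AIC[{k}] = {v:.2f}" for k, v in self.aic.items()),
            f"  F = {self.f_stat:.4g}  (one-tailed p = {self.f_pvalue:.4g})",
            f"  preferred: {self.preferred}",
        ]
        if self.note:
            out.append(f"  note: {self.note}")
        return "\n".join(out)


# Below this relative RSS the residuals sit at the numerical noise floor of
# the optimizer and comparing RSS between nested fits is meaningless: the
# comparison is declared a tie and the simpler model preferred.
_RSS_FLOOR_REL = 1e-12


def compare_models(res1: KineticResults, res2: KineticResults) -> ModelComparison:
    """Compare nested fits on one TAC: AIC decides, F statistic reported.

    ``res1`` is the simpler model (fewer free parameters).  Preferred =
    lower AIC; exact ties and numerically-degenerate comparisons (both RSS
    at the noise floor) go to the simpler model.
    """
    if res1.n != res2.n:
        raise ValueError("fits must use the same frames")
    if res1.p > res2.p:
        res1, res2 = res2, res1
    n, p1, p2 = res1.n, res1.p, res2.p
    scale = float(np.sum(np.asarray(res1.tac.values) ** 2)) if res1.tac is not None else 1.0
    floor = _RSS_FLOOR_REL * max(scale, 1e-300)
    note = ""

    if res2.rss <= 0:
        if res1.rss <= floor:
            # both fits exact to numerical precision: simpler model wins
            return ModelComparison(
                {res1.model_id: res1.aic, res2.model_id: res2.aic},
                np.inf, 0.0, res1.model_id, tie=True,
                note="both RSS at numerical noise floor; simpler model preferred",
            )
        warnings.warn("RSS of the larger model is zero: F undefined, deciding by AIC")
        f_stat, f_p = np.inf, 0.0
        note = "F undefined (RSS2 = 0)"
        preferred = res1.model_id if res1.aic <= res2.aic else res2.model_id
        return ModelComparison({res1.model_id: res1.aic, res2.model_id: res2.aic},
                               f_stat, f_p, preferred, note=note)

    f_stat = ((res1.rss - res2.rss) / (p2 - p1)) / (res2.rss / (n - p2))
    f_stat = max(f_stat, 0.0)
    f_p = float(stats.f.sf(f_stat, p2 - p1, n - p2))

    tie = res1.rss <= floor and res2.rss <= floor
    if tie:
        preferred = res1.model_id
        note = "both RSS at numerical noise floor; simpler model preferred"
    elif np.isclose(res1.aic, res2.aic, rtol=0, atol=1e-12):
        preferred = res1.model_id
        tie = True
    else:
        preferred = res1.model_id if res1.aic < res2.aic else res2.model_id
    return ModelComparison(
        {res1.model_id: res1.aic, res2.model_id: res2.aic}, f_stat, f_p, preferred,
        tie=tie, note=note,
    )
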