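"""Multilinear variant of Logan's graphical analysis (MLLogan).

For a reversible tracer the operational equation after the linearity onset
time t* is

    C_T(T) = P1 * int_0^T Cp dt  +  P2 * int_0^T C_T dt,      T > t*,

fitted by ordinary least squares with C_T(T) as the response — the
multilinear rearrangement that avoids the noisy denominators of the classic
Logan plot — giving V_T = -P1 / P2.  For a one-tissue system the equation
holds exactly at every T (P1 = K1, P2 = -k2), so the linear phase starts at
injection; t* matters for multi-compartment kinetics and noise.

The graphical V_T of an uncorrected lung TAC absorbs the intravascular
signal (it converges to (1-Vb) K1/k2 + Vb/r rather than K1/k2); use
:func:`blood_volume_corrected_tac` first to estimate the tissue V_T on the
compartment-model scale, mirroring the workflow in which the blood-volume
fraction is estimated by a compartment fit and removed before inspection.

Integrals use the trapezoid rule with a (0, 0) anchor: the input on its 1-s
grid, the TAC over frame mid-times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import TimeActivityCurve
from .input_function import InputFunction
from .kinetics import frame_average

__all__ = [
    "LoganResults",
    "MultilinearLogan",
    "select_tstar",
    "classic_logan_points",
    "blood_volume_corrected_tac",
]


def _tac_cum_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Cumulative trapezoid of the TAC at frame mid-times, (0,0)-anchored
    (units: kBq/cm3 * min)."""
    t = np.concatenate([[0.0], tac.mid_times_min])
    v = np.concatenate([[0.0], tac.values])
    return np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))


def _input_cum_integral_at_mids(tac: TimeActivityCurve, input_fn: InputFunction) -> np.ndarray:
    """Cumulative integral of the plasma input on its 1-s grid, sampled at
    frame mid-times (kBq/cm3 * min)."""
    t_min = input_fn.t_s / 60.0
    integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * (input_fn.plasma[1:] + input_fn.plasma[:-1]) * np.diff(t_min))]
    )
    return np.interp(tac.mid_times_min, t_min, integral)


@dataclass
class LoganResults:
    """MLLogan fit: V_T = -P1/P2 with P1 the coefficient on the integrated
    input and P2 the coefficient on the integrated TAC."""

    vt: float
    p1: float
    p2: float
    t_star_min: float
    n_used: int
    resid: np.ndarray
    flagged: bool = False
    note: str = ""

    def summary(self) -> str:
        lines = [
            f"MLLogan fit  (t* = {self.t_star_min:g} min, frames used = {self.n_used})",
            f"  P1 = {self.p1:.5g}   P2 = {self.p2:.5g}",
            f"  V_T = {self.vt:.4g} ml/cm3",
        ]
        if self.flagged:
            lines.append(f"  FLAGGED: {self.note}")
        return "\n".join(lines)


class MultilinearLogan:
    """Multilinear Logan model for one TAC and input function.

    Parameters
    ----------
    tac : TimeActivityCurve
        Tissue curve; apply :func:`blood_volume_corrected_tac` first when a
        V_T on the compartment-model scale is wanted.
    input_fn : InputFunction
        Plasma input on the 1-s grid.
    t_star_min : float
        Linearity onset; frames with mid-time > t* enter the regression.
    """

    def __init__(self, tac: TimeActivityCurve, input_fn: InputFunction, t_star_min: float = 10.0):
        if t_star_min >= tac.schedule.total_duration_min:
            raise ValueError("t* lies beyond the measurement")
        self.tac = tac
        self.input_fn = input_fn
        self.t_star_min = float(t_star_min)

    def fit(self) -> LoganResults:
        tac = self.tac
        int_cp = _input_cum_integral_at_mids(tac, self.input_fn)
        int_ct = _tac_cum_integral(tac)
        use = tac.mid_times_min > self.t_star_min
        if use.sum() < 3:
            raise ValueError("fewer than 3 frames after t*")
        X = np.column_stack([int_cp[use], int_ct[use]])
        y = tac.values[use]
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 2:
            raise np.linalg.LinAlgError("singular MLLogan design matrix")
        p1, p2 = coef
        resid = y - X @ coef
        flagged = p2 >= 0
        note = "P2 >= 0: washout not identifiable (irreversible or degenerate)" if flagged else ""
        vt = -p1 / p2 if p2 < 0 else np.inf
        return LoganResults(float(vt), float(p1), float(p2), self.t_star_min,
                            int(use.sum()), resid, flagged, note)


def classic_logan_points(tac: TimeActivityCurve, input_fn: InputFunction):
    """Classic (ratio-form) Logan plot coordinates for inspection:
    x = int Cp / C_T, y = int C_T / C_T at each frame mid-time."""
    int_cp = _input_cum_integral_at_mids(tac, input_fn)
    int_ct = _tac_cum_integral(tac)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = int_cp / tac.values
        y = int_ct / tac.values
    return x, y


def select_tstar(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    max_rel_dev: float = 0.10,
    fallback_min: float = 10.0,
) -> float:
    """Smallest candidate t* (frame boundaries) whose post-t* classic-Logan
    points deviate from their own straight-line fit by less than
    ``max_rel_dev`` maximum relative error.  Falls back to
    ``fallback_min`` with a warning when no candidate qualifies."""
    if tac.schedule.total_duration_min < 30:
        raise ValueError("TAC must cover at least 30 min to select t*")
    x, y = classic_logan_points(tac, input_fn)
    mids = tac.mid_times_min
    candidates = [0.0] + [float(b) / 60.0 for b in tac.schedule.frame_end_s[:-3]]
    for cand in candidates:
        use = mids > cand
        if use.sum() < 3:
            continue
        xs, ys = x[use], y[use]
        if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(ys))):
            continue
        A = np.column_stack([xs, np.ones(xs.size)])
        coef, *_ = np.linalg.lstsq(A, ys, rcond=None)
        pred = A @ coef
        denom = np.maximum(np.abs(ys), 1e-300)
        if np.max(np.abs(ys - pred) / denom) < max_rel_dev:
            return cand
    warnings.warn(
        f"no t* candidate met the {max_rel_dev:.0%} linearity criterion; "
        f"falling back to t* = {fallback_min} min"
    )
    return float(fallback_min)


def blood_volume_corrected_tac(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    vb: float,
    delta_s: float = 0.0,
    convention: str = "volume",
) -> TimeActivityCurve:
    """Remove the intravascular contribution from a measured lung TAC.

    volume convention:  C_tis = (C - Vb * Cwb(t - delta)) / (1 - Vb)
    additive variant:   C_tis =  C - Vb * Cwb(t - delta)
    """
    if not 0 <= vb < 1:
        raise ValueError("Vb must lie in [0, 1)")
    wb = input_fn.whole_blood_at(input_fn.t_s, delta_s)
    wb_frames = frame_average(wb, input_fn.t_s, tac.schedule)
    corrected = tac.values - vb * wb_frames
    if convention == "volume":
        corrected = corrected / (1.0 - vb)
    return TimeActivityCurve(tac.schedule, corrected, label=f"{tac.label}_tissue", units=tac.units)
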