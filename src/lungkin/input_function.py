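"""Arterial plasma input function for lung PET quantification.

The input function is image-derived: the whole-blood TAC extracted from an
aortic-arch ROI is linearly interpolated to a 1-s grid (anchored at (0, 0)
at injection, constant-held beyond the last frame mid-time) and multiplied
by the average plasma-to-whole-blood activity ratio measured in manual
arterial samples.  Because the ratio is essentially constant over the
measurement, a hematocrit shortcut r = 1/(1 - Hct) — exact when the tracer
is excluded from blood cells — is provided as an alternative.

Radiometabolite correction is available for comparison but is *not* the
default: total plasma activity drives the kinetic models, on the assumption
that labelled metabolites also enter lung tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import TimeActivityCurve

__all__ = [
    "BloodSampleSet",
    "InputFunction",
    "RichardsParentModel",
    "plasma_to_blood_ratio",
    "ratio_from_hematocrit",
    "derive_plasma_input",
    "fit_parent_fraction",
    "apply_parent_correction",
]


@dataclass
class BloodSampleSet:
    """Manual arterial blood samples: times (min), whole-blood and plasma
    activity (kBq/cm3), optional parent fraction, and hematocrit."""

    time_min: np.ndarray
    whole_blood: np.ndarray
    plasma: np.ndarray
    parent_fraction: np.ndarray | None = None
    hematocrit: float | None = None

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.whole_blood = np.asarray(self.whole_blood, dtype=float)
        self.plasma = np.asarray(self.plasma, dtype=float)
        if not np.all(np.diff(self.time_min) > 0):
            raise ValueError("sample times must be strictly increasing")
        if self.whole_blood.shape != self.time_min.shape or self.plasma.shape != self.time_min.shape:
            raise ValueError("sample arrays must share one length")
        if np.any(self.whole_blood < 0) or np.any(self.plasma < 0):
            raise ValueError("activities must be >= 0")
        if self.parent_fraction is not None:
            self.parent_fraction = np.asarray(self.parent_fraction, dtype=float)
            if np.any((self.parent_fraction < 0) | (self.parent_fraction > 1)):
                raise ValueError("parent fraction must lie in [0, 1]")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "time_min": self.time_min,
                "wb_kBq_ml": self.whole_blood,
                "plasma_kBq_ml": self.plasma,
            }
        )
        if self.parent_fraction is not None:
            df["parent_fraction"] = self.parent_fraction
        if self.hematocrit is not None:
            df["hct"] = self.hematocrit
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BloodSampleSet":
        df = pd.read_csv(path)
        required = {"time_min", "wb_kBq_ml", "plasma_kBq_ml"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"blood-sample table missing column(s): {sorted(missing)}")
        pf = df["parent_fraction"].to_numpy() if "parent_fraction" in df else None
        hct = float(df["hct"].iloc[0]) if "hct" in df else None
        return cls(df["time_min"].to_numpy(), df["wb_kBq_ml"].to_numpy(),
                   df["plasma_kBq_ml"].to_numpy(), pf, hct)


@dataclass
class InputFunction:
    """Continuous whole-blood and plasma curves on a uniform 1-s grid.

    When not metabolite-corrected, ``plasma = ratio * whole_blood``
    everywhere on the grid.
    """

    t_s: np.ndarray
    whole_blood: np.ndarray
    plasma: np.ndarray
    ratio: float
    ratio_source: str = "measured-ratio"  # or "hematocrit" / "simulated"
    metabolite_corrected: bool = False

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.whole_blood = np.asarray(self.whole_blood, dtype=float)
        self.plasma = np.asarray(self.plasma, dtype=float)
        dt = np.diff(self.t_s)
        if self.t_s[0] != 0 or not np.allclose(dt, 1.0):
            raise ValueError("input-function grid must start at 0 with uniform 1-s spacing")
        if self.whole_blood.shape != self.t_s.shape or self.plasma.shape != self.t_s.shape:
            raise ValueError("curve arrays must match the grid length")
        if np.any(self.whole_blood < 0) or np.any(self.plasma < 0):
            raise ValueError("input curves must be >= 0")

    @property
    def dt_s(self) -> float:
        return 1.0

    def _sample(self, curve: np.ndarray, t_query_s: np.ndarray, shift_s: float = 0.0) -> np.ndarray:
        """Sample a curve at ``t_query_s - shift_s`` with a zero value before
        injection and constant hold beyond the grid end."""
        t = np.asarray(t_query_s, dtype=float) - shift_s
        return np.interp(t, self.t_s, curve, left=0.0, right=float(curve[-1]))

    def plasma_at(self, t_s, shift_s: float = 0.0) -> np.ndarray:
        return self._sample(self.plasma, t_s, shift_s)

    def whole_blood_at(self, t_s, shift_s: float = 0.0) -> np.ndarray:
        return self._sample(self.whole_blood, t_s, shift_s)

    def shifted(self, shift_s: float) -> "InputFunction":
        """Both curves re-sampled on the native grid at t - shift_s."""
        return replace(
            self,
            whole_blood=self.whole_blood_at(self.t_s, shift_s),
            plasma=self.plasma_at(self.t_s, shift_s),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"t_s": self.t_s, "whole_blood": self.whole_blood, "plasma": self.plasma}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, ratio: float = np.nan, ratio_source: str = "measured-ratio"):
        df = pd.read_csv(path)
        return cls(df["t_s"].to_numpy(), df["whole_blood"].to_numpy(),
                   df["plasma"].to_numpy(), ratio, ratio_source)


def plasma_to_blood_ratio(samples: BloodSampleSet):
    """Average plasma-over-whole-blood activity ratio across manual samples.

    Returns ``(r, per_sample_ratios, cov)`` where ``cov`` is the coefficient
    of variation of the per-sample ratios, so the near-constancy of the
    ratio over the measurement can be inspected.  The mean is unweighted
    over samples.
    """
    if np.any(samples.whole_blood == 0):
        raise ValueError("whole-blood activity of zero: ratio undefined")
    ratios = samples.plasma / samples.whole_blood
    if ratios.size == 1:
        warnings.warn("single blood sample: ratio taken from that sample alone")
        return float(ratios[0]), ratios, 0.0
    r = float(ratios.mean())
    cov = float(ratios.std(ddof=1) / r) if r > 0 else np.nan
    return r, ratios, cov


def ratio_from_hematocrit(hct: float) -> float:
    """Plasma-to-blood ratio r = 1/(1 - Hct) under the cell-exclusion model
    (tracer does not enter blood cells, supported by the constant measured
    ratio)."""
    if not 0 < hct < 1:
        raise ValueError("hematocrit must lie strictly between 0 and 1")
    return 1.0 / (1.0 - hct)


def derive_plasma_input(
    wb_tac: TimeActivityCurve,
    ratio: float,
    grid_end_s: float | None = None,
    ratio_source: str = "measured-ratio",
) -> InputFunction:
    """Build the plasma input function from an image-derived whole-blood TAC.

    The whole-blood TAC (aortic-arch ROI, frame mid-time sampling) is
    linearly interpolated onto a 1-s grid with a (0, 0) anchor at injection
    and constant extrapolation after the last mid-time; the plasma curve is
    the whole-blood curve times ``ratio``.
    """
    if wb_tac.values.size == 0:
        raise ValueError("empty whole-blood TAC")
    if ratio <= 0:
        raise ValueError("plasma-to-blood ratio must be > 0")
    if np.any(wb_tac.values < 0):
        raise ValueError("whole-blood TAC must be nonnegative")
    end = grid_end_s if grid_end_s is not None else wb_tac.schedule.total_duration_s
    t = np.arange(0.0, float(end) + 1.0)
    mids = wb_tac.schedule.mid_times_s
    knots_t = np.concatenate([[0.0], mids])
    knots_v = np.concatenate([[0.0], wb_tac.values])
    wb = np.interp(t, knots_t, knots_v, left=0.0, right=float(wb_tac.values[-1]))
    return InputFunction(t, wb, ratio * wb, float(ratio), ratio_source)


@dataclass
class RichardsParentModel:
    """Generalized-logistic (Richards) model of the plasma parent fraction.

    f(t) = f_inf + (1 - f_inf) * g(t)/g(0), with
    g(t) = (1 + nu * exp(rate * (t - midpoint)))^(-1/nu), t in minutes.

    Normalizing by g(0) pins f(0) = 1 exactly (only parent compound at
    injection).  Defaults reproduce a moderately metabolized tracer with a
    parent fraction near 0.69 at 30 min and 0.60 at 60 min.
    """

    f_inf: float = 0.5639
    rate: float = 0.4169     # 1/min
    midpoint: float = 0.1    # min
    nu: float = 10.0

    def __post_init__(self):
        if not 0 <= self.f_inf <= 1:
            raise ValueError("asymptote f_inf must lie in [0, 1]")
        if self.rate < 0 or self.nu <= 0:
            raise ValueError("rate must be >= 0 and nu > 0")

    def _g(self, t_min):
        z = self.nu * np.exp(np.minimum(self.rate * (np.asarray(t_min, float) - self.midpoint), 500.0))
        return (1.0 + z) ** (-1.0 / self.nu)

    def __call__(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        f = self.f_inf + (1.0 - self.f_inf) * self._g(t) / self._g(0.0)
        return f


@dataclass
class ParentFractionFit:
    model: RichardsParentModel
    residuals: np.ndarray
    rss: float
    degenerate: bool = False

    def __call__(self, t_min):
        return self.model(t_min)


def fit_parent_fraction(samples: BloodSampleSet) -> ParentFractionFit:
    """Least-squares fit of the Richards parent-fraction model to measured
    parent fractions.  Returns the fitted model, residuals and RSS; a
    constant parent fraction of 1 is flagged degenerate (curve = 1)."""
    if samples.parent_fraction is None:
        raise ValueError("samples carry no parent-fraction measurements")
    t, y = samples.time_min, samples.parent_fraction
    if t.size < 4:
        raise ValueError("need at least 4 parent-fraction samples")
    if np.allclose(y, 1.0):
        model = RichardsParentModel(f_inf=1.0)
        return ParentFractionFit(model, y - 1.0, 0.0, degenerate=True)

    def resid(p):
        f_inf, rate, mid, nu = p
        return RichardsParentModel(f_inf, rate, mid, nu)(t) - y

    x0 = np.array([max(min(y.min(), 0.9), 0.05), 0.4, 0.5, 5.0])
    sol = least_squares(
        resid, x0,
        bounds=([0.0, 1e-4, 0.0, 0.05], [1.0, 5.0, 60.0, 50.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(
            f"parent-fraction fit did not converge: last iterate {sol.x}, "
            f"residual norm {np.linalg.norm(sol.fun):.3g}"
        )
    model = RichardsParentModel(*sol.x)
    return ParentFractionFit(model, sol.fun, float(sol.cost * 2))


def apply_parent_correction(input_fn: InputFunction, parent_model) -> InputFunction:
    """Multiply the plasma curve by the parent fraction f(t).

    Provided for comparison only; the default quantification uses the
    uncorrected total-plasma curve.
    """
    f = np.asarray(parent_model(input_fn.t_s / 60.0), dtype=float)
    return replace(input_fn, plasma=input_fn.plasma * f, metabolite_corrected=True)
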