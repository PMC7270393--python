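"""Synthetic dynamic-PET data with the statistical structure the lung
quantification pipeline assumes.

The generator emulates a bolus-injection lung study with an 11C-labelled
reversible tracer: an arterial whole-blood curve with a sharp bolus peak and
multi-exponential washout, a plasma curve at a constant plasma-to-blood
ratio, a slowly declining parent fraction (Richards form), lung tissue
governed by one-tissue kinetics with a fractional blood-volume term, frame
schedules of the printed 38-frame/93-min type, frame-duration and
decay-dependent Gaussian noise, and lognormal between-session parameter
variability for test-retest cohorts.  All randomness flows from a single
seed.

Input-curve shape parameters are illustrative (chosen so that plasma
activity falls rapidly over the first 10 min and slowly thereafter), not
estimates of any particular study's curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import DynamicImage, FrameSchedule, RoiMask, TimeActivityCurve, build_frame_schedule
from .input_function import BloodSampleSet, InputFunction, RichardsParentModel
from .kinetics import (
    C11_LAMBDA_PER_MIN,
    KineticParameters,
    exp_conv,
    frame_average,
    solve_model_tac,
)

__all__ = [
    "ArterialInputParams",
    "CohortSpec",
    "SubjectTruth",
    "Session",
    "Subject",
    "Cohort",
    "PhantomSpec",
    "DEFAULT_SCHEDULE_SPEC",
    "BLOOD_SAMPLE_TIMES_MIN",
    "simulate_arterial_input",
    "simulate_parent_fraction",
    "simulate_lung_tac",
    "add_tac_noise",
    "simulate_test_retest_cohort",
    "simulate_dynamic_phantom",
]

#: The acquisition used throughout: 38 frames, 93 min total.
DEFAULT_SCHEDULE_SPEC = "9x10,2x15,3x20,4x30,4x60,4x180,12x360"

#: Nominal manual arterial sampling times (min).
BLOOD_SAMPLE_TIMES_MIN = (2.5, 5.0, 7.5, 10.0, 15.0, 20.0, 30.0, 45.0, 90.0)


@dataclass(frozen=True)
class ArterialInputParams:
    """Bolus arterial whole-blood curve: exponential rise times
    multi-exponential washout,

        Cwb(t) = A (1 - exp(-rise t)) * sum_i w_i exp(-mu_i t),  t >= 0,

    zero before injection.  ``ratio`` is the constant plasma-to-blood
    activity ratio applied to obtain the plasma curve.
    """

    amplitude: float = 60.0                       # kBq/cm3 scale
    rise_rate: float = 6.0                        # 1/min
    washout_rates: tuple = (2.0, 0.25, 0.015)     # 1/min
    washout_fracs: tuple = (0.70, 0.20, 0.10)
    ratio: float = 1.71

    def __post_init__(self):
        if self.amplitude < 0 or self.rise_rate < 0 or self.ratio <= 0:
            raise ValueError("input-curve parameters must be nonnegative (ratio > 0)")
        if any(r < 0 for r in self.washout_rates) or any(w < 0 for w in self.washout_fracs):
            raise ValueError("washout rates and fractions must be >= 0")
        if len(self.washout_rates) != len(self.washout_fracs):
            raise ValueError("washout_rates and washout_fracs must have equal length")

    def whole_blood(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        rise = 1.0 - np.exp(-self.rise_rate * np.clip(t, 0, None))
        tail = sum(
            w * np.exp(-mu * np.clip(t, 0, None))
            for w, mu in zip(self.washout_fracs, self.washout_rates)
        )
        return np.where(t > 0, self.amplitude * rise * tail, 0.0)


def simulate_arterial_input(params: ArterialInputParams, grid_s: np.ndarray) -> InputFunction:
    """Evaluate the bolus model on a 1-s grid; plasma = ratio * whole blood."""
    grid_s = np.asarray(grid_s, dtype=float)
    wb = params.whole_blood(grid_s / 60.0)
    return InputFunction(grid_s, wb, params.ratio * wb, params.ratio, ratio_source="simulated")


def simulate_parent_fraction(model: RichardsParentModel, t_min) -> np.ndarray:
    """Parent fraction f(t) on the given times; values validated to [0, 1]."""
    f = model(t_min)
    if np.any((f < -1e-12) | (f > 1 + 1e-12)):
        raise ValueError("parent-fraction parameters produce values outside [0, 1]")
    return np.clip(f, 0.0, 1.0)


def simulate_lung_tac(
    truth: KineticParameters,
    input_fn: InputFunction,
    schedule: FrameSchedule,
    convention: str = "volume",
) -> TimeActivityCurve:
    """Noiseless lung TAC: forward compartment solution, frame-averaged."""
    values = solve_model_tac(truth, input_fn, schedule, convention)
    return TimeActivityCurve(schedule, values, label="lung")


def add_tac_noise(tac: TimeActivityCurve, scale: float, seed) -> TimeActivityCurve:
    """Gaussian frame noise with variance ~ scale^2 * value * exp(lambda t) /
    duration — the community-standard frame-weighting heuristic (count
    statistics corrected for 11C decay and frame length).  Values are not
    clipped and may go slightly negative."""
    if scale < 0:
        raise ValueError("noise scale must be >= 0")
    if scale == 0:
        return replace(tac)
    rng = np.random.default_rng(seed)
    t_min = tac.schedule.mid_times_min
    dur_min = tac.schedule.frame_duration / 60.0
    var = scale ** 2 * np.clip(tac.values, 0, None) * np.exp(C11_LAMBDA_PER_MIN * t_min) / dur_min
    noisy = tac.values + rng.standard_normal(tac.values.size) * np.sqrt(var)
    return TimeActivityCurve(tac.schedule, noisy, tac.label, tac.units)


@dataclass
class SubjectTruth:
    """Ground-truth generating quantities for one session."""

    params: KineticParameters
    hematocrit: float
    ratio: float
    input_params: ArterialInputParams
    parent_model: RichardsParentModel = field(default_factory=RichardsParentModel)

    def __post_init__(self):
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must lie in (0, 1)")


@dataclass
class Session:
    truth: SubjectTruth
    input_fn: InputFunction
    tac: TimeActivityCurve            # noisy (equals noiseless when scale = 0)
    tac_noiseless: TimeActivityCurve
    blood_samples: BloodSampleSet


@dataclass
class Subject:
    subject_id: int
    sessions: list


@dataclass
class Cohort:
    spec: "CohortSpec"
    subjects: list

    @property
    def n_sessions(self) -> int:
        return sum(len(s.sessions) for s in self.subjects)


@dataclass(frozen=True)
class CohortSpec:
    """Test-retest cohort design.

    Between-session variability multiplies each kinetic parameter by an
    independent lognormal factor with the given coefficient of variation;
    parameter ranges are the observed lung one-tissue ranges (K1
    0.02-0.05 ml/cm3/min, k2 0.01-0.02 1/min, Vb 0.05-0.27).
    """

    n_subjects: int = 6
    sessions_per_subject: int = 2
    param_cov: float = 0.07
    noise_scale: float = 0.05
    blood_sample_cov: float = 0.0
    seed: int = 0
    k1_range: tuple = (0.02, 0.05)
    k2_range: tuple = (0.01, 0.02)
    vb_range: tuple = (0.05, 0.27)
    delta_range_s: tuple = (0.0, 10.0)
    hct_mean: float = 0.44
    hct_sd: float = 0.03
    schedule_spec: str = DEFAULT_SCHEDULE_SPEC

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.param_cov < 0 or self.noise_scale < 0:
            raise ValueError("CoV and noise scale must be >= 0")


def _lognormal_factor(rng, cov: float) -> float:
    if cov == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cov ** 2))
    return float(np.exp(sigma * rng.standard_normal()))


def simulate_test_retest_cohort(spec: CohortSpec) -> Cohort:
    """Generate per-subject, per-session truths, input functions, lung TACs
    and manual blood-sample tables.

    Session 2+ kinetic parameters are session-1 values times independent
    lognormal perturbations with CoV ``spec.param_cov``.  The plasma-to-
    blood ratio derives from the subject's hematocrit (cell-exclusion
    model, r = 1/(1 - Hct)), so hematocrit- and sample-based ratio
    estimates agree by construction.
    """
    rng = np.random.default_rng(spec.seed)
    schedule = build_frame_schedule(spec.schedule_spec)
    grid_s = np.arange(0.0, schedule.total_duration_s + 61.0)  # 1 min margin for shifts
    parent = RichardsParentModel()
    subjects = []
    for sid in range(spec.n_subjects):
        hct = float(np.clip(rng.normal(spec.hct_mean, spec.hct_sd), 0.2, 0.6))
        ratio = 1.0 / (1.0 - hct)
        base = KineticParameters(
            k1=float(rng.uniform(*spec.k1_range)),
            k2=float(rng.uniform(*spec.k2_range)),
            vb=float(rng.uniform(*spec.vb_range)),
            delta_s=float(rng.uniform(*spec.delta_range_s)),
        )
        base_input = ArterialInputParams(
            amplitude=float(rng.uniform(45.0, 75.0)), ratio=ratio
        )
        sessions = []
        for sess in range(spec.sessions_per_subject):
            if sess == 0:
                p = base
                inp_par = base_input
            else:
                p = KineticParameters(
                    k1=base.k1 * _lognormal_factor(rng, spec.param_cov),
                    k2=base.k2 * _lognormal_factor(rng, spec.param_cov),
                    vb=min(base.vb * _lognormal_factor(rng, spec.param_cov), 0.9),
                    delta_s=base.delta_s,
                )
                inp_par = replace(
                    base_input,
                    amplitude=base_input.amplitude * _lognormal_factor(rng, spec.param_cov),
                )
            input_fn = simulate_arterial_input(inp_par, grid_s)
            truth = SubjectTruth(p, hct, ratio, inp_par, parent)
            tac0 = simulate_lung_tac(p, input_fn, schedule)
            tac = add_tac_noise(tac0, spec.noise_scale, rng)
            samples = _blood_sample_table(truth, rng, spec.blood_sample_cov)
            sessions.append(Session(truth, input_fn, tac, tac0, samples))
        subjects.append(Subject(sid, sessions))
    return Cohort(spec, subjects)


def _blood_sample_table(truth: SubjectTruth, rng, cov: float) -> BloodSampleSet:
    t = np.asarray(BLOOD_SAMPLE_TIMES_MIN)
    wb = truth.input_params.whole_blood(t)
    plasma = truth.ratio * wb
    if cov > 0:
        wb = wb * np.exp(np.sqrt(np.log1p(cov ** 2)) * rng.standard_normal(t.size))
        plasma = plasma * np.exp(np.sqrt(np.log1p(cov ** 2)) * rng.standard_normal(t.size))
    pf = simulate_parent_fraction(truth.parent_model, t)
    return BloodSampleSet(t, wb, plasma, pf, truth.hematocrit)


# ---------------------------------------------------------------------------
# 4-D phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Schematic desk-scale thorax: two lung ellipsoids, an aorta tube and
    excluded heart/liver blocks on a small grid.

    Voxel-wise blood volume follows a periphery-to-hilum gradient; K1 and
    V_T follow an apex-to-base gradient (lowest at the apex, highest
    basally).  ``gradient_amplitude`` = 0 collapses every lung voxel to the
    mid-range parameter values.
    """

    shape: tuple = (32, 32, 24)
    voxel_size_mm: tuple = (10.0, 10.0, 10.0)
    k1_range: tuple = (0.02, 0.05)
    vt_range: tuple = (1.8, 3.8)
    vb_range: tuple = (0.05, 0.27)
    gradient_amplitude: float = 1.0
    noise_scale: float = 0.0
    seed: int = 0

    labels = {"lung": 1, "aorta": 2, "heart": 3, "liver": 4}


def _phantom_masks(shape):
    nx, ny, nz = shape
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    lungs = []
    for cx in (9.5, 22.5):
        e = ((x - cx) / 5.0) ** 2 + ((y - 16.0) / 7.0) ** 2 + ((z - 11.5) / 8.5) ** 2 < 1.0
        lungs.append(e)
    lung = lungs[0] | lungs[1]
    aorta = (((x - 16.0) ** 2 + (y - 6.0) ** 2) < 1.6 ** 2) & (z >= 4) & (z <= 20)
    heart = (x >= 15) & (x <= 17) & (y >= 12) & (y <= 20) & (z >= 3) & (z <= 10)
    liver = (z <= 1) & (x >= 4) & (x <= 27) & (y >= 9) & (y <= 23)
    masks = {"lung": lung, "aorta": aorta, "heart": heart, "liver": liver}
    total = np.zeros(shape, dtype=int)
    for m in masks.values():
        total += m.astype(int)
    if total.max() > 1:
        raise ValueError("phantom region masks overlap")
    return masks, (x, y, z)


def frame_averaged_exp_conv_many(
    input_values: np.ndarray, t_s: np.ndarray, thetas_per_min: np.ndarray,
    schedule: FrameSchedule, chunk: int = 256,
) -> np.ndarray:
    """Frame-averaged convolution of a piecewise-linear input with
    exp(-theta t) for many exponents; returns (n_theta, n_frames)."""
    thetas = np.atleast_1d(np.asarray(thetas_per_min, dtype=float))
    out = np.empty((thetas.size, schedule.n_frames))
    for i0 in range(0, thetas.size, chunk):
        for j, th in enumerate(thetas[i0 : i0 + chunk]):
            conv = exp_conv(input_values, 1.0 / 60.0, th)
            out[i0 + j] = frame_average(conv, t_s, schedule)
    return out


def simulate_dynamic_phantom(
    spec: PhantomSpec,
    input_fn: InputFunction | None = None,
    schedule: FrameSchedule | None = None,
):
    """Build a 4-D dynamic phantom.

    Returns ``(DynamicImage, RoiMask, truth)`` where ``truth`` holds the
    generating parameter volumes (``k1``, ``k2``, ``vb``, ``vt``; NaN
    outside lung).  Aorta voxels carry the frame-averaged whole-blood
    curve; heart and liver blocks carry high-uptake curves and are meant
    to be excluded from voxel-wise analysis.
    """
    if schedule is None:
        schedule = build_frame_schedule(DEFAULT_SCHEDULE_SPEC)
    if input_fn is None:
        grid_s = np.arange(0.0, schedule.total_duration_s + 1.0)
        input_fn = simulate_arterial_input(ArterialInputParams(), grid_s)
    masks, (x, y, z) = _phantom_masks(spec.shape)
    lung = masks["lung"]
    n_lung = int(lung.sum())

    # apex (high z) -> base (low z) gradient in [0, 1]
    zmax = spec.shape[2] - 1.0
    g_base = 1.0 - z[lung] / zmax
    g_base = (g_base - g_base.min()) / (g_base.max() - g_base.min())
    # periphery -> hilum gradient: hilum = medial edge of each lung at mid-height
    d_left = np.sqrt((x[lung] - 14.0) ** 2 + (y[lung] - 16.0) ** 2 + (z[lung] - 11.5) ** 2)
    d_right = np.sqrt((x[lung] - 18.0) ** 2 + (y[lung] - 16.0) ** 2 + (z[lung] - 11.5) ** 2)
    d = np.minimum(d_left, d_right)
    g_hilum = 1.0 - (d - d.min()) / (d.max() - d.min())

    def ramp(rng_pair, g):
        lo, hi = rng_pair
        mid = 0.5 * (lo + hi)
        return mid + spec.gradient_amplitude * (lo + (hi - lo) * g - mid)

    k1 = ramp(spec.k1_range, g_base)
    vt = ramp(spec.vt_range, g_base)
    vb = ramp(spec.vb_range, g_hilum)
    k2 = k1 / vt

    t_s = input_fn.t_s
    wb_frames = frame_average(input_fn.whole_blood, t_s, schedule)
    tis = frame_averaged_exp_conv_many(input_fn.plasma, t_s, k2, schedule)
    lung_tacs = (1.0 - vb)[:, None] * k1[:, None] * tis + vb[:, None] * wb_frames[None, :]

    data = np.zeros(spec.shape + (schedule.n_frames,))
    data[lung] = lung_tacs
    data[masks["aorta"]] = wb_frames
    data[masks["heart"]] = 4.0 * wb_frames
    data[masks["liver"]] = 3.0 * wb_frames
    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        t_min = schedule.mid_times_min
        dur_min = schedule.frame_duration / 60.0
        var = (
            spec.noise_scale ** 2
            * np.clip(data, 0, None)
            * np.exp(C11_LAMBDA_PER_MIN * t_min)
            / dur_min
        )
        body = np.zeros(spec.shape, dtype=bool)
        for m in masks.values():
            body |= m
        noise = rng.standard_normal(data.shape) * np.sqrt(var)
        data[body] += noise[body]

    label_vol = np.zeros(spec.shape, dtype=np.int16)
    for name, m in masks.items():
        label_vol[m] = PhantomSpec.labels[name]
    img = DynamicImage(data, spec.voxel_size_mm, schedule)
    mask = RoiMask(label_vol, dict(PhantomSpec.labels))

    def vol(values):
        v = np.full(spec.shape, np.nan)
        v[lung] = values
        return v

    truth = {
        "k1": vol(k1), "k2": vol(k2), "vb": vol(vb), "vt": vol(vt),
        "n_lung_voxels": n_lung, "input_fn": input_fn, "schedule": schedule,
    }
    return img, mask, truth
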