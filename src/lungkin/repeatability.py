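"""Test-retest reliability and time-stability of V_T estimates.

Absolute variability per subject:

    VAR = |V_T(test) - V_T(retest)| / mean(test, retest) * 100  (percent)

— symmetric in the pair and scale-invariant.  Reliability across subjects
uses the one-way random-effects intraclass correlation ICC(1,1) from the
two-measurement ANOVA decomposition (the standard choice for PET
test-retest; a two-way consistency variant ICC(3,1) is available).

Time stability truncates the TACs to shorter acquisition durations, refits
each method, and reports medians across subjects of the V_T ratio to the
full-duration reference and of the recomputed test-retest VAR.  Medians
are used throughout the cohort summaries because test-retest samples are
small.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import TimeActivityCurve
from .depict import DepictModel, build_basis_table
from .input_function import InputFunction
from .kinetics import OneTissueModel, TwoTissueModel
from .logan import MultilinearLogan, blood_volume_corrected_tac

__all__ = [
    "var_percent",
    "icc_oneway",
    "icc_consistency",
    "estimate_vt",
    "build_test_retest_table",
    "cohort_summary_table",
    "time_stability_analysis",
]

METHODS = ("1TCM", "2TCM", "MLLogan", "DEPICT")


def var_percent(test, retest):
    """Absolute variability (%): |test - retest| / mean of the two * 100."""
    t = np.asarray(test, dtype=float)
    r = np.asarray(retest, dtype=float)
    if np.any(t <= 0) or np.any(r <= 0):
        raise ValueError("VAR requires strictly positive test and retest values")
    out = np.abs(t - r) / ((t + r) / 2.0) * 100.0
    return float(out) if out.ndim == 0 else out


def _icc_anova(test, retest):
    t = np.asarray(test, dtype=float)
    r = np.asarray(retest, dtype=float)
    if t.shape != r.shape or t.ndim != 1 or t.size < 2:
        raise ValueError("need paired 1-D vectors with n >= 2")
    n, k = t.size, 2
    data = np.column_stack([t, r])
    subj_mean = data.mean(axis=1)
    grand = data.mean()
    msb = k * np.sum((subj_mean - grand) ** 2) / (n - 1)
    msw = np.sum((data - subj_mean[:, None]) ** 2) / (n * (k - 1))
    return n, k, data, subj_mean, grand, msb, msw


def icc_oneway(test, retest) -> float:
    """One-way random-effects ICC(1,1): (MSB - MSW)/(MSB + (k-1) MSW) for
    k = 2 repeated measurements."""
    n, k, *_, msb, msw = _icc_anova(test, retest)
    denom = msb + (k - 1) * msw
    if denom == 0:
        warnings.warn("zero total variance: ICC undefined")
        return np.nan
    return float((msb - msw) / denom)


def icc_consistency(test, retest) -> float:
    """Two-way mixed consistency ICC(3,1): session means removed."""
    n, k, data, subj_mean, grand, msb, _ = _icc_anova(test, retest)
    sess_mean = data.mean(axis=0)
    mse = (
        np.sum((data - subj_mean[:, None] - sess_mean[None, :] + grand) ** 2)
        / ((n - 1) * (k - 1))
    )
    denom = msb + (k - 1) * mse
    if denom == 0:
        warnings.warn("zero total variance: ICC undefined")
        return np.nan
    return float((msb - mse) / denom)


def _estimate_vt_methods(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    methods,
    t_star_min: float = 10.0,
    n_basis: int = 100,
    **fit_kwargs,
) -> dict:
    """V_T per method for one TAC, sharing a single 1TCM reference fit.

    MLLogan and DEPICT run after the 1TCM fit supplies the fractional
    blood volume and time shift: MLLogan analyses the blood-volume-
    corrected tissue TAC (so its V_T sits on the compartment-model scale),
    and the DEPICT basis is built with the fitted time shift.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s) {sorted(unknown)}; choose from {METHODS}")
    out = {}
    ref = None
    if {"1TCM", "MLLogan", "DEPICT"} & set(methods):
        ref = OneTissueModel(tac, input_fn, **fit_kwargs).fit()
    if "1TCM" in methods:
        out["1TCM"] = ref.vt
    if "2TCM" in methods:
        out["2TCM"] = TwoTissueModel(tac, input_fn, **fit_kwargs).fit().vt
    if "MLLogan" in methods:
        tissue = blood_volume_corrected_tac(
            tac, input_fn, ref.params.vb, ref.params.delta_s, ref.convention
        )
        out["MLLogan"] = MultilinearLogan(tissue, input_fn, t_star_min).fit().vt
    if "DEPICT" in methods:
        basis = build_basis_table(input_fn, tac.schedule, n_basis=n_basis,
                                  delta_s=ref.params.delta_s)
        out["DEPICT"] = DepictModel(tac, basis).fit().vt
    return out


def estimate_vt(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    method: str,
    t_star_min: float = 10.0,
    n_basis: int = 100,
    **fit_kwargs,
) -> float:
    """Fit one TAC with one method and return V_T (ml/cm3)."""
    return _estimate_vt_methods(tac, input_fn, (method,), t_star_min, n_basis,
                                **fit_kwargs)[method]


def build_test_retest_table(
    cohort,
    methods=("1TCM", "MLLogan"),
    duration_min: float | None = None,
    t_star_min: float = 10.0,
) -> pd.DataFrame:
    """One row per subject x method: V_T at test and retest (optionally on
    truncated TACs).  Subjects without both sessions are dropped with a
    log entry."""
    rows = []
    for subject in cohort.subjects:
        if len(subject.sessions) < 2:
            warnings.warn(f"subject {subject.subject_id}: incomplete pair dropped")
            continue
        vts = []
        for session in subject.sessions[:2]:
            tac = session.tac
            if duration_min is not None:
                tac = tac.truncate(duration_min)
            vts.append(_estimate_vt_methods(tac, session.input_fn, methods, t_star_min))
        for method in methods:
            rows.append(
                {
                    "subject": subject.subject_id,
                    "method": method,
                    "vt_test": vts[0][method],
                    "vt_retest": vts[1][method],
                    "duration_min": duration_min or subject.sessions[0].tac.schedule.total_duration_min,
                }
            )
    return pd.DataFrame(rows)


def cohort_summary_table(trt: pd.DataFrame) -> pd.DataFrame:
    """Summary per method x duration: mean +/- SD of test and retest V_T,
    mean (min-max) and median VAR, ICC, and n."""
    required = {"subject", "method", "vt_test", "vt_retest", "duration_min"}
    missing = required - set(trt.columns)
    if missing:
        raise ValueError(f"test-retest table missing column(s): {sorted(missing)}")
    out = []
    for (method, dur), grp in trt.groupby(["method", "duration_min"]):
        n = len(grp)
        if n < 2:
            warnings.warn(f"{method} @ {dur} min: fewer than 2 pairs, ICC not estimable")
        v = var_percent(grp["vt_test"].to_numpy(), grp["vt_retest"].to_numpy())
        v = np.atleast_1d(v)
        out.append(
            {
                "method": method,
                "duration_min": dur,
                "n": n,
                "vt_test_mean": grp["vt_test"].mean(),
                "vt_test_sd": grp["vt_test"].std(ddof=1),
                "vt_retest_mean": grp["vt_retest"].mean(),
                "vt_retest_sd": grp["vt_retest"].std(ddof=1),
                "var_mean": v.mean(),
                "var_min": v.min(),
                "var_max": v.max(),
                "var_median": np.median(v),
                "icc": icc_oneway(grp["vt_test"], grp["vt_retest"]) if n >= 2 else np.nan,
            }
        )
    return pd.DataFrame(out)


def time_stability_analysis(
    cohort,
    methods=("1TCM", "MLLogan"),
    durations_min=(30, 40, 50, 60, 70, 80, 90),
    t_star_min: float = 10.0,
    min_frames: int = 5,
) -> pd.DataFrame:
    """Progressive-truncation analysis of V_T stability and repeatability.

    For each duration, the TACs are truncated to the frames ending within
    it, each method refit, and two statistics summarized across subjects
    with the median: the V_T ratio to the subject's full-duration
    (reference) estimate, and the test-retest VAR recomputed at that
    duration.  The full duration itself is always included as reference.
    """
    full_min = cohort.subjects[0].sessions[0].tac.schedule.total_duration_min
    durations = sorted(set(float(d) for d in durations_min) | {full_min})
    # per subject/session/method V_T at each duration
    records = []
    for subject in cohort.subjects:
        if len(subject.sessions) < 2:
            warnings.warn(f"subject {subject.subject_id}: incomplete pair dropped")
            continue
        for si, session in enumerate(subject.sessions[:2]):
            for dur in durations:
                try:
                    tac = session.tac.truncate(dur)
                except ValueError:
                    continue
                if tac.schedule.n_frames < min_frames:
                    warnings.warn(f"duration {dur} min leaves <{min_frames} frames; skipped")
                    continue
                vts = _estimate_vt_methods(tac, session.input_fn, methods, t_star_min)
                for method in methods:
                    records.append(
                        {"subject": subject.subject_id, "session": si, "method": method,
                         "duration_min": dur, "vt": vts[method]}
                    )
    df = pd.DataFrame(records)
    ref = (
        df[df["duration_min"] == full_min]
        .set_index(["subject", "session", "method"])["vt"]
        .rename("vt_ref")
    )
    df = df.join(ref, on=["subject", "session", "method"])
    df["vt_ratio"] = df["vt"] / df["vt_ref"]

    out = []
    for (method, dur), grp in df.groupby(["method", "duration_min"]):
        wide = grp.pivot_table(index="subject", columns="session", values="vt")
        pairs = wide.dropna()
        var = var_percent(pairs[0].to_numpy(), pairs[1].to_numpy()) if len(pairs) else np.nan
        out.append(
            {
                "method": method,
                "duration_min": dur,
                "vt_mean": grp["vt"].mean(),
                "vt_ratio_median": grp["vt_ratio"].median(),
                "abs_dev_pct_median": (100.0 * (grp["vt_ratio"] - 1.0).abs()).median(),
                "var_median": float(np.median(np.atleast_1d(var))),
                "n_sessions": len(grp),
            }
        )
    return pd.DataFrame(out).sort_values(["method", "duration_min"]).reset_index(drop=True)
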