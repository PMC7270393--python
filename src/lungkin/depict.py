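"""Data-driven voxel-wise parametric imaging on an exponential basis.

Each voxel TAC is modelled as a nonnegative combination of basis curves

    C(t) ~ sum_j phi_j * [Cp(. - delta) (*) exp(-theta_j t)]  +  phi_b * Cwb,

with exponents theta_j logarithmically spaced between 0.0034 1/min (10% of
the 11C decay constant ln2/20.4) and 0.6 1/min.  The number of distinct
kinetic tissue compartments needed — the model order (MO) — is estimated
from the data: a nonnegative L1-regularized path over a decreasing penalty
proposes candidate supports, each candidate is refit by unpenalized
nonnegative least squares (so the coefficients feeding V_T are unbiased),
and the support minimizing the Gaussian-RSS AIC wins.  Adjacent selected
grid nodes are merged when counting compartments, so grid-discretization
doublets straddling an off-grid rate are not counted twice.

Outputs per voxel: fractional blood volume Vb = phi_b, model order MO,
K1 = sum phi_j and V_T = sum phi_j / theta_j.  Under the volume-conserving
blood convention (the default of the compartment fits) the tissue
coefficients absorb a (1 - Vb) factor, so K1 and V_T are rescaled by
1/(1 - Vb) to sit on the compartment-model scale; the raw coefficient sums
are kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.linear_model import lasso_path

from .core import DynamicImage, FrameSchedule, RoiMask, TimeActivityCurve
from .input_function import InputFunction
from .kinetics import C11_LAMBDA_PER_MIN, exp_conv, frame_average

__all__ = [
    "BasisTable",
    "DepictVoxelResults",
    "ParametricImageSet",
    "DepictModel",
    "default_theta_min",
    "build_basis_table",
    "depict_parametric_images",
    "summarize_roi",
]


def default_theta_min() -> float:
    """Slowest basis exponent: 10% of the 11C decay constant, ln2/20.4 min
    half-life — 0.0034 1/min to two significant figures."""
    return 0.1 * C11_LAMBDA_PER_MIN


DEFAULT_THETA_MAX = 0.6  # 1/min


@dataclass
class BasisTable:
    """Frame-averaged exponential basis plus the whole-blood column."""

    thetas: np.ndarray            # 1/min, ascending
    tissue: np.ndarray            # (n_frames, J)
    blood: np.ndarray             # (n_frames,)
    schedule: FrameSchedule
    delta_s: float = 0.0

    @property
    def n_basis(self) -> int:
        return self.thetas.size

    @property
    def design(self) -> np.ndarray:
        """Full design matrix [tissue columns | blood column]."""
        return np.column_stack([self.tissue, self.blood])


def build_basis_table(
    input_fn: InputFunction,
    schedule: FrameSchedule,
    n_basis: int = 100,
    theta_min: float | None = None,
    theta_max: float = DEFAULT_THETA_MAX,
    delta_s: float = 0.0,
) -> BasisTable:
    """Exact frame averages of the analytic convolution of the piecewise-
    linear plasma input with exp(-theta_j t), for J log-spaced exponents."""
    tmin = default_theta_min() if theta_min is None else float(theta_min)
    if tmin <= 0 or tmin >= theta_max:
        raise ValueError("need 0 < theta_min < theta_max")
    if n_basis < 1:
        raise ValueError("need at least one basis exponent")
    thetas = np.geomspace(tmin, theta_max, n_basis)
    t_s = input_fn.t_s
    cp = input_fn.plasma_at(t_s, delta_s)
    wb = input_fn.whole_blood_at(t_s, delta_s)
    cols = np.empty((schedule.n_frames, n_basis))
    for j, th in enumerate(thetas):
        cols[:, j] = frame_average(exp_conv(cp, 1.0 / 60.0, th), t_s, schedule)
    blood = frame_average(wb, t_s, schedule)
    return BasisTable(thetas, cols, blood, schedule, delta_s)


# Relative RSS below which residuals are numerical noise: AIC comparisons on
# smaller RSS values would reward meaningless refinement of an exact fit.
_RSS_FLOOR_REL = 1e-12
# Tissue components carrying less than this fraction of the coefficient mass
# are numerical dust and are not counted toward the model order.
_MO_MASS_TOL = 1e-3


@dataclass
class DepictVoxelResults:
    """Sparse-basis fit of one voxel (or ROI) TAC."""

    coef: np.ndarray              # phi_j >= 0 on the exponent grid
    vb: float                     # blood coefficient phi_b
    mo: int                       # merged count of tissue components
    k1: float                     # ml/cm3/min, blood-convention corrected
    vt: float                     # ml/cm3, blood-convention corrected
    k1_raw: float                 # sum phi_j
    vt_raw: float                 # sum phi_j / theta_j
    rss: float
    aic: float
    thetas: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        sup = np.flatnonzero(self.coef > 0)
        lines = [
            f"DEPICT voxel fit: MO = {self.mo}, Vb = {self.vb:.3f}",
            f"  K1 = {self.k1:.4g} ml/cm3/min   V_T = {self.vt:.4g} ml/cm3",
            f"  active exponents (1/min): "
            + ", ".join(f"{self.thetas[j]:.4g}" for j in sup),
        ]
        return "\n".join(lines)


def _merged_components(support: np.ndarray, coef: np.ndarray) -> int:
    """Count tissue components: chains of adjacent grid nodes merge into
    one; components below the mass tolerance are not counted."""
    if support.size == 0:
        return 0
    groups = np.split(support, np.flatnonzero(np.diff(support) > 1) + 1)
    total = coef[support].sum()
    return sum(1 for g in groups if coef[g].sum() > _MO_MASS_TOL * total)


class DepictModel:
    """Sparse nonnegative exponential-basis model for one TAC.

    ``fit()`` solves a positive-lasso path, refits every candidate support
    by nonnegative least squares (blood column always available), and picks
    the support with minimal AIC.
    """

    def __init__(
        self,
        tac: TimeActivityCurve,
        basis: BasisTable,
        blood_convention: str = "volume",
        n_alphas: int = 30,
        alpha_eps: float = 1e-4,
    ):
        if tac.schedule.n_frames != basis.schedule.n_frames:
            raise ValueError("TAC and basis table must share the frame schedule")
        self.tac = tac
        self.basis = basis
        self.blood_convention = blood_convention
        self.n_alphas = n_alphas
        self.alpha_eps = alpha_eps

    def fit(self) -> DepictVoxelResults:
        y = self.tac.values
        B = self.basis.tissue
        blood = self.basis.blood
        J = self.basis.n_basis
        n = y.size
        if not np.any(y != 0):
            return self._pack(np.zeros(J), 0.0, 0.0, -np.inf)

        A = self.basis.design
        # The positive-lasso path only proposes candidate supports (the
        # final coefficients come from the exact NNLS refits), so loose
        # convergence of the coordinate descent is acceptable.
        import warnings as _warnings

        from sklearn.exceptions import ConvergenceWarning
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = lasso_path(
                A, y, alphas=self.n_alphas, eps=self.alpha_eps, positive=True,
                tol=1e-3, max_iter=1000,
            )
        candidates: list[tuple] = [()]
        seen = {()}
        for k in range(coefs.shape[1]):
            sup = tuple(np.flatnonzero(coefs[:J, k] > 0))
            if sup not in seen:
                seen.add(sup)
                candidates.append(sup)

        scale = float(np.sum(y * y))
        floor = _RSS_FLOOR_REL * max(scale, 1e-300)
        best = None
        for sup in candidates:
            cols = np.column_stack([B[:, list(sup)], blood]) if sup else blood[:, None]
            try:
                sol, _ = nnls(cols, y)
            except RuntimeError:
                continue
            r = y - cols @ sol
            rss = max(float(r @ r), floor)
            p = len(sup) + 1
            aic = n * np.log(rss / n) + 2 * p
            if best is None or aic < best[0]:
                full = np.zeros(J)
                if sup:
                    full[list(sup)] = sol[:-1]
                best = (aic, full, float(sol[-1]), rss)
        aic, coef, phi_b, rss = best
        return self._pack(coef, phi_b, rss, aic)

    def _pack(self, coef, phi_b, rss, aic) -> DepictVoxelResults:
        thetas = self.basis.thetas
        support = np.flatnonzero(coef > 0)
        mo = _merged_components(support, coef)
        k1_raw = float(coef.sum())
        vt_raw = float(np.sum(coef / thetas)) if support.size else 0.0
        if self.blood_convention == "volume" and phi_b < 1.0:
            corr = 1.0 / (1.0 - phi_b)
        else:
            corr = 1.0
        return DepictVoxelResults(
            coef=coef, vb=float(phi_b), mo=mo,
            k1=k1_raw * corr, vt=vt_raw * corr,
            k1_raw=k1_raw, vt_raw=vt_raw, rss=rss, aic=float(aic), thetas=thetas,
        )


@dataclass
class ParametricImageSet:
    """Voxel-wise Vb, K1, V_T and model-order volumes on the PET grid.
    Excluded voxels carry NaN."""

    vb: np.ndarray
    k1: np.ndarray
    vt: np.ndarray
    mo: np.ndarray

    def to_nifti(self, out_dir, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
        import os

        import nibabel as nib

        affine = np.diag(list(voxel_size_mm) + [1.0])
        os.makedirs(out_dir, exist_ok=True)
        for name in ("vb", "k1", "vt", "mo"):
            nib.save(
                nib.Nifti1Image(getattr(self, name), affine),
                os.path.join(out_dir, f"{name}.nii.gz"),
            )


def depict_parametric_images(
    img: DynamicImage,
    mask: RoiMask,
    basis: BasisTable,
    include_labels=("lung",),
    blood_convention: str = "volume",
    log_every: int = 0,
) -> ParametricImageSet:
    """Per-voxel basis fits over the included labels; everything else
    (background, heart, liver, ...) is set to NaN."""
    include_values = {mask.resolve(l) for l in include_labels}
    sel = np.isin(mask.data, list(include_values))
    if not np.any(sel):
        raise ValueError("inclusion mask selects no voxels")
    shape = img.data.shape[:3]
    out = {k: np.full(shape, np.nan) for k in ("vb", "k1", "vt", "mo")}
    idx = np.argwhere(sel)
    for i, (x, y, z) in enumerate(idx):
        tac = TimeActivityCurve(img.schedule, img.data[x, y, z], label="voxel")
        res = DepictModel(tac, basis, blood_convention=blood_convention).fit()
        out["vb"][x, y, z] = res.vb
        out["k1"][x, y, z] = res.k1
        out["vt"][x, y, z] = res.vt
        out["mo"][x, y, z] = res.mo
        if log_every and (i + 1) % log_every == 0:
            import sys

            print(f"depict: {i + 1}/{idx.shape[0]} voxels", file=sys.stderr)
    return ParametricImageSet(**out)


def summarize_roi(images: ParametricImageSet, mask: RoiMask, label) -> dict:
    """ROI summary: means of the continuous maps, median of MO, voxel count
    (voxels excluded from the voxel-wise estimation are skipped)."""
    value = mask.resolve(label)
    sel = (mask.data == value) & np.isfinite(images.vt)
    if not np.any(sel):
        raise ValueError(f"label {label!r} has no analysed voxels")
    return {
        "vb_mean": float(np.mean(images.vb[sel])),
        "k1_mean": float(np.mean(images.k1[sel])),
        "vt_mean": float(np.mean(images.vt[sel])),
        "mo_median": float(np.median(images.mo[sel])),
        "n_voxels": int(sel.sum()),
    }
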