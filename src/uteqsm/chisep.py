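"""Sign-constrained separation of para- and diamagnetic susceptibility.

A voxel may contain paramagnetic (iron-like, chi > 0) and diamagnetic
(calcium/myelin-like, chi < 0) sources at once.  The dipole field only
senses their *sum*, so mixed voxels cancel and conventional QSM
underestimates both.  The reversible relaxation rate R2' = R2* - R2, by
contrast, senses the *total* susceptibility content: in the static
dephasing regime R2' ~ D_r * (chi_para - chi_dia) with a relaxometric
constant D_r (1/s per ppm).  Jointly fitting both observations splits
the sources:

    min  lambda_field * || W  ( b  - D * (chi_p + chi_d) ) ||^2
       + lambda_relax * || W' ( R2' - D_r (chi_p - chi_d) ) ||^2
       + lambda_reg   * R(chi_p, chi_d)
    s.t. chi_p >= 0,  chi_d <= 0,

where ``b`` is the local field (ppm) and ``D *`` the dipole convolution.
The solver is an alternating projected gradient descent with
backtracking, which keeps every iterate sign-feasible and the objective
monotonically non-increasing.

R2 itself is rarely measurable in short-T2 tissue, so by default R2' is
estimated from R2* through an assumed linear proportionality
R2 = c * R2* (``r2_ratio``); a measured R2 map can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, model_validator

from .core import DipoleKernel, FieldVolume, _apply_kernel, hz_to_ppm

__all__ = [
    "ChiSepParams",
    "RelaxationMaps",
    "SusceptibilityMaps",
    "ChiSepDiagnostics",
    "estimate_r2prime",
    "chi_separate",
]


class ChiSepParams(BaseModel):
    """Model constants and solver controls for the source separation.

    ``d_r`` is the relaxometric constant at 3 T (1/s per ppm); it scales
    linearly with field strength and is a literature-order calibration,
    not a fitted quantity.  ``r2_ratio`` is the assumed R2/R2* fraction
    used when no measured R2 map is available.  ``lambda_relax=None``
    defaults to 1/d_r^2 (at the working field), which expresses the
    relaxation data term on the same ppm^2 scale as the field term.
    """

    d_r: float = 114.0
    r2_ratio: float = 0.3
    lambda_field: float = 1.0
    lambda_relax: float | None = None
    lambda_reg: float = 1e-3
    max_iterations: int = 250
    tolerance: float = 1e-6
    regularizer: str = "tikhonov"
    tv_epsilon: float = 1e-6

    @model_validator(mode="after")
    def _check(self):
        if self.d_r <= 0:
            raise ValueError("d_r must be positive")
        if not (0 <= self.r2_ratio < 1):
            raise ValueError("r2_ratio must be in [0, 1)")
        for name in ("lambda_field", "lambda_reg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.lambda_relax is not None and self.lambda_relax < 0:
            raise ValueError("lambda_relax must be nonnegative")
        if self.regularizer not in ("tikhonov", "total-variation"):
            raise ValueError("regularizer must be 'tikhonov' or 'total-variation'")
        return self

    def d_r_at(self, field_strength_T: float) -> float:
        return self.d_r * field_strength_T / 3.0


@dataclass
class RelaxationMaps:
    """R2* and the derived reversible component R2' (both 1/s)."""

    r2star: np.ndarray
    r2prime: np.ndarray

    def __post_init__(self) -> None:
        self.r2star = np.asarray(self.r2star, dtype=float)
        self.r2prime = np.asarray(self.r2prime, dtype=float)
        if self.r2star.shape != self.r2prime.shape:
            raise ValueError("r2star and r2prime shapes differ")
        if np.any(self.r2prime < 0):
            raise ValueError("r2prime must be nonnegative")
        if np.any(self.r2prime > self.r2star + 1e-9):
            raise ValueError("r2prime must not exceed r2star")


@dataclass
class ChiSepDiagnostics:
    objective_history: np.ndarray
    iterations: int
    converged: bool
    warnings: list[str] = field(default_factory=list)
    #: per-iterate min(chi_para) and max(chi_dia) — sign-feasibility record
    min_chi_para_per_iter: np.ndarray | None = None
    max_chi_dia_per_iter: np.ndarray | None = None


@dataclass
class SusceptibilityMaps:
    """Total, paramagnetic (>=0) and diamagnetic (<=0) maps in ppm."""

    chi_total: np.ndarray
    chi_para: np.ndarray
    chi_dia: np.ndarray
    diagnostics: ChiSepDiagnostics | None = None


def estimate_r2prime(
    r2star: np.ndarray,
    params: ChiSepParams | None = None,
    r2_map: np.ndarray | None = None,
) -> RelaxationMaps:
    """Reversible relaxation R2' = max(0, R2* - R2).

    Without a measured R2 map, R2 is taken as ``r2_ratio * R2*``
    (assumed linear proportionality between R2 and R2*).
    """
    params = params or ChiSepParams()
    r2star = np.asarray(r2star, dtype=float)
    if np.any(r2star < 0):
        raise ValueError("r2star must be nonnegative")
    if r2_map is not None:
        r2 = np.asarray(r2_map, dtype=float)
        if np.any(r2 < 0):
            raise ValueError("supplied R2 map has negative entries")
    else:
        r2 = params.r2_ratio * r2star
    r2prime = np.maximum(0.0, r2star - r2)
    return RelaxationMaps(r2star=r2star, r2prime=r2prime)


def _tv_value_grad(x: np.ndarray, eps: float):
    """Smoothed isotropic TV (periodic forward differences) and its gradient."""
    grads = [np.roll(x, -1, axis=ax) - x for ax in range(3)]
    mag = np.sqrt(sum(g * g for g in grads) + eps * eps)
    value = float(mag.sum())
    grad = np.zeros_like(x)
    for ax, g in enumerate(grads):
        p = g / mag
        grad += np.roll(p, 1, axis=ax) - p
    return value, grad


def chi_separate(
    local_field: FieldVolume,
    relax: RelaxationMaps,
    mask: np.ndarray,
    kernel: DipoleKernel,
    params: ChiSepParams | None = None,
    weights: np.ndarray | None = None,
    weights_relax: np.ndarray | None = None,
) -> SusceptibilityMaps:
    """Decompose a local field + R2' into signed susceptibility components.

    Parameters
    ----------
    local_field : FieldVolume
        Tissue local field in Hz or ppm (Hz is converted internally).
    relax : RelaxationMaps
        R2*/R2' maps from :func:`estimate_r2prime`.
    mask, weights, weights_relax : ndarray
        Binary tissue mask; optional per-voxel data-term weights (e.g.
        zero for voxels whose upstream fit did not converge).
    kernel : DipoleKernel
        Dipole kernel on the same grid.
    """
    params = params or ChiSepParams()
    geom = local_field.geometry
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != geom.shape or kernel.geometry.shape != geom.shape:
        raise ValueError("field, mask and kernel must share one grid")
    if relax.r2star.shape != geom.shape:
        raise ValueError("relaxation maps must match the field grid")

    fv = hz_to_ppm(local_field) if local_field.units == "Hz" else local_field
    b = np.where(mask, fv.values, 0.0)
    d_r = params.d_r_at(geom.field_strength_T)
    lam_f = params.lambda_field
    lam_r = params.lambda_relax if params.lambda_relax is not None else 1.0 / d_r**2
    lam_g = params.lambda_reg

    w = (np.asarray(weights, float) if weights is not None else 1.0) * mask
    wr = (np.asarray(weights_relax, float) if weights_relax is not None else 1.0) * mask
    w2, wr2 = w * w, wr * wr
    r2p = np.where(mask, relax.r2prime, 0.0)

    warnings: list[str] = []
    if lam_r > 0 and not np.any(r2p > 0):
        warnings.append(
            "R2' is zero everywhere: separation is driven by the field term only"
        )

    use_tv = params.regularizer == "total-variation"

    def reg_value_grad(x):
        if use_tv:
            return _tv_value_grad(x, params.tv_epsilon)
        return float((x * x).sum()), 2.0 * x

    xp = np.zeros(geom.shape)
    xd = np.zeros(geom.shape)
    ds = np.zeros(geom.shape)  # D * (xp + xd), kept incrementally

    def objective(rf, rr, xp_, xd_):
        jf = lam_f * float((w2 * rf * rf).sum())
        jr = lam_r * float((wr2 * rr * rr).sum())
        jg = lam_g * (reg_value_grad(xp_)[0] + reg_value_grad(xd_)[0]) if lam_g > 0 else 0.0
        return jf + jr + jg

    rf = b - ds
    rr = r2p - d_r * (xp - xd)
    j_cur = objective(rf, rr, xp, xd)
    history = [j_cur]
    min_p_hist = [float(xp.min())]
    max_d_hist = [float(xd.max())]

    lip = 2.0 * (lam_f * (2.0 / 3.0) ** 2 + lam_r * d_r**2 + lam_g * (6.0 if use_tv else 1.0))
    tau_p = tau_d = 1.0 / lip
    stalled = 0

    for it in range(params.max_iterations):
        # --- paramagnetic block ------------------------------------------
        g_field = _apply_kernel(w2 * rf, kernel)
        grad_p = -2.0 * lam_f * g_field - 2.0 * lam_r * d_r * wr2 * rr
        if lam_g > 0:
            grad_p = grad_p + lam_g * reg_value_grad(xp)[1]
        tau = tau_p * 2.0
        accepted = False
        for _ in range(12):
            xp_new = np.maximum(0.0, np.where(mask, xp - tau * grad_p, 0.0))
            delta = xp_new - xp
            if not np.any(delta):
                break
            ds_new = ds + _apply_kernel(delta, kernel)
            rf_new = b - ds_new
            rr_new = r2p - d_r * (xp_new - xd)
            j_new = objective(rf_new, rr_new, xp_new, xd)
            if j_new <= j_cur:
                xp, ds, rf, rr, j_cur = xp_new, ds_new, rf_new, rr_new, j_new
                tau_p = tau
                accepted = True
                break
            tau *= 0.5

        # --- diamagnetic block -------------------------------------------
        g_field = _apply_kernel(w2 * rf, kernel)
        grad_d = -2.0 * lam_f * g_field + 2.0 * lam_r * d_r * wr2 * rr
        if lam_g > 0:
            grad_d = grad_d + lam_g * reg_value_grad(xd)[1]
        tau = tau_d * 2.0
        accepted_d = False
        for _ in range(12):
            xd_new = np.minimum(0.0, np.where(mask, xd - tau * grad_d, 0.0))
            delta = xd_new - xd
            if not np.any(delta):
                break
            ds_new = ds + _apply_kernel(delta, kernel)
            rf_new = b - ds_new
            rr_new = r2p - d_r * (xp - xd_new)
            j_new = objective(rf_new, rr_new, xp, xd_new)
            if j_new <= j_cur:
                xd, ds, rf, rr, j_cur = xd_new, ds_new, rf_new, rr_new, j_new
                tau_d = tau
                accepted_d = True
                break
            tau *= 0.5

        history.append(j_cur)
        min_p_hist.append(float(xp.min()))
        max_d_hist.append(float(xd.max()))
        prev = history[-2]
        if prev > 0 and (prev - j_cur) / prev < params.tolerance:
            stalled += 1
        else:
            stalled = 0
        if (not accepted and not accepted_d) or stalled >= 3:
            break

    converged = it + 1 < params.max_iterations or stalled >= 3
    if not converged:
        warnings.append("max_iterations reached before the objective stabilized")

    diag = ChiSepDiagnostics(
        objective_history=np.asarray(history),
        iterations=len(history) - 1,
        converged=bool(converged),
        warnings=warnings,
        min_chi_para_per_iter=np.asarray(min_p_hist),
        max_chi_dia_per_iter=np.asarray(max_d_hist),
    )
    return SusceptibilityMaps(
        chi_total=xp + xd, chi_para=xp, chi_dia=xd, diagnostics=diag
    )
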