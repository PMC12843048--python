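"""Background-field removal by projection onto dipole fields (PDF).

The measured off-resonance field inside a tissue mask is the sum of the
field generated by sources inside the mask (the quantity of interest)
and the field of background sources outside it (air, hardware, distant
anatomy).  PDF exploits the near-orthogonality of these two families:
it finds the susceptibility distribution supported *outside* the mask
whose dipole field best matches the measured field *inside* the mask
(weighted least squares), and subtracts that best-fit background field.
The convolution is zero-padded (default factor 2) so background sources
near the volume edge are modeled with open boundaries rather than
circular wrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse.linalg
from pydantic import BaseModel, model_validator

from .core import AcquisitionGeometry, DipoleKernel, FieldVolume, _apply_kernel, make_dipole_kernel

__all__ = ["PdfOptions", "PdfResult", "pdf_remove", "make_mask"]


class PdfOptions(BaseModel):
    """Solver controls for the dipole-field projection."""

    max_iterations: int = 200
    rel_tolerance: float = 1e-6
    weighting: str = "uniform"
    pad_factor: int = 2

    @model_validator(mode="after")
    def _check(self):
        if not (0 < self.rel_tolerance < 1):
            raise ValueError("rel_tolerance must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.weighting not in ("uniform", "magnitude"):
            raise ValueError("weighting must be 'uniform' or 'magnitude'")
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")
        return self


@dataclass
class PdfResult:
    local_field: FieldVolume
    background_field: FieldVolume
    iterations: int
    final_residual: float
    converged: bool


def _check_margin(mask: np.ndarray, margin: int = 2) -> None:
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, margin)
        sl_hi[ax] = slice(mask.shape[ax] - margin, None)
        if mask[tuple(sl_lo)].any() or mask[tuple(sl_hi)].any():
            raise ValueError(
                f"mask touches the volume boundary (needs >= {margin}-voxel margin)"
            )


def pdf_remove(
    total_field: FieldVolume,
    mask: np.ndarray,
    kernel: DipoleKernel,
    weights: np.ndarray | None = None,
    options: PdfOptions | None = None,
) -> PdfResult:
    """Split a total field (Hz) into tissue local field and background field.

    Solves ``min_x || w M (f - D (1-M) x) ||^2`` for a background
    susceptibility ``x`` supported outside the mask ``M`` (LSMR on the
    weighted operator), then returns ``local = M (f - D x)``.  The local
    field is zeroed outside the mask rather than extrapolated.
    """
    options = options or PdfOptions()
    if total_field.units != "Hz":
        raise ValueError("pdf_remove expects the total field in Hz")
    geom = total_field.geometry
    if kernel.geometry.shape != geom.shape:
        raise ValueError("kernel grid does not match field grid")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != geom.shape:
        raise ValueError("mask shape does not match field grid")
    if not mask.any():
        raise ValueError("empty mask")
    _check_margin(mask, margin=2)
    f = total_field.values
    if not np.all(np.isfinite(f[mask])):
        raise ValueError("total field must be finite inside the mask")
    f = np.where(np.isfinite(f), f, 0.0)

    if options.weighting == "magnitude":
        if weights is None:
            raise ValueError("weighting='magnitude' requires a weights volume")
        w = np.asarray(weights, dtype=float) * mask
        wmax = w.max()
        if wmax <= 0:
            raise ValueError("weights must be positive somewhere inside the mask")
        w = w / wmax
    else:
        w = mask.astype(float)

    pad = options.pad_factor
    if pad > 1:
        geom_p = geom.padded(pad)
        kernel_p = make_dipole_kernel(geom_p, dc_value=kernel.dc_value)
        pad_width = [(0, gp - g) for g, gp in zip(geom.shape, geom_p.shape)]
        crop = tuple(slice(0, n) for n in geom.shape)

        def apply_d(vol):
            return _apply_kernel(np.pad(vol, pad_width), kernel_p)[crop]
    else:
        def apply_d(vol):
            return _apply_kernel(vol, kernel)

    outside = ~mask
    out_idx = np.flatnonzero(outside.ravel())
    n_grid = int(np.prod(geom.shape))

    def matvec(x):
        vol = np.zeros(n_grid)
        vol[out_idx] = x
        return (w * apply_d(vol.reshape(geom.shape))).ravel()

    def rmatvec(u):
        vol = w * u.reshape(geom.shape)
        return apply_d(vol).ravel()[out_idx]

    op = scipy.sparse.linalg.LinearOperator(
        shape=(n_grid, out_idx.size), matvec=matvec, rmatvec=rmatvec, dtype=float
    )
    rhs = (w * f).ravel()
    sol = scipy.sparse.linalg.lsmr(
        op, rhs,
        atol=options.rel_tolerance, btol=options.rel_tolerance,
        maxiter=options.max_iterations,
    )
    x, istop, itn = sol[0], sol[1], sol[2]

    bg_vol = np.zeros(n_grid)
    bg_vol[out_idx] = x
    background = apply_d(bg_vol.reshape(geom.shape))
    local = np.where(mask, f - background, 0.0)

    rhs_norm = float(np.linalg.norm(rhs))
    resid = float(np.linalg.norm(w * (f - background)))
    final_residual = resid / rhs_norm if rhs_norm > 0 else 0.0
    converged = istop in (0, 1, 2, 4, 5)  # lsmr stop codes for tolerance-met
    return PdfResult(
        local_field=FieldVolume(values=local, units="Hz", geometry=geom),
        background_field=FieldVolume(values=background, units="Hz", geometry=geom),
        iterations=int(itn),
        final_residual=final_residual,
        converged=bool(converged),
    )


def make_mask(
    magnitude: np.ndarray,
    threshold_fraction: float = 0.5,
    erode_voxels: int = 1,
) -> np.ndarray:
    """Binary tissue mask from a magnitude image.

    Thresholds at ``threshold_fraction`` of the robust maximum (99.5th
    percentile), fills interior holes, erodes by ``erode_voxels``, and
    keeps the largest connected component.
    """
    if not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must be in (0, 1)")
    mag = np.asarray(magnitude, dtype=float)
    robust_max = np.percentile(mag, 99.5)
    if robust_max <= 0:
        raise ValueError("magnitude image is empty (robust max <= 0)")
    mask = mag > threshold_fraction * robust_max
    mask = ndi.binary_fill_holes(mask)
    if erode_voxels > 0:
        mask = ndi.binary_erosion(mask, iterations=erode_voxels)
    labels, n = ndi.label(mask)
    if n == 0:
        raise ValueError("mask is empty after thresholding/erosion")
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask
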