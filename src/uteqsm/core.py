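"""Grid geometry, unit conversions, and dipole-field physics.

A susceptibility distribution chi(r) magnetized by the main field B0
perturbs the measured off-resonance field through a convolution with the
unit dipole response.  In k-space the (Lorentz-corrected) kernel is

    D(k) = 1/3 - (k . b0_hat)^2 / |k|^2,

so the relative field shift (in ppm) induced by chi (in ppm) is
``IFFT( D(k) * FFT(chi) )``.  Every stage of the pipeline — forward
simulation, background-field removal, and dipole inversion — shares the
kernel and FFT conventions defined here.

Conventions
-----------
* k-grids follow the half-open FFT frequency layout with the zero
  frequency at index 0 (``numpy.fft.fftfreq``); anisotropic voxels are
  handled through physical cycles/mm coordinates.
* The kernel value at k = 0 (``dc_value``) defaults to 0: the spatial
  mean of chi is unobservable, so fields are mean-free.
* Fields carry an explicit unit tag (``"ppm"`` or ``"Hz"``); conversion
  uses the reduced gyromagnetic ratio ``GAMMA_BAR_HZ_PER_T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as spfft

#: Proton gyromagnetic ratio over 2*pi, in Hz per tesla.
GAMMA_BAR_HZ_PER_T = 42.577e6

_MIN_DIM = 8


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Voxel grid plus scan geometry shared by every pipeline stage.

    Parameters
    ----------
    shape : tuple of int
        Matrix size (nx, ny, nz); each dimension must be >= 8 so the
        FFT-based stages have a meaningful frequency grid.
    voxel_size_mm : tuple of float
        Voxel edge lengths in mm, all > 0.
    b0_dir : tuple of float
        Unit vector of the main-field direction in array coordinates.
    field_strength_T : float
        Main field strength in tesla.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    b0_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)
    field_strength_T: float = 3.0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < _MIN_DIM for n in self.shape):
            raise ValueError(
                f"geometry shape must be 3 dimensions each >= {_MIN_DIM}, got {self.shape}"
            )
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        b0 = np.asarray(self.b0_dir, dtype=float)
        if abs(float(np.linalg.norm(b0)) - 1.0) > 1e-9:
            raise ValueError(f"b0_dir must be a unit vector, got norm {np.linalg.norm(b0)!r}")
        if self.field_strength_T <= 0:
            raise ValueError("field_strength_T must be positive")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "b0_dir", tuple(float(v) for v in b0))

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size_mm))

    def padded(self, pad_factor: int) -> "AcquisitionGeometry":
        """Geometry of the zero-padded grid used for open-boundary convolution."""
        if pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")
        return AcquisitionGeometry(
            shape=tuple(n * pad_factor for n in self.shape),
            voxel_size_mm=self.voxel_size_mm,
            b0_dir=self.b0_dir,
            field_strength_T=self.field_strength_T,
        )

    def grid_mm(self, sparse: bool = True):
        """Centered physical coordinates (mm) of every voxel, origin at n//2."""
        axes = [
            (np.arange(n) - n // 2) * v
            for n, v in zip(self.shape, self.voxel_size_mm)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=sparse)


@dataclass(frozen=True)
class DipoleKernel:
    """k-space dipole response D(k) on the FFT grid of ``geometry``."""

    values: np.ndarray
    geometry: AcquisitionGeometry
    dc_value: float = 0.0

    def __post_init__(self) -> None:
        if self.values.shape != self.geometry.shape:
            raise ValueError("kernel values do not match geometry shape")


@dataclass
class FieldVolume:
    """A real 3D field map with an explicit unit tag ('Hz' or 'ppm')."""

    values: np.ndarray
    units: str
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        if self.units not in ("Hz", "ppm"):
            raise ValueError(f"units must be 'Hz' or 'ppm', got {self.units!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError("field values do not match geometry shape")


def make_dipole_kernel(geometry: AcquisitionGeometry, dc_value: float = 0.0) -> DipoleKernel:
    """Build the k-space dipole kernel D(k) = 1/3 - (k.b0)^2/|k|^2.

    The kernel is dimensionless, real and even (D(k) = D(-k)), bounded in
    [-2/3, 1/3], and evaluated on the physical frequency grid implied by
    the voxel size, so anisotropic voxels are handled correctly.  The
    value at k = 0 is set to ``dc_value`` (default 0: mean-free fields).
    """
    ks = [
        np.fft.fftfreq(n, d=v)
        for n, v in zip(geometry.shape, geometry.voxel_size_mm)
    ]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij", sparse=True)
    b0 = geometry.b0_dir
    k2 = kx**2 + ky**2 + kz**2
    kb = kx * b0[0] + ky * b0[1] + kz * b0[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 1.0 / 3.0 - kb**2 / k2
    values[0, 0, 0] = dc_value
    return DipoleKernel(values=values, geometry=geometry, dc_value=float(dc_value))


def _apply_kernel(volume: np.ndarray, kernel: DipoleKernel) -> np.ndarray:
    """Multiply a real volume by D(k) in k-space (circular convolution)."""
    nz = kernel.geometry.shape[-1]
    d_half = kernel.values[..., : nz // 2 + 1]
    return spfft.irfftn(spfft.rfftn(volume) * d_half, s=kernel.geometry.shape)


def forward_field(
    chi_ppm, kernel: DipoleKernel, pad_factor: int = 1
) -> FieldVolume:
    """Field shift (ppm) induced by a susceptibility map (ppm).

    Parameters
    ----------
    chi_ppm : FieldVolume or ndarray
        Susceptibility map in ppm on the kernel's grid.
    kernel : DipoleKernel
        Kernel from :func:`make_dipole_kernel` on the same grid.
    pad_factor : int
        Zero-padding factor for the convolution.  The default (1) is the
        periodic circular convolution; 2 approximates the open-boundary
        (linear) convolution and is used by the simulator and the
        background-removal stage.
    """
    if isinstance(chi_ppm, FieldVolume):
        if chi_ppm.units != "ppm":
            raise ValueError(f"susceptibility map must be tagged 'ppm', got {chi_ppm.units!r}")
        chi = chi_ppm.values
    else:
        chi = np.asarray(chi_ppm, dtype=float)
    if chi.shape != kernel.geometry.shape:
        raise ValueError(
            f"grid mismatch: chi {chi.shape} vs kernel {kernel.geometry.shape}"
        )
    if pad_factor == 1:
        out = _apply_kernel(chi, kernel)
    else:
        geom_p = kernel.geometry.padded(pad_factor)
        kernel_p = make_dipole_kernel(geom_p, dc_value=kernel.dc_value)
        pad = [(0, gp - g) for g, gp in zip(kernel.geometry.shape, geom_p.shape)]
        padded = np.pad(chi, pad)
        full = _apply_kernel(padded, kernel_p)
        sl = tuple(slice(0, n) for n in kernel.geometry.shape)
        out = full[sl]
    return FieldVolume(values=out, units="ppm", geometry=kernel.geometry)


def ppm_to_hz(field_ppm: FieldVolume, field_strength_T: float | None = None) -> FieldVolume:
    """Convert a ppm field shift to Hz: f = shift * gamma_bar * B0 * 1e-6."""
    if field_ppm.units != "ppm":
        raise ValueError(f"expected units 'ppm', got {field_ppm.units!r}")
    b0 = field_ppm.geometry.field_strength_T if field_strength_T is None else field_strength_T
    scale = GAMMA_BAR_HZ_PER_T * b0 * 1e-6
    return FieldVolume(values=field_ppm.values * scale, units="Hz", geometry=field_ppm.geometry)


def hz_to_ppm(field_hz: FieldVolume, field_strength_T: float | None = None) -> FieldVolume:
    """Inverse of :func:`ppm_to_hz` (exact round trip)."""
    if field_hz.units != "Hz":
        raise ValueError(f"expected units 'Hz', got {field_hz.units!r}")
    b0 = field_hz.geometry.field_strength_T if field_strength_T is None else field_strength_T
    scale = GAMMA_BAR_HZ_PER_T * b0 * 1e-6
    return FieldVolume(values=field_hz.values / scale, units="ppm", geometry=field_hz.geometry)
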