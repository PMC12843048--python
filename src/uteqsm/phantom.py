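"""Synthetic three-tube phantom and multi-echo acquisition simulator.

The reference scene is a cylindrical agarose container holding three
tubes, each filled with a *mixture* of a diamagnetic calcium-carbonate
proxy (522 / 347 / 174 mg/mL) and a paramagnetic iron-oxide proxy
(12 / 8 / 4 mg/mL).  Concentrations map linearly to susceptibility
(ppm) and to an R2* contribution (1/s); the slopes are free calibration
parameters with defaults chosen so tube susceptibilities land in the
+-1 ppm range and so the reversible relaxation implied by the default
R2/R2* ratio is consistent with the relaxometric constant D_r — no
physical molar calibration is claimed.

The simulator turns ground-truth maps into complex multi-echo images:
chi -> dipole field (zero-padded, open-boundary convolution) -> voxel
signal under the water/fat model with T2* decay -> optional complex
Gaussian noise at a stated SNR.  Signals are generated directly in
image space; k-space trajectories are not simulated, consistent with
the trajectory-robustness of susceptibility estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AcquisitionGeometry, FieldVolume, forward_field, make_dipole_kernel, ppm_to_hz
from .ideal import FatSpectrum, MultiEchoSeries, default_fat_spectrum

__all__ = [
    "TE_PHANTOM_S",
    "TE_KNEE_S",
    "PhantomSpec",
    "GroundTruth",
    "ExternalSphere",
    "FatRegion",
    "phantom_geometry",
    "make_tube_phantom",
    "default_external_sphere",
    "simulated_field_hz",
    "simulate_acquisition",
]

#: Phantom echo schedule (s): four dual-echo interleaves merged and sorted.
TE_PHANTOM_S = (0.05e-3, 0.2e-3, 0.4e-3, 0.8e-3, 2.2e-3, 3.3e-3, 4.4e-3, 5.5e-3)
#: Knee/ankle echo schedule (s): three dual-echo interleaves merged.
TE_KNEE_S = (0.032e-3, 0.2e-3, 0.6e-3, 2.7e-3, 3.7e-3, 4.7e-3)


@dataclass(frozen=True)
class FatRegion:
    """Spherical region with a prescribed fat fraction."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    fat_fraction: float


@dataclass(frozen=True)
class ExternalSphere:
    """Background susceptibility source outside the tissue mask."""

    center_mm: tuple[float, float, float] = (44.0, 44.0, 0.0)
    radius_mm: float = 8.0
    chi_ppm: float = 9.0


@dataclass(frozen=True)
class PhantomSpec:
    """Three-tube mixed-source phantom description.

    Tubes are cylinders along z at ``tube_centers_mm`` (x, y, z of the
    cylinder midpoint, mm from volume center).  ``dia_slope`` (< 0) and
    ``para_slope`` (> 0) convert concentration (mg/mL) to ppm;
    ``r2_slope_*`` convert it to an R2* contribution (1/s).
    """

    tube_centers_mm: tuple = ((-16.0, -10.0, 0.0), (16.0, -10.0, 0.0), (0.0, 18.0, 0.0))
    tube_radius_mm: float = 7.0
    tube_length_mm: float = 80.0
    dia_concentrations: tuple[float, ...] = (522.0, 347.0, 174.0)
    para_concentrations: tuple[float, ...] = (12.0, 8.0, 4.0)
    dia_slope: float = -0.00135
    para_slope: float = 0.07
    r2_slope_para: float = 11.4
    r2_slope_dia: float = 0.22
    background_r2: float = 15.0
    container_radius_mm: float = 40.0
    container_length_mm: float = 116.0
    fat_regions: tuple[FatRegion, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.tube_centers_mm)
        if len(self.dia_concentrations) != n or len(self.para_concentrations) != n:
            raise ValueError("concentration lists must match the number of tubes")
        if self.tube_radius_mm <= 0:
            raise ValueError("tube_radius_mm must be positive")
        if self.dia_slope >= 0:
            raise ValueError("dia_slope must be negative (diamagnetic)")
        if self.para_slope <= 0:
            raise ValueError("para_slope must be positive (paramagnetic)")


@dataclass
class GroundTruth:
    """Ground-truth maps: signed chi components, R2*, fat, mask, tube ROIs."""

    chi_para_gt: np.ndarray
    chi_dia_gt: np.ndarray
    r2star_gt: np.ndarray
    fat_fraction_gt: np.ndarray
    mask_gt: np.ndarray
    tube_rois: np.ndarray
    geometry: AcquisitionGeometry
    signal_amplitude: np.ndarray | None = None


def phantom_geometry(n: int = 64, voxel_mm: float = 2.0,
                     field_strength_T: float = 3.0) -> AcquisitionGeometry:
    """Isotropic grid used for the synthetic phantom (default 64^3 at 2 mm)."""
    return AcquisitionGeometry(
        shape=(n, n, n), voxel_size_mm=(voxel_mm,) * 3,
        b0_dir=(0.0, 0.0, 1.0), field_strength_T=field_strength_T,
    )


# ---------------------------------------------------------------------------
# partial-volume rasterization (supersampled antialiasing)
# ---------------------------------------------------------------------------

_SUPER = 8  # subsamples per axis in boundary voxels


def _axis_mm(geometry: AcquisitionGeometry, ax: int) -> np.ndarray:
    n, v = geometry.shape[ax], geometry.voxel_size_mm[ax]
    return (np.arange(n) - n // 2) * v


def _interval_coverage(z: np.ndarray, dz: float, lo: float, hi: float) -> np.ndarray:
    """Exact overlap fraction of voxel [z - dz/2, z + dz/2] with [lo, hi]."""
    a = np.maximum(z - dz / 2, lo)
    b = np.minimum(z + dz / 2, hi)
    return np.clip(b - a, 0.0, dz) / dz


def _disk_coverage(geometry: AcquisitionGeometry, cx: float, cy: float,
                   radius: float) -> np.ndarray:
    """Antialiased in-plane coverage of a disk, supersampled at the rim."""
    x = _axis_mm(geometry, 0)[:, None]
    y = _axis_mm(geometry, 1)[None, :]
    dx, dy = geometry.voxel_size_mm[:2]
    r = np.hypot(x - cx, y - cy)
    half_diag = 0.5 * np.hypot(dx, dy)
    cov = (r <= radius - half_diag).astype(float)
    rim = np.abs(r - radius) < half_diag
    if rim.any():
        ix, iy = np.nonzero(rim)
        sub = (np.arange(_SUPER) + 0.5) / _SUPER - 0.5
        sx = x[ix, 0, None, None] + sub[:, None] * dx
        sy = y[0, iy, None, None] + sub[None, :] * dy
        inside = np.hypot(sx - cx, sy - cy) <= radius
        cov[ix, iy] = inside.mean(axis=(1, 2))
    return cov


def _cylinder_coverage(geometry: AcquisitionGeometry, center_mm, radius: float,
                       length: float) -> np.ndarray:
    disk = _disk_coverage(geometry, center_mm[0], center_mm[1], radius)
    z = _axis_mm(geometry, 2)
    cz = center_mm[2] if len(center_mm) > 2 else 0.0
    zcov = _interval_coverage(z, geometry.voxel_size_mm[2], cz - length / 2, cz + length / 2)
    return disk[:, :, None] * zcov[None, None, :]


def _sphere_coverage(geometry: AcquisitionGeometry, center_mm, radius: float) -> np.ndarray:
    x = _axis_mm(geometry, 0)[:, None, None]
    y = _axis_mm(geometry, 1)[None, :, None]
    z = _axis_mm(geometry, 2)[None, None, :]
    dx, dy, dz = geometry.voxel_size_mm
    r = np.sqrt((x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2 + (z - center_mm[2]) ** 2)
    half_diag = 0.5 * np.sqrt(dx * dx + dy * dy + dz * dz)
    cov = (r <= radius - half_diag).astype(float)
    shell = np.abs(r - radius) < half_diag
    if shell.any():
        ix, iy, iz = np.nonzero(shell)
        sub = (np.arange(6) + 0.5) / 6 - 0.5
        sx = x[ix, 0, 0][:, None, None, None] + sub[:, None, None] * dx
        sy = y[0, iy, 0][:, None, None, None] + sub[None, :, None] * dy
        sz = z[0, 0, iz][:, None, None, None] + sub[None, None, :] * dz
        inside = (
            (sx - center_mm[0]) ** 2 + (sy - center_mm[1]) ** 2 + (sz - center_mm[2]) ** 2
            <= radius**2
        )
        cov[ix, iy, iz] = inside.mean(axis=(1, 2, 3))
    return cov


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def make_tube_phantom(spec: PhantomSpec, geometry: AcquisitionGeometry) -> GroundTruth:
    """Rasterize the tube phantom into ground-truth maps.

    chi maps are concentration x slope; R2* is the agarose background
    rate plus the concentration-weighted contributions of both sources.
    Tube boundaries are antialiased by supersampled partial volume.
    """
    centers = spec.tube_centers_mm
    n_tubes = len(centers)
    # geometric validity: tubes inside the container, container inside the
    # grid with a 2-voxel margin, and no tube-tube overlap
    fov = geometry.fov_mm
    dx, dy, dz = geometry.voxel_size_mm
    if spec.container_radius_mm + 2 * max(dx, dy) > min(fov[0], fov[1]) / 2:
        raise ValueError("container does not fit inside the grid with margin")
    if spec.container_length_mm / 2 + 2 * dz > fov[2] / 2:
        raise ValueError("container is too long for the grid")
    for i, c in enumerate(centers):
        if np.hypot(c[0], c[1]) + spec.tube_radius_mm > spec.container_radius_mm:
            raise ValueError(f"tube {i} extends beyond the container")
        if spec.tube_length_mm > spec.container_length_mm:
            raise ValueError("tubes are longer than the container")
        for j in range(i + 1, n_tubes):
            d = np.hypot(c[0] - centers[j][0], c[1] - centers[j][1])
            if d < 2 * spec.tube_radius_mm:
                raise ValueError(f"tubes {i} and {j} overlap")

    container = _cylinder_coverage(
        geometry, (0.0, 0.0, 0.0), spec.container_radius_mm, spec.container_length_mm
    )
    chi_para = np.zeros(geometry.shape)
    chi_dia = np.zeros(geometry.shape)
    # the rate is a tissue property (partial volume acts on the signal
    # amplitude, not the rate), so the agarose term is flat in the container
    r2star = np.where(container > 0, spec.background_r2, 0.0)
    rois = np.zeros(geometry.shape, dtype=int)
    for i, c in enumerate(centers):
        cov = _cylinder_coverage(geometry, c, spec.tube_radius_mm, spec.tube_length_mm)
        chi_para += cov * spec.para_concentrations[i] * spec.para_slope
        chi_dia += cov * spec.dia_concentrations[i] * spec.dia_slope
        r2star += cov * (
            spec.r2_slope_para * spec.para_concentrations[i]
            + spec.r2_slope_dia * spec.dia_concentrations[i]
        )
        rois[cov >= 0.999] = i + 1

    fat = np.zeros(geometry.shape)
    for region in spec.fat_regions:
        cov = _sphere_coverage(geometry, region.center_mm, region.radius_mm)
        fat = np.maximum(fat, cov * region.fat_fraction)

    return GroundTruth(
        chi_para_gt=chi_para,
        chi_dia_gt=chi_dia,
        r2star_gt=r2star,
        fat_fraction_gt=fat,
        mask_gt=container > 0.5,
        tube_rois=rois,
        geometry=geometry,
        signal_amplitude=container,
    )


def default_external_sphere(geometry: AcquisitionGeometry | None = None) -> ExternalSphere:
    """A strong background source placed outside the container mask."""
    return ExternalSphere()


def _external_chi(geometry: AcquisitionGeometry, sources) -> np.ndarray:
    chi = np.zeros(geometry.shape)
    for src in sources or ():
        chi += src.chi_ppm * _sphere_coverage(geometry, src.center_mm, src.radius_mm)
    return chi


def simulated_field_hz(
    gt: GroundTruth,
    external_sources=None,
    pad_factor: int = 2,
) -> FieldVolume:
    """Total off-resonance field (Hz) of the scene, open-boundary convolution."""
    chi = gt.chi_para_gt + gt.chi_dia_gt + _external_chi(gt.geometry, external_sources)
    kernel = make_dipole_kernel(gt.geometry)
    return ppm_to_hz(forward_field(chi, kernel, pad_factor=pad_factor))


def simulate_acquisition(
    gt: GroundTruth,
    echo_times_s=TE_PHANTOM_S,
    spectrum: FatSpectrum | None = None,
    snr: float = np.inf,
    seed: int | None = None,
    external_sources=None,
    phi0: float = 0.3,
    pad_factor: int = 2,
) -> MultiEchoSeries:
    """Generate complex multi-echo images of a ground-truth scene.

    The per-voxel signal follows the water/fat model: water amplitude
    ``(1 - FF) * m0`` decaying with the ground-truth R2*, undamped fat
    ``FF * m0`` with the multi-peak spectrum, common initial phase
    ``phi0``, and off-resonance from the dipole field of all sources.
    Complex Gaussian noise is added per echo at the stated SNR (defined
    on the first-echo mean magnitude inside the mask); two runs with the
    same seed are bit-identical.
    """
    te = np.asarray(echo_times_s, dtype=float)
    if te.size == 0:
        raise ValueError("echo time list must not be empty")
    if not (snr > 0):
        raise ValueError("snr must be positive (or infinite)")
    finite_noise = np.isfinite(snr)
    if finite_noise and seed is None:
        raise ValueError("a seed is required when snr is finite")
    geometry = gt.geometry
    spectrum = spectrum or default_fat_spectrum(geometry.field_strength_T)

    f_hz = simulated_field_hz(gt, external_sources, pad_factor).values
    m0 = gt.signal_amplitude if gt.signal_amplitude is not None else gt.mask_gt.astype(float)
    ff = gt.fat_fraction_gt
    s_w = m0 * (1.0 - ff)
    s_f = m0 * ff
    fat_ph = spectrum.phasor(te, geometry.field_strength_T)  # (m,)

    data = np.empty((te.size, *geometry.shape), dtype=complex)
    for e, t in enumerate(te):
        core = s_w * np.exp(-t * gt.r2star_gt) + s_f * fat_ph[e]
        data[e] = core * np.exp(1j * (phi0 + 2 * np.pi * f_hz * t))

    if finite_noise:
        rng = np.random.default_rng(seed)
        mean_mag = float(np.abs(data[0][gt.mask_gt]).mean())
        sigma = mean_mag / snr
        noise = rng.normal(scale=sigma, size=(2, *data.shape))
        data = data + noise[0] + 1j * noise[1]

    return MultiEchoSeries(
        data=data,
        echo_times_s=tuple(float(t) for t in te),
        geometry=geometry,
        meta={"snr": None if not finite_noise else float(snr), "seed": seed,
              "phi0": phi0, "pad_factor": pad_factor},
    )
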