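"""Shared fixtures: geometries, phantoms, and the heavy session-scoped runs."""

from __future__ import annotations

import numpy as np
import pytest

import uteqsm as u
from uteqsm.phantom import TE_PHANTOM_S


@pytest.fixture(scope="session")
def geom64():
    return u.phantom_geometry(64)


@pytest.fixture(scope="session")
def kernel64(geom64):
    return u.make_dipole_kernel(geom64)


@pytest.fixture(scope="session")
def spectrum3t():
    return u.default_fat_spectrum(3.0)


@pytest.fixture(scope="session")
def small_phantom():
    """Compact 48^3 phantom used by fast tests (shorter tubes/container)."""
    geom = u.phantom_geometry(48)
    spec = u.PhantomSpec(
        container_radius_mm=40.0, container_length_mm=80.0, tube_length_mm=56.0
    )
    return spec, u.make_tube_phantom(spec, geom)


@pytest.fixture(scope="session")
def phantom_default():
    """The reference 64^3 three-tube phantom at default calibration."""
    spec = u.PhantomSpec()
    gt = u.make_tube_phantom(spec, u.phantom_geometry(64))
    return spec, gt


@pytest.fixture(scope="session")
def pipeline_snr50(phantom_default):
    """Full pipeline run on the 64^3 phantom at SNR 50 (fixed seed).

    This is the synthetic analogue of the mixed-source phantom
    experiment; several tests read different maps off this one run.
    """
    spec, gt = phantom_default
    series = u.simulate_acquisition(
        gt, TE_PHANTOM_S, snr=50.0, seed=7, external_sources=[u.ExternalSphere()]
    )
    result = u.process_series(series)
    return spec, gt, result


def roi_means(volume, rois, n=3):
    return np.array([volume[rois == i].mean() for i in range(1, n + 1)])


@pytest.fixture(scope="session")
def pdf_scene(geom64, kernel64):
    """Container mask + external/internal source fields and their PDF solves.

    Shared by the background-removal unit tests and the acceptance
    checks so the expensive projections run once per session.
    """
    from uteqsm.phantom import _cylinder_coverage, _sphere_coverage

    mask = _cylinder_coverage(geom64, (0.0, 0.0, 0.0), 40.0, 116.0) > 0.5
    chi_ext = 9.0 * _sphere_coverage(geom64, (44.0, 44.0, 0.0), 8.0)
    chi_int = 0.5 * _cylinder_coverage(geom64, (0.0, 0.0, 0.0), 3.5, 80.0)
    f_ext = u.ppm_to_hz(u.forward_field(chi_ext, kernel64, pad_factor=2))
    f_int = u.ppm_to_hz(u.forward_field(chi_int, kernel64, pad_factor=2))
    f_both = u.FieldVolume(
        values=f_ext.values + f_int.values, units="Hz", geometry=geom64
    )
    return {
        "mask": mask,
        "f_ext": f_ext,
        "f_int": f_int,
        "f_both": f_both,
        "pdf_ext": u.pdf_remove(f_ext, mask, kernel64),
        "pdf_int": u.pdf_remove(f_int, mask, kernel64),
        "pdf_both": u.pdf_remove(f_both, mask, kernel64),
    }
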