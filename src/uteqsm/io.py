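"""NIfTI / JSON readers and writers plus acquisition sidecar handling.

Volumes are stored as NIfTI-1 with the voxel size in the affine; scan
metadata that NIfTI cannot carry (echo times, field strength, B0
direction, units, processing provenance) lives in a JSON sidecar next
to each volume.  Complex multi-echo series are stored either as a
single complex-valued 4D NIfTI (x, y, z, echo) or as real/imaginary or
magnitude/phase pairs; the dialect is auto-detected and recorded.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .core import AcquisitionGeometry, FieldVolume
from .ideal import MultiEchoSeries

__all__ = [
    "Sidecar",
    "read_sidecar",
    "write_sidecar",
    "read_series",
    "write_series",
    "read_map",
    "write_map",
    "sha256_of_array",
]


class Sidecar(BaseModel):
    """Acquisition sidecar: echo times (ms), field strength (T), B0 direction."""

    model_config = ConfigDict(extra="allow")

    echo_times_ms: list[float]
    field_strength_T: float = 3.0
    b0_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)
    complex_dialect: str | None = None
    units: str | None = None

    @model_validator(mode="after")
    def _check(self):
        te = np.asarray(self.echo_times_ms, float)
        if te.size < 1 or np.any(np.diff(te) <= 0) or te[0] < 0:
            raise ValueError("echo_times_ms must be nonnegative and strictly increasing")
        if self.field_strength_T <= 0:
            raise ValueError("field_strength_T must be positive")
        return self


def read_sidecar(path) -> Sidecar:
    with open(path) as fh:
        return Sidecar.model_validate(json.load(fh))


def write_sidecar(sidecar: Sidecar, path) -> None:
    with open(path, "w") as fh:
        json.dump(sidecar.model_dump(mode="json"), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _geometry_from_img(img, sidecar: Sidecar) -> AcquisitionGeometry:
    zooms = img.header.get_zooms()[:3]
    return AcquisitionGeometry(
        shape=tuple(int(n) for n in img.shape[:3]),
        voxel_size_mm=tuple(float(z) for z in zooms),
        b0_dir=tuple(sidecar.b0_dir),
        field_strength_T=sidecar.field_strength_T,
    )


def _affine(geometry: AcquisitionGeometry) -> np.ndarray:
    return np.diag([*geometry.voxel_size_mm, 1.0])


def _load4d(path) -> tuple[np.ndarray, nib.Nifti1Image]:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 3:
        arr = arr[..., None]
    if arr.ndim != 4:
        raise ValueError(f"{path}: expected a 3D or 4D volume, got ndim={arr.ndim}")
    return arr, img


def read_series(paths, sidecar: Sidecar | str | Path) -> MultiEchoSeries:
    """Assemble a complex multi-echo series from NIfTI volume(s).

    ``paths`` may be a single complex 4D file, a dict with keys
    ``{"real", "imag"}`` or ``{"magnitude", "phase"}`` (phase in
    radians), or a list of per-echo complex 3D files.  Echo order
    follows the sidecar's ``echo_times_ms``.
    """
    if not isinstance(sidecar, Sidecar):
        sidecar = read_sidecar(sidecar)
    n_echo = len(sidecar.echo_times_ms)

    if isinstance(paths, dict):
        keys = set(paths)
        if keys == {"real", "imag"}:
            re_arr, img = _load4d(paths["real"])
            im_arr, img2 = _load4d(paths["imag"])
            dialect = "real_imag"
            data4 = re_arr.astype(float) + 1j * im_arr.astype(float)
        elif keys == {"magnitude", "phase"}:
            mag, img = _load4d(paths["magnitude"])
            ph, img2 = _load4d(paths["phase"])
            dialect = "mag_phase"
            data4 = mag.astype(float) * np.exp(1j * ph.astype(float))
        else:
            raise ValueError(
                f"paths dict must have keys real/imag or magnitude/phase, got {sorted(keys)}"
            )
        if img.shape != img2.shape or not np.allclose(img.affine, img2.affine):
            raise ValueError("series pair mismatch: shape/affine differ between volumes")
    elif isinstance(paths, (list, tuple)):
        vols, imgs = zip(*(_load4d(p) for p in paths))
        if len(vols) != n_echo:
            raise ValueError(
                f"echo_times_ms lists {n_echo} echoes but {len(vols)} volumes given"
            )
        shapes = {v.shape for v in vols}
        if len(shapes) > 1:
            raise ValueError(f"per-echo volumes disagree in shape: {sorted(shapes)}")
        for im in imgs[1:]:
            if not np.allclose(im.affine, imgs[0].affine):
                raise ValueError("per-echo volumes disagree in affine")
        img = imgs[0]
        data4 = np.stack([v[..., 0] for v in vols], axis=-1).astype(complex)
        dialect = "per_echo_complex"
    else:
        arr, img = _load4d(paths)
        if not np.iscomplexobj(arr):
            raise ValueError(
                "single-file series must be complex-valued; use a real/imag or "
                "magnitude/phase pair for real-valued storage"
            )
        data4 = arr
        dialect = "complex"

    if data4.shape[-1] != n_echo:
        raise ValueError(
            f"series has {data4.shape[-1]} echoes but echo_times_ms lists {n_echo}"
        )
    geometry = _geometry_from_img(img, sidecar)
    data = np.moveaxis(data4, -1, 0)  # (echo, x, y, z)
    return MultiEchoSeries(
        data=data,
        echo_times_s=tuple(t * 1e-3 for t in sidecar.echo_times_ms),
        geometry=geometry,
        meta={"dialect": dialect},
    )


def write_series(series: MultiEchoSeries, out_base, dialect: str = "complex") -> dict:
    """Write a series (+ sidecar) and return the written paths.

    ``out_base`` is a path prefix; files are ``<base>.nii.gz`` (complex)
    or ``<base>_real/_imag.nii.gz`` / ``<base>_mag/_phase.nii.gz``.
    """
    out_base = Path(out_base)
    out_base.parent.mkdir(parents=True, exist_ok=True)
    affine = _affine(series.geometry)
    data4 = np.moveaxis(series.data, 0, -1)
    paths: dict[str, str] = {}
    if dialect == "complex":
        p = out_base.with_suffix(".nii.gz")
        nib.save(nib.Nifti1Image(data4.astype(np.complex128), affine), str(p))
        paths["series"] = str(p)
    elif dialect == "real_imag":
        for tag, part in (("real", data4.real), ("imag", data4.imag)):
            p = out_base.parent / f"{out_base.name}_{tag}.nii.gz"
            nib.save(nib.Nifti1Image(np.ascontiguousarray(part), affine), str(p))
            paths[tag] = str(p)
    elif dialect == "mag_phase":
        for tag, part in (("mag", np.abs(data4)), ("phase", np.angle(data4))):
            p = out_base.parent / f"{out_base.name}_{tag}.nii.gz"
            nib.save(nib.Nifti1Image(np.ascontiguousarray(part), affine), str(p))
            paths[tag] = str(p)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    sc = Sidecar(
        echo_times_ms=[t * 1e3 for t in series.echo_times_s],
        field_strength_T=series.geometry.field_strength_T,
        b0_dir=series.geometry.b0_dir,
        complex_dialect=dialect,
    )
    sc_path = out_base.parent / f"{out_base.name}.json"
    write_sidecar(sc, sc_path)
    paths["sidecar"] = str(sc_path)
    return paths


def write_map(values: np.ndarray, path, geometry: AcquisitionGeometry,
              units: str | None = None, extra: dict | None = None) -> str:
    """Write a scalar map with a units/provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float64), _affine(geometry)), str(path))
    meta = {"units": units}
    if extra:
        meta.update(extra)
    side = path.parent / (path.name.split(".")[0] + ".json")
    with open(side, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return str(path)


def read_map(path, sidecar: Sidecar | None = None):
    """Read a scalar map; returns (values, geometry-from-header)."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj).astype(float)
    zooms = img.header.get_zooms()[:3]
    geometry = AcquisitionGeometry(
        shape=tuple(int(n) for n in arr.shape[:3]),
        voxel_size_mm=tuple(float(z) for z in zooms),
        b0_dir=tuple(sidecar.b0_dir) if sidecar else (0.0, 0.0, 1.0),
        field_strength_T=sidecar.field_strength_T if sidecar else 3.0,
    )
    return arr, geometry


def sha256_of_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()
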