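"""One-command pipeline: IDEAL fit -> PDF background removal -> chi-separation.

:func:`process_series` is the in-memory pipeline used by the tests and
the acceptance script; :func:`run_pipeline` wraps it with NIfTI/JSON
file handling, provenance recording and per-ROI summary tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .chisep import ChiSepParams, RelaxationMaps, SusceptibilityMaps, chi_separate, estimate_r2prime
from .core import FieldVolume, make_dipole_kernel
from .ideal import (
    FatSpectrum,
    FitOptions,
    IdealFitVolume,
    MultiEchoSeries,
    default_fat_spectrum,
    derive_maps,
    fit_ideal_volume,
)
from .io import Sidecar, read_map, read_sidecar, read_series, sha256_of_array, write_map
from .pdf import PdfOptions, PdfResult, make_mask, pdf_remove

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "PipelineError",
    "process_series",
    "roi_summary",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class PipelineConfig(BaseModel):
    """File-based pipeline configuration (paths + per-stage options)."""

    model_config = ConfigDict(extra="forbid")

    series: str | dict[str, str] | list[str]
    sidecar: str
    out_dir: str
    mask: str | None = None
    rois: str | None = None
    mask_threshold: float = 0.5
    mask_erode_voxels: int = 1
    fit_options: FitOptions = FitOptions()
    pdf_options: PdfOptions = PdfOptions()
    chisep_params: ChiSepParams = ChiSepParams()
    seed: int | None = None
    log_level: str = "INFO"

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    mask: np.ndarray
    fit: IdealFitVolume
    maps: dict[str, np.ndarray]
    total_field: FieldVolume
    pdf: PdfResult
    relax: RelaxationMaps
    susceptibility: SusceptibilityMaps
    warnings: list[str] = field(default_factory=list)


def process_series(
    series: MultiEchoSeries,
    mask: np.ndarray | None = None,
    spectrum: FatSpectrum | None = None,
    fit_options: FitOptions | None = None,
    pdf_options: PdfOptions | None = None,
    chisep_params: ChiSepParams | None = None,
    mask_threshold: float = 0.5,
    mask_erode_voxels: int = 1,
) -> PipelineResult:
    """Run the full source-separation pipeline on an in-memory series.

    If no mask is given, one is derived from the first-echo magnitude.
    Voxels whose model fit did not converge are down-weighted to zero in
    both chi-separation data terms.
    """
    geom = series.geometry
    spectrum = spectrum or default_fat_spectrum(geom.field_strength_T)
    if mask is None:
        mask = make_mask(np.abs(series.data[0]), mask_threshold, mask_erode_voxels)
    mask = np.asarray(mask, dtype=bool)

    fit = fit_ideal_volume(series, spectrum, mask, fit_options)
    maps = derive_maps(fit)
    kernel = make_dipole_kernel(geom)
    total_field = FieldVolume(values=maps["b0_hz"], units="Hz", geometry=geom)

    pdf_res = pdf_remove(total_field, mask, kernel, options=pdf_options)
    relax = estimate_r2prime(maps["r2star"], chisep_params)
    w = (mask & fit.converged).astype(float)
    sus = chi_separate(
        pdf_res.local_field, relax, mask, kernel, chisep_params,
        weights=w, weights_relax=w,
    )
    warnings = list(sus.diagnostics.warnings) if sus.diagnostics else []
    if not pdf_res.converged:
        warnings.append("PDF stage stopped at max_iterations")
    return PipelineResult(
        mask=mask, fit=fit, maps=maps, total_field=total_field,
        pdf=pdf_res, relax=relax, susceptibility=sus, warnings=warnings,
    )


def roi_summary(maps: dict[str, np.ndarray], labels: np.ndarray) -> pd.DataFrame:
    """Mean +- SD of each map per ROI label (labels > 0), one row per label."""
    labels = np.asarray(labels)
    rows = []
    for lab in np.unique(labels[labels > 0]):
        sel = labels == lab
        row: dict[str, float] = {"label": int(lab), "n_voxels": int(sel.sum())}
        for name, arr in maps.items():
            row[f"{name}_mean"] = float(np.mean(arr[sel]))
            row[f"{name}_sd"] = float(np.std(arr[sel]))
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based pipeline runner mirroring the processing workflow.

    Reads the series and optional mask/ROI volumes, runs
    :func:`process_series`, and writes every intermediate map, a
    provenance JSON (package version, options, checksums), and a
    per-ROI summary CSV.  On a stage failure a ``FAILED.json`` marker
    naming the stage is left in the output directory and a
    :class:`PipelineError` is raised; partial outputs are retained.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "read"
    try:
        sidecar = read_sidecar(config.sidecar)
        series = read_series(config.series, sidecar)
        mask = None
        if config.mask:
            mask_arr, _ = read_map(config.mask, sidecar)
            mask = mask_arr > 0.5

        stage = "process"
        result = process_series(
            series, mask=mask,
            fit_options=config.fit_options,
            pdf_options=config.pdf_options,
            chisep_params=config.chisep_params,
            mask_threshold=config.mask_threshold,
            mask_erode_voxels=config.mask_erode_voxels,
        )

        stage = "write"
        geom = series.geometry
        outputs = {
            "mask": (result.mask.astype(float), None),
            "b0_hz": (result.maps["b0_hz"], "Hz"),
            "r2star": (result.maps["r2star"], "1/s"),
            "fat_fraction": (result.maps["fat_fraction"], "fraction"),
            "local_field_hz": (result.pdf.local_field.values, "Hz"),
            "background_field_hz": (result.pdf.background_field.values, "Hz"),
            "r2prime": (result.relax.r2prime, "1/s"),
            "chi_total": (result.susceptibility.chi_total, "ppm"),
            "chi_para": (result.susceptibility.chi_para, "ppm"),
            "chi_dia": (result.susceptibility.chi_dia, "ppm"),
        }
        options_prov = {
            "fit_options": config.fit_options.model_dump(mode="json"),
            "pdf_options": config.pdf_options.model_dump(mode="json"),
            "chisep_params": config.chisep_params.model_dump(mode="json"),
            "mask_threshold": config.mask_threshold,
            "mask_erode_voxels": config.mask_erode_voxels,
            "seed": config.seed,
        }
        checksums = {}
        paths = {}
        for name, (arr, units) in outputs.items():
            p = out_dir / f"{name}.nii.gz"
            write_map(arr, p, geom, units=units, extra={"stage_options": options_prov})
            checksums[name] = sha256_of_array(np.asarray(arr, float))
            paths[name] = str(p)

        stage = "report"
        summary_path = None
        if config.rois:
            rois, _ = read_map(config.rois, sidecar)
            table = roi_summary(
                {k: outputs[k][0] for k in
                 ("chi_total", "chi_para", "chi_dia", "r2star", "b0_hz", "fat_fraction")},
                rois.astype(int),
            )
            summary_path = out_dir / "roi_summary.csv"
            table.to_csv(summary_path, index=False)

        provenance = {
            "package": "uteqsm",
            "version": __version__,
            "config": json.loads(config.canonical_json()),
            "options": options_prov,
            "checksums": checksums,
            "warnings": result.warnings,
            "pdf_iterations": result.pdf.iterations,
            "chisep_iterations": (
                result.susceptibility.diagnostics.iterations
                if result.susceptibility.diagnostics else None
            ),
        }
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        if not isinstance(exc, PipelineError):
            with open(out_dir / "FAILED.json", "w") as fh:
                json.dump({"stage": stage, "error": str(exc)}, fh, indent=2)
            raise PipelineError(stage, str(exc)) from exc
        raise
    return {
        "paths": paths,
        "provenance": provenance,
        "summary": str(summary_path) if summary_path else None,
        "warnings": result.warnings,
    }
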