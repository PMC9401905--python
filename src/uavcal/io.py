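"""Raster/CSV/JSON readers and writers, run configuration and the pipeline.

Conventions used throughout the package: pixel coordinates are 0-based and
row-major; ROIs are half-open rectangles (row0, col0, row1, col1); raster
stacks are (bands, rows, cols); reflectance rasters are written as 32-bit
floats and DN rasters keep their native integer type.  Multiband rasters
are single-file multiband TIFFs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .calibration import (
    CalibrationFit, CalibrationPanel, METHODS, apply_calibration,
    extract_panel_dn, fit_method,
)
from .indices import BandAssignment, compute_all, reflectance_by_center
from .sensor import (
    Band, BandSet, CameraProfile, DEFAULT_BAND_CENTERS, HyperspectralSpectrum,
)
from .unmixing import EndmemberSet, background_factors, fcls_unmix

logger = logging.getLogger("uavcal")


def configure_logging(verbosity: int = 0) -> None:
    """Stderr logging; verbosity <0 quiet, 0 warnings, >=1 info."""
    level = (logging.ERROR if verbosity < 0
             else logging.WARNING if verbosity == 0 else logging.INFO)
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# rasters

def write_raster(path, stack: np.ndarray) -> None:
    """Write a (bands, rows, cols) stack; float data is stored as float32
    only when that is lossless for the values at hand, else float64."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if np.issubdtype(stack.dtype, np.floating):
        as32 = stack.astype(np.float32)
        stack = as32 if np.array_equal(as32.astype(stack.dtype), stack) else stack
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_multiband_raster(
    path, expected_bands: int | None = None
) -> np.ndarray:
    """Read a multiband TIFF into a (bands, rows, cols) array.

    A band count differing from ``expected_bands`` logs a warning but
    proceeds; a missing file is an explicit error naming the path.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"raster not found: {p}")
    arr = tifffile.imread(str(p))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{p}: expected a 2-D or 3-D raster, got {arr.shape}")
    if expected_bands is not None and arr.shape[0] != expected_bands:
        logger.warning(
            "%s: %d bands, camera profile expects %d — proceeding",
            p, arr.shape[0], expected_bands,
        )
    return arr


# ---------------------------------------------------------------------------
# tables and profiles

def read_spectrum_csv(path) -> HyperspectralSpectrum:
    """2-column CSV (wavelength_nm, value) with a header row."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need 2 columns (wavelength_nm, value)")
    return HyperspectralSpectrum.from_arrays(
        df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
    )


def write_spectrum_csv(path, spectrum: HyperspectralSpectrum,
                       value_name: str = "reflectance") -> None:
    pd.DataFrame({
        "wavelength_nm": spectrum.wavelengths, value_name: spectrum.values,
    }).to_csv(path, index=False)


def read_panels_csv(path, n_bands: int = 12) -> list[CalibrationPanel]:
    """Panels CSV: label,row0,col0,row1,col1 then either a single
    ``reflectance`` column (gray panels) or per-band r_<center> columns."""
    df = pd.read_csv(path)
    required = ["label", "row0", "col0", "row1", "col1"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    band_cols = [c for c in df.columns if c.startswith("r_")]
    panels = []
    for row in df.itertuples():
        roi = (int(row.row0), int(row.col0), int(row.row1), int(row.col1))
        refl = None
        if band_cols:
            vals = np.array([getattr(row, c) for c in band_cols], dtype=float)
            if np.all(np.isfinite(vals)):
                if vals.size not in (1, n_bands):
                    raise ValueError(
                        f"{path}: panel {row.label}: {vals.size} band "
                        f"columns, expected 1 or {n_bands}"
                    )
                refl = vals
        if refl is None:
            if "reflectance" not in df.columns or \
                    not np.isfinite(float(row.reflectance)):
                raise ValueError(
                    f"{path}: panel {row.label} has no usable reflectance"
                )
            refl = float(row.reflectance)
        panels.append(CalibrationPanel(str(row.label), roi, refl))
    return panels


def write_panels_csv(path, panels: list[CalibrationPanel],
                     centers=DEFAULT_BAND_CENTERS) -> None:
    rows = []
    for p in panels:
        refl = np.atleast_1d(np.asarray(p.nominal_reflectance, dtype=float))
        rec = {"label": p.label, "row0": p.roi[0], "col0": p.roi[1],
               "row1": p.roi[2], "col1": p.roi[3]}
        if refl.size == 1:
            rec["reflectance"] = refl[0]
        else:
            rec.update({f"r_{int(c)}": v for c, v in zip(centers, refl)})
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rois_csv(path) -> dict[str, tuple[int, int, int, int]]:
    """Plot ROIs: CSV with label,row0,col0,row1,col1."""
    df = pd.read_csv(path)
    return {
        str(r.label): (int(r.row0), int(r.col0), int(r.row1), int(r.col1))
        for r in df.itertuples()
    }


def read_endmembers_csv(path) -> EndmemberSet:
    """Endmember CSV: label column followed by one reflectance column per band."""
    df = pd.read_csv(path)
    labels = tuple(str(v) for v in df.iloc[:, 0])
    spectra = df.iloc[:, 1:].to_numpy(float)
    background = tuple(l for l in labels if "water" in l or "soil" in l)
    return EndmemberSet(labels, spectra, background or (labels[-1],))


def write_endmembers_csv(path, ems: EndmemberSet,
                         centers=DEFAULT_BAND_CENTERS) -> None:
    df = pd.DataFrame(ems.spectra,
                      columns=[f"r_{int(c)}" for c in centers[:ems.n_bands]])
    df.insert(0, "label", list(ems.labels))
    df.to_csv(path, index=False)


def read_camera_json(path) -> CameraProfile:
    with open(path) as fh:
        d = json.load(fh)
    bands = tuple(
        Band(i + 1, float(c)) for i, c in enumerate(d["band_centers"])
    )
    return CameraProfile(
        band_set=BandSet(bands),
        image_width=int(d.get("image_width", 1280)),
        image_height=int(d.get("image_height", 1024)),
        fov_h=float(d.get("fov_h", 38.26)),
        fov_v=float(d.get("fov_v", 30.97)),
    )


def write_camera_json(path, camera: CameraProfile) -> None:
    with open(path, "w") as fh:
        json.dump({
            "band_centers": list(camera.band_set.centers),
            "image_width": camera.image_width,
            "image_height": camera.image_height,
            "fov_h": camera.fov_h,
            "fov_v": camera.fov_v,
        }, fh, indent=2)


def write_fit_json(path, fit: CalibrationFit) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)


def read_fit_json(path) -> CalibrationFit:
    with open(path) as fh:
        return CalibrationFit.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable and hashable."""

    method: str = "PEL"
    panel_file: str | None = None
    plots_file: str | None = None
    endmember_file: str | None = None
    camera_file: str | None = None
    output_dir: str = "."
    clamp: tuple[float, float] | None = None
    red_center: float = 670.0
    nir_center: float = 800.0
    seed: int = 0
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded,
        so reruns into different directories compare equal)."""
        d = asdict(self)
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    image_paths_by_altitude: dict[float, str],
    panels: list[CalibrationPanel] | None = None,
    plot_rois: dict[str, tuple[int, int, int, int]] | None = None,
    endmembers: EndmemberSet | None = None,
    camera: CameraProfile | None = None,
) -> dict:
    """Calibrate, average per plot, compute VIs and (optionally) unmix.

    For every altitude: read the DN stack, extract panel DNs, fit the
    configured calibration method, convert to reflectance, average each
    plot ROI, compute the nine VIs on plot means, and — when endmembers
    are supplied — unmix plot means and report background factors.
    ``plot_rois`` is either one ``{plot_id: roi}`` mapping applied at every
    altitude, or ``{altitude: {plot_id: roi}}`` with per-altitude ROIs
    (rescaled so each plot covers the same ground area at every flight).
    Outputs (plot_reflectance.csv, plot_indices.csv, abundance.csv,
    calibration_<alt>.json, provenance.json) are written to the output
    directory and are byte-identical across reruns of the same config.
    """
    t0 = time.monotonic()
    camera = camera or CameraProfile.reference()
    if config.camera_file:
        camera = read_camera_json(config.camera_file)
    if panels is None:
        if not config.panel_file:
            raise ValueError("no panels supplied (panel_file unset)")
        panels = read_panels_csv(config.panel_file, camera.n_bands)
    if plot_rois is None and config.plots_file:
        plot_rois = read_rois_csv(config.plots_file)
    if endmembers is None and config.endmember_file:
        endmembers = read_endmembers_csv(config.endmember_file)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    assignment = BandAssignment(red=config.red_center, nir=config.nir_center)
    centers = camera.band_set.centers

    refl_rows, vi_rows, ab_rows, diagnostics = [], [], [], {}
    for alt in sorted(image_paths_by_altitude):
        stage = f"altitude {alt:g} m"
        stack = read_multiband_raster(
            image_paths_by_altitude[alt], camera.n_bands
        )
        n_bands = stack.shape[0]
        try:
            dns = np.array([
                [extract_panel_dn(stack[j], p) for j in range(n_bands)]
                for p in panels
            ])
            refl = np.array([
                [p.reflectance_for_band(j) for j in range(n_bands)]
                for p in panels
            ])
            fit = fit_method(config.method, dns, refl)
            reflectance, diag = apply_calibration(stack, fit, config.clamp)
        except Exception as err:
            raise RuntimeError(f"calibration failed at {stage}: {err}") from err
        write_fit_json(out / f"calibration_{alt:g}m.json", fit)
        diagnostics[alt] = {
            "n_negative": diag.n_negative,
            "n_above_one": diag.n_above_one,
            "per_band_negative": diag.per_band_negative,
            "panel_rmse": fit.panel_rmse,
        }
        if plot_rois and all(isinstance(k, (int, float))
                             for k in plot_rois):
            rois = plot_rois[alt]
        else:
            rois = plot_rois or {
                "scene": (0, 0, stack.shape[1], stack.shape[2])
            }
        for pid, (r0, c0, r1, c1) in sorted(rois.items()):
            mean_refl = reflectance[:, r0:r1, c0:c1].mean(axis=(1, 2))
            refl_rows.append({"altitude_m": alt, "plot_id": pid, **{
                f"r_{int(c)}": v for c, v in zip(centers, mean_refl)
            }})
            by_center = reflectance_by_center(mean_refl, centers)
            vi_rows.append({
                "altitude_m": alt, "plot_id": pid,
                **{k: float(v) for k, v in
                   compute_all(by_center, assignment).items()},
            })
            if endmembers is not None:
                try:
                    ab = fcls_unmix(mean_refl, endmembers)
                except Exception as err:
                    raise RuntimeError(
                        f"unmixing failed at {stage}, plot {pid}: {err}"
                    ) from err
                row = {"altitude_m": alt, "plot_id": pid, **ab.as_dict(),
                       "residual_rms": ab.residual_norm}
                if set(endmembers.labels) == set(
                        ("light_leaf", "shaded_leaf", "light_water",
                         "shaded_water", "light_soil", "shaded_soil")):
                    att, enh = background_factors(ab)
                    row["attenuation_nir"] = att
                    row["enhancement_vis"] = enh
                ab_rows.append(row)
        logger.info("%s done (%.2fs elapsed)", stage, time.monotonic() - t0)

    refl_df = pd.DataFrame(refl_rows)
    vi_df = pd.DataFrame(vi_rows)
    refl_df.to_csv(out / "plot_reflectance.csv", index=False)
    vi_df.to_csv(out / "plot_indices.csv", index=False)
    report = {
        "config_hash": config.config_hash(),
        "diagnostics": diagnostics,
        "reflectance": refl_df,
        "indices": vi_df,
    }
    if ab_rows:
        ab_df = pd.DataFrame(ab_rows)
        ab_df.to_csv(out / "abundance.csv", index=False)
        report["abundance"] = ab_df
    logical_config = asdict(config)
    logical_config.pop("output_dir")  # implicit in the file's location
    provenance = {
        "config": logical_config,
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_altitudes": len(image_paths_by_altitude),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    return report
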