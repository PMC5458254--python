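"""File formats and run configuration.

Images travel as NIfTI: a dynamic series is a 4D volume (x, y, 1, t) or
a 3D volume with a declared time axis, with frame times carried in a
JSON sidecar (``<stem>.json`` with key ``frame_times_s``) or supplied by
the caller.  Masks are NIfTI or PNG (nonzero = inside).  Tables are CSV
with a header row.  A run is driven by a single YAML config
(:class:`RunConfig`), round-trippable and validated on load.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import yaml
from pydantic import BaseModel, Field

from .psic import (
    DEFAULT_PSIC_THRESHOLD,
    DEFAULT_SMOOTH_WINDOW,
    DynamicSeries,
    StageTiming,
)

__all__ = [
    "AnalysisConfig",
    "CohortConfig",
    "RunConfig",
    "read_dynamic_series",
    "write_dynamic_series",
    "write_map",
    "read_mask",
    "load_config",
    "save_config",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_dynamic_series(series: DynamicSeries, path: str | Path) -> Path:
    """Write a series as 4D NIfTI (x, y, 1, t) with a frame-time sidecar."""
    path = Path(path)
    # internal (t, row, col) -> NIfTI (col, row, 1, t); zooms carry pixel size
    arr = np.transpose(series.data, (2, 1, 0))[:, :, None, :]
    img = nib.Nifti1Image(arr, affine=np.eye(4))
    img.header.set_zooms((series.pixel_size[1], series.pixel_size[0], 1.0, 1.0))
    nib.save(img, path)
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "frame_times_s": [float(t) for t in series.times],
                "pixel_size_mm": [float(p) for p in series.pixel_size],
            },
            indent=2,
        )
    )
    return path


def read_dynamic_series(
    path: str | Path,
    times: Optional[np.ndarray] = None,
    frame_interval_s: Optional[float] = None,
    t_start: float = 0.0,
    pixel_size_mm: Optional[tuple[float, float]] = None,
) -> DynamicSeries:
    """Load a dynamic series from NIfTI.

    Frame times are resolved in order of precedence: explicit ``times``,
    the JSON sidecar written by :func:`write_dynamic_series`, then a
    uniform grid built from ``frame_interval_s``/``t_start``.  Missing
    time information is an error with an actionable message; so are
    non-monotone times.  Pixel size falls back from the sidecar to the
    NIfTI header zooms to ``pixel_size_mm`` (with a warning when the
    header carries no usable zooms).
    """
    path = Path(path)
    img = nib.load(path)
    arr = np.asarray(img.dataobj, dtype=float)
    if arr.ndim == 4:
        if arr.shape[2] != 1:
            raise ValueError(
                f"{path}: expected a single-slice 4D volume (x, y, 1, t), got {arr.shape}"
            )
        arr = arr[:, :, 0, :]
    elif arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D or 4D volume, got {arr.ndim} dims")
    data = np.transpose(arr, (2, 1, 0))  # (t, row, col)

    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if times is None:
        if "frame_times_s" in meta:
            times = np.asarray(meta["frame_times_s"], dtype=float)
        elif frame_interval_s is not None:
            times = t_start + np.arange(data.shape[0]) * frame_interval_s
        else:
            raise ValueError(
                f"{path}: no frame times available — pass times=, pass "
                f"frame_interval_s=, or provide a sidecar {sidecar.name} "
                'with key "frame_times_s"'
            )
    times = np.asarray(times, dtype=float)
    if len(times) != data.shape[0]:
        raise ValueError(
            f"{path}: {len(times)} frame times for {data.shape[0]} frames"
        )
    if not np.all(np.diff(times) > 0):
        raise ValueError(f"{path}: frame times must be strictly increasing")

    if "pixel_size_mm" in meta:
        psize = tuple(float(p) for p in meta["pixel_size_mm"])
    else:
        zooms = img.header.get_zooms()[:2]
        if all(z > 0 for z in zooms) and not all(z == 1.0 for z in zooms):
            psize = (float(zooms[1]), float(zooms[0]))
        elif pixel_size_mm is not None:
            warnings.warn(
                f"{path}: header carries no pixel size; using the configured "
                f"fallback {pixel_size_mm}",
                stacklevel=2,
            )
            psize = tuple(pixel_size_mm)
        else:
            psize = (1.0, 1.0)
    return DynamicSeries(data=data, times=times, pixel_size=psize)


def write_map(values: np.ndarray, path: str | Path,
              pixel_size: tuple[float, float] = (1.0, 1.0)) -> Path:
    """Write a 2D map (PSIC, labels, masks) as single-slice NIfTI."""
    path = Path(path)
    values = np.asarray(values)
    dtype = np.int16 if np.issubdtype(values.dtype, np.integer) else np.float64
    arr = values.T[:, :, None].astype(dtype)
    img = nib.Nifti1Image(arr, affine=np.eye(4))
    img.header.set_zooms((pixel_size[1], pixel_size[0], 1.0))
    nib.save(img, path)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask from NIfTI or PNG (nonzero = inside)."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
        return arr > 0
    arr = np.asarray(nib.load(path).dataobj)
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be 2D after squeezing, got {arr.shape}")
    return arr.T > 0


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

class AnalysisConfig(BaseModel):
    """Parameters of the mapping/classification stage."""

    psic_threshold: float = DEFAULT_PSIC_THRESHOLD
    smooth_window: int = Field(default=DEFAULT_SMOOTH_WINDOW, ge=1)
    epsilon_baseline: Optional[float] = None  # None -> 1e-6 x series median
    group_cuts: tuple[float, float] = (0.20, 0.30)
    roi_volume_mm3: float = 0.98
    slice_thickness_mm: float = 2.0


class CohortConfig(BaseModel):
    """Synthetic cohort design for the end-to-end pipeline.

    Imaging subjects vary in overall enhancement (``amplitude_scale``
    range) and in penumbra extent, so that low-PSIC area fractions span
    the grouping cuts.  The survival cohort is simulated at a larger
    size than the in-vivo study, with three latent severity classes and
    a hazard that rises steeply with the low-PSIC fraction, so that the
    group ordering of median survival is statistically stable.
    """

    n_imaging: int = Field(default=9, ge=1)
    n_po2: int = Field(default=5, ge=1)
    snr: float = Field(default=20.0, gt=0)
    amplitude_scale_range: tuple[float, float] = (0.75, 1.30)
    penumbra_outer_range_mm: tuple[float, float] = (4.5, 8.5)
    po2_noise_sd: float = 1.0
    # survival cohort
    n_per_survival_group: int = Field(default=30, ge=2)
    survival_class_centers: tuple[float, float, float] = (0.10, 0.25, 0.40)
    survival_class_sd: float = 0.025
    survival_beta: float = 9.0
    survival_baseline_hazard: float = 0.00292  # per day; median 25 d at fraction 0.25
    censor_day: float = 150.0
    # histology surrogates
    histology_slope: float = 0.35
    histology_intercept: float = -0.4
    histology_dispersion: float = 0.15
    section_slope: float = 0.8
    section_intercept: float = 0.1
    section_noise_sd: float = 0.04


class RunConfig(BaseModel):
    """Top-level configuration for ``run-all``; round-trippable YAML."""

    seed: int = 0
    output_dir: str = "results"
    stage_durations_s: tuple[float, float, float] = (300.0, 300.0, 300.0)
    frame_interval_s: float = Field(default=15.0, gt=0)
    analysis: AnalysisConfig = AnalysisConfig()
    cohort: CohortConfig = CohortConfig()
    log_level: str = "INFO"
    make_figures: bool = False

    def stage_timing(self) -> StageTiming:
        return StageTiming.from_durations(self.stage_durations_s)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(payload)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True))
    return path
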