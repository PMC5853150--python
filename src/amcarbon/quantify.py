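"""Quantify black-carbon area per airway macrophage from micrographs.

The measurement pipeline mirrors routine light-microscopy practice: a colour
micrograph is converted to a single intensity channel, an automatic threshold
selects the dark (carbonaceous) pixels inside each cell mask, the pixel count
is converted to μm² through the microscope calibration, and slide-level
summaries (median and 90th percentile over >=25 cells) feed the kinetic
analysis.

Calibrations
------------
``BRIGHTFIELD_100X``   146 pixels = 10 μm (oil-immersion x100 brightfield)
``CONFOCAL_2D``        75 pixels = 10 μm (2-D femtosecond-laser images)
``CONFOCAL_3D``        158 pixels = 41 μm (maximum-intensity projections of
                       3-D z-stacks)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.filters import threshold_isodata, threshold_otsu

__all__ = [
    "CalibrationScale",
    "BRIGHTFIELD_100X",
    "CONFOCAL_2D",
    "CONFOCAL_3D",
    "CALIBRATIONS",
    "CellMeasurement",
    "SlideSummary",
    "pixels_to_area",
    "to_intensity",
    "quantify_cell",
    "summarize_slide",
]

#: Percentile interpolation rule used everywhere (slide summaries, kinetics
#: inputs): linear interpolation between order statistics, numpy's default.
PERCENTILE_METHOD = "linear"


@dataclass(frozen=True)
class CalibrationScale:
    """Spatial calibration of one imaging modality.

    ``pixels_per_unit`` is pixels per μm along one axis, so one pixel covers
    ``(1 / pixels_per_unit)**2`` μm².
    """

    pixels_per_unit: float
    context: str

    def __post_init__(self) -> None:
        if self.pixels_per_unit <= 0:
            raise ValueError("pixels_per_unit must be positive")

    @property
    def um2_per_pixel(self) -> float:
        return (1.0 / self.pixels_per_unit) ** 2


BRIGHTFIELD_100X = CalibrationScale(146 / 10, "brightfield_100x")
CONFOCAL_2D = CalibrationScale(75 / 10, "confocal_2d")
CONFOCAL_3D = CalibrationScale(158 / 41, "confocal_3d_montage")

CALIBRATIONS = {
    "brightfield_100x": BRIGHTFIELD_100X,
    "confocal_2d": CONFOCAL_2D,
    "confocal_3d_montage": CONFOCAL_3D,
}

_THRESHOLDS = {"otsu": threshold_otsu, "isodata": threshold_isodata}


@dataclass(frozen=True)
class CellMeasurement:
    slide_id: str
    cell_id: str
    n_foreground_pixels: int
    bc_area_um2: float


@dataclass(frozen=True)
class SlideSummary:
    slide_id: str
    median_bc_um2: float
    p90_bc_um2: float
    n_cells: int
    valid: bool


def pixels_to_area(n_pixels: int, cal: CalibrationScale) -> float:
    """Convert a foreground pixel count to μm² under ``cal``.

    E.g. a full calibration square of 146x146 = 21316 pixels under the
    brightfield scale (146 px = 10 μm) is exactly 100 μm².
    """
    if n_pixels < 0:
        raise ValueError("pixel count must be non-negative")
    return float(n_pixels) * cal.um2_per_pixel


def to_intensity(image: np.ndarray) -> np.ndarray:
    """Collapse an image to one float intensity channel.

    RGB(A) images use the Rec. 709 luminance weighting (the same convention
    as scikit-image's ``rgb2gray``); single-channel images pass through.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[-1] in (3, 4):
        return img[..., :3] @ np.array([0.2125, 0.7154, 0.0721])
    raise ValueError(f"unsupported image shape {img.shape}")


def quantify_cell(
    image: np.ndarray,
    cell_mask: np.ndarray,
    cal: CalibrationScale,
    threshold_method: str = "otsu",
    slide_id: str = "slide",
    cell_id: str = "cell",
) -> CellMeasurement:
    """Measure the black-inclusion area inside one cell.

    Pixels within ``cell_mask`` whose intensity falls strictly below the
    automatic threshold (Otsu by default, IsoData as the ImageJ-style
    alternative) are counted as carbon and converted to μm².  A mask with
    uniform intensity has no meaningful threshold and yields zero foreground
    by convention.
    """
    if threshold_method not in _THRESHOLDS:
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    mask = np.asarray(cell_mask, dtype=bool)
    intensity = to_intensity(image)
    if mask.shape != intensity.shape:
        raise ValueError("mask shape must match image shape")
    vals = intensity[mask]
    if vals.size == 0:
        raise ValueError("empty cell mask")
    if np.ptp(vals) == 0:
        n_fg = 0
    else:
        thr = _THRESHOLDS[threshold_method](vals)
        n_fg = int((vals < thr).sum())
    return CellMeasurement(
        slide_id=slide_id,
        cell_id=cell_id,
        n_foreground_pixels=n_fg,
        bc_area_um2=pixels_to_area(n_fg, cal),
    )


def summarize_slide(
    measurements: Sequence[CellMeasurement] | Iterable[CellMeasurement],
    min_cells: int = 25,
    slide_id: str | None = None,
) -> SlideSummary:
    """Median and 90th percentile BC area over a slide's measured cells.

    Percentiles use linear interpolation between order statistics.  Slides
    with fewer than ``min_cells`` cells are flagged invalid (their summary is
    still returned so the caller can inspect it, but must not be fed to the
    kinetic model).
    """
    ms = list(measurements)
    if not ms:
        raise ValueError("no cell measurements")
    sid = slide_id if slide_id is not None else ms[0].slide_id
    areas = np.array([m.bc_area_um2 for m in ms], dtype=float)
    med, p90 = np.percentile(areas, [50.0, 90.0], method=PERCENTILE_METHOD)
    return SlideSummary(
        slide_id=sid,
        median_bc_um2=float(med),
        p90_bc_um2=float(p90),
        n_cells=len(ms),
        valid=len(ms) >= min_cells,
    )
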