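"""Scanned-film image handling: loading, ROI statistics, dose-map conversion.

Films are scanned as 48-bit RGB (16 bits/channel) TIFFs at a known dpi;
only the red channel carries the dosimetric signal.  Conversion to dose
applies a fitted HD calibration pixelwise, masking (never clipping) pixels
outside the calibrated span so shielded-region statistics stay unbiased.

Coordinate convention: (row, col), 0-based, row 0 at the top of the image.
Physical scale: mm-per-pixel = 25.4 / dpi.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .film_calibration import HDCurve
from .profile_analytics import DoseProfile

__all__ = [
    "FilmScan",
    "ROI",
    "DoseMap",
    "load_scan",
    "write_scan",
    "roi_mean_pixel",
    "dose_map",
    "save_dose_map",
    "profile_from_dose_map",
]

MM_PER_INCH = 25.4


@dataclass
class FilmScan:
    """A scanned film raster with its physical scale and channel layout."""

    pixels: np.ndarray  # (H, W) or (H, W, 3), uint16
    dpi: float
    channels: str = "RGB"  # or "red-only"
    scan_delay_h: float = 24.0
    film_model: str | None = None

    def __post_init__(self) -> None:
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D or (H, W, 3)")

    @property
    def mm_per_pixel(self) -> float:
        return MM_PER_INCH / self.dpi

    @property
    def red(self) -> np.ndarray:
        """The red channel (the dosimetric channel)."""
        return self.pixels if self.pixels.ndim == 2 else self.pixels[..., 0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


@dataclass(frozen=True)
class ROI:
    """A square region of interest; default 50 x 50 px at the field centre."""

    center: tuple[int, int]  # (row, col)
    size: int = 50

    def bounds(self) -> tuple[int, int, int, int]:
        r, c = self.center
        half = self.size // 2
        return r - half, r - half + self.size, c - half, c - half + self.size


@dataclass
class DoseMap:
    """A per-pixel dose raster with out-of-calibration pixels masked."""

    dose_gy: np.ndarray  # float32, NaN where masked
    mm_per_pixel: float
    source_curve: str
    out_of_range_mask: np.ndarray  # bool

    @property
    def n_masked(self) -> int:
        return int(self.out_of_range_mask.sum())


def _dpi_from_tiff(path: Path) -> float | None:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is None:
            return None
        num, den = xres.value
        res = num / den
        unit_val = getattr(unit.value, "value", unit.value) if unit is not None else 2
        if unit_val == 3:  # pixels per cm
            res *= 2.54
        # writers emit a placeholder (1, 1) when no resolution is known
        return float(res) if res > 1 else None


def load_scan(
    path,
    dpi_override: float | None = None,
    scan_delay_h: float = 24.0,
    film_model: str | None = None,
) -> FilmScan:
    """Read a film scan from a 8/16-bit grayscale or RGB TIFF/PNG.

    8-bit inputs are rescaled onto the 16-bit scale (x257, so 255 maps to
    65535) with a warning; dpi comes from file metadata unless overridden.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
        dpi = _dpi_from_tiff(path)
    elif suffix == ".png":
        with Image.open(path) as im:
            dpi_info = im.info.get("dpi")
            dpi = float(dpi_info[0]) if dpi_info and dpi_info[0] > 0 else None
            pixels = np.asarray(im)
    else:
        raise ValueError(f"unsupported scan format {suffix!r}; use TIFF or PNG")

    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[..., :3]
    if pixels.dtype == np.uint8:
        warnings.warn("8-bit scan rescaled to the 16-bit scale (x257)", stacklevel=2)
        pixels = pixels.astype(np.uint16) * 257
    elif pixels.dtype != np.uint16:
        raise ValueError(f"unsupported pixel dtype {pixels.dtype}; expected uint8/uint16")

    if dpi_override is not None:
        dpi = float(dpi_override)
    if dpi is None:
        raise ValueError(f"{path} has no dpi metadata; pass dpi_override")

    channels = "RGB" if pixels.ndim == 3 else "red-only"
    return FilmScan(pixels=pixels, dpi=dpi, channels=channels,
                    scan_delay_h=scan_delay_h, film_model=film_model)


def write_scan(scan: FilmScan, path) -> None:
    """Write a 16-bit TIFF with dpi resolution metadata."""
    tifffile.imwrite(
        path,
        scan.pixels,
        resolution=(scan.dpi, scan.dpi),
        resolutionunit="INCH",
        photometric="rgb" if scan.pixels.ndim == 3 else "minisblack",
    )


def roi_mean_pixel(scan: FilmScan, roi: ROI) -> float:
    """Arithmetic mean of red-channel values inside the square ROI."""
    r0, r1, c0, c1 = roi.bounds()
    h, w = scan.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError(f"ROI {roi} extends outside the {h}x{w} image")
    return float(scan.red[r0:r1, c0:c1].mean())


def dose_map(scan: FilmScan, curve: HDCurve) -> DoseMap:
    """Convert a film scan to a dose map by pixelwise HD interpolation.

    Pixels outside the curve's calibrated span (plus guard band) are
    masked, not clipped — clipping would silently bias statistics in
    shielded, near-saturated or unexposed regions.
    """
    if scan.film_model is not None and scan.film_model != curve.film_model:
        warnings.warn(
            f"scan film model {scan.film_model!r} does not match "
            f"calibration film model {curve.film_model!r}",
            stacklevel=2,
        )
    dose, mask = curve.evaluate_masked(scan.red)
    return DoseMap(
        dose_gy=dose.astype(np.float32),
        mm_per_pixel=scan.mm_per_pixel,
        source_curve=curve.experiment_id or curve.film_model,
        out_of_range_mask=mask,
    )


def save_dose_map(dm: DoseMap, path) -> None:
    """Write the dose raster as 32-bit float TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, dm.dose_gy, photometric="minisblack")
    sidecar = {
        "mm_per_pixel": dm.mm_per_pixel,
        "source_curve": dm.source_curve,
        "n_masked": dm.n_masked,
        "units": "Gy",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def profile_from_dose_map(
    dm: DoseMap,
    row: int | None = None,
    col: int | None = None,
    band_px: int = 1,
    margin_mm: float | None = None,
    axis_label: str = "",
) -> DoseProfile:
    """Extract a 1-D dose profile along one image row or column.

    Positions are in mm relative to the image centre; masked pixels are
    dropped.  ``band_px`` > 1 averages that many adjacent rows (or columns)
    centred on the requested line, suppressing film grain noise in the same
    way a physical film strip is read across its width.  Exactly one of
    ``row`` / ``col`` must be given.
    """
    if (row is None) == (col is None):
        raise ValueError("specify exactly one of row or col")
    half = max(band_px, 1) // 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        if row is not None:
            band = dm.dose_gy[max(row - half, 0): row + half + 1, :]
            doses = np.nanmean(band, axis=0)
        else:
            band = dm.dose_gy[:, max(col - half, 0): col + half + 1]
            doses = np.nanmean(band, axis=1)
    n = doses.size
    positions = (np.arange(n) - (n - 1) / 2.0) * dm.mm_per_pixel
    keep = ~np.isnan(doses)
    return DoseProfile(
        positions_mm=positions[keep],
        doses=doses[keep].astype(float),
        margin_mm=margin_mm,
        axis_label=axis_label or (f"row {row}" if row is not None else f"col {col}"),
    )
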