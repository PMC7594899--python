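"""Hunter-Driffield (HD) film calibration curves.

Radiochromic (Gafchromic) film darkens with absorbed dose, so the mean
red-channel pixel value of a flatbed scan decreases monotonically as dose
increases.  A calibration ("HD") curve built from film pieces exposed to a
grid of known doses lets any later scan be converted to dose by polynomial
interpolation.  This module fits dose as a third- or fourth-order polynomial
of mean pixel value, evaluates it with an extrapolation guard, and quantifies
inter-experiment (film batch) variability across a set of curves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FILM_DYNAMIC_RANGE_GY",
    "HD_DOSE_GRID_GY",
    "CalibrationPoint",
    "HDCurve",
    "CurveSetDeviation",
    "CalibrationError",
    "ExtrapolationError",
    "build_hd_curve",
    "select_order",
    "dose_from_pixel",
    "curve_set_deviation",
    "load_calibration_csv",
    "curve_to_json",
    "curve_from_json",
]

#: Dynamic dose range (Gy) of the supported Gafchromic film models.
FILM_DYNAMIC_RANGE_GY: dict[str, tuple[float, float]] = {
    "RTQA2": (0.02, 8.0),
    "EBT-XD": (0.1, 60.0),
}

#: Dose grid (Gy) used for building calibration curves; individual
#: experiments use the subset covering their working range.
HD_DOSE_GRID_GY: tuple[float, ...] = (
    0, 0.1, 0.5, 1, 2.5, 3, 3.5, 4, 5, 6, 7, 10, 12, 15, 17, 20, 22, 24, 30, 33,
)

PIXEL_MAX = 65535.0


class CalibrationError(ValueError):
    """Raised when a calibration curve cannot be built or is unusable."""


class ExtrapolationError(ValueError):
    """Raised when a pixel value falls outside the calibrated span."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One (dose, mean red-channel pixel value) calibration measurement."""

    dose_gy: float
    mean_pixel: float
    film_model: str = "EBT-XD"

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ValueError(f"dose must be >= 0 Gy, got {self.dose_gy}")
        if not 0 <= self.mean_pixel <= PIXEL_MAX:
            raise ValueError(f"mean_pixel must lie in [0, 65535], got {self.mean_pixel}")
        if self.film_model not in FILM_DYNAMIC_RANGE_GY:
            raise ValueError(f"unknown film model {self.film_model!r}")


@dataclass
class HDCurve:
    """Fitted dose-of-pixel calibration polynomial with its validity limits.

    ``coefficients`` are in descending power order (``numpy.polyval``
    convention).  The curve refuses evaluation outside ``pixel_span``
    (plus a small configurable guard band) because film response saturates
    outside its calibrated range and the polynomial diverges.
    """

    coefficients: np.ndarray
    order: int
    dose_range_gy: tuple[float, float]
    pixel_span: tuple[float, float]
    film_model: str
    fit_residual: float
    direction: str = "dose_of_pixel"
    guard_band_frac: float = 0.01
    experiment_id: str = ""

    def __call__(self, mean_pixel):
        return dose_from_pixel(self, mean_pixel)

    def evaluate_masked(self, pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised evaluation returning ``(dose, out_of_span_mask)``.

        Out-of-span pixels are masked rather than clipped; in-span results
        are clipped to the calibrated dose range.
        """
        pixels = np.asarray(pixels, dtype=float)
        lo, hi = self._guarded_span()
        mask = (pixels < lo) | (pixels > hi)
        dose = np.polyval(self.coefficients, pixels)
        dose = np.clip(dose, self.dose_range_gy[0], self.dose_range_gy[1])
        dose[mask] = np.nan
        return dose, mask

    def _guarded_span(self) -> tuple[float, float]:
        lo, hi = self.pixel_span
        band = self.guard_band_frac * (hi - lo)
        return lo - band, hi + band


@dataclass(frozen=True)
class CurveSetDeviation:
    """Per-curve percent deviation from the cross-curve mean pixel at one dose."""

    dose_gy: float
    per_curve_deviation_pct: dict[int, float] = field(default_factory=dict)


def _validate_doses(points: Sequence[CalibrationPoint], film_model: str) -> None:
    lo, hi = FILM_DYNAMIC_RANGE_GY[film_model]
    for p in points:
        # dose 0 (unexposed base) is always an admissible anchor
        if p.dose_gy != 0 and not (lo <= p.dose_gy <= hi):
            raise CalibrationError(
                f"dose {p.dose_gy} Gy outside {film_model} dynamic range [{lo}, {hi}] Gy"
            )


def build_hd_curve(
    points: Sequence[CalibrationPoint],
    order: int | None = None,
    guard_band_frac: float = 0.01,
    experiment_id: str = "",
) -> HDCurve:
    """Least-squares fit of dose as an ``order``-degree polynomial of pixel value.

    Parameters
    ----------
    points
        Calibration measurements, all from the same film model.  At least
        ``order + 2`` points are required (one more than the interpolating
        minimum, so the residual is meaningful).
    order
        3 or 4.  ``None`` selects the order with the smaller leave-one-out
        RMS error (see :func:`select_order`).

    Raises
    ------
    CalibrationError
        Too few points, mixed film models, doses outside the film's dynamic
        range, or a fitted mapping that is not monotone over the calibrated
        pixel span (an unusable calibration).
    """
    if order is None:
        order = select_order(points)
    if order not in (3, 4):
        raise CalibrationError(f"polynomial order must be 3 or 4, got {order}")
    models = {p.film_model for p in points}
    if len(models) != 1:
        raise CalibrationError(f"calibration points mix film models: {sorted(models)}")
    film_model = models.pop()
    if len(points) < order + 2:
        raise CalibrationError(
            f"need at least {order + 2} points for an order-{order} fit, got {len(points)}"
        )
    _validate_doses(points, film_model)

    pixels = np.array([p.mean_pixel for p in points], dtype=float)
    doses = np.array([p.dose_gy for p in points], dtype=float)
    coeffs = np.polyfit(pixels, doses, order)

    pred = np.polyval(coeffs, pixels)
    pos = doses > 0
    if pos.any():
        fit_residual = float(np.sqrt(np.mean(((pred[pos] - doses[pos]) / doses[pos]) ** 2)))
    else:
        fit_residual = float(np.sqrt(np.mean((pred - doses) ** 2)))

    span = (float(pixels.min()), float(pixels.max()))
    grid = np.linspace(span[0], span[1], 1000)
    deriv = np.polyval(np.polyder(coeffs), grid)
    if not ((deriv < 0).all() or (deriv > 0).all()):
        raise CalibrationError(
            "fitted dose-of-pixel mapping is not monotone over the calibrated "
            "pixel span; the calibration is unusable"
        )

    return HDCurve(
        coefficients=coeffs,
        order=order,
        dose_range_gy=(float(doses.min()), float(doses.max())),
        pixel_span=span,
        film_model=film_model,
        fit_residual=fit_residual,
        guard_band_frac=guard_band_frac,
        experiment_id=experiment_id,
    )


def select_order(points: Sequence[CalibrationPoint], candidates: Iterable[int] = (3, 4)) -> int:
    """Pick the polynomial order minimising leave-one-out RMS dose error."""
    pixels = np.array([p.mean_pixel for p in points], dtype=float)
    doses = np.array([p.dose_gy for p in points], dtype=float)
    best_order, best_rms = None, np.inf
    for order in candidates:
        if len(points) < order + 2:
            continue
        errs = []
        for i in range(len(points)):
            keep = np.arange(len(points)) != i
            c = np.polyfit(pixels[keep], doses[keep], order)
            errs.append(np.polyval(c, pixels[i]) - doses[i])
        rms = float(np.sqrt(np.mean(np.square(errs))))
        if rms < best_rms:
            best_order, best_rms = order, rms
    if best_order is None:
        raise CalibrationError("too few points for any candidate order")
    return best_order


def dose_from_pixel(curve: HDCurve, mean_pixel: float) -> float:
    """Convert a mean pixel value to dose (Gy) via the fitted polynomial.

    Pixel values outside the calibrated span (plus the guard band) raise
    :class:`ExtrapolationError` — the polynomial has no physical meaning
    there.  In-span results falling outside the calibrated dose range are
    clipped and a warning is emitted.
    """
    lo, hi = curve._guarded_span()
    if not lo <= mean_pixel <= hi:
        raise ExtrapolationError(
            f"pixel value {mean_pixel} outside calibrated span "
            f"[{curve.pixel_span[0]:.0f}, {curve.pixel_span[1]:.0f}] "
            f"(guard band {curve.guard_band_frac:.1%})"
        )
    dose = float(np.polyval(curve.coefficients, mean_pixel))
    d_lo, d_hi = curve.dose_range_gy
    if not d_lo <= dose <= d_hi:
        clipped = min(max(dose, d_lo), d_hi)
        warnings.warn(
            f"interpolated dose {dose:.3f} Gy outside calibrated range "
            f"[{d_lo}, {d_hi}] Gy; clipped to {clipped:.3f} Gy",
            stacklevel=2,
        )
        dose = clipped
    return dose


def curve_set_deviation(
    curve_points: Sequence[Sequence[CalibrationPoint]],
    min_curves: int = 3,
) -> list[CurveSetDeviation]:
    """Percent deviation of each curve's pixel value from the cross-curve mean.

    Quantifies inter-experiment (film batch / scan session) variability.
    Doses measured by fewer than ``min_curves`` curves are excluded; the
    default of 3 keeps only doses with n > 2, where a cross-curve mean is
    meaningful.  At every reported dose the deviations average to zero by
    construction.
    """
    if len(curve_points) < 2:
        raise CalibrationError("need at least two curves to compare")
    by_dose: dict[float, dict[int, float]] = {}
    for idx, pts in enumerate(curve_points):
        for p in pts:
            by_dose.setdefault(p.dose_gy, {})[idx] = p.mean_pixel
    common = {d: v for d, v in by_dose.items() if len(v) >= min_curves}
    if not common:
        raise CalibrationError(f"no dose shared by at least {min_curves} curves")
    out = []
    for dose in sorted(common):
        vals = common[dose]
        mean = float(np.mean(list(vals.values())))
        devs = {i: 100.0 * (v - mean) / mean for i, v in vals.items()}
        out.append(CurveSetDeviation(dose_gy=dose, per_curve_deviation_pct=devs))
    return out


# ---------------------------------------------------------------------------
# I/O: calibration tables as CSV, fitted curves as JSON

def load_calibration_csv(path) -> dict[str, list[CalibrationPoint]]:
    """Read a ``dose_gy,mean_pixel,film_model,experiment_id`` table.

    Returns calibration points grouped by experiment id.
    """
    df = pd.read_csv(path)
    required = {"dose_gy", "mean_pixel", "film_model"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV missing columns: {sorted(missing)}")
    if "experiment_id" not in df.columns:
        df["experiment_id"] = "default"
    out: dict[str, list[CalibrationPoint]] = {}
    for exp, sub in df.groupby("experiment_id", sort=False):
        out[str(exp)] = [
            CalibrationPoint(float(r.dose_gy), float(r.mean_pixel), str(r.film_model))
            for r in sub.itertuples()
        ]
    return out


def curve_to_json(curve: HDCurve, path=None) -> str:
    payload = {
        "coefficients": [float(c) for c in curve.coefficients],
        "order": curve.order,
        "dose_range_gy": list(curve.dose_range_gy),
        "pixel_span": list(curve.pixel_span),
        "film_model": curve.film_model,
        "fit_residual": curve.fit_residual,
        "direction": curve.direction,
        "guard_band_frac": curve.guard_band_frac,
        "experiment_id": curve.experiment_id,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def curve_from_json(source) -> HDCurve:
    if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
        payload = json.loads(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    return HDCurve(
        coefficients=np.asarray(payload["coefficients"], dtype=float),
        order=int(payload["order"]),
        dose_range_gy=tuple(payload["dose_range_gy"]),
        pixel_span=tuple(payload["pixel_span"]),
        film_model=payload["film_model"],
        fit_residual=float(payload["fit_residual"]),
        direction=payload.get("direction", "dose_of_pixel"),
        guard_band_frac=float(payload.get("guard_band_frac", 0.01)),
        experiment_id=payload.get("experiment_id", ""),
    )
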