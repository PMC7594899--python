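"""Dose-profile analytics: field edges, penumbrae, uniformity, margin targeting.

A tangential field is characterised by its cross-profile: a plateau over the
exposed tumour aperture falling off through a penumbra into the shielded
surround.  Standard metrics quantify it — the 50% crossings define the field
edges, the 80–20% lateral distance is the penumbral width (sharpness), the
plateau flatness and the spread of doses across the five restraint positions
measure delivery uniformity, and the signed distance of the exposure edge
from the tumour margin measures targeting accuracy.

Sign convention for margin offsets: positive means the exposure edge sits on
the tumour side of the margin (under-coverage of the margin, no spill);
negative means the beam spills into the shielded side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "DoseProfile",
    "ProfileMetrics",
    "SiteDoseSummary",
    "LevelNotCrossedError",
    "normalize_profile",
    "penumbra_width",
    "field_edge_positions",
    "margin_offset",
    "percent_dose_at",
    "site_uniformity",
    "analyze_profile",
    "read_profile_csv",
    "write_profile_csv",
]


class LevelNotCrossedError(ValueError):
    """Raised when a profile never crosses a requested dose level."""


@dataclass
class DoseProfile:
    """A 1-D dose profile along a named axis.

    ``doses`` are in Gy, or in % of the plateau mean after
    :func:`normalize_profile` (``unit`` records which, ``plateau_gy`` the
    normalisation constant).  ``margin_mm`` marks the tumour-margin position
    on this axis, where one is defined.
    """

    positions_mm: np.ndarray
    doses: np.ndarray
    margin_mm: float | None = None
    axis_label: str = ""
    unit: str = "Gy"
    plateau_gy: float | None = None

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.doses = np.asarray(self.doses, dtype=float)
        if self.positions_mm.shape != self.doses.shape:
            raise ValueError("positions and doses must have equal length")
        if self.positions_mm.size < 2:
            raise ValueError("a profile needs at least two samples")
        if not (np.diff(self.positions_mm) > 0).all():
            raise ValueError("positions must be strictly increasing")


@dataclass(frozen=True)
class ProfileMetrics:
    """Field-edge, penumbra and flatness summary of one cross-profile."""

    edge_50_left_mm: float
    edge_50_right_mm: float
    penumbra_80_20_left_mm: float
    penumbra_80_20_right_mm: float
    plateau_mean_gy: float
    flatness_pct: float


@dataclass(frozen=True)
class SiteDoseSummary:
    """Uniformity of doses across the restraint positions.

    Both spread metrics are reported: SEM% (standard error of the mean as a
    percentage of the mean) and the maximum absolute deviation from the mean
    in percent.  They answer different questions and are never conflated.
    """

    site_doses_gy: tuple[float, ...]
    mean_gy: float
    sem_percent: float
    max_abs_dev_percent: float


def normalize_profile(
    profile: DoseProfile,
    plateau_window: tuple[float, float] | None = None,
) -> DoseProfile:
    """Express a profile in % of its plateau mean.

    ``plateau_window`` is a (lo, hi) mm range containing at least 3 samples;
    when omitted, the plateau is taken as all samples at >= 98% of the 98th
    percentile (a robust top that excludes the penumbra shoulder; for noisy
    profiles an explicit window avoids threshold-selection bias).  Idempotent:
    normalising an already-normalised profile leaves it unchanged (its plateau
    mean is 100 by construction).
    """
    x, d = profile.positions_mm, profile.doses
    if plateau_window is not None:
        sel = (x >= plateau_window[0]) & (x <= plateau_window[1])
        if sel.sum() < 3:
            raise ValueError("plateau window must contain at least 3 samples")
    else:
        sel = d >= 0.98 * np.percentile(d, 98)
    plateau = float(d[sel].mean())
    if plateau <= 0:
        raise ValueError("plateau mean must be positive")
    plateau_gy = plateau if profile.unit == "Gy" else profile.plateau_gy
    return replace(
        profile,
        doses=100.0 * d / plateau,
        unit="%",
        plateau_gy=plateau_gy,
    )


def _as_percent(profile: DoseProfile) -> DoseProfile:
    return profile if profile.unit == "%" else normalize_profile(profile)


def _edge_crossing(x: np.ndarray, d: np.ndarray, level: float, side: str) -> float:
    """Position of the first ``level`` crossing walking outward from the plateau.

    Starts at the outermost sample of the plateau core (>= 90%) and walks
    toward the requested profile end, taking the first bracketing pair and
    interpolating linearly — robust to noise on the plateau.
    """
    core = np.flatnonzero(d >= 90.0)
    if core.size == 0:
        raise LevelNotCrossedError("profile has no plateau core (no samples >= 90%)")
    if side == "left":
        idxs = range(core[0], 0, -1)
        step = -1
    else:
        idxs = range(core[-1], d.size - 1)
        step = 1
    for i in idxs:
        a, b = d[i], d[i + step]
        if (a - level) * (b - level) <= 0 and a != b:
            frac = (a - level) / (a - b)
            return float(x[i] + frac * (x[i + step] - x[i]))
    raise LevelNotCrossedError(f"{side} edge never crosses {level:g}% level")


def field_edge_positions(profile: DoseProfile, level: float = 50.0) -> tuple[float, float]:
    """(left, right) positions in mm where the profile crosses ``level``%."""
    p = _as_percent(profile)
    return (
        _edge_crossing(p.positions_mm, p.doses, level, "left"),
        _edge_crossing(p.positions_mm, p.doses, level, "right"),
    )


def penumbra_width(
    profile: DoseProfile, hi: float = 80.0, lo: float = 20.0
) -> tuple[float, float]:
    """80–20% penumbral width (mm) of the left and right field edges.

    Each edge is analysed independently; an edge that does not cross both
    levels yields NaN with a warning rather than failing the other edge.
    """
    p = _as_percent(profile)
    widths = []
    for side in ("left", "right"):
        try:
            x_hi = _edge_crossing(p.positions_mm, p.doses, hi, side)
            x_lo = _edge_crossing(p.positions_mm, p.doses, lo, side)
            widths.append(abs(x_lo - x_hi))
        except LevelNotCrossedError as exc:
            warnings.warn(f"{side} edge: {exc}", stacklevel=2)
            widths.append(math.nan)
    return tuple(widths)


def margin_offset(profile: DoseProfile, exposure_threshold: float = 50.0) -> float:
    """Signed distance (mm) of the exposure edge from the tumour margin.

    Positive: the edge sits on the tumour side of the margin.  Negative:
    the beam spills into the shielded side.  The edge is the
    ``exposure_threshold``% crossing nearest the margin; which side is
    "tumour" is read off the local dose gradient (the high-dose side).
    """
    if profile.margin_mm is None:
        raise ValueError("profile has no margin_mm set")
    p = _as_percent(profile)
    crossings = []
    for side in ("left", "right"):
        try:
            crossings.append((side, _edge_crossing(p.positions_mm, p.doses, exposure_threshold, side)))
        except LevelNotCrossedError:
            pass
    if not crossings:
        raise LevelNotCrossedError(
            f"profile never crosses the {exposure_threshold:g}% exposure threshold"
        )
    side, x_e = min(crossings, key=lambda c: abs(c[1] - profile.margin_mm))
    # left edge: field (tumour) lies at larger x; right edge: at smaller x
    tumour_sign = 1.0 if side == "left" else -1.0
    return tumour_sign * (x_e - profile.margin_mm)


def percent_dose_at(profile: DoseProfile, position_mm: float, reference_gy: float) -> float:
    """Dose at ``position_mm`` (linear interpolation) as % of ``reference_gy``."""
    if reference_gy <= 0:
        raise ValueError("reference dose must be positive")
    if profile.unit != "Gy":
        raise ValueError("percent_dose_at expects a profile in Gy")
    x, d = profile.positions_mm, profile.doses
    if not x[0] <= position_mm <= x[-1]:
        raise ValueError(f"position {position_mm} mm outside profile span")
    return 100.0 * float(np.interp(position_mm, x, d)) / reference_gy


def site_uniformity(site_doses_gy) -> SiteDoseSummary:
    """Mean, SEM% and max-deviation% of doses across restraint positions."""
    d = np.asarray(site_doses_gy, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two site doses")
    mean = float(d.mean())
    if mean <= 0:
        raise ValueError("mean site dose must be positive")
    sem = float(d.std(ddof=1) / np.sqrt(d.size))
    return SiteDoseSummary(
        site_doses_gy=tuple(float(v) for v in d),
        mean_gy=mean,
        sem_percent=100.0 * sem / mean,
        max_abs_dev_percent=100.0 * float(np.abs(d - mean).max()) / mean,
    )


def analyze_profile(
    profile: DoseProfile,
    plateau_window: tuple[float, float] | None = None,
    flatness_core_frac: float = 0.8,
) -> ProfileMetrics:
    """Full metric set for one cross-profile.

    Flatness is the maximum % deviation from the plateau mean within the
    central ``flatness_core_frac`` of the 50%-edge field width (the paper-free
    default of 80% excludes the penumbrae).
    """
    p = normalize_profile(profile, plateau_window)
    left, right = field_edge_positions(p)
    pen_l, pen_r = penumbra_width(p)
    centre = 0.5 * (left + right)
    half_core = 0.5 * flatness_core_frac * (right - left)
    sel = (p.positions_mm >= centre - half_core) & (p.positions_mm <= centre + half_core)
    flatness = float(np.abs(p.doses[sel] - 100.0).max())
    return ProfileMetrics(
        edge_50_left_mm=left,
        edge_50_right_mm=right,
        penumbra_80_20_left_mm=pen_l,
        penumbra_80_20_right_mm=pen_r,
        plateau_mean_gy=p.plateau_gy if p.plateau_gy is not None else math.nan,
        flatness_pct=flatness,
    )


# ---------------------------------------------------------------------------
# I/O: profiles as position_mm,dose_gy CSV with an optional margin comment

def write_profile_csv(profile: DoseProfile, path) -> None:
    with open(path, "w") as fh:
        if profile.margin_mm is not None:
            fh.write(f"# margin_mm={profile.margin_mm}\n")
        if profile.axis_label:
            fh.write(f"# axis={profile.axis_label}\n")
        fh.write("position_mm,dose_gy\n")
        for x, d in zip(profile.positions_mm, profile.doses):
            fh.write(f"{x:.6g},{d:.6g}\n")


def read_profile_csv(path) -> DoseProfile:
    margin = None
    label = ""
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "margin_mm":
                margin = float(val)
            elif key.strip() == "axis":
                label = val.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    return DoseProfile(
        positions_mm=df["position_mm"].to_numpy(),
        doses=df["dose_gy"].to_numpy(),
        margin_mm=margin,
        axis_label=label,
    )
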