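import numpy as np
import pytest

from sarjdose.film_calibration import CalibrationPoint, build_hd_curve
from sarjdose.synthetic_data import FilmResponseModel


@pytest.fixture
def exact_cubic():
    """A strictly decreasing cubic dose-of-pixel relation and exact points.

    dose(p) = -2e-14 p^3 - 8e-4 p + 55 on p in [20000, 62000]; doses span
    roughly 0.6 to 38.8 Gy, inside the EBT-XD dynamic range.  Pixel knots
    are exact integers so uint16 rasters hold them exactly.
    """
    coeffs = np.array([-2e-14, 0.0, -8e-4, 55.0])
    pixels = np.linspace(20000.0, 62000.0, 8)
    doses = np.polyval(coeffs, pixels)
    points = [CalibrationPoint(float(d), float(p), "EBT-XD") for d, p in zip(doses, pixels)]
    return coeffs, pixels, doses, points


@pytest.fixture
def exact_cubic_curve(exact_cubic):
    _, _, _, points = exact_cubic
    return build_hd_curve(points, 3)


@pytest.fixture
def film_model():
    return FilmResponseModel()


@pytest.fixture
def low_range_film_model():
    """RTQA2-like model restricted to its 0-8 Gy dynamic range."""
    return FilmResponseModel(film_model="RTQA2", dose_span_gy=(0.0, 8.0))
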