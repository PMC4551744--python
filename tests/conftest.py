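import numpy as np
import pandas as pd
import pytest

from spatind.survey import SurveyDataset


def make_dataset(x, y, densities: dict[str, np.ndarray], s=None,
                 origin=(15.0, 37.0), year=2005, sub_area="S1", transect=None):
    """Build a projected SurveyDataset directly from planar coordinates."""
    from spatind.survey import inverse_project
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    s = np.full(n, 1.0) if s is None else np.asarray(s, dtype=float)
    lon, lat = inverse_project(x, y, origin)
    df = pd.DataFrame({
        "survey_year": year, "sub_area": sub_area,
        "transect_id": transect if transect is not None else "T0",
        "lon": lon, "lat": lat, "area_influence": s, "x": x, "y": y,
    })
    for sp, z in densities.items():
        df[f"density_{sp}"] = np.asarray(z, dtype=float)
    return SurveyDataset(df, tuple(densities), origin=origin)


def random_instance(rng, n=None, zero_inflated=True):
    """Small random (x, y, z, s) arrays for oracle cross-checks."""
    n = n or rng.integers(2, 21)
    x = rng.uniform(0, 60, n)
    y = rng.uniform(0, 40, n)
    z = rng.lognormal(0.0, 1.0, n)
    if zero_inflated:
        z[rng.random(n) < 0.3] = 0.0
    if not np.any(z > 0):
        z[rng.integers(n)] = 1.0
    s = rng.uniform(0.5, 10.0, n)
    return x, y, z, s


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)
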