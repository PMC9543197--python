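"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tailsync import Panel

KM_PER_DEG_LAT = 111.1950802335329


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def line_sites(n: int, spacing_km: float = 1.0, lat0: float = 36.0) -> pd.DataFrame:
    """Sites on a meridian so haversine distance equals along-line distance."""
    lat = lat0 - np.arange(n) * spacing_km / KM_PER_DEG_LAT
    return pd.DataFrame(
        {"site_id": [f"s{i}" for i in range(n)], "lon": -120.0, "lat": lat}
    )


def make_panel(values: np.ndarray, start_year: int = 2000, name: str = "x") -> Panel:
    values = np.asarray(values, dtype=float)
    return Panel(
        site_ids=[f"s{i}" for i in range(values.shape[0])],
        years=np.arange(start_year, start_year + values.shape[1]),
        values=values,
        variable_name=name,
    )


def gaussian_copula_panel(
    rng: np.random.Generator,
    corr: np.ndarray,
    n_years: int,
    lognormal: bool = True,
) -> Panel:
    """Panel with a Gaussian copula across sites and iid years."""
    chol = np.linalg.cholesky(corr)
    z = chol @ rng.standard_normal((corr.shape[0], n_years))
    vals = np.exp(z) if lognormal else z
    return make_panel(vals)


def clayton_sample(
    rng: np.random.Generator, theta: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate Clayton copula sample (lower-tail dependent) via gamma frailty."""
    w = rng.gamma(1.0 / theta, 1.0, size=n)
    e = rng.exponential(size=(2, n))
    u = (1.0 + e / w) ** (-1.0 / theta)
    return u[0], u[1]


def clayton_panel(
    rng: np.random.Generator, n_sites: int, n_years: int, theta: float = 2.0
) -> Panel:
    """Panel whose sites share a multivariate Clayton copula.

    Every pair of sites is positively associated with planted lower-tail
    dependence, so the summed tail-dependence strength is strongly
    negative relative to a tail-symmetric null.
    """
    w = rng.gamma(1.0 / theta, 1.0, size=n_years)
    e = rng.exponential(size=(n_sites, n_years))
    return make_panel((1.0 + e / w) ** (-1.0 / theta))
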