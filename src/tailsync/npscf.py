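"""Nonparametric spatial covariance functions with bootstrap envelopes.

The distance decay of synchrony is estimated by smoothing the cloud of
(pairwise distance, pairwise synchrony) points with a penalized cubic
B-spline whose flexibility is expressed as equivalent degrees of freedom
(the trace of the smoother matrix).  The penalty is the integrated squared
second derivative, so constants and straight lines are reproduced exactly
and the smoother is linear in the synchrony values.  Confidence envelopes
come from resampling sites (not pairs) with replacement and refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .io_panels import DistanceMatrix, Panel
from .tail_stats import TailBand

logger = logging.getLogger("tailsync")

#: Latitude of Point Conception, the conventional central/southern
#: California divide, degrees North.
POINT_CONCEPTION_LAT = 34.449


# ---------------------------------------------------------------------------
# Penalized cubic spline smoother with fixed equivalent df
# ---------------------------------------------------------------------------


class _Pspline:
    """Weighted cubic P-spline with flexibility fixed by equivalent df.

    The roughness penalty is the exact second-derivative Gram matrix of
    the basis, and the penalty weight is solved (bisection on its log) so
    that the trace of the hat matrix equals the requested df.  Because the
    penalty weight depends only on the design and weights, never on the
    response, the fitted curve is linear in the response.
    """

    def __init__(self, x: np.ndarray, df: float, n_basis: int = 30):
        x = np.asarray(x, dtype=float)
        self.x_min, self.x_max = float(x.min()), float(x.max())
        if self.x_max <= self.x_min:
            raise ValueError("need at least two distinct distances to smooth")
        n_unique = len(np.unique(x))
        self.n_basis = int(min(n_basis, max(4, n_unique)))
        n_interior = self.n_basis - 4
        interior = np.linspace(self.x_min, self.x_max, n_interior + 2)[1:-1]
        self.knots = np.concatenate(
            [[self.x_min] * 4, interior, [self.x_max] * 4]
        )
        self.df = float(np.clip(df, 2.0, self.n_basis))
        self.design = self._design(x)
        self.penalty = self._second_derivative_gram()

    def _design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.x_min, self.x_max)
        return BSpline.design_matrix(x, self.knots, 3).toarray()

    def _second_derivative_gram(self) -> np.ndarray:
        """Exact integral of products of basis second derivatives.

        Each second derivative is piecewise linear, so two-point
        Gauss-Legendre per inter-knot interval integrates the quadratic
        products exactly.
        """
        nb = self.n_basis
        breaks = np.unique(self.knots)
        gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
        pts, wts = [], []
        for a, b in zip(breaks[:-1], breaks[1:]):
            half = (b - a) / 2.0
            pts.extend(((a + b) / 2.0 + half * gauss).tolist())
            wts.extend([half, half])
        pts = np.asarray(pts)
        wts = np.asarray(wts)
        d2 = np.empty((len(pts), nb))
        for j in range(nb):
            coef = np.zeros(nb)
            coef[j] = 1.0
            d2[:, j] = BSpline(self.knots, coef, 3).derivative(2)(pts)
        return (d2 * wts[:, None]).T @ d2

    def solve(self, y: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
        """Return spline coefficients for responses y (can be 2-D: (m, n))."""
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if w is None:
            w = np.ones(self.design.shape[0])
        bw = self.design * w[:, None]
        btb = bw.T @ self.design
        bty = bw.T @ y.T
        lam = self._lambda_for_df(btb)
        ridge = 1e-12 * np.trace(btb) / self.n_basis * np.eye(self.n_basis)
        coefs = np.linalg.solve(btb + lam * self.penalty + ridge, bty)
        return coefs.T

    def _lambda_for_df(self, btb: np.ndarray) -> float:
        # Work on lambda relative to the natural scale of the problem so
        # the search stays in a numerically trustworthy window.
        scale = np.trace(btb) / max(np.trace(self.penalty), 1e-300)
        ridge = 1e-12 * np.trace(btb) / self.n_basis * np.eye(self.n_basis)

        def edf(log_rel: float) -> float:
            g = btb + scale * 10.0**log_rel * self.penalty + ridge
            try:
                return float(np.trace(np.linalg.solve(g, btb)))
            except np.linalg.LinAlgError:
                return float(self.n_basis)

        lo, hi = -12.0, 6.0
        if edf(lo) <= self.df:
            return scale * 10.0**lo
        if edf(hi) >= self.df:
            return scale * 10.0**hi
        for _ in range(60):
            mid = (lo + hi) / 2.0
            if edf(mid) > self.df:
                lo = mid
            else:
                hi = mid
        return scale * 10.0 ** ((lo + hi) / 2.0)

    def predict(self, coefs: np.ndarray, grid: np.ndarray) -> np.ndarray:
        basis = self._design(np.asarray(grid, dtype=float))
        return np.atleast_2d(coefs) @ basis.T


# ---------------------------------------------------------------------------
# Spatial covariance function estimation
# ---------------------------------------------------------------------------


@dataclass
class NpscfResult:
    """Smoothed distance decay of synchrony with a bootstrap envelope."""

    distance_grid: np.ndarray
    estimate: np.ndarray
    lower95: np.ndarray | None
    upper95: np.ndarray | None
    equivalent_df: float
    n_boot: int
    band: TailBand | None = None
    region_label: str = "all"
    extrapolated: np.ndarray | None = None


def _pair_cloud(M: np.ndarray, dist: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices_from(M, k=1)
    x = dist.d[iu]
    y = M[iu]
    ok = np.isfinite(y)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("dropping %d pairs with missing synchrony", dropped)
    return x[ok], y[ok]


def default_grid(dist: DistanceMatrix, n_points: int = 100) -> np.ndarray:
    """Evenly spaced grid from 0 to the 75th percentile of pair distances."""
    iu = np.triu_indices_from(dist.d, k=1)
    return np.linspace(0.0, np.percentile(dist.d[iu], 75.0), n_points)


def fit_npscf(
    M: np.ndarray,
    dist: DistanceMatrix,
    df: float | None = None,
    grid: np.ndarray | None = None,
    band: TailBand | None = None,
    region_label: str = "all",
) -> NpscfResult:
    """Smooth the pairwise synchrony cloud against distance.

    ``df`` defaults to ``sqrt(n_sites)``.  Grid points outside the
    observed distance range are evaluated (the spline is clamped to the
    boundary) but flagged in ``extrapolated``.
    """
    n_sites = M.shape[0]
    if df is None:
        df = float(np.sqrt(n_sites))
    x, y = _pair_cloud(M, dist)
    if len(x) < 10:
        raise ValueError("need at least 10 site pairs to fit the smoother")
    if grid is None:
        grid = default_grid(dist)
    grid = np.asarray(grid, dtype=float)
    spline = _Pspline(x, df)
    coefs = spline.solve(y)
    est = spline.predict(coefs, grid)[0]
    extrap = (grid < x.min()) | (grid > x.max())
    if extrap.any():
        logger.warning("%d grid points lie outside the observed distance range", int(extrap.sum()))
    return NpscfResult(
        distance_grid=grid,
        estimate=est,
        lower95=None,
        upper95=None,
        equivalent_df=df,
        n_boot=0,
        band=band,
        region_label=region_label,
        extrapolated=extrap,
    )


def bootstrap_npscf(
    M: np.ndarray,
    dist: DistanceMatrix,
    df: float | None = None,
    grid: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    band: TailBand | None = None,
    region_label: str = "all",
) -> NpscfResult:
    """Fit the spatial covariance function with a 95% bootstrap envelope.

    Sites (not pairs) are resampled with replacement; each replicate keeps
    the pairs among distinct resampled sites, weighting pair (i, j) by the
    product of the sites' resampling multiplicities (self-pairs arising
    from duplicated sites are dropped), and refits the smoother at the
    same equivalent df.  The envelope is the pointwise 2.5/97.5 percentile
    band of the replicate curves.
    """
    n_sites = M.shape[0]
    if n_sites < 10:
        raise ValueError("bootstrap envelope needs at least 10 sites")
    if df is None:
        df = float(np.sqrt(n_sites))
    if grid is None:
        grid = default_grid(dist)
    grid = np.asarray(grid, dtype=float)
    point = fit_npscf(M, dist, df=df, grid=grid, band=band, region_label=region_label)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    iu = np.triu_indices(n_sites, k=1)
    pair_y = M[iu]
    ok = np.isfinite(pair_y)
    x = dist.d[iu][ok]
    y = pair_y[ok]
    ii, jj = iu[0][ok], iu[1][ok]
    spline = _Pspline(x, df)
    curves = np.empty((n_boot, len(grid)))
    for b in range(n_boot):
        while True:
            draw = rng.integers(0, n_sites, size=n_sites)
            counts = np.bincount(draw, minlength=n_sites)
            if (counts > 0).sum() >= 2:
                break
        w = counts[ii] * counts[jj]
        if (w > 0).sum() < 10 or len(np.unique(x[w > 0])) < 2:
            # Degenerate replicate (too few usable pairs); redraw.
            curves[b] = np.nan
            continue
        coefs = spline.solve(y, w=w.astype(float))
        curves[b] = spline.predict(coefs, grid)[0]
    good = np.isfinite(curves).all(axis=1)
    lo, hi = np.percentile(curves[good], [2.5, 97.5], axis=0)
    return NpscfResult(
        distance_grid=grid,
        estimate=point.estimate,
        lower95=lo,
        upper95=hi,
        equivalent_df=df,
        n_boot=int(good.sum()),
        band=band,
        region_label=region_label,
        extrapolated=point.extrapolated,
    )


def regional_split(
    panel: Panel,
    sites,
    boundary_lat: float = POINT_CONCEPTION_LAT,
) -> tuple[Panel, Panel]:
    """Partition a panel into (northern, southern) sides of a latitude.

    A site exactly on the boundary goes to the northern (central
    California) side.  Either side empty is an error.
    """
    from .io_panels import validate_site_table

    sites = validate_site_table(sites)
    lat = sites.set_index("site_id")["lat"]
    missing = [s for s in panel.site_ids if s not in lat.index]
    if missing:
        raise ValueError(f"sites absent from site table: {missing[:5]}")
    north_mask = np.array([lat[s] >= boundary_lat for s in panel.site_ids])
    if not north_mask.any() or north_mask.all():
        raise ValueError(
            f"boundary latitude {boundary_lat} leaves one side empty"
        )

    def _take(mask: np.ndarray) -> Panel:
        return Panel(
            site_ids=[s for s, m in zip(panel.site_ids, mask) if m],
            years=panel.years.copy(),
            values=panel.values[mask].copy(),
            variable_name=panel.variable_name,
        )

    return _take(north_mask), _take(~north_mask)
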