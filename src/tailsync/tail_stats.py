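"""Partial Spearman correlations over quantile bands and tail dependence.

The Spearman rank correlation between two positively associated variables
can be decomposed by where in the copula each time point falls.  Writing
``u_t``, ``v_t`` for the normalized ranks (ranks divided by ``n + 1``), the
band statistic for bounds ``0 <= b_l < b_u <= 1`` is

    rho(b_l, b_u) = sum_{t in S} (u_t - 1/2)(v_t - 1/2)
                    / sqrt( sum_t (u_t - 1/2)^2 * sum_t (v_t - 1/2)^2 )

where membership of ``S`` is decided by the mean normalized rank
``(u_t + v_t)/2`` falling inside ``[b_l, b_u)`` (closed at the global
ends; a point exactly on an interior bound contributes with weight 1/2
to each adjacent band) and the denominator runs over all points.
Complementary bands therefore partition the sample exactly: their
statistics add to the full-band value, which for untied data is the
classical Spearman coefficient, and the decomposition is exactly
antisymmetric under joint reflection of both variables.

Tail dependence strength is the upper-half band statistic minus the
lower-half one: positive values mean the association is stronger when both
variables are high (synchronized booms), negative values when both are low
(synchronized crashes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_panels import Panel

logger = logging.getLogger("tailsync")

#: Minimum number of complete pairs required for a rank statistic.
MIN_PAIRS = 5


@dataclass(frozen=True)
class TailBand:
    """A quantile band ``[b_l, b_u)`` of the copula (closed top at b_u=1)."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower < self.upper <= 1.0):
            raise ValueError(f"need 0 <= b_l < b_u <= 1, got ({self.lower}, {self.upper})")

    def contains(self, mean_rank: np.ndarray) -> np.ndarray:
        """Membership of mean normalized ranks in the band."""
        m = np.asarray(mean_rank)
        hi = m <= self.upper if self.upper == 1.0 else m < self.upper
        return (m >= self.lower) & hi

    def weights(self, rank_sum: np.ndarray, n: int) -> np.ndarray:
        """Band weight of each point from the sum of its two raw ranks.

        Points strictly inside the band weigh 1; a point whose mean
        normalized rank falls exactly on an interior band bound weighs
        1/2, shared with the adjacent band.  This makes complementary
        bands partition the sample exactly and makes the statistic
        exactly antisymmetric under joint reflection of both variables
        (reflection maps a boundary point to itself).  Rank sums are
        compared as (near-)integers, so the boundary is detected exactly.
        """
        s = np.asarray(rank_sum, dtype=float)
        lo = 2.0 * self.lower * (n + 1)
        hi = 2.0 * self.upper * (n + 1)
        w = ((s > lo) & (s < hi)).astype(float)
        w[np.isclose(s, lo, rtol=0.0, atol=1e-9)] = 0.5
        w[np.isclose(s, hi, rtol=0.0, atol=1e-9)] = 0.5
        # Global ends are closed: the smallest and largest possible rank
        # sums lie strictly inside (0, 2(n+1)), so no correction needed.
        return w


LOWER_HALF = TailBand(0.0, 0.5)
UPPER_HALF = TailBand(0.5, 1.0)
FULL_BAND = TailBand(0.0, 1.0)


@dataclass
class RankedPair:
    """Normalized ranks of a pairwise-complete bivariate sample."""

    u: np.ndarray
    v: np.ndarray

    @property
    def n(self) -> int:
        return len(self.u)


def normalized_ranks(x: np.ndarray, y: np.ndarray) -> RankedPair:
    """Rank both vectors over their complete pairs, normalized by n + 1.

    Pairs with a missing value in either vector are dropped; ties get
    average ranks, keeping every normalized rank strictly inside (0, 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < MIN_PAIRS:
        raise ValueError(f"only {n} complete pairs; need at least {MIN_PAIRS}")
    u = rankdata(x[ok]) / (n + 1.0)
    v = rankdata(y[ok]) / (n + 1.0)
    return RankedPair(u=u, v=v)


def partial_spearman(pair: RankedPair, band: TailBand) -> float:
    """Portion of the Spearman correlation arising inside a quantile band."""
    a = pair.u - 0.5
    b = pair.v - 0.5
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0.0:
        logger.warning("degenerate ranks (all tied); partial Spearman set to 0")
        return 0.0
    w = band.weights((pair.u + pair.v) * (pair.n + 1), pair.n)
    if not w.any():
        logger.warning("band (%g, %g) contains no points", band.lower, band.upper)
        return 0.0
    return float((w * a * b).sum() / denom)


def spearman(pair: RankedPair) -> float:
    """Full-band statistic (classical Spearman coefficient for untied data)."""
    return partial_spearman(pair, FULL_BAND)


def tail_dependence_strength(pair: RankedPair) -> float:
    """Upper-half minus lower-half partial Spearman correlation.

    The decomposition is meaningful for positively associated variables;
    a non-positive overall association triggers a logged warning but the
    value is still computed.
    """
    total = spearman(pair)
    if total <= 0.0:
        logger.warning(
            "overall Spearman correlation %.3f is not positive; the tail "
            "decomposition is intended for positively associated variables",
            total,
        )
    return partial_spearman(pair, UPPER_HALF) - partial_spearman(pair, LOWER_HALF)


# ---------------------------------------------------------------------------
# Panel-level matrices
# ---------------------------------------------------------------------------


@dataclass
class SynchronySet:
    """Upper- and lower-band synchrony matrices and their difference.

    ``d = m_upper - m_lower`` elementwise; the diagonal holds self-pair
    values and is excluded from all downstream summaries.
    """

    site_ids: list[str]
    m_upper: np.ndarray
    m_lower: np.ndarray
    d: np.ndarray
    band_lower: TailBand = LOWER_HALF
    band_upper: TailBand = UPPER_HALF


def _band_matrix(R: np.ndarray, band: TailBand, block: int = 128) -> np.ndarray:
    """All-pairs partial Spearman for one band, on complete data.

    ``R`` holds raw (average) ranks per row.  Blocked over rows to keep
    the (block, n, T) broadcast temporaries small.
    """
    T = R.shape[1]
    A = R / (T + 1.0) - 0.5
    ss = (A * A).sum(axis=1)
    denom = np.sqrt(np.outer(ss, ss))
    n = R.shape[0]
    out = np.empty((n, n))
    for start in range(0, n, block):
        stop = min(start + block, n)
        rank_sum = R[start:stop, None, :] + R[None, :, :]
        w = band.weights(rank_sum, T)
        out[start:stop] = np.einsum("it,jt,ijt->ij", A[start:stop], A, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, out / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def pairwise_synchrony(
    panel: Panel,
    band_lower: TailBand = LOWER_HALF,
    band_upper: TailBand = UPPER_HALF,
) -> SynchronySet:
    """Band-specific synchrony matrices over all pairs of sites.

    Complete panels use a vectorized all-pairs path; panels with missing
    values fall back to per-pair ranking over pairwise-complete years.
    The diagonal holds each site's self-pair (comonotone) band values.
    """
    if panel.n_sites < 2:
        raise ValueError("pairwise synchrony needs at least 2 sites")
    vals = panel.values
    if not np.isnan(vals).any():
        R = rankdata(vals, axis=1)
        m_u = _band_matrix(R, band_upper)
        m_l = _band_matrix(R, band_lower)
    else:
        n = panel.n_sites
        m_u = np.empty((n, n))
        m_l = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                try:
                    pair = normalized_ranks(vals[i], vals[j])
                except ValueError as err:
                    raise ValueError(
                        f"pair ({panel.site_ids[i]}, {panel.site_ids[j]}): {err}"
                    ) from err
                m_u[i, j] = m_u[j, i] = partial_spearman(pair, band_upper)
                m_l[i, j] = m_l[j, i] = partial_spearman(pair, band_lower)
    m_u = (m_u + m_u.T) / 2.0
    m_l = (m_l + m_l.T) / 2.0
    return SynchronySet(
        site_ids=list(panel.site_ids),
        m_upper=m_u,
        m_lower=m_l,
        d=m_u - m_l,
        band_lower=band_lower,
        band_upper=band_upper,
    )


def driver_tail_profile(
    response: Panel,
    driver: Panel,
    band_lower: TailBand = LOWER_HALF,
    band_upper: TailBand = UPPER_HALF,
) -> pd.DataFrame:
    """Per-site band correlations between a response and a driver panel.

    A one-site driver (a spatially constant climate index) is paired with
    every response site.  Returns a tidy frame with columns ``site_id``,
    ``driver``, ``rho_l``, ``rho_u``, ``d``.
    """
    if not np.array_equal(response.years, driver.years):
        raise ValueError("response and driver years are not aligned")
    if driver.n_sites not in (1, response.n_sites):
        raise ValueError("driver must have 1 site or match the response sites")
    if driver.n_sites == response.n_sites and driver.site_ids != response.site_ids:
        raise ValueError("response and driver site ids are not aligned")
    rows = []
    for i, sid in enumerate(response.site_ids):
        drow = driver.values[0] if driver.n_sites == 1 else driver.values[i]
        pair = normalized_ranks(response.values[i], drow)
        rho_l = partial_spearman(pair, band_lower)
        rho_u = partial_spearman(pair, band_upper)
        rows.append(
            {
                "site_id": sid,
                "driver": driver.variable_name,
                "rho_l": rho_l,
                "rho_u": rho_u,
                "d": rho_u - rho_l,
            }
        )
    return pd.DataFrame(rows)


def synchrony_to_frame(s: SynchronySet, which: str = "d") -> pd.DataFrame:
    """One synchrony matrix as a site-indexed DataFrame (for CSV export)."""
    mat = {"upper": s.m_upper, "lower": s.m_lower, "d": s.d}[which]
    return pd.DataFrame(mat, index=s.site_ids, columns=s.site_ids)
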