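"""Tail-symmetric surrogate panels and the two synchrony hypothesis tests.

The null hypothesis is "no asymmetry of tail association": the data's
pairwise Spearman structure and per-site marginals are real, but upper- and
lower-tail synchrony are equal up to sampling variation.  Surrogates embody
the null by drawing from a Gaussian copula whose correlation matrix is the
data's Spearman matrix mapped through ``r = 2 sin(pi * rho_s / 6)`` (the
exact Spearman-to-Pearson relation for bivariate normals), then restoring
each site's empirical marginal by rank reordering.  The Gaussian copula is
reflection-symmetric, so surrogate panels carry no tail asymmetry while
matching the observed correlation matrix and marginals.

Two statistics are referred to their surrogate null distributions:

* the total tail dependence, ``sum_{i<j} D_ij`` — a two-sided test of
  overall tail asymmetry (significant outside the 0.025–0.975 quantiles);
* the geography statistic ``1 - cor(M_u, M_l)`` over site pairs — one-sided
  (significant above the 0.95 quantile, p = 1 - quantile), sensitive to
  spatially structured asymmetry even when the total cancels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .io_panels import Panel
from .tail_stats import (
    LOWER_HALF,
    UPPER_HALF,
    SynchronySet,
    TailBand,
    pairwise_synchrony,
)

logger = logging.getLogger("tailsync")


def spearman_matrix(panel: Panel) -> np.ndarray:
    """Pairwise-complete classical Spearman correlations between sites."""
    if panel.n_sites < 2:
        raise ValueError("need at least 2 sites")
    frame = pd.DataFrame(panel.values.T, columns=panel.site_ids)
    return frame.corr(method="spearman", min_periods=5).to_numpy()


def nearest_correlation(mat: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the diagonal rescaled to
    one; adequate for mild indefiniteness from pairwise-complete
    estimation (a full alternating-projection scheme is unnecessary at
    these dimensions).
    """
    if not np.isfinite(mat).all():
        raise ValueError("correlation target contains non-finite entries")
    sym = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() >= eig_floor:
        out = sym
    else:
        w = np.clip(w, eig_floor, None)
        out = (v * w) @ v.T
    scale = 1.0 / np.sqrt(np.diag(out))
    out = out * np.outer(scale, scale)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


@dataclass
class SurrogateEnsemble:
    """Null distributions of the two test statistics over surrogate panels."""

    n_surrogates: int
    seed: int | None
    spearman_target: np.ndarray
    null_total: np.ndarray
    null_geography: np.ndarray
    panels: list[Panel] = field(default_factory=list)


def _surrogate_stream(
    panel: Panel, n: int, rng: np.random.Generator
) -> Iterator[Panel]:
    """Yield tail-symmetric surrogate panels one at a time."""
    rho_s = spearman_matrix(panel)
    pearson = 2.0 * np.sin(np.pi * rho_s / 6.0)
    target = nearest_correlation(pearson)
    chol = np.linalg.cholesky(target)
    vals = panel.values
    missing = np.isnan(vals)
    sorted_vals = [np.sort(row[~m]) for row, m in zip(vals, missing)]
    n_sites, n_years = vals.shape
    for _ in range(n):
        z = chol @ rng.standard_normal((n_sites, n_years))
        out = np.full_like(vals, np.nan)
        for i in range(n_sites):
            obs = ~missing[i]
            zi = z[i, obs]
            order = np.argsort(np.argsort(zi))
            out[i, obs] = sorted_vals[i][order]
        yield Panel(
            site_ids=list(panel.site_ids),
            years=panel.years.copy(),
            values=out,
            variable_name=panel.variable_name,
        )


def make_surrogates(
    panel: Panel,
    n: int = 1000,
    seed: int | np.random.Generator | None = None,
    band_lower: TailBand = LOWER_HALF,
    band_upper: TailBand = UPPER_HALF,
    keep_panels: bool = False,
) -> SurrogateEnsemble:
    """Build a surrogate ensemble and accumulate the two null statistics.

    Surrogate panels are streamed: by default only the statistics are
    retained, so peak memory does not grow with ``n``.  Pass
    ``keep_panels=True`` to store the panels as well.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null_total = np.empty(n)
    null_geo = np.empty(n)
    kept: list[Panel] = []
    for k, surr in enumerate(_surrogate_stream(panel, n, rng)):
        s = pairwise_synchrony(surr, band_lower, band_upper)
        null_total[k] = stat_total_tail_dependence(s)
        null_geo[k] = stat_geography(s)
        if keep_panels:
            kept.append(surr)
    return SurrogateEnsemble(
        n_surrogates=n,
        seed=seed if isinstance(seed, int) else None,
        spearman_target=spearman_matrix(panel),
        null_total=null_total,
        null_geography=null_geo,
        panels=kept,
    )


def stat_total_tail_dependence(s: SynchronySet) -> float:
    """Sum of tail dependence strength over unordered site pairs."""
    iu = np.triu_indices_from(s.d, k=1)
    return float(s.d[iu].sum())


def stat_geography(s: SynchronySet) -> float:
    """``1 - cor(M_u, M_l)`` over the strict upper triangles.

    Large values mean the upper- and lower-tail synchrony matrices have
    different spatial structure.
    """
    iu = np.triu_indices_from(s.m_upper, k=1)
    x = s.m_upper[iu]
    y = s.m_lower[iu]
    if len(x) < 3:
        raise ValueError("geography statistic needs at least 3 site pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a synchrony matrix triangle")
    return float(1.0 - np.corrcoef(x, y)[0, 1])


def null_quantile(null: np.ndarray, value: float) -> float:
    """Mid-rank quantile of a value within a null sample."""
    null = np.asarray(null)
    return float(((null < value).sum() + 0.5 * (null == value).sum()) / len(null))


@dataclass
class TestResult:
    """Outcome of one surrogate test."""

    statistic_name: str
    empirical_value: float
    quantile_in_null: float
    significant: bool
    decision_rule: str
    p_value: float | None = None


def run_tests(
    panel: Panel,
    n_surrogates: int = 1000,
    seed: int | np.random.Generator | None = None,
    band_lower: TailBand = LOWER_HALF,
    band_upper: TailBand = UPPER_HALF,
) -> tuple[TestResult, TestResult, SurrogateEnsemble]:
    """Run both surrogate tests from a single shared ensemble.

    Returns the two-sided total-tail-dependence result, the one-sided
    geography result, and the ensemble (null draws) used for both.
    """
    emp = pairwise_synchrony(panel, band_lower, band_upper)
    emp_total = stat_total_tail_dependence(emp)
    emp_geo = stat_geography(emp)
    ens = make_surrogates(panel, n_surrogates, seed, band_lower, band_upper)
    q_total = null_quantile(ens.null_total, emp_total)
    q_geo = null_quantile(ens.null_geography, emp_geo)
    total = TestResult(
        statistic_name="total_tail_dependence",
        empirical_value=emp_total,
        quantile_in_null=q_total,
        significant=q_total < 0.025 or q_total > 0.975,
        decision_rule="two-sided: significant if null quantile < 0.025 or > 0.975",
        p_value=None,
    )
    geo = TestResult(
        statistic_name="geography_of_tail_dependence",
        empirical_value=emp_geo,
        quantile_in_null=q_geo,
        significant=q_geo > 0.95,
        decision_rule="one-sided: significant if null quantile > 0.95; p = 1 - quantile",
        p_value=1.0 - q_geo,
    )
    return total, geo, ens
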