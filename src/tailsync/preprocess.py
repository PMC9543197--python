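"""Data preparation: persistence filtering, sign flips, linear detrending.

The statistics downstream are rank-based and assume positively associated,
trend-free series, so preparation is deliberately minimal: drop sites where
the population was absent too often, flip the sign of drivers expected to
correlate negatively with the response (wave height becomes "wave
calmness"), and remove a per-site linear trend in time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_panels import Panel

logger = logging.getLogger("tailsync")


@dataclass(frozen=True)
class PersistenceRule:
    """Retain sites absent (zero or missing) in at most ``max_absent_years``."""

    max_absent_years: int = 3

    def __post_init__(self) -> None:
        if self.max_absent_years < 0:
            raise ValueError("max_absent_years must be non-negative")


def absence_counts(panel: Panel) -> np.ndarray:
    """Number of years per site in which the variable is zero or missing."""
    return (np.isnan(panel.values) | (panel.values == 0)).sum(axis=1)


def select_persistent_sites(panel: Panel, rule: PersistenceRule | None = None) -> Panel:
    """Keep only sites whose absence count is within the persistence rule.

    The bound is inclusive: a site absent for exactly ``max_absent_years``
    is retained.  Site order is preserved.
    """
    rule = rule or PersistenceRule()
    if rule.max_absent_years > panel.n_years:
        raise ValueError("max_absent_years exceeds the panel's year span")
    keep = absence_counts(panel) <= rule.max_absent_years
    if not keep.any():
        raise ValueError("persistence filter removed every site")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "persistence filter kept %d of %d sites (dropped %d)",
            int(keep.sum()), panel.n_sites, n_drop,
        )
    return Panel(
        site_ids=[s for s, k in zip(panel.site_ids, keep) if k],
        years=panel.years.copy(),
        values=panel.values[keep].copy(),
        variable_name=panel.variable_name,
    )


def negate(panel: Panel) -> Panel:
    """Multiply every value by -1 (e.g. wave height -> wave calmness)."""
    out = panel.copy()
    out.values = -out.values
    return out


def detrend_linear(panel: Panel) -> Panel:
    """Remove a per-site ordinary least squares linear trend in time.

    Missing years are excluded from each fit and remain missing in the
    output.  Sites with fewer than 3 non-missing years cannot be detrended
    and raise an error naming them.
    """
    t = np.arange(panel.n_years, dtype=float)
    n_obs = (~np.isnan(panel.values)).sum(axis=1)
    bad = [s for s, n in zip(panel.site_ids, n_obs) if n < 3]
    if bad:
        raise ValueError(f"sites with fewer than 3 non-missing years: {bad}")
    resid = np.full_like(panel.values, np.nan)
    for i in range(panel.n_sites):
        row = panel.values[i]
        ok = ~np.isnan(row)
        slope, intercept = np.polyfit(t[ok], row[ok], 1)
        resid[i, ok] = row[ok] - (intercept + slope * t[ok])
    out = panel.copy()
    out.values = resid
    return out
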