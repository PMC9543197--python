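"""Site-by-year panels, site metadata, and inter-site distances.

A :class:`Panel` is the universal exchange object of the pipeline: a
sites-by-years matrix of one variable (population biomass, wave calmness,
nitrate concentration, a climate index, ...) together with site identifiers
and consecutive integer year labels.  Missing observations are carried as
NaN, never as zero.  Sites live in a :class:`SiteTable` (longitude/latitude
of segment centroids) from which great-circle distances are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("tailsync")

#: Mean Earth radius, km (IUGG).
EARTH_RADIUS_KM = 6371.0088

#: Strings read as missing values in panel files (besides empty cells).
NA_STRINGS = ("NA",)


def setup_logging(level: int | str = logging.INFO) -> None:
    """Configure the package logger once, with a plain stderr handler."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------


@dataclass
class Panel:
    """A sites-by-years matrix of one variable.

    Parameters
    ----------
    site_ids
        Unique site identifiers, one per row.
    years
        Consecutive, strictly increasing integer year labels, one per column.
    values
        Float matrix of shape ``(n_sites, n_years)``; NaN marks missing.
    variable_name
        Name of the variable held by the panel.
    """

    site_ids: list[str]
    years: np.ndarray
    values: np.ndarray
    variable_name: str = "value"

    def __post_init__(self) -> None:
        self.site_ids = [str(s) for s in self.site_ids]
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.site_ids)) != len(self.site_ids):
            dupes = sorted({s for s in self.site_ids if self.site_ids.count(s) > 1})
            raise ValueError(f"duplicate site ids: {dupes}")
        if self.values.shape != (len(self.site_ids), len(self.years)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.years)} years"
            )
        if len(self.years) > 1:
            diffs = np.diff(self.years)
            if np.any(diffs <= 0):
                raise ValueError("years must be strictly increasing")
            if np.any(diffs != 1):
                raise ValueError(
                    "years must be consecutive integers (detrending and rank "
                    "statistics assume a common time grid)"
                )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def copy(self) -> "Panel":
        return replace(self, years=self.years.copy(), values=self.values.copy())

    def site_index(self, site_id: str) -> int:
        return self.site_ids.index(site_id)

    def to_frame(self) -> pd.DataFrame:
        """Return a DataFrame with site_id index and year columns."""
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.years)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, variable_name: str = "value") -> "Panel":
        return cls(
            site_ids=[str(s) for s in frame.index],
            years=np.asarray(frame.columns, dtype=int),
            values=frame.to_numpy(dtype=float),
            variable_name=variable_name,
        )


def read_panel(
    path: str | Path,
    orientation: str = "sites-as-rows",
    variable_name: str | None = None,
) -> Panel:
    """Read a panel from a delimited text file.

    The canonical layout has a ``site_id`` first column and one column per
    year; ``orientation="sites-as-columns"`` reads the transposed layout
    (one row per year, one column per site).  Empty cells and ``NA`` are
    read as missing.
    """
    if orientation not in ("sites-as-rows", "sites-as-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(
        path,
        dtype=str,
        keep_default_na=False,
        na_values=list(NA_STRINGS),
        index_col=0,
    )
    if orientation == "sites-as-columns":
        raw = raw.T
    ids = [str(s) for s in raw.index]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate site ids in {path}: {dupes}")
    values = np.full(raw.shape, np.nan)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            if not isinstance(cell, str) or cell.strip() == "":
                continue  # missing
            try:
                values[i, j] = float(cell)  # exact strtod round-trip
            except ValueError:
                raise ValueError(
                    f"non-numeric cell in {path} at site {ids[i]!r}, column {col!r}"
                ) from None
    years = np.asarray([int(str(c).strip()) for c in raw.columns])
    name = variable_name if variable_name is not None else Path(path).stem
    return Panel(site_ids=ids, years=years, values=values, variable_name=name)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel in the canonical layout (sites as rows, missing empty)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("site_id," + ",".join(str(y) for y in panel.years) + "\n")
        for sid, row in zip(panel.site_ids, panel.values):
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(sid + "," + ",".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Site table and distances
# ---------------------------------------------------------------------------


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a site table (columns site_id, lon, lat) and validate it."""
    sites = pd.read_csv(path, dtype={"site_id": str})
    return validate_site_table(sites)


def validate_site_table(sites: pd.DataFrame) -> pd.DataFrame:
    required = {"site_id", "lon", "lat"}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    sites = sites.copy()
    sites["site_id"] = sites["site_id"].astype(str)
    if sites["site_id"].duplicated().any():
        raise ValueError("duplicate site ids in site table")
    if ((sites["lat"] < -90) | (sites["lat"] > 90)).any():
        raise ValueError("latitude outside [-90, 90]")
    if ((sites["lon"] < -180) | (sites["lon"] > 180)).any():
        raise ValueError("longitude outside [-180, 180]")
    if "along_coast_order" not in sites.columns:
        # Along-coast rank: the California coast runs roughly NW to SE, so
        # descending latitude (longitude breaking ties) orders segments.
        order = np.lexsort((sites["lon"].to_numpy(), -sites["lat"].to_numpy()))
        rank = np.empty(len(sites), dtype=int)
        rank[order] = np.arange(1, len(sites) + 1)
        sites["along_coast_order"] = rank
    return sites


def write_site_table(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, index=False)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of great-circle distances between sites, km."""

    site_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.site_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match site ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def subset(self, site_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.site_ids.index(s) for s in site_ids]
        return DistanceMatrix(list(site_ids), self.d[np.ix_(idx, idx)])


def haversine_km(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def great_circle_distance_matrix(sites: pd.DataFrame) -> DistanceMatrix:
    """Pairwise haversine distances between the sites of a site table."""
    sites = validate_site_table(sites)
    lat = sites["lat"].to_numpy()
    lon = sites["lon"].to_numpy()
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry
    return DistanceMatrix(list(sites["site_id"]), d)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a user-supplied distance matrix (CSV, site_id header row/col)."""
    frame = pd.read_csv(path, index_col=0)
    ids = [str(s) for s in frame.index]
    if list(map(str, frame.columns)) != ids:
        raise ValueError("distance matrix rows and columns must list the same sites")
    return DistanceMatrix(ids, frame.to_numpy(dtype=float))


def write_distance_matrix(dist: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dist.d, index=dist.site_ids, columns=dist.site_ids).to_csv(path)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def align(
    panels: Iterable[Panel], sites: pd.DataFrame | None = None
) -> list[Panel]:
    """Restrict panels to their common sites and years, in a canonical order.

    Sites are ordered along the coast when a site table is supplied,
    otherwise lexicographically, so the result does not depend on the input
    ordering.  Spatially constant index series stored as 1-site panels are
    aligned on years only and keep their single row.
    """
    panels = list(panels)
    if not panels:
        raise ValueError("align requires at least one panel")
    spatial = [p for p in panels if p.n_sites > 1]
    pool = spatial if spatial else panels
    common_sites = set(pool[0].site_ids)
    for p in pool[1:]:
        common_sites &= set(p.site_ids)
    common_years = set(panels[0].years.tolist())
    for p in panels[1:]:
        common_years &= set(p.years.tolist())
    if not common_sites or not common_years:
        raise ValueError("empty site or year intersection across panels")
    if sites is not None:
        sites = validate_site_table(sites)
        ordered = [
            s
            for s in sites.sort_values("along_coast_order")["site_id"]
            if s in common_sites
        ]
        if set(ordered) != common_sites:
            raise ValueError("site table does not cover all common panel sites")
    else:
        ordered = sorted(common_sites)
    years = np.asarray(sorted(common_years))
    out = []
    for p in panels:
        ycols = [int(np.flatnonzero(p.years == y)[0]) for y in years]
        if p.n_sites == 1 and spatial:
            vals = p.values[:, ycols]
            out.append(Panel([p.site_ids[0]], years, vals, p.variable_name))
        else:
            rows = [p.site_index(s) for s in ordered]
            vals = p.values[np.ix_(rows, ycols)]
            out.append(Panel(list(ordered), years, vals, p.variable_name))
    return out
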