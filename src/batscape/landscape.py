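"""Per-cell landscape covariates from categorical land-cover rasters.

A 10 x 10 km monitoring cell is summarised by the composition and
configuration of its land cover: percent cover of aggregated classes
(agriculture, development, upland forest, forested wetland), the contagion
index of land-cover aggregation, and edge densities of focal classes.
These covariates, screened for collinearity and standardized, are the
inputs to the occupancy models.

Adjacency convention used throughout: 4-neighborhood, interior pixel pairs
only (the landscape boundary contributes no edge), and double-counting
(each unordered pixel pair appears once per ordered direction, so the
adjacency matrix ``g`` is symmetric with even diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandscapeRaster",
    "ClassAdjacency",
    "CorrelationReport",
    "Standardization",
    "read_ascii_grid",
    "write_ascii_grid",
    "percent_cover",
    "edge_density",
    "adjacency_counts",
    "contagion",
    "pearson_screen",
    "standardize",
    "CONTINUOUS_COVARIATES",
]

#: Continuous covariate columns of the cell covariate table, in canonical order.
CONTINUOUS_COVARIATES = [
    "Ag", "Dev", "Forest", "F.Wet", "Contagion", "F.ED", "F.Wet.ED",
    "Stream", "Pri", "Sec", "Ter", "Qua",
]


class MetricUndefinedError(ValueError):
    """Raised when a landscape metric is undefined for the input raster."""


@dataclass(frozen=True)
class LandscapeRaster:
    """Categorical land-cover raster for one (already buffered) cell.

    Parameters
    ----------
    grid
        2-D integer array of class codes.  ``nodata`` codes are ignored by
        all metrics.
    pixel_size
        Side length of a square pixel in meters (NLCD uses 30 m).
    nodata
        Integer code marking pixels outside the landscape.
    """

    grid: np.ndarray
    pixel_size: float = 30.0
    nodata: int = -9999

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.size == 0:
            raise ValueError("raster grid must be a non-empty 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "grid", g.astype(np.int64))

    @property
    def valid_mask(self) -> np.ndarray:
        return self.grid != self.nodata


@dataclass(frozen=True)
class ClassAdjacency:
    """Class proportions and pixel-adjacency counts of a raster.

    ``g[i, k]`` counts ordered adjacencies between pixels of class
    ``classes[i]`` and ``classes[k]`` (symmetric, double-count convention).
    """

    classes: np.ndarray
    proportions: np.ndarray
    g: np.ndarray

    @property
    def m(self) -> int:
        return len(self.classes)


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations with a |r| screening threshold.

    ``flagged`` pairs may not co-occur in one occupancy model.
    """

    r: pd.DataFrame
    threshold: float
    flagged: list[tuple[str, str]] = field(default_factory=list)

    def allowed_together(self, names: list[str]) -> bool:
        """True if no flagged pair is contained in ``names``."""
        s = set(names)
        return not any(a in s and b in s for a, b in self.flagged)


@dataclass(frozen=True)
class Standardization:
    """Stored location/scale so prediction covariates reuse the fitting
    set's transform."""

    location: pd.Series
    scale: pd.Series

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.location.index:
            if col in out.columns:
                out[col] = (out[col] - self.location[col]) / self.scale[col]
        return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def read_ascii_grid(path) -> LandscapeRaster:
    """Read an ESRI ASCII grid (.asc) of integer class codes."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        grid = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    nrows, ncols = int(header.get("nrows", grid.shape[0])), int(header.get("ncols", grid.shape[1]))
    if grid.shape != (nrows, ncols):
        grid = grid.reshape(nrows, ncols)
    return LandscapeRaster(
        grid=grid,
        pixel_size=float(header.get("cellsize", 30.0)),
        nodata=int(header.get("nodata_value", -9999)),
    )


def write_ascii_grid(raster: LandscapeRaster, path) -> None:
    nrows, ncols = raster.grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {raster.pixel_size:g}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        for row in raster.grid:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Metrics


def percent_cover(raster: LandscapeRaster, class_map: dict[int, str]) -> dict[str, float]:
    """Percent of valid pixels per aggregated class.

    Raw codes absent from ``class_map`` are pooled into ``"other"``.
    Percentages sum to 100 over all returned keys.
    """
    valid = raster.grid[raster.valid_mask]
    if valid.size == 0:
        raise ValueError("raster contains only NODATA pixels")
    names = sorted(set(class_map.values()))
    counts = dict.fromkeys(names + ["other"], 0)
    codes, code_counts = np.unique(valid, return_counts=True)
    for code, n in zip(codes, code_counts):
        counts[class_map.get(int(code), "other")] += int(n)
    total = valid.size
    return {name: 100.0 * n / total for name, n in counts.items()}


def _interior_adjacent_pairs(grid: np.ndarray, valid: np.ndarray):
    """Yield (a, b) arrays of class codes for horizontally and vertically
    adjacent valid pixel pairs (each unordered pair once)."""
    h = valid[:, :-1] & valid[:, 1:]
    v = valid[:-1, :] & valid[1:, :]
    yield grid[:, :-1][h], grid[:, 1:][h]
    yield grid[:-1, :][v], grid[1:, :][v]


def edge_density(raster: LandscapeRaster, focal_classes) -> float:
    """Edge density of ``focal_classes`` in meters of edge per hectare.

    Edge length counts shared boundaries between a focal and a non-focal
    pixel (4-neighborhood); the outer landscape boundary is excluded.
    Area is the full valid landscape area.
    """
    valid = raster.valid_mask
    if not valid.any():
        raise ValueError("raster contains only NODATA pixels")
    focal = np.asarray(sorted(set(focal_classes)))
    n_edges = 0
    for a, b in _interior_adjacent_pairs(raster.grid, valid):
        fa, fb = np.isin(a, focal), np.isin(b, focal)
        n_edges += int(np.count_nonzero(fa != fb))
    length_m = n_edges * raster.pixel_size
    area_ha = valid.sum() * raster.pixel_size**2 / 10_000.0
    return length_m / area_ha


def adjacency_counts(raster: LandscapeRaster) -> ClassAdjacency:
    """Tabulate class proportions and double-counted adjacency counts."""
    valid = raster.valid_mask
    if not valid.any():
        raise ValueError("raster contains only NODATA pixels")
    classes, counts = np.unique(raster.grid[valid], return_counts=True)
    idx = {int(c): i for i, c in enumerate(classes)}
    m = len(classes)
    g = np.zeros((m, m), dtype=np.int64)
    for a, b in _interior_adjacent_pairs(raster.grid, valid):
        for ca, cb in zip(a, b):
            i, k = idx[int(ca)], idx[int(cb)]
            g[i, k] += 1
            g[k, i] += 1
    return ClassAdjacency(classes=classes, proportions=counts / counts.sum(), g=g)


def contagion(adj: ClassAdjacency | LandscapeRaster) -> float:
    """Contagion index in [0, 100]; high when cover types clump.

    CONTAG = [1 + sum_ik q_ik ln q_ik / (2 ln m)] * 100 with
    q_ik = P_i * g_ik / sum_k g_ik, and 0 ln 0 := 0.  Undefined for
    single-class landscapes (m < 2).
    """
    if isinstance(adj, LandscapeRaster):
        adj = adjacency_counts(adj)
    if adj.m < 2:
        raise MetricUndefinedError("contagion is undefined for a single-class landscape")
    row_tot = adj.g.sum(axis=1, dtype=float)
    # isolated classes with no adjacencies contribute q = 0 rows
    with np.errstate(invalid="ignore", divide="ignore"):
        q = adj.proportions[:, None] * np.where(row_tot[:, None] > 0, adj.g / row_tot[:, None], 0.0)
        term = np.where(q > 0, q * np.log(np.where(q > 0, q, 1.0)), 0.0)
    return float((1.0 + term.sum() / (2.0 * np.log(adj.m))) * 100.0)


# ---------------------------------------------------------------------------
# Pre-fit covariate processing


def pearson_screen(
    table: pd.DataFrame,
    threshold: float = 0.7,
    columns: list[str] | None = None,
) -> CorrelationReport:
    """Flag covariate pairs with Pearson |r| > ``threshold``.

    Flagged pairs are excluded from co-occurring in any one model.
    """
    if columns is None:
        columns = [c for c in CONTINUOUS_COVARIATES if c in table.columns]
    sub = table[columns].astype(float)
    if len(sub) < 3:
        raise ValueError("correlation screen requires at least 3 cells")
    for col in columns:
        if sub[col].std() == 0:
            raise ValueError(f"degenerate covariate (constant column): {col!r}")
    r = sub.corr(method="pearson")
    flagged = [
        (a, b)
        for i, a in enumerate(columns)
        for b in columns[i + 1:]
        if abs(r.loc[a, b]) > threshold
    ]
    return CorrelationReport(r=r, threshold=threshold, flagged=flagged)


def standardize(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    params: Standardization | None = None,
) -> tuple[pd.DataFrame, Standardization]:
    """Center/scale continuous columns to mean 0, sample SD 1 (n-1).

    Pass the ``Standardization`` returned from the fitting table to
    transform prediction-grid covariates with the fitting set's
    location/scale rather than their own.
    """
    if params is not None:
        return params.apply(table), params
    if columns is None:
        columns = [c for c in CONTINUOUS_COVARIATES if c in table.columns]
    loc = table[columns].mean()
    scale = table[columns].std(ddof=1)
    bad = scale.index[(scale == 0) | scale.isna()].tolist()
    if bad:
        raise ValueError(f"cannot standardize constant column(s): {bad}")
    params = Standardization(location=loc, scale=scale)
    return params.apply(table), params
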