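"""Daily oceanographic covariate rasters: aggregation, averaging, ranking, sampling.

Satellite fields (sea surface temperature in °C, turbidity as the diffuse
attenuation coefficient Kd(490) in m⁻¹, chlorophyll-a in mg m⁻³) arrive as
one single-band raster per variable per day with missing cells from cloud
cover.  The preparation chain is:

1. aggregate to a coarser grid (default 0.05°) by NA-ignoring block means, to
   fill cloud holes;
2. average each day with the previous day cellwise (the animal's recent
   experience of the field);
3. rank-standardise the averaged image onto [0, 20], because absolute ranges
   differ wildly between days and only relative habitat quality within the
   reachable window is comparable across days.

Sampling is containing-cell (no bilinear smoothing): behaviour is related to
the habitat pixel the bird is in.  Rasters are stored as ESRI ASCII grids, a
plain-text single-band format with an explicit geotransform.

Grid convention: row 0 is the northern edge; cells are half-open
[west, east) × [south, north), so a point on a shared edge belongs to the
east/north neighbour.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .errors import OutOfWindowError

logger = logging.getLogger(__name__)

VARIABLES = ("sst", "turbidity", "chla")
UNITS = {"sst": "degC", "turbidity": "m-1", "chla": "mg m-3"}


@dataclass(frozen=True)
class GridWindow:
    """Geographic analysis window, degrees WGS84."""

    west: float
    south: float
    east: float
    north: float

    def contains(self, lon: float, lat: float) -> bool:
        return self.west <= lon < self.east and self.south <= lat < self.north


@dataclass
class DailyRaster:
    """One variable, one day: a 2-D grid with NaN for missing cells.

    ``west``/``north`` locate the outer corner of cell (0, 0); ``cell`` is
    the square cell size in decimal degrees.
    """

    variable: str
    date: dt.date
    values: np.ndarray
    west: float
    north: float
    cell: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def south(self) -> float:
        return self.north - self.shape[0] * self.cell

    @property
    def east(self) -> float:
        return self.west + self.shape[1] * self.cell

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point, half-open convention."""
        nrows, ncols = self.shape
        if not (self.west <= lon < self.east and self.south <= lat < self.north):
            raise OutOfWindowError(
                f"point ({lon:.4f}, {lat:.4f}) outside raster "
                f"[{self.west}, {self.east}) x [{self.south}, {self.north})"
            )
        col = int(np.floor((lon - self.west) / self.cell))
        # measure from the south edge so a point on a shared horizontal edge
        # lands in the cell to its north
        row = nrows - 1 - int(np.floor((lat - self.south) / self.cell))
        return row, col


def sample_at(r: DailyRaster, lon: float, lat: float) -> float:
    """Value of the cell containing the point; NaN if the cell is missing."""
    row, col = r.cell_index(lon, lat)
    return float(r.values[row, col])


def aggregate(r: DailyRaster, window: GridWindow, target_cell: float = 0.05) -> DailyRaster:
    """Block-average onto a coarser grid anchored at the analysis window.

    Each target cell is the NA-ignoring mean of the source cells whose
    centres fall inside it; a target cell is missing only when it contains no
    valid source cell.  Requires ``target_cell`` >= the source cell size.
    """
    if target_cell < r.cell - 1e-12:
        raise ValueError(f"target cell {target_cell} finer than source {r.cell}")
    nrows = int(round((window.north - window.south) / target_cell))
    ncols = int(round((window.east - window.west) / target_cell))
    src_rows, src_cols = r.shape
    lon_c = r.west + (np.arange(src_cols) + 0.5) * r.cell
    lat_c = r.north - (np.arange(src_rows) + 0.5) * r.cell
    col_t = np.floor((lon_c - window.west) / target_cell).astype(int)
    row_t = nrows - 1 - np.floor((lat_c - window.south) / target_cell).astype(int)
    in_lon = (col_t >= 0) & (col_t < ncols)
    in_lat = (row_t >= 0) & (row_t < nrows)
    if not (in_lon.any() and in_lat.any()):
        raise OutOfWindowError("raster does not overlap the analysis window")

    rt = row_t[in_lat][:, None]
    ct = col_t[None, in_lon]
    vals = r.values[np.ix_(in_lat, in_lon)]
    flat = (rt * ncols + ct).ravel()
    v = vals.ravel()
    ok = np.isfinite(v)
    sums = np.bincount(flat[ok], weights=v[ok], minlength=nrows * ncols)
    counts = np.bincount(flat[ok], minlength=nrows * ncols)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DailyRaster(r.variable, r.date, mean.reshape(nrows, ncols),
                       window.west, window.north, target_cell)


def two_day_average(rasters: dict[dt.date, DailyRaster], variable: str,
                    date: dt.date) -> DailyRaster:
    """Cellwise NA-ignoring mean of a day's raster and the previous day's.

    If one of the two days is absent entirely the other is returned with a
    warning; both absent is an error.
    """
    today = rasters.get(date)
    before = rasters.get(date - dt.timedelta(days=1))
    if today is None and before is None:
        raise KeyError(f"{variable}: no raster for {date} or the day before")
    if today is None or before is None:
        have = today if today is not None else before
        logger.warning("%s %s: only one of the two days available", variable, date)
        return replace(have, date=date, values=have.values.copy())
    stacked = np.stack([today.values, before.values])
    valid = np.isfinite(stacked)
    n = valid.sum(axis=0)
    mean = np.where(n > 0, np.where(valid, stacked, 0.0).sum(axis=0) / np.maximum(n, 1),
                    np.nan)
    return replace(today, values=mean)


def rank_standardise(r: DailyRaster) -> DailyRaster:
    """Replace valid cells by their rank mapped linearly onto [0, 20].

    Average ranks for ties; missing cells stay missing.  A constant image is
    degenerate and maps to 10 everywhere (with a warning): every cell is at
    the middle of the ordering.
    """
    v = r.values
    ok = np.isfinite(v)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("rank standardisation needs >= 2 valid cells")
    out = np.full(v.shape, np.nan)
    vals = v[ok]
    if np.ptp(vals) == 0:
        logger.warning("%s %s: constant image, all ranks set to 10", r.variable, r.date)
        out[ok] = 10.0
    else:
        ranks = rankdata(vals, method="average")
        out[ok] = 20.0 * (ranks - 1.0) / (n - 1.0)
    return replace(r, values=out)


def temporal_predictability(rasters: dict[dt.date, DailyRaster]) -> float:
    """Mean pairwise Pearson correlation between the images of one variable.

    Computed over jointly valid cells for every date pair; pairs with fewer
    than 3 jointly valid cells are skipped with a warning.  Near-zero values
    diagnose an environment that is unpredictable day to day.
    """
    dates = sorted(rasters)
    if len(dates) < 2:
        raise ValueError("need at least 2 dates")
    rs = []
    for i in range(len(dates)):
        a = rasters[dates[i]].values.ravel()
        for j in range(i + 1, len(dates)):
            b = rasters[dates[j]].values.ravel()
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 3:
                logger.warning("pair (%s, %s): < 3 jointly valid cells, skipped", dates[i], dates[j])
                continue
            aa, bb = a[ok], b[ok]
            if aa.std() == 0 or bb.std() == 0:
                logger.warning("pair (%s, %s): constant image, skipped", dates[i], dates[j])
                continue
            rs.append(float(np.corrcoef(aa, bb)[0, 1]))
    return float(np.mean(rs)) if rs else np.nan


def covariate_correlations(annotated) -> dict[tuple[str, str], float]:
    """Pairwise Pearson r between the three ranked covariates at model fixes.

    ``annotated`` is a DataFrame with columns ``sst_rank``, ``turbidity_rank``,
    ``chla_rank``; rows with any missing covariate are dropped first.
    """
    cols = [f"{v}_rank" for v in VARIABLES]
    sub = annotated[cols].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 fixes with all covariates defined")
    out = {}
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = sub[cols[i]].to_numpy(), sub[cols[j]].to_numpy()
            if a.std() == 0 or b.std() == 0:
                logger.warning("constant covariate column; correlation undefined")
                out[(VARIABLES[i], VARIABLES[j])] = np.nan
            else:
                out[(VARIABLES[i], VARIABLES[j])] = float(np.corrcoef(a, b)[0, 1])
    return out


# --- plain-text raster I/O (ESRI ASCII grid) ---------------------------------

_NODATA = -9999.0


def write_ascii_grid(r: DailyRaster, path) -> None:
    """Write a raster as an ESRI ASCII grid (.asc), NaN as the nodata value."""
    nrows, ncols = r.shape
    vals = np.where(np.isfinite(r.values), r.values, _NODATA)
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {r.west:.10f}\nyllcorner {r.south:.10f}\n"
        f"cellsize {r.cell:.10f}\nNODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.6g")


def read_ascii_grid(path, variable: str, date: dt.date) -> DailyRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            k, v = fh.readline().split()
            hdr[k.lower()] = float(v)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)
    nodata = hdr.get("nodata_value", _NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    cell = hdr["cellsize"]
    north = hdr["yllcorner"] + hdr["nrows"] * cell
    return DailyRaster(variable, date, vals, hdr["xllcorner"], north, cell)


_FNAME_RE = re.compile(r"^(?P<var>[a-z]+)_(?P<date>\d{8})\.asc$")


def load_raster_directory(directory) -> dict[str, dict[dt.date, DailyRaster]]:
    """Load all ``<variable>_<YYYYMMDD>.asc`` files from a directory."""
    out: dict[str, dict[dt.date, DailyRaster]] = {v: {} for v in VARIABLES}
    for p in sorted(Path(directory).glob("*.asc")):
        m = _FNAME_RE.match(p.name)
        if not m or m.group("var") not in VARIABLES:
            logger.warning("unrecognised raster file name %s, skipped", p.name)
            continue
        date = dt.datetime.strptime(m.group("date"), "%Y%m%d").date()
        out[m.group("var")][date] = read_ascii_grid(p, m.group("var"), date)
    return out


class CovariateStack:
    """Daily rasters per variable plus their ranked two-day-averaged derivatives.

    ``rank_after_average`` selects the preparation order: by default raw
    daily images are aggregated, the day-pair is averaged, and the averaged
    image is rank-standardised; the alternative ranks each day first and
    averages ranks.
    """

    def __init__(self, raw: dict[str, dict[dt.date, DailyRaster]], window: GridWindow,
                 target_cell: float = 0.05, rank_after_average: bool = True):
        self.window = window
        self.target_cell = target_cell
        self.rank_after_average = rank_after_average
        self.aggregated = {
            var: {d: aggregate(r, window, target_cell) for d, r in days.items()}
            for var, days in raw.items()
        }
        self._ranked_cache: dict[tuple[str, dt.date], DailyRaster] = {}

    def dates(self, variable: str) -> list[dt.date]:
        return sorted(self.aggregated[variable])

    def ranked(self, variable: str, date: dt.date) -> DailyRaster:
        """Ranked two-day-averaged image for a tracking day (cached)."""
        key = (variable, date)
        if key not in self._ranked_cache:
            days = self.aggregated[variable]
            if self.rank_after_average:
                avg = two_day_average(days, variable, date)
                self._ranked_cache[key] = rank_standardise(avg)
            else:
                ranked = {
                    d: rank_standardise(days[d])
                    for d in (date, date - dt.timedelta(days=1)) if d in days
                }
                self._ranked_cache[key] = two_day_average(ranked, variable, date)
        return self._ranked_cache[key]

    def predictability(self, variable: str) -> float:
        return temporal_predictability(self.aggregated[variable])
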