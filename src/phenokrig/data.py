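"""Domain types, phenophase scoring, and delimited-text / raster I/O.

Coordinates are planar metres (UTM-like eastings/northings) and all distances
are Euclidean: at the ~17 km extent of a municipal phenology network the
geodesic distortion is negligible, so no geodesy is performed anywhere in the
package.

Flowering is scored on a five-stage scale driven by the fraction of open
flowers in the inflorescence (a flower counts as open once its stamens are
exerted):

====  =================  ==========================================
code  name               definition
====  =================  ==========================================
0     before flowering   inflorescence emerged, no flower open yet
1     start flowering    up to ~25 % of flowers open
2     full flowering     ~25–75 % open, maximum pollen shedding
3     ending flowering   >75 % open, anthers releasing the last pollen
4     past flowering     anthers (almost) empty
====  =================  ==========================================

Field values are means of five 1 m² quadrat scores, hence real numbers on
[0, 4] rather than integers.
"""

from __future__ import annotations

import datetime as _dt
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Zone",
    "Phenophase",
    "SamplingPoint",
    "PhenoObservation",
    "PhenoDataset",
    "PollenSeries",
    "PhenoGrid",
    "assign_phenophase",
    "read_points",
    "write_points",
    "read_observations",
    "write_observations",
    "build_datasets",
    "read_pollen",
    "write_pollen",
    "read_ascii_grid",
    "write_ascii_grid",
]

#: sentinel written for missing raster cells
NODATA_DEFAULT = -9999.0

PHASE_MIN, PHASE_MAX = 0.0, 4.0


class Zone(str, enum.Enum):
    """Bioclimatic belt of a sampling point (proxy for the low/high altitude split)."""

    TERMO = "termomediterranean"
    MESO = "mesomediterranean"

    @classmethod
    def parse(cls, text: str) -> "Zone":
        t = str(text).strip().lower()
        for z in cls:
            if t == z.value or t == z.name.lower():
                return z
        raise ValueError(f"unknown bioclimatic zone: {text!r}")


class Phenophase(enum.IntEnum):
    """Discrete flowering stage, 0 (pre-flowering) through 4 (past flowering)."""

    BEFORE_FLOWERING = 0
    START_FLOWERING = 1
    FULL_FLOWERING = 2
    ENDING_FLOWERING = 3
    PAST_FLOWERING = 4


@dataclass(frozen=True)
class SamplingPoint:
    """A georeferenced monitoring site."""

    id: str
    x: float  # projected easting, metres
    y: float  # projected northing, metres
    altitude: float  # metres a.s.l.
    zone: Zone

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"point {self.id!r}: non-finite coordinates")
        if not math.isfinite(self.altitude) or self.altitude < 0:
            raise ValueError(f"point {self.id!r}: altitude must be finite and >= 0")


@dataclass(frozen=True)
class PhenoObservation:
    """One phenophase reading (mean of 5 quadrat scores) at a point on a date."""

    point_id: str
    date: _dt.date
    phase: float

    def __post_init__(self) -> None:
        if not (PHASE_MIN <= self.phase <= PHASE_MAX):
            raise ValueError(
                f"observation ({self.point_id}, {self.date}): phase {self.phase} "
                f"outside [{PHASE_MIN}, {PHASE_MAX}]"
            )


@dataclass
class PhenoDataset:
    """Phase values for a set of points on one survey date."""

    date: _dt.date
    points: list[SamplingPoint]
    values: np.ndarray  # shape (n,), phase units on [0, 4]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.points):
            raise ValueError("values must be 1-D with one entry per point")
        if len(self.points) and (
            self.values.min() < PHASE_MIN or self.values.max() > PHASE_MAX
        ):
            raise ValueError(f"dataset {self.date}: phase values outside [0, 4]")
        ids = [p.id for p in self.points]
        if len(set(ids)) != len(ids):
            raise ValueError(f"dataset {self.date}: duplicate point ids")

    @property
    def n(self) -> int:
        return len(self.points)

    def coords(self) -> np.ndarray:
        """(n, 2) array of x/y coordinates."""
        return np.array([[p.x, p.y] for p in self.points], dtype=float)


@dataclass
class PollenSeries:
    """Daily airborne pollen concentrations (grains/m³) from a volumetric trap."""

    dates: list[_dt.date]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.dates) != len(self.counts):
            raise ValueError("dates and counts must have equal length")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("pollen dates must be strictly increasing")
        if len(self.counts) and self.counts.min() < 0:
            raise ValueError("pollen counts must be >= 0")

    def __len__(self) -> int:
        return len(self.dates)


@dataclass
class PhenoGrid:
    """Regular north-up raster of phase values over the study bounding box.

    ``values[0, :]`` is the northernmost row.  Cells may hold the NODATA
    sentinel; valid cells are on [0, 4].  ``clamp_flags`` records cells whose
    kriged estimate was clamped into the phase range.
    """

    xll: float
    yll: float
    cellsize: float
    values: np.ndarray  # (nrows, ncols)
    nodata: float = NODATA_DEFAULT
    clamp_flags: np.ndarray | None = None  # bool (nrows, ncols)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid values must be a non-empty 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if self.clamp_flags is not None:
            self.clamp_flags = np.asarray(self.clamp_flags, dtype=bool)
            if self.clamp_flags.shape != self.values.shape:
                raise ValueError("clamp_flags shape must match values")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (X, Y) of cell-centre coordinates, same shape as ``values``."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (np.arange(self.nrows)[::-1] + 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def value_at(self, x: float, y: float) -> float:
        """Value of the cell containing (x, y); raises if outside the grid."""
        col = int(np.floor((x - self.xll) / self.cellsize))
        row_from_bottom = int(np.floor((y - self.yll) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"({x}, {y}) outside grid extent")
        return float(self.values[row, col])


# ---------------------------------------------------------------------------
# phenophase scoring
# ---------------------------------------------------------------------------

def assign_phenophase(
    fraction_open: float,
    inflorescence_emerged: bool = True,
    anthers_empty: bool = False,
) -> Phenophase:
    """Score a single inflorescence observation into a phenophase.

    Boundary fractions (exactly 0.25 or 0.75) go to the lower-numbered phase;
    the stage definitions are approximate percentages, so ties are resolved
    conservatively.  Once the anthers are empty the stage is 4 regardless of
    ``fraction_open``.
    """
    if not (0.0 <= fraction_open <= 1.0):
        raise ValueError(f"fraction_open {fraction_open} outside [0, 1]")
    if anthers_empty:
        return Phenophase.PAST_FLOWERING
    if fraction_open == 0.0:
        if not inflorescence_emerged:
            raise ValueError("no phase before inflorescence emergence")
        return Phenophase.BEFORE_FLOWERING
    if fraction_open <= 0.25:
        return Phenophase.START_FLOWERING
    if fraction_open <= 0.75:
        return Phenophase.FULL_FLOWERING
    return Phenophase.ENDING_FLOWERING


# ---------------------------------------------------------------------------
# delimited-text readers / writers (comma separator, '.' decimal, UTF-8)
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_points(path) -> list[SamplingPoint]:
    """Read sampling points from CSV with header ``id,x,y,altitude,zone``."""
    df = pd.read_csv(path, dtype={"id": str})
    _require_columns(df, ["id", "x", "y", "altitude", "zone"], path)
    points: list[SamplingPoint] = []
    seen: set[str] = set()
    for row_no, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            pt = SamplingPoint(
                id=str(rec.id),
                x=float(rec.x),
                y=float(rec.y),
                altitude=float(rec.altitude),
                zone=Zone.parse(rec.zone),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} row {row_no}: {exc}") from exc
        if pt.id in seen:
            raise ValueError(f"{path} row {row_no}: duplicate point id {pt.id!r}")
        seen.add(pt.id)
        points.append(pt)
    return points


def write_points(points: Iterable[SamplingPoint], path) -> None:
    df = pd.DataFrame(
        [(p.id, p.x, p.y, p.altitude, p.zone.value) for p in points],
        columns=["id", "x", "y", "altitude", "zone"],
    )
    df.to_csv(path, index=False)


def read_observations(path) -> list[PhenoObservation]:
    """Read phenology observations from CSV ``point_id,date,phase`` (ISO dates)."""
    df = pd.read_csv(path, dtype={"point_id": str})
    _require_columns(df, ["point_id", "date", "phase"], path)
    out: list[PhenoObservation] = []
    for row_no, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                PhenoObservation(
                    point_id=str(rec.point_id),
                    date=_dt.date.fromisoformat(str(rec.date)),
                    phase=float(rec.phase),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} row {row_no}: {exc}") from exc
    return out


def write_observations(datasets: Iterable[PhenoDataset], path) -> None:
    rows = [
        (p.id, ds.date.isoformat(), v)
        for ds in datasets
        for p, v in zip(ds.points, ds.values)
    ]
    pd.DataFrame(rows, columns=["point_id", "date", "phase"]).to_csv(path, index=False)


def build_datasets(
    observations: Iterable[PhenoObservation], points: Sequence[SamplingPoint]
) -> list[PhenoDataset]:
    """Group observations by date into per-date datasets, keeping the order of
    ``points`` for the points present on each date."""
    by_id = {p.id: p for p in points}
    order = {p.id: i for i, p in enumerate(points)}
    by_date: dict[_dt.date, list[PhenoObservation]] = {}
    for ob in observations:
        if ob.point_id not in by_id:
            raise ValueError(f"observation references unknown point {ob.point_id!r}")
        by_date.setdefault(ob.date, []).append(ob)
    datasets = []
    for date in sorted(by_date):
        obs = sorted(by_date[date], key=lambda o: order[o.point_id])
        datasets.append(
            PhenoDataset(
                date=date,
                points=[by_id[o.point_id] for o in obs],
                values=np.array([o.phase for o in obs]),
            )
        )
    return datasets


def read_pollen(path) -> PollenSeries:
    """Read a daily pollen series from CSV ``date,count``."""
    df = pd.read_csv(path)
    _require_columns(df, ["date", "count"], path)
    dates = [_dt.date.fromisoformat(str(d)) for d in df["date"]]
    return PollenSeries(dates=dates, counts=df["count"].to_numpy(dtype=float))


def write_pollen(series: PollenSeries, path) -> None:
    pd.DataFrame(
        {"date": [d.isoformat() for d in series.dates], "count": series.counts}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

def write_ascii_grid(grid: PhenoGrid, path) -> None:
    """Write a grid as an ESRI ASCII raster (.asc), north-up, row-major."""
    lines = [
        f"ncols {grid.ncols}",
        f"nrows {grid.nrows}",
        f"xllcorner {grid.xll:.6f}",
        f"yllcorner {grid.yll:.6f}",
        f"cellsize {grid.cellsize:.6f}",
        f"NODATA_value {grid.nodata:g}",
    ]
    for row in grid.values:
        lines.append(" ".join(f"{v:.10g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ascii_grid(path) -> PhenoGrid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    text = Path(path).read_text(encoding="utf-8").split()
    header: dict[str, float] = {}
    i = 0
    while i < len(text) and text[i].lstrip("-").replace(".", "", 1).isalpha() is False:
        break
    # parse the six key/value header lines
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    idx = 0
    while idx + 1 < len(text) and text[idx].lower() in keys:
        header[text[idx].lower()] = float(text[idx + 1])
        idx += 2
    for k in keys:
        if k not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {k!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = np.array([float(t) for t in text[idx:]], dtype=float)
    if data.size != nrows * ncols:
        raise ValueError(
            f"{path}: expected {nrows * ncols} values, found {data.size}"
        )
    return PhenoGrid(
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        values=data.reshape(nrows, ncols),
        nodata=header["nodata_value"],
    )
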