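"""Longitudinal census-tract socioeconomic panels.

The neighborhood unit throughout the package is the census tract.  A
:class:`TractSeries` holds one tract's year-indexed observations (and an
optional polygon); a :class:`RegionPanel` holds every tract in a metro
region.  All classifiers consume a panel plus region-level statistics
(:func:`region_stats`): the regional median tract income, the regional
median share of recently built housing, and the region-wide change in
college education.

Percent variables are stored on the 0-100 scale everywhere.  Input files
carrying fractions (0-1) are rejected rather than silently rescaled,
because silent rescaling is the classic data-corruption path for this
kind of table.  Monetary values are nominal; no deflator is applied
unless the caller supplies one.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .errors import ConfigError, MissingDataError, PanelValidationError

logger = logging.getLogger(__name__)

YEAR_MIN = 1900
YEAR_MAX = 2100

#: Percent-scale variables (0-100), in canonical CSV column order.
PERCENT_FIELDS = (
    "pct_bachelor_25plus",
    "pct_low_income_hh",
    "pct_housing_built_prior_20yr",
    "pct_urban_blocks",
    "pct_renter_hh",
    "pct_nonwhite",
)

#: Non-negative dollar-valued variables.
MONEY_FIELDS = ("median_hh_income", "median_home_price")

#: Canonical long-format CSV columns.
CSV_COLUMNS = (
    "tract_id",
    "year",
    "population",
    "median_hh_income",
    "median_home_price",
    "pct_bachelor_25plus",
    "pct_low_income_hh",
    "pct_housing_built_prior_20yr",
    "pct_urban_blocks",
    "pct_renter_hh",
    "pct_nonwhite",
    "college_town",
)


@dataclass(frozen=True)
class TractObservation:
    """One tract's socioeconomic measurements in one calendar year.

    Missing measurements are ``None``, never zero: a tract with no
    reported income is excluded from income medians, not counted as
    destitute.
    """

    year: int
    population: int | None = None
    median_hh_income: float | None = None
    median_home_price: float | None = None
    pct_bachelor_25plus: float | None = None
    pct_low_income_hh: float | None = None
    pct_housing_built_prior_20yr: float | None = None
    pct_urban_blocks: float | None = None
    pct_renter_hh: float | None = None
    pct_nonwhite: float | None = None
    college_town: bool = False

    def __post_init__(self) -> None:
        if not (YEAR_MIN <= self.year <= YEAR_MAX):
            raise PanelValidationError(
                f"year {self.year} outside plausible range [{YEAR_MIN}, {YEAR_MAX}]"
            )
        if self.population is not None and self.population < 0:
            raise PanelValidationError(f"population must be non-negative, got {self.population}")
        for name in MONEY_FIELDS:
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise PanelValidationError(f"{name} must be a non-negative finite value, got {v}")
        for name in PERCENT_FIELDS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise PanelValidationError(
                    f"{name} must lie in [0, 100] (percent scale), got {v}"
                )


@dataclass
class TractSeries:
    """A tract's year-indexed observations plus an optional polygon.

    ``geometry`` is a shapely Polygon/MultiPolygon in geographic
    lon/lat (WGS84) coordinates, as carried by GeoJSON.
    """

    tract_id: str
    observations: dict[int, TractObservation] = field(default_factory=dict)
    geometry: BaseGeometry | None = None

    def __post_init__(self) -> None:
        if not self.tract_id:
            raise PanelValidationError("tract_id must be non-empty")
        for year, obs in self.observations.items():
            if year != obs.year:
                raise PanelValidationError(
                    f"tract {self.tract_id}: observation keyed {year} carries year {obs.year}"
                )

    @property
    def years(self) -> list[int]:
        return sorted(self.observations)

    def get(self, year: int) -> TractObservation | None:
        return self.observations.get(year)

    def value(self, year: int, variable: str) -> float | None:
        """A single variable at a year, or ``None`` if absent."""
        obs = self.observations.get(year)
        return None if obs is None else getattr(obs, variable)


@dataclass
class RegionPanel:
    """All tracts of one region over the covered years."""

    region_name: str
    tracts: list[TractSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.tract_id for t in self.tracts]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelValidationError(f"duplicate tract_ids in panel: {dupes}")

    @property
    def years(self) -> list[int]:
        return sorted({y for t in self.tracts for y in t.observations})

    @property
    def n_tracts(self) -> int:
        return len(self.tracts)

    def __iter__(self):
        return iter(self.tracts)

    def __len__(self) -> int:
        return len(self.tracts)

    def tract(self, tract_id: str) -> TractSeries:
        for t in self.tracts:
            if t.tract_id == tract_id:
                return t
        raise KeyError(tract_id)

    def require_years(self, years: Iterable[int], context: str) -> None:
        """Raise :class:`ConfigError` unless every year is covered."""
        have = set(self.years)
        missing = sorted(set(years) - have)
        if missing:
            raise ConfigError(f"{context}: years {missing} absent from panel (covered: {sorted(have)})")

    def values(self, year: int, variable: str) -> dict[str, float]:
        """Non-missing values of one variable at one year, keyed by tract."""
        out: dict[str, float] = {}
        for t in self.tracts:
            v = t.value(year, variable)
            if v is not None:
                out[t.tract_id] = v
        return out

    def total_population(self, year: int) -> int:
        return int(sum(v for v in self.values(year, "population").values()))


@dataclass(frozen=True)
class RegionStats:
    """Region-level reference statistics for classifier thresholds.

    ``median_tract_income`` operationalizes "the regional median income"
    as the median across tracts of tract median household income; a
    region-wide household median is not computable from tract medians
    alone.  ``region_edu_pp_change`` is the population-weighted (by
    default) percentage-point change in the college-educated share over
    ``window``, the closest panel-computable proxy for the education
    trend of the region as a whole.
    """

    year: int
    window: tuple[int, int]
    median_tract_income: float
    median_pct_housing_prior20: float
    region_edu_pp_change: float


def region_stats(
    panel: RegionPanel,
    year: int,
    window: tuple[int, int],
    *,
    edu_weighting: str = "population",
) -> RegionStats:
    """Regional medians at ``year`` and the education change over ``window``.

    Parameters
    ----------
    edu_weighting:
        ``"population"`` weights each tract's percentage-point education
        change by its population at the window end; ``"unweighted"``
        averages tract changes equally.
    """
    start, end = window
    panel.require_years([year, start, end], "region_stats")
    if edu_weighting not in ("population", "unweighted"):
        raise ConfigError(f"unknown edu_weighting {edu_weighting!r}")

    incomes = list(panel.values(year, "median_hh_income").values())
    if not incomes:
        raise MissingDataError(f"median_hh_income missing for every tract at {year}")
    housing = list(panel.values(year, "pct_housing_built_prior_20yr").values())
    if not housing:
        raise MissingDataError(f"pct_housing_built_prior_20yr missing for every tract at {year}")

    edu_start = panel.values(start, "pct_bachelor_25plus")
    edu_end = panel.values(end, "pct_bachelor_25plus")
    pop_end = panel.values(end, "population")
    changes: list[float] = []
    weights: list[float] = []
    for tid in edu_start.keys() & edu_end.keys():
        w = pop_end.get(tid) if edu_weighting == "population" else 1.0
        if w is None:
            continue
        changes.append(edu_end[tid] - edu_start[tid])
        weights.append(float(w))
    if not changes or sum(weights) == 0:
        raise MissingDataError(
            f"pct_bachelor_25plus change not computable over {start}-{end} for any tract"
        )
    edu_pp = float(np.average(changes, weights=weights))

    return RegionStats(
        year=year,
        window=window,
        median_tract_income=float(np.median(incomes)),
        median_pct_housing_prior20=float(np.median(housing)),
        region_edu_pp_change=edu_pp,
    )


# ---------------------------------------------------------------------------
# CSV I/O (long format, one row per tract-year)
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no", ""}


def _parse_float(cell: str, row: int, col: str) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise PanelValidationError(
            f"row {row}, column {col!r}: malformed numeric value {cell!r}"
        ) from None


def _parse_int(cell: str, row: int, col: str) -> int | None:
    v = _parse_float(cell, row, col)
    if v is None:
        return None
    if v != int(v):
        raise PanelValidationError(f"row {row}, column {col!r}: expected integer, got {cell!r}")
    return int(v)


def read_tract_csv(
    path: str | Path,
    schema_config: Mapping[str, str] | None = None,
    region_name: str | None = None,
) -> RegionPanel:
    """Read a long-format tract panel CSV.

    ``schema_config`` maps canonical column names (see ``CSV_COLUMNS``)
    to the names actually used in the file, for ingesting tables with
    foreign headers.  Empty cells become missing values; malformed
    numbers, out-of-range percents and duplicate (tract, year) rows are
    errors that name the offending row and column.
    """
    path = Path(path)
    rename = dict(schema_config or {})
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        colmap = {canon: rename.get(canon, canon) for canon in CSV_COLUMNS}
        for required in ("tract_id", "year"):
            if colmap[required] not in header:
                raise PanelValidationError(
                    f"{path.name}: required column {colmap[required]!r} not found in header"
                )
        present = {c for c in CSV_COLUMNS if colmap[c] in header}
        if present <= {"tract_id", "year"}:
            raise PanelValidationError(f"{path.name}: no data columns present besides tract_id/year")

        rows: dict[str, dict[int, TractObservation]] = {}
        for i, rec in enumerate(reader, start=2):  # header is line 1
            tid = (rec.get(colmap["tract_id"]) or "").strip()
            if not tid:
                raise PanelValidationError(f"row {i}: empty tract_id")
            year = _parse_int(rec.get(colmap["year"], ""), i, "year")
            if year is None:
                raise PanelValidationError(f"row {i}: empty year")
            kwargs: dict[str, object] = {"year": year}
            if "population" in present:
                kwargs["population"] = _parse_int(rec.get(colmap["population"], ""), i, "population")
            for name in MONEY_FIELDS + PERCENT_FIELDS:
                if name in present:
                    kwargs[name] = _parse_float(rec.get(colmap[name], ""), i, name)
            if "college_town" in present:
                cell = (rec.get(colmap["college_town"]) or "").strip().lower()
                if cell in _TRUE:
                    kwargs["college_town"] = True
                elif cell in _FALSE:
                    kwargs["college_town"] = False
                else:
                    raise PanelValidationError(
                        f"row {i}, column 'college_town': unrecognized boolean {cell!r}"
                    )
            try:
                obs = TractObservation(**kwargs)  # type: ignore[arg-type]
            except PanelValidationError as exc:
                raise PanelValidationError(f"row {i}: {exc}") from None
            series = rows.setdefault(tid, {})
            if year in series:
                raise PanelValidationError(f"row {i}: duplicate observation for ({tid!r}, {year})")
            series[year] = obs

    tracts = [TractSeries(tid, obs) for tid, obs in sorted(rows.items())]
    return RegionPanel(region_name or path.stem, tracts)


def _format_cell(v: object) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, int):
        return str(v)
    if isinstance(v, float):
        return str(int(v)) if v == int(v) and abs(v) < 1e15 else repr(v)
    return str(v)


def write_tract_csv(panel: RegionPanel, path: str | Path) -> Path:
    """Write the panel in long format, deterministically ordered.

    Rows are sorted by (tract_id, year) and floats use ``repr`` so the
    file is byte-identical across runs and round-trips exactly.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for tract in sorted(panel.tracts, key=lambda t: t.tract_id):
            for year in tract.years:
                obs = tract.observations[year]
                writer.writerow(
                    [tract.tract_id]
                    + [_format_cell(getattr(obs, c)) for c in CSV_COLUMNS[1:]]
                )
    return path


# ---------------------------------------------------------------------------
# GeoJSON geometries
# ---------------------------------------------------------------------------


def read_geojson_geometries(path: str | Path) -> dict[str, BaseGeometry]:
    """Read tract polygons from a GeoJSON FeatureCollection.

    Each feature must carry a ``tract_id`` property and a polygon or
    multipolygon geometry in lon/lat.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise PanelValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    out: dict[str, BaseGeometry] = {}
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        tid = props.get("tract_id")
        if tid is None:
            raise PanelValidationError("GeoJSON feature lacks a 'tract_id' property")
        geom = shapely_shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise PanelValidationError(
                f"tract {tid}: geometry type {geom.geom_type} is not a polygon"
            )
        out[str(tid)] = geom
    return out


def attach_geometries(panel: RegionPanel, geometries: Mapping[str, BaseGeometry]) -> int:
    """Attach polygons to matching tracts; returns the number attached."""
    n = 0
    for tract in panel.tracts:
        geom = geometries.get(tract.tract_id)
        if geom is not None:
            tract.geometry = geom
            n += 1
    unmatched = set(geometries) - {t.tract_id for t in panel.tracts}
    if unmatched:
        logger.warning("%d geometries had no matching tract", len(unmatched))
    return n


def geometry_feature(tract: TractSeries, properties: Mapping[str, object]) -> dict:
    """A GeoJSON Feature dict for one tract."""
    return {
        "type": "Feature",
        "geometry": shapely_mapping(tract.geometry),
        "properties": {"tract_id": tract.tract_id, **properties},
    }
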