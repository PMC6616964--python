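"""Seeded synthetic tract panels with planted neighborhood-change regimes.

The generator emulates a Bay-Area-like metro region: ~1,500 census
tracts observed in 1990, 2000, 2010 and 2013, with a regional median
tract income near $79,671 and a college-educated share near 43%.  Each
tract is assigned one of four change regimes — STABLE, GENTRIFYING,
DECLINING, HOT_MARKET_NO_LOSS — which dictates the drift of its income,
home price, education, low-income share and renter share between 2000
and 2013 (values at 2010 are linearly interpolated; 1990 is a scaled-
back baseline).  Cross-sectional structure is enforced at baseline:
income is negatively associated with the low-income-household share and
the renter share, positively with education.

Drifts are exact when ``noise_sd = 0`` (a tract in a regime with +42%
income drift changes income by exactly +42%), which is what makes
planted-truth recovery tests sharp.  With ``noise_sd > 0``, independent
Gaussian perturbations are added to each drift and results are clipped
into valid ranges (clipping is logged).  The generator makes no attempt
at spatial autocorrelation or realistic street geography: polygons are
a synthetic square grid, labelled as such.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .errors import ConfigError
from .landis import LandisConfig, assign_deciles
from .panel import RegionPanel, TractObservation, TractSeries

logger = logging.getLogger(__name__)

REGIME_NAMES = ("STABLE", "GENTRIFYING", "DECLINING", "HOT_MARKET_NO_LOSS")


@dataclass(frozen=True)
class RegimeConfig:
    """One planted change regime.

    Relative drifts (``income_drift``, ``home_price_drift``) are
    fractions over the 2000-2013 window (+0.42 = +42%); ``*_pp`` drifts
    are percentage points.  ``noise_sd`` scales the Gaussian
    perturbation added to every drift (0 = deterministic drifts).
    """

    name: str
    weight: float
    income_drift: float
    edu_pp_drift: float
    home_price_drift: float
    li_share_drift: float
    renter_drift: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in REGIME_NAMES:
            raise ConfigError(f"unknown regime name {self.name!r}")
        if not (0.0 <= self.weight <= 1.0):
            raise ConfigError(f"regime weight must lie in [0, 1], got {self.weight}")
        for v in (
            self.income_drift, self.edu_pp_drift, self.home_price_drift,
            self.li_share_drift, self.renter_drift, self.noise_sd,
        ):
            if not math.isfinite(v):
                raise ConfigError("regime drifts must be finite")


def default_regimes(noise_sd: float = 0.0) -> list[RegimeConfig]:
    """The default regime mixture.

    Mixture weights mirror the shape of a large metro region where the
    vast majority of tracts are stable; drift magnitudes are directional
    caricatures of a gentrifying-vs-declining contrast (gentrifying
    tracts: income +42%, education +15 pp, hot market, losing low-income
    households; declining tracts: income -35%, cooling market, gaining
    low-income households).
    """
    return [
        RegimeConfig("STABLE", 0.87, -0.07, 2.0, 0.00, 1.0, 1.0, noise_sd),
        RegimeConfig("GENTRIFYING", 0.06, 0.42, 15.0, 0.50, -8.0, -4.0, noise_sd),
        RegimeConfig("DECLINING", 0.04, -0.35, 1.0, -0.15, 6.0, 8.0, noise_sd),
        RegimeConfig("HOT_MARKET_NO_LOSS", 0.03, 0.05, 2.0, 0.45, 1.0, 2.0, noise_sd),
    ]


@dataclass(frozen=True)
class SyntheticSpec:
    """Scale and shape of the synthetic region."""

    n_tracts: int = 1500
    years: tuple[int, ...] = (1990, 2000, 2010, 2013)
    regional_median_income: float = 79671.0
    income_log_sd: float = 0.45
    urban_fraction: float = 0.9
    college_town_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracts < 0:
            raise ConfigError(f"n_tracts must be >= 0, got {self.n_tracts}")
        if list(self.years) != sorted(set(self.years)):
            raise ConfigError("years must be strictly ascending")
        if len(self.years) < 2:
            raise ConfigError("need at least two years")
        if not (0.0 <= self.urban_fraction <= 1.0):
            raise ConfigError("urban_fraction must lie in [0, 1]")


def _clip_pct(x: np.ndarray, what: str) -> np.ndarray:
    clipped = np.clip(x, 0.0, 100.0)
    n = int(np.sum(clipped != x))
    if n:
        logger.info("synthetic: clipped %d %s values into [0, 100]", n, what)
    return clipped


def _grid_polygon(i: int, n: int) -> Polygon:
    """Unit cell of a synthetic square grid near (-122, 37.5) lon/lat."""
    side = max(1, math.ceil(math.sqrt(n)))
    col, row = i % side, i // side
    x0 = -122.5 + 0.01 * col
    y0 = 37.0 + 0.01 * row
    return Polygon([(x0, y0), (x0 + 0.01, y0), (x0 + 0.01, y0 + 0.01), (x0, y0 + 0.01), (x0, y0)])


def generate_region(
    spec: SyntheticSpec, regimes: list[RegimeConfig] | None = None
) -> tuple[RegionPanel, dict[str, str]]:
    """Generate a panel and the planted truth (tract -> regime name).

    Deterministic given ``spec.seed``; tract ids are ``T0000``-style and
    do not depend on regime assignment.
    """
    regimes = regimes if regimes is not None else default_regimes()
    wsum = sum(r.weight for r in regimes)
    if abs(wsum - 1.0) > 1e-9:
        raise ConfigError(f"regime weights must sum to 1, got {wsum}")
    n = spec.n_tracts
    rng = np.random.default_rng(spec.seed)
    ids = [f"T{i:04d}" for i in range(n)]
    if n == 0:
        return RegionPanel("synthetic", []), {}

    regime_idx = rng.choice(len(regimes), size=n, p=[r.weight for r in regimes])
    truth = {ids[i]: regimes[regime_idx[i]].name for i in range(n)}

    # Baseline (2000) cross-section.  Gentrifying tracts draw from the
    # lower income range and old, urban housing stock so they are
    # gentrifiable; declining tracts draw from the upper range.
    z = rng.normal(size=n)
    offset = np.zeros(n)
    for i, r in enumerate(regimes):
        if r.name == "GENTRIFYING":
            offset[regime_idx == i] = -0.9
        elif r.name == "DECLINING":
            offset[regime_idx == i] = 0.6
    income0 = spec.regional_median_income * np.exp(spec.income_log_sd * (0.6 * z + offset))
    zscore = np.log(income0 / spec.regional_median_income) / spec.income_log_sd

    edu0 = _clip_pct(43.0 + 14.0 * zscore + rng.normal(0, 4.0, n), "pct_bachelor_25plus")
    li0 = _clip_pct(41.0 - 16.0 * zscore + rng.normal(0, 4.0, n), "pct_low_income_hh")
    renter0 = _clip_pct(43.0 - 13.0 * zscore + rng.normal(0, 5.0, n), "pct_renter_hh")
    nonwhite0 = _clip_pct(55.0 - 9.0 * zscore + rng.normal(0, 8.0, n), "pct_nonwhite")
    price0 = income0 * 5.0 * np.exp(rng.normal(0, 0.15, n))

    housing0 = rng.uniform(5.0, 60.0, n)
    urban = np.where(
        rng.random(n) < spec.urban_fraction, rng.uniform(50.0, 100.0, n), rng.uniform(0.0, 50.0, n)
    )
    for i, r in enumerate(regimes):
        sel = regime_idx == i
        if r.name == "GENTRIFYING":
            housing0[sel] = rng.uniform(5.0, 22.0, int(sel.sum()))
            urban[sel] = rng.uniform(55.0, 100.0, int(sel.sum()))
    population = rng.integers(1200, 8000, size=n)
    college_town = rng.random(n) < spec.college_town_fraction

    # Window drifts (2000 -> 2013), perturbed per tract when noise_sd > 0.
    def drift(attr: str, scale: float) -> np.ndarray:
        base = np.empty(n)
        noise = np.zeros(n)
        for i, r in enumerate(regimes):
            sel = regime_idx == i
            base[sel] = getattr(r, attr)
            if r.noise_sd > 0:
                noise[sel] = rng.normal(0, r.noise_sd * scale, int(sel.sum()))
        return base + noise

    g_income = drift("income_drift", 0.1)   # relative-drift noise unit: 10% per sd
    g_edu = drift("edu_pp_drift", 3.0)      # pp-drift noise unit: 3 pp per sd
    g_price = drift("home_price_drift", 0.1)
    g_li = drift("li_share_drift", 3.0)
    g_renter = drift("renter_drift", 3.0)

    first, last = spec.years[0], spec.years[-1]
    anchor = 2000 if 2000 in spec.years else spec.years[0]
    span = last - anchor

    tracts: list[TractSeries] = []
    for i in range(n):
        obs: dict[int, TractObservation] = {}
        for year in spec.years:
            if year <= anchor:
                # pre-anchor years: mild uniform backcast, rank-preserving
                back = 1.0 - 0.012 * (anchor - year)
                inc = income0[i] * back
                price = price0[i] * back
                edu = max(0.0, edu0[i] - 0.1 * (anchor - year))
                li = min(100.0, li0[i] + 0.05 * (anchor - year))
                renter = renter0[i]
                nonwhite = max(0.0, nonwhite0[i] - 0.2 * (anchor - year))
            else:
                f = (year - anchor) / span
                inc = income0[i] * (1.0 + f * g_income[i])
                price = price0[i] * (1.0 + f * g_price[i])
                edu = edu0[i] + f * g_edu[i]
                li = li0[i] + f * g_li[i]
                renter = renter0[i] + f * g_renter[i]
                nonwhite = nonwhite0[i] + f * 2.0
            obs[year] = TractObservation(
                year=year,
                population=int(population[i]),
                median_hh_income=float(max(0.0, inc)),
                median_home_price=float(max(0.0, price)),
                pct_bachelor_25plus=float(np.clip(edu, 0.0, 100.0)),
                pct_low_income_hh=float(np.clip(li, 0.0, 100.0)),
                pct_housing_built_prior_20yr=float(housing0[i]),
                pct_urban_blocks=float(urban[i]),
                pct_renter_hh=float(np.clip(renter, 0.0, 100.0)),
                pct_nonwhite=float(np.clip(nonwhite, 0.0, 100.0)),
                college_town=bool(college_town[i]),
            )
        tracts.append(TractSeries(ids[i], obs, geometry=_grid_polygon(i, n)))
    return RegionPanel("synthetic", tracts), truth


def write_truth_csv(truth: dict[str, str], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["tract_id", "regime"])
        for tid in sorted(truth):
            writer.writerow([tid, truth[tid]])


def plant_decile_jumpers(
    spec: SyntheticSpec, k: int, jump: int = 2
) -> tuple[RegionPanel, list[str]]:
    """A two-year income panel with exactly ``k`` planted decile jumpers.

    The ``k`` poorest tracts at baseline (all within deciles 1-4) are
    moved up by at least ``jump`` deciles at the end year; every other
    tract keeps its relative income order.  Returns the panel and the
    planted jumper ids.  Raises :class:`ConfigError` when the requested
    plant is infeasible (k too large for the jump to leave non-jumpers'
    deciles within ``jump - 1`` of their baseline).
    """
    n = spec.n_tracts
    if k > n:
        raise ConfigError(f"k={k} exceeds n_tracts={n}")
    if jump < 1:
        raise ConfigError(f"jump must be >= 1, got {jump}")
    if n == 0:
        return RegionPanel("planted", []), []
    rng = np.random.default_rng(spec.seed)
    ids = [f"T{i:04d}" for i in range(n)]

    # Distinct, ascending baseline incomes: tract i has baseline rank i+1.
    base = np.sort(spec.regional_median_income * np.exp(spec.income_log_sd * rng.normal(size=n)))
    base += np.arange(n)  # enforce strict ordering even after ties

    def decile_of_rank(r: int) -> int:
        return min(10, 1 + (10 * (r - 1)) // n)

    jumpers = list(range(k))
    for i in jumpers:
        if decile_of_rank(i + 1) > 4:
            raise ConfigError(
                f"k={k} reaches baseline decile {decile_of_rank(i + 1)} > 4; reduce k"
            )

    # Target end ranks: each jumper lands in decile (baseline + jump),
    # capped at 10, filling the target decile's rank block from the
    # bottom up (spill into higher deciles only); non-jumpers fill the
    # remaining ranks in baseline order (rank-stable among themselves).
    taken: set[int] = set()
    end_rank = np.empty(n, dtype=int)
    for i in jumpers:
        d_target = min(10, decile_of_rank(i + 1) + jump)
        r = (d_target - 1) * n // 10 + 1  # first rank of the target decile
        while r in taken:
            r += 1
        if r > n:
            raise ConfigError(f"plant infeasible: rank overflow for n={n}, k={k}, jump={jump}")
        taken.add(r)
        end_rank[i] = r
    free = [r for r in range(1, n + 1) if r not in taken]
    for j, i in enumerate(range(k, n)):
        end_rank[i] = free[j]

    end_sorted = np.sort(base) * 1.05  # distinct end incomes, same spacing
    end = np.empty(n)
    for i in range(n):
        end[i] = end_sorted[end_rank[i] - 1]

    y0, y1 = spec.years[0], spec.years[-1]
    tracts = [
        TractSeries(
            ids[i],
            {
                y0: TractObservation(year=y0, population=4000, median_hh_income=float(base[i])),
                y1: TractObservation(year=y1, population=4000, median_hh_income=float(end[i])),
            },
        )
        for i in range(n)
    ]
    panel = RegionPanel("planted", tracts)

    # Verify the plant: jumpers transition by >= jump, nobody else does.
    cfg = LandisConfig(baseline_year=y0, end_year=y1, jump=jump)
    d0 = assign_deciles({t.tract_id: t.value(y0, "median_hh_income") for t in panel.tracts})
    d1 = assign_deciles({t.tract_id: t.value(y1, "median_hh_income") for t in panel.tracts})
    planted = {ids[i] for i in jumpers}
    recovered = {
        tid
        for tid in ids
        if d0[tid] <= cfg.low_decile_max and d1[tid] - d0[tid] >= jump
    }
    if recovered != planted:
        raise ConfigError(
            f"plant infeasible for n={n}, k={k}, jump={jump}: "
            f"{len(recovered ^ planted)} tracts off target"
        )
    return panel, sorted(planted)
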