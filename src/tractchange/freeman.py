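"""Modified Freeman gentrification classifier.

The Freeman approach proceeds in two stages.  A tract is *gentrifiable*
(eligible) if, at a baseline year, it is (1) at or below the regional
median tract income, (2) at or below the regional median share of
housing built in the prior twenty years, and (3) sufficiently urban
(here: at least 50% of census blocks urban, replacing Freeman's original
"central city" designation).  An eligible tract is then *gentrifying*
over a later window if its median home sale price increased (strictly)
and its percentage-point gain in college-educated adults strictly
exceeded the region's.

Boundary semantics follow the wording of the criteria: eligibility's
"at or below" / "at least" are inclusive; the gentrification test's
"increase" / "exceeding" are strict.  Exclusion reasons are attributed
sequentially — income, then urbanicity, then housing age — so a tract
failing several criteria reports only the first, which is how regional
exclusion tallies are conventionally narrated.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .errors import ConfigError, MissingDataError
from .panel import RegionPanel, RegionStats, TractSeries, region_stats

logger = logging.getLogger(__name__)


class FreemanCategory(str, Enum):
    GENTRIFYING = "GENTRIFYING"
    NOT_GENTRIFYING = "NOT_GENTRIFYING"
    EXCLUDED = "EXCLUDED"


class ExclusionReason(str, Enum):
    NONE = "none"
    MEDIUM_HIGH_INCOME = "MEDIUM_HIGH_INCOME"
    NOT_URBAN = "NOT_URBAN"
    HOUSING_TOO_NEW = "HOUSING_TOO_NEW"
    MISSING_DATA = "MISSING_DATA"


@dataclass(frozen=True)
class FreemanLabel:
    category: FreemanCategory
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    def __post_init__(self) -> None:
        excluded = self.category is FreemanCategory.EXCLUDED
        has_reason = self.exclusion_reason is not ExclusionReason.NONE
        if excluded != has_reason:
            raise ValueError(
                f"exclusion_reason {self.exclusion_reason.value!r} inconsistent "
                f"with category {self.category.value!r}"
            )


@dataclass(frozen=True)
class FreemanConfig:
    """Baseline year, gentrification window and urbanicity cutoff.

    ``edu_change_mode``: ``"pp"`` compares percentage-point changes in
    the college-educated share (the conventional reading); ``"relative"``
    compares relative percent changes instead.
    """

    baseline_year: int = 2000
    gentrify_window: tuple[int, int] = (2010, 2013)
    urban_threshold: float = 50.0
    edu_change_mode: str = "pp"
    edu_weighting: str = "population"

    def __post_init__(self) -> None:
        if self.gentrify_window[0] >= self.gentrify_window[1]:
            raise ConfigError(f"gentrify_window must increase, got {self.gentrify_window}")
        if not (0.0 <= self.urban_threshold <= 100.0):
            raise ConfigError(f"urban_threshold must lie in [0, 100], got {self.urban_threshold}")
        if self.edu_change_mode not in ("pp", "relative"):
            raise ConfigError(f"unknown edu_change_mode {self.edu_change_mode!r}")


_ELIGIBLE = FreemanLabel(FreemanCategory.NOT_GENTRIFYING)  # provisional


def freeman_eligibility(
    tract: TractSeries, stats: RegionStats, config: FreemanConfig
) -> FreemanLabel:
    """Stage 1: is the tract gentrifiable at the baseline year?

    Returns an EXCLUDED label (with the first failing criterion as
    reason), or a provisional NOT_GENTRIFYING label meaning *eligible*.
    """
    obs = tract.get(config.baseline_year)
    income = obs.median_hh_income if obs else None
    urban = obs.pct_urban_blocks if obs else None
    housing = obs.pct_housing_built_prior_20yr if obs else None
    if income is None or urban is None or housing is None:
        logger.info("tract %s: missing baseline variable(s), excluded", tract.tract_id)
        return FreemanLabel(FreemanCategory.EXCLUDED, ExclusionReason.MISSING_DATA)
    if income > stats.median_tract_income:
        return FreemanLabel(FreemanCategory.EXCLUDED, ExclusionReason.MEDIUM_HIGH_INCOME)
    if urban < config.urban_threshold:
        return FreemanLabel(FreemanCategory.EXCLUDED, ExclusionReason.NOT_URBAN)
    if housing > stats.median_pct_housing_prior20:
        return FreemanLabel(FreemanCategory.EXCLUDED, ExclusionReason.HOUSING_TOO_NEW)
    return _ELIGIBLE


def freeman_classify(
    tract: TractSeries, stats: RegionStats, config: FreemanConfig
) -> FreemanLabel:
    """Stage 2: does an eligible tract gentrify over the window?"""
    label = freeman_eligibility(tract, stats, config)
    if label.category is FreemanCategory.EXCLUDED:
        return label
    start, end = config.gentrify_window
    price0 = tract.value(start, "median_home_price")
    price1 = tract.value(end, "median_home_price")
    edu0 = tract.value(start, "pct_bachelor_25plus")
    edu1 = tract.value(end, "pct_bachelor_25plus")
    if None in (price0, price1, edu0, edu1):
        logger.info("tract %s: missing window variable(s), excluded", tract.tract_id)
        return FreemanLabel(FreemanCategory.EXCLUDED, ExclusionReason.MISSING_DATA)
    if config.edu_change_mode == "pp":
        edu_change = edu1 - edu0
        region_change = stats.region_edu_pp_change
    else:
        if edu0 == 0:
            return FreemanLabel(FreemanCategory.EXCLUDED, ExclusionReason.MISSING_DATA)
        edu_change = 100.0 * (edu1 - edu0) / edu0
        region_change = stats.region_edu_pp_change  # caller supplies matching mode
    price_up = price1 > price0  # "increase": strict
    edu_exceeds = edu_change > region_change  # "exceeding": strict
    if price_up and edu_exceeds:
        return FreemanLabel(FreemanCategory.GENTRIFYING)
    return FreemanLabel(FreemanCategory.NOT_GENTRIFYING)


def freeman_run(
    panel: RegionPanel, config: FreemanConfig = FreemanConfig()
) -> dict[str, FreemanLabel]:
    """Classify every tract in the panel; labels partition the panel."""
    start, end = config.gentrify_window
    panel.require_years([config.baseline_year, start, end], "freeman_run")
    for year, var in ((start, "median_home_price"), (end, "median_home_price"),
                      (start, "pct_bachelor_25plus"), (end, "pct_bachelor_25plus")):
        if not panel.values(year, var):
            raise MissingDataError(f"freeman_run: {var} missing for every tract at {year}")
    stats = region_stats(
        panel, config.baseline_year, config.gentrify_window, edu_weighting=config.edu_weighting
    )
    if config.edu_change_mode == "relative":
        stats = replace(stats, region_edu_pp_change=_region_edu_relative_change(panel, config))
    labels = {t.tract_id: freeman_classify(t, stats, config) for t in panel.tracts}
    summary = exclusion_summary(labels)
    logger.info("Freeman run: %s", summary)
    return labels


def _region_edu_relative_change(panel: RegionPanel, config: FreemanConfig) -> float:
    """Weighted mean of tract-level relative (%) education changes."""
    start, end = config.gentrify_window
    edu0 = panel.values(start, "pct_bachelor_25plus")
    edu1 = panel.values(end, "pct_bachelor_25plus")
    pop = panel.values(end, "population")
    changes, weights = [], []
    for tid in edu0.keys() & edu1.keys():
        if edu0[tid] == 0:
            continue
        w = pop.get(tid, None) if config.edu_weighting == "population" else 1.0
        if w is None:
            continue
        changes.append(100.0 * (edu1[tid] - edu0[tid]) / edu0[tid])
        weights.append(float(w))
    return float(np.average(changes, weights=weights))


def exclusion_summary(labels: dict[str, FreemanLabel]) -> dict[str, int]:
    """Category and per-reason exclusion counts (the accounting tally)."""
    out: Counter[str] = Counter()
    for label in labels.values():
        out[label.category.value] += 1
        if label.category is FreemanCategory.EXCLUDED:
            out[f"excluded:{label.exclusion_reason.value}"] += 1
    return dict(out)


def write_labels_csv(labels: dict[str, FreemanLabel], path) -> None:
    """Output CSV: tract_id, category, exclusion_reason (sorted by tract)."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["tract_id", "category", "exclusion_reason"])
        for tid in sorted(labels):
            lab = labels[tid]
            writer.writerow([tid, lab.category.value, lab.exclusion_reason.value])


#: Canonical category order for tables.
CATEGORY_ORDER = [c.value for c in FreemanCategory]
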