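"""Landis 3-D decile-transition classifier of neighborhood change.

The Landis approach classifies tracts by how their median household
income moves through the *regional decile distribution* between a
baseline and an end year.  A tract starting in the lowest four deciles
that climbs two or more deciles is *gentrifying*; a tract starting in
the top four deciles that falls two or more is *declining*; everything
else is *stable*.  Because deciles are recomputed within-region at each
year, the classifier responds to relative movement only: a uniform
regional boom changes no decile and no label.

Deciles use average (mid) ranks so tied incomes always land in the same
decile and labels never depend on tract ordering:

    decile(i) = min(10, 1 + floor(10 * (r_i - 1) / n))

with r_i the mid-rank of tract i among the n non-missing incomes,
ascending (decile 1 = poorest tenth).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from scipy.stats import rankdata

from .errors import ConfigError, MissingDataError
from .panel import RegionPanel

logger = logging.getLogger(__name__)


class LandisCategory(str, Enum):
    DECLINING = "DECLINING"
    STABLE = "STABLE"
    GENTRIFYING = "GENTRIFYING"
    UNCLASSIFIED_MISSING = "UNCLASSIFIED_MISSING"


@dataclass(frozen=True)
class LandisConfig:
    """Decile-transition thresholds.

    ``low_decile_max = 4`` means "lowest four deciles" start the
    gentrifying path; ``high_decile_min = 7`` means "top four deciles"
    (7-10, ascending-income convention) start the declining path;
    ``jump`` is the minimum decile movement (2 = "two or more deciles").
    """

    baseline_year: int = 1990
    end_year: int = 2013
    low_decile_max: int = 4
    high_decile_min: int = 7
    jump: int = 2

    def __post_init__(self) -> None:
        if not (1 <= self.low_decile_max < self.high_decile_min <= 10):
            raise ConfigError(
                f"need 1 <= low_decile_max < high_decile_min <= 10, "
                f"got {self.low_decile_max}, {self.high_decile_min}"
            )
        if self.jump < 1:
            raise ConfigError(f"jump must be >= 1, got {self.jump}")
        if self.baseline_year >= self.end_year:
            raise ConfigError(
                f"baseline_year {self.baseline_year} must precede end_year {self.end_year}"
            )


@dataclass(frozen=True)
class LandisLabel:
    category: LandisCategory
    baseline_decile: int | None = None
    end_decile: int | None = None

    def __post_init__(self) -> None:
        for d in (self.baseline_decile, self.end_decile):
            if d is not None and not (1 <= d <= 10):
                raise ValueError(f"decile {d} outside 1-10")
        missing = self.baseline_decile is None or self.end_decile is None
        if missing != (self.category is LandisCategory.UNCLASSIFIED_MISSING):
            raise ValueError("UNCLASSIFIED_MISSING iff a decile is missing")


def assign_deciles(values: Mapping[str, float | None]) -> dict[str, int]:
    """Within-year income deciles from mid-ranks; missing values get none."""
    ids = [k for k, v in values.items() if v is not None]
    if not ids:
        raise MissingDataError("assign_deciles: no non-missing values")
    vec = [values[k] for k in ids]
    n = len(vec)
    ranks = rankdata(vec, method="average")  # mid-ranks: ties share a decile
    return {
        k: min(10, 1 + math.floor(10.0 * (r - 1.0) / n)) for k, r in zip(ids, ranks)
    }


def landis_classify(
    baseline_decile: int, end_decile: int, config: LandisConfig = LandisConfig()
) -> LandisLabel:
    """Apply the decile-transition rules to one tract."""
    for d in (baseline_decile, end_decile):
        if not (1 <= d <= 10):
            raise ValueError(f"decile {d} outside 1-10")
    if baseline_decile <= config.low_decile_max and end_decile - baseline_decile >= config.jump:
        cat = LandisCategory.GENTRIFYING
    elif baseline_decile >= config.high_decile_min and baseline_decile - end_decile >= config.jump:
        cat = LandisCategory.DECLINING
    else:
        cat = LandisCategory.STABLE
    return LandisLabel(cat, baseline_decile, end_decile)


def landis_run(
    panel: RegionPanel, config: LandisConfig = LandisConfig()
) -> dict[str, LandisLabel]:
    """Classify every tract; tracts missing income at either year are
    UNCLASSIFIED_MISSING (reported, never folded into STABLE)."""
    panel.require_years([config.baseline_year, config.end_year], "landis_run")
    dec0 = assign_deciles(
        {t.tract_id: t.value(config.baseline_year, "median_hh_income") for t in panel.tracts}
    )
    dec1 = assign_deciles(
        {t.tract_id: t.value(config.end_year, "median_hh_income") for t in panel.tracts}
    )
    labels: dict[str, LandisLabel] = {}
    n_missing = 0
    for t in panel.tracts:
        d0 = dec0.get(t.tract_id)
        d1 = dec1.get(t.tract_id)
        if d0 is None or d1 is None:
            labels[t.tract_id] = LandisLabel(LandisCategory.UNCLASSIFIED_MISSING, d0, d1)
            n_missing += 1
        else:
            labels[t.tract_id] = landis_classify(d0, d1, config)
    if n_missing:
        logger.warning("landis_run: %d tracts unclassified for missing income", n_missing)
    return labels


def write_labels_csv(labels: dict[str, LandisLabel], path) -> None:
    """Output CSV: tract_id, baseline_decile, end_decile, category."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["tract_id", "baseline_decile", "end_decile", "category"])
        for tid in sorted(labels):
            lab = labels[tid]
            writer.writerow(
                [
                    tid,
                    "" if lab.baseline_decile is None else lab.baseline_decile,
                    "" if lab.end_decile is None else lab.end_decile,
                    lab.category.value,
                ]
            )


#: Canonical category order for tables (declining, stable, gentrifying).
CATEGORY_ORDER = [
    LandisCategory.DECLINING.value,
    LandisCategory.STABLE.value,
    LandisCategory.GENTRIFYING.value,
    LandisCategory.UNCLASSIFIED_MISSING.value,
]
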