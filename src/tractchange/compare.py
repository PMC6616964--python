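"""Comparison machinery: category shares, cross-tabulations, summaries.

Classifier outputs are compared descriptively — category shares of the
regional tract count, pairwise cross-tabulations with column
percentages, per-category demographic summaries and focused overlap
percentages.  No inferential statistics are attached: these are
bookkeeping operations over complete enumerations of a region's tracts,
not samples.  Printed percentages are rounded half-up to one decimal in
one shared routine; the raw values are always retained, since sums of
independently rounded shares can drift from the share of the summed
counts by a few tenths of a point.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._format import percent, percent_1dp, round_half_up_1dp
from .errors import ConfigError, MissingDataError
from .panel import RegionPanel

logger = logging.getLogger(__name__)

#: Percent-scale variables summarized per category.
SUMMARY_PCT_VARS = (
    "pct_low_income_hh",
    "pct_nonwhite",
    "pct_bachelor_25plus",
    "pct_renter_hh",
)


@dataclass
class LabelSet:
    """One classifier's per-tract categorical output."""

    method_name: str
    labels: dict[str, str]
    category_order: list[str]

    def __post_init__(self) -> None:
        unknown = sorted(set(self.labels.values()) - set(self.category_order))
        if unknown:
            raise ConfigError(
                f"{self.method_name}: categories {unknown} not in category_order"
            )

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in self.category_order}
        for cat in self.labels.values():
            out[cat] += 1
        return out

    def ids_in(self, category: str) -> set[str]:
        return {t for t, c in self.labels.items() if c == category}

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(
            {"tract_id": sorted(self.labels), "category": [self.labels[t] for t in sorted(self.labels)]}
        )
        df.to_csv(path, index=False, lineterminator="\n")
        return path

    @classmethod
    def from_csv(
        cls, path: str | Path, method_name: str | None = None, category_order: list[str] | None = None
    ) -> "LabelSet":
        path = Path(path)
        df = pd.read_csv(path, dtype=str)
        cat_col = "category" if "category" in df.columns else "typology"
        if not {"tract_id", cat_col} <= set(df.columns):
            raise ConfigError(f"{path.name}: need columns tract_id and category (or typology)")
        labels = dict(zip(df["tract_id"], df[cat_col]))
        order = category_order or sorted(set(labels.values()))
        return cls(method_name or path.stem, labels, order)


class ShareReport(NamedTuple):
    """Category shares of a denominator, with the unlabeled remainder."""

    shares: dict[str, float]  # rounded, 1 decimal
    shares_raw: dict[str, float]
    counts: dict[str, int]
    denominator: int
    unlabeled: int
    unlabeled_pct: float


def category_shares(labels: LabelSet, denominator: int) -> ShareReport:
    """Share of the denominator in each category, half-up to 1 decimal.

    The denominator is typically the regional tract count; tracts it
    covers but the label set does not are reported as ``unlabeled``,
    never silently dropped.
    """
    counts = labels.counts()
    n_labeled = sum(counts.values())
    if denominator < n_labeled:
        raise ConfigError(
            f"denominator {denominator} smaller than labeled tract count {n_labeled}"
        )
    raw = {c: percent(k, denominator) for c, k in counts.items()}
    unlabeled = denominator - n_labeled
    return ShareReport(
        shares={c: round_half_up_1dp(v) for c, v in raw.items()},
        shares_raw=raw,
        counts=counts,
        denominator=denominator,
        unlabeled=unlabeled,
        unlabeled_pct=percent_1dp(unlabeled, denominator),
    )


@dataclass
class CrossTab:
    """Contingency counts and column percentages between two label sets.

    ``counts`` is rows x cols over the tract-id intersection;
    ``col_pct[i, j] = 100 * counts[i, j] / colsum[j]`` (half-up, one
    decimal; raw values in ``col_pct_raw``).  Tracts present in only one
    label set are counted in ``n_only_rows`` / ``n_only_cols`` so the
    accounting is exact.
    """

    row_method: str
    col_method: str
    counts: pd.DataFrame
    col_pct: pd.DataFrame
    col_pct_raw: pd.DataFrame
    n_common: int
    n_only_rows: int
    n_only_cols: int

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# counts: rows={self.row_method} cols={self.col_method}\n")
            self.counts.to_csv(fh, lineterminator="\n")
            fh.write("# column percentages\n")
            self.col_pct.to_csv(fh, lineterminator="\n")
        return path

    def to_json(self) -> str:
        return json.dumps(
            {
                "row_method": self.row_method,
                "col_method": self.col_method,
                "row_categories": list(self.counts.index),
                "col_categories": list(self.counts.columns),
                "counts": self.counts.values.tolist(),
                "col_pct": self.col_pct.values.tolist(),
                "n_common": self.n_common,
                "n_only_rows": self.n_only_rows,
                "n_only_cols": self.n_only_cols,
            },
            indent=2,
            sort_keys=True,
        )

    def to_text(self) -> str:
        body = self.col_pct.copy()
        body.index.name = self.row_method
        body.columns = [
            f"{c} (N={int(self.counts[c].sum())})" for c in self.counts.columns
        ]
        return f"Column % of {self.col_method} categories\n{body.to_string()}"


def crosstab(rows: LabelSet, cols: LabelSet) -> CrossTab:
    """Cross-tabulate two label sets over their tract-id intersection."""
    common = rows.labels.keys() & cols.labels.keys()
    if not common:
        raise ConfigError(
            f"no tracts shared between {rows.method_name} and {cols.method_name}"
        )
    ordered = sorted(common)
    r = pd.Categorical([rows.labels[t] for t in ordered], categories=rows.category_order)
    c = pd.Categorical([cols.labels[t] for t in ordered], categories=cols.category_order)
    counts = pd.crosstab(r, c, dropna=False)
    counts = counts.reindex(index=rows.category_order, columns=cols.category_order, fill_value=0)
    counts.index.name = rows.method_name
    counts.columns.name = cols.method_name
    colsum = counts.sum(axis=0)
    raw = 100.0 * counts / colsum.replace(0, np.nan)
    raw = raw.fillna(0.0)
    rounded = raw.map(round_half_up_1dp)
    n_only_rows = len(rows.labels.keys() - common)
    n_only_cols = len(cols.labels.keys() - common)
    if n_only_rows or n_only_cols:
        logger.info(
            "crosstab %s x %s: %d tracts only in rows, %d only in cols",
            rows.method_name, cols.method_name, n_only_rows, n_only_cols,
        )
    return CrossTab(
        row_method=rows.method_name,
        col_method=cols.method_name,
        counts=counts,
        col_pct=rounded,
        col_pct_raw=raw,
        n_common=len(common),
        n_only_rows=n_only_rows,
        n_only_cols=n_only_cols,
    )


def summarize_by_category(
    panel: RegionPanel,
    labels: LabelSet,
    window: tuple[int, int],
    *,
    income_stat: str = "median",
    pct_change_mode: str = "relative",
) -> pd.DataFrame:
    """Per-category demographic summary table.

    Per category, at the window end year: tract count, total population
    and its share of the regional population, the median across tracts
    of tract median household income, and unweighted means of the
    percent variables.  Change columns (``chg_``) give the relative
    percent change of the category-level aggregate over the window
    (``pct_change_mode="pp"`` switches percent variables to
    percentage-point differences).
    """
    start, end = window
    panel.require_years([start, end], "summarize_by_category")
    if income_stat not in ("median", "mean"):
        raise ConfigError(f"unknown income_stat {income_stat!r}")
    if pct_change_mode not in ("relative", "pp"):
        raise ConfigError(f"unknown pct_change_mode {pct_change_mode!r}")
    agg = np.median if income_stat == "median" else np.mean

    total_pop = panel.total_population(end)
    rows = []
    for cat in labels.category_order:
        ids = labels.ids_in(cat)
        tracts = [t for t in panel.tracts if t.tract_id in ids]
        row: dict[str, object] = {"category": cat, "n_tracts": len(tracts)}
        if not tracts:
            rows.append(row)
            continue
        pops = [t.value(end, "population") for t in tracts]
        pop_total = int(sum(p for p in pops if p is not None))
        row["population_total"] = pop_total
        row["pct_of_total_population"] = (
            percent_1dp(pop_total, total_pop) if total_pop else None
        )

        def cat_values(year: int, var: str) -> list[float]:
            return [v for v in (t.value(year, var) for t in tracts) if v is not None]

        inc_end = cat_values(end, "median_hh_income")
        inc_start = cat_values(start, "median_hh_income")
        if inc_end:
            row["median_hh_income"] = float(agg(inc_end))
        if inc_end and inc_start and agg(inc_start) != 0:
            row["chg_median_hh_income"] = round_half_up_1dp(
                100.0 * (float(agg(inc_end)) - float(agg(inc_start))) / float(agg(inc_start))
            )
        for var in SUMMARY_PCT_VARS:
            v_end = cat_values(end, var)
            v_start = cat_values(start, var)
            if v_end:
                row[var] = float(np.mean(v_end))
            if v_end and v_start:
                m0, m1 = float(np.mean(v_start)), float(np.mean(v_end))
                if pct_change_mode == "pp":
                    row[f"chg_{var}"] = round_half_up_1dp(m1 - m0)
                elif m0 != 0:
                    row[f"chg_{var}"] = round_half_up_1dp(100.0 * (m1 - m0) / m0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")


def overlap_report(a: LabelSet, b: LabelSet, focus: tuple[str, str]) -> float:
    """Percent of a's focus-category tracts also in b's focus category."""
    cat_a, cat_b = focus
    if cat_a not in a.category_order:
        raise ConfigError(f"{cat_a!r} not a category of {a.method_name}")
    if cat_b not in b.category_order:
        raise ConfigError(f"{cat_b!r} not a category of {b.method_name}")
    set_a = a.ids_in(cat_a)
    if not set_a:
        raise MissingDataError(f"{a.method_name}: no tracts in focus category {cat_a!r}")
    return percent_1dp(len(set_a & b.ids_in(cat_b)), len(set_a))
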