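"""Comparison machinery: shares, crosstabs, summaries, overlap."""

import numpy as np
import pytest

from tractchange.compare import (
    LabelSet,
    category_shares,
    crosstab,
    overlap_report,
    summarize_by_category,
)
from tractchange.errors import ConfigError, MissingDataError
from tractchange.panel import RegionPanel, TractObservation, TractSeries


def labelset(name, assignments, order=None):
    order = order or sorted(set(assignments.values()))
    return LabelSet(name, assignments, order)


def synthetic_labels(name, counts, order):
    """A label set with the requested per-category counts."""
    labels = {}
    i = 0
    for cat, n in counts.items():
        for _ in range(n):
            labels[f"T{i:05d}"] = cat
            i += 1
    return LabelSet(name, labels, order)


class TestCategoryShares:
    def test_bay_area_scale_three_way_split(self):
        # 97 / 92 / 1391 of 1580 tracts -> 6.1% / 5.8% / 88.0%
        ls = synthetic_labels(
            "freeman",
            {"GENTRIFYING": 97, "NOT_GENTRIFYING": 92, "EXCLUDED": 1391},
            ["GENTRIFYING", "NOT_GENTRIFYING", "EXCLUDED"],
        )
        report = category_shares(ls, 1580)
        assert report.shares == {"GENTRIFYING": 6.1, "NOT_GENTRIFYING": 5.8, "EXCLUDED": 88.0}
        assert report.unlabeled == 0

    def test_single_low_income_category_share(self):
        # 329 of 1580 -> 20.8%
        ls = synthetic_labels("udp", {"LI_EARLY": 329}, ["LI_EARLY"])
        report = category_shares(ls, 1580)
        assert report.shares["LI_EARLY"] == 20.8
        assert report.unlabeled == 1580 - 329

    def test_identity_share(self):
        ls = synthetic_labels("m", {"A": 7}, ["A"])
        assert category_shares(ls, 7).shares == {"A": 100.0}

    def test_denominator_smaller_than_labeled_is_error(self):
        ls = synthetic_labels("m", {"A": 7}, ["A"])
        with pytest.raises(ConfigError):
            category_shares(ls, 6)

    def test_partition_shares_sum_near_100(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = {f"C{i}": int(v) for i, v in enumerate(rng.integers(1, 400, size=5))}
            ls = synthetic_labels("m", counts, sorted(counts))
            total = sum(counts.values())
            s = sum(category_shares(ls, total).shares.values())
            assert abs(s - 100.0) <= 0.1 * len(counts)

    def test_raw_values_are_retained_unrounded(self):
        ls = synthetic_labels("m", {"A": 1, "B": 2}, ["A", "B"])
        report = category_shares(ls, 3)
        assert report.shares_raw["A"] == pytest.approx(100.0 / 3.0)


class TestCrossTab:
    def test_self_comparison_is_diagonal(self):
        ls = labelset("m", {"T1": "A", "T2": "B", "T3": "A"}, ["A", "B"])
        ct = crosstab(ls, ls)
        assert ct.counts.values.tolist() == [[2, 0], [0, 1]]
        assert ct.col_pct.values.tolist() == [[100.0, 0.0], [0.0, 100.0]]

    def test_hand_enumerated_2x2(self):
        # 6 tracts: A/A, A/B, A/B, B/B, B/B, B/B
        rows = labelset("r", {"T1": "A", "T2": "A", "T3": "A", "T4": "B", "T5": "B", "T6": "B"}, ["A", "B"])
        cols = labelset("c", {"T1": "A", "T2": "B", "T3": "B", "T4": "B", "T5": "B", "T6": "B"}, ["A", "B"])
        ct = crosstab(rows, cols)
        assert ct.counts.values.tolist() == [[1, 2], [0, 3]]
        assert ct.col_pct.values.tolist() == [[100.0, 40.0], [0.0, 60.0]]

    def test_margin_conservation_on_seeded_labels(self):
        rng = np.random.default_rng(4)
        ids = [f"T{i}" for i in range(500)]
        a = labelset("a", {t: str(rng.integers(0, 4)) for t in ids}, ["0", "1", "2", "3"])
        b = labelset("b", {t: str(rng.integers(0, 3)) for t in ids}, ["0", "1", "2"])
        ct = crosstab(a, b)
        assert ct.counts.values.sum() == 500
        for cat, n in b.counts().items():
            assert ct.counts[cat].sum() == n
        for cat, n in a.counts().items():
            assert ct.counts.loc[cat].sum() == n
        # column percentages sum to 100 within rounding
        for cat in b.category_order:
            if ct.counts[cat].sum() > 0:
                assert ct.col_pct_raw[cat].sum() == pytest.approx(100.0)

    def test_partial_overlap_counted_not_dropped(self):
        a = labelset("a", {"T1": "A", "T2": "A", "T9": "A"}, ["A"])
        b = labelset("b", {"T1": "B", "T2": "B", "T8": "B"}, ["B"])
        ct = crosstab(a, b)
        assert (ct.n_common, ct.n_only_rows, ct.n_only_cols) == (2, 1, 1)

    def test_empty_intersection_is_error(self):
        a = labelset("a", {"T1": "A"}, ["A"])
        b = labelset("b", {"T2": "B"}, ["B"])
        with pytest.raises(ConfigError):
            crosstab(a, b)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        ids = [f"T{i}" for i in range(100)]
        amap = {t: str(rng.integers(0, 3)) for t in ids}
        bmap = {t: str(rng.integers(0, 3)) for t in ids}
        a1 = labelset("a", amap, ["0", "1", "2"])
        b1 = labelset("b", bmap, ["0", "1", "2"])
        perm = dict(reversed(list(amap.items())))
        a2 = labelset("a", perm, ["0", "1", "2"])
        ct1, ct2 = crosstab(a1, b1), crosstab(a2, b1)
        assert ct1.counts.equals(ct2.counts)


def summary_panel():
    """Three one-tract categories with region-scale populations."""
    pops = {"NOT_GENTRIFYING": 384152, "GENTRIFYING": 363446, "EXCLUDED": 6509903}
    tracts = []
    for i, (cat, pop) in enumerate(pops.items()):
        obs = {
            year: TractObservation(
                year=year, population=pop,
                median_hh_income=50000.0 + 1000.0 * i * (1 + (year == 2013)),
                pct_bachelor_25plus=20.0 + i + (5.0 if year == 2013 else 0.0),
                pct_low_income_hh=50.0, pct_nonwhite=60.0, pct_renter_hh=55.0,
            )
            for year in (2000, 2013)
        }
        tracts.append(TractSeries(f"T{i}", obs))
    labels = labelset(
        "freeman", {f"T{i}": cat for i, cat in enumerate(pops)}, list(pops)
    )
    return RegionPanel("r", tracts), labels


class TestSummaries:
    def test_population_shares_at_region_scale(self):
        # populations 384,152 / 363,446 / 6,509,903 of 7,257,501 -> 5.3 / 5.0 / 89.7
        panel, labels = summary_panel()
        table = summarize_by_category(panel, labels, (2000, 2013))
        assert table.loc["NOT_GENTRIFYING", "pct_of_total_population"] == 5.3
        assert table.loc["GENTRIFYING", "pct_of_total_population"] == 5.0
        assert table.loc["EXCLUDED", "pct_of_total_population"] == 89.7

    def test_singleton_category_levels_equal_tract_values(self):
        panel, labels = summary_panel()
        table = summarize_by_category(panel, labels, (2000, 2013))
        t1 = panel.tract("T1")
        assert table.loc["GENTRIFYING", "median_hh_income"] == t1.value(2013, "median_hh_income")
        assert table.loc["GENTRIFYING", "pct_bachelor_25plus"] == t1.value(2013, "pct_bachelor_25plus")

    def test_empty_category_row_has_zero_tracts(self):
        panel, _ = summary_panel()
        labels = labelset("m", {"T0": "A"}, ["A", "B"])
        table = summarize_by_category(panel, labels, (2000, 2013))
        assert table.loc["B", "n_tracts"] == 0

    def test_matches_brute_force_groupby(self, demo_panel):
        from tractchange.freeman import CATEGORY_ORDER, freeman_run

        labels_map = {t: l.category.value for t, l in freeman_run(demo_panel).items()}
        labels = LabelSet("freeman", labels_map, CATEGORY_ORDER)
        table = summarize_by_category(demo_panel, labels, (2000, 2013))
        for cat in CATEGORY_ORDER:
            ids = [t for t, c in labels_map.items() if c == cat]
            tracts = [demo_panel.tract(t) for t in ids]
            assert table.loc[cat, "n_tracts"] == len(ids)
            if not ids:
                continue
            incomes = sorted(t.value(2013, "median_hh_income") for t in tracts)
            n = len(incomes)
            med = (incomes[n // 2 - 1] + incomes[n // 2]) / 2 if n % 2 == 0 else incomes[n // 2]
            assert table.loc[cat, "median_hh_income"] == pytest.approx(med)
            renters = [t.value(2013, "pct_renter_hh") for t in tracts]
            assert table.loc[cat, "pct_renter_hh"] == pytest.approx(sum(renters) / len(renters))
            assert table.loc[cat, "population_total"] == sum(
                t.value(2013, "population") for t in tracts
            )


class TestOverlap:
    def test_disjoint_and_identical(self):
        a = labelset("a", {"T1": "G", "T2": "G"}, ["G"])
        b_disjoint = labelset("b", {"T1": "X", "T2": "X", "T3": "G"}, ["G", "X"])
        b_same = labelset("b", {"T1": "G", "T2": "G"}, ["G"])
        assert overlap_report(a, b_disjoint, ("G", "G")) == 0.0
        assert overlap_report(a, b_same, ("G", "G")) == 100.0

    def test_thirteen_of_ninetyseven(self):
        # 13 of a 97-tract focus set -> 13.4%
        a_ids = {f"T{i}": "G" for i in range(97)}
        b_ids = {f"T{i}": ("G" if i < 13 else "S") for i in range(97)}
        a = labelset("freeman", a_ids, ["G"])
        b = labelset("landis", b_ids, ["G", "S"])
        assert overlap_report(a, b, ("G", "G")) == 13.4

    def test_empty_focus_category_is_error(self):
        a = labelset("a", {"T1": "S"}, ["S", "G"])
        b = labelset("b", {"T1": "G"}, ["G"])
        with pytest.raises(MissingDataError):
            overlap_report(a, b, ("G", "G"))
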