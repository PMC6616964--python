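"""Income-stratified displacement typologies (UDP/REWS style).

The Urban Displacement Project's Regional Early Warning System (REWS)
assigns Bay-Area tracts to eight income-stratified stages of
gentrification and displacement, plus a college-town designation.  The
true REWS estimation draws on proprietary home-sales, business and
transit data and cannot be re-run from a public tract panel, so this
module offers two explicit, never-conflated paths:

* :func:`read_rews_table` — verbatim ingest of an official typology
  table re-expressed as CSV (provenance ``"rews_ingest"``);
* :func:`udp_run` — a documented, simplified three-signal rule tree
  computed from the tract panel itself (provenance
  ``"simplified_rule_tree"``).  It is a stand-in for self-contained
  analysis, not a REWS replication.

The simplified tree stratifies tracts by low-income-household share
(strictly above 39% = low income), then inspects three boolean signals
over a window: is the tract losing low-income households, is its home
price appreciating at or above the regional median ("hot market"), and
is its college-educated share growing at or above the regional median
("demographic shift").  Stage assignment:

    losing_li and demo_shift      -> ADVANCED (LI) / ADV_EXCLUSION (MHI)
    losing_li and not demo_shift  -> UNDERGOING
    not losing_li and market_hot  -> AT_RISK
    otherwise                     -> EARLY
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ConfigError, MissingDataError, PanelValidationError
from .panel import RegionPanel, TractSeries

logger = logging.getLogger(__name__)


class Stratum(str, Enum):
    LOW_INCOME = "LOW_INCOME"
    MID_HIGH_INCOME = "MID_HIGH_INCOME"
    NONE = "none"


class UdpTypology(str, Enum):
    LI_EARLY = "LI_EARLY"
    LI_AT_RISK = "LI_AT_RISK"
    LI_UNDERGOING = "LI_UNDERGOING"
    LI_ADVANCED = "LI_ADVANCED"
    MHI_EARLY = "MHI_EARLY"
    MHI_AT_RISK = "MHI_AT_RISK"
    MHI_UNDERGOING = "MHI_UNDERGOING"
    MHI_ADV_EXCLUSION = "MHI_ADV_EXCLUSION"
    COLLEGE_TOWN = "COLLEGE_TOWN"
    UNCLASSIFIED_MISSING = "UNCLASSIFIED_MISSING"


#: The nine assignable typology codes accepted in REWS-style tables.
REWS_CODES = frozenset(t.value for t in UdpTypology if t is not UdpTypology.UNCLASSIFIED_MISSING)

_STRATUM_OF = {
    UdpTypology.LI_EARLY: Stratum.LOW_INCOME,
    UdpTypology.LI_AT_RISK: Stratum.LOW_INCOME,
    UdpTypology.LI_UNDERGOING: Stratum.LOW_INCOME,
    UdpTypology.LI_ADVANCED: Stratum.LOW_INCOME,
    UdpTypology.MHI_EARLY: Stratum.MID_HIGH_INCOME,
    UdpTypology.MHI_AT_RISK: Stratum.MID_HIGH_INCOME,
    UdpTypology.MHI_UNDERGOING: Stratum.MID_HIGH_INCOME,
    UdpTypology.MHI_ADV_EXCLUSION: Stratum.MID_HIGH_INCOME,
    UdpTypology.COLLEGE_TOWN: Stratum.NONE,
    UdpTypology.UNCLASSIFIED_MISSING: Stratum.NONE,
}


@dataclass(frozen=True)
class Signals:
    losing_li: bool
    market_hot: bool
    demo_shift: bool


@dataclass(frozen=True)
class UdpLabel:
    typology: UdpTypology
    stratum: Stratum
    signals: Signals | None = None
    provenance: str = "simplified_rule_tree"

    def __post_init__(self) -> None:
        if _STRATUM_OF[self.typology] is not self.stratum:
            raise ValueError(
                f"stratum {self.stratum.value!r} inconsistent with typology {self.typology.value!r}"
            )


@dataclass(frozen=True)
class UdpConfig:
    """Thresholds and references of the simplified rule tree.

    ``li_threshold``: a tract is low income iff its low-income-household
    share is strictly above this percent (default 39; exactly 39% falls
    to mid/high income because the low-income definition is strict).
    ``loss_threshold``: percentage points of low-income-share decline
    beyond which the tract counts as losing low-income households
    (default 0, strict).  The stratum is evaluated at the window end.
    """

    li_threshold: float = 39.0
    loss_threshold: float = 0.0
    window: tuple[int, int] = (2000, 2013)
    stratum_year: str = "end"  # "end" or "start"

    def __post_init__(self) -> None:
        if not (0.0 < self.li_threshold < 100.0):
            raise ConfigError(f"li_threshold must lie in (0, 100), got {self.li_threshold}")
        if self.window[0] >= self.window[1]:
            raise ConfigError(f"window must increase, got {self.window}")
        if self.stratum_year not in ("end", "start"):
            raise ConfigError(f"stratum_year must be 'end' or 'start', got {self.stratum_year!r}")


def udp_stratum(pct_low_income_hh: float | None, config: UdpConfig = UdpConfig()) -> Stratum:
    """LOW_INCOME iff the low-income-household share strictly exceeds
    the threshold; missing values propagate as ``Stratum.NONE``."""
    if pct_low_income_hh is None:
        return Stratum.NONE
    if not (0.0 <= pct_low_income_hh <= 100.0):
        raise PanelValidationError(f"pct_low_income_hh {pct_low_income_hh} outside [0, 100]")
    return Stratum.LOW_INCOME if pct_low_income_hh > config.li_threshold else Stratum.MID_HIGH_INCOME


def panel_references(panel: RegionPanel, config: UdpConfig = UdpConfig()) -> tuple[float, float]:
    """Regional reference values: (median home-price appreciation,
    median percentage-point growth in college-educated share)."""
    start, end = config.window
    p0 = panel.values(start, "median_home_price")
    p1 = panel.values(end, "median_home_price")
    apprec = [p1[t] / p0[t] - 1.0 for t in p0.keys() & p1.keys() if p0[t] > 0]
    e0 = panel.values(start, "pct_bachelor_25plus")
    e1 = panel.values(end, "pct_bachelor_25plus")
    growth = [e1[t] - e0[t] for t in e0.keys() & e1.keys()]
    if not apprec or not growth:
        raise MissingDataError("panel_references: no tract with both window endpoints observed")
    return float(np.median(apprec)), float(np.median(growth))


def udp_signals(
    tract: TractSeries,
    panel_refs: tuple[float, float],
    config: UdpConfig = UdpConfig(),
) -> Signals:
    """The three booleans of the simplified tree for one tract.

    Raises :class:`MissingDataError` if a required variable is absent at
    either window endpoint; callers map that to UNCLASSIFIED_MISSING.
    """
    market_ref, demo_ref = panel_refs
    start, end = config.window
    li0 = tract.value(start, "pct_low_income_hh")
    li1 = tract.value(end, "pct_low_income_hh")
    p0 = tract.value(start, "median_home_price")
    p1 = tract.value(end, "median_home_price")
    e0 = tract.value(start, "pct_bachelor_25plus")
    e1 = tract.value(end, "pct_bachelor_25plus")
    if None in (li0, li1, p0, p1, e0, e1) or p0 == 0:
        raise MissingDataError(f"tract {tract.tract_id}: window variables incomplete")
    return Signals(
        losing_li=(li0 - li1) > config.loss_threshold,
        market_hot=(p1 / p0 - 1.0) >= market_ref,
        demo_shift=(e1 - e0) >= demo_ref,
    )


def udp_classify(
    stratum: Stratum, signals: Signals, college_town: bool = False
) -> UdpLabel:
    """Pure rule tree mapping (stratum, signals, flag) to a typology."""
    if college_town:
        return UdpLabel(UdpTypology.COLLEGE_TOWN, Stratum.NONE, signals)
    if stratum is Stratum.NONE:
        raise ValueError("udp_classify needs a resolved income stratum")
    if signals.losing_li and signals.demo_shift:
        stage = "ADVANCED"
    elif signals.losing_li:
        stage = "UNDERGOING"
    elif signals.market_hot:
        stage = "AT_RISK"
    else:
        stage = "EARLY"
    if stratum is Stratum.LOW_INCOME:
        typ = UdpTypology[f"LI_{stage}"]
    else:
        typ = UdpTypology["MHI_ADV_EXCLUSION" if stage == "ADVANCED" else f"MHI_{stage}"]
    return UdpLabel(typ, stratum, signals)


def udp_run(panel: RegionPanel, config: UdpConfig = UdpConfig()) -> dict[str, UdpLabel]:
    """Run the simplified rule tree over a whole panel."""
    start, end = config.window
    panel.require_years([start, end], "udp_run")
    refs = panel_references(panel, config)
    stratum_year = end if config.stratum_year == "end" else start
    labels: dict[str, UdpLabel] = {}
    n_missing = 0
    for t in panel.tracts:
        obs = t.get(stratum_year)
        college = bool(obs.college_town) if obs else False
        try:
            signals = udp_signals(t, refs, config)
            stratum = udp_stratum(t.value(stratum_year, "pct_low_income_hh"), config)
            if stratum is Stratum.NONE and not college:
                raise MissingDataError(f"tract {t.tract_id}: low-income share missing")
            labels[t.tract_id] = udp_classify(stratum, signals, college)
        except MissingDataError:
            if college:
                labels[t.tract_id] = UdpLabel(UdpTypology.COLLEGE_TOWN, Stratum.NONE)
            else:
                labels[t.tract_id] = UdpLabel(UdpTypology.UNCLASSIFIED_MISSING, Stratum.NONE)
                n_missing += 1
    if n_missing:
        logger.warning("udp_run: %d tracts unclassified for missing data", n_missing)
    return labels


# ---------------------------------------------------------------------------
# REWS-style table ingest (official typologies, taken verbatim)
# ---------------------------------------------------------------------------


def read_rews_table(path: str | Path) -> dict[str, UdpLabel]:
    """Read an official typology table (CSV: tract_id, typology).

    Labels are taken verbatim (provenance ``"rews_ingest"``); signals
    are left unset.  Unrecognized typology codes are rejected with the
    offending rows listed.
    """
    path = Path(path)
    labels: dict[str, UdpLabel] = {}
    bad: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"tract_id", "typology"} <= set(reader.fieldnames):
            raise PanelValidationError(f"{path.name}: need columns tract_id, typology")
        for i, rec in enumerate(reader, start=2):
            tid = (rec["tract_id"] or "").strip()
            code = (rec["typology"] or "").strip()
            if code not in REWS_CODES:
                bad.append(f"row {i}: {code!r}")
                continue
            typ = UdpTypology(code)
            labels[tid] = UdpLabel(typ, _STRATUM_OF[typ], provenance="rews_ingest")
    if bad:
        raise PanelValidationError(
            f"{path.name}: unknown typology code(s): " + "; ".join(bad)
        )
    return labels


def write_rews_table(labels: Mapping[str, UdpLabel], path: str | Path) -> Path:
    """Write labels as a REWS-style CSV (deterministic order)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["tract_id", "typology", "source"])
        for tid in sorted(labels):
            lab = labels[tid]
            writer.writerow([tid, lab.typology.value, lab.provenance])
    return path


def write_labels_csv(labels: Mapping[str, UdpLabel], path: str | Path) -> Path:
    """Output CSV: tract_id, typology, stratum, the three signals, provenance."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["tract_id", "typology", "stratum", "losing_li", "market_hot", "demo_shift", "provenance"]
        )
        for tid in sorted(labels):
            lab = labels[tid]
            sig = lab.signals
            writer.writerow(
                [
                    tid,
                    lab.typology.value,
                    lab.stratum.value,
                    "" if sig is None else str(sig.losing_li).lower(),
                    "" if sig is None else str(sig.market_hot).lower(),
                    "" if sig is None else str(sig.demo_shift).lower(),
                    lab.provenance,
                ]
            )
    return path


#: Canonical typology order for tables (low-income block, then mid/high, then special).
CATEGORY_ORDER = [t.value for t in UdpTypology]
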