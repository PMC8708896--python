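"""Seasonal descriptive statistics for element concentrations.

Handles left-censored (below-detection-limit) measurements, ranks elements by
seasonal mean, screens means against ambient air quality standards, and tests
the wet-vs-dry seasonal contrast with a rank-sum test.

The canonical in-memory container is a long-format :class:`pandas.DataFrame`
with columns ``site, season, day, element, value, censored`` — one row per
measurement, ``value`` in µg/m³; for censored rows ``value`` holds the
detection limit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import load_defaults
from .errors import ConfigError, DomainError, NotTestable
from .risk_model import ELEMENTS

log = logging.getLogger(__name__)

SEASONS = ("wet", "dry")
POLLUTANTS = ELEMENTS + ("TSP",)

RECORD_COLUMNS = ["site", "season", "day", "element", "value", "censored"]

BdlStrategy = Literal["zero", "half_limit", "exclude"]


@dataclass(frozen=True)
class ConcentrationRecord:
    """One measurement at a site/season/day; ``value`` is the detection limit when censored."""

    site: int
    season: str
    day: int
    element: str
    value: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise DomainError(f"season must be one of {SEASONS}, got {self.season!r}")
        if self.element not in POLLUTANTS:
            raise DomainError(
                f"unknown element {self.element!r}; expected one of {POLLUTANTS}"
            )
        if not self.value >= 0:
            raise DomainError(f"value must be non-negative, got {self.value}")


def records_to_frame(records) -> pd.DataFrame:
    """Build the canonical long-format frame from ConcentrationRecord objects."""
    return pd.DataFrame([vars(r) for r in records], columns=RECORD_COLUMNS)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = set(RECORD_COLUMNS) - set(records.columns)
        if missing:
            raise DomainError(f"records frame missing columns: {sorted(missing)}")
        return records
    return records_to_frame(records)


def substitute_bdl(records, strategy: BdlStrategy = "exclude") -> pd.DataFrame:
    """Apply a below-detection-limit substitution strategy.

    ``zero``: censored values become 0; ``half_limit``: half the detection
    limit (the stored value); ``exclude``: censored rows are dropped.  The
    number of affected rows is logged.  Uncensored rows are never touched.
    """
    df = _as_frame(records).copy()
    n_censored = int(df["censored"].sum())
    if strategy == "exclude":
        out = df.loc[~df["censored"]].reset_index(drop=True)
    elif strategy == "zero":
        out = df
        out.loc[out["censored"], "value"] = 0.0
        out["censored"] = False
    elif strategy == "half_limit":
        bad = df["censored"] & (df["value"].isna() | (df["value"] <= 0))
        if bad.any():
            raise DomainError(
                "half_limit substitution requires a positive detection limit; "
                f"missing for rows {list(df.index[bad])}"
            )
        out = df
        out.loc[out["censored"], "value"] = out.loc[out["censored"], "value"] / 2.0
        out["censored"] = False
    else:
        raise ConfigError(f"unknown BDL strategy {strategy!r}")
    log.info("substitute_bdl(%s): %d censored record(s) affected", strategy, n_censored)
    return out


def seasonal_summary(records, bdl_strategy: BdlStrategy = "exclude") -> pd.DataFrame:
    """Mean/min/max/std (sample, n−1) per element × season.

    Groups whose records are entirely censored are kept with NaN statistics
    and ``bdl=True`` — they print as "BDL" rather than vanishing.  A group
    with a single value reports std 0 (flagged through ``n``).
    """
    df = _as_frame(records)
    if df.empty:
        raise DomainError("seasonal_summary requires at least one record")
    censored_counts = (
        df.groupby(["element", "season"], sort=False)["censored"].sum().astype(int)
    )
    usable = substitute_bdl(df, bdl_strategy)

    rows = []
    for (element, season), n_cens in censored_counts.items():
        group = usable.loc[(usable["element"] == element) & (usable["season"] == season), "value"]
        n = len(group)
        if n == 0:
            rows.append(
                dict(element=element, season=season, mean=np.nan, min=np.nan,
                     max=np.nan, std=np.nan, n=0, n_censored=n_cens, bdl=True)
            )
            continue
        values = group.to_numpy(dtype=float)
        rows.append(
            dict(
                element=element,
                season=season,
                mean=float(values.mean()),
                min=float(values.min()),
                max=float(values.max()),
                std=float(values.std(ddof=1)) if n > 1 else 0.0,
                n=n,
                n_censored=n_cens,
                bdl=False,
            )
        )
    return pd.DataFrame(rows).set_index(["element", "season"]).sort_index()


def rank_elements(summary: pd.DataFrame | Mapping[str, float | None], season: str | None = None):
    """Elements in strictly descending order of seasonal mean.

    Accepts either the frame from :func:`seasonal_summary` (with ``season``)
    or a plain ``{element: mean}`` mapping (``None`` meaning BDL).  BDL-only
    elements are placed last and flagged; exact ties break alphabetically
    with a warning.  TSP is not an element and is ignored.

    Returns a list of ``(element, bdl_flag)`` pairs.
    """
    if isinstance(summary, pd.DataFrame):
        if season is None:
            raise ConfigError("season is required when ranking from a summary frame")
        sub = summary.xs(season, level="season")
        means = {el: (None if bool(row["bdl"]) else float(row["mean"]))
                 for el, row in sub.iterrows() if el in ELEMENTS}
    else:
        means = {el: v for el, v in summary.items() if el in ELEMENTS}

    detected = {el: m for el, m in means.items() if m is not None}
    bdl_only = sorted(el for el, m in means.items() if m is None)

    values = list(detected.values())
    if len(set(values)) < len(values):
        warnings.warn("tied seasonal means; breaking ties alphabetically", stacklevel=2)
    ordered = sorted(detected, key=lambda el: (-detected[el], el))
    return [(el, False) for el in ordered] + [(el, True) for el in bdl_only]


NG_PER_UG = 1000.0


def ng_to_ug(x):
    """Exact ng/m³ → µg/m³."""
    return x / NG_PER_UG


def ug_to_ng(x):
    """Exact µg/m³ → ng/m³."""
    return x * NG_PER_UG


def default_standards() -> pd.DataFrame:
    """Packaged ambient air quality limits (µg/m³) as a tidy frame."""
    return pd.DataFrame(load_defaults()["standards"])


def compare_to_standards(
    means: Mapping[str, float | None] | pd.DataFrame,
    standards: pd.DataFrame | None = None,
    season: str | None = None,
) -> pd.DataFrame:
    """Screen seasonal means against every applicable standard.

    One output row per pollutant × authority × period with the measured
    value, the limit, their ratio, and a strict-``>`` exceedance flag.
    Pollutants with no standard get an explicit ``no standard`` row; BDL
    means are screened as not exceeding (flagged).
    """
    if isinstance(means, pd.DataFrame):
        if season is None:
            raise ConfigError("season is required when screening from a summary frame")
        sub = means.xs(season, level="season")
        means = {el: (None if bool(row["bdl"]) else float(row["mean"]))
                 for el, row in sub.iterrows()}
    standards = standards if standards is not None else default_standards()

    rows = []
    for pollutant, measured in means.items():
        applicable = standards.loc[standards["pollutant"] == pollutant]
        if applicable.empty:
            rows.append(dict(pollutant=pollutant, authority="(none)", period="(none)",
                             measured=measured, limit=np.nan, ratio=np.nan,
                             exceeds=False, note="no standard"))
            continue
        for _, std in applicable.iterrows():
            if measured is None:
                rows.append(dict(pollutant=pollutant, authority=std["authority"],
                                 period=std["period"], measured=np.nan,
                                 limit=float(std["limit"]), ratio=np.nan,
                                 exceeds=False, note="BDL"))
                continue
            limit = float(std["limit"])
            rows.append(dict(pollutant=pollutant, authority=std["authority"],
                             period=std["period"], measured=measured, limit=limit,
                             ratio=measured / limit, exceeds=measured > limit, note=""))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SeasonalTestResult:
    element: str
    method: str
    statistic: float
    pvalue: float
    direction: str  # "dry>wet", "wet>dry" or "equal" (by sample medians)
    n_wet: int
    n_dry: int


def seasonal_difference_test(
    records, element: str, method: Literal["mannwhitney", "ttest"] = "mannwhitney"
) -> SeasonalTestResult:
    """Two-sided wet-vs-dry test on uncensored values for one element.

    Default is the Mann–Whitney rank-sum test (small n per season, no
    normality assumption); Welch's t-test is available for comparison.
    Requires ≥3 uncensored values per season.
    """
    df = _as_frame(records)
    sub = df.loc[(df["element"] == element) & (~df["censored"])]
    wet = sub.loc[sub["season"] == "wet", "value"].to_numpy(dtype=float)
    dry = sub.loc[sub["season"] == "dry", "value"].to_numpy(dtype=float)
    if len(wet) < 3 or len(dry) < 3:
        raise NotTestable(
            f"{element}: need >=3 uncensored values per season "
            f"(got wet={len(wet)}, dry={len(dry)})"
        )
    if method == "mannwhitney":
        res = stats.mannwhitneyu(wet, dry, alternative="two-sided")
    elif method == "ttest":
        res = stats.ttest_ind(wet, dry, equal_var=False)
    else:
        raise ConfigError(f"unknown test method {method!r}")
    med_w, med_d = float(np.median(wet)), float(np.median(dry))
    direction = "dry>wet" if med_d > med_w else ("wet>dry" if med_w > med_d else "equal")
    return SeasonalTestResult(
        element=element,
        method=method,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        direction=direction,
        n_wet=len(wet),
        n_dry=len(dry),
    )
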