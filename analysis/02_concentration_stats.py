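"""Seasonal descriptive statistics of the concentration panel.

Summarises each element by season (mean/min/max/sd with censored groups
flagged BDL), ranks elements by seasonal mean, screens means against the
Indonesian and WHO ambient standards, and tests the wet-vs-dry contrast per
element with a two-sided Mann-Whitney rank-sum test.

Reads results/data/concentrations.csv; writes tables under results/stats/.
"""

from pathlib import Path

import pandas as pd

from pterisk.concentration_stats import (compare_to_standards, rank_elements,
                                         seasonal_difference_test,
                                         seasonal_summary)
from pterisk.errors import NotTestable
from pterisk.io_utils import read_concentrations, render_reports, write_table

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "stats"


def main() -> None:
    records = read_concentrations(ROOT / "results" / "data" / "concentrations.csv")
    summary = seasonal_summary(records)
    render_reports(OUT, seasonal_summary=summary.reset_index())

    rank_rows = []
    for season in ("wet", "dry"):
        ranked = rank_elements(summary, season)
        order = " > ".join(el + (" (BDL)" if bdl else "") for el, bdl in ranked)
        print(f"{season} season order: {order}")
        rank_rows += [{"season": season, "rank": i, "element": el, "bdl": bdl}
                      for i, (el, bdl) in enumerate(ranked, start=1)]
    write_table(pd.DataFrame(rank_rows), OUT / "element_ranking.csv",
                OUT / "element_ranking.txt", "Elements by descending seasonal mean")

    screens = []
    for season in ("wet", "dry"):
        screen = compare_to_standards(summary, season=season)
        screen.insert(0, "season", season)
        screens.append(screen)
    screen = pd.concat(screens, ignore_index=True)
    write_table(screen, OUT / "standards_screen.csv", OUT / "standards_screen.txt",
                "Seasonal means vs ambient air quality standards")
    exceed = screen[screen["exceeds"]]
    print(f"standards: {len(exceed)} exceedance(s): "
          + "; ".join(f"{r.pollutant} {r.season} vs {r.authority} {r.period} "
                      f"(x{r.ratio:.2f})" for r in exceed.itertuples()))

    tests = []
    for element in sorted(records["element"].unique()):
        try:
            res = seasonal_difference_test(records, element)
            tests.append(vars(res))
            flag = "significant" if res.pvalue < 0.05 else "not significant"
            print(f"{element}: {res.direction}, p={res.pvalue:.2e} ({flag})")
        except NotTestable as exc:
            print(f"{element}: not testable ({exc})")
    write_table(pd.DataFrame(tests), OUT / "seasonal_tests.csv",
                OUT / "seasonal_tests.txt", "Wet vs dry Mann-Whitney tests")


if __name__ == "__main__":
    main()
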