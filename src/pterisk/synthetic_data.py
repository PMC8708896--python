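"""Synthetic exposure survey and seasonal concentration panel generators.

The field study's raw inputs (a 317-respondent door-to-door exposure survey
and per-sample element concentrations at 6 sites × 7 days × 2 seasons) were
never deposited, so this module generates panels with the same design and
the qualitative structure the analysis assumes: lognormal, right-skewed
concentrations; a strong dry-over-wet seasonal contrast for most elements
(Al reversed); Zn ≫ all other elements; Ni entirely below the detection
limit in the dry season; and a survey with body weight, residence duration
(≥ 1 year) and exposed skin area per respondent in two age groups.

Default magnitudes echo the published seasonal summary table; the survey
distributions are conventional exposure-handbook-style placeholders (the
study published no survey summaries).  Everything is seeded and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .concentration_stats import RECORD_COLUMNS
from .errors import DomainError
from .risk_model import ELEMENTS
from .uncertainty import DistributionSpec

SURVEY_COLUMNS = ["id", "group", "bw_kg", "ed_years", "sa_cm2"]


def _truncnorm(variable: str, mean: float, sd: float, lower: float,
               upper: float | None = None) -> DistributionSpec:
    return DistributionSpec(variable, "normal", {"mean": mean, "sd": sd},
                            lower=lower, upper=upper)


@dataclass(frozen=True)
class PopulationSpec:
    """Design of the synthetic respondent survey.

    Distributions are per group where physiology differs (body weight, skin
    area) and shared for residence duration, whose support is bounded below
    at 1 year by the study inclusion rule.  Children are 4–12 y, adults
    13–60 y (context only; age itself is not modelled).
    """

    n_total: int = 317
    fraction_children: float = 0.35
    seed: int = 0
    bw: dict = field(default_factory=lambda: {
        "adult": _truncnorm("BW", 60.0, 10.0, 35.0),
        "child": _truncnorm("BW", 25.0, 6.0, 12.0),
    })
    ed: dict = field(default_factory=lambda: {
        "adult": DistributionSpec("ED", "uniform", {"low": 1.0, "high": 30.0}),
        "child": DistributionSpec("ED", "uniform", {"low": 1.0, "high": 12.0}),
    })
    sa: dict = field(default_factory=lambda: {
        "adult": _truncnorm("SA", 5700.0, 800.0, 2000.0),
        "child": _truncnorm("SA", 2800.0, 500.0, 1000.0),
    })

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise DomainError("n_total must be >= 2 (at least one respondent per group)")
        if not 0 < self.fraction_children < 1:
            raise DomainError("fraction_children must lie strictly between 0 and 1")


def generate_survey(spec: PopulationSpec) -> pd.DataFrame:
    """One row per respondent: id, group, bw_kg, ed_years, sa_cm2.

    Group sizes are deterministic (round of the child fraction, clamped so
    both groups are non-empty); all draws flow from the single seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_children = min(max(int(round(spec.n_total * spec.fraction_children)), 1),
                     spec.n_total - 1)
    n_adults = spec.n_total - n_children
    frames = []
    offset = 0
    for group, n in (("adult", n_adults), ("child", n_children)):
        frames.append(pd.DataFrame({
            "id": [f"R{offset + i + 1:04d}" for i in range(n)],
            "group": group,
            "bw_kg": spec.bw[group].sample(n, rng),
            "ed_years": spec.ed[group].sample(n, rng),
            "sa_cm2": spec.sa[group].sample(n, rng),
        }))
        offset += n
    return pd.concat(frames, ignore_index=True)[SURVEY_COLUMNS]


@dataclass(frozen=True)
class ElementScenario:
    """Lognormal wet-season baseline and seasonal shift for one element.

    ``wet_median`` µg/m³; ``gsd`` the geometric standard deviation shared by
    both seasons; ``dry_multiplier`` scales the dry-season median;
    ``detection_limit`` µg/m³; ``censor_dry`` forces every dry-season value
    below the detection limit (the fully-censored Ni pattern).
    """

    wet_median: float
    gsd: float = 1.35
    dry_multiplier: float = 1.0
    detection_limit: float = 0.01
    censor_dry: bool = False

    def __post_init__(self) -> None:
        if not self.wet_median > 0:
            raise DomainError(f"wet_median must be positive, got {self.wet_median}")
        if not self.gsd > 1:
            raise DomainError(f"gsd must exceed 1, got {self.gsd}")
        if not self.dry_multiplier > 0:
            raise DomainError(f"dry_multiplier must be positive, got {self.dry_multiplier}")
        if self.detection_limit < 0:
            raise DomainError("detection_limit must be non-negative")


def default_element_scenarios() -> dict[str, ElementScenario]:
    """Defaults echoing the published seasonal magnitudes (not the real site data).

    Wet medians and dry/wet ratios track the published means: Zn dominant,
    dry ≫ wet for As/Cr/Cu/Pb/Zn, reversed for Al, Ni censored when dry.
    TSP is carried alongside the seven elements for the standards screen.
    """
    return {
        "Al": ElementScenario(wet_median=2558.5, dry_multiplier=0.33),
        "As": ElementScenario(wet_median=1.61, dry_multiplier=57.0),
        "Cr": ElementScenario(wet_median=11.88, dry_multiplier=6.8),
        "Cu": ElementScenario(wet_median=4.68, dry_multiplier=17.0),
        "Ni": ElementScenario(wet_median=1.80, dry_multiplier=1.0, censor_dry=True,
                              detection_limit=0.5),
        "Pb": ElementScenario(wet_median=6.90, dry_multiplier=108.0),
        "Zn": ElementScenario(wet_median=9844.5, dry_multiplier=2.36),
        "TSP": ElementScenario(wet_median=51.75, dry_multiplier=3.0),
    }


@dataclass(frozen=True)
class ConcentrationScenario:
    """Design of the synthetic seasonal sampling campaign."""

    elements: dict = field(default_factory=default_element_scenarios)
    n_sites: int = 6
    n_days: int = 7
    site_effect_sd: float = 0.15  # sd of a per-site lognormal random effect (log scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_days < 1:
            raise DomainError("n_sites and n_days must be >= 1")
        if self.site_effect_sd < 0:
            raise DomainError("site_effect_sd must be non-negative")


def generate_concentrations(scenario: ConcentrationScenario) -> pd.DataFrame:
    """Long-format panel: n_sites × n_days × 2 seasons × elements.

    Each value is lognormal around the seasonal median times a per-site
    multiplicative random effect.  After drawing, any value below the
    element's detection limit — and every dry-season value of a
    ``censor_dry`` element — is recorded as censored with the detection
    limit stored in ``value``.
    """
    rng = np.random.default_rng(scenario.seed)
    sigma_site = scenario.site_effect_sd
    rows = []
    for element, el in scenario.elements.items():
        site_effects = np.exp(rng.normal(0.0, sigma_site, scenario.n_sites)) \
            if sigma_site > 0 else np.ones(scenario.n_sites)
        sigma = np.log(el.gsd)
        for season in ("wet", "dry"):
            median = el.wet_median * (el.dry_multiplier if season == "dry" else 1.0)
            for site in range(1, scenario.n_sites + 1):
                draws = rng.lognormal(np.log(median * site_effects[site - 1]),
                                      sigma, scenario.n_days)
                for day, value in enumerate(draws, start=1):
                    forced = el.censor_dry and season == "dry"
                    censored = forced or value < el.detection_limit
                    rows.append({
                        "site": site,
                        "season": season,
                        "day": day,
                        "element": element,
                        "value": el.detection_limit if censored else float(value),
                        "censored": censored,
                    })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def make_fixture_bundle(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Deterministic miniature dataset plus a brute-force summary manifest.

    Writes ``survey.csv`` (20 respondents), ``concentrations.csv``
    (2 sites × 3 days × 2 seasons × 8 pollutants = 96 records ≤ 200) and
    ``manifest.yaml`` holding record counts and per element × season means
    of uncensored values computed here by direct arithmetic, for use as
    frozen expected values in tests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    survey = generate_survey(PopulationSpec(n_total=20, fraction_children=0.4, seed=seed))
    scenario = ConcentrationScenario(n_sites=2, n_days=3, seed=seed)
    conc = generate_concentrations(scenario)

    survey_path = outdir / "survey.csv"
    conc_path = outdir / "concentrations.csv"
    survey.to_csv(survey_path, index=False, float_format="%.6f")
    conc.to_csv(conc_path, index=False, float_format="%.6f")

    # brute-force means from the written file, so the manifest certifies the
    # on-disk artefact (round-tripped precision), not the in-memory frame
    written = pd.read_csv(conc_path)
    means: dict[str, dict[str, float | None]] = {}
    for element in list(scenario.elements):
        means[element] = {}
        for season in ("wet", "dry"):
            vals = [
                float(v)
                for v, e, s, c in zip(written["value"], written["element"],
                                      written["season"], written["censored"])
                if e == element and s == season and not c
            ]
            means[element][season] = (sum(vals) / len(vals)) if vals else None

    manifest = {
        "seed": int(seed),
        "n_survey": int(len(survey)),
        "n_concentration_records": int(len(conc)),
        "elements": list(scenario.elements),
        "uncensored_means": means,
    }
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8")
    return {"survey": survey_path, "concentrations": conc_path, "manifest": manifest_path}
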