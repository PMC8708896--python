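"""Glue between data frames and the risk engine / Monte Carlo layer.

These are the steps the analysis drivers and the CLI share: collapsing a
concentration panel to per-element means, collapsing a survey to group-mean
receptor archetypes, fitting input distributions from data, and running the
per-carcinogen Monte Carlo with sensitivity output.

A note on units: the concentration panel carries air concentrations (µg/m³)
while the dose equations' dust mode nominally expects a particulate-phase
concentration (mg/kg).  Following the source study's practice, the numeric
concentration values are fed to all three routes unchanged; see the methods
note for the dimensional caveat.
"""

from __future__ import annotations

from typing import Literal, Mapping

import numpy as np
import pandas as pd

from . import risk_model as rm
from . import uncertainty as unc
from .concentration_stats import seasonal_summary
from .errors import DomainError

GROUPS = ("adult", "child")


def mean_concentrations(records: pd.DataFrame, season: str | None = None,
                        bdl_strategy: str = "exclude") -> dict[str, float]:
    """Per-element mean of (optionally one season's) uncensored values.

    Elements entirely censored in the selected window contribute 0.0 — the
    conservative floor for a dose model is no measurable concentration, and
    the gap is visible in the seasonal summary's BDL flag.
    """
    summary = seasonal_summary(records, bdl_strategy=bdl_strategy)
    means: dict[str, float] = {}
    for element in rm.ELEMENTS:
        rows = summary.loc[element] if element in summary.index.get_level_values(0) else None
        if rows is None:
            raise DomainError(f"no records for element {element}")
        if season is not None:
            if season not in rows.index:
                raise DomainError(f"no {season}-season records for element {element}")
            m = rows.loc[season, "mean"]
            means[element] = 0.0 if pd.isna(m) else float(m)
        else:
            weights = rows["n"].to_numpy(dtype=float)
            vals = rows["mean"].fillna(0.0).to_numpy(dtype=float)
            means[element] = float((vals * weights).sum() / weights.sum()) \
                if weights.sum() > 0 else 0.0
    return means


def group_receptors(survey: pd.DataFrame) -> dict[str, rm.ReceptorProfile]:
    """Collapse the survey to one mean-receptor archetype per group."""
    receptors = {}
    for group in GROUPS:
        sub = survey.loc[survey["group"] == group]
        if sub.empty:
            continue
        receptors[group] = rm.ReceptorProfile(
            group=group,
            body_weight=float(sub["bw_kg"].mean()),
            exposure_duration=float(sub["ed_years"].mean()),
            skin_area=float(sub["sa_cm2"].mean()),
        )
    if not receptors:
        raise DomainError("survey contains neither adults nor children")
    return receptors


def risk_tables(concentrations: Mapping[str, float], survey: pd.DataFrame,
                convention: rm.AveragingConvention = rm.RESIDENTIAL,
                inhalation_mode: Literal["dust", "air"] = "dust") -> dict[str, rm.RiskAssessment]:
    """Deterministic assessment for each group's mean receptor."""
    return {
        group: rm.assess_receptor(
            concentrations, receptor, convention=convention,
            inhalation_mode=inhalation_mode,
        )
        for group, receptor in group_receptors(survey).items()
    }


def fit_input_specs(records: pd.DataFrame, survey: pd.DataFrame, element: str,
                    group: str, season: str | None = None) -> dict[str, unc.DistributionSpec]:
    """Empirical distribution specs for the four uncertain inputs.

    C: lognormal with the geometric mean/sd of the uncensored values
    (season-filtered if requested); BW and SA: truncated normals at the
    observed mean/sd, bounded below by the observed minimum; ED: uniform
    over the observed range (collapsing to a point if degenerate).
    """
    sub = records.loc[(records["element"] == element) & (~records["censored"])]
    if season is not None:
        sub = sub.loc[sub["season"] == season]
    values = sub["value"].to_numpy(dtype=float)
    values = values[values > 0]
    if values.size < 3:
        raise DomainError(f"too few uncensored positive values to fit C for {element}")
    logs = np.log(values)
    gsd = float(np.exp(logs.std(ddof=1)))
    c_spec = (
        unc.DistributionSpec("C", "lognormal",
                             {"median": float(np.exp(logs.mean())), "gsd": gsd})
        if gsd > 1
        else unc.point("C", float(values.mean()))
    )

    people = survey.loc[survey["group"] == group]
    if people.empty:
        raise DomainError(f"survey has no {group} respondents")

    def truncated_normal(name, col):
        x = people[col].to_numpy(dtype=float)
        sd = float(x.std(ddof=1))
        if sd == 0:
            return unc.point(name, float(x.mean()))
        return unc.DistributionSpec(name, "normal",
                                    {"mean": float(x.mean()), "sd": sd},
                                    lower=float(x.min()))

    ed = people["ed_years"].to_numpy(dtype=float)
    ed_spec = (
        unc.DistributionSpec("ED", "uniform", {"low": float(ed.min()), "high": float(ed.max())})
        if ed.min() < ed.max()
        else unc.point("ED", float(ed.mean()))
    )
    return {
        "C": c_spec,
        "BW": truncated_normal("BW", "bw_kg"),
        "ED": ed_spec,
        "SA": truncated_normal("SA", "sa_cm2"),
    }


def monte_carlo_cancer_risk(records: pd.DataFrame, survey: pd.DataFrame, element: str,
                            config: unc.SimulationConfig, season: str | None = None):
    """Per-carcinogen Monte Carlo: (SimulationResult, sensitivity frame)."""
    specs = fit_input_specs(records, survey, element, config.group, season)
    model = unc.cancer_risk_model(element, config)
    result = unc.propagate(model, specs, config)
    sens = unc.sensitivity_contributions(result.inputs, result.samples)
    return result, sens
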