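"""Generate the synthetic study inputs.

The raw field inputs — a 317-respondent exposure survey and element
concentrations at 6 sites × 7 days × 2 seasons — are not publicly
deposited, so every downstream stage runs on a seeded synthetic stand-in
with the same design: lognormal right-skewed concentrations, dry ≫ wet for
most elements (Al reversed), Zn dominant, Ni fully below the detection
limit in the dry season, and a two-group survey with body weight, residence
duration (≥ 1 year) and exposed skin area.

Writes results/data/survey.csv and results/data/concentrations.csv.
"""

from pathlib import Path

from pterisk.synthetic_data import (ConcentrationScenario, PopulationSpec,
                                    generate_concentrations, generate_survey)

SEED = 20210328
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    survey = generate_survey(PopulationSpec(seed=SEED))
    survey.to_csv(OUT / "survey.csv", index=False)
    panel = generate_concentrations(ConcentrationScenario(seed=SEED))
    panel.to_csv(OUT / "concentrations.csv", index=False)

    n_child = int((survey["group"] == "child").sum())
    n_cens = int(panel["censored"].sum())
    print(f"survey: {len(survey)} respondents ({n_child} children, "
          f"{len(survey) - n_child} adults) -> {OUT / 'survey.csv'}")
    print(f"concentrations: {len(panel)} records, {n_cens} censored "
          f"(all Ni x dry season) -> {OUT / 'concentrations.csv'}")


if __name__ == "__main__":
    main()
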