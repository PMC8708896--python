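"""Published summary values from the motivating field survey (industrial
district of Maros Regency, South Sulawesi, Indonesia).

The raw site data behind these summaries (per-sample concentrations and the
317-respondent exposure survey) were never deposited, so the printed
summaries are the only reproducible anchor: seasonal concentration means,
per-route hazard quotients and per-route cancer risks.  They are *inputs*
for cross-checks — element-ordering, standards screening, and the HI/TCR
summation identities — never substitutes for computation.

Concentration means are µg/m³; ``None`` marks a cell reported as below the
detection limit (BDL).
"""

from __future__ import annotations

SEASONAL_MEAN_UG_M3: dict[str, dict[str, float | None]] = {
    "wet": {
        "TSP": 51.75,
        "Al": 2558.5,
        "As": 1.61,
        "Cr": 11.88,
        "Cu": 4.68,
        "Ni": 1.80,
        "Pb": 6.90,
        "Zn": 9844.5,
    },
    "dry": {
        "TSP": 156.86,
        "Al": 844.50,
        "As": 91.63,
        "Cr": 81.17,
        "Cu": 78.97,
        "Ni": None,  # BDL
        "Pb": 746.78,
        "Zn": 23247.1,
    },
}

# Hazard quotients by group and (element, route); summing each group's 21
# entries reproduces the reported hazard index (0.64 adults, 2.12 children)
# to within the rounding of the printed addends.
HQ_TABLE: dict[str, dict[tuple[str, str], float]] = {
    "adult": {
        ("Al", "inhalation"): 3.88e-4,
        ("As", "inhalation"): 3.55e-4,
        ("Cr", "inhalation"): 1.32e-2,
        ("Cu", "inhalation"): 7.96e-4,
        ("Ni", "inhalation"): 2.93e-7,
        ("Pb", "inhalation"): 3.61e-8,
        ("Zn", "inhalation"): 1.05e-1,
        ("Al", "ingestion"): 1.27e-3,
        ("As", "ingestion"): 2.41e-1,
        ("Cr", "ingestion"): 2.40e-2,
        ("Cu", "ingestion"): 1.62e-6,
        ("Ni", "ingestion"): 1.39e-7,
        ("Pb", "ingestion"): 1.67e-1,
        ("Zn", "ingestion"): 8.56e-2,
        ("Al", "dermal"): 5.85e-5,
        ("As", "dermal"): 4.33e-10,
        ("Cr", "dermal"): 4.80e-3,
        ("Cu", "dermal"): 2.16e-8,
        ("Ni", "dermal"): 2.06e-9,
        ("Pb", "dermal"): 4.49e-3,
        ("Zn", "dermal"): 1.70e-6,
    },
    "child": {
        ("Al", "inhalation"): 2.93e-4,
        ("As", "inhalation"): 2.61e-4,
        ("Cr", "inhalation"): 9.78e-3,
        ("Cu", "inhalation"): 5.86e-4,
        ("Ni", "inhalation"): 2.16e-7,
        ("Pb", "inhalation"): 2.66e-8,
        ("Zn", "inhalation"): 7.73e-2,
        ("Al", "ingestion"): 4.94e-3,
        ("As", "ingestion"): 9.36e-1,
        ("Cr", "ingestion"): 9.34e-2,
        ("Cu", "ingestion"): 6.29e-6,
        ("Ni", "ingestion"): 5.42e-7,
        ("Pb", "ingestion"): 6.48e-1,
        ("Zn", "ingestion"): 3.32e-1,
        ("Al", "dermal"): 1.41e-4,
        ("As", "dermal"): 2.62e-3,
        ("Cr", "dermal"): 1.01e-2,
        ("Cu", "dermal"): 5.87e-8,
        ("Ni", "dermal"): 5.62e-9,
        ("Pb", "dermal"): 1.22e-2,
        ("Zn", "dermal"): 4.65e-6,
    },
}

# Cancer risks by group and (element, route) for the carcinogens; summing
# each group's 9 entries reproduces the reported total cancer risk
# (3.11e-5 adults, 1.32e-4 children) to within printed rounding.
CR_TABLE: dict[str, dict[tuple[str, str], float]] = {
    "adult": {
        ("As", "inhalation"): 1.55e-10,
        ("Pb", "inhalation"): 3.52e-8,
        ("Cr", "inhalation"): 4.24e-8,
        ("As", "ingestion"): 1.05e-7,
        ("Pb", "ingestion"): 2.08e-6,
        ("Cr", "ingestion"): 2.89e-5,
        ("As", "dermal"): 2.41e-11,
        ("Pb", "dermal"): 5.46e-8,
        ("Cr", "dermal"): 6.58e-9,
    },
    "child": {
        ("As", "inhalation"): 1.14e-10,
        ("Pb", "inhalation"): 2.60e-8,
        ("Cr", "inhalation"): 3.14e-8,
        ("As", "ingestion"): 4.11e-7,
        ("Pb", "ingestion"): 1.89e-5,
        ("Cr", "ingestion"): 1.12e-4,
        ("As", "dermal"): 1.66e-10,
        ("Pb", "dermal"): 3.77e-7,
        ("Cr", "dermal"): 4.55e-8,
    },
}

# Reported aggregate values and element orderings, used as expected values in
# cross-checks of the summation/ordering machinery.
REPORTED_HI = {"adult": 0.64, "child": 2.12}
REPORTED_TCR = {"adult": 3.11e-5, "child": 1.32e-4}
REPORTED_ORDER = {
    "wet": ["Zn", "Al", "Cr", "Pb", "Cu", "Ni", "As"],
    "dry": ["Zn", "Al", "Pb", "As", "Cr", "Cu", "Ni"],
}
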