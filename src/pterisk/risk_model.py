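"""Deterministic multi-route exposure and risk engine.

Implements the standard USEPA-style chain for particulate-bound potentially
toxic elements (PTEs): average daily dose (ADD) via ingestion, inhalation and
dermal contact, hazard quotients (HQ = ADD / RfD or RfC) aggregated to a
hazard index (HI = ΣHQ), and cancer risk (CR = ADD × CSF) aggregated to a
total cancer risk (TCR = ΣCR) over the carcinogens As, Cr and Pb.

All dose functions are pure arithmetic in their concentration argument, so
they broadcast transparently over numpy arrays — the Monte Carlo layer in
:mod:`pterisk.uncertainty` relies on this.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .config import load_defaults
from .errors import ConfigError, DomainError, NoReferenceValue, NoSlopeFactor

ELEMENTS: tuple[str, ...] = ("Al", "As", "Cr", "Cu", "Ni", "Pb", "Zn")
CARCINOGENS: tuple[str, ...] = ("As", "Cr", "Pb")
ROUTES: tuple[str, ...] = ("ingestion", "inhalation", "dermal")

Route = Literal["ingestion", "inhalation", "dermal"]
Group = Literal["adult", "child"]

DAYS_PER_YEAR = 365.0

# CR classification bands (dimensionless lifetime probability)
CR_NEGLIGIBLE_BELOW = 1e-6
CR_UNACCEPTABLE_ABOVE = 1e-4


def validate_element(symbol: str) -> str:
    """Return ``symbol`` if it is one of the seven modelled elements, else raise."""
    if symbol not in ELEMENTS:
        raise DomainError(f"unknown element {symbol!r}; expected one of {ELEMENTS}")
    return symbol


@dataclass(frozen=True)
class ExposureConstants:
    """Group-specific intake factors (defaults via :func:`default_constants`).

    Units: ingestion_rate mg/day; inhalation_rate m³/day; exposure_frequency
    days/year; conversion_factor kg/mg; particulate_emission_factor m³/kg;
    dermal_absorption unitless; skin_adherence mg·cm⁻²·h.

    ``allow_degenerate`` permits a zero dermal absorption fraction for
    what-if analyses; by default a zero ABS is rejected as a likely
    configuration mistake.
    """

    ingestion_rate: float
    inhalation_rate: float
    skin_adherence: float
    exposure_frequency: float = 350.0
    conversion_factor: float = 1e-6
    particulate_emission_factor: float = 1.36e9
    dermal_absorption: float = 0.001
    allow_degenerate: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        strictly_positive = {
            "ingestion_rate": self.ingestion_rate,
            "inhalation_rate": self.inhalation_rate,
            "skin_adherence": self.skin_adherence,
            "conversion_factor": self.conversion_factor,
            "particulate_emission_factor": self.particulate_emission_factor,
        }
        for name, value in strictly_positive.items():
            if not value > 0:
                raise DomainError(f"{name} must be strictly positive, got {value}")
        if not 0 < self.exposure_frequency <= DAYS_PER_YEAR:
            raise DomainError(
                f"exposure_frequency must lie in (0, 365], got {self.exposure_frequency}"
            )
        lower_ok = self.dermal_absorption > 0 or (
            self.allow_degenerate and self.dermal_absorption == 0
        )
        if not (lower_ok and self.dermal_absorption <= 1):
            raise DomainError(
                f"dermal_absorption must lie in (0, 1], got {self.dermal_absorption}"
            )


@dataclass(frozen=True)
class ReceptorProfile:
    """One exposed person (or group archetype): body weight kg, residence years, skin cm²."""

    group: Group
    body_weight: float
    exposure_duration: float
    skin_area: float

    def __post_init__(self) -> None:
        if self.group not in ("adult", "child"):
            raise DomainError(f"group must be 'adult' or 'child', got {self.group!r}")
        if not self.body_weight > 0:
            raise DomainError(f"body_weight must be positive, got {self.body_weight}")
        if not self.exposure_duration >= 1:
            raise DomainError(
                f"exposure_duration must be >= 1 year (study inclusion rule), got {self.exposure_duration}"
            )
        if not self.skin_area > 0:
            raise DomainError(f"skin_area must be positive, got {self.skin_area}")


@dataclass(frozen=True)
class AveragingConvention:
    """How the averaging time AT (days) is formed.

    ``residential``: AT = ED × 365, under which ED cancels algebraically in
    every ADD.  ``lifetime``: AT = lifetime_years × 365, the usual convention
    for carcinogens, under which longer residence raises the dose.
    """

    mode: Literal["residential", "lifetime"] = "residential"
    lifetime_years: float = 70.0

    def __post_init__(self) -> None:
        if self.mode not in ("residential", "lifetime"):
            raise ConfigError(f"unknown averaging mode {self.mode!r}")
        if not self.lifetime_years > 0:
            raise DomainError(f"lifetime_years must be positive, got {self.lifetime_years}")

    def averaging_time_days(self, exposure_duration):
        if self.mode == "residential":
            return exposure_duration * DAYS_PER_YEAR
        return self.lifetime_years * DAYS_PER_YEAR


RESIDENTIAL = AveragingConvention("residential")
LIFETIME = AveragingConvention("lifetime")


@dataclass(frozen=True)
class ToxicityReference:
    """Per-element reference dose / concentration and optional slope factors."""

    element: str
    rfd_dermal: float
    rfd_ingestion: float
    rfc_inhalation: float
    csf_ingestion: float | None = None
    csf_dermal: float | None = None
    csf_inhalation: float | None = None

    def __post_init__(self) -> None:
        validate_element(self.element)
        for name in (
            "rfd_dermal",
            "rfd_ingestion",
            "rfc_inhalation",
            "csf_ingestion",
            "csf_dermal",
            "csf_inhalation",
        ):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise DomainError(f"{self.element}: {name} must be strictly positive, got {value}")

    def reference_for(self, route: Route) -> float:
        """RfD (ingestion/dermal) or RfC (inhalation) for the route, or raise NoReferenceValue."""
        value = {
            "ingestion": self.rfd_ingestion,
            "dermal": self.rfd_dermal,
            "inhalation": self.rfc_inhalation,
        }.get(route)
        if route not in ROUTES:
            raise ConfigError(f"unknown route {route!r}")
        if value is None:
            raise NoReferenceValue(f"no reference value for {self.element}/{route}")
        return value

    def slope_for(self, route: Route) -> float:
        if route not in ROUTES:
            raise ConfigError(f"unknown route {route!r}")
        value = {
            "ingestion": self.csf_ingestion,
            "dermal": self.csf_dermal,
            "inhalation": self.csf_inhalation,
        }[route]
        if value is None:
            raise NoSlopeFactor(f"no cancer slope factor for {self.element}/{route}")
        return value


def default_constants(group: Group, config_path=None) -> ExposureConstants:
    """Packaged intake factors for a receptor group (editable via YAML override)."""
    cfg = load_defaults(config_path)
    try:
        block = cfg["exposure"][group]
    except KeyError as exc:
        raise ConfigError(f"no exposure constants for group {group!r}") from exc
    return ExposureConstants(**block)


def default_toxicity(config_path=None) -> dict[str, ToxicityReference]:
    """Packaged toxicity grid, one :class:`ToxicityReference` per element."""
    cfg = load_defaults(config_path)
    return {el: ToxicityReference(element=el, **vals) for el, vals in cfg["toxicity"].items()}


def _check_concentration(c) -> None:
    if np.any(np.asarray(c) < 0):
        raise DomainError(f"concentration must be non-negative, got {c}")


def add_oral(c, constants: ExposureConstants, receptor: ReceptorProfile,
             convention: AveragingConvention = RESIDENTIAL):
    """Average daily dose via incidental ingestion, mg·kg⁻¹·day⁻¹.

    ADD = C · IngR · CF · EF · ED / (BW · AT) with C a dust-phase
    concentration in mg/kg.
    """
    _check_concentration(c)
    at = convention.averaging_time_days(receptor.exposure_duration)
    return (
        c
        * constants.ingestion_rate
        * constants.conversion_factor
        * constants.exposure_frequency
        * receptor.exposure_duration
        / (receptor.body_weight * at)
    )


def add_inhalation(c, constants: ExposureConstants, receptor: ReceptorProfile,
                   convention: AveragingConvention = RESIDENTIAL,
                   mode: Literal["dust", "air"] = "dust"):
    """Average daily dose via inhalation, mg·kg⁻¹·day⁻¹.

    ``dust`` mode (default): C is a dust-phase concentration in mg/kg and the
    particulate emission factor PEF (m³/kg) converts it to an equivalent air
    concentration: ADD = C · InhR · EF · ED / (PEF · BW · AT).
    ``air`` mode: C is a direct air concentration in mg/m³ and PEF is omitted.
    """
    _check_concentration(c)
    at = convention.averaging_time_days(receptor.exposure_duration)
    core = (
        c
        * constants.inhalation_rate
        * constants.exposure_frequency
        * receptor.exposure_duration
        / (receptor.body_weight * at)
    )
    if mode == "dust":
        return core / constants.particulate_emission_factor
    if mode == "air":
        return core
    raise ConfigError(f"unknown inhalation mode {mode!r}; expected 'dust' or 'air'")


def add_dermal(c, constants: ExposureConstants, receptor: ReceptorProfile,
               convention: AveragingConvention = RESIDENTIAL):
    """Average daily dose via dermal contact, mg·kg⁻¹·day⁻¹.

    ADD = C · SA · CF · SL · EF · ABS · ED / (BW · AT).
    """
    _check_concentration(c)
    at = convention.averaging_time_days(receptor.exposure_duration)
    return (
        c
        * receptor.skin_area
        * constants.conversion_factor
        * constants.skin_adherence
        * constants.exposure_frequency
        * constants.dermal_absorption
        * receptor.exposure_duration
        / (receptor.body_weight * at)
    )


def hazard_quotient(add, ref: ToxicityReference, route: Route):
    """HQ = ADD / RfD (ingestion, dermal) or ADD / RfC (inhalation)."""
    if np.any(np.asarray(add) < 0):
        raise DomainError(f"ADD must be non-negative, got {add}")
    return add / ref.reference_for(route)


@dataclass(frozen=True)
class HazardIndex:
    value: float
    classification: str

    def __float__(self) -> float:
        return self.value


def classify_hi(hi: float) -> str:
    return (
        "adverse non-carcinogenic effects not expected"
        if hi < 1
        else "adverse non-carcinogenic effects may appear"
    )


def hazard_index(hqs) -> HazardIndex:
    """HI = ΣHQ over elements and routes, with its risk classification.

    Accepts a mapping keyed by (element, route) or any iterable of HQ values.
    """
    values = list(hqs.values()) if isinstance(hqs, Mapping) else list(hqs)
    if not values:
        raise DomainError("hazard_index requires at least one hazard quotient")
    if any(v < 0 for v in values):
        raise DomainError("hazard quotients must be non-negative")
    total = float(math.fsum(values))
    return HazardIndex(total, classify_hi(total))


def cancer_risk(add, csf):
    """CR = ADD × CSF, a lifetime excess cancer probability.

    A product exceeding 1 is clamped to 1 with a warning (a probability
    cannot exceed certainty); pass ``csf=None`` is not allowed — use
    :meth:`ToxicityReference.slope_for` which raises :class:`NoSlopeFactor`.
    """
    if csf is None:
        raise NoSlopeFactor("cancer slope factor absent (non-carcinogen)")
    if not csf > 0:
        raise DomainError(f"cancer slope factor must be positive, got {csf}")
    if np.any(np.asarray(add) < 0):
        raise DomainError(f"ADD must be non-negative, got {add}")
    risk = add * csf
    if np.any(np.asarray(risk) > 1):
        warnings.warn("cancer risk exceeded 1 and was clamped", stacklevel=2)
        risk = np.minimum(risk, 1.0) if isinstance(risk, np.ndarray) else 1.0
    return risk


@dataclass(frozen=True)
class TotalCancerRisk:
    value: float
    classification: str

    def __float__(self) -> float:
        return self.value


def classify_cr(cr: float) -> str:
    if cr < CR_NEGLIGIBLE_BELOW:
        return "negligible"
    if cr <= CR_UNACCEPTABLE_ABOVE:
        return "acceptable/low"
    return "unacceptable"


def total_cancer_risk(crs) -> TotalCancerRisk:
    """TCR = ΣCR over carcinogens and routes, with its classification band."""
    values = list(crs.values()) if isinstance(crs, Mapping) else list(crs)
    if not values:
        raise DomainError("total_cancer_risk requires at least one cancer risk value")
    if any(v < 0 for v in values):
        raise DomainError("cancer risks must be non-negative")
    total = float(math.fsum(values))
    return TotalCancerRisk(total, classify_cr(total))


@dataclass
class RiskAssessment:
    """Full per-receptor result: doses, hazard quotients, cancer risks, aggregates."""

    receptor: ReceptorProfile
    add: dict[tuple[str, str], float]
    hq: dict[tuple[str, str], float]
    cr: dict[tuple[str, str], float]
    hi: HazardIndex
    tcr: TotalCancerRisk

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: element, route, ADD, HQ, CR plus HI/TCR summary rows."""
        rows = []
        for (element, route), dose in sorted(self.add.items()):
            rows.append(
                {
                    "element": element,
                    "route": route,
                    "ADD": dose,
                    "HQ": self.hq.get((element, route), float("nan")),
                    "CR": self.cr.get((element, route), float("nan")),
                }
            )
        rows.append({"element": "HI", "route": "all", "ADD": float("nan"),
                     "HQ": self.hi.value, "CR": float("nan")})
        rows.append({"element": "TCR", "route": "all", "ADD": float("nan"),
                     "HQ": float("nan"), "CR": self.tcr.value})
        return pd.DataFrame(rows)


def assess_receptor(
    concentrations: Mapping[str, float],
    receptor: ReceptorProfile,
    constants: ExposureConstants | None = None,
    refs: Mapping[str, ToxicityReference] | None = None,
    convention: AveragingConvention = RESIDENTIAL,
    routes: Iterable[Route] = ROUTES,
    inhalation_mode: Literal["dust", "air"] = "dust",
) -> RiskAssessment:
    """Run the full dose → HQ/HI → CR/TCR chain for one receptor.

    ``concentrations`` must cover all seven elements (missing ones are
    reported together in the error).  HQ is computed for every element and
    enabled route; CR only for the carcinogens As, Cr and Pb.
    """
    constants = constants if constants is not None else default_constants(receptor.group)
    refs = refs if refs is not None else default_toxicity()
    routes = tuple(routes)
    for route in routes:
        if route not in ROUTES:
            raise ConfigError(f"unknown route {route!r}")

    missing = [el for el in ELEMENTS if el not in concentrations]
    if missing:
        raise DomainError(f"missing concentrations for elements: {', '.join(missing)}")

    add: dict[tuple[str, str], float] = {}
    hq: dict[tuple[str, str], float] = {}
    cr: dict[tuple[str, str], float] = {}
    for element in ELEMENTS:
        c = concentrations[element]
        for route in routes:
            if route == "ingestion":
                dose = add_oral(c, constants, receptor, convention)
            elif route == "inhalation":
                dose = add_inhalation(c, constants, receptor, convention, mode=inhalation_mode)
            else:
                dose = add_dermal(c, constants, receptor, convention)
            add[(element, route)] = dose
            hq[(element, route)] = hazard_quotient(dose, refs[element], route)
            if element in CARCINOGENS:
                cr[(element, route)] = cancer_risk(dose, refs[element].slope_for(route))

    return RiskAssessment(
        receptor=receptor,
        add=add,
        hq=hq,
        cr=cr,
        hi=hazard_index(hq),
        tcr=total_cancer_risk(cr) if cr else TotalCancerRisk(0.0, classify_cr(0.0)),
    )


def with_constants(constants: ExposureConstants, **overrides) -> ExposureConstants:
    """Convenience: a modified copy of an :class:`ExposureConstants`."""
    return replace(constants, **overrides)
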