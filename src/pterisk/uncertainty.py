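"""Seeded Monte Carlo propagation of the risk model and sensitivity analysis.

The propagated quantity is Y = h(X₁, …, Xₖ): the deterministic dose→risk
chain evaluated on joint draws of the uncertain inputs (element
concentration C, exposure duration ED, body weight BW, skin surface area
SA), all other factors held at their point values.  Inputs are sampled
independently.  Summaries follow the field convention: mean, sd, 5th/50th/
95th percentiles (linear interpolation between order statistics) and
exceedance probabilities against the 10⁻⁶ and 10⁻⁴ risk benchmarks.

Sensitivity uses the spreadsheet-tool contribution-to-variance convention:
signed shares proportional to the squared Spearman rank correlation between
each input and the output, normalised so the absolute shares sum to 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import risk_model as rm
from .errors import ConfigError, DomainError

Family = Literal["point", "uniform", "normal", "lognormal", "triangular"]

_MAX_REJECTION_ROUNDS = 1000

CR_BENCHMARKS = (1e-6, 1e-4)


@dataclass(frozen=True)
class DistributionSpec:
    """One uncertain model input.

    Parameter conventions per family:
      point(value); uniform(low, high); normal(mean, sd);
      lognormal(median, gsd) with gsd > 1 the geometric standard deviation;
      triangular(left, mode, right).
    ``lower``/``upper`` optionally truncate by rejection resampling.
    """

    variable: str
    family: Family
    params: Mapping[str, float]
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        p = dict(self.params)
        required = {
            "point": {"value"},
            "uniform": {"low", "high"},
            "normal": {"mean", "sd"},
            "lognormal": {"median", "gsd"},
            "triangular": {"left", "mode", "right"},
        }.get(self.family)
        if required is None:
            raise ConfigError(f"unknown distribution family {self.family!r}")
        if set(p) != required:
            raise ConfigError(
                f"{self.variable}: family {self.family!r} needs parameters {sorted(required)}, "
                f"got {sorted(p)}"
            )
        if self.family == "uniform" and not p["low"] < p["high"]:
            raise ConfigError(f"{self.variable}: uniform needs low < high")
        if self.family == "normal" and not p["sd"] > 0:
            raise ConfigError(f"{self.variable}: normal needs sd > 0")
        if self.family == "lognormal" and not (p["median"] > 0 and p["gsd"] > 1):
            raise ConfigError(f"{self.variable}: lognormal needs median > 0 and gsd > 1")
        if self.family == "triangular" and not p["left"] <= p["mode"] <= p["right"]:
            raise ConfigError(f"{self.variable}: triangular needs left <= mode <= right")
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ConfigError(f"{self.variable}: truncation bounds must satisfy lower < upper")

    def _base_draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "point":
            return np.full(n, float(p["value"]))
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], n)
        if self.family == "normal":
            return rng.normal(p["mean"], p["sd"], n)
        if self.family == "lognormal":
            return rng.lognormal(np.log(p["median"]), np.log(p["gsd"]), n)
        return rng.triangular(p["left"], p["mode"], p["right"], n)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n draws, truncation enforced by rejection with resampling."""
        if n < 1:
            raise DomainError(f"n must be >= 1, got {n}")
        out = self._base_draw(n, rng)
        if self.lower is None and self.upper is None:
            return out
        lo = -np.inf if self.lower is None else self.lower
        hi = np.inf if self.upper is None else self.upper
        bad = (out < lo) | (out > hi)
        rounds = 0
        while bad.any():
            rounds += 1
            if rounds > _MAX_REJECTION_ROUNDS:
                raise DomainError(
                    f"{self.variable}: truncation to [{lo}, {hi}] leaves essentially no mass"
                )
            out[bad] = self._base_draw(int(bad.sum()), rng)
            bad = (out < lo) | (out > hi)
        return out


def point(variable: str, value: float) -> DistributionSpec:
    """Shorthand for a degenerate (fixed-value) input."""
    return DistributionSpec(variable, "point", {"value": value})


def draw_samples(spec: DistributionSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Seeded draws from a spec; same seed ⇒ identical vector."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return spec.sample(n, rng)


@dataclass(frozen=True)
class SimulationConfig:
    n_iterations: int = 10_000
    seed: int = 0
    group: rm.Group = "adult"
    convention: rm.AveragingConvention = rm.RESIDENTIAL
    routes: tuple[str, ...] = rm.ROUTES
    inhalation_mode: Literal["dust", "air"] = "dust"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise DomainError(f"n_iterations must be >= 1, got {self.n_iterations}")


@dataclass
class SimulationResult:
    """Output samples plus the summaries the field reports."""

    samples: np.ndarray
    inputs: dict[str, np.ndarray]
    mean: float
    sd: float
    percentiles: dict[float, float]
    exceedance: dict[float, float]

    @property
    def p5(self) -> float:
        return self.percentiles[5]

    @property
    def p50(self) -> float:
        return self.percentiles[50]

    @property
    def p95(self) -> float:
        return self.percentiles[95]

    def summary_frame(self) -> pd.DataFrame:
        row = {"mean": self.mean, "sd": self.sd}
        row.update({f"p{int(q) if float(q).is_integer() else q}": v
                    for q, v in self.percentiles.items()})
        row.update({f"P(>{t:g})": v for t, v in self.exceedance.items()})
        return pd.DataFrame([row])


def summarize(samples, percentiles: Sequence[float] = (5, 50, 95)) -> dict:
    """Mean, sd and percentiles by linear interpolation of order statistics."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise DomainError("summarize requires a non-empty sample")
    pct = {float(q): float(np.percentile(x, q, method="linear")) for q in percentiles}
    # a constant sample has sd exactly 0 (mean-subtraction rounding otherwise
    # leaves a ~1e-21 residual that breaks degenerate-distribution identities)
    sd = 0.0 if x.size < 2 or np.ptp(x) == 0 else float(x.std(ddof=1))
    return {"mean": float(x.mean()), "sd": sd, "percentiles": pct}


def exceedance_probability(samples, threshold: float) -> float:
    """Fraction of samples strictly above the threshold."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise DomainError("exceedance_probability requires a non-empty sample")
    return float(np.mean(x > threshold))


def propagate(
    model: Callable[[Mapping[str, np.ndarray]], np.ndarray],
    specs: Mapping[str, DistributionSpec],
    config: SimulationConfig,
    benchmarks: Sequence[float] = CR_BENCHMARKS,
) -> SimulationResult:
    """Joint independent draw of every input, vectorised model evaluation.

    Variables are sampled in sorted name order from a single generator seeded
    with ``config.seed``, so results are bit-identical across reruns.  The
    model receives ``{name: array}`` and must return an output array of the
    same length (any failure is re-raised with the offending draws attached).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_iterations
    inputs = {name: specs[name].sample(n, rng) for name in sorted(specs)}
    try:
        y = np.asarray(model(inputs), dtype=float)
    except Exception as exc:  # noqa: BLE001 — contract: report draws on failure
        raise DomainError(f"model evaluation failed on the joint draw: {exc}") from exc
    if y.shape != (n,):
        y = np.broadcast_to(y, (n,)).astype(float)
    bad = ~np.isfinite(y)
    if bad.any():
        i = int(np.argmax(bad))
        context = {k: float(v[i]) for k, v in inputs.items()}
        raise DomainError(f"model produced non-finite output at iteration {i}: inputs {context}")
    summary = summarize(y)
    return SimulationResult(
        samples=y,
        inputs=inputs,
        mean=summary["mean"],
        sd=summary["sd"],
        percentiles=summary["percentiles"],
        exceedance={float(t): exceedance_probability(y, t) for t in benchmarks},
    )


def rank_correlation(x, y) -> float:
    """Spearman ρ with midrank ties; constant input is undefined (warned, NaN)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DomainError("rank_correlation needs equal-length vectors with >=3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("rank correlation undefined for a constant vector", stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def sensitivity_contributions(
    inputs: Mapping[str, np.ndarray], output: np.ndarray
) -> pd.DataFrame:
    """Signed contribution-to-variance shares per uncertain input.

    share_i = sign(ρ_i) · ρ_i² / Σ_j ρ_j² × 100, with ρ the Spearman rank
    correlation between input i and the output.  Zero-variance inputs get
    ρ = 0 with a flag.  Absolute shares sum to 100 whenever any ρ ≠ 0.
    """
    y = np.asarray(output, dtype=float)
    if y.size < 3:
        raise DomainError("sensitivity analysis needs >=3 observations")
    rows = []
    for name in sorted(inputs):
        x = np.asarray(inputs[name], dtype=float)
        if x.shape != y.shape:
            raise DomainError(f"input {name!r} length {x.size} != output length {y.size}")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"variable": name, "rho": 0.0, "flag": "constant"})
        else:
            rows.append({"variable": name,
                         "rho": float(stats.spearmanr(x, y).statistic),
                         "flag": ""})
    df = pd.DataFrame(rows)
    ss = float(np.sum(df["rho"] ** 2))
    if ss > 0:
        df["share_pct"] = np.sign(df["rho"]) * df["rho"] ** 2 / ss * 100.0
    else:
        df["share_pct"] = 0.0
    return df[["variable", "rho", "share_pct", "flag"]]


# ---------------------------------------------------------------------------
# Model factories bridging the deterministic engine to the sampler.  Because
# the dose functions are plain arithmetic they accept arrays directly, so
# point-mass specs reproduce the deterministic result to full precision.

def _receptor_arrays(group: rm.Group, draws: Mapping[str, np.ndarray]):
    """A ReceptorProfile-like namespace holding arrays (bypasses scalar validation)."""
    class _R:
        pass

    r = _R()
    r.group = group
    r.body_weight = draws["BW"]
    r.exposure_duration = draws["ED"]
    r.skin_area = draws["SA"]
    return r


def _route_doses(c, constants, receptor, config: SimulationConfig):
    doses = {}
    if "ingestion" in config.routes:
        doses["ingestion"] = rm.add_oral(c, constants, receptor, config.convention)
    if "inhalation" in config.routes:
        doses["inhalation"] = rm.add_inhalation(
            c, constants, receptor, config.convention, mode=config.inhalation_mode
        )
    if "dermal" in config.routes:
        doses["dermal"] = rm.add_dermal(c, constants, receptor, config.convention)
    return doses


def cancer_risk_model(
    element: str,
    config: SimulationConfig,
    constants: rm.ExposureConstants | None = None,
    refs: Mapping[str, rm.ToxicityReference] | None = None,
    per_route: bool = False,
):
    """Vectorised CR model for one carcinogen.

    Expects draw keys ``C`` (concentration), ``BW``, ``ED``, ``SA``.  By
    default routes are summed before reporting (per-element total CR); with
    ``per_route=True`` the model returns a dict of per-route arrays instead.
    """
    rm.validate_element(element)
    if element not in rm.CARCINOGENS:
        raise ConfigError(f"{element} has no cancer slope factors")
    constants = constants if constants is not None else rm.default_constants(config.group)
    refs = refs if refs is not None else rm.default_toxicity()
    ref = refs[element]

    def model(draws: Mapping[str, np.ndarray]):
        receptor = _receptor_arrays(config.group, draws)
        doses = _route_doses(draws["C"], constants, receptor, config)
        crs = {route: dose * ref.slope_for(route) for route, dose in doses.items()}
        if per_route:
            return crs
        return sum(crs.values())

    return model


def hazard_index_model(
    config: SimulationConfig,
    constants: rm.ExposureConstants | None = None,
    refs: Mapping[str, rm.ToxicityReference] | None = None,
    elements: Sequence[str] = rm.ELEMENTS,
):
    """Vectorised HI model over several elements.

    Expects draw keys ``C_<element>`` for each element plus ``BW``, ``ED``,
    ``SA``; returns the summed hazard index per iteration.
    """
    constants = constants if constants is not None else rm.default_constants(config.group)
    refs = refs if refs is not None else rm.default_toxicity()

    def model(draws: Mapping[str, np.ndarray]):
        receptor = _receptor_arrays(config.group, draws)
        total = 0.0
        for element in elements:
            doses = _route_doses(draws[f"C_{element}"], constants, receptor, config)
            for route, dose in doses.items():
                total = total + dose / refs[element].reference_for(route)
        return total

    return model
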