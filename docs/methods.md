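# Methods

## The risk chain

`pterisk` implements the standard USEPA-style chronic exposure chain for
elements bound to suspended particulates, for two receptor groups (children
4–12 y, adults 13–60 y, both resident ≥ 1 year):

1. **Average daily dose** per route. Ingestion:
   `ADD = C·IngR·CF·EF·ED/(BW·AT)`; inhalation:
   `ADD = C·InhR·EF·ED/(PEF·BW·AT)`; dermal:
   `ADD = C·SA·CF·SL·EF·ABS·ED/(BW·AT)`. All three are linear in the
   concentration, strictly decreasing in body weight, and pure arithmetic,
   so they broadcast over numpy arrays — the Monte Carlo layer evaluates
   the same functions vectorised, which is what makes the
   point-mass-equals-deterministic identity exact rather than approximate.
2. **Hazard**: `HQ = ADD/RfD` (oral, dermal) or `ADD/RfC` (inhalation);
   `HI = ΣHQ` over 7 elements × 3 routes, classified against 1.
3. **Cancer risk**: `CR = ADD·CSF` for the carcinogens As, Cr and Pb only;
   `TCR = ΣCR` classified as negligible (< 10⁻⁶), acceptable/low
   (10⁻⁶–10⁻⁴) or unacceptable (> 10⁻⁴). A CR above 1 is clamped with a
   warning — the slope-factor linearisation is not meaningful there.

Aggregation uses `math.fsum`, so HI/TCR equal the exact sum of their
addends to the last ulp.

### Parameters and defaults

All constants live in `src/pterisk/defaults.yaml` and are overridable per
run; nothing is hard-coded. Intake defaults: ingestion 100 (adult) / 200
(child) mg/d, inhalation 20 / 7.6 m³/d, skin adherence 0.07 / 0.2
mg·cm⁻²·h, EF 350 d/y, CF 10⁻⁶ kg/mg, PEF 1.36×10⁹ m³/kg, ABS 0.001. The
toxicity grid carries per-route RfD/RfC for all seven elements and slope
factors for As, Cr, Pb — including the unusually large Cr inhalation CSF
(41) and the Pb dermal CSF (0.42) exceeding its ingestion CSF; both are
kept verbatim in the editable config precisely because they are
surprising and a user may wish to substitute other derivations.

### Design choices where the convention is genuinely open

- **Inhalation concentration basis.** The dose equation divides by PEF,
  the dust-resuspension convention, which is only dimensionally coherent
  if C is a particulate-phase mg/kg concentration. That is the default
  ("dust" mode). An explicit "air" mode (C in mg/m³, no PEF) is provided
  for direct air measurements. The analysis drivers feed the numeric
  values of the µg/m³ panel to all three routes in dust mode — the
  practice the source workflow implies — and this dimensional looseness
  is a known limitation of the risk magnitudes (not of the identities or
  calibrations the tests check, which are unit-free).
- **Averaging time.** Residential averaging (`AT = ED×365`) is the
  default; ED then cancels in every route, which the test suite asserts
  to 10⁻¹² relative. Lifetime averaging (`AT = 70×365`, configurable) is
  selectable, and is what the sensitivity driver uses, since ED can only
  be an influential variable when it does not cancel.
- **Classification bands.** CR bands are < 10⁻⁶ / [10⁻⁶, 10⁻⁴] / > 10⁻⁴;
  HI is a *non*-carcinogenic screen.
- **Dermal time factor.** The dermal equation uses SL in mg·cm⁻²·h with
  no separate hours-per-event factor, exactly as conventional in this
  screening formulation.

## Concentration statistics

Measurements are long-format records (site, season, day, element, value,
censored) in µg/m³; a censored record stores its detection limit.
Below-detection-limit handling defaults to **exclude-with-flag** (groups
with no uncensored values print as BDL rather than a number), with
zero-substitution and half-limit substitution available. Summaries use the
sample (n−1) standard deviation, reporting 0 for singletons. Ranking is by
descending seasonal mean with alphabetical, warned tie-breaks and BDL
elements placed last and flagged. Standards screening is strict-`>` at the
limit; WHO metal guidelines are converted exactly from ng/m³ and carried
as annual-average values. The wet-vs-dry contrast uses a two-sided
Mann–Whitney rank-sum test (n = 42 values per season in the default
design; no normality assumption; Welch's t is available for comparison),
run on uncensored values only.

## Monte Carlo layer

`Y = h(X₁,…,Xₖ)` with independent inputs (no copula — a documented
limitation; concentration–behaviour correlations are not modelled). Input
families: point, uniform, normal, lognormal (median/GSD parameterisation),
triangular; truncation by rejection resampling with a bounded retry count
so an infeasible truncation fails loudly. All draws flow from one
`numpy.random.default_rng(seed)` in sorted-variable order, making results
bit-identical across reruns. Percentiles use linear interpolation between
order statistics (`numpy.percentile(..., method="linear")`), stated so
results are reproducible to the bit. Exceedance probabilities are strict
fractions above the 10⁻⁶ and 10⁻⁴ benchmarks.

Sensitivity is the spreadsheet-tool **contribution to variance**: per
input, Spearman ρ against the output (midrank ties), then signed shares
`sign(ρ)·ρ²/Σρ²·100`, so absolute shares sum to 100% whenever any ρ ≠ 0;
zero-variance inputs are reported as ρ = 0 with a "constant" flag. Routes
are summed per element before sensitivity (per-route output is available
via `per_route=True`). Body weight appears only in denominators, so its
share is structurally negative.

## Synthetic data

The generator emulates the study design, not the study's (undeposited)
data: 6 sites × 7 days × 2 seasons × (7 elements + TSP), values lognormal
around a seasonal median with a per-site multiplicative random effect
(log-sd 0.15), wet medians and dry/wet median ratios chosen once to echo
the published seasonal means (Zn dominant; dry ≫ wet for As/Cr/Cu/Pb/Zn;
Al reversed; Ni forced censored in the dry season, detection limit 0.5
µg/m³). The survey generator draws 317 respondents (35% children — the
published count fixes the total, not the split), body weight
truncated-normal (60±10 kg ≥ 35 adult; 25±6 kg ≥ 12 child), skin area
truncated-normal (5700±800 cm² adult; 2800±500 child), residence duration
uniform on [1, 30] y (adult) / [1, 12] y (child). The survey moments are
conventional exposure-handbook-style placeholders, since no survey
summaries were published — synthetic results therefore demonstrate that
the machinery is correct and calibrated, not that these specific risk
magnitudes hold in the field. Features of real data not emulated: spatial
dispersion structure, day-to-day autocorrelation, age–body-weight joint
distribution, measurement error.

`make_fixture_bundle` emits a deterministic ≤ 200-record miniature panel
plus a YAML manifest of brute-force-recomputed means, used as frozen
expected values in round-trip tests.

## Numerical and scale choices

Default simulations use 10,000 iterations (the convention for this kind of
assessment; the standard error of a mean shrinks as 1/√n, which the suite
verifies empirically over n ∈ {10², 10³, 10⁴} with 60 seeded replicates
per size). The degenerate-distribution identity is asserted at 10⁻¹²
relative; sum conservation at 10⁻⁹ absolute on percentage shares.
Degenerate inputs fail loudly: empty collections, zero body weight,
infeasible truncations, a zero dermal absorption fraction (allowed only
with an explicit override), and missing reference values raise typed
errors rather than propagating zeros.

## Known limitations

- The published per-receptor tables cannot be regenerated from the
  published concentration summaries alone (the survey BW/ED/SA values are
  unpublished), so the deterministic engine is validated against hand
  oracles, algebraic identities and the published *aggregation* identities
  (ΣHQ → HI, ΣCR → TCR), not against the per-cell table values.
- Dust-mode dosing of an air-concentration panel reuses numeric values
  across bases (above); absolute HI/TCR magnitudes from the synthetic
  pipeline are illustrative.
- Independence between Monte Carlo inputs; no spatial or temporal
  structure in exposure.
- The published seasonal summary table contains internal inconsistencies
  (a wet-season mean below its own minimum; a dry TSP maximum below its
  mean); this package computes statistics only from raw records and uses
  the printed means solely for ordering/screening cross-checks.
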