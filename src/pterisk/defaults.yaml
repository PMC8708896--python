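# Default constants for the multi-route exposure and risk model.
# Every value here can be overridden: load_defaults() returns a plain dict,
# and each constructor accepts explicit values.
#
# exposure: group-specific intake factors.
#   ingestion_rate   mg/day   incidental dust ingestion rate
#   inhalation_rate  m3/day   daily breathing volume
#   exposure_frequency  days/year
#   conversion_factor   kg/mg
#   particulate_emission_factor  m3/kg  (dust -> air conversion for inhalation)
#   dermal_absorption   unitless fraction
#   skin_adherence      mg/(cm2 h)  dust adherence to skin
exposure:
  adult:
    ingestion_rate: 100.0
    inhalation_rate: 20.0
    exposure_frequency: 350.0
    conversion_factor: 1.0e-6
    particulate_emission_factor: 1.36e+9
    dermal_absorption: 0.001
    skin_adherence: 0.07
  child:
    ingestion_rate: 200.0
    inhalation_rate: 7.6
    exposure_frequency: 350.0
    conversion_factor: 1.0e-6
    particulate_emission_factor: 1.36e+9
    dermal_absorption: 0.001
    skin_adherence: 0.2

# toxicity: per-element reference doses (mg/kg/day), inhalation reference
# concentration, and cancer slope factors ((mg/kg/day)^-1).  Slope factors are
# present only for the carcinogens As, Cr and Pb.
toxicity:
  Al: {rfd_dermal: 1.0e-1, rfd_ingestion: 4.0e-4, rfc_inhalation: 5.0e-3}
  As:
    rfd_dermal: 3.0e-4
    rfd_ingestion: 3.0e-4
    rfc_inhalation: 3.0e-4
    csf_ingestion: 1.5e-3
    csf_dermal: 1.5e-3
    csf_inhalation: 1.5e-3
  Cr:
    rfd_dermal: 6.0e-5
    rfd_ingestion: 3.0e-3
    rfc_inhalation: 8.0e-6
    csf_ingestion: 5.0e-1
    csf_dermal: 4.2e-1
    csf_inhalation: 41.0
  Cu: {rfd_dermal: 12.0, rfd_ingestion: 40.0, rfc_inhalation: 1.2e-4}
  Ni: {rfd_dermal: 5.4, rfd_ingestion: 20.0, rfc_inhalation: 1.4e-2}
  Pb:
    rfd_dermal: 5.2e-4
    rfd_ingestion: 3.5e-3
    rfc_inhalation: 5.2e-4
    csf_ingestion: 8.5e-3
    csf_dermal: 4.2e-1
    csf_inhalation: 4.2e-2
  Zn: {rfd_dermal: 60.0, rfd_ingestion: 3.0e-1, rfc_inhalation: 3.6e-4}

# standards: ambient air quality limits used for exceedance screening.
# All limits expressed in ug/m3 (WHO metal guidelines converted from ng/m3
# where applicable; they are annual-average guideline values).
standards:
  - {pollutant: TSP, authority: Indonesian, period: 24h, limit: 230.0}
  - {pollutant: TSP, authority: Indonesian, period: annual, limit: 90.0}
  - {pollutant: Pb, authority: Indonesian, period: 24h, limit: 2.0}
  - {pollutant: Pb, authority: Indonesian, period: annual, limit: 1.0}
  - {pollutant: TSP, authority: WHO, period: 24h, limit: 230.0}
  - {pollutant: TSP, authority: WHO, period: annual, limit: 90.0}
  - {pollutant: As, authority: WHO, period: annual, limit: 0.0066}
  - {pollutant: Cr, authority: WHO, period: annual, limit: 0.001}
  - {pollutant: Ni, authority: WHO, period: annual, limit: 0.025}
  - {pollutant: Pb, authority: WHO, period: annual, limit: 0.5}
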