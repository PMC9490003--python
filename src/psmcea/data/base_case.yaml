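# Base-case inputs: first-line nivolumab+cabozantinib vs sunitinib for
# advanced renal cell carcinoma, Chinese healthcare-system perspective.
# All costs in US$ (January-2022 rate, 6.3746 RMB/US$); times in months
# unless named otherwise.
schema: 1

settings:
  cycle_days: 42.0
  horizon_years: 20.0
  annual_discount: 0.05
  eval_point: end          # start | mid (half-cycle correction) | end
  discounting: annual      # annual (end-of-year steps) | continuous

wtp_threshold_usd_per_qaly: 38024.0
exchange_rate_rmb_per_usd: 6.3746
patient: {weight_kg: 65.0, bsa_m2: 1.72}

pricing:
  # whole_unit: whole vials per infusion / one listed-price tablet per dosing
  # day (reproduces the published scenario arithmetic); per_mg: exact per-mg
  # billing with no wastage.
  mode: whole_unit
  multiplier_targets: [nivolumab, cabozantinib]

conventions:
  ici_max_months: 24.0     # immune checkpoint inhibitors capped at 2 years
  ae_cost_mode: sum        # sum | mean of per-event management costs
  ae_timing: one_time      # one_time | first_cycle QALY decrement
  followup_in_pd: true     # follow-up/management accrue in PD as well as PFS
  psa_sd_rule: interval95  # interval95: SD=(high-low)/(2*1.96) | fraction20

# units_per_cycle encodes schedule x pricing mode:
#   nivolumab 240 mg q2w (3 infusions/cycle): 3x3 100-mg vials vs 3x2.4 per-mg
#   cabozantinib 40 mg/day x42: one 60-mg unit/day vs 28 per-mg equivalents
#   pembrolizumab 200 mg q3w (2 infusions): 2x2 100-mg vials either way
#   sunitinib 50 mg/day, 4 weeks on / 2 off: 1 tablet/dosing day vs 4x12.5 mg
#   axitinib 5 mg bid x42: 1 tablet/day vs 2x5 mg
#   pazopanib 800 mg/day x42: 1 tablet/day vs 2x400 mg
drugs:
  nivolumab:
    unit: 100 mg vial
    unit_cost: {base: 1451.07, low: 1160.85, high: 1741.28, distribution: gamma}
    ici: true
    units_per_cycle: {whole_unit: 9.0, per_mg: 7.2}
  cabozantinib:
    unit: 60 mg tablet
    unit_cost: {base: 491.30, low: 393.04, high: 589.56, distribution: gamma}
    ici: false
    units_per_cycle: {whole_unit: 42.0, per_mg: 28.0}
  pembrolizumab:
    unit: 100 mg vial
    unit_cost: {base: 2810.84, low: 2248.67, high: 3373.01, distribution: gamma}
    ici: true
    units_per_cycle: {whole_unit: 4.0, per_mg: 4.0}
  sunitinib:
    unit: tablet
    unit_cost: {base: 15.37, low: 12.29, high: 18.44, distribution: gamma}
    ici: false
    units_per_cycle: {whole_unit: 28.0, per_mg: 112.0}
  axitinib:
    unit: tablet
    unit_cost: {base: 30.85, low: 24.67, high: 37.02, distribution: gamma}
    ici: false
    units_per_cycle: {whole_unit: 42.0, per_mg: 84.0}
  pazopanib:
    unit: tablet
    unit_cost: {base: 25.10, low: 20.08, high: 30.12, distribution: gamma}
    ici: false
    units_per_cycle: {whole_unit: 42.0, per_mg: 84.0}

costs:
  followup_per_cycle: {base: 72.48, low: 57.98, high: 86.97, distribution: gamma}
  management_per_cycle: {base: 46.43, low: 37.15, high: 55.72, distribution: gamma}
  supportive_per_cycle: {base: 315.18, low: 282.0, high: 423.0, distribution: gamma}
  terminal_care: {base: 1893.0, low: 946.5, high: 2839.5, distribution: gamma}

adverse_event_costs:
  diarrhea: {base: 43.30, low: 34.64, high: 51.96, distribution: gamma}
  hypertension: {base: 12.61, low: 10.09, high: 15.14, distribution: gamma}
  alt_elevation: {base: 25.09, low: 20.07, high: 30.12, distribution: gamma}
  proteinuria: {base: 121.65, low: 97.32, high: 145.98, distribution: gamma}
  palmar_plantar: {base: 102.21, low: 81.77, high: 122.65, distribution: gamma}

utilities:
  pfs_nivo_cabo: {base: 0.82, low: 0.73, high: 0.90, distribution: beta}
  pfs_sunitinib: {base: 0.73, low: 0.657, high: 0.803, distribution: beta}
  # published range printed inverted (0.726 low, 0.594 high); normalized here
  pd: {base: 0.66, low: 0.594, high: 0.726, distribution: beta}
  ae_disutility: {base: 0.157, low: 0.127, high: 0.188, distribution: beta}

probabilities:
  subsequent_nivo_cabo: {base: 0.86, low: 0.77, high: 0.94, distribution: beta}
  subsequent_sunitinib: {base: 0.73, low: 0.66, high: 0.80, distribution: beta}
  ae_risk_sunitinib: {base: 0.75, low: 0.602, high: 0.903, distribution: beta}
  ae_risk_nivo_cabo: {base: 0.71, low: 0.564, high: 0.847, distribution: beta}

discount_rate: {base: 0.05, low: 0.0, high: 0.08, distribution: fixed}

survival:
  sunitinib:
    pfs:
      family: log_logistic
      params: {shape: 1.6417, scale: 8.4452}
      se: {shape: 0.0976, scale: 0.5531}
      aic: 1316.0
    os:
      family: log_normal
      params: {meanlog: 3.6682, sdlog: 1.6679}
      se: {meanlog: 0.1574, sdlog: 0.1349}
      aic: 1316.0
  nivo_cabo:
    pfs:
      # NOTE: implies median PFS ~8.5 months, inconsistent with the trial's
      # reported 16.6-month median; used as published, surfaced in fit reports
      family: log_normal
      params: {meanlog: 2.1406, sdlog: 1.0623}
      se: {meanlog: 0.0686, sdlog: 0.0569}
      aic: 709.0
    os:
      family: log_normal
      params: {meanlog: 4.1874, sdlog: 1.5868}
      se: {meanlog: 0.2046, sdlog: 0.1603}
      aic: 958.0

arms:
  sunitinib:
    first_line: [sunitinib]
    utility: pfs_sunitinib
    ae_risk: ae_risk_sunitinib
    subsequent_proportion: subsequent_sunitinib
    subsequent_mix: {nivolumab: 0.5, pembrolizumab: 0.5}
  nivo_cabo:
    first_line: [nivolumab, cabozantinib]
    utility: pfs_nivo_cabo
    ae_risk: ae_risk_nivo_cabo
    subsequent_proportion: subsequent_nivo_cabo
    subsequent_mix:
      axitinib: 0.333333333333333
      sunitinib: 0.333333333333333
      pazopanib: 0.333333333333334

scenarios:
  horizons_years: [5.0, 10.0, 15.0, 20.0]
  price_multipliers: [0.25, 0.5, 0.75, 1.0]
  os_families: [mixture_cure, nonmixture_cure, royston_parmar]

simulation:
  n_per_arm: 320
  accrual_months: 12.0
  cutoff_months: 24.0
  dropout_rate_per_month: 0.005
  digitize_grid_months: 0.5
  digitize_jitter: 0.005
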