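# Methods

## Model structure

A standard three-state partitioned survival model (PSM): progression-free
(PFS), progressed disease (PD), dead. Occupancy is read off the survival
curves at each cycle rather than derived from transition probabilities;
`p_PFS = min(S_PFS, S_OS)` clamps curve crossings (standard PSM practice —
extrapolated parametric curves can cross even when the underlying KM curves
do not), `p_dead = 1 - S_OS`, and PD is the remainder. Patients cannot
return from PD to PFS, and death is absorbing.

Time runs in months (30.4375 days) over 6-week (42-day) cycles; the default
horizon is 20 years (174 cycles, the last truncated at the horizon). Costs,
life-years and QALYs are all discounted at 5% per year.

## Survival inputs and extrapolation

The default configuration carries the published fitted parameters:

| arm | endpoint | family | parameters |
|---|---|---|---|
| sunitinib | PFS | log-logistic | shape 1.6417, scale 8.4452 |
| sunitinib | OS  | log-normal   | meanlog 3.6682, sdlog 1.6679 |
| NI+CA | PFS | log-normal | meanlog 2.1406, sdlog 1.0623 |
| NI+CA | OS  | log-normal | meanlog 4.1874, sdlog 1.5868 |

The log-logistic uses the median-scale form `S(t) = 1/(1+(t/scale)^shape)`,
which makes the printed scale (8.4452) reproduce the trial's 8.3-month
sunitinib median PFS and fixes the time unit as months. The NI+CA OS curve
reproduces the trial's 85.7% 12-month OS to three decimals, which validates
the parameterization end to end.

**A known inconsistency in the inputs.** The printed NI+CA PFS log-normal
implies a median PFS of exp(2.1406) ~ 8.5 months, but the trial reports a
16.6-month median, and back-solving the published one-way-sensitivity ICERs
implies a discounted PFS duration near 2 years — consistent with the longer
curve. This package implements the printed parameters as published. The
consequence is predictable and is visible in the acceptance outputs: all
base-case and price-scenario quantities land within ~1–10% of the published
values, while the two quantities most sensitive to NI+CA's PFS duration —
the 5-year-horizon ICER and the upper one-way-sensitivity ICER — deviate by
~15–20% and cannot be matched from the printed inputs.

The fitting machinery (used for the reconstruction path and the scenario-3
robustness models) maximizes the right-censored likelihood
`sum_events ln f(t) + sum_censored ln S(t)` on an unconstrained scale (log
for positive parameters, logit for cure fractions), Nelder-Mead followed by
a BFGS polish, with standard errors from the numerically evaluated observed
information matrix. Initialization is deterministic (method of moments on
log event times; cure fraction 0.2; spline started at the exponential
special case), so fits are reproducible. The Royston-Parmar model places a
restricted cubic spline on ln H(t) against ln t with two internal knots at
the 33rd/67th percentiles of uncensored log event times and boundary knots
at the extremes; cure models wrap a Weibull base by default. Generalized
gamma uses the Prentice (mu, sigma, Q) form with the log-normal as the
Q -> 0 limit. Model selection is minimum AIC, ties broken by BIC and then
by a fixed family order.

## Conventions calibrated against the published results

The source publication does not state where within a cycle occupancy is
evaluated, how discounting is timed, how vials/tablets are priced, or which
drugs make up the subsequent-treatment mixes. These were fixed by a
calibration principle: *the published scenario table itself identifies the
conventions*, because the sunitinib-arm totals under the price-reduction
scenarios step down linearly with the nivolumab price. Solving that
arithmetic pins the discounted nivolumab cost embedded in the sunitinib arm
(~US$23.6k) and the nivolumab+cabozantinib cost in the NI+CA arm (~US$273k),
which is reproduced by the following defaults (each remains a config switch):

- **Cycle evaluation at cycle end, no half-cycle correction**
  (`settings.eval_point`), and **discrete end-of-year discounting**,
  `DF = (1+r)^(-ceil(t_years))` (`settings.discounting`). The continuous /
  half-cycle alternative leaves the NI+CA life-years 13% above the published
  value; the discrete convention lands all four LY/QALY cells within 10%.
- **Whole-unit drug pricing** (`pricing.mode: whole_unit`): nivolumab
  240 mg q2w = 3 x 100 mg vials per infusion, three infusions per cycle;
  pembrolizumab 200 mg q3w = 2 vials; cabozantinib 40 mg/day = one 60 mg
  unit per day; oral TKIs (sunitinib 50 mg/day 4-on/2-off, axitinib 5 mg
  bid, pazopanib 800 mg/day) at one listed-price tablet per dosing day.
  Exact per-mg billing (`per_mg`, e.g. sunitinib as 4 x 12.5 mg tablets) is
  retained as the alternative but under-predicts the published drug-cost
  steps by 15–25%.
- **Immune checkpoint inhibitors capped at 24 months of model time** in
  both treatment lines (`conventions.ici_max_months`). A per-patient cap
  timed from progression would need tunnel states the PSM deliberately
  avoids; the model-time cap reproduces the published sunitinib-arm price
  steps to within ~8%.
- **Subsequent treatment**: 73% of progressed sunitinib-arm patients
  receive PD-1 inhibitors (half nivolumab, half pembrolizumab); 86% of
  progressed NI+CA patients receive VEGFR TKIs (equal thirds axitinib /
  sunitinib / pazopanib); the remainder receive best supportive care
  (US$315.18/cycle). Subsequent treatment and supportive care accrue while
  in PD until death (no stated stopping rule), subject to the ICI cap.
- **Follow-up (US$72.48) and management (US$46.43) per cycle accrue in both
  alive states** (`conventions.followup_in_pd`); **adverse-event management
  is a one-time cost** (aggregate grade>=3 risk x the sum of the five
  printed per-event costs) at treatment start, and the AE disutility is a
  one-time QALY decrement there too (`conventions.ae_timing`; a
  first-cycle-duration alternative is provided). Terminal care (US$1,893)
  is charged against each cycle's incremental death probability.

Patient weight (65 kg) and body surface area (1.72 m^2) are carried in the
configuration for completeness but unused: every regimen here is flat-dosed.

## Sensitivity analysis

One-way analysis re-evaluates the ICER at each parameter's published bounds
(costs +/-20%, utilities and AE risks +/-10%, discount rate 0–8%); rows are
sorted by ICER spread. The printed PD-utility range is inverted in the
source table and is normalized (0.594, 0.726) on load.

The PSA draws all parameters jointly and independently: gamma for costs,
beta for utilities/probabilities (moment-matched), discount fixed. The
published table gives ranges but no SDs; the default rule treats the range
as a 95% interval, SD = (high - low)/3.92 (`conventions.psa_sd_rule`;
SD = 20% of mean is the alternative). 5,000 iterations take ~1 s. The CEAC
reports the fraction of draws with positive net monetary benefit over a
US$0–600k grid. Because the deterministic ICER here (~US$283k) sits ~3%
below the published US$292,945, the CEAC at US$300k lands near 0.70 rather
than the published 0.60; at US$38,024, 100k and 500k it reproduces the
published ~0 / ~0 / ~0.95–1.0 anchors.

## Pseudo-IPD reconstruction

`reconstruct_ipd` implements the Guyot interval algorithm: events explain
the digitized survival drops through the product-limit relation, censorings
(assumed uniform within each number-at-risk interval) account for the
residual risk-table loss, and the censor count per interval is found by
bisection on the implied number at risk. Digitizer jitter up to 0.02 in the
survival coordinate is absorbed by an isotonic clamp; larger rises are
rejected as corrupt input. When the risk table ends before the curve does,
remaining patients are censored at the last digitized time. Round-trip
accuracy (KM of reconstruction vs digitized input) is below 0.02 sup-norm at
trial size (n = 320/arm, 0.5-month digitization grid, +/-0.005 jitter).

## Synthetic trial generator

`simulate_trial` draws event times from the configured true curves with a
shared uniform per subject (comonotone coupling, PFS truncated at OS so
PFS <= OS holds record-wise), staggered entry over a 12-month accrual
window, administrative cutoff at 24 months (matching the trial's ~18-month
median follow-up), and exponential dropout at 0.5%/month — a typical
phase-III attrition rate; none of these values is tuned to any output. The
generator reproduces its generating curves (KM sup-deviation < 0.03 at
n = 5,000) and its exports feed the reconstruction and fitting stages.

What it does **not** emulate: informative censoring, covariate
heterogeneity, treatment switching/crossover, or digitization biases beyond
uniform jitter. Tests passing on these fixtures therefore validate the
machinery, not the clinical generalizability of the inputs.

## Scenario 3 (alternative OS models)

The published cure/spline parameters were never printed, so these scenarios
refit mixture-cure, non-mixture-cure and Royston-Parmar models to
reconstructed or synthetic IPD (both arms refitted). Their results are
checked as properties — valid survival functions, cure-fraction plateaus,
QALY <= LY, finite ICERs — not as published values: fits to 24-month
follow-up leave the cure fraction weakly identified, so extrapolated totals
are fixture-dependent by construction.

## Numerical choices and limitations

- Quadrature (`restricted_mean`) is the independent oracle for the engine's
  cycle sums; the two agree to < 0.5 cycle under matching conventions.
- Survival values are clipped to [0,1]; Gompertz with negative shape
  plateaus at exp(rate/shape); underflow clips to 0.
- The non-mixture cure form `S = pi^F0` degenerates at pi = 0 (S -> 0, not
  the base family) and is rejected there; the mixture form at pi = 0
  reproduces its base family exactly.
- ICERs are computed from unrounded increments; a zero incremental effect
  is flagged (dominant/dominated/equivalent) instead of divided.
- The model is near-linear in costs and utilities given the survival
  curves, which is why PSA means sit within Monte-Carlo error of the base
  case; correlation between parameters is not modeled.
- Currency is US$ throughout; the RMB conversion (6.3746) is metadata only.
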