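# Methods

This note records the modelling conventions, numerical choices, and the
deliberate scope limits of `phenoproc`. It is the reference for anyone
auditing the package's behaviour; the README covers usage.

## Daily axis and driver window

All models evaluate one enclosure-year on a daily axis running from 1
September of the previous calendar year through 31 December of the focal
year. Day-of-year (DOY) is 1-based in the focal year; previous-year days
carry non-positive indices (31 Dec = 0, 1 Sep = −121). Chilling start dates
(`t0_chill`) are therefore typically negative. Accumulation start dates are
clipped into the window.

`DriverSeries` holds one enclosure-year (air temperature, soil temperature
at 0–200 cm, water-table depth, CO₂, daylength, VPD). `DriverStack` aligns
many series on the intersection of their axes as 2-D arrays so a model
evaluates every enclosure-year in one vectorised pass — this is what makes
annealing budgets of 10⁶ objective evaluations affordable.

Daylength uses solar declination δ = −23.44°·cos(2π(doy+10)/365) and the
sunset hour angle at solar elevation −0.83° (civil daylength with
refraction and solar-disc radius). VPD uses the Tetens saturation pressure,
e_sat = 0.6108·exp(17.27 T/(T+237.3)) kPa, times (1 − RH/100).

## Spring models (19)

Rate functions:

- linear forcing: R_f(T) = max(T − T_base, 0)
- sigmoidal forcing: R_f(T) = 1/(1 + exp(−b_f (T − c_f)))
- triangular chilling: 0 outside (T_min, T_max), 1 at T_opt, linear flanks
- bell chilling: R_c(T) = 1/(1 + exp(a_c ΔT² + b_c ΔT)), ΔT = T − c_c
- photoperiod multipliers: L/24 (PTT) and (L/10)^k (M1)

Model families, each predicting the first day an accumulation crosses its
requirement (sentinel −9999 when never crossed):

- `LIN` (k=2): linear regression of DOY on mean temperature over DOY 1–120.
- `TT`, `TTs`, `PTT`, `PTTs`, `M1`, `M1s` (k=3–5): forcing-only, with the
  linear or sigmoidal response, optionally photoperiod-weighted.
- `AT` (k=5): forcing requirement a + b·exp(c·N_chill) declines with the
  running count of days below T_base.
- `SQ`, `SQb`, `SM1`, `SM1b` (k=8–9): sequential — chilling (triangular or
  bell) must reach C_star before forcing counts; forcing starts at the later
  of the release day and `t0`, and pre-release forcing is discarded.
- `PA`, `PAb`, `PM1`, `PM1b` (k=9–10): parallel — forcing is weighted by
  K(t) = min(1, (C_ini + C(t))/C_star) while chilling accumulates. `C_ini`
  (chill state carried into the window) is what distinguishes the
  parameter count from the sequential family.
- `UM1` (k=9): unified — requirement w·exp(−z·C(t)) decays with accumulated
  bell chilling; forcing is sigmoidal and photoperiod-weighted.
- `SGSI`, `AGSI` (k=9): growing-season index — product of clamped ramps in
  temperature, VPD (inverted: high deficit suppresses) and photoperiod
  (raised to k). SGSI thresholds its 21-day moving average (zero-padded at
  the window edges); AGSI accumulates the daily index from `t0`.

Triangular-chilling parameter vectors violating T_min < T_opt < T_max
return the sentinel for every series during optimisation (the standalone
rate function raises `ValueError`).

## Autumn models (10)

Cold-degree accumulation from `t0` (or the solstice) to a requirement
F_star:

- `CDD`: R(T) = max(T_base − T, 0); `CDDs`: sigmoidal
  1/(1 + exp(b_s (T − c_s))).
- `CDDP`: linear cold rate × night fraction (1 − L/24).
- `CDDM`: linear cold rate × water-table weight max(1 + m·W, 0).
- `PPM`: daylength deficit max(L_crit − L, 0) × water-table weight,
  accumulated from the focal-year daylength maximum.

Each has a CO₂ variant (`CDDCO2`, …) replacing the requirement with
F_eff = max(F_star − c_co2·max(CO₂_gs − 400, 0), 0.05·F_star), where
CO₂_gs is the enclosure's growing-season (DOY 120–280) mean. Elevated CO₂
therefore lowers the cold forcing needed, advancing senescence; the 5%
floor keeps the requirement positive.

## Calibration and model selection

Objective: RMSE between observed and predicted dates, with sentinel
predictions replaced by a penalty (9999) before squaring so infeasible
parameter vectors are dominated, never NaN.

Engine: generalized simulated annealing
(`scipy.optimize.dual_annealing`, `no_local_search=True`) with documented
fixed defaults (initial_temp 5230, visit 2.62, accept −5) inside uniform
per-parameter bounds shipped in `phenoproc/data/parameter_bounds.yaml`.
Default budget: 25 independent chains × 40,000 objective evaluations.
Chains draw sub-seeds from `numpy.random.SeedSequence(seed).spawn`, so runs
are reproducible and chain results are independent of execution order; the
reported fit is the chain with the lowest AIC.

Model comparison uses the sum-of-squares AIC = 2k + n·ln(SSE/n) (natural
log), with SSE floored at 10⁻⁸ (with a warning) for perfect fits. ΔAIC
support classes: < 2 essentially equivalent, 2–10 little support, ≥ 10 no
support. `rank_models` refuses to compare fits made against different
observation sets.

The driver-depth scan refits one model with identical seeds across
temperature channels (air, each soil depth); channels absent from the data
are reported as unavailable rather than failing the scan.

## Transition extraction

1. Drop snow-flagged days (snow shifts greenness toward blue-white).
2. Composite the 90th percentile of Gcc over a centred 3-day window on a
   continuous daily axis; empty window positions are linearly interpolated.
3. Threshold at baseline + 0.25 × amplitude (curve minimum and range).
4. Spring: first upward crossing between the pre-peak minimum and the peak.
   Autumn: last downward crossing between the peak and the post-peak
   minimum. Crossings are linearly interpolated between bracketing days.
5. A curve that never crosses returns `None` — a distinguishable
   no-transition outcome, not an error.

Confidence bounds shift the curve by ± one residual SD (daily Gcc about the
composite) and re-extract; this is a heuristic interval because greenness
noise maps to date uncertainty through the local slope.

## Sensitivity statistics

Per functional type and season: a linear mixed-effects model
DOY ~ ΔT × CO₂ with a random intercept per year, fitted by maximum
likelihood for backward elimination (drop the interaction, then the CO₂
main effect, when Wald p ≥ 0.05) and refitted by REML for the reported
estimates. ΔT is the measured warming differential (days per °C); CO₂ is a
0/1 indicator. Optimiser: BFGS with a Powell fallback for boundary fits
(zero year variance). Per-year ordinary regressions and the season
extension (autumn slope − spring slope) complement the mixed model.

## Synthetic experiment generator

Design: 10 enclosures at five nominal warming levels (0, 2.25, 4.5, 6.75,
9 °C; one ambient-CO₂ and one +500 ppm enclosure per level), five years,
47.5° N, mean annual temperature 3.4 °C.

- Air temperature: seasonal sinusoid (amplitude 15.5 °C, coldest DOY 15)
  plus AR(1) noise (ρ = 0.7, innovation SD 3 °C) shared by all enclosures,
  plus the enclosure's warming offset. Shared weather makes the mean
  temperature difference between enclosures exactly their offset
  difference.
- Soil temperature: exponential moving average of air with depth-increasing
  damping (α = 1/(1.25 + depth/8 cm)), relaxing toward the enclosure's mean
  annual temperature.
- Water table: seasonal drawdown curve plus AR(1) noise, deepened by
  0.4 cm/°C of warming.
- CO₂: 400 ppm, +500 during DOY 120–280 in elevated enclosures.
- Transition dates: either from a mixed-effects structure (fixed
  temperature/CO₂/interaction effects, shared year effects of SD 3 d,
  residual noise whose SD is derived from the generating slope's standard
  error via SE ≈ σ/(sd(ΔT)·√n)), or by running a named process model
  forward (`EXAMPLE_TRUTHS` supplies ground-truth parameter vectors) plus
  Gaussian observation noise.
- Greenness: double logistic placing the 25%-amplitude crossings exactly at
  the supplied dates (s1 = spring + τ·ln 3 for the rising limb), with
  optional noise and snow depression/flags.

Everything is reproducible bit-for-bit from (config, seed); sub-streams are
derived with `SeedSequence([seed, salt])` so drivers, dates and greenness
are independently reproducible.

### The sequential ground truth

`EXAMPLE_TRUTHS["SM1"]` places the triangular chilling band at roughly
0–6 °C effective with C_star = 35. At a site whose deep winter sits near
−12 °C, control enclosures then complete chilling slowly and erratically in
the shoulder seasons, while warmed enclosures chill readily in mid-winter:
chilling release, not spring forcing, sets much of the date variance. This
is the "strong chilling signal" regime in which the sequential structure is
statistically identifiable against thermal-time models; with a chilling
band comfortably inside every enclosure's winter the release date stops
binding and TT fits sequential data to the noise floor.

### Deliberate omissions

The generator captures the statistical structure a sensitivity analysis
needs, not bog physics. Not represented: microtopography (hummock/hollow),
snowpack dynamics and snow-vegetation interactions, enclosure wall effects
and within-enclosure gradients, humidity and cloud responses to warming,
CO₂ fertilisation feedbacks on greenness amplitude, observation gaps and
camera artefacts (beyond optional noise/snow flags), and leap days — all
years are 365 days.

Leap days also shape the IO boundary: when a 365-day synthetic series falls
in a leap focal year, `write_driver_table` maps its dates to the real
calendar minus 29 February, so consecutive focal-year windows in one table
stay mutually consistent, and reading the table back interpolates the
missing day as an ordinary 1-day gap. Real (non-synthetic) leap-year data
with 366-day axes are written date-faithfully.

## Acceptance protocol

- Coefficient recovery (t1–t8): 20 replicate experiments per target,
  refitting the generating fixed-effect structure; the mean recovered
  coefficient must fall within ±2 reported SE of the generating value.
- Identifiability: SM1-generated data fitted by {TT, SM1} at 5 chains ×
  2,000 evaluations must prefer SM1 (ΔAIC ≥ 2) in ≥ 8/10 replicates, and
  TT-generated data must not penalise TT; likewise CDDCO₂ vs CDD with
  c_co2 > 0 and c_co2 = 0 truths.
- Every model matches an independently coded day-by-day accumulation oracle
  exactly on random traces.
- The AIC formula, ΔAIC classes, extraction closed form and invariances,
  the air-vs-soil depth scan, and an end-to-end smoke run complete the
  suite (see `tests/test_acceptance.py`).
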