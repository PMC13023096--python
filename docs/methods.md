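# Methods

## Model structure and assumptions

`stemboost` is a discrete-time Markov cohort model with seven states:
CAR_T, NEUTROPENIA (prolonged, >30 days), INFECTION (severe), RECOVERY,
RELAPSE, and two cause-split absorbing death states (DEATH_INFECTION,
DEATH_RELAPSE). Cycles are monthly; the default horizon is 96 cycles
(8 years) for a cohort of 10,000 patients. Death is split by cause purely
for event accounting — overall survival merges the two states.

Structural choices, made once and fixed:

- **CAR_T resolves in the first cycle**: a patient either enters prolonged
  neutropenia (probability 0.26) or moves directly to recovery. This makes
  the expected severe-infection count exactly
  `n x p_neutropenia x p_infection|neutropenia` when the neutropenia row
  has no residual mass, which is what the base-case event counts assume.
- **NEUTROPENIA carries residual "stay" mass** `1 − p_infect − p_recover`.
  It is exactly 0 at base case (0.25 + 0.75) but positive for stress-test
  draws such as (0.15, 0.60), where patients can remain neutropenic for
  multiple cycles. If a sampled pair sums to more than 1, the pair is
  rescaled proportionally; this renormalization is opt-in
  (`build_transition_matrix(..., renormalize=True)`) so that ordinary
  parameterization errors still fail loudly.
- **INFECTION resolves in one cycle**: death with the 12.5% case fatality,
  otherwise recovery. 12.5% is the midpoint of the 10–15% range reported
  for infection-related mortality and the value that makes ~50 averted
  deaths arithmetically consistent with 390 averted infections.
- **No retreatment pathway**: relapse leads only to continued relapse or
  relapse-related death; a second CAR T course is out of scope.
- **No half-cycle correction**: counters are event counts (expected inflows
  into a state, excluding self-loops), not person-time, so the usual
  half-cycle argument does not apply. Expected counts are kept fractional;
  rounding happens only at the display layer.

## Parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| p_neutropenia | 0.26 | /first cycle | grade 3–4 prolonged neutropenia rate in the CAR T trial arm |
| p_infection_given_neutropenia | 0.25 (no boost) / 0.10 (boost) | /cycle | derived from trial infection rates; boost value from the stem-cell boost case series |
| p_recovery_given_neutropenia | 0.75 / 0.90 | /cycle | complements of the above at base case |
| p_infection_death | 0.125 | per episode | midpoint of the 10–15% infection-mortality range |
| p_relapse_monthly | 0.023 | /month | constant-hazard conversion of 75.9% 12-month PFS |
| p_relapse_death_monthly | 0.03 | /month | published base-case value (see calibration note) |
| hospitalization_cost_usd | 64,012 | USD/admission | inpatient cost of neutropenic infection, inflation-adjusted |
| reserve_collection_cost_usd | 17,918 | USD/patient | collection + storage of an extra CD34+ reserve, charged universally in the boost arm |

Costs are undiscounted and not inflation-adjusted inside the model (the
inputs are already expressed in current dollars); there is no QALY weighting
— the outputs are event counts and dollars.

## Constant-hazard conversion and calibration

`survival_to_monthly_prob(S, t) = 1 − S**(1/t)` converts a survival
fraction over `t` months to a per-month probability; compounding
`(1 − p)**t` recovers `S` to 1e-12. The CI endpoints of the 12-month PFS
(69.4%, 81.1%) map to 3.0%/month and 1.7%/month.

`calibrate_relapse_mortality` bisects on the relapse-death probability
(tolerance 1e-6 on the probability scale, at most 60 iterations; the
OS-vs-probability map is monotone and each evaluation is a cheap 12–24
cycle cohort run) until the model's overall survival at a target month
matches a target. Infeasible targets — outside the OS bracket attained at
probabilities 1 and 0 — raise an error reporting the bracket.

**Known inconsistency, reported rather than patched.** With monthly relapse
risk 0.023 and relapse mortality 0.03/month, the model's 12-month OS is
≈0.961: first-year relapse exposure is far too short to produce ~16%
cumulative mortality. Matching an 84% 12-month OS requires ≈0.28/month.
The stated pairing of 3%/month with 84% OS therefore cannot hold under this
state structure. The base case retains 3%/month for fidelity to the stated
inputs; the calibration utility computes and reports the true root and a
`matches_printed_base_case` flag, and the full report carries both numbers.
Because relapse is modeled identically in both arms, this affects absolute
survival levels, not any between-arm comparison.

## Microsimulation

`simulate_patients` realizes the same chain per patient: a single
user-supplied seed spawns one `numpy.random.SeedSequence` substream per
patient, whose uniforms are pre-drawn so propagation is vectorized and
results are bit-reproducible and independent of iteration order. Because
neutropenia can only be entered from CAR_T and relapse only from recovery,
each patient experiences at most one infection and one relapse, so event
flags equal event counts. Trajectory storage is optional; aggregates are
always produced.

What the stochastic generator emulates — and does not: it reproduces the
*model's* sampling variability (binomial noise around cohort expectations,
e.g. SE ≈ 25 infections at n = 10,000 in the no-boost arm), which is what
the agreement tests exercise. It inherits all structural simplifications of
the model itself: no covariates (age, CAR-HEMATOTOX score, prior lines), no
time-varying hazards, no repeat infections, no tunnel states for
neutropenia duration. Passing tests therefore validate internal
consistency of the two engines, not fidelity to any patient-level dataset.

## Sensitivity analyses

- **One-way (tornado)**: each parameter group varied over its grid with all
  else at base case — complementary neutropenia splits (no-boost infection
  0.20/0.25/0.30; boost 0.05/0.10/0.15), hospitalization cost
  $60,000–$68,000, reserve cost $16,000–$20,000. Results sort descending by
  absolute incremental-cost range, ties alphabetical. Under these grids the
  widest swings come from the reserve cost ($4,000) and the two infection
  splits ($1,664.31 each), with hospitalization cost ($312) last; the
  received claim that hospitalization cost is a top-two driver is carried
  as an annotation in the report, not asserted.
- **Probabilistic stress test**: 500 draws (configurable), each sampling
  all six parameters independently and uniformly over the stress ranges
  (no-boost recovery 0.60–0.85, infection 0.15–0.35; boost recovery
  0.80–1.00, infection 0.00–0.20; hospitalization $50k–$70k; reserve
  $14k–$22k). Uniform-independent sampling is a declared choice: the ranges
  come with no stated distribution, and independence plus proportional
  renormalization of over-full neutropenia rows is the least-assumption
  reading. The maximum achievable per-patient hospitalization saving over
  these ranges (≈0.26 × 0.37 × $70,000 ≈ $6,700) never reaches the minimum
  reserve charge ($14,000), so the incremental cost is positive in every
  draw — comfortably above the 95% robustness threshold.
- **Key-driver regression**: OLS (statsmodels) of cost savings (no-boost
  minus boost, the dependent-variable convention used throughout) on the
  six sampled parameters, reporting raw and standardized
  (`β·σx/σy`) coefficients ranked by absolute standardized size.
  Zero-variance columns are dropped with a logged warning; an all-constant
  design is refused. Analytic slopes under the zero-residual structure:
  +0.039 savings per hospitalization dollar, −1 per reserve dollar.

## Numerical choices

- Matrix validation: row sums within 1e-12, entries in [0, 1], death rows
  exact unit vectors. Cohort mass conservation asserted each cycle at 1e-6
  relative tolerance.
- Neutropenia-pair renormalization tolerance 1e-9; within it, small
  floating excesses are clipped into the "stay" mass.
- Currency held as floats in USD, rounded to cents only in reports.
- Reports serialize with sorted keys and no timestamps, so identical
  configurations produce byte-identical JSON.

## Problem sizes

The default configuration is the full study size — 10,000 patients,
96 cycles, 500 stress draws — because the deterministic engine is a
96-step, 7-state matrix recursion and the whole pipeline completes in
seconds. Tests that exercise the microsimulation use 10,000 patients for
the agreement checks and smaller cohorts (200–5,000) for trajectory
invariants; the convergence check contrasts n = 1,000 with n = 100,000.

## Limitations

- Costs cover only infection hospitalizations and reserve collection; ICU
  stays, transfusions, growth factors, and CRS/ICANS management are
  excluded, which biases against the boost strategy.
- The reserve charge is universal; targeting collection to high-risk
  patients (or patients with already-stored cells) would lower the boost
  arm's cost and is not modeled.
- Transition probabilities are time-homogeneous; real post-CAR T hazards
  decay over months.
- The relapse parameterization uses PFS, which bundles progression with
  death from any cause and slightly overstates relapse risk.
- The OS calibration inconsistency above means absolute survival output
  should not be read as a trial emulation.
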