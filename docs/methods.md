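# Methods

This note documents the model implemented in `bxk`: its equations,
parameter defaults and units, the numerical choices, what the synthetic
cohort generator does and does not emulate, and the design decisions
taken where the problem was genuinely open.

## 1. Blast dose and mechanical damage

The dose input is the peak blast overpressure (BOP, psi) of each
exposure event. A training schedule is converted to an event timeline
in one of two modes:

* `daily_aggregate` (default): one event per training day at the
  midpoint of the 6-h window, carrying the day's average BOP. This
  matches how training datasets report exposure (a daily average), and
  is the mode used everywhere unless stated.
* `per_shot`: the day's shots spread uniformly across the window, each
  at the day's average BOP — retained for sensitivity studies only.

Mechanical damage R_M (dimensionless) obeys

    dR_M/dt = s(t) − k (R_M − λ(t)),     k = α / t_d

with α = 1 (dimensionless) and t_d = 5 h by default, i.e. a relaxation
rate of 0.2 h⁻¹. The residual damage λ is a threshold map of the dose:
λ = c_λ · max(0, BOP − θ) with θ = 4 (non-dimensional, proportional to
4 psi) and c_λ = 0.25 psi⁻¹, so an 8-psi blast leaves λ = 1 (25 % of
threshold). When several events have occurred, the λ in force is the
running maximum over past events: chronic damage does not resolve
within the study window. Exceedance (rather than absolute BOP) scaling
keeps λ continuous at the threshold.

No equation governs the sub-second rise of R_M, only its observed
scale: peak damage on the order of 500 ms after the blast. We model
each event as a first-order source pulse s(t) = A e^{−(t−t_e)/τ_r}.
For this source the response is a double exponential peaking at
t_p = ln(a/k)/(a − k), a = 1/τ_r; the default τ_r = 0.0383 s places
t_p at 0.5 s for the default k, and A is normalized per event so the
peak increment equals `dose_scale · BOP` (dose_scale = 1 psi⁻¹: peak
R_M numerically equals the BOP in psi, consistent with a threshold of
4 ↔ 4 psi). `bxk.damage.rise_tau_for_peak` re-solves τ_r if the decay
rate is changed.

Because the R_M equation is linear, its exact solution (superposed
pulse responses plus piecewise relaxation toward λ) is available as
`DamageSystem.rm_closed_form` and serves as an oracle for the
integrators.

## 2. Biological responses

Hyperacute (R_B1) and acute (R_B2) response phases follow the damage:

    dR_B1/dt = k_in R_M − k_out1 R_B1 / (R_M + R_M0)
    dR_B2/dt = k_out1 R_B1 − k_out2 R_B2

Defaults: k_in = 1.0 h⁻¹, k_out1 = 0.5 h⁻¹, k_out2 = 0.1 h⁻¹,
R_M0 = 1 (basal mechanical repair). The divisor (R_M + R_M0) makes
R_B1 clearance slow while damage is high — recovery is prolonged after
heavy exposure, which is the window-of-vulnerability picture. An
alternative reading places the whole difference over (R_M + R_M0);
both share the same fixed points (R_B1* = k_in λ (λ + R_M0)/k_out1,
R_B2* = k_out1 R_B1*/k_out2), which is what the steady-state tests
pin down. With the chosen form and defaults, R_B1 peaks a few hours
after a large exposure and R_B2 lags it, keeping the two phases
ordered; both decay overnight once R_M has relaxed.

Additivity of repeated exposure requires no special logic: the state
is continuous across events, so a second blast inside the recovery
window stacks on the unresolved remnant of the first, and blasts far
apart (with λ = 0) reproduce identical peaks.

## 3. Whole-body Aβ42 kinetics

Brain APP synthesis is amplified by the hyperacute response:

    k_APP(t) = k_APP0 · (1 + x · R_B1(t)),   x = 1.5 by default.

Which phase drives synthesis is configurable (`pbpk.rb_drive`:
`rb1` | `rb2` | `sum`); R_B1 is the default and the analyzed choice.
The amyloidogenic pathway is APP →(BACE1, 0.4 h⁻¹) sAPPβ + C99
→(γ-secretase, 1.2 h⁻¹) Aβ + AICD, with a fraction f_42 = 0.10 of the
Aβ flux produced as Aβ42 and released into the brain interstitial
fluid. Peripheral tissue synthesizes APP at f_per = 0.10 of the brain
rate (in amount), unmodulated by blast unless
`pbpk.modulate_peripheral` is set. BACE1/γ-secretase activities are
constants; their possible blast dependence is an open experimental
question and not modeled. Byproducts (sAPPβ, AICD, sBACE1) and a
parallel Aβ40 species can be tracked behind config flags; they are
inert bookkeeping and are off by default.

Aβ42 moves among six compartments — brain ISF, brain vascular,
perivascular (glymphatic) space, central plasma, peripheral tissue,
lymph — through:

* transporters at the BBB: LRP1 (0.4 h⁻¹) + P-gP (0.1 h⁻¹) efflux
  ISF→vascular, RAGE (0.05 h⁻¹) influx vascular→ISF; first-order by
  default, with an optional Michaelis form (`saturable_transport`,
  K_m = 1000 pg/mL) off by default because no K_m is established;
* bidirectional BBB fluid exchange F_BBB = 5 mL/h;
* glymphatic flux F_gly = 20 mL/h, ISF → perivascular → lymph;
* plasma/tissue flows Q_br = 21 L/h and Q_per = 160 L/h with lymph
  drainage L_br = 10 mL/h, L_per = 120 mL/h returning to plasma.

Volumes (70-kg male, order-of-magnitude physiology): ISF 250 mL, brain
vascular 60 mL, perivascular 30 mL, plasma 3000 mL, peripheral tissue
36 L, lymph 1000 mL. First-order degradation: plasma 0.35 h⁻¹
(≈ 2-h half-life), peripheral 0.3 h⁻¹, ISF 0.1 h⁻¹, lymph 0.05 h⁻¹.
Serum is identified with the plasma compartment (no serum/plasma
partition coefficient is applied).

Every inter-compartment term is built pairwise — an amount flux leaves
one compartment and enters another scaled by the receiving volume — so
the transport subsystem conserves Aβ42 mass by construction; the test
suite checks volume-weighted column sums exactly and total mass over
100 h to 1e-8 relative.

**Absolute calibration.** The baseline synthesis rate k_APP0 is
auto-scaled so baseline plasma Aβ42 equals 20 pg/mL (a typical
literature magnitude). All scored outputs are normalized per subject,
and the PBPK block is linear, so this absolute anchor cancels exactly:
when transport is linear the simulator integrates at a canonical
synthesis scale and rescales the raw output, making normalized series
invariant to k_APP0 to machine precision rather than merely to
integrator tolerance. With the shipped rate constants the *normalized*
response amplitude to a supra-threshold day is considerably larger
than the ±20 % swings typical of real serum data; absolute response
calibration would need the original rate constants, which are not
published, and does not affect any normalized or self-consistency
result.

## 4. Simulation

Damage and PBPK states form one state vector (one-way coupling
R_B1 → k_APP), integrated with LSODA at rtol = 1e-8 and an absolute
tolerance of 1e-10 scaled by the state magnitude. The integrator stops
and restarts at each blast event (state carried over continuously) and
bounds the step inside a 2-s post-event window to resolve the
millisecond rise without a globally tiny step. Output lands on a dense
grid (0.1 h) plus exactly the draw times; the normalized series
divides by the value at the first draw, which must precede the first
blast, so its first entry is exactly 1. A fixed-step RK4 run at
dt = 1e-3 h on a smooth 48-h scenario agrees with the adaptive path to
1e-4 relative (the pulse itself is checked against the closed form
instead, since no fixed 1e-3-h step can resolve a 0.04-s rise).

The default draw placement uses the study-average offsets (2.48 h
before training start, 1.40 h after training end, 6-h training days
starting at 09:00); per-day offsets can be supplied.

## 5. Calibration

The only free parameter by default is the amplification constant x,
shared across all subjects, bounded in [0, 10], fit by least squares
on normalized concentrations (the first draw is excluded — its
residual is identically zero). Since R_M, R_B1, R_B2 do not depend on
x, the PBPK block is linear, and the normalization baseline is x-free,
the normalized prediction is exactly affine in x:
pred(t; x) = 1 + x·u(t), with u obtained from one simulation per
subject at x = 1. The default fit therefore solves a one-dimensional
linear least-squares problem in closed form — exact, deterministic and
cheap. Any other free parameter (dotted config names, e.g.
`damage.k_in`) routes to a seeded multistart L-BFGS-B over the same
objective; the two paths agree on x-only problems, which is tested.
If no draw carries any blast response (blast-free cohort), x is not
identifiable and `fit()` raises `NonIdentifiableError` rather than
returning an arbitrary value.

## 6. Validation statistics

* Signed relative percent error 100·(pred − obs)/obs on normalized
  concentrations; positive = over-approximation.
* Cohort summary: mean and SD of |error| over all scored entries;
  population SD by default, sample SD reported alongside (both round
  identically on the packaged table).
* Pre/post contrast: per subject, mean |error| over the two
  pre-training draws (days 2–3) vs the three post-training draws;
  exact two-sided Wilcoxon signed-rank via a generating-function
  convolution over doubled ranks — identical to enumerating all 2^n
  sign assignments (verified against literal enumeration for n ≤ 12),
  with average ranks for ties and zero differences dropped.
* Over-approximation: fraction of strictly positive pre-training
  errors (a zero entry counts as not over-approximated), reported as
  an exact rational and a float.
* Demographics: OLS of per-subject mean pre-training |error| on age
  and on service years; R² is the scored quantity, slope and Pearson r
  are reported for transparency. A constant response is defined to
  have R² = 0; a constant covariate is an error.

The packaged `table1.csv` holds the 15-subject, five-draw error table
with demographics; `validation_report` recomputes mean ≈ 6.5 %,
SD ≈ 5.2 %, exact p ≈ 0.0067, 24/30 = 80 % over-approximated, and
R² < 0.1 for both covariates from it at run time.

## 7. Synthetic cohorts

`generate_cohort` draws, per subject and per day: average BOP
~ U(3, 8) psi (bracketing the 4-psi threshold; the true per-subject
doses are unpublished, so this range is a stand-in, not a claim about
the study data), shots ~ integer U[4, 50], pre-draw offset
~ U(2.1, 3.16) h, post-draw offset ~ U(0.48, 2.90) h, age ~ U[33, 52]
and service years ~ U[8, 26], all from one seeded generator.
Demographics are independent of exposure by design, so demographic
regressions on synthetic data have a known near-zero truth. Noise-free
truth comes from `predict_serum`; observations multiply the truth at
draw times by mean-one lognormal noise with CV 5 % (a typical
immunoassay figure; configurable). Determinism is byte-level: the same
design, seed and config reproduce identical CSV exports, and a
provenance JSON records the design, seed and a config hash.

What the generator does *not* emulate: assay batch effects, diurnal
Aβ rhythms, inter-subject physiological variability (all subjects
share one parameter set), sleep/stress effects on clearance, and any
dependence of baseline Aβ42 on age. Passing recovery tests on these
cohorts therefore demonstrates self-consistency of the estimation
machinery under the stated noise model — not that the model explains
real serum data beyond what the packaged error table encodes.

## 8. Problem sizes and determinism

The shipped tests and the acceptance script use the study-scale design
throughout: 15 subjects × 3 days for calibration checks (50 replicates
for the noise-recovery distribution), millisecond grids over 2 s for
pulse timing, 100–300 h windows for conservation and recovery checks.
Every stochastic path takes an explicit seed; fits are bitwise
reproducible for a fixed seed.

## 9. Known limitations

* The exact functional forms of the damage/response equations and all
  rate constants of the original compartment model are not published;
  the forms above are documented interpretations and the constants are
  config defaults, so absolute (un-normalized) predictions are not
  calibrated.
* One parameter set for all subjects; no person-specific modifiers
  (age, weight, APOE4, exposure history, sleep).
* BBB permeability is not itself blast-dependent; aggregation,
  antibody complexes and microglial clearance are out of scope.
* Aβ40 is implemented structurally but not validated against any
  target.
* The Wilcoxon enumeration is exact up to n = 25 pairs; beyond that
  the convolution remains exact but memory grows quadratically.
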