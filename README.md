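# bxk — blast-dose biomarker kinetics of serum Aβ42

`bxk` is a mechanistic model of how serum amyloid-β 42 (Aβ42) responds to
repeated low-level blast overpressure (BOP) exposure, of the kind service
members experience during heavy-weapons training. It is aimed at
researchers in blast-induced traumatic brain injury (bTBI) who want to
relate recorded blast doses (psi, shots per day, training schedules) to
blood-biomarker time courses, calibrate the blast→biomarker coupling
against serum draws, and score model accuracy the way biomarker
validation studies report it.

## The model

Three coupled layers, integrated as one ODE system on the study clock:

1. **Blast dose → mechanical damage.** Each blast event injects a short
   source pulse so the dimensionless mechanical damage R_M peaks ≈ 500 ms
   after the event with amplitude proportional to the peak overpressure,
   then relaxes:

   dR_M/dt = s(t) − (α/t_d) (R_M − λ)

   Below a non-dimensional injury threshold (4, proportional to 4 psi)
   the residual damage λ is zero and recovery is complete; above it
   λ grows linearly with the exceedance, leaving chronic damage.
   Repeated blasts inside the recovery window are additive: the second
   peak rides on the unresolved remnant of the first.

2. **Damage → biological response.** Hyperacute (R_B1) and acute (R_B2)
   response phases follow the damage:

   dR_B1/dt = k_in R_M − k_out1 R_B1 / (R_M + R_M0)
   dR_B2/dt = k_out1 R_B1 − k_out2 R_B2

3. **Response → serum Aβ42 (PBPK).** R_B1 amplifies brain APP synthesis,
   k_APP = k_APP0 (1 + x·R_B1); APP is cleaved by BACE1 (→ sAPPβ + C99)
   and γ-secretase (→ Aβ + AICD), and Aβ42 moves through a whole-body
   physiologically based pharmacokinetic model — brain ISF, brain
   vascular, perivascular/glymphatic, plasma, peripheral tissue and
   lymph compartments, with LRP1/P-gP efflux, RAGE influx, BBB fluid
   exchange, glymphatic flux and plasma/lymph flows.

Predicted serum traces are normalized to each subject's first
pre-training draw, so the single calibrated quantity is the
amplification constant **x**, shared across subjects. Because the PBPK
block is linear in concentrations, the normalized prediction is exactly
affine in x and the cohort fit reduces to a closed-form least-squares
problem (a bounded multistart optimizer handles any other free
parameter).

The validation layer mirrors how such a study scores itself: signed
relative percent errors per draw, cohort mean ± SD of |error|, an exact
two-tailed Wilcoxon signed-rank contrast of pre- vs post-training
accuracy (full enumeration of the sign-flip null, average ranks for
ties), the fraction of pre-training draws over-approximated, and R² of
error against age and years of service. A packaged 15-subject error
table ships with the package and `bxk validate-table1` recomputes its
summary statistics.

## Worked example

Generate a synthetic three-day training cohort (15 subjects, daily
average BOPs of 3–8 psi, 5 % assay noise) and recover the amplification
constant from it:

```python
from bxk import BlastDoseModel, CohortDesign, ModelConfig, generate_cohort

config = ModelConfig()  # defaults: x = 1.5, threshold 4 psi
cohort = generate_cohort(CohortDesign(noise_cv=0.05, seed=1), config)
model = BlastDoseModel.from_cohort(cohort, config)
results = model.fit()
print(results.summary())
```

```
Blast-dose BxK model calibration
================================================
subjects:          15
scored draws:      75
method:            linear least squares (exact, x-affine structure)
converged:         True
objective (SSE):   21.921
------------------------------------------------
x                  1.5216   bounds [0, 10]
------------------------------------------------
RMS residual (normalized conc.): 0.5406
```

The cohort was generated with x = 1.5; the fit recovers 1.52 under 5 %
multiplicative measurement noise. `results.validation_report()` then
scores the fitted predictions the same way the study table is scored
(mean |error|, exact Wilcoxon pre/post p-value, over-approximation
fraction, R² against demographics), and `results.plot_fit()` overlays
fitted serum traces on the observed draws.

The same pipeline is scriptable from the shell:

```sh
bxk generate-cohort --seed 1 --out cohort/
bxk calibrate --exposures cohort/exposures.csv --serum cohort/serum.csv \
    --seed 1 --out calibration.json
bxk validate-table1 --out report.json
```

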