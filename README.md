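# cd4traj

Nonlinear mixed-effects modelling of CD4+ cell-count recovery after
antiretroviral therapy (ART) initiation, for epidemiologists and
biostatisticians analysing longitudinal HIV treatment-programme data.

After a patient starts ART, their CD4+ count (cells/mm³) rises from a
depleted baseline toward a long-term plateau. `cd4traj` fits the
three-parameter asymptotic curve

    log CD4_ij = Asym_j − (Asym_j − Int_j) · exp(−c_j · t_ij) + ε_ij

where, for patient *j*, `Int` is the log count at initiation, `Asym` the
log of the plateau, and `c` the approach rate (1/year, summarised
clinically as the half-life of the log-scale gain, `t50 = 12·ln2/c`
months). Each parameter carries a fixed effect — constant, sex, age
stratum, or age-by-sex — and a patient-level random effect; the three
random effects are jointly normal with unstructured covariance, and
observation noise is log-normal. The 4³ = 64 candidate fixed-effect
structures are compared by AIC. The marginal likelihood is evaluated
near-exactly by integrating the (Int, Asym) pair in closed form
conditional on the rate effect and applying adaptive Gauss-Hermite
quadrature to the remaining one-dimensional integral (see
`docs/methods.md`).

The package also ships a calibrated synthetic-cohort simulator (the
national treatment database the analysis design targets is not public), the
study's eligibility filters and descriptive tables, and a simulation study
showing that per-patient asymptotic fits often fail to converge on noisy,
sparse data even when the truth is asymptotic.

## Worked example

```python
import cd4traj as c

cohort = c.generate_cohort(c.default_published_config(n_patients=500, seed=7))
res = c.CD4TrajectoryModel(cohort, structure=c.PUBLISHED_BEST).fit()
print(res.summary())
```

prints (abridged):

```
structure: age_sex/age_sex/age    patients: 500    visits: 3398
logLik: -3727.04    AIC: 7518.07    k: 32    converged: True

Fixed effects (log scale)
----------------------------------------------------------------------
  intercept[female:19-29]         4.6654  (se 0.1264)  exp:    106.2
  intercept[male:19-29]           4.5632  (se 0.3364)  exp:     95.9
  asymptote[female:19-29]         5.9842  (se 0.0763)  exp:    397.1
  asymptote[male:19-29]           5.8648  (se 0.1630)  exp:    352.4
  log_rate[19-29]                 0.5598  (se 0.1736)  exp:      1.8
  ...

Random effects (patient level)
----------------------------------------------------------------------
  sd(intercept) 0.865   sd(asymptote) 0.525   sd(log_rate) 0.801
  corr(Int,Asym) 0.434   corr(Asym,logc) -0.637   corr(Int,logc) -0.043
  residual sd (log CD4): 0.593
```

The exponentiated coefficients are group-level CD4 counts: women aged
19–29 in this synthetic cohort start at ~106 cells/mm³ (generating value
107) and plateau near 397 (generating value 377); the patient-level SDs
and correlations recover the generating heterogeneity (0.90 / 0.51 / 0.74,
corr +0.40 and −0.60) within single-cohort sampling error. Derived
clinical quantities and group contrasts:

```python
ratio, lo, hi = res.fold_change("intercept", ("female", "19-29"), ("male", "19-29"))
# 1.11 (95% CI 0.55-2.24) on this 500-patient cohort

res.derived_table().head(1)
#    sex age_group  initial_cd4  asymptotic_cd4  t50_months  t90_months  time_to_gain_50_months
# female     19-29        106.2           397.1         4.8        15.8                     2.4
```

A command-line pipeline wraps the same functions:

```sh
cd4traj simulate --n 1000 --seed 1 --out cohort.csv
cd4traj describe cohort.csv
cd4traj fit cohort.csv --out fit.json
cd4traj select cohort.csv --grid reduced     # AIC sweep (use --grid full for all 64)
cd4traj convergence-study --n 2000 --seed 1 --out report.json
```

## Acceptance script

`scripts/acceptance.py` re-runs the parameter-recovery experiment from
scratch: it simulates 10 independent cohorts of 1,000 patients at the
package's default population values, fits the best-supported model
structure to each, and writes the across-replicate means of the recovered
group-level quantities (asymptotic count and half-life for the youngest
stratum, random-effect SDs and correlations, residual SD) as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It takes roughly 15 minutes on one CPU.
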