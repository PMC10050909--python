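# tbpopk

Population pharmacokinetics of the first-line antitubercular drugs
**rifampicin, isoniazid and pyrazinamide** in hospitalized HIV-associated
TB patients and TB outpatients.

Hospitalized TB/HIV patients die early and often despite treatment, and
critical illness (delayed gastric emptying, impaired gut barrier, altered
hepatic function) could plausibly lower their drug exposure.  This package
implements, as reusable and tested code, the nonlinear mixed-effects (NLME)
analysis that compared the pharmacokinetics of the three bactericidal
first-line drugs between outpatients, hospitalized survivors and
hospitalized patients who died within 12 weeks: the three final population
models, the estimation machinery needed to fit them, a synthetic-cohort
generator emulating the study design (so no patient data are required),
simulation-based diagnostics, and the derived exposure metrics.  It is
aimed at pharmacometricians who want to re-examine, extend or power future
studies against these models.

## The models

All three drugs: transit-compartment absorption — a chain of *n* transit
compartments (12/8/4 for RIF/INH/PZA) with rate k_tr = (n+1)/MTT feeding a
depot that empties at rate k_a into a 1-compartment (RIF, PZA) or
2-compartment (INH) disposition model; mean absorption time
MAT = MTT + 1/k_a.  Clearances scale with fat-free mass^0.75 and volumes
with FFM^1 (reference 43 kg).  Random effects are log-normal:
between-subject variability (BSV) on CL, between-occasion variability
(BOV) on F, k_a and MTT (two occasions: the pre-dose sample belongs to the
previous day's dose).  Residual error is proportional + additive with the
additive part floored at 20% of the LLOQ; sub-LLOQ samples are handled by
Beal's M6 rule.  Drug-specific structure:

* rifampicin — hospitalized groups absorb more slowly through a single
  effect θ on (k_a, 1/MTT); conjugated bilirubin lowers CL through
  CL·(BRC/6)^β (biliary competition), β ≈ −0.333;
* isoniazid — two-component clearance mixture standing in for the NAT2
  acetylator phenotype (fast fraction ≈ 64.5%, CL 25.5 vs 9.76 L/h),
  peripheral volume via Vratio = Vc/Vp with a weakly informative prior;
* pyrazinamide — BSV-CL inflated 1.70× / 3.56× in hospitalized
  survivors / deaths.

Estimation is Laplace/FOCE-class with η–ε interaction: vectorized inner
Newton optimization of each subject's random effects, exact-curvature
Laplace for reported objective values, adaptive Gauss–Hermite quadrature as
an internal cross-check, χ² likelihood-ratio covariate testing, VPC and
nonparametric bootstrap.  See `docs/methods.md` for the full account.

## Worked example

Simulate the full study design (108 subjects: 48 outpatients,
49 hospitalized survivors, 11 hospitalized deaths) from the final
rifampicin model and refit it:

```python
from tbpopk import (CohortSpec, generate_cohort, simulate_trial, preprocess,
                    PopPKModel, final_model, default_params)

struct = final_model("rifampicin")
truth = default_params("rifampicin")
trial = simulate_trial(struct, truth,
                       generate_cohort(CohortSpec(), "rifampicin", seed=42),
                       seed=43)
model = PopPKModel(preprocess(trial.cohort), struct)
res = model.fit()
print(res.summary())
```

```
Population PK fit: rifampicin (1-compartment, 12 transit compartments)
subjects: 108   observations: 642
OFV: 2055.962   converged: True (27 outer iterations)

  parameter estimate unit shrinkage [%]
         cl    9.018
          v    64.78
         ka    1.424
        mtt    0.418
 theta_surv   0.6698
theta_death    0.539
   beta_brc  -0.3669
   omega_cl       39    %           4.9
      bov_f    23.02    %          39.5
     bov_ka    112.3    %          35.6
    bov_mtt    95.51    %          49.9
 sigma_prop    20.62    %              
```

The typical clearance (9.02 L/h at 43 kg fat-free mass) recovers the
generating value 8.82 L/h within sampling error; `theta_surv = 0.67` means
hospitalized survivors' mean absorption time is 1/0.67 ≈ 1.5× the
outpatient MAT of MTT + 1/ka ≈ 1.1 h; `beta_brc = −0.37` is the recovered
bilirubin exponent (truth −0.333).  Variability rows are log-scale
SD × 100 with their η-shrinkage — the high BOV shrinkage reflects six
samples around a single dose, as expected for this design.

Model-derived individual exposures:

```python
exp = res.derive_exposure()
print(exp.groupby("group")[["auc_0_24", "cmax"]].median().round(1))
```

```
               auc_0_24  cmax
group
hosp_death         73.9   6.6
hosp_survivor      48.9   5.9
outpatient         61.1   6.6
```

AUC0–24h (mg·h/L, as F·Dose/CL) is similar across groups while the peak is
slightly lower in hospitalized survivors — the slower-absorption,
similar-exposure pattern the models encode.  83 of 108 subjects sit below
the 8 mg/L rifampicin Cmax reference threshold.

A thin CLI wraps the same functions:

```
tbpopk simulate --model rifampicin_final --n 48,49,11 --seed 1 --out trial.csv
tbpopk fit --model rifampicin_final --data trial.csv --out fit.json
tbpopk vpc --model rifampicin_final --data trial.csv --fit fit.json --nsim 1000
tbpopk bootstrap --model rifampicin_final --data trial.csv --n 500 --seed 7
tbpopk exposures --model rifampicin_final --data trial.csv --fit fit.json
```

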