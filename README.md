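# warfarin-pkpd

Steady-state warfarin PK-PD modelling and anticoagulation analytics.

Warfarin dosing is individualized by monitoring the prothrombin-time
international normalized ratio (PT-INR), but the pharmacokinetic
parameters that drive a patient's dose-response — peak concentration
*C*<sub>max</sub>, elimination rate *k*, clearance *CL* and volume of
distribution *V*<sub>d</sub> — are rarely measured directly. This
package back-predicts them from routine clinic records (visit dates,
INR values, doses) the way Bayesian-feedback therapeutic drug
monitoring does, and computes the anticoagulation-quality indices used
to characterize control: warfarin sensitivity index (WSI), Rosendaal
time-in-therapeutic-range (TTR) with the NICE good/poor threshold,
log-INR variability, the warfarin composite measure (WCM), and
predicted liver weight. It is aimed at clinical-pharmacology and
biostatistics researchers studying anticoagulation quality in cohorts.

## Model

The steady-state model links a maintenance regimen (dose *D* mg every
*τ* hours) to INR through the power-law PD transform

```
f(INR) = b·INR^p − a,          a = 3.36,  b = 4.368,  p = 0.383
```

and the steady-state PK expression for the reciprocal response

```
1/f = −(m·CL/V_d)/k² · (1 − (kτ/24)/(1 − e^(−kτ/24)))
      − (m/k) · ln[ (D/V_d) / (C_max·(1 − e^(−(CL/V_d)·τ/24))) ]
```

with *k* in day⁻¹, *CL* in L/day and *m* a dimensionless PD slope
(default 1). The closed-form dose equation is the exact algebraic
inverse, so `dose_for_target_inr` and `steady_state_inr` round-trip to
1e-8 relative error.

Individual parameters are recovered by MAP estimation — penalized
nonlinear least squares on the transformed-INR scale with independent
normal population priors (*C*<sub>max</sub> 5.8 ± 0.4 mg/L, *k*
1.0 ± 0.1 day⁻¹, *CL* 2.1 ± 0.2 L/day, *V*<sub>d</sub> 7.6 ± 0.2 L)
and residual SD 0.1, optimized by bounded L-BFGS-B with multi-start.
A synthetic cohort generator draws patients from those same population
distributions, titrates doses with the model, and adds 5 % lognormal
INR observation noise, so the whole chain is testable end to end.
See `docs/methods.md` for assumptions and design choices.

## Worked example

```python
from warfarin_pkpd import PKParameters, DoseRegimen, dose_for_target_inr, steady_state_inr

p = PKParameters(c_max=5.8, k=1.0, cl=2.1, v_d=7.6)
dose = dose_for_target_inr(p, target_inr=2.5, tau=24.0)
print(round(dose, 2), round(steady_state_inr(p, DoseRegimen(dose, 24.0)), 2))
```

prints `8.79 2.5`: a patient with population-average kinetics needs
about 8.8 mg once daily to sit at INR 2.5 at steady state, and the
forward model maps that dose straight back to the target.

The numbered drivers under `analysis/` run the full study on a
simulated cohort:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_fit_parameters.py
python analysis/03_anticoag_metrics.py
python analysis/04_cohort_report.py
```

`02_fit_parameters.py` prints the parameter-recovery table, e.g.

```
parameter  truth_mean  estimate_mean  mean_rel_bias   rmse  rel_err_of_means
    c_max      5.7672         5.7622         0.0022 0.3274           -0.0009
        k      0.9967         0.9976         0.0074 0.0842            0.0009
       cl      2.0711         2.0677         0.0022 0.1195           -0.0016
      v_d      7.5898         7.6001         0.0020 0.1976            0.0014
```

meaning the cohort means of the MAP estimates recover the generating
population means to within a few tenths of a percent under 5 % INR
noise. `04_cohort_report.py` writes the report bundle (`summary.tsv`,
`outliers_<param>.tsv`, `comparisons.tsv`, `correlations.tsv`,
`report.json`) with per-parameter ±1.96 SD outlier counts,
Mann-Whitney/chi-square group comparisons and Pearson correlations.

The same stages are exposed as a CLI:
`warfarin-pkpd simulate|fit|metrics|report|run --seed 42 --out results`.

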