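# Methods

## The steady-state dose–INR model

The package models warfarin maintenance therapy at steady state only:
no time-course simulation, no enantiomer-specific kinetics. The
pharmacodynamic link is a fixed power-law transform
`f(INR) = 4.368·INR^0.383 − 3.36`, strictly increasing on INR > 0 with
root at INR ≈ 0.504, so `f` and its inverse are bijections between the
physiologic INR range and the transformed response. The pharmacokinetic
part expresses the *reciprocal* transformed response `1/f` as a linear
function of `ln(Dose)` for fixed parameters:

```
1/f = A(k, CL/V_d) − (m/k)·ln( D / [V_d·C_max·(1 − e^(−(CL/V_d)·τ/24))] )
A   = −(m·CL/V_d)/k² · (1 − x/(1 − e^(−x))),   x = k·τ/24
```

Units: the dosing interval τ is stored in hours and every occurrence of
τ/24 converts it to days, which is the only reading consistent with k in
day⁻¹ and CL in L/day. The default regimen is once-daily (τ = 24 h).

Two anomalies of the source model are handled explicitly:

* The concentration equation (`steady_state_cs`) is textually identical
  to the INR equation, so the package implements it as an alias rather
  than inventing a separate concentration formula.
* The PD slope `m` has no published value. It defaults to 1.0. Because
  the generator and the estimator share `m`, all round-trip and
  recovery properties hold for any positive `m`; only the absolute
  scale of fitted parameters against external data would depend on it.

Valid domain: for given parameters, INR is strictly increasing in dose
on a finite window; at the upper end `1/f → 0` (predicted INR diverges)
and beyond it `f + a ≤ 0`. Domain errors name the failing
sub-expression (`ln-argument`, `reciprocal`, `transform-offset`,
`singular-target`) so the fitter can penalize invalid proposals instead
of crashing.

## MAP estimation

Individual parameters θ = (C_max, k, CL, V_d) are recovered by
maximizing the posterior under independent normal priors and additive
normal residuals on the transformed-INR scale, i.e. minimizing

```
J(θ) = Σ_j [f(INR_obs,j) − f_pred,j(θ)]²/σ_res² + Σ_p (θ_p − μ_p)²/σ_p²
```

subject to θ > 0 (L-BFGS-B box bounds at 1e-6). Working on the `f`
scale is the natural choice here: the model is linear in `1/f`, and the
transform keeps residuals approximately homoscedastic across the
therapeutic range. Defaults: σ_res = 0.1; priors are the population
distributions (C_max 5.8/0.4, k 1.0/0.1, CL 2.1/0.2, V_d 7.6/0.2).
Multi-start from the prior mean and mean ± 1 SD guards against the flat
invalid region; the best objective wins, with a successful start
preferred when objectives tie (a start placed exactly at the optimum
can fail its first line search while a neighbouring start converges to
the same point).

**Identifiability.** With all visits at a common τ, the data determine
`m/k` (slope in ln D) and one intercept combining CL/V_d and
V_d·C_max — two functionals for four parameters. C_max and V_d
therefore sit on a ridge that the prior resolves; with sparse dosing
variation even k shrinks toward its prior mean. Consequences:

* Cohort means of MAP estimates recover the generating population
  means tightly (shrinkage is toward those same means), which is what
  the recovery experiment measures.
* Correlations among *estimated* parameters partly reflect the
  estimator's ridge geometry rather than population structure: on
  synthetic cohorts with independently drawn truths, estimated C_max
  and CL are strongly correlated because both move along the
  identifiable combination. Correlation analyses on fitted parameters
  should be read with this in mind.
* The optional finite-difference Hessian condition number on
  `IndividualFit` quantifies this per patient.

A zero-noise closed-loop check requires care for the same reason: at
zero noise the truth has zero data misfit but non-zero prior penalty
under a population prior, so the MAP point is *not* the truth. The
closed-loop test therefore centres the prior on each patient's own
truth, making the truth the exact global optimum; it verifies that the
generator and estimator implement the same model with no transcription
drift, not that sparse data identify four parameters.

Visits with INR outside (0.5, 10) or dose outside (0.5, 20] mg are
excluded before fitting as a physiologic plausibility screen and
logged; `last_n` restricts fitting to the most recent visits.

## Anticoagulation indices

* **WSI** = INR at the final visit divided by the dose (mg) recorded at
  that visit. "Last dose" is read as the per-administration dose at the
  final visit, not a weekly total.
* **TTR** uses Rosendaal linear interpolation between consecutive
  visits; gaps longer than 56 days are dropped from numerator and
  denominator (configurable), the standard convention for sparse
  follow-up. Default range [2.0, 3.0]; [2.5, 3.5] selectable for valve
  indications. TTR = 65.0 % classifies as good (≥ threshold).
* **INR variability**: per consecutive pair,
  `v_i = (ΔINR)²/Δt · mean(INR_i, INR_{i+1})`; pairs are averaged
  *before* the square root (mean → sqrt → log10) — the aggregation
  order across multiple pairs is a package choice. A patient with no
  INR change gets σ = 0 and a flagged −inf log value; such patients are
  excluded from WCM standardization rather than propagating −inf into
  Z-scores.
* **WCM** = z(log-INR variability) − z(TTR) with cohort-sample
  Z-scores (ddof = 1), so higher WCM = worse control (more variable,
  less time in range). The sign/combination convention is ambiguous in
  the source material; the additive convention is selectable via
  configuration. Cohort mean WCM is 0 by construction.
* **Liver weight** [g] = 218 + 12.3·weight[kg] + 51·[male].

## Cohort analysis

Outlier classification fits a normal band per PK parameter from the
cohort itself and flags values outside mean ± 1.96 SD. The uniform
two-sided rule is the default for all four parameters; `z` and `sided`
overrides allow one-sided variants. Group comparisons use the two-sided
Mann-Whitney U test for numeric variables and Pearson chi-square
without continuity correction for categorical ones; no multiple-testing
correction is applied to the primary p-values, but a Holm-adjusted
column is emitted alongside. Pearson correlations are computed for the
default pair set (C_max against CL, V_d, k; CL and V_d against liver
weight). Age strata for the stratified summary are <65 / 65–74 / 75–84 /
≥85 years (configurable; the boundaries are a package choice).

## Synthetic cohort generator

The generator emulates the study population: 220 patients; age
66.6 ± 13.4 y (truncated at 18), body weight 75.2 ± 18.1 kg (truncated
at 35), half male, interacting-drug prevalence 61.8 %; true PK
parameters from truncated-at-zero normals with the population
means/SDs above (lognormal selectable; at these small CVs the families
are nearly indistinguishable). Each patient gets 8 visits with
inter-visit gaps U(20, 40) days (total follow-up ≈ 200–280 days), a
target INR drawn U(2, 3) and redrawn between visits with probability
0.3, the model's exact dose for that target rounded to 0.5 mg, and an
observed INR equal to the model INR times `exp(N(0, 0.05))` noise
(5 % CV).

The dose-retargeting is synthetic-only structure: real titration reacts
to observed INRs, but the within-patient dose variation it creates is
what makes the dose-response slope (hence k) identifiable, and it keeps
the generator free of feedback loops. Features of real data the
generator does not emulate: INR assay error structure beyond a constant
CV, non-adherence, drug-interaction effects on kinetics, visit
scheduling driven by poor control, and covariate dependence of PK
parameters (age/weight/sex do not influence the simulated truths, as no
covariate model is fitted either). Passing recovery tests therefore
demonstrates internal consistency of model + estimator under the stated
population, not transferability to real cohorts.

## Numerical and reporting choices

All model comparisons in tests use relative tolerance 1e-8 unless a
looser statistical bound is stated. Report tables are written with a
fixed `%.6f` decimal format and JSON with sorted keys so a fixed seed
regenerates byte-identical bundles. The recovery experiment (220
patients × 3 optimizer starts) runs in well under a minute on one CPU;
the test suite uses reduced cohort sizes (10–60 patients, 20 for the
closed loop, 25 for determinism) where full size adds nothing to the
property being checked.

## Known limitations

* Point (MAP) estimates only; no posterior sampling, so parameter
  uncertainty per patient is summarized only by the curvature
  diagnostic.
* The estimator assumes every visit reflects steady state on the
  recorded regimen; early-titration visits in real data violate this.
* The PD constants (3.36, 4.368, 0.383) are treated as fixed model
  structure; overriding them is possible but logged prominently, and no
  attempt is made to refit them.
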