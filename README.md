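# busulfanpk

Population pharmacokinetics of twice-daily intravenous busulfan in pediatric
hematopoietic stem-cell transplantation.

Busulfan conditioning is dosed to a cumulative exposure target (cAUC), and
missing the window matters in both directions: overexposure drives liver
toxicity, underexposure drives graft failure and relapse. Children are the
hard case — clearance scales with body composition, matures during the first
year of life, and *falls during therapy itself*, so repeated therapeutic drug
monitoring (TDM) with dose adjustment is standard practice. This package is a
complete, tested analysis pipeline for that setting, aimed at pharmacometric
analyses of twice-daily IV busulfan: dataset IO, derived covariates,
non-compartmental exposure estimation, nonlinear mixed-effects estimation by
SAEM, stepwise covariate selection, model diagnostics, and a synthetic-cohort
generator that emulates the clinical study design end to end (the source
cohort itself is confidential).

## The model

One-compartment disposition with zero-order infusion input, superposed over
all past infusions. The elimination rate constant declines exponentially from
the start of therapy,

    k*(t) = k · (1 + d_k · (1 − e^(−κ_k t))),

and within dosing interval *j* the model uses a single effective constant
k′ = the time-average of k\* from t = 0 to the interval's mid-time point, so
elimination changes between intervals but never within one (this keeps the
within-interval washout mono-exponential and stops the time trend from
imitating a second compartment). Plasma concentration during/after each
infusion follows the standard infusion solution with rate R₀, duration T_inf
and volume V.

Subject-level parameters are log-normal around covariate-adjusted typical
values (packaged estimates):

| parameter | typical value | covariates |
|---|---|---|
| V  | 11.70 L | total body water (power 0.931), infusion duration |
| k  | 0.365 h⁻¹ | TBW (−0.189), maturation F_mat (0.697), albumin (0.331), ALL (−0.210), infusion duration |
| d_k | −0.167 | HLH/XLP (−0.145) |
| κ_k | 0.0516 h⁻¹ | — |

with diagonal between-subject variances on ln V, ln k and d_k and an additive
residual error (σ = 0.076 mg/L). F_mat = 1/(1 + (PMA/46 weeks)^−2.3) is the
sigmoidal maturation of busulfan elimination with postmenstrual age. In plain
terms: clearance drops by 16.7 % on average over the first 2–3 days
(half-life of the change ≈ 13.4 h), and by 31 % in HLH/XLP patients.

## A worked example

```
python examples/worked_examples.py
```

prints, from the packaged final model:

```
reference V = 11.69 L, reference k = 0.365 1/h
half-life of the change in k: 13.4 h
steady-state reduction of k and CL: 16.7 %
instantaneous reduction of k at 24 h: 11.9 %
maturation factor at 46 weeks PMA: 0.50
maturation factor at 98 weeks PMA: 0.85
HLH/XLP total amplitude of the decline: 31.2 %
```

i.e. a population-typical child clears busulfan at k = 0.365 h⁻¹ from an
11.7 L volume; elimination slows by ~12 % within the first day and levels off
at −16.7 % (−31 % with HLH/XLP); an infant at 46 weeks postmenstrual age has
half the mature elimination capacity.

The other scripts in `examples/` each demonstrate one capability:
`simulate_cohort.py` (study-like synthetic data with TDM),
`nca_exposure.py` (per-interval AUC/CL/MRT and dose-linearity ratios),
`fit_population_model.py` (SAEM fit with shrinkage and importance-sampled
−2LL), `covariate_selection.py` (stepwise model building with the χ²
thresholds), and `model_diagnostics.py` (icwres, npde, VPC, train/test split,
population CL(t) bands).

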