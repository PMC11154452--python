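# Methods

## Structural model

Plasma busulfan after repeated intravenous infusions is described by a
one-compartment model with zero-order input. For a subject with infusions
starting at t₀ⱼ, rate R₀ⱼ and duration T_inf,ⱼ, the concentration at time t
is the superposition of the standard infusion solutions of all past doses,
each evaluated with a single effective elimination rate constant k′ for the
dosing interval containing t.

The instantaneous elimination rate constant moves exponentially from its
value k at the first infusion towards k·(1 + d_k):

    k*(t) = k · (1 + d_k · (1 − exp(−κ_k t))),   t = hours from first infusion.

k′ for interval j is the exact time-average of k* over [0, t_mid,ⱼ]:

    k′ = k · (1 + d_k · (1 − (1 − e^(−κ_k τ)) / (κ_k τ))),   τ = t_mid,ⱼ,

which is continuous at τ = 0 (k′ → k) and tends to k·(1 + d_k) for late
intervals. Holding k′ constant within an interval keeps the washout
mono-exponential there; concentration is therefore continuous everywhere
except at interval boundaries, where k′ switches (the jump is ~1 % of C_max
at the packaged parameter values, and is asserted small in the tests).

Conventions: time origin at each subject's first infusion start; intervals
are half-open [t₀ⱼ, t₀ⱼ₊₁), so a trough drawn at exactly the next infusion
start belongs to the next interval (where the new dose contributes zero at
that instant); t_mid of interval j is the midpoint of its bounding infusion
starts, and for the final interval its start plus half the subject's median
inter-dose gap (6 h under 12-hourly dosing). Units are fixed: hours, mg,
L, mg/L, AUC in mg·h/L.

## Covariates

Derived covariates: BSA = √(H·W/3600); TBW from the Mellits–Cheek-type
log-linear formula in weight, height, age and sex; fat-free mass from the
sexed two-constant formula (height in meters); postmenstrual age = postnatal
age + 40 weeks, with 52.1775 weeks/year (mean calendar year; the source
analysis does not state its conversion, so it is a package constant);
F_mat = 1/(1 + (PMA/46)^−2.3).

Continuous covariates enter as centered logs, Δln X = ln(X/X_ref), with
reference values near the population medians (TBW 10 L, albumin 30 g/L,
T_inf 3 h are fixed by the packaged model; the remaining references used
during covariate screening — weight 17 kg, height 105 cm, BSA 0.7 m²,
FFM 14 kg, hematocrit 0.3, leukocytes 4 G/L, total protein 60 g/L — are
rounded medians of the emulated population). A missing covariate is replaced
by its reference, which zeroes the centered term; this happens in the
covariates module with a logged warning, never silently at IO time.

## Estimation (SAEM)

The observation model is y = f(t; φᵢ) + ε with additive Gaussian error
(ε ~ N(0, σ²)); φᵢ = (ln V, ln k, d_k, ln κ_k) on the transformed scale, each
a linear function of the subject's covariate terms, with diagonal Gaussian
random effects on ln V, ln k and d_k. κ_k carries no random effect.

The E-step samples each subject's random effects by Metropolis–Hastings: one
independent proposal from the population model plus two componentwise
random-walk passes with step sizes adapted towards ~25–45 % acceptance. The
M-step updates the linear fixed effects by least squares on the
stochastically averaged subject parameters, and the variances (Ω², σ²) from
averaged second moments; during the exploration phase the step size is 1 and
variances may shrink by at most 5 % per iteration (simulated annealing),
during the smoothing phase the step size decays as 1/iteration. Starting
values: ln V = 2.5, ln k = −1, d_k = 0, ln κ_k = ln(ln 2/24 h) = −3.5,
covariate coefficients 0; repeated final fits may perturb the ln V/ln k
starts by ±1 (bootstrap refits keep them fixed).

Fixed effects without random effects (ln κ_k, co-medication effects) admit no
finite sufficient statistics; they are updated each iteration by a damped
Newton step on the complete-data sum of squares, evaluated on the current
samples during exploration and on the averaged (Polyak) subject parameters
during smoothing — the averaging quenches the Monte-Carlo wander that
otherwise dominates these weakly identified scalars. ln κ_k is constrained to
[−6, 0] (half-life of the change between ~40 minutes and ~12 days); a fit
ending on a bound is flagged non-converged, because on the κ→0 ridge d_k
loses identifiability. An update burn-in of ≤50 iterations prevents κ from
chasing the meaningless early samples.

The marginal −2 log-likelihood is computed afterwards by importance sampling:
per subject, a location-scale multivariate t proposal (df 4, scale 1.3× the
conditional covariance estimated from a post-fit conditional MCMC run).
Shared seeds across nested models correlate the estimates, keeping Δ(−2LL)
noise well below the χ² decision thresholds (SD ≲ 1 at 1000 draws). Empirical
Bayes estimates are per-subject posterior modes (Nelder–Mead refinement of
the conditional means); shrinkage is 1 − var(EBE η)/Ω².

Iteration counts follow the study protocol: 2000/300
(exploration/smoothing) for final fits, 600/100 for model building. Tests and
examples use further-reduced counts (noted inline) chosen so the Monte-Carlo
noise stays small against the quantity under test.

## Non-compartmental analysis

Per measured interval: k from the OLS slope of ln C vs t over the descending
phase (all samples strictly after the interval's observed C_max; non-positive
concentrations excluded with a warning); AUC/AUMC by the linear trapezoidal
rule. The first interval integrates from the pre-dose anchor and adds the
mono-exponential tail C(t_n)/k_n (AUMC tail C(t_n)·t_n/k_n + C(t_n)/k_n²)
with k_n from the last three log-concentrations. Later intervals are treated
as at steady state and integrated between infusion starts, log-linearly
extrapolating the end-point concentration when the last sample comes early
(exact on mono-exponentials); their AUMC uses time relative to the interval
start so MRT stays interpretable. CL = dose/AUC, V = dose/(AUC·k),
t½ = ln2/k, MRT = AUMC/AUC.

A design-intrinsic limitation: the sampling schedule reads the 3 h infusion
rise from two points only (pre-dose and end of infusion), so the linear
trapezoid underestimates AUC by ~2 % at k = 0.2 h⁻¹ and ~6 % at the typical
0.37 h⁻¹; CL is biased high by the same amounts. The tests bound this bias
rather than pretending it away.

## Covariate selection workflow

Basic model: static (constant k) vs dynamic (d_k, κ_k; random effects on
ln V, ln k, d_k only) compared at the χ²(3 df) 5 % value 7.82. A variant with
a random effect on ln κ_k can be fitted for bookkeeping; its shrinkage
(>40–60 %) is why that random effect is omitted. Forward inclusion: per
round, every remaining candidate is refitted and the best is kept iff
Δ(−2LL) ≤ −3.84 (χ²(1), 5 %); the five body-size metrics (W, H, BSA, FFM,
TBW) compete for a single slot per parameter; ties break by candidate order.
The clinical-relevance filter — maximal effect across the population range
inside (−0.1, +0.1) → drop — applies to the finished forward model, not
within rounds: coefficients of correlated covariates (body size and
maturation) are attenuated until both partners have entered, and filtering
mid-round would veto exactly the TBW-then-F_mat sequence the data support.
Backward elimination then removes each covariate singly and keeps it only if
removal worsens −2LL by more than 6.63 (χ²(1), 1 %). Per-coefficient
p-value exclusion is not implemented (it would need standard errors of SAEM
fixed effects; the likelihood and magnitude rules carry the selection).

Co-medication effects are multiplicative on a PK parameter, active for
observations whose dosing interval starts within 24 h after an
administration, and are estimated as direct fixed effects (same machinery as
ln κ_k). They are judged by the same Δ(−2LL) and magnitude criteria. Note an
identifiability constraint the tests make explicit: a drug given before
*every* dose of a subject is indistinguishable from that subject's random
effect; only within-subject exposure contrast identifies the effect.

## Diagnostics

icwres = (observation − conditional prediction)/σ. npde: Monte-Carlo
simulation over each subject's design, per-subject mean/covariance
decorrelation, rank-based probability integral transform, Φ⁻¹; ~N(0,1) under
a correct model. VPC without time binning: per exact sampling time point,
observed 5th/50th/95th percentiles against the 95 % band of the same
percentiles across simulations (points with <5 observations flagged).
Bootstrap: subject-level resampling with replacement at the original size,
refits with fixed starts, percentile CIs (2.5/97.5 %); non-converged
replicates are counted and excluded. Train/test: subject-level 75/25 split
(124 → 93/31), population-level SSR per observation on both sets, flag if
the test/train ratio exceeds 2. Covariate-stripped clearance: refit without
selected covariates (default: ALL and albumin on ln k), report subject CL as
a multiple of its population prediction, with a two-sided t-test (ALL vs
rest) and the OLS slope against albumin. Dose linearity: per subject,
(AUC/dose)ₘ/(AUC/dose)₁ against doseₘ/dose₁ for odd m ∈ {3,5,7}
(even-numbered measured doses excluded), with an OLS slope per interval.

CL(t) population simulation: d_k ~ N(θ_dk, Ω_dk), κ_k ~ N(κ̂, SE·√N) — the
SE inflation emulates population spread for a parameter without a random
effect; non-positive κ draws violate the model invariant and are rejected
and redrawn (the sampling distribution is silent on them). Curves
1 + d_k(1 − e^(−κt)); the solid reference curves use the fixed effects (with
and without the HLH/XLP shift); 80/95 % bands from the draws.

## Synthetic cohorts

The generator emulates the study design, not any individual patient: 124
subjects; 18 % infants (<1 y), 5 % adults, ages log-uniform in childhood
(band edges tuned so the cohort median sits near 4.3 y); 72 % male; nine
disease groups at the reported proportions; weight/height from a coarse
built-in growth table with correlated log-normal scatter (this induces the
age–size–TBW correlation structure the model feeds on — it is *not* a growth
reference standard); laboratory values spanning the reported ranges
(albumin and hematocrit uniform, leukocytes log-normal about the median);
a 35 % 4 h-infusion arm reflecting the earlier treatment era (without it the
infusion-duration effects would be unidentifiable).

Dosing: 12-hourly; the dose count is the cumulative target (57.5 mg·h/L
midpoint for reduced-intensity, 90 for myeloablative — malignant plus
metabolic groups) divided by the 10.5 mg·h/L first-dose midpoint, rounded up
and clipped to 4–10, which keeps every per-dose AUC inside the 9–12 window;
the first dose is that AUC times the population-predicted clearance.
Sampling: measured *morning* doses only (first dose morning with probability
½), per-subject measured-interval count drawn from {1..5} with median 3;
pre-dose plus 0/30/60/120/240/360 min after the end of infusion; additive
N(0, σ) noise truncated at 0. TDM: after each measured interval the interval
AUC is estimated by the package's own NCA and the remaining doses are
rescaled to (target − accrued)/(n_remaining · AUC-per-mg); doses floored at
zero (withheld doses are neither given nor sampled). Co-medication: NAC
(69 % of subjects, 80 % of days), fludarabine (80 %, daily), paracetamol
(30 %, half the days), clofarabine (8 %); day-to-day variation is what makes
such effects estimable at all.

What the generator does not emulate: assay error structure beyond additive
Gaussian noise, true growth-reference anthropometry, real co-medication
schedules, pharmacogenetics (GSTA1), disease-specific organ dysfunction
beyond the coded covariate effects, or clinical outcomes. Passing tests
therefore demonstrate correctness of the machinery under the study's design
and the packaged model — not external validity on new clinical data.

A consequence worth knowing: because TDM adjusts later doses using the same
noisy measurements the model then fits, estimates inherit a small feedback
bias (~−0.015 on ln V at study size). The clinical study shares this
feedback by construction, so the package reproduces it rather than removing
it.

## Numerical choices and limitations

(1 − e⁻ˣ)/x is evaluated by series below x = 10⁻⁸; each infusion's
contribution is written as e^(−k′t_el) − e^(−k′t_on), which vanishes
automatically before the dose starts. Invalid parameter vectors (1 + d_k ≤ 0)
propagate as NaN/−∞ and act as rejection signals in the samplers. Estimates
are exactly reproducible given (dataset, spec, settings); subject *relabeling*
leaves them unchanged, subject *reordering* permutes the random streams and
so changes them only statistically. On η ≈ 0 (no-variability) data the
(d_k, κ_k) pair is weakly identified along a ridge — between-subject
variability is, somewhat counterintuitively, what anchors it — so
self-consistency at zero variability is only guaranteed for the static
parameters. Ω is diagonal throughout; inter-occasion variability beyond the
deterministic k′(t) trend, two-compartment disposition, and proportional
error models are out of scope.
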