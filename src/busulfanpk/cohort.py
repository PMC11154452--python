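"""Synthetic study cohorts: covariates, dosing with TDM, and observations.

The confidential clinical dataset cannot be shipped, so every pipeline stage
is exercised on simulated cohorts that emulate the study design:

* 124 mostly pediatric subjects (18% younger than 1 year, 72% male), nine
  disease groups, weight/height generated from age via a coarse growth table,
  laboratory values spanning the reported ranges;
* twice-daily (12-hourly) intravenous infusions over 3 h (or 4 h in an
  earlier-era arm), 4-10 doses over 2-5 days, the first dose sized for a
  target first-interval AUC of 9-12 mg*h/L and the dose count for a
  cumulative AUC of 45-70 mg*h/L (reduced-intensity conditioning) or
  80-100 mg*h/L (myeloablative conditioning);
* plasma samples on measured morning doses only (median 3, max 5 per
  subject): pre-dose and 0, 30, 60, 120, 240 and 360 min after the infusion
  ends, with additive measurement noise;
* therapeutic drug monitoring: after each measured interval the interval AUC
  is estimated non-compartmentally and the remaining doses are rescaled
  toward the cumulative target.

All randomness flows from a single seed, so a cohort is fully reproducible,
and the generator returns the simulation truth (random effects, individual
parameters, noise-free concentrations) alongside the dataset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .covariates import derive
from .datamodel import DoseEvent, Observation, StudyDataset, Subject, SubjectCovariates
from .nca import NCAError, interval_auc_first, interval_auc_ss
from .popmodel import PopulationModel, individual_params
from .structural import DoseSchedule, IndividualParameters, predict_profile

log = logging.getLogger(__name__)

#: Disease-group proportions of the study population.
DISEASE_PROPORTIONS = {
    "ALL": 0.10, "AML": 0.10, "CGD": 0.26, "HLH/XLP": 0.11,
    "hemoglobinopathies": 0.10, "PID": 0.11, "metabolic": 0.06,
    "neuroblastoma": 0.05, "other": 0.11,
}

#: Groups conditioned myeloablatively (malignant plus metabolic diseases);
#: the remaining (non-malignant) groups receive reduced-intensity targets.
MAC_GROUPS = frozenset({"ALL", "AML", "neuroblastoma", "other", "metabolic"})

#: Coarse median weight (kg) and height (cm) by age (years).  A deliberately
#: simple stand-in for a growth reference: it only needs to induce the
#: age-weight-height-TBW correlation structure the model feeds on.
GROWTH_TABLE = np.array([
    # age,   W,    H
    [0.2, 5.0, 58.0],
    [0.5, 7.0, 66.0],
    [1.0, 9.5, 75.0],
    [2.0, 12.0, 87.0],
    [3.0, 14.0, 95.0],
    [4.0, 16.0, 102.0],
    [6.0, 21.0, 116.0],
    [8.0, 26.0, 128.0],
    [10.0, 32.0, 139.0],
    [12.0, 40.0, 150.0],
    [14.0, 50.0, 161.0],
    [16.0, 58.0, 168.0],
    [18.0, 62.0, 171.0],
    [27.0, 68.0, 173.0],
])

#: Sampling offsets after the end of the infusion, hours.
SAMPLE_OFFSETS_H = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0)

#: Distribution of the number of measured (morning) dosing intervals per
#: subject; median 3, maximum 5, minimum 1.
MEASURED_DOSES_PMF = {1: 0.10, 2: 0.20, 3: 0.35, 4: 0.20, 5: 0.15}


@dataclass
class CohortSpec:
    """Design parameters of a synthetic cohort (defaults: the study design)."""

    n_subjects: int = 124
    frac_age_lt1: float = 0.18
    frac_age_gt18: float = 0.05
    age_range: tuple[float, float] = (0.2, 27.0)
    frac_male: float = 0.72
    disease_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DISEASE_PROPORTIONS))
    albumin_range: tuple[float, float] = (19.0, 50.0)
    total_protein_range: tuple[float, float] = (34.0, 84.0)
    hematocrit_range: tuple[float, float] = (0.17, 0.41)
    leukocyte_range: tuple[float, float] = (0.16, 20.9)
    frac_tinf4: float = 0.35          # earlier-era 4 h infusion arm
    dose_interval_h: float = 12.0
    first_dose_auc_target: float = 10.5   # mg*h/L, middle of the 9-12 window
    cauc_window_ric: tuple[float, float] = (45.0, 70.0)
    cauc_window_mac: tuple[float, float] = (80.0, 100.0)
    dose_range: tuple[int, int] = (4, 10)
    tdm: bool = True
    frac_nac: float = 0.69
    frac_paracetamol: float = 0.30
    frac_fludarabine: float = 0.80
    frac_clofarabine: float = 0.08

    def __post_init__(self):
        total = sum(self.disease_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"disease proportions must sum to 1, got {total}")


@dataclass
class SimulationTruth:
    """What the generator actually simulated, for parameter-recovery tests."""

    eta: dict[str, np.ndarray]
    parameters: list[IndividualParameters]
    noise_free: dict[str, np.ndarray]  # subject id -> concentrations
    seed: int


def _sample_age(spec: CohortSpec, rng: np.random.Generator) -> float:
    u = rng.uniform()
    lo, hi = spec.age_range
    if u < spec.frac_age_lt1:
        return rng.uniform(lo, 1.0)
    if u < spec.frac_age_lt1 + spec.frac_age_gt18:
        return rng.uniform(18.0, hi)
    # log-uniform across childhood; lower edge trimmed so the cohort median
    # lands near the reported 4.3 years
    return math.exp(rng.uniform(math.log(1.3), math.log(18.0)))


def _growth(age: float) -> tuple[float, float]:
    w = float(np.interp(age, GROWTH_TABLE[:, 0], GROWTH_TABLE[:, 1]))
    h = float(np.interp(age, GROWTH_TABLE[:, 0], GROWTH_TABLE[:, 2]))
    return w, h


def generate_covariates(spec: CohortSpec, seed_or_rng) -> list[SubjectCovariates]:
    """Draw subject covariates consistent with the study's Table-1 profile."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    groups = sorted(spec.disease_proportions)
    probs = np.array([spec.disease_proportions[g] for g in groups])
    out = []
    for _ in range(spec.n_subjects):
        age = _sample_age(spec, rng)
        w_med, h_med = _growth(age)
        z = rng.standard_normal()
        height = h_med * math.exp(0.035 * z)
        weight = w_med * math.exp(0.16 * (0.6 * z + 0.8 * rng.standard_normal()))
        sex = "male" if rng.uniform() < spec.frac_male else "female"
        disease = str(rng.choice(groups, p=probs))
        leu = float(np.clip(4.0 * math.exp(0.9 * rng.standard_normal()),
                            *spec.leukocyte_range))
        out.append(SubjectCovariates(
            weight=weight, height=height, age=age, sex=sex,
            disease_group=disease,
            albumin=rng.uniform(*spec.albumin_range),
            total_protein=rng.uniform(*spec.total_protein_range),
            hematocrit=rng.uniform(*spec.hematocrit_range),
            leukocytes=leu,
            tinf_h=4.0 if rng.uniform() < spec.frac_tinf4 else 3.0,
        ))
    return out


def plan_dosing(cov: SubjectCovariates, pop: PopulationModel,
                spec: CohortSpec | None = None) -> list[DoseEvent]:
    """Initial twice-daily schedule for one subject.

    The first dose targets the middle of the 9-12 mg*h/L first-interval AUC
    window via the population-predicted clearance, and the number of doses is
    chosen so the planned cumulative AUC lands inside the regimen's window.
    """
    spec = spec or CohortSpec()
    dcov = derive(cov)
    p = individual_params(pop, dcov)  # population prediction, eta = 0
    cl_pop = p.k * p.v
    target = _cauc_target(cov.disease_group, spec)
    n_doses = int(np.clip(math.ceil(target / spec.first_dose_auc_target),
                          spec.dose_range[0], spec.dose_range[1]))
    per_dose_auc = target / n_doses
    dose = per_dose_auc * cl_pop
    return [
        DoseEvent(subject_id="", t0=j * spec.dose_interval_h, amount=dose,
                  duration=cov.tinf_h, dose_index=j + 1)
        for j in range(n_doses)
    ]


def _cauc_target(disease: str, spec: CohortSpec) -> float:
    window = (spec.cauc_window_mac if disease in MAC_GROUPS
              else spec.cauc_window_ric)
    return 0.5 * (window[0] + window[1])


def _measured_indices(n_doses: int, first_is_morning: bool,
                      n_measured: int) -> list[int]:
    """1-based indices of the measured (morning) doses."""
    start = 1 if first_is_morning else 2
    morning = list(range(start, n_doses + 1, 2))
    return morning[:n_measured]


def simulate_observations(p: IndividualParameters, doses: list[DoseEvent],
                          measured: list[int], sigma: float,
                          rng: np.random.Generator,
                          ) -> tuple[list[Observation], np.ndarray]:
    """Noisy concentrations on the measured dosing intervals.

    Samples are drawn pre-dose and at the fixed offsets after the end of the
    infusion; additive N(0, sigma) noise truncated at zero.  Returns the
    observations and the matching noise-free concentrations.
    """
    sched = DoseSchedule(doses)
    times = []
    for j in measured:
        d = doses[j - 1]
        times.append(d.t0)
        times.extend(d.t0 + d.duration + off for off in SAMPLE_OFFSETS_H)
    times = np.array(sorted(set(times)))
    clean = predict_profile(p, sched, times)
    noisy = clean + sigma * rng.standard_normal(times.size)
    noisy = np.clip(noisy, 0.0, None)
    obs = [Observation(subject_id="", t=float(t), conc=float(c),
                       dosing_interval=sched.interval_of(float(t)))
           for t, c in zip(times, noisy)]
    return obs, clean


def _interval_auc_estimate(obs: list[Observation], doses: list[DoseEvent],
                           j: int, interval_h: float) -> float | None:
    """NCA estimate of interval j's AUC from its own samples (TDM view)."""
    pts = [(o.t, o.conc) for o in obs if o.dosing_interval == j]
    pts.sort()
    times = np.array([t for t, _ in pts])
    concs = np.array([c for _, c in pts])
    try:
        if j == 1:
            auc, _, _, _ = interval_auc_first(times, concs)
        else:
            start = doses[j - 1].t0
            auc, _ = interval_auc_ss(times, concs, start, start + interval_h)
    except NCAError as exc:
        log.warning("TDM AUC estimate failed for interval %d: %s", j, exc)
        return None
    return auc


def simulate_tdm_adjustment(p: IndividualParameters, doses: list[DoseEvent],
                            measured: list[int], target_cauc: float,
                            sigma: float, rng: np.random.Generator,
                            interval_h: float = 12.0,
                            ) -> tuple[list[DoseEvent], list[Observation],
                                       np.ndarray, dict]:
    """Closed-loop dosing: measure, estimate exposure, rescale later doses.

    After each measured interval the interval AUC is estimated
    non-compartmentally; the remaining doses become
    ``(target - accrued AUC) / (n_remaining * AUC-per-mg)`` with AUC-per-mg
    taken from the last measured interval, floored at zero.  Returns the
    final schedule, all observations, the noise-free concentrations and an
    exposure report.
    """
    doses = [DoseEvent(d.subject_id, d.t0, d.amount, d.duration, d.dose_index)
             for d in doses]
    all_obs: list[Observation] = []
    all_clean: list[np.ndarray] = []
    auc_per_mg = None
    measured_auc: dict[int, float] = {}
    for j in measured:
        if doses[j - 1].amount <= 0:
            continue  # dose withheld by an earlier adjustment; nothing to sample
        obs, clean = simulate_observations(p, doses, [j], sigma, rng)
        all_obs.extend(obs)
        all_clean.append(clean)
        auc = _interval_auc_estimate(obs, doses, j, interval_h)
        if auc is None:
            continue
        measured_auc[j] = auc
        auc_per_mg = auc / doses[j - 1].amount
        accrued = sum(
            measured_auc.get(m, doses[m - 1].amount * auc_per_mg)
            for m in range(1, j + 1)
        )
        remaining = [d for d in doses if d.dose_index > j]
        if not remaining:
            continue
        if accrued >= target_cauc:
            log.warning("accrued exposure %.1f exceeds target %.1f; "
                        "remaining doses set to 0", accrued, target_cauc)
            new_amount = 0.0
        else:
            new_amount = (target_cauc - accrued) / (len(remaining) * auc_per_mg)
        for d in remaining:
            d.amount = max(new_amount, 0.0)
    doses = [d for d in doses if d.amount > 0]
    for i, d in enumerate(doses, start=1):
        d.dose_index = i
    clean = (np.concatenate(all_clean) if all_clean else np.zeros(0))
    report = {
        "measured_auc": measured_auc,
        "planned_cauc": (sum(measured_auc.values())
                         + (auc_per_mg or 0.0)
                         * sum(d.amount for d in doses
                               if d.dose_index not in measured_auc)),
        "target_cauc": target_cauc,
    }
    return doses, all_obs, clean, report


def _comedication(cov: SubjectCovariates, doses: list[DoseEvent],
                  spec: CohortSpec, rng: np.random.Generator) -> None:
    """Attach time-stamped co-medication administrations to a subject."""
    days = sorted({int(d.t0 // 24) for d in doses})
    # (drug, lead time before the morning dose, per-day probability): NAC and
    # paracetamol vary from day to day within a patient, which is what makes
    # their effects separable from the subject-level random effects
    drugs = []
    if rng.uniform() < spec.frac_nac:
        drugs.append(("NAC", 2.0, 0.8))
    if rng.uniform() < spec.frac_fludarabine:
        drugs.append(("fludarabine", 1.0, 1.0))
    if rng.uniform() < spec.frac_paracetamol:
        drugs.append(("paracetamol", 5.0, 0.5))
    if rng.uniform() < spec.frac_clofarabine:
        drugs.append(("clofarabine", 1.5, 1.0))
    for drug, lead_h, p_day in drugs:
        for day in days:
            if rng.uniform() < p_day:
                cov.comedication.append((drug, 24.0 * day - lead_h))


def generate_cohort(spec: CohortSpec | None = None,
                    pop: PopulationModel | None = None,
                    seed: int = 0) -> tuple[StudyDataset, SimulationTruth]:
    """Generate a full synthetic cohort under a population model.

    Covariates, dosing (with TDM adjustment when ``spec.tdm``), sampling and
    measurement noise are all drawn from one seeded generator, so the cohort
    is fully reproducible from ``(spec, pop, seed)``.
    """
    from .popmodel import final_model

    spec = spec or CohortSpec()
    pop = pop or final_model()
    rng = np.random.default_rng(seed)
    covs = generate_covariates(spec, rng)
    re_names = sorted(pop.omega2)
    eta_mat = np.zeros((spec.n_subjects, len(re_names)))
    subjects, parameters, noise_free = [], [], {}
    for i, cov in enumerate(covs):
        sid = f"S{i + 1:03d}"
        dcov = derive(cov)
        eta = {}
        for jn, name in enumerate(re_names):
            draw = rng.standard_normal() * math.sqrt(pop.omega2[name])
            eta[name] = draw
            eta_mat[i, jn] = draw
        # redraw until the subject's parameters are admissible (1 + d_k > 0)
        for _ in range(100):
            try:
                p = individual_params(pop, dcov, eta)
                break
            except ValueError:
                if "dk" not in re_names:
                    raise
                eta["dk"] = (rng.standard_normal()
                             * math.sqrt(pop.omega2["dk"]))
                eta_mat[i, re_names.index("dk")] = eta["dk"]
        doses = plan_dosing(cov, pop, spec)
        n_measured = min(
            _draw_pmf(MEASURED_DOSES_PMF, rng),
            (len(doses) + 1) // 2,
        )
        first_is_morning = rng.uniform() < 0.5
        measured = _measured_indices(len(doses), first_is_morning, n_measured)
        if not measured:
            measured = [1]
        target = _cauc_target(cov.disease_group, spec)
        if spec.tdm:
            doses, obs, clean, _ = simulate_tdm_adjustment(
                p, doses, measured, target, pop.sigma, rng,
                interval_h=spec.dose_interval_h)
        else:
            obs, clean = simulate_observations(p, doses, measured, pop.sigma, rng)
        _comedication(cov, doses, spec, rng)
        for d in doses:
            d.subject_id = sid
        for o in obs:
            o.subject_id = sid
        subjects.append(Subject(sid, cov, doses, obs))
        parameters.append(p)
        noise_free[sid] = clean
    ds = StudyDataset(subjects=subjects,
                      provenance=f"synthetic cohort, seed={seed}").validate()
    truth = SimulationTruth(
        eta={name: eta_mat[:, j] for j, name in enumerate(re_names)},
        parameters=parameters, noise_free=noise_free, seed=seed)
    return ds, truth


def _draw_pmf(pmf: dict[int, float], rng: np.random.Generator) -> int:
    keys = sorted(pmf)
    probs = np.array([pmf[k] for k in keys])
    return int(rng.choice(keys, p=probs / probs.sum()))
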