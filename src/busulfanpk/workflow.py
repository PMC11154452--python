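"""Stepwise model building: basic model, forward inclusion, backward
elimination, and co-medication effect testing.

Nested models are compared on the importance-sampled -2 log-likelihood.
A covariate enters the model when it gives the largest likelihood improvement
of its round, the improvement exceeds the chi-square(1) 5% critical value
(Delta(-2LL) <= -3.84), and its maximal effect across the population is at
least 0.1 on the log scale (roughly 10% on the natural scale).  Included
covariates must survive backward elimination at the chi-square(1) 1% level
(removal must worsen -2LL by more than 6.63).  Alternative body-size metrics
(weight, height, BSA, FFM, TBW) compete for a single slot per parameter.

Co-medication is handled separately: a multiplicative effect on a PK
parameter, active for dosing intervals starting within 24 h after an
administration, is added as a fit parameter and judged by the same criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import StudyDataset
from .saem import (
    FitResult,
    ModelSpec,
    SaemSettings,
    basic_model_spec,
    fit_saem,
    loglik_is,
    static_model_spec,
)

log = logging.getLogger(__name__)

#: Body-size metrics competing for the same covariate slot.
BODY_SIZE_TERMS = frozenset({"dlnW", "dlnBSA", "dlnH", "dlnFFM", "dlnTBW"})

#: Default candidate list: (parameter, covariate term) pairs, screened in
#: this order.  Body-size alternates for ln V first, then the remaining
#: candidates from the study's screening set.
DEFAULT_CANDIDATES = (
    ("lV", "dlnW"), ("lV", "dlnBSA"), ("lV", "dlnH"), ("lV", "dlnFFM"),
    ("lV", "dlnTBW"),
    ("lV", "dTinf"), ("lk", "dTinf"), ("lk", "ALL"), ("dk", "HLHXLP"),
    ("lk", "dlnAlb"), ("lk", "dlnTBW"), ("lk", "lnFmat"),
    ("lk", "dlnLeu"), ("lV", "dlnHct"),
)


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds of the stepwise procedure."""

    include_delta_2ll: float = 3.84   # chi-square(1), p = 0.05
    exclude_delta_2ll: float = 6.63   # chi-square(1), p = 0.01
    basic_delta_2ll_3df: float = 7.82  # chi-square(3), p = 0.05
    min_effect_magnitude: float = 0.1
    shrinkage_cap: float = 0.4
    comed_window_h: float = 24.0


@dataclass
class SelectionStep:
    candidate: str
    parameter: str
    delta_2ll: float
    effect: float
    decision: str
    reason: str = ""


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)

    def add(self, **kwargs) -> None:
        self.steps.append(SelectionStep(**kwargs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])


def effect_magnitude(fit: FitResult, param: str, term: str) -> float:
    """Maximal |coefficient x covariate term| across the fitted population."""
    coef = fit.theta.get(f"{param}:{term}")
    if coef is None:
        return 0.0
    values = fit.data.terms[term]
    return float(np.max(np.abs(coef * values)))


def _m2ll(fit: FitResult, n_mc: int, seed: int) -> float:
    return loglik_is(fit, n_mc=n_mc, seed=seed)


def build_basic_model(ds: StudyDataset, settings: SaemSettings | None = None,
                      criteria: SelectionCriteria | None = None,
                      n_mc: int = 1000, check_kappa_eta: bool = False,
                      ) -> tuple[FitResult, SelectionTrace]:
    """Choose the basic structural model: static vs time-varying elimination.

    Fits the static one-compartment model and its extension with the
    exponential change in k (random effects on lV, lk and d_k only; the
    variant with a random effect on ln kappa is overparameterized, which
    ``check_kappa_eta`` records via its shrinkage).  The extension is kept if
    it improves -2LL by more than the chi-square critical value for the three
    added parameters.
    """
    settings = settings or SaemSettings()
    criteria = criteria or SelectionCriteria()
    trace = SelectionTrace()
    ll_seed = settings.seed + 7919
    fit_static = fit_saem(ds, static_model_spec(), settings)
    fit_dyn = fit_saem(ds, basic_model_spec(), settings)
    if not (fit_static.converged or fit_dyn.converged):
        raise RuntimeError("neither basic-model candidate converged")
    m2_static = _m2ll(fit_static, n_mc, ll_seed)
    m2_dyn = _m2ll(fit_dyn, n_mc, ll_seed)
    delta = m2_dyn - m2_static
    keep_dyn = delta <= -criteria.basic_delta_2ll_3df
    trace.add(candidate="dynamic k (d_k, kappa_k)", parameter="lk",
              delta_2ll=delta,
              effect=abs(fit_dyn.theta.get("dk", 0.0)),
              decision="included" if keep_dyn else "rejected-Δ2LL",
              reason=f"Δ-2LL {delta:+.2f} vs chi2(3df) -{criteria.basic_delta_2ll_3df}")
    if check_kappa_eta:
        spec_full = ModelSpec(random_effects=("lV", "lk", "dk", "lkappa"))
        fit_full = fit_saem(ds, spec_full, settings)
        shr = fit_full.shrinkage.get("lkappa", float("nan"))
        trace.add(candidate="eta on ln(kappa_k)", parameter="lkappa",
                  delta_2ll=float("nan"), effect=shr,
                  decision="rejected-Δ2LL" if shr > criteria.shrinkage_cap
                  else "included",
                  reason=f"shrinkage {shr:.2f} vs cap {criteria.shrinkage_cap}")
    return (fit_dyn if keep_dyn else fit_static), trace


def forward_select(ds: StudyDataset, basic: FitResult,
                   candidates=DEFAULT_CANDIDATES,
                   criteria: SelectionCriteria | None = None,
                   settings: SaemSettings | None = None,
                   n_mc: int = 1000) -> tuple[FitResult, SelectionTrace]:
    """Greedy forward inclusion of covariates.

    Per round, every remaining candidate is added to the current model and
    refitted; the best one is kept if it improves -2LL beyond the
    chi-square(1) criterion.  Rounds stop when no candidate qualifies.  Ties
    on Delta(-2LL) break by candidate-list order (the first wins).  The
    effect-magnitude rule applies to the finished model (see
    :func:`magnitude_filter`), not within rounds, because coefficients of
    correlated covariates (body size and maturation in particular) are
    attenuated until both partners have entered.
    """
    criteria = criteria or SelectionCriteria()
    settings = settings or SaemSettings()
    trace = SelectionTrace()
    current = basic
    remaining = list(candidates)
    ll_seed = settings.seed + 7919
    current_m2 = (current.m2ll if current.m2ll is not None
                  else _m2ll(current, n_mc, ll_seed))
    round_no = 0
    while remaining:
        round_no += 1
        results = []
        for param, term in remaining:
            spec_c = current.spec.with_covariate(param, term)
            fit_c = fit_saem(ds, spec_c, settings)
            m2 = _m2ll(fit_c, n_mc, ll_seed)
            results.append((param, term, fit_c, m2 - current_m2))
        best = min(results, key=lambda r: r[3])
        param, term, fit_b, delta = best
        if delta > -criteria.include_delta_2ll:
            for p, t, _, d in results:
                trace.add(candidate=t, parameter=p, delta_2ll=d, effect=0.0,
                          decision="rejected-Δ2LL",
                          reason=f"round {round_no}: no candidate passed")
            break
        trace.add(candidate=term, parameter=param, delta_2ll=delta,
                  effect=effect_magnitude(fit_b, param, term),
                  decision="included",
                  reason=f"round {round_no}: best of {len(results)}")
        current, current_m2 = fit_b, current_m2 + delta
        remaining.remove((param, term))
        if term in BODY_SIZE_TERMS:
            dropped = [(p, t) for p, t in remaining
                       if p == param and t in BODY_SIZE_TERMS]
            for p, t in dropped:
                remaining.remove((p, t))
                trace.add(candidate=t, parameter=p, delta_2ll=float("nan"),
                          effect=0.0, decision="rejected-Δ2LL",
                          reason=f"round {round_no}: body-size slot taken by {term}")
    return current, trace


def magnitude_filter(ds: StudyDataset, fit: FitResult,
                     criteria: SelectionCriteria | None = None,
                     settings: SaemSettings | None = None,
                     n_mc: int = 1000) -> tuple[FitResult, SelectionTrace]:
    """Drop covariates whose maximal effect in the fitted model is below 0.1.

    The effect of a covariate is judged across the population range of its
    term (coefficient times the extreme term values); covariates inside
    (-0.1, 0.1) are considered clinically irrelevant regardless of their
    likelihood contribution and removed, with a single refit at the end.
    """
    criteria = criteria or SelectionCriteria()
    settings = settings or SaemSettings()
    trace = SelectionTrace()
    spec = fit.spec
    dropped = False
    for param, terms in list(spec.covariates.items()):
        for term in terms:
            effect = effect_magnitude(fit, param, term)
            if effect < criteria.min_effect_magnitude:
                trace.add(candidate=term, parameter=param,
                          delta_2ll=float("nan"), effect=effect,
                          decision="rejected-effect",
                          reason=f"|effect| {effect:.3f} < "
                                 f"{criteria.min_effect_magnitude}")
                spec = spec.without_covariate(param, term)
                dropped = True
    if not dropped:
        return fit, trace
    refit = fit_saem(ds, spec, settings)
    _m2ll(refit, n_mc, settings.seed + 7919)
    return refit, trace


def backward_eliminate(ds: StudyDataset, full: FitResult,
                       criteria: SelectionCriteria | None = None,
                       settings: SaemSettings | None = None,
                       n_mc: int = 1000) -> tuple[FitResult, SelectionTrace]:
    """Remove each covariate singly; keep it only if removal worsens -2LL
    by more than the chi-square(1) 1% critical value."""
    criteria = criteria or SelectionCriteria()
    settings = settings or SaemSettings()
    trace = SelectionTrace()
    current = full
    ll_seed = settings.seed + 7919
    current_m2 = (current.m2ll if current.m2ll is not None
                  else _m2ll(current, n_mc, ll_seed))
    for param, terms in list(current.spec.covariates.items()):
        for term in terms:
            spec_r = current.spec.without_covariate(param, term)
            fit_r = fit_saem(ds, spec_r, settings)
            m2 = _m2ll(fit_r, n_mc, ll_seed)
            delta = m2 - current_m2  # increase on removal
            if delta > criteria.exclude_delta_2ll:
                trace.add(candidate=term, parameter=param, delta_2ll=delta,
                          effect=effect_magnitude(current, param, term),
                          decision="included",
                          reason=f"removal raises -2LL by {delta:.2f} > "
                                 f"{criteria.exclude_delta_2ll}")
            else:
                trace.add(candidate=term, parameter=param, delta_2ll=delta,
                          effect=effect_magnitude(current, param, term),
                          decision="rejected-backward",
                          reason=f"removal raises -2LL by only {delta:.2f}")
                current, current_m2 = fit_r, m2
    return current, trace


#: Co-medication effects screened in the study: drug on parameter.
DEFAULT_COMED_CANDIDATES = (
    ("NAC", "lk"), ("NAC", "lV"),
    ("clofarabine", "lk"), ("clofarabine", "lV"),
    ("paracetamol", "lk"), ("paracetamol", "lV"),
    ("fludarabine", "lk"), ("fludarabine", "lV"),
)


def test_comedication(ds: StudyDataset, model: FitResult,
                      drugs=DEFAULT_COMED_CANDIDATES,
                      criteria: SelectionCriteria | None = None,
                      settings: SaemSettings | None = None,
                      n_mc: int = 1000) -> SelectionTrace:
    """Test multiplicative co-medication effects on the PK parameters.

    Each (drug, parameter) pair is added singly to the reference model as a
    fit parameter active during exposure windows; the inclusion criteria are
    the same as for covariates.  Drugs never administered in the dataset are
    skipped with a note.
    """
    criteria = criteria or SelectionCriteria()
    settings = settings or SaemSettings()
    trace = SelectionTrace()
    ll_seed = settings.seed + 7919
    ref_m2 = (model.m2ll if model.m2ll is not None
              else _m2ll(model, n_mc, ll_seed))
    administered = {d for s in ds.subjects for d, _ in s.covariates.comedication}
    for drug, param in drugs:
        if drug not in administered:
            trace.add(candidate=drug, parameter=param, delta_2ll=float("nan"),
                      effect=float("nan"), decision="rejected-Δ2LL",
                      reason="drug never administered; skipped")
            continue
        spec_c = ModelSpec(
            covariates=model.spec.covariates,
            random_effects=model.spec.random_effects,
            fixed_params=model.spec.fixed_params,
            comed_effects=model.spec.comed_effects + ((drug, param),),
            comed_window_h=criteria.comed_window_h,
        )
        fit_c = fit_saem(ds, spec_c, settings)
        m2 = _m2ll(fit_c, n_mc, ll_seed)
        delta = m2 - ref_m2
        beta = fit_c.comed_theta.get(f"b:{drug}:{param}", 0.0)
        if delta > -criteria.include_delta_2ll:
            decision, reason = "rejected-Δ2LL", f"Δ-2LL {delta:+.2f} > -3.84"
        elif abs(beta) < criteria.min_effect_magnitude:
            decision, reason = ("rejected-effect",
                                f"|effect| {abs(beta):.3f} < 0.1")
        else:
            decision, reason = "included", "passed both criteria"
        trace.add(candidate=drug, parameter=param, delta_2ll=delta,
                  effect=beta, decision=decision, reason=reason)
    return trace


def run_workflow(ds: StudyDataset, settings: SaemSettings | None = None,
                 criteria: SelectionCriteria | None = None,
                 candidates=DEFAULT_CANDIDATES, n_mc: int = 1000,
                 ) -> tuple[FitResult, SelectionTrace]:
    """Full pipeline: basic model, forward, magnitude filter, backward."""
    basic, trace = build_basic_model(ds, settings, criteria, n_mc)
    fit_fw, t_fw = forward_select(ds, basic, candidates, criteria, settings, n_mc)
    fit_mf, t_mf = magnitude_filter(ds, fit_fw, criteria, settings, n_mc)
    fit_bw, t_bw = backward_eliminate(ds, fit_mf, criteria, settings, n_mc)
    trace.steps.extend(t_fw.steps)
    trace.steps.extend(t_mf.steps)
    trace.steps.extend(t_bw.steps)
    return fit_bw, trace
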