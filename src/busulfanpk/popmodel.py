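"""Population model container: fixed effects, covariate map, variances.

Fixed effects are stored in a flat dictionary keyed ``"<param>"`` for the
intercept of a structural parameter and ``"<param>:<term>"`` for the
coefficient of a centered covariate term, e.g. ``"lk:dlnTBW"``.  Structural
parameters are

* ``lV``     : ln of the distribution volume (L),
* ``lk``     : ln of the baseline elimination rate constant (1/h),
* ``dk``     : amplitude of the exponential change in k (untransformed),
* ``lkappa`` : ln of the rate of that change (1/h), no random effect.

A subject's parameters are obtained by summing intercept, covariate
contributions and the subject's random effects on the transformed scale, then
back-transforming (exp for the log-scale parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import params as _params
from .covariates import DerivedCovariates
from .structural import IndividualParameters

STRUCTURAL_PARAMS = ("lV", "lk", "dk", "lkappa")


@dataclass
class PopulationModel:
    """Fixed effects, random-effect variances and residual error."""

    theta: dict[str, float]
    omega2: dict[str, float]
    sigma: float
    se: dict[str, float] = field(default_factory=dict)
    n_subjects: int | None = None

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma!r}")
        for name, var in self.omega2.items():
            if var < 0:
                raise ValueError(f"omega2[{name!r}] must be >= 0, got {var!r}")
        for key in self.theta:
            param = key.split(":", 1)[0]
            if param not in STRUCTURAL_PARAMS:
                raise ValueError(f"unknown structural parameter in theta key {key!r}")

    def covariate_terms(self, param: str) -> list[str]:
        """Names of the covariate terms attached to one structural parameter."""
        prefix = param + ":"
        return [k.split(":", 1)[1] for k in self.theta if k.startswith(prefix)]

    def linear_predictor(self, param: str, terms: dict[str, float]) -> float:
        """Intercept plus covariate contributions on the transformed scale."""
        value = self.theta.get(param, 0.0)
        for term in self.covariate_terms(param):
            value += self.theta[param + ":" + term] * terms[term]
        return value

    def with_theta(self, **updates: float) -> "PopulationModel":
        return replace(self, theta={**self.theta, **updates})


def individual_params(
    pop: PopulationModel,
    dcov: DerivedCovariates,
    eta: dict[str, float] | None = None,
) -> IndividualParameters:
    """Individual PK parameters for one subject.

    ``eta`` holds the subject's random effects on ``lV``, ``lk`` and ``dk``
    (missing entries are 0, i.e. the population-typical subject).  Raises
    ``ValueError`` if the resulting parameters are invalid (e.g. elimination
    would become negative); samplers use this as a rejection signal.
    """
    eta = eta or {}
    lv = pop.linear_predictor("lV", dcov.terms) + eta.get("lV", 0.0)
    lk = pop.linear_predictor("lk", dcov.terms) + eta.get("lk", 0.0)
    dk = pop.linear_predictor("dk", dcov.terms) + eta.get("dk", 0.0)
    lkappa = pop.linear_predictor("lkappa", dcov.terms)
    return IndividualParameters(
        v=float(np.exp(lv)), k=float(np.exp(lk)), d_k=float(dk),
        kappa_k=float(np.exp(lkappa)),
    )


def final_model() -> PopulationModel:
    """The packaged final busulfan model (fixed effects, Omega^2, sigma)."""
    return PopulationModel(
        theta=dict(_params.FINAL_THETA),
        omega2=dict(_params.FINAL_OMEGA2),
        sigma=_params.FINAL_SIGMA,
        se=dict(_params.FINAL_SE),
        n_subjects=_params.FINAL_N_SUBJECTS,
    )
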