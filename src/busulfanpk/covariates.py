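"""Derived body-size and maturation covariates.

Busulfan clearance in a mostly pediatric transplant population depends on body
composition and on the maturation of the elimination machinery during the
first year of life.  This module computes the derived covariates used by the
population model:

* body surface area (BSA, m^2) from the square-root height-weight formula,
* total body water (TBW, L) from weight, height, age and sex,
* fat-free mass (FFM, kg) from the sexed two-constant formula,
* a sigmoidal maturation function ``F_mat`` of postmenstrual age (PMA), which
  rises from 0.5 at 46 weeks PMA towards 1 in older children,

and assembles the centered covariate terms the mixed-effects model consumes
(``dlnTBW = ln(TBW / 10 L)`` and so on).  A missing covariate is replaced by
its reference value, which makes the corresponding centered term exactly 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .params import REFERENCE_VALUES

log = logging.getLogger(__name__)

#: Mean calendar year length in weeks; used for the years -> weeks conversion
#: in the postmenstrual-age calculation.
WEEKS_PER_YEAR = 52.1775

#: Gestational offset added to postnatal age to obtain PMA, weeks.
PMA_OFFSET_WEEKS = 40.0

#: PMA (weeks) at which the maturation function equals 0.5.
FMAT_PMA50 = 46.0

#: Hill coefficient of the maturation function.
FMAT_HILL = 2.3


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value!r}")


def bsa(weight: float, height: float) -> float:
    """Body surface area (m^2) from weight (kg) and height (cm)."""
    _require_positive(weight=weight, height=height)
    return math.sqrt(height * weight / 3600.0)


def tbw(weight: float, height: float, age: float, sex: str) -> float:
    """Total body water (L) from weight (kg), height (cm), age (y) and sex."""
    _require_positive(weight=weight, height=height, age=age)
    female = 1.0 if _is_female(sex) else 0.0
    return math.exp(
        -2.952
        + 0.551 * math.log(weight)
        + 0.796 * math.log(height)
        + 0.008 * age
        - 0.047 * female
    )


def ffm(weight: float, height: float, sex: str) -> float:
    """Fat-free mass (kg) from weight (kg), height (cm) and sex.

    Height enters in meters; the result is always below total body weight.
    """
    _require_positive(weight=weight, height=height)
    h_m = height / 100.0
    if _is_female(sex):
        a, b = 37.99, 35.98
    else:
        a, b = 42.92, 30.93
    return a * h_m**2 * weight / (b * h_m**2 + weight)


def pma_weeks(age_years: float) -> float:
    """Postmenstrual age in weeks: postnatal age plus a fixed 40 weeks."""
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years!r}")
    return age_years * WEEKS_PER_YEAR + PMA_OFFSET_WEEKS


def fmat(age_years: float) -> float:
    """Maturation factor of busulfan elimination, in (0, 1).

    ``F_mat = 1 / (1 + (PMA / 46 weeks)^-2.3)`` with PMA the postmenstrual
    age.  Strictly increasing in age; 0.5 at 46 weeks PMA and close to 1
    beyond roughly two years of age.
    """
    pma = pma_weeks(age_years)
    return 1.0 / (1.0 + (pma / FMAT_PMA50) ** (-FMAT_HILL))


def _is_female(sex: str) -> bool:
    s = str(sex).strip().lower()
    if s in ("f", "female", "1"):
        return True
    if s in ("m", "male", "0"):
        return False
    raise ValueError(f"unrecognized sex {sex!r}")


@dataclass
class DerivedCovariates:
    """All derived covariates of one subject plus the model's centered terms.

    ``terms`` maps covariate-term names (``dlnTBW``, ``lnFmat``, ``ALL``,
    ``dTinf``, ...) to numeric values; these are the quantities that multiply
    fixed effects in the population model.
    """

    bsa: float
    tbw: float
    ffm: float
    pma: float
    fmat: float
    terms: dict[str, float] = field(default_factory=dict)


def _centered_log(value: float | None, reference: float, label: str) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        log.warning("missing %s substituted by reference value %g", label, reference)
        return 0.0
    if value <= 0:
        raise ValueError(f"{label} must be positive, got {value!r}")
    return math.log(value / reference)


def derive(cov, refs: dict[str, float] | None = None) -> DerivedCovariates:
    """Compute all derived covariates for one subject.

    ``cov`` is a :class:`busulfanpk.datamodel.SubjectCovariates` (or anything
    with the same attributes).  Missing laboratory values are substituted by
    their reference values, which zeroes the corresponding centered term.
    """
    refs = dict(REFERENCE_VALUES, **(refs or {}))
    bsa_v = bsa(cov.weight, cov.height)
    tbw_v = tbw(cov.weight, cov.height, cov.age, cov.sex)
    ffm_v = ffm(cov.weight, cov.height, cov.sex)
    fmat_v = fmat(cov.age)
    disease = str(cov.disease_group)
    terms = {
        "dlnTBW": math.log(tbw_v / refs["tbw"]),
        "dlnW": math.log(cov.weight / refs["weight"]),
        "dlnH": math.log(cov.height / refs["height"]),
        "dlnBSA": math.log(bsa_v / refs["bsa"]),
        "dlnFFM": math.log(ffm_v / refs["ffm"]),
        "lnFmat": math.log(fmat_v),
        "dlnAlb": _centered_log(cov.albumin, refs["albumin"], "albumin"),
        "dlnHct": _centered_log(cov.hematocrit, refs["hematocrit"], "hematocrit"),
        "dlnLeu": _centered_log(cov.leukocytes, refs["leukocytes"], "leukocytes"),
        "dlnTprot": _centered_log(
            cov.total_protein, refs["total_protein"], "total protein"
        ),
        "ALL": 1.0 if disease == "ALL" else 0.0,
        "HLHXLP": 1.0 if disease == "HLH/XLP" else 0.0,
        "dTinf": float(cov.tinf_h) - refs["tinf"],
        "female": 1.0 if _is_female(cov.sex) else 0.0,
    }
    return DerivedCovariates(
        bsa=bsa_v, tbw=tbw_v, ffm=ffm_v, pma=pma_weeks(cov.age), fmat=fmat_v,
        terms=terms,
    )
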