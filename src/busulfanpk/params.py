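"""Packaged final population-PK model for twice-daily intravenous busulfan.

The model describes plasma busulfan after repeated intravenous infusions with a
one-compartment disposition model whose elimination rate constant declines
exponentially from the start of therapy:

* ``ln V``  (volume of distribution, L) scales with total body water (TBW) and
  shifts with infusion duration,
* ``ln k``  (elimination rate constant, 1/h) scales with TBW, an age maturation
  function, serum albumin, an ALL diagnosis indicator, and infusion duration,
* ``d_k``   (fractional amplitude of the change in ``k`` over time) shifts for
  the HLH/XLP diagnosis group,
* ``ln kappa_k`` (rate of the change, 1/h) is a plain fixed effect.

Random effects (diagonal variances ``omega2``) act on ``ln V``, ``ln k`` and
``d_k``; the residual error is additive with standard deviation ``sigma`` in
mg/L.  Fixed-effect names follow the ``<parameter>`` /
``<parameter>:<covariate-term>`` convention used by
:class:`busulfanpk.popmodel.PopulationModel`.
"""

from __future__ import annotations

# Fixed effects of the final model (log-scale where the parameter is fitted
# in logs).  Covariate terms are centered at the reference values below, so the
# intercepts are the typical values at TBW 10 L, albumin 30 g/L, 3 h infusions,
# mature age, and no ALL / HLH-XLP diagnosis.
FINAL_THETA: dict[str, float] = {
    "lV": 2.459,            # ln(V [L]) at reference covariates  -> V = 11.70 L
    "lV:dlnTBW": 0.931,     # effect of ln(TBW / 10 L)
    "lV:dTinf": 0.226,      # effect of (T_inf - 3 h) [1/h]
    "lk": -1.007,           # ln(k [1/h]) at reference covariates -> k = 0.365/h
    "lk:dlnTBW": -0.189,
    "lk:lnFmat": 0.697,     # effect of ln(F_mat); 0 for mature subjects
    "lk:dlnAlb": 0.331,     # effect of ln(albumin / 30 g/L)
    "lk:ALL": -0.210,       # acute lymphoblastic leukemia indicator
    "lk:dTinf": -0.161,
    "dk": -0.167,           # amplitude of the exponential change in k
    "dk:HLHXLP": -0.145,    # extra amplitude for HLH/XLP patients
    "lkappa": -2.965,       # ln(kappa_k [1/h]); half-life of the change 13.4 h
}

#: Variances of the between-subject random effects (diagonal).
FINAL_OMEGA2: dict[str, float] = {"lV": 0.029, "lk": 0.033, "dk": 0.032}

#: Additive residual error SD, mg/L.
FINAL_SIGMA: float = 0.076

#: Standard errors of the fixed effects (same keys as FINAL_THETA).
FINAL_SE: dict[str, float] = {
    "lV": 0.0189,
    "lV:dlnTBW": 0.0233,
    "lV:dTinf": 0.0356,
    "lk": 0.0329,
    "lk:dlnTBW": 0.0411,
    "lk:lnFmat": 0.2001,
    "lk:dlnAlb": 0.1073,
    "lk:ALL": 0.0592,
    "lk:dTinf": 0.0420,
    "dk": 0.0191,
    "dk:HLHXLP": 0.0540,
    "lkappa": 0.1094,
}

#: 95% bootstrap confidence intervals of the fixed effects.
FINAL_BOOTSTRAP_CI: dict[str, tuple[float, float]] = {
    "lV": (2.432, 2.491),
    "lV:dlnTBW": (0.872, 0.987),
    "lV:dTinf": (0.134, 0.329),
    "lk": (-1.065, -0.952),
    "lk:dlnTBW": (-0.291, -0.106),
    "lk:lnFmat": (0.348, 1.061),
    "lk:dlnAlb": (0.090, 0.653),
    "lk:ALL": (-0.398, -0.030),
    "lk:dTinf": (-0.264, -0.085),
    "dk": (-0.198, -0.122),
    "dk:HLHXLP": (-0.255, -0.030),
    "lkappa": (-3.204, -2.390),
}

#: Number of subjects behind the packaged estimates.
FINAL_N_SUBJECTS: int = 124

# Reference (centering) values for the covariate terms.  TBW, albumin and
# T_inf come with the packaged model; the remaining entries are rounded
# population medians used when alternative body-size or laboratory covariates
# are screened during model building.
REFERENCE_VALUES: dict[str, float] = {
    "tbw": 10.0,      # L
    "albumin": 30.0,  # g/L
    "tinf": 3.0,      # h
    "weight": 17.0,   # kg
    "height": 105.0,  # cm
    "bsa": 0.7,       # m^2
    "ffm": 14.0,      # kg
    "hematocrit": 0.3,   # L/L
    "leukocytes": 4.0,   # G/L
    "total_protein": 60.0,  # g/L
}
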