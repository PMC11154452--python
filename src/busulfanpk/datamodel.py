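"""Dataset schema, CSV readers/writers and run configuration.

The pipeline exchanges data in a NONMEM-like long CSV format: one row per
event, where ``EVID=1`` rows are infusion starts (``AMT`` mg over ``DUR``
hours), ``EVID=0`` rows are measured plasma concentrations (``DV`` mg/L), and
``EVID=2`` rows time-stamp co-medication administrations (``COMED`` drug
label).  Subject-level covariates are carried on every row of a subject;
missing values use an explicit ``NA`` token.

All times are hours from the subject's first infusion start; concentrations
are mg/L and doses mg throughout the package.
"""

from __future__ import annotations

import logging
import math
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DISEASE_GROUPS = (
    "ALL", "AML", "CGD", "hemoglobinopathies", "HLH/XLP", "PID",
    "metabolic", "neuroblastoma", "other",
)

REQUIRED_COLUMNS = (
    "ID", "TIME", "EVID", "AMT", "DUR", "DV", "WT", "HT", "AGE", "SEX",
    "DISEASE", "ALB", "TPROT", "HCT", "LEU", "TINF", "COMED", "COMED_TIME",
)


class SchemaError(ValueError):
    """A required column is missing or a value violates the schema."""


class ValidationError(ValueError):
    """The dataset violates a structural invariant."""


@dataclass
class DoseEvent:
    """One intravenous infusion: start time t0 (h), amount (mg), duration (h)."""

    subject_id: str
    t0: float
    amount: float
    duration: float
    dose_index: int

    @property
    def rate(self) -> float:
        """Infusion rate R0 = amount / duration, mg/h."""
        return self.amount / self.duration

    def validate(self) -> None:
        if not self.duration > 0:
            raise ValidationError(
                f"subject {self.subject_id}: infusion duration must be > 0, "
                f"got {self.duration!r}"
            )
        if not self.amount > 0:
            raise ValidationError(
                f"subject {self.subject_id}: dose amount must be > 0, "
                f"got {self.amount!r}"
            )


@dataclass
class Observation:
    """One measured plasma concentration (mg/L) at time t (h)."""

    subject_id: str
    t: float
    conc: float
    dosing_interval: int = 0

    def validate(self) -> None:
        if self.conc < 0 or self.t < 0:
            raise ValidationError(
                f"subject {self.subject_id}: observation must have t >= 0 and "
                f"conc >= 0, got t={self.t!r}, conc={self.conc!r}"
            )


@dataclass
class SubjectCovariates:
    """Demographics, disease group, labs and treatment factors of one subject.

    Laboratory values may be ``None`` (missing); substitution by reference
    values happens downstream in the covariates module, never here.
    """

    weight: float
    height: float
    age: float
    sex: str
    disease_group: str
    albumin: float | None = None
    total_protein: float | None = None
    hematocrit: float | None = None
    leukocytes: float | None = None
    tinf_h: float = 3.0
    comedication: list[tuple[str, float]] = field(default_factory=list)

    def validate(self) -> None:
        if not (self.weight > 0 and self.height > 0 and self.age > 0):
            raise ValidationError(
                f"weight, height and age must be positive, got "
                f"W={self.weight!r}, H={self.height!r}, age={self.age!r}"
            )
        if self.albumin is not None and not self.albumin > 0:
            raise ValidationError(f"albumin must be positive, got {self.albumin!r}")
        if self.tinf_h not in (3.0, 4.0):
            raise ValidationError(f"tinf_h must be 3 or 4, got {self.tinf_h!r}")
        if self.disease_group not in DISEASE_GROUPS:
            raise ValidationError(
                f"unknown disease group {self.disease_group!r}; "
                f"expected one of {DISEASE_GROUPS}"
            )


@dataclass
class Subject:
    subject_id: str
    covariates: SubjectCovariates
    doses: list[DoseEvent]
    observations: list[Observation]

    def validate(self) -> None:
        if not self.doses:
            raise ValidationError(f"subject {self.subject_id} has no dose events")
        self.covariates.validate()
        t_prev = -math.inf
        for i, d in enumerate(self.doses, start=1):
            d.validate()
            if d.t0 <= t_prev:
                raise ValidationError(
                    f"subject {self.subject_id}: dose times must be strictly "
                    f"increasing (dose {i} at t={d.t0})"
                )
            if d.dose_index != i:
                raise ValidationError(
                    f"subject {self.subject_id}: dose_index must be consecutive "
                    f"from 1, got {d.dose_index} at position {i}"
                )
            t_prev = d.t0
        starts = [d.t0 for d in self.doses]
        for obs in self.observations:
            obs.validate()
            j = int(np.searchsorted(starts, obs.t, side="right"))
            if obs.dosing_interval == 0:
                obs.dosing_interval = max(j, 1)
            elif obs.dosing_interval != max(j, 1) and obs.t >= starts[0]:
                raise ValidationError(
                    f"subject {self.subject_id}: observation at t={obs.t} "
                    f"labelled interval {obs.dosing_interval}, expected {j}"
                )


@dataclass
class StudyDataset:
    """A validated cohort: subjects with covariates, doses and observations."""

    subjects: list[Subject]
    provenance: str = ""

    def validate(self) -> "StudyDataset":
        seen = set()
        for s in self.subjects:
            if s.subject_id in seen:
                raise ValidationError(f"duplicate subject id {s.subject_id!r}")
            seen.add(s.subject_id)
            s.validate()
        return self

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_dataset(path, schema_config: dict | None = None) -> StudyDataset:
    """Read a long-format event CSV into a validated :class:`StudyDataset`."""
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True, dtype={"ID": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    subjects = []
    for sid, grp in df.groupby("ID", sort=False):
        first = grp.iloc[0]
        cov = SubjectCovariates(
            weight=float(first["WT"]),
            height=float(first["HT"]),
            age=float(first["AGE"]),
            sex=str(first["SEX"]),
            disease_group=str(first["DISEASE"]),
            albumin=_opt(first["ALB"]),
            total_protein=_opt(first["TPROT"]),
            hematocrit=_opt(first["HCT"]),
            leukocytes=_opt(first["LEU"]),
            tinf_h=float(first["TINF"]),
        )
        doses, obs = [], []
        for _, row in grp.iterrows():
            evid = int(row["EVID"])
            if evid == 1:
                doses.append(
                    DoseEvent(
                        subject_id=str(sid),
                        t0=float(row["TIME"]),
                        amount=float(row["AMT"]),
                        duration=float(row["DUR"]),
                        dose_index=len(doses) + 1,
                    )
                )
            elif evid == 0:
                obs.append(
                    Observation(subject_id=str(sid), t=float(row["TIME"]),
                                conc=float(row["DV"]))
                )
            elif evid == 2:
                cov.comedication.append(
                    (str(row["COMED"]), float(row["COMED_TIME"]))
                )
            else:
                raise SchemaError(f"subject {sid}: unknown EVID {evid}")
        subjects.append(Subject(str(sid), cov, doses, obs))
    return StudyDataset(subjects=subjects, provenance=str(path)).validate()


def write_dataset(ds: StudyDataset, path) -> None:
    """Write a dataset in the same long CSV schema :func:`read_dataset` reads."""
    rows = []

    def base(s: Subject) -> dict:
        c = s.covariates
        return {
            "ID": s.subject_id, "WT": c.weight, "HT": c.height, "AGE": c.age,
            "SEX": c.sex, "DISEASE": c.disease_group,
            "ALB": c.albumin, "TPROT": c.total_protein, "HCT": c.hematocrit,
            "LEU": c.leukocytes, "TINF": c.tinf_h,
            "COMED": None, "COMED_TIME": None,
        }

    for s in ds.subjects:
        for d in s.doses:
            rows.append(base(s) | {"TIME": d.t0, "EVID": 1, "AMT": d.amount,
                                   "DUR": d.duration, "DV": None})
        for o in s.observations:
            rows.append(base(s) | {"TIME": o.t, "EVID": 0, "AMT": None,
                                   "DUR": None, "DV": o.conc})
        for drug, t in s.covariates.comedication:
            rows.append(base(s) | {"TIME": t, "EVID": 2, "AMT": None,
                                   "DUR": None, "DV": None,
                                   "COMED": drug, "COMED_TIME": t})
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    if not rows:
        df = pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    df.to_csv(path, index=False, na_rep="NA", float_format="%.17g")


#: Valid configuration keys and their defaults.  Iteration counts follow the
#: study protocol: 2000/300 exploration/smoothing iterations for final fits,
#: 600/100 during model building; 10000 simulations for npde, 1000 for the
#: visual predictive check, 500 bootstrap replicates.
CONFIG_DEFAULTS: dict[str, object] = {
    "saem_exploration": 2000,
    "saem_smoothing": 300,
    "build_exploration": 600,
    "build_smoothing": 100,
    "npde_simulations": 10000,
    "vpc_simulations": 1000,
    "bootstrap": 500,
    "seed": 12345,
    "output_dir": "output",
}


def load_config(path) -> dict:
    """Load a plain ``key = value`` configuration file, filling defaults."""
    config = dict(CONFIG_DEFAULTS)
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in CONFIG_DEFAULTS:
            raise SchemaError(
                f"{path}:{lineno}: unknown key {key!r}; valid keys: "
                f"{sorted(CONFIG_DEFAULTS)}"
            )
        default = CONFIG_DEFAULTS[key]
        config[key] = type(default)(value) if not isinstance(default, str) else value
    return config


@contextmanager
def stage_timer(name: str):
    """Log the wall-clock duration of a pipeline stage to stderr."""
    t0 = time.perf_counter()
    log.info("stage %s started", name)
    try:
        yield
    finally:
        log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
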