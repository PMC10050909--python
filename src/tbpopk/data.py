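"""Dataset containers, NONMEM-dialect I/O, occasion assignment, and BLQ handling.

The longitudinal concentration data are held in a light object model
(:class:`Cohort` -> :class:`SubjectRecord` -> :class:`DoseEvent` /
:class:`Observation`) mirroring the usual NONMEM dataset semantics:
one row per event, ``EVID=1`` dose records and ``EVID=0`` observation
records, with covariates carried on every row.

Censored observations below the assay's lower limit of quantification
(LLOQ) are pre-processed with Beal's M6 rule: within each consecutive
run of BLQ samples the first is imputed at LLOQ/2 and the remainder are
dropped from the likelihood.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DRUGS",
    "LLOQ",
    "GROUPS",
    "DoseEvent",
    "Observation",
    "SubjectRecord",
    "Cohort",
    "read_dataset",
    "write_dataset",
    "assign_occasions",
    "apply_m6",
    "compute_ffm",
    "impute_height",
    "impute_bilirubin",
]

DRUGS = ("rifampicin", "isoniazid", "pyrazinamide")

#: Assay lower limit of quantification per drug (mg/L).
LLOQ = {"rifampicin": 0.117, "isoniazid": 0.105, "pyrazinamide": 0.203}

GROUPS = ("outpatient", "hosp_survivor", "hosp_death")

#: Reference conjugated bilirubin used both as the covariate centering value
#: and as the imputation value for subjects with a missing measurement (µmol/L).
BRC_REFERENCE = 6.0


@dataclass
class DoseEvent:
    """A single dosing event, time in hours relative to the PK-day dose."""

    time: float
    amount: float  # mg of the specific drug
    occasion: int | None = None


@dataclass
class Observation:
    """A single concentration sample.

    ``status`` is one of ``measured``, ``imputed_half_lloq`` or ``dropped``;
    dropped observations contribute nothing to the likelihood.
    """

    time: float
    value: float | None
    blq: bool = False
    lloq: float = np.nan
    status: str = "measured"

    @property
    def in_likelihood(self) -> bool:
        return self.status != "dropped" and self.value is not None


@dataclass
class SubjectRecord:
    """One subject: covariates plus dosing history and observations."""

    subject_id: str
    group: str
    sex: str  # "male" / "female"
    weight: float  # kg
    height: float | None  # m; None until imputed
    age: float
    conjugated_bilirubin: float | None  # µmol/L; None until imputed
    hiv_positive: bool = True
    formulation: str = "FDC"
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)
    height_imputed: bool = False
    brc_imputed: bool = False
    total_bilirubin: float | None = None
    #: true NAT2 phenotype label when known (synthetic cohorts carry it)
    nat2_fast: bool | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")
        if self.weight is None or self.weight <= 0:
            raise ValueError(f"subject {self.subject_id}: weight must be positive")

    @property
    def ffm(self) -> float:
        """Fat-free mass (kg), derived from weight, height and sex."""
        if self.height is None:
            raise ValueError(
                f"subject {self.subject_id}: height missing; run impute_height first"
            )
        return compute_ffm(self.weight, self.height, self.sex)


@dataclass
class Cohort:
    """All subjects for one drug; LLOQ is uniform within the cohort."""

    drug: str
    subjects: list[SubjectRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug label {self.drug!r}")

    @property
    def lloq(self) -> float:
        return LLOQ[self.drug]

    def __len__(self) -> int:
        return len(self.subjects)

    def copy(self) -> "Cohort":
        return copy.deepcopy(self)

    def n_observations(self, likelihood_only: bool = False) -> int:
        return sum(
            sum(1 for o in s.observations if (o.in_likelihood or not likelihood_only))
            for s in self.subjects
        )


# ---------------------------------------------------------------------------
# covariate derivations
# ---------------------------------------------------------------------------

def compute_ffm(weight, height, sex):
    """Fat-free mass (kg) from the Janmahasatian sex-specific formula.

    FFM_male   = 9270·WT / (6680 + 216·BMI)
    FFM_female = 9270·WT / (8780 + 244·BMI),  BMI = WT/HT² (kg/m²)

    Parameters may be scalars or arrays; ``sex`` is "male"/"female" (or an
    array of those labels).
    """
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be positive")
    bmi = weight / height**2
    male = np.asarray(sex) == "male"
    denom = np.where(male, 6680.0 + 216.0 * bmi, 8780.0 + 244.0 * bmi)
    out = 9270.0 * weight / denom
    return float(out) if out.ndim == 0 else out


def impute_height(cohort: Cohort) -> Cohort:
    """Replace missing heights by the least-squares fit of height on sex.

    A regression of height on a sex indicator has fitted values equal to the
    per-sex means, so the imputed value is the mean observed height of the
    subject's sex stratum.  Returns a new cohort; imputation is flagged.
    """
    out = cohort.copy()
    means: dict[str, float] = {}
    for sex in ("male", "female"):
        obs = [s.height for s in out.subjects if s.sex == sex and s.height is not None]
        if obs:
            means[sex] = float(np.mean(obs))
    for s in out.subjects:
        if s.height is None:
            if s.sex not in means:
                raise ValueError(
                    f"cannot impute height for {s.subject_id}: "
                    f"no observed heights for sex {s.sex!r}"
                )
            s.height = means[s.sex]
            s.height_imputed = True
    return out


def impute_bilirubin(cohort: Cohort, value: float = BRC_REFERENCE) -> Cohort:
    """Fill missing conjugated bilirubin with the reference median.

    Using the covariate-centering median (6 µmol/L) makes the bilirubin
    covariate factor exactly 1 for imputed subjects.
    """
    out = cohort.copy()
    for s in out.subjects:
        if s.conjugated_bilirubin is None:
            s.conjugated_bilirubin = value
            s.brc_imputed = True
    return out


# ---------------------------------------------------------------------------
# occasions
# ---------------------------------------------------------------------------

def assign_occasions(cohort: Cohort) -> Cohort:
    """Assign between-occasion-variability occasion indices to dose events.

    An occasion is a dosing event followed by at least one sample before the
    next dose.  A sample drawn at exactly a dose time is a pre-dose sample
    and belongs to the preceding dose.  Doses without any following sample
    are merged into the preceding occasion (leading ones, which have no
    preceding occasion, join the first sampled dose), so every occasion
    contains exactly one sampled dose.  Occasions are numbered 1, 2, ... in
    time order; with the study design (two prior daily doses, a pre-dose
    sample and five post-dose samples) every subject gets exactly two
    occasions.
    """
    out = cohort.copy()
    for s in out.subjects:
        doses = sorted(s.doses, key=lambda d: d.time)
        if not doses:
            continue
        times = np.array([d.time for d in doses])
        obs_times = np.array([o.time for o in s.observations])
        # owning dose of each observation: last dose strictly before the sample
        sampled = np.zeros(len(doses), dtype=bool)
        for t in obs_times:
            k = int(np.searchsorted(times, t, side="left")) - 1
            if k >= 0:
                sampled[k] = True
        occ = np.zeros(len(doses), dtype=int)
        current = 0
        leading = []  # unsampled doses before the first sampled dose
        for k in range(len(doses)):
            if sampled[k]:
                current += 1
                for j in leading:
                    occ[j] = current
                leading = []
                occ[k] = current
            elif current == 0:
                leading.append(k)
            else:
                occ[k] = current  # merged into the preceding occasion
        for j in leading:  # degenerate: no sampled dose at all
            occ[j] = 1
        occ[occ == 0] = np.maximum(occ[occ == 0], 1)
        for d, o in zip(doses, occ):
            d.occasion = int(o)
        s.doses = doses
    return out


# ---------------------------------------------------------------------------
# BLQ (Beal M6)
# ---------------------------------------------------------------------------

def apply_m6(cohort: Cohort) -> Cohort:
    """Apply Beal's M6 rule to BLQ observations.

    Within each consecutive run of BLQ samples (in time order) the first is
    set to LLOQ/2 with status ``imputed_half_lloq`` and the rest are marked
    ``dropped``.  Non-BLQ observations are untouched.  Pre-dose BLQ runs are
    treated the same as runs inside the profile.
    """
    out = cohort.copy()
    half = out.lloq / 2.0
    for s in out.subjects:
        obs = sorted(s.observations, key=lambda o: o.time)
        prev_blq = False
        for o in obs:
            if o.blq:
                if prev_blq:
                    o.status = "dropped"
                    o.value = None
                else:
                    o.status = "imputed_half_lloq"
                    o.value = half
                prev_blq = True
            else:
                prev_blq = False
        s.observations = obs
    return out


def preprocess(cohort: Cohort) -> Cohort:
    """Standard preparation pipeline: impute covariates, occasions, M6."""
    return apply_m6(assign_occasions(impute_bilirubin(impute_height(cohort))))


# ---------------------------------------------------------------------------
# NONMEM-dialect I/O
# ---------------------------------------------------------------------------

_SEX_CODE = {0: "male", 1: "female"}
_GROUP_CODE = {0: "outpatient", 1: "hosp_survivor", 2: "hosp_death"}
_FORM_CODE = {0: "FDC", 1: "separate_tablets"}


def _decode(mapping, value):
    return mapping[int(value)]


def _encode(mapping, label):
    for k, v in mapping.items():
        if v == label:
            return k
    raise ValueError(f"unknown label {label!r}")


def read_dataset(path, drug: str) -> Cohort:
    """Read a comma-delimited NONMEM-style dataset into a :class:`Cohort`.

    Expected columns: ID, TIME, AMT, EVID, DV, MDV, BLQ plus covariates
    GROUP, SEX, WT, HT, AGE, BRC, HIV, FORM.  Missing values are empty cells
    or ".".  EVID=1 rows are doses; EVID=0 rows with MDV=0 are observations
    that enter the likelihood.
    """
    if drug not in DRUGS:
        raise ValueError(f"unknown drug label {drug!r}")
    df = pd.read_csv(path, na_values=["."])
    lloq = LLOQ[drug]
    cohort = Cohort(drug=drug)
    bad_subjects = []
    for sid, g in df.groupby("ID", sort=False):
        row0 = g.iloc[0]
        rec = SubjectRecord(
            subject_id=str(sid),
            group=_decode(_GROUP_CODE, row0["GROUP"]),
            sex=_decode(_SEX_CODE, row0["SEX"]),
            weight=float(row0["WT"]),
            height=None if pd.isna(row0["HT"]) else float(row0["HT"]),
            age=float(row0["AGE"]),
            conjugated_bilirubin=None if pd.isna(row0["BRC"]) else float(row0["BRC"]),
            hiv_positive=bool(row0["HIV"]),
            formulation=_decode(_FORM_CODE, row0.get("FORM", 0)),
        )
        for _, row in g.iterrows():
            if int(row["EVID"]) == 1:
                rec.doses.append(DoseEvent(time=float(row["TIME"]), amount=float(row["AMT"])))
            else:
                mdv = int(row["MDV"])
                dv = row["DV"]
                if mdv == 1 or pd.isna(dv):
                    # non-dose record excluded from the likelihood set
                    continue
                rec.observations.append(
                    Observation(
                        time=float(row["TIME"]),
                        value=float(dv),
                        blq=bool(int(row.get("BLQ", 0))),
                        lloq=lloq,
                    )
                )
        if rec.observations and rec.doses:
            first_dose = min(d.time for d in rec.doses)
            if any(o.time < first_dose for o in rec.observations):
                bad_subjects.append(str(sid))
        cohort.subjects.append(rec)
    if bad_subjects:
        raise ValueError(
            "observation before first recorded dose for subjects: "
            + ", ".join(bad_subjects)
        )
    return cohort


def write_dataset(cohort: Cohort, path) -> None:
    """Write a cohort back to the comma-delimited NONMEM dialect."""
    rows = []
    for s in cohort.subjects:
        cov = dict(
            GROUP=_encode(_GROUP_CODE, s.group),
            SEX=_encode(_SEX_CODE, s.sex),
            WT=s.weight,
            HT=np.nan if s.height is None else s.height,
            AGE=s.age,
            BRC=np.nan if s.conjugated_bilirubin is None else s.conjugated_bilirubin,
            HIV=int(s.hiv_positive),
            FORM=_encode(_FORM_CODE, s.formulation),
        )
        events = [("obs", o.time, o) for o in s.observations] + [
            ("dose", d.time, d) for d in s.doses
        ]
        # pre-dose samples sort before a dose at the same time
        events.sort(key=lambda e: (e[1], e[0] == "dose"))
        for kind, t, ev in events:
            if kind == "dose":
                rows.append(
                    dict(ID=s.subject_id, TIME=t, AMT=ev.amount, EVID=1, DV=np.nan,
                         MDV=1, BLQ=0, **cov)
                )
            else:
                rows.append(
                    dict(ID=s.subject_id, TIME=t, AMT=np.nan, EVID=0,
                         DV=np.nan if ev.value is None else ev.value,
                         MDV=int(ev.value is None), BLQ=int(ev.blq), **cov)
                )
    pd.DataFrame(rows).to_csv(path, index=False, na_rep=".")
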