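"""Patient-level cohort schema, validation, and CSV round-trip I/O.

The cohort is a flat table, one row per patient, carrying the
clinicopathological variables used by the clinical risk classifiers
(histology, grade, myometrial invasion, FIGO stage, LVSI), the molecular
marker calls (POLE exonuclease-domain variant, MMR and p53 IHC, CTNNB1
exon-3 status, plus the auxiliary IHC biomarkers), and the two
disease-specific endpoints as (time, event) pairs in months:

* RFS — time from surgery to first recurrence or death from disease;
* OS  — time from surgery to death from disease.

Non-evaluable molecular or pathological calls are an explicit ``"NE"``
state rather than an absent cell, so that imputation is a visible, logged
transformation instead of silent NaN handling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "CATEGORICAL_VOCAB",
    "PatientRecord",
    "Cohort",
    "Violation",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

#: Canonical column order of the cohort CSV.
COLUMNS = [
    "patient_id",
    "age_years",
    "histology",
    "grade",
    "myometrial_invasion",
    "figo_stage",
    "lvsi",
    "pole_variant",
    "mmr_status",
    "p53_ihc",
    "ctnnb1_exon3",
    "er",
    "pr",
    "ecad",
    "her2",
    "arid1a",
    "pten",
    "l1cam",
    "rfs_time_months",
    "rfs_event",
    "os_time_months",
    "os_event",
]

NE = "NE"

_MARKER = ["positive", "negative", NE]

#: Allowed tokens per categorical column. ``pole_variant`` is a free string
#: (amino-acid change, e.g. "P286R") or empty for wild type, so it is absent
#: from this table.
CATEGORICAL_VOCAB: dict[str, list[str]] = {
    "histology": ["EEC", "NEEC"],
    "grade": ["G1", "G2", "G3"],
    "myometrial_invasion": ["none", "lt50", "ge50"],
    "figo_stage": ["IA", "IB", "II"],
    "lvsi": ["negative", "positive", NE],
    "mmr_status": ["deficient", "proficient", NE],
    "p53_ihc": ["abnormal", "wildtype", NE],
    "ctnnb1_exon3": ["mutated", "wildtype", NE],
    "er": _MARKER,
    "pr": _MARKER,
    "ecad": _MARKER,
    "her2": _MARKER,
    "arid1a": _MARKER,
    "pten": _MARKER,
    "l1cam": _MARKER,
}

_NUMERIC = ["age_years", "rfs_time_months", "os_time_months"]
_EVENTS = ["rfs_event", "os_event"]


class SchemaError(ValueError):
    """Raised when a CSV does not conform to the cohort schema."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's clinicopathological, molecular, and follow-up fields."""

    patient_id: str
    age_years: float
    histology: str
    grade: str
    myometrial_invasion: str
    figo_stage: str
    lvsi: str
    pole_variant: str
    mmr_status: str
    p53_ihc: str
    ctnnb1_exon3: str
    er: str
    pr: str
    ecad: str
    her2: str
    arid1a: str
    pten: str
    l1cam: str
    rfs_time_months: float
    rfs_event: bool
    os_time_months: float
    os_event: bool

    @property
    def low_grade(self) -> bool:
        """Derived binary grade: low = G1 or G2, high = G3."""
        return self.grade in ("G1", "G2")


@dataclass(frozen=True)
class Violation:
    patient_id: str
    rule: str
    message: str


@dataclass
class Cohort:
    """An ordered collection of patients backed by a pandas DataFrame."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        self.df = self.df[COLUMNS].reset_index(drop=True)
        _check_vocab(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[PatientRecord]:
        return (self.record(i) for i in range(len(self)))

    def record(self, i: int) -> PatientRecord:
        row = self.df.iloc[i]
        return PatientRecord(
            patient_id=str(row["patient_id"]),
            age_years=float(row["age_years"]),
            histology=row["histology"],
            grade=row["grade"],
            myometrial_invasion=row["myometrial_invasion"],
            figo_stage=row["figo_stage"],
            lvsi=row["lvsi"],
            pole_variant=row["pole_variant"],
            mmr_status=row["mmr_status"],
            p53_ihc=row["p53_ihc"],
            ctnnb1_exon3=row["ctnnb1_exon3"],
            er=row["er"],
            pr=row["pr"],
            ecad=row["ecad"],
            her2=row["her2"],
            arid1a=row["arid1a"],
            pten=row["pten"],
            l1cam=row["l1cam"],
            rfs_time_months=float(row["rfs_time_months"]),
            rfs_event=bool(row["rfs_event"]),
            os_time_months=float(row["os_time_months"]),
            os_event=bool(row["os_event"]),
        )

    @classmethod
    def from_records(cls, records: list[PatientRecord], provenance: dict | None = None) -> "Cohort":
        df = pd.DataFrame([vars(r) for r in records], columns=COLUMNS)
        df[_EVENTS] = df[_EVENTS].astype(int)
        return cls(df, provenance or {})

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), dict(self.provenance))


def _check_vocab(df: pd.DataFrame) -> None:
    for col, vocab in CATEGORICAL_VOCAB.items():
        bad = ~df[col].isin(vocab)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"column '{col}', row {row}: invalid category "
                f"{df[col].iloc[row]!r} (allowed: {vocab})"
            )
    for col in _EVENTS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if not vals.isin([0, 1]).all():
            row = int(np.flatnonzero(~vals.isin([0, 1]).to_numpy())[0])
            raise SchemaError(f"column '{col}', row {row}: event flag must be 0/1")


def read_cohort(path) -> Cohort:
    """Read a cohort CSV into a validated :class:`Cohort`.

    ``NE`` and empty cells map to the explicit missing states; unknown
    category tokens raise :class:`SchemaError` naming the column and row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in _EVENTS:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    cohort = Cohort(df, provenance={"source": str(path)})
    dup = cohort.df["patient_id"][cohort.df["patient_id"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"duplicate patient_id: {dup.iloc[0]!r}")
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV in canonical column order (NE stays "NE")."""
    out = cohort.df.copy()
    for col in _NUMERIC:
        # integral values serialise without a trailing ".0" so round-trips
        # are byte-stable
        out[col] = [
            str(int(v)) if float(v) == int(v) else repr(float(v)) for v in out[col]
        ]
    out[_EVENTS] = out[_EVENTS].astype(int)
    out.to_csv(path, index=False, lineterminator="\n")


def cohort_to_csv_bytes(cohort: Cohort) -> bytes:
    buf = io.StringIO()
    write_cohort(cohort, buf)
    return buf.getvalue().encode()


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Report every invariant violation; an empty list means valid.

    Checked rules:

    * ``unique_patient_id`` — identifiers are unique;
    * ``stage_depth`` — FIGO IA requires no/inner-half myometrial invasion,
      IB requires outer-half invasion (stage II is unconstrained);
    * ``rfs_le_os`` — RFS time never exceeds OS time;
    * ``positive_age`` / ``nonneg_times`` — numeric sanity.
    """
    out: list[Violation] = []
    df = cohort.df
    for pid in df["patient_id"][df["patient_id"].duplicated()].unique():
        out.append(Violation(str(pid), "unique_patient_id", "duplicate patient_id"))
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        stage, inv = row["figo_stage"], row["myometrial_invasion"]
        if stage == "IA" and inv not in ("none", "lt50"):
            out.append(Violation(pid, "stage_depth", f"stage IA with invasion {inv!r}"))
        elif stage == "IB" and inv != "ge50":
            out.append(Violation(pid, "stage_depth", f"stage IB with invasion {inv!r}"))
        if float(row["rfs_time_months"]) > float(row["os_time_months"]):
            out.append(
                Violation(
                    pid,
                    "rfs_le_os",
                    f"RFS time {row['rfs_time_months']} > OS time {row['os_time_months']}",
                )
            )
        if float(row["age_years"]) <= 0:
            out.append(Violation(pid, "positive_age", "age must be positive"))
        if float(row["rfs_time_months"]) < 0 or float(row["os_time_months"]) < 0:
            out.append(Violation(pid, "nonneg_times", "negative follow-up time"))
    return out
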