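"""Longitudinal blood-pressure phenotypes and their three analysis views.

Measurements taken under antihypertensive medication are preadjusted by a fixed
offset (+10 mm Hg systolic, +5 mm Hg diastolic) to approximate the untreated
value.  The preadjusted trait is then analyzed as (a) the baseline visit only,
(b) the per-subject time average, or (c) all repeated measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

__all__ = [
    "MEDICATION_OFFSET",
    "LongitudinalPhenotypes",
    "PhenotypeView",
    "read_phenotypes",
    "medication_preadjust",
    "make_view",
]

#: mm Hg added to treated measurements, by trait.
MEDICATION_OFFSET = {"SBP": 10.0, "DBP": 5.0}

VIEW_MODES = ("baseline", "averaged", "repeated")


@dataclass(frozen=True)
class LongitudinalPhenotypes:
    """Long-format phenotype records: one row per subject per visit.

    ``data`` columns: ``subject_id, visit, value, age, sex, smoke, med`` with
    visits contiguous from 1 per subject.  ``medication_adjusted`` guards
    against applying the preadjustment twice.
    """

    data: pd.DataFrame
    trait: str
    medication_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.trait not in MEDICATION_OFFSET:
            raise ValueError(
                f"unknown trait {self.trait!r}; expected one of {sorted(MEDICATION_OFFSET)}"
            )
        req = ["subject_id", "visit", "value", "age", "sex", "smoke", "med"]
        missing = [c for c in req if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        if self.data.duplicated(subset=["subject_id", "visit"]).any():
            raise ValueError("duplicate (subject, visit) phenotype records")
        for sid, grp in self.data.groupby("subject_id", sort=False):
            visits = sorted(grp["visit"])
            if visits != list(range(1, len(visits) + 1)):
                raise ValueError(
                    f"subject {sid!r}: visits must be contiguous from 1, got {visits}"
                )

    @property
    def subject_ids(self) -> list:
        return list(self.data["subject_id"].drop_duplicates())


@dataclass(frozen=True)
class PhenotypeView:
    """A response/covariate table for one analysis mode.

    ``frame`` columns: ``subject_id, y, age, sex, smoke`` plus ``visit`` in
    repeated mode.  Baseline keeps visit 1 only; averaged has one row per
    subject with trait and age averaged over visits; repeated keeps all rows
    with time-varying age.
    """

    mode: str
    frame: pd.DataFrame
    trait: str


def read_phenotypes(path, trait: str = "SBP") -> LongitudinalPhenotypes:
    """Read a long-format TSV: subject_id, visit, sbp, dbp, age, sex, smoke, med."""
    df = pd.read_csv(path, sep="\t")
    value_col = trait.lower()
    if value_col not in df.columns:
        raise ValueError(f"{path}: no column {value_col!r} for trait {trait}")
    data = pd.DataFrame(
        dict(
            subject_id=df["subject_id"].astype(str),
            visit=df["visit"].astype(int),
            value=df[value_col].astype(float),
            age=df["age"].astype(float),
            sex=df["sex"].astype(int),
            smoke=df["smoke"].astype(int),
            med=df["med"].astype(int),
        )
    )
    return LongitudinalPhenotypes(data=data, trait=trait)


def medication_preadjust(ph: LongitudinalPhenotypes) -> LongitudinalPhenotypes:
    """Add the medication offset to treated records (visit-specific medication honored).

    Raises if the phenotypes were already preadjusted — the offset must be
    applied exactly once.
    """
    if ph.medication_adjusted:
        raise ValueError("medication preadjustment already applied")
    offset = MEDICATION_OFFSET[ph.trait]
    data = ph.data.copy()
    data["value"] = data["value"] + offset * data["med"]
    return replace(ph, data=data, medication_adjusted=True)


def make_view(ph: LongitudinalPhenotypes, mode: str) -> PhenotypeView:
    """Derive the baseline, averaged, or repeated response view.

    Requires the medication preadjustment to have been applied.  Sex and
    smoking are taken as visit-constant (first visit's value in the averaged
    view); age is averaged in the averaged view and time-varying in the
    repeated view.
    """
    if mode not in VIEW_MODES:
        raise ValueError(f"unknown view mode {mode!r}; expected one of {VIEW_MODES}")
    if not ph.medication_adjusted:
        raise ValueError("apply medication_preadjust before deriving views")
    d = ph.data
    if mode == "baseline":
        first = d[d["visit"] == 1]
        lacking = set(d["subject_id"]) - set(first["subject_id"])
        if lacking:
            raise ValueError(f"subjects lacking visit 1: {sorted(lacking)[:10]}")
        frame = first.rename(columns={"value": "y"})[
            ["subject_id", "y", "age", "sex", "smoke"]
        ].reset_index(drop=True)
    elif mode == "averaged":
        grp = d.groupby("subject_id", sort=False)
        frame = pd.DataFrame(
            dict(
                subject_id=list(grp.groups),
                y=grp["value"].mean().to_numpy(),
                age=grp["age"].mean().to_numpy(),
                sex=grp["sex"].first().to_numpy(),
                smoke=grp["smoke"].first().to_numpy(),
            )
        )
    else:  # repeated
        frame = d.rename(columns={"value": "y"})[
            ["subject_id", "visit", "y", "age", "sex", "smoke"]
        ].reset_index(drop=True)
    return PhenotypeView(mode=mode, frame=frame, trait=ph.trait)
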