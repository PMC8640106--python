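"""Bundled worked-example data.

``load_example_cohort`` returns the clinical records of a published-style
GTN provocation day: 24 migraine-without-aura patients (21 of whom develop
a migraine-like attack, onsets between 45 and 345 min after GTN start) and
13 healthy controls (7 with unspecific headache, one of them with an
anomalously high end-of-day VRS).  Each patient row carries the headache
characteristics, associated symptoms, mimicry and treatment information
needed by the attack-classification rules.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .clinical import ClinicalRecord, HeadacheAssessment, Treatment


def _assessment(row, time_col: str, vrs_col: str) -> HeadacheAssessment | None:
    if pd.isna(row[time_col]):
        return None
    return HeadacheAssessment(
        time_min=float(row[time_col]),
        vrs=int(row[vrs_col]),
        unilateral=bool(row["unilateral"]),
        pulsating=bool(row["pulsating"]),
        aggravated_by_movement=bool(row["aggravated"]),
        nausea=bool(row["nausea"]),
        vomiting=bool(row["vomiting"]),
        photophobia=bool(row["photophobia"]),
        phonophobia=bool(row["phonophobia"]),
        premonitory_symptoms=bool(row["premonitory"]),
    )


def load_example_cohort() -> list[ClinicalRecord]:
    """Clinical records of the bundled GTN provocation example cohort."""
    with resources.files("mrsphase.data").joinpath("example_cohort.csv").open() as fh:
        table = pd.read_csv(fh)
    records = []
    for _, row in table.iterrows():
        assessments = [
            a
            for a in (_assessment(row, "a1_time", "a1_vrs"),
                      _assessment(row, "a2_time", "a2_vrs"))
            if a is not None
        ]
        treatments = []
        if int(row["treated"]):
            treatments.append(Treatment(time_min=300.0, drug=str(row["treatment_drug"])))
        records.append(
            ClinicalRecord(
                subject_id=str(row["subject_id"]),
                diagnosis=str(row["diagnosis"]),
                assessments=assessments,
                treatments=treatments,
                mimics_usual=bool(row["mimics_usual"]),
                premonitory=bool(row["premonitory"]),
            )
        )
    return records
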