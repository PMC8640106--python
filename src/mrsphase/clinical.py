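"""Rule-based clinical computations for GTN provocation studies.

Covers migraine-like-attack classification, responder status, per-session
migraine-phase assignment, GTN dosing, and cohort-level response summaries.

A provoked attack counts as migraine-like when either criterion holds:

1. moderate-to-severe headache (VRS >= 4) with at least two of the four
   ICHD-3 C features (unilateral, pulsating, moderate/severe intensity,
   aggravation by movement) and the D requirement (nausea or vomiting, or
   photophobia together with phonophobia); or
2. a headache described as mimicking the patient's usual migraine attack
   and treated with acute migraine medication.

Phases relative to attack onset: a scan before GTN is interictal; for a
responder a post-GTN scan is preictal before onset, ictal from onset until
attack end, and postictal afterwards.  Controls and nonresponders are
interictal throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHASES = ("interictal", "preictal", "ictal", "postictal")

#: Latest allowed attack onset, minutes after GTN start (12 h).
ONSET_WINDOW_MIN = 720.0


@dataclass(frozen=True)
class HeadacheAssessment:
    """One time-stamped headache questionnaire entry."""

    time_min: float
    vrs: int
    unilateral: bool = False
    pulsating: bool = False
    aggravated_by_movement: bool = False
    nausea: bool = False
    vomiting: bool = False
    photophobia: bool = False
    phonophobia: bool = False
    premonitory_symptoms: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.vrs <= 10:
            raise ValueError("VRS must lie in [0, 10]")

    @property
    def moderate_or_severe(self) -> bool:
        return self.vrs >= 4

    @property
    def c_feature_count(self) -> int:
        return sum(
            (self.unilateral, self.pulsating, self.moderate_or_severe,
             self.aggravated_by_movement)
        )

    @property
    def d_fulfilled(self) -> bool:
        return (self.nausea or self.vomiting) or (self.photophobia and self.phonophobia)


@dataclass(frozen=True)
class Treatment:
    time_min: float
    drug: str
    efficacy: str | None = None
    acute_migraine_medication: bool = True


@dataclass
class ClinicalRecord:
    """Clinical data of one participant on the provocation day."""

    subject_id: str
    diagnosis: str  # "migraine" | "control"
    assessments: list[HeadacheAssessment] = field(default_factory=list)
    treatments: list[Treatment] = field(default_factory=list)
    mimics_usual: bool = False
    premonitory: bool = False
    responder: bool | None = None
    attack_onset_min: float | None = None
    attack_end_min: float | None = None
    manual_override_nonresponder: bool = False
    session_phases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [a.time_min for a in self.assessments]
        if times != sorted(times):
            raise ValueError("assessments must be time-ordered")

    @property
    def any_headache(self) -> bool:
        return any(a.vrs >= 1 for a in self.assessments)


def classify_attack(record: ClinicalRecord) -> tuple[bool, float | None]:
    """Decide responder status and attack onset for one participant.

    Returns ``(responder, onset_min)``.  Criterion 1 onset is the first
    assessment satisfying it; criterion 2 onset is the first nonzero-VRS
    assessment of the episode containing the treatment.  Only onsets within
    12 h of GTN start qualify.  Controls are never responders, matching the
    study design in which only migraine patients can have migraine-like
    attacks; ``manual_override_nonresponder`` mirrors clinical adjudication
    of anomalous cases.
    """
    if not record.assessments:
        raise ValueError(f"{record.subject_id}: empty assessment list")
    if record.diagnosis == "control" or record.manual_override_nonresponder:
        return False, None

    onset_1 = None
    for a in record.assessments:
        if a.vrs >= 4 and a.c_feature_count >= 2 and a.d_fulfilled:
            onset_1 = a.time_min
            break

    onset_2 = None
    treated = any(t.acute_migraine_medication for t in record.treatments)
    if record.mimics_usual and treated:
        headache_times = [a.time_min for a in record.assessments if a.vrs >= 1]
        if headache_times:
            onset_2 = headache_times[0]

    candidates = [t for t in (onset_1, onset_2)
                  if t is not None and 0 <= t <= ONSET_WINDOW_MIN]
    if not candidates:
        return False, None
    return True, min(candidates)


def phase_for_time(
    time_min: float,
    responder: bool,
    onset_min: float | None,
    end_min: float | None = None,
) -> str:
    """Migraine phase at a given study-day time.

    Pre-GTN times are interictal.  An onset exactly at the scan time counts
    as ictal.
    """
    if time_min < 0 or not responder:
        return "interictal"
    if onset_min is None:
        raise ValueError("responder without attack onset")
    if time_min < onset_min:
        return "preictal"
    if end_min is not None and time_min >= end_min:
        return "postictal"
    return "ictal"


def assign_phase(
    record: ClinicalRecord, session_times: dict[str, float]
) -> dict[str, str]:
    """Assign a migraine phase to every scan session of a participant."""
    if "Baseline" not in session_times or session_times["Baseline"] >= 0:
        raise ValueError("session_times must contain a pre-GTN Baseline")
    responder = bool(record.responder)
    if responder and record.attack_onset_min is None:
        raise ValueError(f"{record.subject_id}: responder without onset time")
    return {
        label: phase_for_time(t, responder, record.attack_onset_min,
                              record.attack_end_min)
        for label, t in session_times.items()
    }


def gtn_dose(
    weight_kg: float, rate_ug_per_kg_min: float = 0.5, duration_min: float = 20.0
) -> float:
    """Total GTN dose in micrograms (rate x weight x infusion duration)."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    return rate_ug_per_kg_min * weight_kg * duration_min


def classify_cohort(records: list[ClinicalRecord]) -> list[ClinicalRecord]:
    """Run ``classify_attack`` over a cohort, filling responder/onset in place."""
    for rec in records:
        responder, onset = classify_attack(rec)
        rec.responder = responder
        rec.attack_onset_min = onset
    return records


def summarize_response(records: list[ClinicalRecord]) -> dict:
    """Cohort-level response counts and percentages (one decimal)."""
    if not records:
        raise ValueError("empty cohort")
    if any(r.responder is None for r in records):
        raise ValueError("cohort must be classified first (responder is None)")
    migraine = [r for r in records if r.diagnosis == "migraine"]
    controls = [r for r in records if r.diagnosis == "control"]
    responders = [r for r in migraine if r.responder]
    onsets = [r.attack_onset_min for r in responders if r.attack_onset_min is not None]
    mimic = [r for r in responders if r.mimics_usual]
    ctrl_headache = [r for r in controls if r.any_headache]

    def pct(k: int, n: int) -> float:
        return round(100.0 * k / n, 1) if n else float("nan")

    return {
        "n_migraine": len(migraine),
        "n_control": len(controls),
        "n_responders": len(responders),
        "n_nonresponders": len(migraine) - len(responders),
        "responder_percent": pct(len(responders), len(migraine)),
        "n_controls_with_headache": len(ctrl_headache),
        "control_headache_percent": pct(len(ctrl_headache), len(controls)),
        "n_mimic": len(mimic),
        "mimic_percent": pct(len(mimic), len(responders)),
        "onset_min": min(onsets) if onsets else None,
        "onset_max": max(onsets) if onsets else None,
        "onset_median": float(np.median(onsets)) if onsets else None,
    }
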