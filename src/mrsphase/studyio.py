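"""On-disk study bundles.

A study bundle is a directory:

* ``cohort.csv`` - one row per subject (id, diagnosis, age, weight,
  tissue fractions, responder status, onset/end, premonitory, mimicry);
* ``sessions/<subject>__<session>.h5`` - HDF5 containers with datasets
  ``fid`` (channels x averages x points, complex), ``water_fid``
  (channels x points, complex), ``edit_condition`` (per-average strings),
  and the acquisition parameters plus identifiers as attributes;
* ``truth.json`` - full ground truth including per-session true
  concentrations (omitted when writing a blind bundle).

Round-trips are lossless: integers exactly, floats to full double
precision (JSON uses ``repr``-exact encoding; HDF5 stores doubles).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import AcquisitionParams, TissueFractions
from .simulate import SpectralSession, SubjectTruth

SCHEMA_VERSION = 1

_ACQ_FIELDS = [f.name for f in dataclasses.fields(AcquisitionParams)]


def _session_filename(session: SpectralSession) -> str:
    return f"{session.subject_id}__{session.session_label}.h5"


def write_study(
    cohort: list[SubjectTruth],
    sessions: list[SpectralSession],
    path: str | Path,
    blind: bool = False,
) -> Path:
    """Write a study bundle; with ``blind=True`` the ground truth is omitted."""
    path = Path(path)
    known = {s.subject_id for s in cohort}
    for session in sessions:
        if session.subject_id not in known:
            raise ValueError(f"session references unknown subject {session.subject_id}")
    (path / "sessions").mkdir(parents=True, exist_ok=True)

    rows = []
    for s in cohort:
        rows.append(
            dict(
                subject_id=s.subject_id,
                diagnosis=s.diagnosis,
                age=s.age,
                weight_kg=s.weight_kg,
                f_gm=s.tissue_fractions.f_gm,
                f_wm=s.tissue_fractions.f_wm,
                f_csf=s.tissue_fractions.f_csf,
                responder=s.responder,
                attack_onset_min=s.attack_onset_min,
                attack_end_min=s.attack_end_min,
                premonitory=s.premonitory,
                mimics_usual=s.mimics_usual,
            )
        )
    pd.DataFrame(rows).to_csv(path / "cohort.csv", index=False)

    manifest = {"schema_version": SCHEMA_VERSION, "n_subjects": len(cohort),
                "sessions": [_session_filename(s) for s in sessions]}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    if not blind:
        truth = {
            s.subject_id: {
                "session_phases": s.session_phases,
                "true_concentrations": s.true_concentrations,
                "tissue_fractions": s.tissue_fractions.as_dict(),
                "age": s.age,
                "weight_kg": s.weight_kg,
                "diagnosis": s.diagnosis,
                "responder": s.responder,
                "attack_onset_min": s.attack_onset_min,
                "attack_end_min": s.attack_end_min,
                "premonitory": s.premonitory,
                "mimics_usual": s.mimics_usual,
            }
            for s in cohort
        }
        (path / "truth.json").write_text(json.dumps(truth, indent=1))

    for session in sessions:
        with h5py.File(path / "sessions" / _session_filename(session), "w") as fh:
            fh.create_dataset("fid", data=session.channel_fids)
            fh.create_dataset("water_fid", data=session.water_reference_fids)
            fh.create_dataset(
                "edit_condition",
                data=np.array(session.edit_condition, dtype="S4"),
            )
            fh.attrs["subject_id"] = session.subject_id
            fh.attrs["session_label"] = session.session_label
            fh.attrs["artifact_flag"] = session.artifact_flag
            fh.attrs["schema_version"] = SCHEMA_VERSION
            for name in _ACQ_FIELDS:
                value = getattr(session.acquisition, name)
                fh.attrs[f"acq_{name}"] = "" if value is None else value
    return path


def _read_session(file: Path) -> SpectralSession:
    with h5py.File(file, "r") as fh:
        if int(fh.attrs["schema_version"]) != SCHEMA_VERSION:
            raise ValueError(
                f"{file.name}: schema version {fh.attrs['schema_version']} "
                f"!= {SCHEMA_VERSION}"
            )
        acq_kwargs = {}
        for name in _ACQ_FIELDS:
            value = fh.attrs[f"acq_{name}"]
            if isinstance(value, bytes):
                value = value.decode()
            if isinstance(value, str) and value == "":
                value = None
            elif name in ("n_points", "n_averages", "n_channels"):
                value = int(value)
            elif name != "sequence_label":
                value = float(value)
            acq_kwargs[name] = value
        return SpectralSession(
            subject_id=str(fh.attrs["subject_id"]),
            session_label=str(fh.attrs["session_label"]),
            channel_fids=fh["fid"][...],
            water_reference_fids=fh["water_fid"][...],
            acquisition=AcquisitionParams(**acq_kwargs),
            edit_condition=[c.decode() for c in fh["edit_condition"][...]],
            artifact_flag=bool(fh.attrs["artifact_flag"]),
        )


def read_study(path: str | Path) -> tuple[list[SubjectTruth], list[SpectralSession]]:
    """Read a study bundle back; blind bundles yield truth-less subjects."""
    path = Path(path)
    manifest_file = path / "manifest.json"
    if not manifest_file.exists():
        raise FileNotFoundError(f"{path} is not a study bundle (no manifest.json)")
    manifest = json.loads(manifest_file.read_text())
    if manifest["schema_version"] != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {manifest['schema_version']}")

    # round_trip parsing: the default C float parser loses the last digit
    cohort_df = (
        pd.read_csv(path / "cohort.csv", float_precision="round_trip")
        if manifest["n_subjects"]
        else pd.DataFrame(columns=["subject_id"])
    )
    truth_file = path / "truth.json"
    truth = json.loads(truth_file.read_text()) if truth_file.exists() else {}

    cohort = []
    for _, row in cohort_df.iterrows():
        sid = str(row["subject_id"])
        extra = truth.get(sid, {})
        onset = row["attack_onset_min"]
        end = row["attack_end_min"]
        cohort.append(
            SubjectTruth(
                subject_id=sid,
                diagnosis=str(row["diagnosis"]),
                age=float(row["age"]),
                weight_kg=float(row["weight_kg"]),
                tissue_fractions=TissueFractions(
                    float(row["f_gm"]), float(row["f_wm"]), float(row["f_csf"])
                ),
                responder=bool(row["responder"]),
                attack_onset_min=None if pd.isna(onset) else float(onset),
                attack_end_min=None if pd.isna(end) else float(end),
                premonitory=bool(row["premonitory"]),
                mimics_usual=bool(row["mimics_usual"]),
                session_phases=extra.get("session_phases", {}),
                true_concentrations=extra.get("true_concentrations", {}),
            )
        )
    known = {s.subject_id for s in cohort}

    sessions = []
    for name in manifest["sessions"]:
        session = _read_session(path / "sessions" / name)
        if session.subject_id not in known:
            raise ValueError(
                f"session {name} references unknown subject {session.subject_id}"
            )
        sessions.append(session)
    return cohort, sessions
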