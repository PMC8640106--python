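"""Synthetic GTN-provocation cohorts and synthetic MRS sessions.

The generator produces (a) a cohort of migraine patients and healthy
controls with known per-session "true" metabolite concentrations driven by
a migraine-phase timeline, and (b) raw multi-channel spectral sessions
built with the same forward model that the quantification stage inverts,
so that every downstream step can be validated against ground truth.

Forward signal model for one session: each metabolite ``m`` contributes

    S_m = g * c_m * (N_H / 2) * (f_gm + f_wm) * exp(-TE / T2_m)

times its unit-normalised multiplet FID, where ``g`` is an arbitrary
scanner gain, ``c_m`` the true parenchymal concentration (mmol/L) and
``N_H`` the modelled proton count.  The unsuppressed water reference
carries

    S_w = g * C_w * sum_i f_i * d_i * A_i(TR, TE)

with per-compartment MR-visible densities ``d_i`` and attenuations
``A_i = exp(-TE/T2_i) * (1 - exp(-TR/T1_i))``.  Channel sensitivities,
eddy-current phase, per-average frequency drift and white complex Gaussian
noise are applied on top; water and metabolite FIDs share the channel and
eddy distortions so the preprocessing stage can remove them.

MEGA-edited sessions alternate edit-off and edit-on averages; in the
on-condition every metabolite with a nonzero ``edit_co_factor`` (GABA by
default) is scaled by ``1 + edit_co_factor`` so that the on-minus-off
difference retains exactly that fraction of its off-condition signal while
non-edited resonances (creatine in particular) cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .clinical import phase_for_time
from .core import (
    DEFAULT_EDITING_EFFICIENCY,
    PURE_WATER_MM,
    SESSION_LABELS,
    AcquisitionParams,
    MetaboliteModel,
    RelaxationTable,
    TissueFractions,
    default_basis,
)
from .quantify import visible_water_factor

#: Default per-subject baseline concentration (mean, between-subject SD),
#: mmol/L referred to parenchyma.  Plausible occipital grey/white values;
#: these are generator parameters, not literature claims.
DEFAULT_BASELINE_CONCENTRATIONS: dict[str, tuple[float, float]] = {
    "tNAA": (12.0, 0.8),
    "tCr": (8.0, 0.5),
    "tCho": (1.8, 0.15),
    "glutamate": (9.0, 0.7),
    "glutamine": (3.0, 0.4),
    "GABA": (1.2, 0.25),
    "myo-inositol": (6.0, 0.5),
    "glutathione": (1.5, 0.2),
    "aspartate": (2.5, 0.4),
    "phosphoethanolamine": (1.5, 0.2),
}

#: Default true phase shifts (mmol/L) added to the subject baseline when a
#: session falls in the given phase; the preictal GABA increase of
#: +0.45 mmol/L is the headline injected effect.
DEFAULT_PHASE_EFFECTS: dict[str, dict[str, float]] = {
    "glutamate": {"preictal": 0.25, "ictal": 0.17},
    "glutamine": {"preictal": 0.19, "ictal": 0.25},
    "GABA": {"preictal": 0.45, "ictal": 0.27},
    "glutathione": {"preictal": -0.11, "ictal": -0.04},
    "tNAA": {"preictal": 0.19, "ictal": 0.17},
    "tCr": {"preictal": 0.06, "ictal": 0.10},
    "myo-inositol": {"preictal": -0.02, "ictal": 0.05},
    "tCho": {"preictal": 0.03, "ictal": 0.004},
    "aspartate": {"preictal": 0.11, "ictal": -0.23},
    "phosphoethanolamine": {"preictal": 0.23, "ictal": 0.17},
}

DEFAULT_SESSION_TIMES_MIN = {"Baseline": -30.0, "GTN-90": 90.0, "GTN-270": 270.0}


@dataclass(frozen=True)
class CohortConfig:
    """Study-day conditions of a synthetic provocation cohort."""

    n_migraine: int = 24
    n_control: int = 13
    responder_prob: float = 0.875
    onset_range_min: tuple[float, float] = (45.0, 345.0)
    session_times_min: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SESSION_TIMES_MIN)
    )
    baseline_concentrations: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_CONCENTRATIONS)
    )
    phase_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PHASE_EFFECTS.items()}
    )
    #: Session-to-session measurement noise of a reported concentration,
    #: mmol/L; used when concentrations are read out without spectra.
    residual_sd: float = 0.5
    #: Attack-duration model (log-normal), minutes.
    attack_duration_median_min: float = 480.0
    attack_duration_log_sd: float = 0.5
    premonitory_prob: float = 19.0 / 21.0
    mimic_prob: float = 20.0 / 21.0
    age_mean_sd: tuple[float, float] = (36.2, 8.1)
    control_age_mean_sd: tuple[float, float] = (31.0, 9.0)
    weight_mean_sd_kg: tuple[float, float] = (70.0, 10.0)
    gm_mean_sd: tuple[float, float] = (0.59, 0.03)
    wm_mean_sd: tuple[float, float] = (0.35, 0.04)

    def __post_init__(self) -> None:
        if self.n_migraine <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")
        for p in (self.responder_prob, self.premonitory_prob, self.mimic_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.onset_range_min
        if not 0 < lo <= hi:
            raise ValueError("invalid onset range")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be nonnegative")


@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth for one synthetic participant."""

    subject_id: str
    diagnosis: str  # "migraine" | "control"
    age: float
    weight_kg: float
    tissue_fractions: TissueFractions
    responder: bool
    attack_onset_min: float | None
    attack_end_min: float | None
    premonitory: bool
    mimics_usual: bool
    session_phases: dict[str, str]
    true_concentrations: dict[str, dict[str, float]]  # metabolite -> session -> mmol/L

    def __post_init__(self) -> None:
        if self.diagnosis == "control" and self.responder:
            raise ValueError("controls are never responders")
        if self.responder != (self.attack_onset_min is not None):
            raise ValueError("attack onset present iff responder")
        for sessions in self.true_concentrations.values():
            if any(c < 0 for c in sessions.values()):
                raise ValueError("concentrations must be nonnegative")


@dataclass(frozen=True)
class DistortionConfig:
    """Instrumental imperfections applied to a synthetic session."""

    channel_gain_log_sd: float = 0.15
    channel_phase_range_deg: float = 180.0
    channel_amplitudes: tuple[float, ...] | None = None
    channel_phases_deg: tuple[float, ...] | None = None
    freq_drift_sd_hz: float = 1.5
    freq_offsets_hz: tuple[float, ...] | None = None
    eddy_amplitude_rad: float = 0.5
    eddy_tau_ms: float = 60.0
    noise_sd: float = 3.0
    shim_broadening_hz: float = 6.0  # common Lorentzian broadening of all lines
    artifact_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")

    @classmethod
    def none(cls, shim_broadening_hz: float = 6.0) -> "DistortionConfig":
        """Distortion-free configuration (for noiseless identity checks)."""
        return cls(
            channel_gain_log_sd=0.0,
            channel_phase_range_deg=0.0,
            freq_drift_sd_hz=0.0,
            eddy_amplitude_rad=0.0,
            noise_sd=0.0,
            shim_broadening_hz=shim_broadening_hz,
        )

    def eddy_phase(self, t_s: np.ndarray) -> np.ndarray:
        """Eddy-current phase course phi(t), radians (decaying exponential)."""
        return self.eddy_amplitude_rad * np.exp(-t_s / (self.eddy_tau_ms / 1000.0))


@dataclass
class SpectralSession:
    """Raw multi-channel data of one scan of one subject."""

    subject_id: str
    session_label: str
    channel_fids: np.ndarray  # (n_channels, n_averages, n_points) complex
    water_reference_fids: np.ndarray  # (n_channels, n_points) complex
    acquisition: AcquisitionParams
    edit_condition: list[str]  # per average: "on" | "off" | "none"
    artifact_flag: bool = False

    def __post_init__(self) -> None:
        acq = self.acquisition
        expected = (acq.n_channels, acq.n_averages, acq.n_points)
        if self.channel_fids.shape != expected:
            raise ValueError(
                f"channel_fids shape {self.channel_fids.shape} != {expected}"
            )
        if self.water_reference_fids.shape != (acq.n_channels, acq.n_points):
            raise ValueError("water reference shape mismatch")
        if len(self.edit_condition) != acq.n_averages:
            raise ValueError("edit_condition length mismatch")


def _draw_fractions(rng: np.random.Generator, config: CohortConfig) -> TissueFractions:
    gm = float(np.clip(rng.normal(*config.gm_mean_sd), 0.3, 0.8))
    wm = float(np.clip(rng.normal(*config.wm_mean_sd), 0.1, 0.6))
    csf = max(1.0 - gm - wm, 0.01)
    total = gm + wm + csf
    return TissueFractions(gm / total, wm / total, csf / total)


def simulate_cohort(config: CohortConfig, seed: int) -> list[SubjectTruth]:
    """Draw a full synthetic cohort with per-session true concentrations.

    Deterministic for a fixed (config, seed).  Responder flags are drawn
    only for migraine subjects; onset times come from the configured
    uniform window; each session's true concentration is the subject
    baseline plus the configured phase effect for that session's phase.
    """
    rng = np.random.default_rng(seed)
    subjects: list[SubjectTruth] = []
    specs = [("M", "migraine", config.n_migraine), ("C", "control", config.n_control)]
    for prefix, diagnosis, n in specs:
        for i in range(n):
            age_mean_sd = (
                config.age_mean_sd if diagnosis == "migraine" else config.control_age_mean_sd
            )
            age = float(np.clip(rng.normal(*age_mean_sd), 18.0, 65.0))
            weight = float(np.clip(rng.normal(*config.weight_mean_sd_kg), 45.0, 110.0))
            fractions = _draw_fractions(rng, config)
            if diagnosis == "migraine":
                responder = bool(rng.random() < config.responder_prob)
                premonitory = responder and bool(rng.random() < config.premonitory_prob)
                mimics = responder and bool(rng.random() < config.mimic_prob)
            else:
                responder, premonitory, mimics = False, False, False
            onset = end = None
            if responder:
                onset = float(rng.uniform(*config.onset_range_min))
                duration = float(
                    config.attack_duration_median_min
                    * math.exp(rng.normal(0.0, config.attack_duration_log_sd))
                )
                end = onset + duration
            phases = {
                label: phase_for_time(t, responder, onset, end)
                for label, t in config.session_times_min.items()
            }
            concentrations: dict[str, dict[str, float]] = {}
            for metab, (mean, sd) in config.baseline_concentrations.items():
                base = max(float(rng.normal(mean, sd)), 0.05)
                effects = config.phase_effects.get(metab, {})
                concentrations[metab] = {
                    label: max(base + effects.get(phase, 0.0), 0.0)
                    for label, phase in phases.items()
                }
            subjects.append(
                SubjectTruth(
                    subject_id=f"{prefix}{i + 1:02d}",
                    diagnosis=diagnosis,
                    age=age,
                    weight_kg=weight,
                    tissue_fractions=fractions,
                    responder=responder,
                    attack_onset_min=onset,
                    attack_end_min=end,
                    premonitory=premonitory,
                    mimics_usual=mimics,
                    session_phases=phases,
                    true_concentrations=concentrations,
                )
            )
    return subjects


def metabolite_signal_amplitude(
    concentration_mm: float,
    metabolite: MetaboliteModel,
    fractions: TissueFractions,
    echo_time_ms: float,
    scanner_gain: float = 1.0,
) -> float:
    """Time-domain amplitude of a metabolite under the forward model."""
    return (
        scanner_gain
        * concentration_mm
        * (metabolite.proton_count / 2.0)
        * (fractions.f_gm + fractions.f_wm)
        * math.exp(-echo_time_ms / metabolite.t2_ms)
    )


def water_signal_amplitude(
    fractions: TissueFractions,
    acquisition: AcquisitionParams,
    table: RelaxationTable | None = None,
    scanner_gain: float = 1.0,
) -> float:
    """Time-domain amplitude of the unsuppressed water reference."""
    table = table or RelaxationTable()
    return (
        scanner_gain
        * table.pure_water_mm
        * visible_water_factor(
            fractions, table, acquisition.repetition_time_ms, acquisition.echo_time_ms
        )
    )


def synthesize_session(
    truth: SubjectTruth,
    session_label: str,
    acquisition: AcquisitionParams,
    distortions: DistortionConfig,
    seed: int,
    basis: dict[str, MetaboliteModel] | None = None,
    relaxation: RelaxationTable | None = None,
    scanner_gain: float = 1.0,
    mm_level: float = 4.0,
    water_linewidth_hz: float = 8.0,
) -> SpectralSession:
    """Synthesize the raw multi-channel data of one scan session.

    ``mm_level`` is the concentration-equivalent driving the macromolecule
    background ("MM" basis entry) if present.  Water and metabolite FIDs
    share the channel sensitivities and eddy-current phase.
    """
    basis = basis if basis is not None else default_basis()
    relaxation = relaxation or RelaxationTable()
    rng = np.random.default_rng(seed)
    acq = acquisition
    t = acq.time_axis_s()
    is_mega = acq.sequence_label == "MEGA-sLASER"

    concentrations = {
        metab: sessions[session_label]
        for metab, sessions in truth.true_concentrations.items()
    }
    missing = set(concentrations) - set(basis)
    if missing:
        raise KeyError(f"no metabolite model for: {sorted(missing)}")
    if "MM" in basis and "MM" not in concentrations:
        concentrations["MM"] = mm_level

    off_fid = np.zeros(acq.n_points, dtype=complex)
    diff_part = np.zeros(acq.n_points, dtype=complex)
    for name, conc in concentrations.items():
        model = basis[name]
        amp = metabolite_signal_amplitude(
            conc, model, truth.tissue_fractions, acq.echo_time_ms, scanner_gain
        )
        unit = model.unit_fid(acq, extra_broadening_hz=distortions.shim_broadening_hz)
        off_fid += amp * unit
        if is_mega and model.edit_co_factor > 0:
            diff_part += model.edit_co_factor * amp * unit
    on_fid = off_fid + diff_part

    water_amp = water_signal_amplitude(
        truth.tissue_fractions, acq, relaxation, scanner_gain
    )
    water_base = water_amp * np.exp(-np.pi * water_linewidth_hz * t)

    if distortions.channel_amplitudes is not None:
        gains = np.asarray(distortions.channel_amplitudes, dtype=float)
    else:
        gains = np.exp(rng.normal(0.0, distortions.channel_gain_log_sd, acq.n_channels))
    if distortions.channel_phases_deg is not None:
        phases = np.deg2rad(np.asarray(distortions.channel_phases_deg, dtype=float))
    else:
        phases = np.deg2rad(
            rng.uniform(
                -distortions.channel_phase_range_deg,
                distortions.channel_phase_range_deg,
                acq.n_channels,
            )
        )
    if len(gains) != acq.n_channels or len(phases) != acq.n_channels:
        raise ValueError("channel sensitivity arrays must match n_channels")
    sens = gains * np.exp(1j * phases)

    if distortions.freq_offsets_hz is not None:
        offsets = np.asarray(distortions.freq_offsets_hz, dtype=float)
        if len(offsets) != acq.n_averages:
            raise ValueError("freq_offsets_hz must match n_averages")
    else:
        # drift is referenced to the first average: the scanner frequency is
        # calibrated at acquisition start and wanders afterwards
        offsets = rng.normal(0.0, distortions.freq_drift_sd_hz, acq.n_averages)
        offsets -= offsets[0]

    eddy = np.exp(1j * distortions.eddy_phase(t))

    if is_mega:
        if acq.n_averages % 2:
            raise ValueError("MEGA acquisition needs an even number of averages")
        edit_condition = ["off", "on"] * (acq.n_averages // 2)
    else:
        edit_condition = ["none"] * acq.n_averages

    def noise(shape):
        if distortions.noise_sd == 0:
            return 0.0
        return distortions.noise_sd * (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        )

    channel_fids = np.empty((acq.n_channels, acq.n_averages, acq.n_points), dtype=complex)
    for a in range(acq.n_averages):
        base = on_fid if edit_condition[a] == "on" else off_fid
        avg = base * eddy * np.exp(2j * np.pi * offsets[a] * t)
        channel_fids[:, a, :] = sens[:, None] * avg[None, :] + noise(
            (acq.n_channels, acq.n_points)
        )
    water_fids = sens[:, None] * (water_base * eddy)[None, :] + noise(
        (acq.n_channels, acq.n_points)
    )

    artifact = bool(rng.random() < distortions.artifact_prob)
    return SpectralSession(
        subject_id=truth.subject_id,
        session_label=session_label,
        channel_fids=channel_fids,
        water_reference_fids=water_fids,
        acquisition=acq,
        edit_condition=edit_condition,
        artifact_flag=artifact,
    )
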