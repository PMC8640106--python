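"""Shared domain types for in vivo proton-MRS simulation and quantification.

The types here are deliberately minimal: an acquisition description, a
parametric metabolite signal model (1-3 simplified resonance lines per
metabolite), voxel tissue composition and the relaxation/water-density
constants used for water-referenced absolute quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Proton gyromagnetic ratio, MHz per tesla.
GYROMAGNETIC_RATIO_MHZ_PER_T = 42.577

#: Chemical shift of water at brain temperature (ppm); the transmitter is
#: assumed to sit on the water resonance.
WATER_PPM = 4.68

#: Concentration of pure water, mmol/L.
PURE_WATER_MM = 55_510.0

SESSION_LABELS = ("Baseline", "GTN-90", "GTN-270")


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition settings of a single-voxel MRS scan.

    Defaults describe a 7 T sLASER acquisition (TR 5000 ms, TE 36 ms,
    4 kHz spectral width, 2048 complex points, 32 averages, 32 receive
    channels).  ``mega_slaser_7t`` gives the matching GABA-edited variant.
    """

    field_strength_t: float = 7.0
    larmor_frequency_mhz: float = 7.0 * GYROMAGNETIC_RATIO_MHZ_PER_T
    repetition_time_ms: float = 5000.0
    echo_time_ms: float = 36.0
    spectral_width_hz: float = 4000.0
    n_points: int = 2048
    n_averages: int = 32
    n_channels: int = 32
    edit_on_offset_ppm: float | None = None
    edit_off_offset_ppm: float | None = None
    sequence_label: str = "sLASER"

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")
        if self.spectral_width_hz <= 0:
            raise ValueError("spectral_width_hz must be positive")
        if self.n_averages <= 0 or self.n_channels <= 0:
            raise ValueError("n_averages and n_channels must be positive")
        nominal = GYROMAGNETIC_RATIO_MHZ_PER_T * self.field_strength_t
        if abs(self.larmor_frequency_mhz - nominal) > 0.01 * nominal:
            raise ValueError(
                f"larmor_frequency_mhz {self.larmor_frequency_mhz} is not within "
                f"1% of {nominal:.2f} MHz for {self.field_strength_t} T"
            )
        if self.sequence_label == "MEGA-sLASER":
            if self.edit_on_offset_ppm is None or self.edit_off_offset_ppm is None:
                raise ValueError("MEGA-sLASER requires both editing offsets")
            if self.edit_on_offset_ppm == self.edit_off_offset_ppm:
                raise ValueError("editing offsets must differ")

    @property
    def dwell_time_s(self) -> float:
        return 1.0 / self.spectral_width_hz

    def time_axis_s(self) -> np.ndarray:
        """Sampling times of the FID, seconds."""
        return np.arange(self.n_points) * self.dwell_time_s

    def freq_axis_hz(self) -> np.ndarray:
        """Frequency axis (ascending, Hz offset from the transmitter)."""
        return np.fft.fftshift(np.fft.fftfreq(self.n_points, d=self.dwell_time_s))

    def ppm_axis(self) -> np.ndarray:
        """Chemical-shift axis, descending ppm (conventional display order)."""
        asc = WATER_PPM + self.freq_axis_hz() / self.larmor_frequency_mhz
        return asc[::-1]


def slaser_7t(**overrides) -> AcquisitionParams:
    """The default 7 T sLASER acquisition."""
    return replace(AcquisitionParams(), **overrides) if overrides else AcquisitionParams()


def mega_slaser_7t(**overrides) -> AcquisitionParams:
    """The default 7 T MEGA-sLASER GABA-edited acquisition.

    TE 74 ms, 64 averages, editing pulse alternating between 1.9 ppm (on)
    and 1.5 ppm (off), placed symmetrically around the GABA C3 resonance.
    """
    params = AcquisitionParams(
        echo_time_ms=74.0,
        n_averages=64,
        edit_on_offset_ppm=1.9,
        edit_off_offset_ppm=1.5,
        sequence_label="MEGA-sLASER",
    )
    return replace(params, **overrides) if overrides else params


def spectrum_from_fid(fid: np.ndarray) -> np.ndarray:
    """Complex spectrum on the descending-ppm axis of ``AcquisitionParams.ppm_axis``."""
    return np.fft.fftshift(np.fft.fft(fid))[::-1]


def fid_from_spectrum(spec: np.ndarray) -> np.ndarray:
    return np.fft.ifft(np.fft.ifftshift(spec[::-1]))


@dataclass(frozen=True)
class Resonance:
    """One (simplified) spectral line of a metabolite."""

    shift_ppm: float
    amplitude: float  # proton-count weight
    linewidth_hz: float
    lineshape: str = "lorentzian"  # or "gaussian"

    def __post_init__(self) -> None:
        if self.linewidth_hz <= 0:
            raise ValueError("linewidth must be positive")
        if not 0.0 <= self.shift_ppm <= 10.0:
            raise ValueError("chemical shift outside 0-10 ppm")
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown lineshape {self.lineshape!r}")


@dataclass(frozen=True)
class MetaboliteModel:
    """Parametric signal model of a metabolite.

    ``proton_count`` is the effective number of protons represented by the
    model (the sum of the resonance weights); it enters water-referenced
    quantification through the 2/N_H factor.  ``edit_co_factor`` is the
    fraction of the signal surviving in a MEGA difference spectrum (0 for
    non-edited singlets such as creatine).
    """

    name: str
    resonances: tuple[Resonance, ...]
    t2_ms: float
    proton_count: float
    edit_co_factor: float = 0.0

    def __post_init__(self) -> None:
        if not self.resonances:
            raise ValueError("metabolite model needs at least one resonance")
        if self.t2_ms <= 0:
            raise ValueError("t2_ms must be positive")
        if not 0.0 <= self.edit_co_factor <= 1.0:
            raise ValueError("edit_co_factor must lie in [0, 1]")

    def reference_fraction(self, shift_ppm: float, tol_ppm: float = 0.1) -> float:
        """Fraction of the total model weight carried by the line at ``shift_ppm``."""
        total = sum(r.amplitude for r in self.resonances)
        sel = sum(r.amplitude for r in self.resonances
                  if abs(r.shift_ppm - shift_ppm) <= tol_ppm)
        if sel == 0:
            raise ValueError(f"{self.name} has no resonance near {shift_ppm} ppm")
        return sel / total

    def unit_fid(
        self,
        acquisition: AcquisitionParams,
        extra_broadening_hz: float = 0.0,
        freq_shift_hz: float = 0.0,
    ) -> np.ndarray:
        """Complex FID of the model, normalised so that ``fid[0] == 1``.

        ``extra_broadening_hz`` adds a common Lorentzian broadening (FWHM)
        on top of each line's own width; ``freq_shift_hz`` translates the
        whole multiplet in frequency.
        """
        t = acquisition.time_axis_s()
        f0 = acquisition.larmor_frequency_mhz
        total = sum(r.amplitude for r in self.resonances)
        fid = np.zeros(acquisition.n_points, dtype=complex)
        for r in self.resonances:
            f_hz = (r.shift_ppm - WATER_PPM) * f0 + freq_shift_hz
            osc = np.exp(2j * np.pi * f_hz * t)
            if r.lineshape == "lorentzian":
                env = np.exp(-np.pi * r.linewidth_hz * t)
            else:  # gaussian FWHM -> time envelope
                sigma_t = np.pi * r.linewidth_hz / (2.0 * np.sqrt(np.log(2.0)))
                env = np.exp(-((sigma_t * t) ** 2))
            fid += (r.amplitude / total) * osc * env
        if extra_broadening_hz:
            fid *= np.exp(-np.pi * extra_broadening_hz * t)
        return fid


def _m(name, lines, t2, edit=0.0):
    resonances = tuple(Resonance(s, a, w, shape) for s, a, w, shape in lines)
    return MetaboliteModel(
        name=name,
        resonances=resonances,
        t2_ms=t2,
        proton_count=sum(r.amplitude for r in resonances),
        edit_co_factor=edit,
    )


def default_basis() -> dict[str, MetaboliteModel]:
    """Reduced default basis: the ten quantified metabolites plus a broad
    macromolecule background.

    Shifts and proton weights follow standard in vivo assignments but each
    multiplet is collapsed to 1-3 effective lines; linewidths are intrinsic
    (shim broadening is added separately).  T2 values (ms) are plausible
    7 T literature-range constants; glutamate uses 93 ms.
    """
    L = "lorentzian"
    G = "gaussian"
    basis = [
        _m("tNAA", [(2.01, 3.0, 4.0, L), (2.60, 1.0, 6.0, L)], 130.0),
        _m("tCr", [(3.03, 3.0, 4.0, L), (3.92, 2.0, 4.5, L)], 92.0),
        _m("tCho", [(3.19, 9.0, 4.0, L)], 110.0),
        _m("glutamate", [(2.35, 2.0, 7.0, L), (3.75, 1.0, 5.0, L)], 93.0),
        _m("glutamine", [(2.45, 2.0, 7.0, L), (3.77, 1.0, 5.0, L)], 90.0),
        _m("GABA", [(3.01, 2.0, 8.0, L), (2.28, 2.0, 8.0, L), (1.89, 2.0, 8.0, L)],
           88.0, edit=0.5),
        _m("myo-inositol", [(3.52, 4.0, 5.0, L), (4.05, 1.0, 5.0, L)], 95.0),
        _m("glutathione", [(2.95, 2.0, 7.0, L)], 85.0),
        _m("aspartate", [(2.68, 2.0, 8.0, L), (3.89, 1.0, 6.0, L)], 90.0),
        _m("phosphoethanolamine", [(3.98, 2.0, 6.0, L), (3.22, 2.0, 6.0, L)], 95.0),
        _m("MM", [(0.91, 3.0, 45.0, G), (1.40, 4.0, 55.0, G), (2.05, 3.0, 60.0, G)],
           40.0),
    ]
    return {m.name: m for m in basis}


#: Default editing efficiency for GABA in the MEGA difference spectrum; the
#: simulator and the quantifier share this constant.
DEFAULT_EDITING_EFFICIENCY = 0.5


@dataclass(frozen=True)
class TissueFractions:
    """Grey-matter / white-matter / CSF composition of the voxel."""

    f_gm: float
    f_wm: float
    f_csf: float

    def __post_init__(self) -> None:
        for f in (self.f_gm, self.f_wm, self.f_csf):
            if not 0.0 <= f <= 1.0:
                raise ValueError("tissue fractions must lie in [0, 1]")
        if abs(self.f_gm + self.f_wm + self.f_csf - 1.0) > 1e-6:
            raise ValueError("tissue fractions must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {"GM": self.f_gm, "WM": self.f_wm, "CSF": self.f_csf}


@dataclass(frozen=True)
class RelaxationTable:
    """Water densities and relaxation times used for absolute quantification.

    Defaults: MR-visible water densities GM 0.78, WM 0.65, CSF 0.97;
    water T1 (ms) GM 2130, WM 1220, CSF 4425; water T2 (ms) GM 50, WM 55,
    CSF 141; metabolite T2 values taken from the basis models (glutamate
    93 ms).  ``pure_water_mm`` is the proton concentration standard.
    """

    water_density: dict[str, float] = field(
        default_factory=lambda: {"GM": 0.78, "WM": 0.65, "CSF": 0.97}
    )
    water_t1_ms: dict[str, float] = field(
        default_factory=lambda: {"GM": 2130.0, "WM": 1220.0, "CSF": 4425.0}
    )
    water_t2_ms: dict[str, float] = field(
        default_factory=lambda: {"GM": 50.0, "WM": 55.0, "CSF": 141.0}
    )
    pure_water_mm: float = PURE_WATER_MM

    def __post_init__(self) -> None:
        for d in self.water_density.values():
            if not 0.0 < d <= 1.0:
                raise ValueError("water densities must lie in (0, 1]")
        for table in (self.water_t1_ms, self.water_t2_ms):
            if any(v <= 0 for v in table.values()):
                raise ValueError("relaxation times must be positive")
        if self.pure_water_mm <= 0:
            raise ValueError("pure_water_mm must be positive")
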