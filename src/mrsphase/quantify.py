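"""Water-referenced absolute quantification and CRLB-based quality control.

Fitted signal amplitudes are converted to mmol/L with the unsuppressed
water reference from the same voxel, a Gasparovic-style compartment model
(per-compartment MR-visible water densities and T1/T2 attenuations),
metabolite T2 correction, and a CSF correction that refers concentrations
to parenchyma.  Metabolite T1 saturation is deliberately neglected: the
long TR (5 s) makes it a sub-percent effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core import AcquisitionParams, MetaboliteModel, RelaxationTable, TissueFractions

__all__ = [
    "water_attenuation",
    "visible_water_factor",
    "absolute_concentration",
    "ConcentrationRecord",
    "qc_exclude",
    "RelaxationTable",
    "TissueFractions",
]


def water_attenuation(
    table: RelaxationTable, tr_ms: float, te_ms: float
) -> dict[str, float]:
    """Per-compartment water attenuation A_i = exp(-TE/T2_i)(1 - exp(-TR/T1_i))."""
    if tr_ms <= 0 or te_ms < 0:
        raise ValueError("TR must be positive and TE nonnegative")
    return {
        comp: math.exp(-te_ms / table.water_t2_ms[comp])
        * (1.0 - math.exp(-tr_ms / table.water_t1_ms[comp]))
        for comp in table.water_t1_ms
    }


def visible_water_factor(
    fractions: TissueFractions,
    table: RelaxationTable,
    tr_ms: float,
    te_ms: float,
) -> float:
    """Voxel MR-visible water signal factor  sum_i f_i d_i A_i."""
    atten = water_attenuation(table, tr_ms, te_ms)
    f = fractions.as_dict()
    return sum(f[c] * table.water_density[c] * atten[c] for c in atten)


def absolute_concentration(
    metab_amplitude: float,
    water_amplitude: float,
    metabolite: MetaboliteModel,
    fractions: TissueFractions,
    acquisition: AcquisitionParams,
    table: RelaxationTable | None = None,
    reference: str = "parenchyma",
) -> float:
    """Absolute metabolite concentration in mmol/L.

        c = (S_m / S_w) * (2 / N_H) * C_w * sum_i f_i d_i A_i
            / ( exp(-TE / T2_m) * (f_gm + f_wm) )

    ``reference="parenchyma"`` divides by the parenchymal fraction
    (concentration per litre of brain tissue); ``"voxel"`` omits that
    denominator and reports per litre of voxel.
    """
    table = table or RelaxationTable()
    if water_amplitude <= 0:
        raise ValueError("water amplitude must be positive")
    if reference not in ("parenchyma", "voxel"):
        raise ValueError(f"unknown reference {reference!r}")
    parenchyma = fractions.f_gm + fractions.f_wm
    if reference == "parenchyma" and parenchyma <= 0:
        raise ValueError("voxel contains no parenchyma (f_csf = 1)")
    t2_factor = math.exp(-acquisition.echo_time_ms / metabolite.t2_ms)
    conc = (
        (metab_amplitude / water_amplitude)
        * (2.0 / metabolite.proton_count)
        * table.pure_water_mm
        * visible_water_factor(
            fractions, table, acquisition.repetition_time_ms, acquisition.echo_time_ms
        )
        / t2_factor
    )
    if reference == "parenchyma":
        conc /= parenchyma
    return conc


@dataclass
class ConcentrationRecord:
    """One quantified metabolite of one scan session."""

    subject_id: str
    session_label: str
    metabolite: str
    concentration_mm: float
    crlb_percent: float
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.concentration_mm < 0:
            self.qc_flags.add("negative_concentration")


def qc_exclude(
    records: list[ConcentrationRecord],
    crlb_threshold_percent: float = 15.0,
    fraction: float = 0.5,
) -> tuple[set[str], list[ConcentrationRecord]]:
    """Apply the CRLB reliability filter.

    A metabolite is dropped for *all* records when the proportion of its
    records with CRLB strictly above the threshold exceeds ``fraction``
    (strictly greater than, so exactly 50% is retained).  Records whose
    spectrum carried an artifact flag are excluded record-wise.  Returns
    the retained metabolite set and the flagged records.
    """
    if not records:
        raise ValueError("no records to filter")
    metabolites = sorted({r.metabolite for r in records})
    included: set[str] = set()
    for metab in metabolites:
        sub = [r for r in records if r.metabolite == metab]
        n_bad = sum(r.crlb_percent > crlb_threshold_percent for r in sub)
        if n_bad / len(sub) > fraction:
            for r in sub:
                r.qc_flags.add("metabolite_excluded_crlb")
        else:
            included.add(metab)
    for r in records:
        if "artifact" in r.qc_flags:
            continue  # already flagged upstream
        if r.crlb_percent > crlb_threshold_percent:
            r.qc_flags.add("high_crlb")
    return included, records
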