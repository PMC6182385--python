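"""Derived photophysiology: quenching coefficients, yield partition, ETR.

Implements the standard published estimators used to convert paired in-light
and 1-s-dark induction fits into the photochemical quenching coefficient
``qP``, the quantum-yield partition Y(PSII) + Y(NPQ) + Y(NO) = 1, and an
absolute electron transport rate per PSII.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DivisionDegenerate

__all__ = [
    "YieldPartition",
    "LightStepRecord",
    "estimate_F0prime",
    "yield_partition",
    "compute_etr",
    "PHOTON_FLUX_PER_UMOL",
]

#: photons A^-2 s^-1 per umol photons m^-2 s^-1
#: (Avogadro number per umol, times 1e-20 m^2 per A^2)
PHOTON_FLUX_PER_UMOL = 6.022140e-3


@dataclass(frozen=True)
class YieldPartition:
    """Quenching coefficient and quantum-yield partition for one light step.

    ``Y_PSII + Y_NPQ + Y_NO == 1`` is an algebraic identity of the three
    formulas.  Out-of-range values (possible on noisy fits) are stored as-is
    and flagged, never clipped.
    """

    F0p: float
    qP: float
    excitation_pressure: float
    Y_PSII: float
    Y_NPQ: float
    Y_NO: float
    flags: tuple[str, ...] = ()


@dataclass
class LightStepRecord:
    """One protocol step's paired fits plus derived yields and ETR."""

    step_index: int
    timestamp_s: float
    par: float
    duration_s: float
    # in-light induction fit (FS is its minimal-fluorescence analog)
    FS: float
    FMp: float
    sigma_p: float
    rho_p: float
    # paired fit following 1 s of darkness
    F0p_1s: float
    FMp_1s: float
    sigma_p_1s: float
    rho_p_1s: float
    tau1_light: float
    tau1_dark1s: float
    # dark-adapted reference
    F0_ref: float
    FM_ref: float
    sigma_ref: float
    partition: YieldPartition | None = None
    etr: float = float("nan")
    flags: list[str] = field(default_factory=list)


def estimate_F0prime(F0p_1s: float, FMp_1s: float, FMp: float) -> tuple[float, tuple[str, ...]]:
    """Estimate the minimal fluorescence under actinic light, F0'.

    F0' = F0'1s * (1 - (FM'1s - FM') / FM'1s), i.e. F0'1s scaled by
    FM'/FM'1s.  Returns the estimate and a flag tuple; FM' > FM'1s yields
    F0' > F0'1s, which is physically odd but retained per the formula and
    flagged.
    """
    if FMp_1s <= 0:
        raise DivisionDegenerate("FM'1s must be > 0")
    flags: tuple[str, ...] = ()
    if FMp > FMp_1s * (1.0 + 1e-9):
        flags = ("FMp_above_FMp_1s",)
    return F0p_1s * (1.0 - (FMp_1s - FMp) / FMp_1s), flags


def yield_partition(FS: float, FMp: float, FM_ref: float, F0p: float) -> YieldPartition:
    """Partition absorbed excitation into Y(PSII), Y(NPQ) and Y(NO).

    qP = (FM'-FS)/(FM'-F0'); Y(PSII) = (FM'-FS)/FM';
    Y(NPQ) = FS/FM' - FS/FM; Y(NO) = FS/FM.  The three yields sum to 1
    exactly.  Inputs outside 0 <= F0' < FS,FM' <= FM are flagged but the
    record is computed and retained.
    """
    if FMp == F0p or FMp == 0 or FM_ref == 0:
        raise DivisionDegenerate("FM' == F0' or zero denominator")
    flags: list[str] = []
    eps = 1e-9 * max(abs(FMp), abs(FM_ref))  # numerical slack only
    if not (-eps <= F0p < FMp and FMp <= FM_ref + eps):
        flags.append("ordering_violation")
    qP = (FMp - FS) / (FMp - F0p)
    Y_PSII = (FMp - FS) / FMp
    Y_NPQ = FS / FMp - FS / FM_ref
    Y_NO = FS / FM_ref
    if not (-1e-9 <= qP <= 1 + 1e-9):
        flags.append("qP_out_of_range")
    for name, val in (("Y_PSII", Y_PSII), ("Y_NPQ", Y_NPQ), ("Y_NO", Y_NO)):
        if not (-1e-9 <= val <= 1 + 1e-9):
            flags.append(f"{name}_out_of_range")
    return YieldPartition(
        F0p=F0p,
        qP=qP,
        excitation_pressure=1.0 - qP,
        Y_PSII=Y_PSII,
        Y_NPQ=Y_NPQ,
        Y_NO=Y_NO,
        flags=tuple(flags),
    )


def compute_etr(
    par: float,
    sigma_p: float,
    Y_PSII: float,
    F0_ref: float,
    FM_ref: float,
) -> float:
    """Absolute electron transport rate, e- PSII^-1 s^-1.

    ETR = E * sigma' * Y(PSII) / (Fv/Fm), with the photon flux E converted
    from umol photons m^-2 s^-1 to photons A^-2 s^-1 and Fv/Fm taken from
    the dark-adapted reference.  No per-cell PSII number is applied.
    """
    if FM_ref <= F0_ref:
        raise DivisionDegenerate("FM_ref must exceed F0_ref")
    if F0_ref < 0:
        raise ValueError("F0_ref must be >= 0")
    fv_fm = (FM_ref - F0_ref) / FM_ref
    return par * PHOTON_FLUX_PER_UMOL * sigma_p * Y_PSII / fv_fm
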