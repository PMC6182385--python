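"""Light protocols and assembly of paired measurements into experiments.

A non-sequential rapid light curve (RLC) applies 30-s steps whose light
levels revisit earlier values out of monotone order; an induction-recovery
run holds one actinic level for 1200 s and then darkness for 900 s.  At each
measurement slot an induction/relaxation pair is taken in the light and
again after 1 s of darkness; this module fits those pairs, derives the yield
partition and ETR per step, and compares ETR between visits to the same
light level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .derived_params import (
    LightStepRecord,
    compute_etr,
    estimate_F0prime,
    yield_partition,
)
from .errors import DegenerateInput, NoRevisit, ProtocolMismatch
from .fitting import fit_induction, fit_relaxation, induction_final_closure
from .frrf_model import FlashletTrain, FrrfTransient, PhotophysState

__all__ = [
    "LightSequence",
    "ExperimentTable",
    "default_rlc_sequence",
    "default_induction_recovery_sequence",
    "measurement_schedule",
    "pair_measurements",
    "upregulation_index",
]

#: maximum lag (s) between an in-light measurement and its 1-s-dark partner
PAIRING_WINDOW_S = 5.0

#: canonical non-sequential RLC light levels; the first two low steps are
#: not pinned by any quoted value and may be overridden
DEFAULT_RLC_PAR = (34.0, 74.0, 114.0, 300.0, 470.0, 300.0, 470.0, 540.0, 74.0)


@dataclass(frozen=True)
class LightSequence:
    """Ordered actinic light steps preceded by a dark-adaptation period."""

    steps: tuple[tuple[float, float], ...]  # (par, duration_s)
    design: str = "nonsequential_rlc"  # | "induction_recovery"
    dark_adapt_s: float = 120.0
    measurement_interval_s: float | None = None  # None: one per step, at its end

    def __post_init__(self) -> None:
        if self.design not in ("nonsequential_rlc", "induction_recovery"):
            raise ValueError(f"unknown design {self.design!r}")
        if not self.steps:
            raise ValueError("sequence needs at least one step")
        for par, dur in self.steps:
            if par < 0 or dur <= 0:
                raise ValueError("steps need par >= 0 and duration > 0")
        if self.design == "induction_recovery" and len(self.steps) != 2:
            raise ValueError("induction_recovery has exactly two segments")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.steps))


def default_rlc_sequence(
    low_steps: Sequence[float] = DEFAULT_RLC_PAR[:3],
    step_duration_s: float = 30.0,
    dark_adapt_s: float = 120.0,
) -> LightSequence:
    """The canonical 9-step, 30-s-per-step non-sequential RLC.

    Light levels rise to 470 (measured 180 s in, counting the dark slot),
    drop back to 300, are re-raised to 470 and 540, and finish at the 74
    growth irradiance; total lit duration is 270 s.
    """
    par = tuple(low_steps) + DEFAULT_RLC_PAR[3:]
    return LightSequence(
        steps=tuple((float(p), float(step_duration_s)) for p in par),
        design="nonsequential_rlc",
        dark_adapt_s=dark_adapt_s,
    )


def default_induction_recovery_sequence(
    par: float = 300.0,
    induction_s: float = 1200.0,
    recovery_s: float = 900.0,
    measurement_interval_s: float = 60.0,
    dark_adapt_s: float = 120.0,
) -> LightSequence:
    """A 1200-s actinic induction followed by a 900-s dark recovery."""
    return LightSequence(
        steps=((float(par), float(induction_s)), (0.0, float(recovery_s))),
        design="induction_recovery",
        dark_adapt_s=dark_adapt_s,
        measurement_interval_s=measurement_interval_s,
    )


def measurement_schedule(sequence: LightSequence) -> list[tuple[float, float, float]]:
    """Measurement slots as (timestamp_s, par, elapsed_at_par_s).

    Timestamps count from the end of dark adaptation (the dark-adapted
    reference measurement sits at t=0, before the first step).  RLC designs
    measure once at the end of each step; induction-recovery designs measure
    every ``measurement_interval_s`` within each segment.
    """
    slots: list[tuple[float, float, float]] = []
    t = 0.0
    for par, dur in sequence.steps:
        interval = sequence.measurement_interval_s or dur
        k = interval
        while k <= dur + 1e-9:
            slots.append((t + k, par, k))
            k += interval
        t += dur
    return slots


@dataclass
class ExperimentTable:
    """Ordered per-step records plus the dark-adapted reference state."""

    records: list[LightStepRecord]
    dark_reference: PhotophysState
    design: str = "nonsequential_rlc"
    strain_label: str = ""
    treatment: str = "control"  # | "dtt"

    def __post_init__(self) -> None:
        if self.treatment not in ("control", "dtt"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        ts = [r.timestamp_s for r in self.records]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("record timestamps must be strictly increasing")

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for r in self.records:
            p = r.partition
            rows.append(
                {
                    "step_index": r.step_index,
                    "timestamp_s": r.timestamp_s,
                    "par": r.par,
                    "duration_s": r.duration_s,
                    "FS": r.FS,
                    "FMp": r.FMp,
                    "sigma_p": r.sigma_p,
                    "rho_p": r.rho_p,
                    "F0p_1s": r.F0p_1s,
                    "FMp_1s": r.FMp_1s,
                    "sigma_p_1s": r.sigma_p_1s,
                    "rho_p_1s": r.rho_p_1s,
                    "tau1_light": r.tau1_light,
                    "tau1_dark1s": r.tau1_dark1s,
                    "F0_ref": r.F0_ref,
                    "FM_ref": r.FM_ref,
                    "sigma_ref": r.sigma_ref,
                    "F0p": p.F0p if p else np.nan,
                    "qP": p.qP if p else np.nan,
                    "excitation_pressure": p.excitation_pressure if p else np.nan,
                    "Y_PSII": p.Y_PSII if p else np.nan,
                    "Y_NPQ": p.Y_NPQ if p else np.nan,
                    "Y_NO": p.Y_NO if p else np.nan,
                    "etr": r.etr,
                    "flags": ";".join(r.flags),
                }
            )
        return pd.DataFrame(rows)


def _group_measurements(transients: Iterable[FrrfTransient]):
    """Group transients by measurement_id into (induction, relaxation) pairs."""
    groups: dict[str, dict[str, FrrfTransient]] = {}
    for tr in transients:
        slot = groups.setdefault(tr.measurement_id, {})
        if tr.phase in slot:
            raise ProtocolMismatch(
                f"duplicate {tr.phase} transient for measurement {tr.measurement_id!r}"
            )
        slot[tr.phase] = tr
    return groups


def pair_measurements(
    transients: Sequence[FrrfTransient],
    train: FlashletTrain,
    design: str = "nonsequential_rlc",
    strain_label: str = "",
    treatment: str = "control",
    sigma_for_etr: str = "light",
) -> ExperimentTable:
    """Fit all transients and assemble them into an :class:`ExperimentTable`.

    Pairing keys on timestamps, not input order: each in-light measurement is
    matched to the nearest 1-s-dark measurement within (0, 5] s after it.
    The earliest dark-adapted measurement supplies the reference F0/FM/sigma.
    Unmatched or unconverged measurements carry quality flags; they are never
    silently dropped.  ``sigma_for_etr`` chooses whether the in-light
    ("light") or 1-s-dark ("dark_1s") cross section enters the ETR formula.
    """
    if sigma_for_etr not in ("light", "dark_1s"):
        raise ValueError("sigma_for_etr must be 'light' or 'dark_1s'")
    groups = _group_measurements(transients)

    fitted: list[dict] = []
    for mid, slot in sorted(groups.items()):
        if "induction" not in slot:
            raise ProtocolMismatch(f"measurement {mid!r} lacks an induction transient")
        ind_tr = slot["induction"]
        flags: list[str] = []
        try:
            ind = fit_induction(ind_tr, train)
        except DegenerateInput:
            flags.append("degenerate_induction")
            ind = None
        rel = None
        if ind is not None and "relaxation" in slot:
            rel = fit_relaxation(
                slot["relaxation"], ind, C0=induction_final_closure(ind, train)
            )
            if not rel.converged:
                flags.append("relaxation_not_converged")
        if ind is not None and not ind.converged:
            flags.append("induction_not_converged")
        fitted.append(
            {
                "id": mid,
                "timestamp_s": ind_tr.timestamp_s,
                "context": ind_tr.light_context,
                "par": ind_tr.actinic_par,
                "induction": ind,
                "relaxation": rel,
                "flags": flags,
            }
        )
    fitted.sort(key=lambda m: m["timestamp_s"])

    darks = [m for m in fitted if m["context"] == "dark_adapted" and m["induction"]]
    if not darks:
        raise ProtocolMismatch("no dark-adapted reference measurement found")
    ref = darks[0]
    ref_ind, ref_rel = ref["induction"], ref["relaxation"]
    dark_reference = PhotophysState(
        F0=ref_ind.F0_hat,
        FM=ref_ind.FM_hat,
        sigma=ref_ind.sigma_hat,
        rho=ref_ind.rho_hat,
        tau1=ref_rel.tau1_hat if ref_rel else 500.0,
        tau2=ref_rel.tau2_hat if ref_rel else 5000.0,
        alpha1=ref_rel.alpha1_hat if ref_rel else 1.0,
        alpha2=ref_rel.alpha2_hat if ref_rel else 0.0,
    )

    lights = [m for m in fitted if m["context"] == "actinic"]
    dark1s = [m for m in fitted if m["context"] == "dark_1s"]
    used: set[str] = set()

    records: list[LightStepRecord] = []
    prev_t = 0.0
    for idx, m in enumerate(lights, start=1):
        t = m["timestamp_s"]
        partner = None
        best = PAIRING_WINDOW_S + 1.0
        for d in dark1s:
            lag = d["timestamp_s"] - t
            if 0 < lag <= PAIRING_WINDOW_S and lag < best and d["id"] not in used:
                partner, best = d, lag
        flags = list(m["flags"])
        ind = m["induction"]
        if ind is None:
            continue
        rec = LightStepRecord(
            step_index=idx,
            timestamp_s=t,
            par=m["par"],
            duration_s=t - prev_t,
            FS=ind.F0_hat,
            FMp=ind.FM_hat,
            sigma_p=ind.sigma_hat,
            rho_p=ind.rho_hat,
            F0p_1s=np.nan,
            FMp_1s=np.nan,
            sigma_p_1s=np.nan,
            rho_p_1s=np.nan,
            tau1_light=m["relaxation"].tau1_hat if m["relaxation"] else np.nan,
            tau1_dark1s=np.nan,
            F0_ref=dark_reference.F0,
            FM_ref=dark_reference.FM,
            sigma_ref=dark_reference.sigma,
            flags=flags,
        )
        prev_t = t
        if partner is None or partner["induction"] is None:
            rec.flags.append("missing_dark_1s")
            records.append(rec)
            continue
        used.add(partner["id"])
        pind = partner["induction"]
        rec.F0p_1s = pind.F0_hat
        rec.FMp_1s = pind.FM_hat
        rec.sigma_p_1s = pind.sigma_hat
        rec.rho_p_1s = pind.rho_hat
        rec.tau1_dark1s = (
            partner["relaxation"].tau1_hat if partner["relaxation"] else np.nan
        )
        rec.flags.extend(f"dark1s_{f}" for f in partner["flags"])

        F0p, f0_flags = estimate_F0prime(rec.F0p_1s, rec.FMp_1s, rec.FMp)
        rec.flags.extend(f0_flags)
        part = yield_partition(rec.FS, rec.FMp, rec.FM_ref, F0p)
        rec.partition = part
        rec.flags.extend(part.flags)
        sigma_etr = rec.sigma_p if sigma_for_etr == "light" else rec.sigma_p_1s
        rec.etr = compute_etr(rec.par, sigma_etr, part.Y_PSII, rec.F0_ref, rec.FM_ref)
        records.append(rec)

    return ExperimentTable(
        records=records,
        dark_reference=dark_reference,
        design=design,
        strain_label=strain_label,
        treatment=treatment,
    )


def upregulation_index(table: ExperimentTable) -> list[dict]:
    """Compare ETR between visits to the same light level.

    For each PAR value visited more than once, returns the ETRs in visit
    order and the second-visit / first-visit ratio; ratio > 1 indicates
    upregulation of electron transport at the revisit.
    """
    if table.design != "nonsequential_rlc":
        raise ValueError("upregulation_index requires a nonsequential_rlc table")
    by_par: dict[float, list[LightStepRecord]] = {}
    for r in table.records:
        by_par.setdefault(r.par, []).append(r)
    out = []
    for par, recs in by_par.items():
        if len(recs) < 2:
            continue
        recs = sorted(recs, key=lambda r: r.timestamp_s)
        etrs = [r.etr for r in recs]
        out.append(
            {
                "par": par,
                "first_visit_etr": etrs[0],
                "revisit_etr": etrs[1],
                "etrs": etrs,
                "ratio": etrs[1] / etrs[0] if etrs[0] else float("nan"),
            }
        )
    if not out:
        raise NoRevisit("no light level was visited more than once")
    return sorted(out, key=lambda d: d["par"])
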