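"""Synthetic FRRf experiments with known ground truth.

Generates complete experiments — a physiological state trajectory under a
light sequence, rendered into noisy flashlet transients — with the
statistical structure the analysis pipeline assumes, so every stage can be
tested without instrument data.

Dynamics (minimal functional forms chosen to reproduce the qualitative
patterns the pipeline must detect):

* regulated dissipation Y(NPQ) ramps as ``dY/dt = npq_rate * (npq_max - Y)``
  while PAR exceeds ``npq_par_threshold`` and decays slowly otherwise, so
  dark reversal within 900 s is incomplete;
* the in-light cross section declines linearly with Y(NPQ):
  ``sigma' = sigma_dark * (1 + sigma_slope * Y_NPQ)``;
* the fast reopening lifetime rises with the closed fraction,
  ``tau1 = tau1_base + (tau1_max - tau1_base) * C``, and — when
  ``upregulation`` is on — is multiplied by ``upreg_factor`` (< 1) once
  cumulative supra-threshold exposure (evaluated with a short lag) passes a
  trigger, relaxing when PAR falls to the growth irradiance;
* the steady-state closed fraction balances the excitation rate
  ``PAR * sigma'`` against reopening at ``1/tau1`` (solved as a fixed point
  with the tau1 coupling);
* quenching acts through an added thermal rate constant ``k_n``, chosen per
  step so that the pipeline's measured Y(NPQ) equals the trajectory value;
  ``dtt_mode`` forces Y(NPQ) = 0 so non-regulated dissipation saturates
  instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .derived_params import PHOTON_FLUX_PER_UMOL
from .frrf_model import (
    FlashletTrain,
    FrrfTransient,
    PhotophysState,
    calibrate_dose,
    closure_to_fluorescence,
    induction_closure,
    simulate_induction,
    simulate_relaxation,
)
from .protocol import LightSequence, measurement_schedule

__all__ = [
    "GeneratorConfig",
    "TruthPoint",
    "state_trajectory",
    "render_transients",
    "default_train",
    "generate_experiment",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth physiology and noise model for one synthetic experiment."""

    seed: int = 0
    F0_dark: float = 0.2
    FM_dark: float = 0.5  # Fv/Fm = 0.6, so dark Y(NO) = 0.4
    sigma_dark: float = 400.0  # A^2 quantum^-1
    rho_dark: float = 0.3
    tau1_base: float = 500.0  # us
    tau1_max: float = 1800.0  # us
    tau2: float = 5000.0  # us
    alpha1: float = 0.7
    npq_par_threshold: float = 305.0  # umol photons m^-2 s^-1
    npq_rate: float = 0.01  # s^-1
    npq_max: float = 0.6  # asymptote of the Y(NPQ) ramp
    npq_relax_rate: float = 5e-4  # s^-1; incomplete reversal in 900 s dark
    npq_recovery_1s: float = 0.1  # fraction of quenching relaxing in 1 s dark
    sigma_slope: float = -0.65  # d(normalised sigma') / d(Y_NPQ)
    upregulation: bool = True
    upreg_factor: float = 0.5  # tau1 multiplier once high-light history is set
    upreg_trigger_s: float = 30.0  # cumulative supra-threshold exposure needed
    upreg_lag_s: float = 30.0  # delay before accumulated exposure takes effect
    growth_par: float = 74.0  # at or below this, high-light history resets
    dtt_mode: bool = False  # suppress Y(NPQ) induction entirely
    noise_cv: float = 0.01  # multiplicative Gaussian noise on fluorescence
    light_rendering: str = "baseline"  # | "closure"

    def __post_init__(self) -> None:
        if not 0 < self.F0_dark < self.FM_dark:
            raise ValueError("need 0 < F0_dark < FM_dark")
        if not 0 < self.tau1_base <= self.tau1_max:
            raise ValueError("need 0 < tau1_base <= tau1_max")
        for name in ("npq_rate", "npq_relax_rate", "noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.npq_max <= 1:
            raise ValueError("npq_max must be in (0, 1]")
        if abs(self.sigma_slope) > 1:
            raise ValueError("|sigma_slope| must be <= 1")
        if self.light_rendering not in ("baseline", "closure"):
            raise ValueError("light_rendering must be 'baseline' or 'closure'")

    @property
    def fv_fm(self) -> float:
        return (self.FM_dark - self.F0_dark) / self.FM_dark


@dataclass(frozen=True)
class TruthPoint:
    """Ground truth for one measurement slot (in-light + 1-s-dark pair)."""

    timestamp_s: float
    par: float
    context: str  # "dark_adapted" | "actinic"
    FS: float
    FMp: float
    F0p: float
    F0p_1s: float
    FMp_1s: float
    sigma_p: float
    sigma_p_1s: float
    rho: float
    tau1_light: float
    tau1_dark1s: float
    tau2: float
    C_ss: float
    Y_NPQ: float
    Y_NO: float
    Y_PSII: float
    etr: float
    upregulated: bool


def _quench_endpoints(cfg: GeneratorConfig, k_n: float) -> tuple[float, float]:
    """(F0', FM') for thermal quenching rate k_n (k_n = 0: dark values)."""
    k_p = cfg.FM_dark / cfg.F0_dark - 1.0  # photochemical rate constant
    FMp = cfg.FM_dark / (1.0 + k_n)
    F0p = cfg.FM_dark / (1.0 + k_p + k_n)
    return F0p, FMp


def _fs_at(cfg: GeneratorConfig, k_n: float, C: float) -> float:
    F0p, FMp = _quench_endpoints(cfg, k_n)
    return float(closure_to_fluorescence(C, F0p, FMp, cfg.rho_dark))


def _solve_k_n(cfg: GeneratorConfig, y_npq: float, C: float) -> float:
    """Quenching rate constant making measured Y(NPQ) equal ``y_npq``.

    Measured Y(NPQ) = FS/FM' - FS/FM is 0 at k_n = 0 and increases
    monotonically toward 1, so a bracketing root always exists for
    y_npq in [0, 1).
    """
    if y_npq <= 0:
        return 0.0

    def gap(k_n: float) -> float:
        FS = _fs_at(cfg, k_n, C)
        _, FMp = _quench_endpoints(cfg, k_n)
        return FS / FMp - FS / cfg.FM_dark - y_npq

    hi = 1.0
    while gap(hi) < 0:
        hi *= 4.0
        if hi > 1e12:  # pragma: no cover - unreachable for y_npq < 1
            raise RuntimeError("quenching solve failed to bracket")
    return float(brentq(gap, 0.0, hi, xtol=1e-14, rtol=1e-14))


def _steady_closure(
    cfg: GeneratorConfig, par: float, sigma_p: float, upreg_mult: float
) -> tuple[float, float]:
    """Fixed point of the closed fraction / tau1 coupling.

    Returns (C_ss, tau1_us).  Excitation closes centres at
    ``par * sigma'`` (s^-1); reopening proceeds at 1/tau1 where tau1 itself
    rises with the closed fraction and is scaled by ``upreg_mult``.
    """
    k_ex = par * PHOTON_FLUX_PER_UMOL * sigma_p  # s^-1
    C = 0.0
    tau1 = cfg.tau1_base * upreg_mult
    if k_ex > 0:
        for _ in range(200):
            tau1 = (cfg.tau1_base + (cfg.tau1_max - cfg.tau1_base) * C) * upreg_mult
            C_new = k_ex / (k_ex + 1.0 / (tau1 * 1e-6))
            if abs(C_new - C) < 1e-13:
                C = C_new
                break
            C = C_new
        tau1 = (cfg.tau1_base + (cfg.tau1_max - cfg.tau1_base) * C) * upreg_mult
    return C, tau1


def state_trajectory(
    cfg: GeneratorConfig, sequence: LightSequence
) -> list[TruthPoint]:
    """Ground-truth trajectory at every measurement slot.

    The first point (t = 0, after dark adaptation) is the dark-adapted
    reference; subsequent points follow :func:`frrf.protocol.measurement_schedule`.
    Deterministic — all randomness lives in :func:`render_transients`.
    """
    slots = measurement_schedule(sequence)
    # integrate Y(NPQ) and supra-threshold exposure on a 1-s grid
    total = int(round(sequence.total_duration_s))
    par_at = np.zeros(total)
    t0 = 0
    for par, dur in sequence.steps:
        d = int(round(dur))
        par_at[t0 : t0 + d] = par
        t0 += d
    y = 0.0
    cum = 0.0
    y_hist = np.zeros(total + 1)
    cum_hist = np.zeros(total + 1)
    for t in range(total):
        par = par_at[t]
        if not cfg.dtt_mode and par > cfg.npq_par_threshold:
            y = cfg.npq_max - (cfg.npq_max - y) * np.exp(-cfg.npq_rate)
        else:
            y *= np.exp(-cfg.npq_relax_rate)
        if par > cfg.npq_par_threshold:
            cum += 1.0
        elif par <= cfg.growth_par:
            cum = 0.0
        y_hist[t + 1] = y
        cum_hist[t + 1] = cum

    def upregulated_at(t_s: float) -> bool:
        if not cfg.upregulation:
            return False
        t_eff = int(round(max(t_s - cfg.upreg_lag_s, 0.0)))
        return cum_hist[min(t_eff, total)] >= cfg.upreg_trigger_s

    points = [
        TruthPoint(
            timestamp_s=0.0,
            par=0.0,
            context="dark_adapted",
            FS=cfg.F0_dark,
            FMp=cfg.FM_dark,
            F0p=cfg.F0_dark,
            F0p_1s=cfg.F0_dark,
            FMp_1s=cfg.FM_dark,
            sigma_p=cfg.sigma_dark,
            sigma_p_1s=cfg.sigma_dark,
            rho=cfg.rho_dark,
            tau1_light=cfg.tau1_base,
            tau1_dark1s=cfg.tau1_base,
            tau2=cfg.tau2,
            C_ss=0.0,
            Y_NPQ=0.0,
            Y_NO=cfg.F0_dark / cfg.FM_dark,
            Y_PSII=cfg.fv_fm,
            etr=0.0,
            upregulated=False,
        )
    ]
    for t_s, par, _elapsed in slots:
        y_t = float(y_hist[min(int(round(t_s)), total)])
        sigma_p = cfg.sigma_dark * (1.0 + cfg.sigma_slope * y_t)
        upreg = upregulated_at(t_s) and par > cfg.growth_par
        mult = cfg.upreg_factor if upreg else 1.0
        C_ss, tau1_light = _steady_closure(cfg, par, sigma_p, mult)
        k_n = _solve_k_n(cfg, y_t, C_ss)
        F0p, FMp = _quench_endpoints(cfg, k_n)
        FS = _fs_at(cfg, k_n, C_ss)
        k_n_1s = k_n * (1.0 - cfg.npq_recovery_1s)
        F0p_1s, FMp_1s = _quench_endpoints(cfg, k_n_1s)
        y_1s = y_t * (1.0 - cfg.npq_recovery_1s)
        sigma_1s = cfg.sigma_dark * (1.0 + cfg.sigma_slope * y_1s)
        y_psii = (FMp - FS) / FMp
        etr = par * PHOTON_FLUX_PER_UMOL * sigma_p * y_psii / cfg.fv_fm
        points.append(
            TruthPoint(
                timestamp_s=float(t_s),
                par=float(par),
                context="actinic",
                FS=FS,
                FMp=FMp,
                F0p=F0p,
                F0p_1s=F0p_1s,
                FMp_1s=FMp_1s,
                sigma_p=sigma_p,
                sigma_p_1s=sigma_1s,
                rho=cfg.rho_dark,
                tau1_light=tau1_light,
                tau1_dark1s=cfg.tau1_base,
                tau2=cfg.tau2,
                C_ss=C_ss,
                Y_NPQ=y_t,
                Y_NO=FS / cfg.FM_dark,
                Y_PSII=y_psii,
                etr=etr,
                upregulated=upreg,
            )
        )
    return points


#: relaxation sampling grid, us since reopening began
RELAX_TIMES_US = np.geomspace(20.0, 30000.0, 48)


def _render_measurement(
    state: PhotophysState,
    train: FlashletTrain,
    C_init: float,
    rng: np.random.Generator,
    noise_cv: float,
    **kw,
) -> list[FrrfTransient]:
    ind = simulate_induction(state, train, C_init=C_init, **kw)
    # closed fraction at end of the train seeds the relaxation
    C_end = induction_closure(
        state.sigma * train.dose_per_flashlet, state.rho, train.n_flashlets,
        C_init=C_init,
    )[-1]
    rel = simulate_relaxation(state, C_end, RELAX_TIMES_US, **kw)
    for tr in (ind, rel):
        if noise_cv > 0:
            tr.fluorescence = tr.fluorescence * (
                1.0 + noise_cv * rng.standard_normal(tr.fluorescence.size)
            )
            np.clip(tr.fluorescence, 1e-12, None, out=tr.fluorescence)
    return [ind, rel]


def render_transients(
    points: list[TruthPoint],
    train: FlashletTrain,
    cfg: GeneratorConfig,
) -> list[FrrfTransient]:
    """Render a truth trajectory into the full paired measurement schedule.

    Each in-light slot yields an induction + relaxation pair under actinic
    light and a second pair 1 s later in darkness; the t = 0 slot is the
    dark-adapted reference.  Multiplicative Gaussian noise (CV =
    ``cfg.noise_cv``) is drawn from a single generator seeded with
    ``cfg.seed``, so output is deterministic given the config.

    With ``light_rendering="baseline"`` (default) the steady-state closed
    fraction enters as a static background: the in-light induction runs from
    C = 0 between the FS and FM' levels, exactly matching the fit model's
    treatment of in-light curves.  ``"closure"`` instead starts the
    recursion at the steady-state closed fraction between F0' and FM'.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[FrrfTransient] = []
    for i, p in enumerate(points):
        if p.context == "dark_adapted":
            state = PhotophysState(
                F0=p.FS, FM=p.FMp, sigma=p.sigma_p, rho=p.rho,
                tau1=p.tau1_light, tau2=p.tau2,
                alpha1=cfg.alpha1, alpha2=1.0 - cfg.alpha1,
            )
            out.extend(
                _render_measurement(
                    state, train, 0.0, rng, cfg.noise_cv,
                    light_context="dark_adapted", actinic_par=0.0,
                    measurement_id=f"m{i:03d}R", timestamp_s=p.timestamp_s,
                )
            )
            continue
        if cfg.light_rendering == "baseline":
            light_state = PhotophysState(
                F0=p.FS, FM=p.FMp, sigma=p.sigma_p, rho=p.rho,
                tau1=p.tau1_light, tau2=p.tau2,
                alpha1=cfg.alpha1, alpha2=1.0 - cfg.alpha1,
            )
            c_init = 0.0
        else:
            light_state = PhotophysState(
                F0=p.F0p, FM=p.FMp, sigma=p.sigma_p, rho=p.rho,
                tau1=p.tau1_light, tau2=p.tau2,
                alpha1=cfg.alpha1, alpha2=1.0 - cfg.alpha1,
            )
            c_init = min(p.C_ss, 1.0 - 1e-9)
        out.extend(
            _render_measurement(
                light_state, train, c_init, rng, cfg.noise_cv,
                light_context="actinic", actinic_par=p.par,
                measurement_id=f"m{i:03d}L", timestamp_s=p.timestamp_s,
            )
        )
        dark_state = PhotophysState(
            F0=p.F0p_1s, FM=p.FMp_1s, sigma=p.sigma_p_1s, rho=p.rho,
            tau1=p.tau1_dark1s, tau2=p.tau2,
            alpha1=cfg.alpha1, alpha2=1.0 - cfg.alpha1,
        )
        out.extend(
            _render_measurement(
                dark_state, train, 0.0, rng, cfg.noise_cv,
                light_context="dark_1s", actinic_par=0.0,
                measurement_id=f"m{i:03d}D", timestamp_s=p.timestamp_s + 1.0,
            )
        )
    return out


def default_train(cfg: GeneratorConfig, n_flashlets: int = 40) -> FlashletTrain:
    """Train whose dose saturates the dark-adapted rise by flashlet 30."""
    return FlashletTrain(
        n_flashlets=n_flashlets,
        dose_per_flashlet=calibrate_dose(cfg.sigma_dark, 30, 0.98),
    )


def generate_experiment(
    cfg: GeneratorConfig,
    sequence: LightSequence,
    train: FlashletTrain | None = None,
):
    """Convenience wrapper: (transients, truth points, train)."""
    if train is None:
        train = default_train(cfg)
    points = state_trajectory(cfg, sequence)
    transients = render_transients(points, train, cfg)
    return transients, points, train
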