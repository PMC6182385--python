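"""Nonlinear least-squares estimation of photophysiology from transients.

Induction fits estimate (F0, FM, sigma, rho) from the flashlet-train rise;
relaxation fits then estimate (tau1, tau2, alpha1) with the induction
parameters held fixed.  Fits are sequential rather than joint, mirroring the
two-curve measurement structure, and use a trust-region reflective
least-squares solver with box bounds (rho in [0, 0.8], sigma capped at 10x
its initial guess to keep the sigma-rho ridge from diverging on noisy
high-light transients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateInput
from .frrf_model import (
    FlashletTrain,
    FrrfTransient,
    closure_to_fluorescence,
    induction_closure,
)

__all__ = [
    "InductionFit",
    "RelaxationFit",
    "fit_induction",
    "fit_relaxation",
    "induction_final_closure",
]

RHO_MAX = 0.8
FTOL = 1e-14
XTOL = 1e-14
MAX_ITER = 500
#: relative late-trace slope above which the rise is flagged as unsaturated
SATURATION_SLOPE_TOL = 8e-3


@dataclass(frozen=True)
class InductionFit:
    """Estimated induction parameters for one measurement."""

    F0_hat: float
    FM_hat: float
    sigma_hat: float
    rho_hat: float
    rss: float
    converged: bool
    n_points: int
    C_init: float = 0.0


@dataclass(frozen=True)
class RelaxationFit:
    """Estimated reopening kinetics; canonicalized so tau1_hat <= tau2_hat."""

    tau1_hat: float
    tau2_hat: float
    alpha1_hat: float
    alpha2_hat: float
    rss: float
    converged: bool
    n_points: int


def _saturated(F: np.ndarray) -> bool:
    """True when the rise has plateaued within the trace.

    Compares the means of the last two quarters of the trace (window means
    keep the check robust to per-sample noise) and converts their difference
    to a per-flashlet slope in amplitude units.
    """
    n = F.size
    q = n // 4
    amp = float(F.max() - F.min())
    if amp <= 0 or q < 2:
        return False
    slope = (float(F[-q:].mean()) - float(F[-2 * q : -q].mean())) / q / amp
    return slope < SATURATION_SLOPE_TOL


def fit_induction(
    transient: FrrfTransient,
    train: FlashletTrain,
    C_init: float = 0.0,
) -> InductionFit:
    """Fit (F0, FM, sigma, rho) to a flashlet-train induction curve.

    Deterministic given the data: initialization is F0 = mean of the first
    two points, FM = max, sigma from the half-amplitude flashlet index
    (closed form at rho=0), rho = 0.3.  A rise that has not plateaued (high
    actinic light can suppress variable fluorescence to small values) is
    returned with ``converged=False`` rather than raised.

    Raises
    ------
    DegenerateInput
        If the trace is constant (no variable fluorescence).
    """
    if transient.phase != "induction":
        raise ValueError("fit_induction requires an induction-phase transient")
    F = transient.fluorescence
    n = F.size
    if n < 8:
        raise ValueError("induction fit needs at least 8 points")
    if np.ptp(F) == 0:
        raise DegenerateInput("constant fluorescence trace")

    F0_0 = float(F[:2].mean())
    FM_0 = float(F.max())
    Fv_0 = max(FM_0 - F0_0, 1e-12 * max(FM_0, 1.0))
    half = F0_0 + 0.5 * (FM_0 - F0_0)
    k_half = int(np.argmax(F >= half)) + 1  # 1-based flashlet index
    frac = 1.0 - 0.5 ** (1.0 / k_half)
    sigma_0 = max(frac / train.dose_per_flashlet, 1e-12)

    dose = train.dose_per_flashlet
    nfl = train.n_flashlets

    def model(p: np.ndarray) -> np.ndarray:
        F0, Fv, sigma, rho = p
        C = induction_closure(sigma * dose, rho, nfl, C_init=C_init)
        return closure_to_fluorescence(C, F0, F0 + Fv, rho)

    def resid(p: np.ndarray) -> np.ndarray:
        return model(p) - F

    p0 = np.array([F0_0, Fv_0, sigma_0, 0.3])
    lo = np.array([0.0, 1e-12, 1e-12, 0.0])
    hi = np.array([2.0 * FM_0 + 1e-12, 2.0 * FM_0 + 1e-12, 10.0 * sigma_0, RHO_MAX])
    p0 = np.clip(p0, lo, hi)
    sol = least_squares(
        resid, p0, bounds=(lo, hi), method="trf",
        ftol=FTOL, xtol=XTOL, gtol=FTOL, max_nfev=MAX_ITER * 5,
    )
    F0_hat, Fv_hat, sigma_hat, rho_hat = sol.x
    rss = float(2.0 * sol.cost)
    converged = bool(sol.success) and _saturated(F)
    return InductionFit(
        F0_hat=float(F0_hat),
        FM_hat=float(F0_hat + Fv_hat),
        sigma_hat=float(sigma_hat),
        rho_hat=float(rho_hat),
        rss=rss,
        converged=converged,
        n_points=n,
        C_init=C_init,
    )


def induction_final_closure(fit: InductionFit, train: FlashletTrain) -> float:
    """Closed fraction at the end of the train implied by a fitted induction."""
    C = induction_closure(
        fit.sigma_hat * train.dose_per_flashlet,
        fit.rho_hat,
        train.n_flashlets,
        C_init=fit.C_init,
    )
    return float(C[-1])


def fit_relaxation(
    transient: FrrfTransient,
    induction: InductionFit,
    C0: float | None = None,
) -> RelaxationFit:
    """Fit biexponential reopening (tau1, tau2, alpha1) to a relaxation curve.

    F0, FM and rho are held fixed from the paired induction fit; ``C0`` is
    the closed fraction at the start of the relaxation (by default inverted
    from the first sample).  Output is canonicalized so tau1_hat <= tau2_hat;
    a genuinely single-phase trace yields tau1_hat ~= tau2_hat with an
    ill-identified amplitude split, which is reported, not raised.
    """
    if transient.phase != "relaxation":
        raise ValueError("fit_relaxation requires a relaxation-phase transient")
    F0, FM, rho = induction.F0_hat, induction.FM_hat, induction.rho_hat
    t = transient.times_us
    F = transient.fluorescence
    if np.ptp(F) == 0:
        raise DegenerateInput("constant fluorescence trace")
    if C0 is None:
        V = (float(F[0]) - F0) / (FM - F0)
        V = min(max(V, 1e-6), 1.0)
        C0 = V / (1.0 - rho + rho * V)
    if not 0 < C0 <= 1:
        raise ValueError("C0 must lie in (0, 1]")

    # initial tau from the half-decay time of the normalized trace
    V = np.clip((F - F0) / (FM - F0), 0.0, 1.0)
    u = V / (1.0 - rho + rho * V) / C0  # normalized closure decay
    below = np.nonzero(u <= 0.5)[0]
    t_half = float(t[below[0]]) if below.size else float(t[-1])
    tau1_0 = max(t_half / np.log(2.0), 1.0)
    tau2_0 = 10.0 * tau1_0

    def resid(p: np.ndarray) -> np.ndarray:
        tau1, tau2, a1 = p
        C = C0 * (a1 * np.exp(-t / tau1) + (1.0 - a1) * np.exp(-t / tau2))
        return closure_to_fluorescence(C, F0, FM, rho) - F

    t_max = float(t[-1])
    lo = np.array([1e-3, 1e-3, 0.0])
    hi = np.array([100.0 * t_max, 100.0 * t_max, 1.0])
    p0 = np.clip(np.array([tau1_0, tau2_0, 0.7]), lo, hi)
    sol = least_squares(
        resid, p0, bounds=(lo, hi), method="trf",
        ftol=FTOL, xtol=XTOL, gtol=FTOL, max_nfev=MAX_ITER * 5,
    )
    tau1, tau2, a1 = sol.x
    a2 = 1.0 - a1
    if tau1 > tau2:  # canonical order: fast phase first
        tau1, tau2 = tau2, tau1
        a1, a2 = a2, a1
    return RelaxationFit(
        tau1_hat=float(tau1),
        tau2_hat=float(tau2),
        alpha1_hat=float(a1),
        alpha2_hat=float(a2),
        rss=float(2.0 * sol.cost),
        converged=bool(sol.success),
        n_points=int(t.size),
    )
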