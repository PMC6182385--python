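"""Forward model of single-turnover fluorescence induction and relaxation.

A measurement excites photosystem II (PSII) with a train of microsecond
flashlets.  Each flashlet closes a fraction of the open reaction centres
(reduces the first quinone acceptor), driving the closed fraction ``C`` from
its initial value toward 1; the observed fluorescence yield is a saturating
function of ``C`` shaped by the excitonic connectivity ``rho``.  After the
train, centres reopen with biexponential kinetics (lifetimes ``tau1`` and
``tau2``).  The same model serves as the synthetic-data generator and as the
fit model used by :mod:`frrf.fitting`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FlashletTrain",
    "PhotophysState",
    "FrrfTransient",
    "closure_to_fluorescence",
    "closure_from_fluorescence",
    "induction_closure",
    "simulate_induction",
    "simulate_relaxation",
    "calibrate_dose",
]


@dataclass(frozen=True)
class FlashletTrain:
    """Excitation protocol: ``n_flashlets`` pulses of ``flashlet_duration_us``
    separated by ``gap_duration_us`` of darkness, each delivering
    ``dose_per_flashlet`` photons per squared angstrom."""

    n_flashlets: int = 40
    flashlet_duration_us: float = 1.2
    gap_duration_us: float = 1.0
    dose_per_flashlet: float = 3.0e-4
    wavelength_nm: float = 455.0  # metadata only

    def __post_init__(self) -> None:
        if self.n_flashlets < 1:
            raise ValueError("n_flashlets must be >= 1")
        if self.flashlet_duration_us <= 0:
            raise ValueError("flashlet_duration_us must be > 0")
        if self.gap_duration_us < 0:
            raise ValueError("gap_duration_us must be >= 0")
        if self.dose_per_flashlet <= 0:
            raise ValueError("dose_per_flashlet must be > 0")

    @property
    def period_us(self) -> float:
        return self.flashlet_duration_us + self.gap_duration_us

    def timestamps_us(self) -> np.ndarray:
        """Timestamp of flashlet k (1-based) is ``k * period``; strictly increasing."""
        return np.arange(1, self.n_flashlets + 1, dtype=float) * self.period_us

    @property
    def span_us(self) -> float:
        return self.n_flashlets * self.period_us


@dataclass(frozen=True)
class PhotophysState:
    """Biophysical parameters of one measurement.

    ``F0``/``FM`` are the minimal/maximal fluorescence yields (arbitrary
    instrument units), ``sigma`` the effective absorption cross section for
    PSII photochemistry (A^2 quantum^-1), ``rho`` the excitonic connectivity,
    ``tau1``/``tau2`` the fast/slow reopening lifetimes (us) with fractional
    amplitudes ``alpha1``/``alpha2``.  The same type holds dark-adapted,
    in-light (primed) and 1-s-dark variants.
    """

    F0: float
    FM: float
    sigma: float
    rho: float = 0.0
    tau1: float = 500.0
    tau2: float = 5000.0
    alpha1: float = 1.0
    alpha2: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.F0 < self.FM:
            raise ValueError(f"need 0 <= F0 < FM, got F0={self.F0}, FM={self.FM}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if not 0 < self.tau1 <= self.tau2:
            raise ValueError("need 0 < tau1 <= tau2")
        if not (0 <= self.alpha1 <= 1 and 0 <= self.alpha2 <= 1):
            raise ValueError("alpha1, alpha2 must be in [0, 1]")
        if abs(self.alpha1 + self.alpha2 - 1.0) > 1e-9:
            raise ValueError("alpha1 + alpha2 must equal 1")


@dataclass
class FrrfTransient:
    """One induction or relaxation time series.

    ``times_us`` are microseconds from the start of the phase (induction
    flashlet timestamps, or time since reopening began), ``timestamp_s`` the
    position of the measurement within the experiment.
    """

    times_us: np.ndarray
    fluorescence: np.ndarray
    phase: str  # "induction" | "relaxation"
    light_context: str = "dark_adapted"  # | "actinic" | "dark_1s"
    actinic_par: float = 0.0
    measurement_id: str = ""
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        self.times_us = np.asarray(self.times_us, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.phase not in ("induction", "relaxation"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.light_context not in ("dark_adapted", "actinic", "dark_1s"):
            raise ValueError(f"unknown light_context {self.light_context!r}")
        if self.times_us.shape != self.fluorescence.shape:
            raise ValueError("times and fluorescence must have equal length")
        if self.times_us.size < 4:
            raise ValueError("transient needs at least 4 samples")
        if np.any(np.diff(self.times_us) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.fluorescence < 0):
            raise ValueError("fluorescence must be >= 0")
        if self.light_context != "actinic" and self.actinic_par != 0:
            raise ValueError("dark contexts require actinic_par == 0")

    @property
    def n_points(self) -> int:
        return int(self.times_us.size)


def closure_to_fluorescence(C, F0: float, FM: float, rho: float):
    """Fluorescence yield at closed fraction ``C``.

    F = F0 + (FM - F0) * C*(1-rho) / (1 - rho*C); continuous and
    nondecreasing in C, with F(0) = F0 and F(1) = FM for any rho.
    """
    C = np.asarray(C, dtype=float)
    if np.any((C < 0) | (C > 1)):
        raise ValueError("closed fraction C must lie in [0, 1]")
    denom = 1.0 - rho * C
    if np.any(denom <= 0):
        raise ValueError("rho * C >= 1: connectivity mapping undefined")
    out = F0 + (FM - F0) * C * (1.0 - rho) / denom
    return out if out.ndim else float(out)


def closure_from_fluorescence(F, F0: float, FM: float, rho: float):
    """Inverse of :func:`closure_to_fluorescence` (clipped to [0, 1])."""
    V = (np.asarray(F, dtype=float) - F0) / (FM - F0)
    V = np.clip(V, 0.0, 1.0)
    out = V / (1.0 - rho + rho * V)
    return out if out.ndim else float(out)


def induction_closure(
    sigma_dose: float,
    rho: float,
    n_flashlets: int,
    C_init: float = 0.0,
    relax_factor: float = 1.0,
) -> np.ndarray:
    """Closed fraction after each flashlet of the train.

    Per flashlet: ``C+ = C + sigma_dose * (1-C) / (1 - rho*C)`` (clipped to
    1), optionally followed by ``C <- C+ * relax_factor`` to model reopening
    in the inter-flashlet interval.  Returns the post-flashlet values
    ``C_1..C_n`` (relaxation, when enabled, applied after recording).
    """
    C = float(C_init)
    out = np.empty(n_flashlets, dtype=float)
    for k in range(n_flashlets):
        C = min(1.0, C + sigma_dose * (1.0 - C) / (1.0 - rho * C))
        out[k] = C
        if relax_factor != 1.0:
            C *= relax_factor
    return out


def simulate_induction(
    state: PhotophysState,
    train: FlashletTrain,
    C_init: float = 0.0,
    relax_between_flashlets: bool = False,
    **transient_kwargs,
) -> FrrfTransient:
    """Simulate the fluorescence rise over a flashlet train.

    With ``relax_between_flashlets`` off (the default; the ~88 us train is
    short against tau1) the trace is monotonically nondecreasing from near
    ``F0`` toward ``FM``.
    """
    if not 0 <= C_init < 1:
        raise ValueError("C_init must lie in [0, 1)")
    relax = (
        float(np.exp(-train.period_us / state.tau1))
        if relax_between_flashlets
        else 1.0
    )
    C = induction_closure(
        state.sigma * train.dose_per_flashlet,
        state.rho,
        train.n_flashlets,
        C_init=C_init,
        relax_factor=relax,
    )
    F = closure_to_fluorescence(C, state.F0, state.FM, state.rho)
    return FrrfTransient(
        times_us=train.timestamps_us(),
        fluorescence=F,
        phase="induction",
        **transient_kwargs,
    )


def simulate_relaxation(
    state: PhotophysState,
    C0: float,
    times_us: np.ndarray,
    **transient_kwargs,
) -> FrrfTransient:
    """Simulate PSII reopening after the train closed a fraction ``C0``.

    ``C(t) = C0 * (alpha1 * exp(-t/tau1) + alpha2 * exp(-t/tau2))``, with
    ``t`` measured from the start of the relaxation phase.
    """
    if not 0 < C0 <= 1:
        raise ValueError("C0 must lie in (0, 1]")
    t = np.asarray(times_us, dtype=float)
    if t.size and t[0] < 0:
        raise ValueError("times must be >= 0")
    C = C0 * (
        state.alpha1 * np.exp(-t / state.tau1)
        + state.alpha2 * np.exp(-t / state.tau2)
    )
    F = closure_to_fluorescence(C, state.F0, state.FM, state.rho)
    return FrrfTransient(
        times_us=t,
        fluorescence=F,
        phase="relaxation",
        **transient_kwargs,
    )


def calibrate_dose(
    sigma_ref: float,
    target_flashlet: int = 30,
    target_closure: float = 0.98,
) -> float:
    """Per-flashlet dose that saturates the rise by ``target_flashlet``.

    For rho=0 the closure after k flashlets is 1-(1-sigma*dose)^k, so the
    dose solving closure(target_flashlet)=target_closure is
    ``(1 - (1-target_closure)**(1/target_flashlet)) / sigma_ref``.
    """
    if not 0 < target_closure < 1:
        raise ValueError("target_closure must lie in (0, 1)")
    if target_flashlet < 1:
        raise ValueError("target_flashlet must be >= 1")
    if sigma_ref <= 0:
        raise ValueError("sigma_ref must be > 0")
    return (1.0 - (1.0 - target_closure) ** (1.0 / target_flashlet)) / sigma_ref
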