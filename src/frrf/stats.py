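"""Cross-measurement regressions and summary relationships."""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats as _sps

from .errors import DegenerateX, DivisionDegenerate

if TYPE_CHECKING:  # pragma: no cover
    from .protocol import ExperimentTable

__all__ = ["RegressionResult", "regress", "normalise_sigma"]


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares fit of y on x."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def regress(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Closed-form OLS with a two-sided t-test on the slope.

    Raises :class:`DegenerateX` when the predictor has no variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("regression needs at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    dx = x - x.mean()
    sxx = float(dx @ dx)
    if sxx == 0:
        raise DegenerateX("predictor has zero variance")
    slope = float(dx @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ssr = float(resid @ resid)
    syy = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 if syy == 0 else 1.0 - ssr / syy
    df = n - 2
    if ssr <= 0:
        p = 0.0
    else:
        se = np.sqrt(ssr / df / sxx)
        tstat = slope / se
        p = float(2.0 * _sps.t.sf(abs(tstat), df))
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=float(np.clip(r_squared, 0.0, 1.0)),
        p_value=p,
        n=int(n),
    )


def normalise_sigma(table: "ExperimentTable", reference: str = "dark") -> np.ndarray:
    """Per-record sigma' divided by the experiment's own reference.

    ``reference`` is "dark" (the dark-adapted fit, default) or "max" (series
    maximum), since published "normalised" cross sections are defined both
    ways.
    """
    sig = np.array([r.sigma_p for r in table.records], dtype=float)
    if reference == "dark":
        ref = table.dark_reference.sigma
    elif reference == "max":
        ref = float(np.nanmax(sig))
    else:
        raise ValueError("reference must be 'dark' or 'max'")
    if not ref > 0:
        raise DivisionDegenerate("reference sigma must be > 0")
    return sig / ref
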