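"""Hill-equation fitting of fraction-bound titration data.

Gel-shift (EMSA) titrations yield, per protein concentration X, the
fraction of labelled probe bound, Y in [0, 1].  The binding model is

    Y = Bmax * X**h / (Kd**h + X**h)

with maximum response Bmax in (0, 1], dissociation constant Kd > 0 (in
the units of X) and Hill coefficient h > 0 describing cooperativity.
Fitting is bounded nonlinear least squares on the natural parameter
scale, so reported standard errors apply directly to Bmax, Kd and h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

from .errors import InputError

__all__ = [
    "BindingCurve",
    "HillFitResult",
    "hill_model",
    "fit_hill",
    "cooperativity_class",
]

_LOWER = np.array([1e-9, 1e-9, 1e-9])
_UPPER = np.array([1.0, np.inf, np.inf])


def hill_model(X, bmax: float, kd: float, h: float):
    """Hill curve Y = Bmax·X^h / (Kd^h + X^h); Y(0)=0, Y→Bmax as X→∞."""
    if kd <= 0:
        raise InputError("Kd must be > 0")
    if h <= 0:
        raise InputError("Hill coefficient h must be > 0")
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise InputError("concentrations must be >= 0")
    with np.errstate(divide="ignore"):
        # work in ratio space for numerical stability at large X
        r = np.where(X > 0, (X / kd) ** h, 0.0)
    return bmax * r / (1.0 + r)


@dataclass
class BindingCurve:
    """A titration: concentrations X (nM or µM) and fractions bound Y.

    Replicates are stacked; within each replicate the concentrations
    must be distinct.  Y outside [-0.05, 1.05] is rejected (values in
    the small negative/super-unity band are tolerated as quantification
    noise and clipped only at fit time, not here).
    """

    concentrations: np.ndarray
    responses: np.ndarray
    units: str = "nM"
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.concentrations, dtype=float)
        Y = np.asarray(self.responses, dtype=float)
        if X.shape != Y.shape or X.ndim != 1:
            raise InputError("concentrations and responses must be equal-length 1-D")
        if np.any(X < 0):
            raise InputError("concentrations must be >= 0")
        if np.any((Y < -0.05) | (Y > 1.05)):
            raise InputError("fraction bound outside [-0.05, 1.05]")
        if self.replicate is None:
            reps = np.zeros(len(X), dtype=int)
        else:
            reps = np.asarray(self.replicate)
            if reps.shape != X.shape:
                raise InputError("replicate labels must match data length")
        for r in np.unique(reps):
            sub = np.sort(X[reps == r])
            if np.any(np.diff(sub) <= 0):
                raise InputError(
                    f"replicate {r}: concentrations must be distinct"
                )
        self.concentrations = X
        self.responses = Y
        self.replicate = reps


@dataclass
class HillFitResult:
    """Fitted (Bmax, Kd, h) with standard errors and diagnostics."""

    bmax: float
    kd: float
    h: float
    se_bmax: float
    se_kd: float
    se_h: float
    converged: bool
    rss: float
    n_points: int
    units: str = "nM"
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.bmax, self.kd, self.h)


def _default_init(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Bmax0 = max(Y) clipped to (0,1]; Kd0 = X nearest half-max; h0 = 1."""
    bmax0 = float(np.clip(Y.max(), 0.05, 1.0))
    kd0 = float(X[np.argmin(np.abs(Y - bmax0 / 2.0))])
    if kd0 <= 0:
        pos = X[X > 0]
        kd0 = float(np.median(pos)) if pos.size else 1.0
    return np.array([bmax0, kd0, 1.0])


def fit_hill(
    curve: BindingCurve, init: Sequence[float] | None = None
) -> HillFitResult:
    """Constrained least-squares Hill fit of a binding curve.

    Replicates are fitted jointly by stacking points.  Requires at least
    four distinct concentrations.  Non-convergence yields a flagged
    result with NaN parameters, never fabricated values; a fitted Kd
    beyond 10x the largest concentration is reported with a
    ``kd_extrapolated`` warning, and a response trend that decreases
    with concentration with a ``decreasing_response`` warning.
    """
    X = curve.concentrations
    Y = curve.responses
    if np.all(Y == 0):
        raise InputError("no binding signal: all responses are zero")
    if len(np.unique(X)) < 4:
        raise InputError("at least 4 distinct concentrations required")

    warnings: list[str] = []
    rho = spearmanr(X, Y).statistic
    if np.isfinite(rho) and rho < 0:
        warnings.append("decreasing_response")

    p0 = np.asarray(init, dtype=float) if init is not None else _default_init(X, Y)
    p0 = np.clip(p0, _LOWER, np.minimum(_UPPER, np.nan_to_num(p0, posinf=1e12)))

    def model(x, bmax, kd, h):
        return hill_model(x, bmax, kd, h)

    try:
        popt, pcov = curve_fit(
            model,
            X,
            Y,
            p0=p0,
            bounds=(_LOWER, _UPPER),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        nan = float("nan")
        return HillFitResult(
            nan, nan, nan, nan, nan, nan,
            converged=False, rss=nan, n_points=len(X), units=curve.units,
            warnings=tuple(warnings + ["no_convergence"]),
        )

    bmax, kd, h = (float(v) for v in popt)
    resid = Y - hill_model(X, bmax, kd, h)
    rss = float(np.sum(resid**2))
    with np.errstate(invalid="ignore"):
        ses = np.sqrt(np.diag(pcov))
    ses = [float(s) if np.isfinite(s) else float("nan") for s in ses]

    if kd > 10.0 * X.max():
        warnings.append("kd_extrapolated")
    if h <= float(_LOWER[2]) * 10 or np.isclose(h, _LOWER[2]):
        warnings.append("h_at_bound")

    return HillFitResult(
        bmax, kd, h, ses[0], ses[1], ses[2],
        converged=True, rss=rss, n_points=len(X), units=curve.units,
        warnings=tuple(warnings),
    )


def cooperativity_class(h: float) -> str:
    """Interpretive cooperativity band for a fitted Hill coefficient.

    h >= 1.5: "moderate positive"; h < 1.3: "weak"; in between:
    "intermediate".  The thresholds are descriptive conventions, not
    fitted quantities.
    """
    if h >= 1.5:
        return "moderate positive"
    if h < 1.3:
        return "weak"
    return "intermediate"
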