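"""Fit-point Ct quantification and the residual CI defining true outliers.

The classical Ct readout is the fractional cycle at which the trace first
crosses a fixed fluorescence threshold (default 0.4, matching a manually set
instrument threshold). A dilution series of standards gives the regression
``Ct = intercept + slope * log10(N)``; inverting it converts any Ct into an
observed copy number ``Nob``. For runs with known input ``Nexp``, the
quantification residual ``log10(Nob/Nexp)`` is, over well-behaved standards,
normal with mean ~0; its 95% interval (mean +- z * SD) defines which runs are
*true* quantification outliers — the ground truth the kinetic outlier tests
are scored against.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .plate_io import AmplificationRun

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.4

__all__ = [
    "DEFAULT_THRESHOLD",
    "BaselineError",
    "NoCtError",
    "ResidualCI",
    "StandardCurve",
    "build_standard_curve",
    "ct_fit_point",
    "estimate_copies",
    "residual_ci",
    "truth_label",
]


class NoCtError(ValueError):
    """Trace never crosses the threshold: total amplification failure."""


class BaselineError(ValueError):
    """Trace already above threshold at the first cycle (bad baseline)."""


@dataclass(frozen=True)
class StandardCurve:
    """OLS regression of Ct on log10 input copies over the dilution series."""

    intercept: float
    slope: float
    r_squared: float
    efficiency_from_slope: float
    threshold: float
    n_runs: int


@dataclass(frozen=True)
class ResidualCI:
    """95% confidence interval of log10(Nob/Nexp) over standard runs."""

    mean_resid: float
    sigma_resid: float
    lower: float
    upper: float
    n: int


def ct_fit_point(run: AmplificationRun, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Fractional threshold-crossing cycle (fit-point method).

    Linear interpolation between the flanking readings of the first upward
    crossing. Raises :class:`NoCtError` if the trace never reaches the
    threshold and :class:`BaselineError` if it starts above it.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    f = run.fluorescence
    if f[0] >= threshold:
        raise BaselineError(
            f"run {run.run_id!r}: fluorescence {f[0]:g} already >= threshold "
            f"{threshold:g} at cycle {int(run.cycles[0])}"
        )
    crossing = np.nonzero((f[:-1] < threshold) & (f[1:] >= threshold))[0]
    if crossing.size == 0:
        raise NoCtError(
            f"run {run.run_id!r}: never crosses threshold {threshold:g} "
            f"(max {f.max():g})"
        )
    i = int(crossing[0])
    x0, x1 = float(run.cycles[i]), float(run.cycles[i + 1])
    f0, f1 = float(f[i]), float(f[i + 1])
    return x0 + (threshold - f0) / (f1 - f0) * (x1 - x0)


def build_standard_curve(
    cts: Sequence[float],
    log10_inputs: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
) -> StandardCurve:
    """Regress Ct on log10 input copies (the standard curve).

    Needs at least two distinct concentrations. The slope implies the
    assay-wide amplification efficiency ``E = 10^(-1/slope)`` (2 = perfect
    doubling); values outside (1, 2.2] are allowed but warned about.
    """
    ct = np.asarray(cts, dtype=float)
    lg = np.asarray(log10_inputs, dtype=float)
    if ct.shape != lg.shape or ct.ndim != 1:
        raise ValueError("cts and log10_inputs must be 1-D and the same length")
    if np.unique(lg).size < 2:
        raise ValueError("standard curve needs >= 2 distinct input concentrations")
    fit = stats.linregress(lg, ct)
    slope = float(fit.slope)
    if slope >= 0:
        warnings.warn("standard-curve slope is non-negative; dilution series suspect")
        eff = np.nan
    else:
        eff = float(10.0 ** (-1.0 / slope))
        if not (1.0 < eff <= 2.2):
            warnings.warn(f"implausible efficiency {eff:.3f} from slope {slope:.3f}")
    return StandardCurve(
        intercept=float(fit.intercept),
        slope=slope,
        r_squared=float(fit.rvalue) ** 2,
        efficiency_from_slope=eff,
        threshold=threshold,
        n_runs=int(ct.size),
    )


def estimate_copies(ct, curve: StandardCurve):
    """Observed copy number ``Nob = 10^((ct - intercept)/slope)``.

    Strictly decreasing in ``ct`` for a valid (negative-slope) curve.
    Accepts scalars or arrays.
    """
    ct = np.asarray(ct, dtype=float)
    nob = 10.0 ** ((ct - curve.intercept) / curve.slope)
    return float(nob) if nob.ndim == 0 else nob


def residual_ci(
    log10_nob: Sequence[float], log10_nexp: Sequence[float]
) -> ResidualCI:
    """95% CI for log10(Nob/Nexp) over the standard runs.

    Residuals are ``log10(Nob) - log10(Nexp)`` per run; the interval is
    ``mean +- z_{0.975} * SD`` (SD with denominator n-1), relying on the
    empirically-checked normality of the residuals.
    """
    nob = np.asarray(log10_nob, dtype=float)
    nexp = np.asarray(log10_nexp, dtype=float)
    if nob.shape != nexp.shape or nob.ndim != 1:
        raise ValueError("log10_nob and log10_nexp must be 1-D and the same length")
    if nob.size < 10:
        raise ValueError(f"need >= 10 standard runs for the residual CI, got {nob.size}")
    resid = nob - nexp
    mean = float(np.mean(resid))
    sd = float(np.std(resid, ddof=1))
    if sd == 0.0:
        warnings.warn("zero residual SD: degenerate confidence interval")
    z = float(stats.norm.ppf(0.975))
    return ResidualCI(
        mean_resid=mean, sigma_resid=sd,
        lower=mean - z * sd, upper=mean + z * sd, n=int(nob.size),
    )


def truth_label(resid: float, ci: ResidualCI) -> bool:
    """True iff the residual falls strictly outside the 95% CI.

    Bounds are inclusive: a residual exactly on a bound is not an outlier.
    """
    if not np.isfinite(ci.lower) or not np.isfinite(ci.upper) or ci.lower >= ci.upper:
        raise ValueError("degenerate residual CI; cannot label outliers")
    return bool(resid < ci.lower or resid > ci.upper)
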