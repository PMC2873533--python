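"""Richards-curve parameterization of amplification traces.

The amplification trajectory of a real-time PCR run is modelled with the
5-parameter Richards function, an asymmetric generalization of the logistic
growth curve::

    F(x) = Fb + Fmax * (1 + exp(-(x - c) / b)) ** (-d)

where ``x`` is the cycle number, ``Fb`` the background fluorescence, ``Fmax``
the plateau height above background, ``b`` a scale (cycles), ``c`` a location
(cycles) and ``d`` the asymmetry exponent (``d = 1`` recovers the symmetric
logistic). The curve's *shape fingerprint* — plateau ``Fmax``, inflection
height ``Yf`` and inflection-tangent slope ``m`` — is concentration
independent: the template amount only translates the curve along the cycle
axis. That is what makes the fingerprint usable for outlier detection.

Closed forms derived from the model (all heights above background):

    x_f  = c + b*ln(d)                      inflection abscissa
    Yf   = Fmax * (1 + 1/d)^(-d)            inflection height
    m    = (Fmax/b) * (1 + 1/d)^(-(d+1))    tangent slope at inflection
    Asym = (Fmax - 2*Yf)/Fmax = 1 - 2*(1 + 1/d)^(-d)

``d = 1`` gives ``2*Yf = Fmax`` and ``Asym = 0``; ``d > 1`` gives ``Asym > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .plate_io import AmplificationRun

__all__ = [
    "FitConfig",
    "NoAmplificationError",
    "NotConvergedError",
    "RichardsFit",
    "ShapeFingerprint",
    "fit_richards",
    "fits_to_frame",
    "richards_model",
    "shape_fingerprint",
]


class NoAmplificationError(ValueError):
    """The trace shows no amplification signal worth fitting."""


class NotConvergedError(ValueError):
    """Shape parameters requested from a non-converged fit."""


@dataclass(frozen=True)
class RichardsFit:
    """Least-squares estimates of the 5 Richards parameters for one run."""

    Fmax: float
    Fb: float
    b: float
    c: float
    d: float
    converged: bool
    rss: float
    n_points: int


@dataclass(frozen=True)
class ShapeFingerprint:
    """Concentration-independent shape summary of a fitted curve.

    ``(Fmax, Yf, m)`` is the test vector used by the shape-based outlier
    test; ``Asym`` is the normalized asymmetry and ``x_f`` the inflection
    abscissa, both reported descriptively.
    """

    Fmax: float
    Yf: float
    m: float
    Asym: float
    x_f: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.Fmax, self.Yf, self.m], dtype=float)


@dataclass(frozen=True)
class FitConfig:
    """Settings for :func:`fit_richards`.

    ``range_floor`` — minimum fluorescence range below which a trace is
    treated as flat (no amplification). ``reference_plateau`` — when given,
    traces never reaching ``min_plateau_fraction`` of it are likewise
    rejected as NoAmplification instead of being force-fitted.
    Parameter bounds define the plausible region; an optimum outside them
    marks the fit non-converged.
    """

    range_floor: float = 1e-6
    min_plateau_fraction: float = 0.10
    reference_plateau: float | None = None
    baseline_cycles: int = 5
    b_bounds: tuple[float, float] = (0.1, 20.0)
    d_bounds: tuple[float, float] = (0.05, 20.0)
    fmax_range_factor: float = 10.0
    max_nfev: int = 20000


_DEFAULT_CONFIG = FitConfig()


def richards_model(x, Fmax: float, Fb: float, b: float, c: float, d: float):
    """Evaluate the Richards function at cycle(s) ``x``.

    Total on valid parameters (``b > 0``, ``d > 0``); monotone non-decreasing
    in ``x``, tending to ``Fb`` as ``x -> -inf`` and ``Fb + Fmax`` as
    ``x -> +inf``. Computed as ``exp(-d*log1p(exp(z)))`` with the exponent
    clipped at +-700 to avoid overflow far from the transition.
    """
    x = np.asarray(x, dtype=float)
    z = np.clip(-(x - c) / b, -700.0, 700.0)
    log_term = np.logaddexp(0.0, z)  # log(1 + exp(z)), overflow-safe
    return Fb + Fmax * np.exp(np.clip(-d * log_term, -700.0, 700.0))


def initial_guess(cycles: np.ndarray, fluor: np.ndarray,
                  config: FitConfig = _DEFAULT_CONFIG) -> np.ndarray:
    """Heuristic start values placing the optimizer in the sigmoid basin."""
    k = min(config.baseline_cycles, fluor.size)
    fb0 = float(np.mean(fluor[:k]))
    fmax0 = float(np.max(fluor) - fb0)
    if fmax0 <= 0:
        fmax0 = float(np.ptp(fluor)) or 1.0
    above = np.nonzero(fluor - fb0 > fmax0 / 2)[0]
    c0 = float(cycles[above[0]]) if above.size else float(cycles[len(cycles) // 2])
    return np.array([fmax0, fb0, 2.0, c0, 1.0])


def fit_richards(run: AmplificationRun, config: FitConfig | None = None) -> RichardsFit:
    """Unweighted least-squares Richards fit of one amplification trace.

    Uses the Levenberg-Marquardt algorithm from the heuristic start of
    :func:`initial_guess`. Optimizer failure, non-finite estimates or
    estimates outside the plausibility bounds yield ``converged=False``
    (never an exception); genuinely flat or never-amplifying traces raise
    :class:`NoAmplificationError`.
    """
    config = config or _DEFAULT_CONFIG
    x = run.cycles.astype(float)
    y = run.fluorescence
    if y.size < 8:
        raise ValueError(f"run {run.run_id!r}: need >= 8 readings, got {y.size}")
    span = float(np.ptp(y))
    if span <= config.range_floor:
        raise NoAmplificationError(f"run {run.run_id!r}: flat trace (range {span:g})")
    if (
        config.reference_plateau is not None
        and span < config.min_plateau_fraction * config.reference_plateau
    ):
        raise NoAmplificationError(
            f"run {run.run_id!r}: range {span:g} below "
            f"{config.min_plateau_fraction:.0%} of reference plateau"
        )

    p0 = initial_guess(run.cycles, y, config)

    def residuals(p):
        return richards_model(x, *p) - y

    result = least_squares(residuals, p0, method="lm", max_nfev=config.max_nfev)
    fmax, fb, b, c, d = (float(v) for v in result.x)
    rss = float(np.sum(result.fun**2))

    in_bounds = (
        0.0 < fmax <= config.fmax_range_factor * span
        and config.b_bounds[0] <= b <= config.b_bounds[1]
        and config.d_bounds[0] <= d <= config.d_bounds[1]
        and 1.0 <= c <= 2.0 * float(x[-1])
    )
    converged = bool(
        result.success
        and in_bounds
        and np.all(np.isfinite(result.x))
        and np.isfinite(rss)
    )
    return RichardsFit(
        Fmax=fmax, Fb=fb, b=b, c=c, d=d,
        converged=converged, rss=rss, n_points=int(y.size),
    )


def shape_fingerprint(fit: RichardsFit) -> ShapeFingerprint:
    """Closed-form shape fingerprint (Fmax, Yf, m, Asym, x_f) of a fit.

    Heights are measured above background (``Fb`` excluded), which makes the
    symmetry identity exact: ``d = 1  <=>  Asym = 0``.
    """
    if not fit.converged:
        raise NotConvergedError(
            "fit did not converge; treat the run as unanalyzable (shape-aberrant)"
        )
    d = fit.d
    # (1 + 1/d)^(-d) computed via exp/log1p for stability at extreme d
    q = float(np.exp(-d * np.log1p(1.0 / d)))
    yf = fit.Fmax * q
    m = (fit.Fmax / fit.b) * float(np.exp(-(d + 1.0) * np.log1p(1.0 / d)))
    asym = (fit.Fmax - 2.0 * yf) / fit.Fmax
    x_f = fit.c + fit.b * float(np.log(d))
    return ShapeFingerprint(Fmax=fit.Fmax, Yf=yf, m=m, Asym=asym, x_f=x_f)


def fits_to_frame(
    run_ids: Sequence[str], fits: Iterable[RichardsFit | None]
) -> pd.DataFrame:
    """Tabulate fits (and derived shape parameters) for CSV export."""
    rows = []
    for rid, fit in zip(run_ids, fits):
        row = {"run_id": rid, "Fb": np.nan, "Fmax": np.nan, "b": np.nan,
               "c": np.nan, "d": np.nan, "Yf": np.nan, "m": np.nan,
               "Asym": np.nan, "rss": np.nan, "converged": False}
        if fit is not None:
            row.update(Fb=fit.Fb, Fmax=fit.Fmax, b=fit.b, c=fit.c, d=fit.d,
                       rss=fit.rss, converged=fit.converged)
            if fit.converged:
                fp = shape_fingerprint(fit)
                row.update(Yf=fp.Yf, m=fp.m, Asym=fp.Asym)
        rows.append(row)
    return pd.DataFrame(rows)
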