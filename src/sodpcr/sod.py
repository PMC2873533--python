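"""Shape-based kinetic outlier detection (SOD) and its diagnostics.

The shape fingerprints (Fmax, Yf, m) of the standard-curve runs define a
trivariate reference distribution with mean vector ``mu`` and sample
covariance ``Sigma``. For any run, the squared Mahalanobis distance

    d2 = (y - mu)' Sigma^{-1} (y - mu)

is asymptotically chi-square distributed with 3 degrees of freedom under
multivariate normality, so a run whose ``d2`` exceeds the chi-square(3)
critical value (7.81 at alpha = 0.05) has a curve shape significantly
different from the standards and is flagged as a kinetic outlier.

The module also carries the supporting diagnostics used to validate the
reference set: one-sample Kolmogorov-Smirnov normality checks per parameter,
the Pearson-correlation t-test of each parameter against log10 input DNA
(the concentration-independence check that justifies calling the triple a
"fingerprint"), and a chi-square Q-Q diagnostic of multivariate normality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .richards import ShapeFingerprint

__all__ = [
    "ReferenceModel",
    "SodResult",
    "build_reference",
    "correlation_t_test",
    "ks_normality",
    "mahalanobis_d2",
    "multivariate_normality_d2",
    "sod_test",
]

PARAMETER_ORDER = ("Fmax", "Yf", "m")


@dataclass(frozen=True)
class ReferenceModel:
    """Mean vector and covariance of the standard runs' shape fingerprints."""

    mu: np.ndarray
    sigma: np.ndarray
    n_ref: int
    parameter_order: tuple[str, str, str] = PARAMETER_ORDER


@dataclass(frozen=True)
class SodResult:
    run_id: str
    y: np.ndarray
    d2: float
    is_outlier: bool
    reason: str = "shape"  # "shape" for tested runs, "unfittable" for sentinels


def _as_matrix(fingerprints) -> np.ndarray:
    """Accept a (n, 3) array or a sequence of ShapeFingerprint."""
    if isinstance(fingerprints, np.ndarray):
        y = np.asarray(fingerprints, dtype=float)
    else:
        fingerprints = list(fingerprints)
        if fingerprints and isinstance(fingerprints[0], ShapeFingerprint):
            y = np.array([fp.as_vector() for fp in fingerprints])
        else:
            y = np.asarray(fingerprints, dtype=float)
    if y.ndim != 2 or y.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) fingerprint matrix, got {y.shape}")
    return y


def build_reference(fingerprints) -> ReferenceModel:
    """Estimate (mu, Sigma) from converged standard-run fingerprints.

    Requires at least 10 fingerprints (warns below 30, where the asymptotic
    chi-square calibration is rough). The sample covariance uses denominator
    n-1. A singular or near-singular covariance (condition number > 1e12,
    e.g. all-identical replicates) is rejected.
    """
    y = _as_matrix(fingerprints)
    n = y.shape[0]
    if n < 10:
        raise ValueError(f"need >= 10 reference fingerprints, got {n}")
    if n < 30:
        warnings.warn(
            f"only {n} reference runs: chi-square calibration of the "
            "Mahalanobis test is approximate below ~30 replicates"
        )
    mu = y.mean(axis=0)
    sigma = np.cov(y, rowvar=False, ddof=1)
    sigma = 0.5 * (sigma + sigma.T)
    if not np.all(np.isfinite(sigma)) or np.linalg.cond(sigma) > 1e12:
        raise ValueError(
            "singular or near-singular covariance; add replicates or jitter"
        )
    if np.any(np.linalg.eigvalsh(sigma) <= 0):
        raise ValueError("covariance is not positive definite")
    return ReferenceModel(mu=mu, sigma=sigma, n_ref=n)


def mahalanobis_d2(y, ref: ReferenceModel):
    """Squared Mahalanobis distance(s) of fingerprint vector(s) from mu.

    Solved through a Cholesky factorization of Sigma (no explicit inverse).
    Accepts a single 3-vector or an (n, 3) matrix.
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    y2 = np.atleast_2d(y)
    if not np.all(np.isfinite(y2)):
        raise ValueError("non-finite fingerprint")
    delta = y2 - ref.mu
    factor = cho_factor(ref.sigma, lower=True)
    solved = cho_solve(factor, delta.T)
    d2 = np.einsum("ij,ji->i", delta, solved)
    d2 = np.maximum(d2, 0.0)
    return float(d2[0]) if single else d2


def sod_test(
    fp: ShapeFingerprint | np.ndarray,
    ref: ReferenceModel,
    alpha: float = 0.05,
    run_id: str = "",
) -> SodResult:
    """Mahalanobis chi-square test of one fingerprint against the reference."""
    y = fp.as_vector() if isinstance(fp, ShapeFingerprint) else np.asarray(fp, float)
    d2 = mahalanobis_d2(y, ref)
    critical = float(stats.chi2.ppf(1.0 - alpha, df=3))
    return SodResult(run_id=run_id, y=y, d2=d2, is_outlier=bool(d2 > critical))


def ks_normality(values: Sequence[float]) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against Normal(mean, SD).

    Returns ``(Z, p)`` with ``Z = sqrt(n) * D_n`` and the asymptotic
    Kolmogorov p-value — the scaling convention of classic statistics
    packages, so reference-set tables read directly.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError(f"need n >= 8 for the K-S normality check, got {x.size}")
    sd = float(np.std(x, ddof=1))
    if sd <= 1e-12 * max(1.0, abs(float(np.mean(x)))):
        raise ValueError("zero variance: K-S normality test undefined")
    d = stats.kstest(x, "norm", args=(float(np.mean(x)), sd)).statistic
    z = float(np.sqrt(x.size) * d)
    p = float(stats.kstwobign.sf(z))
    return z, p


def correlation_t_test(
    values: Sequence[float], log10_inputs: Sequence[float]
) -> tuple[float, float, float, float]:
    """Significance of the correlation between a shape parameter and log input.

    Returns ``(r, r2, t, p)`` with ``t = r*sqrt(n-2)/sqrt(1-r^2)`` and the
    two-sided p-value from Student's t with n-2 df. A non-significant result
    is what licenses treating the parameter as concentration independent.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(log10_inputs, dtype=float)
    if x.shape != g.shape or x.ndim != 1:
        raise ValueError("values and log10_inputs must be 1-D and the same length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for the correlation t-test")
    if np.std(x) == 0.0 or np.std(g) == 0.0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.corrcoef(x, g)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 1.0, float(np.inf) * np.sign(r), 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, r * r, float(t), p


def multivariate_normality_d2(
    fingerprints, ref: ReferenceModel
) -> tuple[pd.DataFrame, float]:
    """Chi-square Q-Q diagnostic of the reference set's multivariate normality.

    Pairs the sorted squared distances of the reference runs with
    chi-square(3) quantiles at plotting positions ``(i - 0.5)/n`` and returns
    the table together with the Pearson correlation of the Q-Q pairs (values
    near 1 support multivariate normality). With the n-1 covariance the
    reference distances satisfy ``sum(d2) = 3*(n-1)`` identically.
    """
    y = _as_matrix(fingerprints)
    d2 = np.sort(mahalanobis_d2(y, ref))
    n = d2.size
    q = stats.chi2.ppf((np.arange(1, n + 1) - 0.5) / n, df=3)
    table = pd.DataFrame({"d2": d2, "chi2_quantile": q})
    qq_r = float(np.corrcoef(d2, q)[0, 1])
    return table, qq_r
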