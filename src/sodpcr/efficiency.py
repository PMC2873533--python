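"""Per-run PCR efficiency (window-of-linearity) and the KOD outlier test.

During the exponential phase the product doubles by a constant factor E per
cycle, so log10 fluorescence grows linearly with cycle number. The per-run
efficiency is estimated as ``10**slope`` of the best log-linear regression
over a short contiguous *window of linearity* — the convention popularized
by the LinRegPCR program: windows of 4-6 cycles whose readings lie between a
noise floor and the lower part of the plateau, chosen to maximize R².

KOD (kinetic outlier detection) standardizes a test run's efficiency against
the standard-curve runs: ``z = (x_eff - mu_eff) / sigma_eff``; ``z**2`` is
asymptotically chi-square with 1 df, so the run is an outlier when
``z**2 > 3.84`` (equivalently ``|z| > 1.96``) at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .plate_io import AmplificationRun
from .quantify import DEFAULT_THRESHOLD, BaselineError, NoCtError, ct_fit_point

__all__ = [
    "EfficiencyEstimate",
    "EfficiencyUndeterminedError",
    "KodResult",
    "WindowConfig",
    "kod_test",
    "window_of_linearity",
]


class EfficiencyUndeterminedError(ValueError):
    """No eligible window of linearity: efficiency cannot be estimated."""


@dataclass(frozen=True)
class WindowConfig:
    """Window-search settings (LinRegPCR-style conventions, configurable)."""

    min_width: int = 4
    max_width: int = 6
    noise_floor_fraction: float = 0.01  # of the run's plateau
    plateau_fraction: float = 0.80
    threshold: float = DEFAULT_THRESHOLD


@dataclass(frozen=True)
class EfficiencyEstimate:
    run_id: str
    efficiency: float
    window_start: int
    window_end: int
    window_r_squared: float


@dataclass(frozen=True)
class KodResult:
    run_id: str
    z: float
    chi2: float
    is_outlier: bool


_DEFAULT_WINDOW = WindowConfig()


def window_of_linearity(
    run: AmplificationRun, config: WindowConfig | None = None
) -> EfficiencyEstimate:
    """Estimate per-cycle amplification efficiency from the log-linear phase.

    Candidate windows are contiguous stretches of ``min_width``-``max_width``
    cycles whose readings are all positive, above the noise floor and below
    ``plateau_fraction`` of the plateau; the window maximizing the R² of
    log10(F) vs cycle wins (ties: wider, then earlier). When the trace
    crosses the quantification threshold, only windows overlapping that
    crossing are considered (with a fallback to the unconstrained best), so
    the efficiency describes the phase the Ct is read in.
    """
    config = config or _DEFAULT_WINDOW
    f = run.fluorescence
    plateau = float(np.max(f))
    if plateau <= 0:
        raise EfficiencyUndeterminedError(f"run {run.run_id!r}: no positive signal")
    lo = config.noise_floor_fraction * plateau
    hi = config.plateau_fraction * plateau
    eligible = (f > 0) & (f > lo) & (f < hi)

    candidates = []  # (r2, width, start_index, slope)
    n = f.size
    for width in range(config.min_width, config.max_width + 1):
        for start in range(0, n - width + 1):
            window = slice(start, start + width)
            if not eligible[window].all():
                continue
            xs = run.cycles[window].astype(float)
            ys = np.log10(f[window])
            reg = stats.linregress(xs, ys)
            candidates.append((float(reg.rvalue) ** 2, width, start, float(reg.slope)))
    if not candidates:
        raise EfficiencyUndeterminedError(
            f"run {run.run_id!r}: fewer than {config.min_width} eligible points "
            "for the window of linearity"
        )

    try:
        ct = ct_fit_point(run, config.threshold)
    except (NoCtError, BaselineError):
        ct = None
    if ct is not None:
        containing = [
            cand for cand in candidates
            if run.cycles[cand[2]] <= math.ceil(ct)
            and run.cycles[cand[2] + cand[1] - 1] >= math.floor(ct)
        ]
        if containing:
            candidates = containing

    # round R2 so float dust does not defeat the wider-then-earlier tie rule
    r2, width, start, slope = min(
        candidates, key=lambda cand: (-round(cand[0], 12), -cand[1], cand[2])
    )
    return EfficiencyEstimate(
        run_id=run.run_id,
        efficiency=float(10.0**slope),
        window_start=int(run.cycles[start]),
        window_end=int(run.cycles[start + width - 1]),
        window_r_squared=r2,
    )


def kod_test(
    x_eff: float,
    ref_effs: Sequence[float],
    alpha: float = 0.05,
    run_id: str = "",
) -> KodResult:
    """Efficiency z-test of one run against the standard-run efficiencies.

    ``z = (x_eff - mu)/sigma`` with mean and SD (denominator n-1) from the
    reference efficiencies; ``z**2`` is compared with the chi-square(1 df)
    critical value at ``1 - alpha`` (3.84 for alpha = 0.05).
    """
    ref = np.asarray(ref_effs, dtype=float)
    if ref.size < 3:
        raise ValueError(f"need >= 3 reference efficiencies, got {ref.size}")
    sigma = float(np.std(ref, ddof=1))
    if sigma <= 1e-12 * max(1.0, abs(float(np.mean(ref)))):
        raise ValueError("zero reference-efficiency SD: degenerate reference")
    z = (float(x_eff) - float(np.mean(ref))) / sigma
    chi2 = z * z
    critical = float(stats.chi2.ppf(1.0 - alpha, df=1))
    return KodResult(run_id=run_id, z=z, chi2=chi2, is_outlier=bool(chi2 > critical))
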