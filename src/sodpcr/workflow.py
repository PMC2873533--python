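"""End-to-end analysis pipeline: fit -> quantify -> KOD -> SOD -> evaluate.

Glues the individual modules together the way the command-line ``analyze``
subcommand (and the acceptance machinery) uses them. Policy decisions made
here rather than in the statistical modules:

* standard runs whose Richards fit does not converge are excluded from the
  reference model (counted and logged); test runs that cannot be fitted are
  reported as SOD outliers with a ``d2 = inf`` sentinel and reason
  ``"unfittable"`` — a curve the model cannot describe is by definition
  shape-aberrant;
* runs whose efficiency is undetermined (no window of linearity) are
  counted as KOD positives for the same reason;
* runs with a known input amount but no threshold crossing are labelled
  true outliers (their quantification failed outright).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluate as _evaluate
from .efficiency import (
    EfficiencyUndeterminedError,
    WindowConfig,
    kod_test,
    window_of_linearity,
)
from .plate_io import ROLE_STANDARD, AmplificationRun
from .quantify import (
    BaselineError,
    NoCtError,
    build_standard_curve,
    ct_fit_point,
    estimate_copies,
    residual_ci,
    truth_label,
)
from .richards import (
    FitConfig,
    NoAmplificationError,
    fit_richards,
    fits_to_frame,
    shape_fingerprint,
)
from .sod import build_reference, sod_test

logger = logging.getLogger(__name__)

__all__ = ["AnalysisResult", "analyze"]


@dataclass
class AnalysisResult:
    """The pipeline's output tables plus the fitted calibration objects."""

    fits: pd.DataFrame
    quantification: pd.DataFrame
    kod: pd.DataFrame
    sod: pd.DataFrame
    evaluation: pd.DataFrame
    curve: object
    ci: object
    reference: object


def analyze(
    runs: Sequence[AmplificationRun],
    threshold: float = 0.4,
    sod_alpha: float = 0.05,
    kod_alpha: float = 0.05,
    fit_config: FitConfig | None = None,
    window_config: WindowConfig | None = None,
) -> AnalysisResult:
    """Run the full outlier-detection pipeline on a plate."""
    runs = list(runs)
    ids = [r.run_id for r in runs]
    std_ids = {r.run_id for r in runs if r.role == ROLE_STANDARD}
    if not std_ids:
        raise ValueError("no standard runs: reference model and standard curve "
                         "cannot be built")

    # --- Richards fits and fingerprints -----------------------------------
    fits, fps = {}, {}
    n_noamp = n_nonconv = 0
    for run in runs:
        try:
            fit = fit_richards(run, fit_config)
        except NoAmplificationError:
            fits[run.run_id] = None
            n_noamp += 1
            continue
        fits[run.run_id] = fit
        if fit.converged:
            fps[run.run_id] = shape_fingerprint(fit)
        else:
            n_nonconv += 1
    if n_noamp or n_nonconv:
        logger.info("fitting: %d run(s) without amplification, %d non-converged",
                    n_noamp, n_nonconv)
    fits_df = fits_to_frame(ids, [fits[i] for i in ids])

    # --- reference model from converged standards -------------------------
    ref_fp_ids = [i for i in ids if i in std_ids and i in fps]
    n_excluded = len(std_ids) - len(ref_fp_ids)
    if n_excluded:
        logger.info("reference: excluded %d unfittable standard run(s)", n_excluded)
    reference = build_reference([fps[i] for i in ref_fp_ids])

    # --- quantification ----------------------------------------------------
    cts = {}
    for run in runs:
        try:
            cts[run.run_id] = ct_fit_point(run, threshold)
        except (NoCtError, BaselineError) as err:
            cts[run.run_id] = None
            logger.info("Ct: %s", err)
    std_pairs = [
        (cts[r.run_id], r.log10_input)
        for r in runs
        if r.role == ROLE_STANDARD and cts[r.run_id] is not None
    ]
    curve = build_standard_curve([p[0] for p in std_pairs],
                                 [p[1] for p in std_pairs], threshold)

    quant_rows = []
    for run in runs:
        ct = cts[run.run_id]
        log10_nob = (
            float(np.log10(estimate_copies(ct, curve))) if ct is not None else np.nan
        )
        nexp = run.log10_input if run.log10_input is not None else np.nan
        resid = log10_nob - nexp
        quant_rows.append(
            {"run_id": run.run_id, "ct": np.nan if ct is None else ct,
             "log10_nob": log10_nob, "log10_nexp": nexp, "resid": resid}
        )
    quant = pd.DataFrame(quant_rows)

    std_mask = quant["run_id"].isin(std_ids) & quant["resid"].notna()
    ci = residual_ci(
        quant.loc[std_mask, "log10_nob"], quant.loc[std_mask, "log10_nexp"]
    )
    labels = []
    for row, run in zip(quant_rows, runs):
        if run.log10_input is None:
            labels.append(None)  # no ground truth possible
        elif not np.isfinite(row["resid"]):
            labels.append(True)  # quantification failed outright
        else:
            labels.append(truth_label(row["resid"], ci))
    quant["is_true_outlier"] = pd.array(labels, dtype="boolean")

    # --- KOD ----------------------------------------------------------------
    wconf = window_config or WindowConfig(threshold=threshold)
    effs = {}
    for run in runs:
        try:
            effs[run.run_id] = window_of_linearity(run, wconf)
        except EfficiencyUndeterminedError as err:
            effs[run.run_id] = None
            logger.info("efficiency: %s", err)
    ref_effs = [effs[i].efficiency for i in ids if i in std_ids and effs[i] is not None]
    kod_rows = []
    for run in runs:
        est = effs[run.run_id]
        if est is None:
            kod_rows.append(
                {"run_id": run.run_id, "efficiency": np.nan, "window_start": np.nan,
                 "window_end": np.nan, "window_r2": np.nan, "z": np.nan,
                 "chi2": np.nan, "is_outlier": True, "reason": "undetermined"}
            )
            continue
        res = kod_test(est.efficiency, ref_effs, kod_alpha, run_id=run.run_id)
        kod_rows.append(
            {"run_id": run.run_id, "efficiency": est.efficiency,
             "window_start": est.window_start, "window_end": est.window_end,
             "window_r2": est.window_r_squared, "z": res.z, "chi2": res.chi2,
             "is_outlier": res.is_outlier, "reason": "efficiency"}
        )
    kod = pd.DataFrame(kod_rows)

    # --- SOD ----------------------------------------------------------------
    sod_rows = []
    for run in runs:
        fp = fps.get(run.run_id)
        if fp is None:
            sod_rows.append(
                {"run_id": run.run_id, "Fmax": np.nan, "Yf": np.nan, "m": np.nan,
                 "d2": np.inf, "is_outlier": True, "reason": "unfittable"}
            )
            continue
        res = sod_test(fp, reference, sod_alpha, run_id=run.run_id)
        sod_rows.append(
            {"run_id": run.run_id, "Fmax": fp.Fmax, "Yf": fp.Yf, "m": fp.m,
             "d2": res.d2, "is_outlier": res.is_outlier, "reason": "shape"}
        )
    sod = pd.DataFrame(sod_rows)

    # --- evaluation ---------------------------------------------------------
    inhibitors = pd.DataFrame(
        [{"run_id": r.run_id, "inhibitor": r.inhibitor} for r in runs]
    )
    labelled = quant[quant["is_true_outlier"].notna()][["run_id", "is_true_outlier"]]
    reports = []
    for method, calls in (("SOD", sod), ("KOD", kod)):
        merged = labelled.merge(
            calls[["run_id", "is_outlier"]], on="run_id"
        ).merge(inhibitors, on="run_id")
        reports.extend(_evaluate.evaluate_calls(merged, method))
    evaluation = _evaluate.reports_to_frame(reports)

    for method in ("SOD", "KOD"):
        flagged = int((sod if method == "SOD" else kod)["is_outlier"].sum())
        logger.info("%s flagged %d of %d runs", method, flagged, len(runs))

    return AnalysisResult(
        fits=fits_df, quantification=quant, kod=kod, sod=sod,
        evaluation=evaluation, curve=curve, ci=ci, reference=reference,
    )
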