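"""Confusion-matrix evaluation of outlier calls against quantification truth.

A call is *true positive* when the detector flags a run whose quantification
residual log10(Nob/Nexp) lies outside the 95% CI; *false positive* when it
flags a run inside the CI; and so on. Sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP); either is reported as missing (None), not zero,
when its denominator is empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["EvaluationReport", "confusion", "evaluate_calls"]


@dataclass(frozen=True)
class EvaluationReport:
    method: str
    stratum: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    calls: Sequence[bool],
    truths: Sequence[bool],
    method: str = "SOD",
    stratum: str = "all",
    run_ids: Sequence[str] | None = None,
) -> EvaluationReport:
    """Count TP/FP/TN/FN and derive sensitivity and specificity.

    ``calls`` are the detector's outlier flags, ``truths`` the ground-truth
    labels; both must be complete — missing entries are rejected with the
    offending run ids.
    """
    c = pd.array(calls, dtype="boolean")
    t = pd.array(truths, dtype="boolean")
    if len(c) != len(t):
        raise ValueError("calls and truths must be the same length")
    missing = c.isna() | t.isna()
    if missing.any():
        idx = np.nonzero(np.asarray(missing))[0]
        names = (
            [run_ids[i] for i in idx] if run_ids is not None else [str(i) for i in idx]
        )
        raise ValueError(f"missing call or truth label for run(s): {names}")
    c = np.asarray(c, dtype=bool)
    t = np.asarray(t, dtype=bool)
    tp = int(np.sum(c & t))
    fp = int(np.sum(c & ~t))
    tn = int(np.sum(~c & ~t))
    fn = int(np.sum(~c & t))
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return EvaluationReport(method=method, stratum=stratum, tp=tp, fp=fp,
                            tn=tn, fn=fn, sensitivity=sens, specificity=spec)


def evaluate_calls(df: pd.DataFrame, method: str) -> list[EvaluationReport]:
    """Stratified evaluation of a calls table.

    ``df`` needs columns ``run_id``, ``is_outlier``, ``is_true_outlier`` and
    optionally ``inhibitor``; one report per distinct inhibitor plus the
    ``"all"`` aggregate (always emitted, even with no strata).
    """
    reports = [
        confusion(df["is_outlier"], df["is_true_outlier"], method=method,
                  stratum="all", run_ids=list(df["run_id"]))
    ]
    if "inhibitor" in df.columns:
        for name, grp in df.dropna(subset=["inhibitor"]).groupby("inhibitor"):
            reports.append(
                confusion(grp["is_outlier"], grp["is_true_outlier"], method=method,
                          stratum=str(name), run_ids=list(grp["run_id"]))
            )
    return reports


def reports_to_frame(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Tabulate reports as ``stratum,method,tp,fp,tn,fn,sensitivity,specificity``."""
    return pd.DataFrame(
        [
            {
                "stratum": r.stratum,
                "method": r.method,
                "tp": r.tp,
                "fp": r.fp,
                "tn": r.tn,
                "fn": r.fn,
                "sensitivity": np.nan if r.sensitivity is None else r.sensitivity,
                "specificity": np.nan if r.specificity is None else r.specificity,
            }
            for r in reports
        ]
    )
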