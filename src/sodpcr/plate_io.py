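"""Reading, writing and assembling real-time PCR amplification runs.

A plate is represented as a collection of :class:`AmplificationRun` objects,
one per well, each carrying a cycle-indexed fluorescence trace plus metadata:
the run's role (``standard`` runs build the reference model and the standard
curve; ``test`` runs are the samples under scrutiny), the known log10 input
copy number where applicable, and optional inhibitor annotations.

Two plain-CSV layouts are supported:

* ``long`` — columns ``run_id,cycle,fluorescence``, one row per reading;
* ``wide`` — a ``cycle`` column plus one fluorescence column per run.

Metadata travel in a separate CSV with columns
``run_id,role,log10_input,inhibitor,inhibitor_conc`` (empty cells = missing).
Fluorescence values are assumed background-subtracted; for raw exports a
baseline can be removed by subtracting the mean of the first few cycles
(``baseline_cycles``) — the Richards background term absorbs any residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLE_STANDARD = "standard"
ROLE_TEST = "test"

_META_COLUMNS = ["run_id", "role", "log10_input", "inhibitor", "inhibitor_conc"]


@dataclass
class AmplificationRun:
    """One well's amplification trace plus plate metadata.

    Parameters
    ----------
    run_id:
        Unique well/run identifier.
    cycles:
        Strictly increasing, consecutive integer cycle indices (1..C).
    fluorescence:
        Background-subtracted fluorescence readings, one per cycle,
        in arbitrary fluorescence units; must be finite.
    role:
        ``"standard"`` (dilution-series calibrator, known input) or
        ``"test"`` (unknown or spiked sample).
    log10_input:
        log10 of the expected template copy number (Nexp); required for
        standards, optional for spiked test runs.
    inhibitor, inhibitor_conc:
        Optional inhibitor annotation (name, mg/mL).
    """

    run_id: str
    cycles: np.ndarray
    fluorescence: np.ndarray
    role: str = ROLE_TEST
    log10_input: float | None = None
    inhibitor: str | None = None
    inhibitor_conc: float | None = None

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.cycles.ndim != 1 or self.fluorescence.ndim != 1:
            raise ValueError(f"run {self.run_id!r}: cycles and fluorescence must be 1-D")
        if self.cycles.shape != self.fluorescence.shape:
            raise ValueError(
                f"run {self.run_id!r}: {len(self.cycles)} cycles but "
                f"{len(self.fluorescence)} fluorescence readings"
            )
        if self.cycles.size == 0:
            raise ValueError(f"run {self.run_id!r}: empty trace")
        steps = np.diff(self.cycles)
        if np.any(steps != 1):
            bad = int(self.cycles[np.argmax(steps != 1)])
            raise ValueError(
                f"run {self.run_id!r}: cycles must be consecutive integers; "
                f"gap or repeat after cycle {bad}"
            )
        if not np.all(np.isfinite(self.fluorescence)):
            bad = int(self.cycles[~np.isfinite(self.fluorescence)][0])
            raise ValueError(f"run {self.run_id!r}: non-finite fluorescence at cycle {bad}")
        if self.role not in (ROLE_STANDARD, ROLE_TEST):
            raise ValueError(f"run {self.run_id!r}: unknown role {self.role!r}")
        if self.role == ROLE_STANDARD and self.log10_input is None:
            raise ValueError(f"standard run {self.run_id!r} lacks log10_input")

    @property
    def n_cycles(self) -> int:
        return int(self.cycles.size)


def _apply_baseline(f: np.ndarray, baseline_cycles: int) -> np.ndarray:
    if baseline_cycles <= 0:
        return f
    k = min(baseline_cycles, f.size)
    return f - float(np.mean(f[:k]))


def read_fluorescence(
    path: str | Path,
    layout: str = "long",
    baseline_cycles: int = 0,
) -> list[AmplificationRun]:
    """Read amplification traces from a CSV file.

    ``layout="long"`` expects columns ``run_id,cycle,fluorescence``;
    ``layout="wide"`` expects a ``cycle`` column plus one column per run.
    Set ``baseline_cycles=k`` to subtract the mean of the first *k* readings
    from each trace (for raw, non-background-subtracted exports).

    Returns one :class:`AmplificationRun` per distinct run, cycles sorted
    ascending; metadata fields are left missing until :func:`join_metadata`.
    """
    df = pd.read_csv(path)
    if layout == "long":
        required = {"run_id", "cycle", "fluorescence"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: long layout missing columns {sorted(missing)}")
        dup = df.duplicated(subset=["run_id", "cycle"])
        if dup.any():
            r = df.loc[dup.idxmax()]
            raise ValueError(
                f"{path}: duplicate reading for run {r['run_id']!r} cycle {r['cycle']!r}"
            )
        long = df[["run_id", "cycle", "fluorescence"]].copy()
    elif layout == "wide":
        if "cycle" not in df.columns:
            raise ValueError(f"{path}: wide layout requires a 'cycle' column")
        if df["cycle"].duplicated().any():
            c = df.loc[df["cycle"].duplicated().idxmax(), "cycle"]
            raise ValueError(f"{path}: duplicate cycle {c!r}")
        run_cols = [c for c in df.columns if c != "cycle"]
        if not run_cols:
            raise ValueError(f"{path}: wide layout has no run columns")
        long = df.melt(id_vars="cycle", value_vars=run_cols,
                       var_name="run_id", value_name="fluorescence")
    else:
        raise ValueError(f"unknown layout {layout!r} (expected 'long' or 'wide')")

    for col in ("cycle", "fluorescence"):
        numeric = pd.to_numeric(long[col], errors="coerce")
        bad = numeric.isna() & long[col].notna()
        if bad.any():
            i = bad.idxmax()
            raise ValueError(
                f"{path}: non-numeric {col} {long.loc[i, col]!r} "
                f"(run {long.loc[i, 'run_id']!r})"
            )
        long[col] = numeric
    if long["fluorescence"].isna().any():
        i = long["fluorescence"].isna().idxmax()
        raise ValueError(
            f"{path}: missing fluorescence for run {long.loc[i, 'run_id']!r} "
            f"cycle {long.loc[i, 'cycle']!r}"
        )

    runs: list[AmplificationRun] = []
    for run_id, grp in long.groupby("run_id", sort=False):
        grp = grp.sort_values("cycle")
        runs.append(
            AmplificationRun(
                run_id=str(run_id),
                cycles=grp["cycle"].to_numpy(),
                fluorescence=_apply_baseline(grp["fluorescence"].to_numpy(float),
                                             baseline_cycles),
            )
        )
    return runs


def write_fluorescence(
    runs: Iterable[AmplificationRun], path: str | Path, layout: str = "long"
) -> None:
    """Write traces back to CSV in the given layout (inverse of reading)."""
    runs = list(runs)
    if layout == "long":
        frames = [
            pd.DataFrame(
                {"run_id": r.run_id, "cycle": r.cycles, "fluorescence": r.fluorescence}
            )
            for r in runs
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    elif layout == "wide":
        cycles = runs[0].cycles
        for r in runs[1:]:
            if not np.array_equal(r.cycles, cycles):
                raise ValueError("wide layout requires identical cycle vectors")
        wide = pd.DataFrame({"cycle": cycles})
        for r in runs:
            wide[r.run_id] = r.fluorescence
        wide.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def _clean(value):
    """NaN/empty -> None for optional metadata cells."""
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return value


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a plate-metadata CSV (``run_id,role,...``)."""
    meta = pd.read_csv(path)
    if "run_id" not in meta.columns or "role" not in meta.columns:
        raise ValueError(f"{path}: metadata requires run_id and role columns")
    return meta


def join_metadata(
    runs: Sequence[AmplificationRun], meta: pd.DataFrame
) -> list[AmplificationRun]:
    """Annotate runs with roles and input copy numbers from a metadata table.

    Runs absent from ``meta`` default to ``role=test`` with missing
    annotations (logged). Metadata rows whose run_id matches no trace produce
    a warning. A ``standard`` row without ``log10_input`` is rejected.
    """
    if len(meta) and "run_id" not in meta.columns:
        raise ValueError("metadata requires a run_id column")
    by_id = {str(row["run_id"]): row for _, row in meta.iterrows()} if len(meta) else {}
    known = {r.run_id for r in runs}
    for rid in by_id:
        if rid not in known:
            logger.warning("metadata run_id %r matches no fluorescence trace", rid)

    out: list[AmplificationRun] = []
    n_defaulted = 0
    for run in runs:
        row = by_id.get(run.run_id)
        if row is None:
            n_defaulted += 1
            out.append(replace(run, role=ROLE_TEST, log10_input=None,
                               inhibitor=None, inhibitor_conc=None))
            continue
        role = _clean(row.get("role"))
        role = str(role).strip().lower() if role is not None else ROLE_TEST
        log10_input = _clean(row.get("log10_input"))
        if role == ROLE_STANDARD and log10_input is None:
            raise ValueError(f"standard run {run.run_id!r} lacks log10_input in metadata")
        inhibitor = _clean(row.get("inhibitor"))
        conc = _clean(row.get("inhibitor_conc"))
        out.append(
            replace(
                run,
                role=role,
                log10_input=None if log10_input is None else float(log10_input),
                inhibitor=None if inhibitor is None else str(inhibitor),
                inhibitor_conc=None if conc is None else float(conc),
            )
        )
    if n_defaulted:
        logger.info("%d run(s) absent from metadata defaulted to role=test", n_defaulted)
    return out


def runs_to_metadata(runs: Iterable[AmplificationRun]) -> pd.DataFrame:
    """Export the metadata of a run collection as a table."""
    return pd.DataFrame(
        [
            {
                "run_id": r.run_id,
                "role": r.role,
                "log10_input": r.log10_input,
                "inhibitor": r.inhibitor,
                "inhibitor_conc": r.inhibitor_conc,
            }
            for r in runs
        ],
        columns=_META_COLUMNS,
    )
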