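"""Synthetic amplification plates with known ground truth.

The generator emulates the experimental design the method was developed on:
a standard curve spanning 3.14e7 down to 3.14e2 template copies (6 ten-fold
dilutions, 12 replicates each, 40 cycles), plus optional inhibited test runs.

Each run's curve is a Richards sigmoid with per-run shape parameters
``(Fmax, b, d)`` drawn independently from lognormal distributions (means
anchored at the reference assay's plateau ~46 and typical scale/asymmetry,
coefficients of variation of the order observed across replicate standards),
zero background, plus i.i.d. Gaussian reading noise. Template amount enters
only through the location: ``c = c_top + (log10_top - log10_N)/log10(E)``,
so shape is concentration independent by construction.

Inhibition of strength ``s`` in [0, 1] suppresses the plateau
(``Fmax *= 1 - 0.6 s``), flattens the rise (``b *= 1 + s``) and — for the
``plateau_slope_asym`` kind — skews the curve (``d *= 1 + 2 s``). The
``plateau_slope_only`` kind leaves ``d`` untouched, mimicking inhibitors
that distort kinetics without breaking curve symmetry. The coefficients are
qualitative dose-response knobs, exposed in the config, not chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .plate_io import ROLE_STANDARD, ROLE_TEST, AmplificationRun
from .richards import richards_model

__all__ = [
    "InhibitionConfig",
    "SimulationConfig",
    "simulate_inhibition_study",
    "simulate_plate",
]

INHIBITION_KINDS = ("plateau_slope_asym", "plateau_slope_only")


@dataclass(frozen=True)
class InhibitionConfig:
    """Graded inhibition applied to every run of a plate."""

    kind: str = "plateau_slope_asym"
    strength: float = 0.0

    def __post_init__(self):
        if self.kind not in INHIBITION_KINDS:
            raise ValueError(f"unknown inhibition kind {self.kind!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("inhibition strength must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one simulated plate.

    Defaults reproduce the standard-curve design: 6 concentrations x 12
    replicates from 3.14e7 copies in decade steps, efficiency 1.9, 40
    cycles. ``log10_inputs`` overrides the dilution ladder (e.g. a single
    spiked concentration for inhibited test runs) while keeping the
    ``(c_top, log10_input_top)`` position anchor shared across plates.
    """

    seed: int = 0
    n_concentrations: int = 6
    replicates: int = 12
    log10_input_top: float = math.log10(3.14e7)
    dilution_step_log10: float = 1.0
    efficiency: float = 1.9
    shape_means: tuple[float, float, float] = (46.41, 2.0, 1.2)  # Fmax, b, d
    shape_cvs: tuple[float, float, float] = (0.13, 0.10, 0.08)
    noise_sd: float = 0.05
    cycles: int = 40
    c_top: float = 14.0
    role: str = ROLE_STANDARD
    inhibitor: str | None = None
    inhibition: InhibitionConfig | None = None
    log10_inputs: tuple[float, ...] | None = None
    run_prefix: str = "S"

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must lie in (1, 2]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def concentrations(self) -> np.ndarray:
        if self.log10_inputs is not None:
            return np.asarray(self.log10_inputs, dtype=float)
        return self.log10_input_top - self.dilution_step_log10 * np.arange(
            self.n_concentrations, dtype=float
        )


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int):
    """Lognormal draws with the requested arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean)
    s2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * s2
    return rng.lognormal(mu, math.sqrt(s2), size)


def simulate_plate(
    config: SimulationConfig,
) -> tuple[list[AmplificationRun], pd.DataFrame]:
    """Simulate one plate; returns the runs and a ground-truth table.

    Fully reproducible: identical config (including seed) gives bit-identical
    traces and truth. The truth table records per run the generating shape
    parameters, the expected copy number, the exponential-phase efficiency
    implied by the generated shape (``exp(d/b)``) and the inhibition dose.
    """
    rng = np.random.default_rng(config.seed)
    concs = config.concentrations
    n_runs = concs.size * config.replicates

    means, cvs = config.shape_means, config.shape_cvs
    fmax = _lognormal(rng, means[0], cvs[0], n_runs)
    b = _lognormal(rng, means[1], cvs[1], n_runs)
    d = _lognormal(rng, means[2], cvs[2], n_runs)

    s = config.inhibition.strength if config.inhibition is not None else 0.0
    kind = config.inhibition.kind if config.inhibition is not None else "plateau_slope_asym"
    fmax = fmax * (1.0 - 0.6 * s)
    b = b * (1.0 + 1.0 * s)
    if kind == "plateau_slope_asym":
        d = d * (1.0 + 2.0 * s)

    cycles = np.arange(1, config.cycles + 1)
    noise = rng.normal(0.0, config.noise_sd, size=(n_runs, config.cycles))

    log_e = math.log10(config.efficiency)
    runs: list[AmplificationRun] = []
    truth_rows = []
    i = 0
    for j, log10_n in enumerate(concs):
        c = config.c_top + (config.log10_input_top - log10_n) / log_e
        for k in range(config.replicates):
            run_id = f"{config.run_prefix}{j:02d}_{k:02d}"
            trace = richards_model(cycles, fmax[i], 0.0, b[i], c, d[i]) + noise[i]
            runs.append(
                AmplificationRun(
                    run_id=run_id,
                    cycles=cycles,
                    fluorescence=trace,
                    role=config.role,
                    log10_input=float(log10_n),
                    inhibitor=config.inhibitor,
                    inhibitor_conc=s if config.inhibitor is not None else None,
                )
            )
            truth_rows.append(
                {
                    "run_id": run_id,
                    "role": config.role,
                    "log10_input": float(log10_n),
                    "copies": 10.0 ** float(log10_n),
                    "fmax_true": fmax[i],
                    "b_true": b[i],
                    "c_true": c,
                    "d_true": d[i],
                    "eff_exponential_true": math.exp(d[i] / b[i]),
                    "inhibitor": config.inhibitor,
                    "inhibition_strength": s,
                }
            )
            i += 1
    return runs, pd.DataFrame(truth_rows)


def simulate_inhibition_study(
    seed: int,
    strengths: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    replicates_per_strength: int = 6,
    kind: str = "plateau_slope_asym",
    inhibitor: str = "tannic_acid",
    test_log10_input: float = math.log10(3.5e4),
    base_config: SimulationConfig | None = None,
) -> tuple[list[AmplificationRun], pd.DataFrame]:
    """A full experiment: one standard plate plus graded inhibited test runs.

    Mirrors the inhibitor protocol: test reactions all start from the same
    template amount (default 3.5e4 copies) with increasing inhibitor dose,
    scored against the standard curve generated alongside. Returns combined
    runs and truth.
    """
    base = base_config or SimulationConfig()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=len(strengths) + 1)

    std_cfg = replace(base, seed=int(child_seeds[0]), role=ROLE_STANDARD,
                      inhibitor=None, inhibition=None, run_prefix="STD")
    runs, truth = simulate_plate(std_cfg)
    truths = [truth]
    for idx, s in enumerate(strengths):
        cfg = replace(
            base,
            seed=int(child_seeds[idx + 1]),
            role=ROLE_TEST,
            inhibitor=inhibitor,
            inhibition=InhibitionConfig(kind=kind, strength=float(s)),
            log10_inputs=(test_log10_input,),
            replicates=replicates_per_strength,
            run_prefix=f"T{idx}_",
        )
        r, t = simulate_plate(cfg)
        runs.extend(r)
        truths.append(t)
    return runs, pd.concat(truths, ignore_index=True)
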