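"""Synaptic-weight perturbation protocol.

Each of the six pathways is scaled by {0, 1/8, 1/4, 1/2, 1, 2, 4, 8} of its
control weight (0 is a lesion, 1 the control), giving 48 single-pathway
conditions; every condition is simulated with n replicate runs that differ
only in their noise seed (seed = base_seed + replicate index, identical
across conditions so that conditions differ in weights, not in noise).  Joint
sweeps manipulate the two output pathways of one population over a scale
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParameters, PathwayWeights, PATHWAYS
from .scoring import MetricsRecord, STATES, build_hypnogram, compute_metrics
from .simulate import IntegrationError, run_simulation

__all__ = [
    "SCALES",
    "POPULATION_OUTPUTS",
    "SweepCondition",
    "build_sweep_table",
    "apply_condition",
    "run_condition",
    "run_sweep",
    "run_joint_sweep",
    "sweep_results_frame",
]

#: The perturbation scale grid; 0 denotes a lesion, 1 the control condition.
SCALES = (0.0, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

#: The two output pathways of each population (for joint sweeps).
POPULATION_OUTPUTS = {
    "W": ("WNi", "WRi"),
    "N": ("NRi", "NWi"),
    "R": ("RRe", "RWe"),
}

DEFAULT_REPLICATES = 8


@dataclass(frozen=True)
class SweepCondition:
    """One point of a sweep: one or two pathways at fixed scale factors."""

    pathways: tuple[str, ...]
    scales: tuple[float, ...]
    weights: tuple[float, ...]  # resolved = control * scale, exactly
    replicates: int = DEFAULT_REPLICATES
    base_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pathways) != len(self.scales) or len(self.pathways) != len(self.weights):
            raise ValueError("pathways, scales and weights must align")
        for p in self.pathways:
            if p not in PATHWAYS:
                raise KeyError(f"unknown pathway {p!r}; expected one of {PATHWAYS}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def label(self) -> str:
        return "+".join(f"{p}x{s:g}" for p, s in zip(self.pathways, self.scales))

    @property
    def is_control(self) -> bool:
        return all(s == 1.0 for s in self.scales)

    @property
    def is_lesion(self) -> bool:
        return any(s == 0.0 for s in self.scales)


def make_condition(
    control: PathwayWeights,
    pathways: tuple[str, ...] | str,
    scales: tuple[float, ...] | float,
    replicates: int = DEFAULT_REPLICATES,
    base_seed: int = 0,
) -> SweepCondition:
    if isinstance(pathways, str):
        pathways = (pathways,)
    if isinstance(scales, (int, float)):
        scales = (float(scales),)
    weights = tuple(control[p] * s for p, s in zip(pathways, scales))
    return SweepCondition(tuple(pathways), tuple(float(s) for s in scales), weights,
                          replicates, base_seed)


def build_sweep_table(
    control: PathwayWeights,
    replicates: int = DEFAULT_REPLICATES,
    base_seed: int = 0,
    scales: tuple[float, ...] = SCALES,
) -> list[SweepCondition]:
    """All single-pathway conditions: 6 pathways x the scale grid (48 by
    default, including the 6 lesions and the shared control)."""
    return [
        make_condition(control, p, s, replicates, base_seed)
        for p in PATHWAYS
        for s in scales
    ]


def sweep_table_frame(conditions: list[SweepCondition]) -> pd.DataFrame:
    """Sweep manifest: one row per (condition, pathway) with resolved weight."""
    rows = []
    for cond in conditions:
        for p, s, w in zip(cond.pathways, cond.scales, cond.weights):
            rows.append(
                {
                    "condition": cond.label,
                    "pathway": p,
                    "scale": s,
                    "weight": w,
                    "replicates": cond.replicates,
                    "base_seed": cond.base_seed,
                }
            )
    return pd.DataFrame(rows)


def apply_condition(params: ModelParameters, cond: SweepCondition) -> ModelParameters:
    """Parameters with the condition's pathway weights substituted."""
    weights = params.weights
    for p, s in zip(cond.pathways, cond.scales):
        weights = weights.scaled(p, s)
    return params.replace(weights=weights)


@dataclass
class ReplicateResult:
    replicate: int
    seed: int
    metrics: MetricsRecord | None
    error: str | None = None


def run_condition(
    cond: SweepCondition,
    params: ModelParameters,
    store_stride: int = 100,
    noise_free: bool = False,
) -> list[ReplicateResult]:
    """Simulate and score every replicate of one condition.

    Replicate seeds are base_seed + replicate index.  A failed integration is
    recorded per replicate (with its message) without aborting the rest of
    the sweep.
    """
    cond_params = apply_condition(params, cond)
    results: list[ReplicateResult] = []
    for i in range(cond.replicates):
        seed = cond.base_seed + i
        try:
            ts = run_simulation(cond_params, seed=None if noise_free else seed,
                                store_stride=store_stride)
            metrics = compute_metrics(build_hypnogram(ts))
            metrics.metadata.update(
                {
                    "condition": cond.label,
                    "pathway": "+".join(cond.pathways),
                    "scale": cond.scales[0] if len(cond.scales) == 1 else str(cond.scales),
                    "replicate": i,
                    "seed": seed,
                }
            )
            results.append(ReplicateResult(i, seed, metrics))
        except IntegrationError as exc:  # keep the sweep alive
            results.append(ReplicateResult(i, seed, None, error=str(exc)))
    return results


def run_sweep(
    params: ModelParameters,
    pathways: tuple[str, ...] = PATHWAYS,
    scales: tuple[float, ...] = SCALES,
    replicates: int = DEFAULT_REPLICATES,
    base_seed: int = 0,
    store_stride: int = 100,
) -> pd.DataFrame:
    """Single-pathway sweep over the requested grid; long-format results."""
    conditions = [
        make_condition(params.weights, p, s, replicates, base_seed)
        for p in pathways
        for s in scales
    ]
    frames = []
    for cond in conditions:
        results = run_condition(cond, params, store_stride=store_stride)
        frames.append(sweep_results_frame(results))
    return pd.concat(frames, ignore_index=True)


def sweep_results_frame(results: list[ReplicateResult]) -> pd.DataFrame:
    """Long format: one row per (replicate, metric)."""
    rows = []
    for r in results:
        if r.metrics is None:
            rows.append(
                {"replicate": r.replicate, "seed": r.seed, "metric": "error",
                 "value": np.nan, "note": r.error}
            )
            continue
        base = {k: v for k, v in r.metrics.metadata.items()}
        for key, value in r.metrics.to_row().items():
            if key in base:
                continue
            rows.append({**base, "metric": key, "value": value})
    return pd.DataFrame(rows)


def run_joint_sweep(
    population: str,
    params: ModelParameters,
    scales_a: tuple[float, ...] = SCALES,
    scales_b: tuple[float, ...] = SCALES,
    replicates: int = DEFAULT_REPLICATES,
    base_seed: int = 0,
    store_stride: int = 100,
) -> pd.DataFrame:
    """Joint manipulation of the two output pathways of one population.

    Returns one row per (scale_a, scale_b) grid cell with the mean percentage
    of time in each state over the replicates (cell percentages sum to 100).
    """
    if population not in POPULATION_OUTPUTS:
        raise KeyError(f"unknown population {population!r}; expected W, N or R")
    path_a, path_b = POPULATION_OUTPUTS[population]
    rows = []
    for sa in scales_a:
        for sb in scales_b:
            cond = make_condition(
                params.weights, (path_a, path_b), (sa, sb), replicates, base_seed
            )
            results = run_condition(cond, params, store_stride=store_stride)
            ok = [r.metrics for r in results if r.metrics is not None]
            row = {
                "population": population,
                "pathway_a": path_a,
                "scale_a": sa,
                "pathway_b": path_b,
                "scale_b": sb,
                "n": len(ok),
                "failed": len(results) - len(ok),
            }
            for s in STATES:
                row[f"percent_{s}"] = (
                    float(np.mean([m.percent[s] for m in ok])) if ok else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)
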