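"""Orchestration of full in-silico experiments.

``run_open_loop`` reproduces the training-data acquisition protocol:
cells receive pre-determined random-walk light sequences while their 8
feature channels are recorded every 5 minutes.  ``run_closed_loop`` runs
the receding-horizon control campaign: 3 hours of all-red equilibration,
then, every 5 minutes, measurement -> encode past -> binary PSO planning ->
apply the first bit of the winning strategy to each cell.

All randomness flows from one root seed via per-purpose child streams, so
records are exactly reproducible from their configuration snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .control import BatchPlanner, ControlConfig
from .datastore import Dataset, random_walk_stimulation
from .objectives import ObjectiveTrack
from .simcell import CH_FLUO, ChamberBatch, N_FEATURES, SimParams

__all__ = ["ExperimentConfig", "ExperimentRecord", "run_open_loop",
           "run_closed_loop"]

DT_MIN = 5.0
STEPS_PER_HOUR = 12


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one in-silico experiment."""

    mode: str = "open_loop"            # open_loop | closed_loop
    n_cells: int = 100
    duration_h: float = 16.0
    equilibration_h: float = 3.0       # all-red warm-up before control
    predictor: str = "deep"            # deep | linear | ode_kalman | none
    rng_seed: int = 0
    sim_params: SimParams = field(default_factory=SimParams)
    control: ControlConfig = field(default_factory=ControlConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("open_loop", "closed_loop"):
            raise ValueError("mode must be open_loop or closed_loop")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.mode == "closed_loop" and \
                self.duration_h < self.equilibration_h:
            # equality = a record containing only the equilibration phase
            raise ValueError("duration must cover the equilibration")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_h * STEPS_PER_HOUR))

    @property
    def equilibration_steps(self) -> int:
        return int(round(self.equilibration_h * STEPS_PER_HOUR))


@dataclass
class ExperimentRecord:
    """Self-describing result of one experiment."""

    config: ExperimentConfig
    dataset: Dataset
    applied_stims: np.ndarray                 # (n_cells, T)
    objectives: list | None = None            # per-cell ObjectiveTrack
    planning_costs: np.ndarray | None = None  # (n_cells, n_control_steps)
    control_start_step: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.dataset)

    def fluorescence(self) -> np.ndarray:
        return self.dataset.values[:, CH_FLUO, :]

    def summary(self) -> dict:
        from .evalmetrics import rmse_time
        out = {"mode": self.config.mode, "n_cells": self.n_cells,
               "n_steps": self.applied_stims.shape[1]}
        if self.objectives is not None:
            t0 = self.control_start_step
            errs = [rmse_time(self.dataset.values[i, CH_FLUO, t0:],
                              self.objectives[i].values[t0:self.applied_stims.shape[1]])
                    for i in range(self.n_cells)]
            out["median_rmse_time"] = float(np.nanmedian(errs))
            out["rmse_time"] = errs
        return out


def _make_batch(config: ExperimentConfig, rng: np.random.Generator,
                ) -> ChamberBatch:
    return ChamberBatch(config.sim_params, config.n_cells, rng)


def _neighbor_stims(n_cells: int, T: int, rng: np.random.Generator,
                    ) -> np.ndarray:
    walks = np.cumsum(rng.standard_normal((n_cells, T)), axis=1)
    return (walks > 0).astype(float)


def run_open_loop(config: ExperimentConfig) -> ExperimentRecord:
    """Simulate cells under independent pre-determined random-walk stimulations."""
    if config.mode != "open_loop":
        raise ValueError("config.mode must be open_loop")
    root = np.random.default_rng(config.rng_seed)
    seeds = root.spawn(3)
    T = config.n_steps
    n = config.n_cells
    stims = np.stack([random_walk_stimulation(T, s)
                      for s in seeds[0].spawn(n)])
    neighbor = _neighbor_stims(n, T, seeds[1])
    batch = _make_batch(config, seeds[2])
    values = np.empty((n, N_FEATURES, T))
    for t in range(T):
        batch.step(stims[:, t])
        values[:, :, t] = batch.measure(stims[:, t], neighbor[:, t])
    manifest = pd.DataFrame({
        "cell_id": [f"cell{i:05d}" for i in range(n)],
        "rng_seed": config.rng_seed,
        "mode": "open_loop",
    })
    dataset = Dataset(values=values, manifest=manifest)
    return ExperimentRecord(config=config, dataset=dataset,
                            applied_stims=stims)


def _build_predictor_planner(config: ExperimentConfig, model, normalizer):
    """Return a per-step planning callable bits = plan(pasts_norm, targets, rng)."""
    if config.predictor == "deep":
        planner = BatchPlanner(model, config.control)
        return planner.plan
    if config.predictor in ("linear", "ode_kalman"):
        from .control import bpso_optimize

        def plan(pasts, targets, rng):
            bits = np.empty(len(pasts), dtype=int)
            costs = np.empty(len(pasts))
            for i in range(len(pasts)):
                ctx = model.encode(pasts[i])
                tgt = targets[i]

                def cost_fn(candidates):
                    preds = model.predict_candidates(ctx, candidates)
                    return np.sqrt(np.mean((preds - tgt) ** 2, axis=1))

                strat, cost, _ = bpso_optimize(cost_fn, config.control, rng)
                bits[i], costs[i] = int(strat[0]), cost
            return bits, costs
        return plan
    raise ValueError(f"unknown predictor {config.predictor!r}")


def run_closed_loop(config: ExperimentConfig, model,
                    objectives: list[ObjectiveTrack]) -> ExperimentRecord:
    """Receding-horizon control campaign against per-cell objectives.

    ``model`` must expose the trained predictor surface and, for the deep
    predictor, a fitted normalizer (its bounds are the same ones used at
    training time).  ``predictor='none'`` applies random-walk stimulations
    instead of planning — the matched no-feedback control condition.
    """
    if config.mode != "closed_loop":
        raise ValueError("config.mode must be closed_loop")
    n = config.n_cells
    if len(objectives) != n:
        raise ValueError("one objective per cell required")
    root = np.random.default_rng(config.rng_seed)
    seeds = root.spawn(4)
    T = config.n_steps
    t0 = config.equilibration_steps
    H = config.control.H
    neighbor = _neighbor_stims(n, T, seeds[1])
    batch = _make_batch(config, seeds[2])
    plan_rng = seeds[3]
    random_stims = np.stack([random_walk_stimulation(T, s)
                             for s in seeds[0].spawn(n)]) \
        if config.predictor == "none" else None
    planner = None if config.predictor == "none" else \
        _build_predictor_planner(config, model, getattr(model, "normalizer_", None))
    normalizer = getattr(model, "normalizer_", None)
    values = np.empty((n, N_FEATURES, T))
    applied = np.zeros((n, T))
    n_control_steps = T - t0
    costs = np.full((n, n_control_steps), np.nan)
    # objectives ideally extend H steps past the experiment end so late
    # planning windows see the true target; edge-hold only if they do not
    obj_matrix = np.stack([o.values[:T + H] if len(o) >= T + H else
                           np.pad(o.values, (0, T + H - len(o)), mode="edge")
                           for o in objectives])
    for t in range(T):
        if t < t0:
            bits = np.zeros(n)  # all-red equilibration
        elif config.predictor == "none":
            bits = random_stims[:, t]
        else:
            past = values[:, :, max(0, t - 144):t]
            past_norm = np.stack([normalizer.transform(p) for p in past]) \
                if normalizer is not None else past
            targets = obj_matrix[:, t:t + H]
            if targets.shape[1] < H:
                targets = np.pad(targets, ((0, 0), (0, H - targets.shape[1])),
                                 mode="edge")
            if normalizer is not None:
                targets = normalizer.transform_channel(targets, CH_FLUO)
            bits, step_costs = planner(past_norm, targets, plan_rng)
            costs[:, t - t0] = step_costs
        applied[:, t] = bits
        batch.step(np.asarray(bits, dtype=float))
        values[:, :, t] = batch.measure(np.asarray(bits, dtype=float),
                                        neighbor[:, t])
    manifest = pd.DataFrame({
        "cell_id": [o.cell_id or f"cell{i:05d}"
                    for i, o in enumerate(objectives)],
        "rng_seed": config.rng_seed,
        "mode": f"closed_loop/{config.predictor}",
    })
    dataset = Dataset(values=values, manifest=manifest)
    return ExperimentRecord(config=config, dataset=dataset,
                            applied_stims=applied, objectives=list(objectives),
                            planning_costs=costs, control_start_step=t0)
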