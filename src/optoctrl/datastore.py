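"""Data model for 8-feature single-cell timeseries.

Covers the random-walk stimulation design used in open-loop training
experiments, [0, 1] normalization with persisted per-channel bounds,
extraction of (past, future stimulations, future fluorescence) training
samples, the ablation transforms (feature masking, past truncation), and a
simple on-disk dataset container (one array file + CSV manifest).

Conventions: a feature timeseries is an (8, T) float array in acquisition
order (stimulation, mother fluorescence, mother area in pixels, chamber
mean fluorescence, chamber fluorescence SD, cell count, neighbor
stimulation, sharpness), sampled every 5 minutes.  Missing values (e.g.
dead-cell artifacts) are NaN.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simcell import CH_FLUO, CH_STIM, N_FEATURES

__all__ = [
    "FeatureTimeseries", "ForecastSample", "Normalizer",
    "random_walk_stimulation", "fit_normalizer", "apply_normalizer",
    "extract_training_sample", "mask_feature", "truncate_past",
    "SampleTooShort", "Dataset", "save_dataset", "load_dataset",
    "P_MIN", "P_MAX", "HORIZONS",
]

logger = logging.getLogger(__name__)

#: allowed past lengths (3-12 h at 5-min sampling) and horizons (1-4 h)
P_MIN, P_MAX = 36, 144
HORIZONS = (12, 24, 36, 48)

#: channels that are binary by construction and keep fixed (0, 1) bounds
BINARY_CHANNELS = (CH_STIM, 6)


@dataclass
class FeatureTimeseries:
    """One cell's (8, T) feature record at 5-minute sampling."""

    values: np.ndarray
    cell_id: str = ""
    dt: float = 5.0  # minutes

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != N_FEATURES:
            raise ValueError(
                f"expected ({N_FEATURES}, T) array, got {self.values.shape}")

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @property
    def stimulation(self) -> np.ndarray:
        return self.values[CH_STIM]

    @property
    def fluorescence(self) -> np.ndarray:
        return self.values[CH_FLUO]


@dataclass
class ForecastSample:
    """One training/validation sample: a past block and the future it led to.

    ``past`` is the normalized (8, P) block ending one step before
    ``split_index``; ``future_stims`` are the H applied light bits and
    ``future_fluo`` the H ground-truth normalized fluorescence values from
    ``split_index`` onward.
    """

    past: np.ndarray
    future_stims: np.ndarray
    future_fluo: np.ndarray
    split_index: int = 0
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.past = np.asarray(self.past, dtype=float)
        self.future_stims = np.asarray(self.future_stims, dtype=float)
        self.future_fluo = np.asarray(self.future_fluo, dtype=float)
        if self.past.ndim != 2 or self.past.shape[0] != N_FEATURES:
            raise ValueError("past must be (8, P)")
        if len(self.future_stims) != len(self.future_fluo):
            raise ValueError("future stimulation/fluorescence length mismatch")

    @property
    def P(self) -> int:
        return self.past.shape[1]

    @property
    def H(self) -> int:
        return len(self.future_stims)


class SampleTooShort(Exception):
    """Raised when a timeseries cannot host a (past, future) split."""


def random_walk_stimulation(T: int, rng_seed=None) -> np.ndarray:
    """Binary stimulation sequence from a sign-binarized random walk.

    The cumulative sum of i.i.d. standard normal steps is thresholded at
    zero (bit = 1 where the walk is positive), which produces long
    correlated red/green epochs rather than rapid toggling.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    rng = rng_seed if hasattr(rng_seed, "standard_normal") \
        else np.random.default_rng(rng_seed)
    walk = np.cumsum(rng.standard_normal(T))
    return (walk > 0).astype(float)


@dataclass
class Normalizer:
    """Per-channel affine map to [0, 1] with clipping outside the bounds.

    Bounds default to robust 0.1/99.9 percentiles of the training corpus
    (glitch spikes would otherwise dominate a raw min/max); binary channels
    keep fixed (0, 1) bounds.  A constant channel (hi == lo) maps to 0.
    The fitted bounds are persisted with the model so that control-time
    normalization uses the same parameters.
    """

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if self.lo.shape != (N_FEATURES,) or self.hi.shape != (N_FEATURES,):
            raise ValueError("bounds must have one (lo, hi) pair per channel")
        if np.any(self.hi < self.lo):
            raise ValueError("hi must be >= lo")

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        span = self.hi - self.lo
        safe = np.where(span > 0, span, 1.0)
        out = (values - self.lo[:, None]) / safe[:, None]
        out = np.where(span[:, None] > 0, out, 0.0)
        n_clip = int(np.sum((out < 0) | (out > 1)))
        if n_clip:
            logger.debug("normalizer clipped %d values", n_clip)
        return np.clip(out, 0.0, 1.0)

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return values * (self.hi - self.lo)[:, None] + self.lo[:, None]

    def transform_channel(self, x: np.ndarray, channel: int) -> np.ndarray:
        span = self.hi[channel] - self.lo[channel]
        if span <= 0:
            return np.zeros_like(np.asarray(x, dtype=float))
        return np.clip((np.asarray(x, dtype=float) - self.lo[channel]) / span,
                       0.0, 1.0)

    def inverse_transform_channel(self, x: np.ndarray, channel: int) -> np.ndarray:
        return np.asarray(x, dtype=float) * (self.hi[channel] - self.lo[channel]) \
            + self.lo[channel]

    # -- persistence ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({"lo": self.lo.tolist(), "hi": self.hi.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "Normalizer":
        d = json.loads(text)
        return cls(lo=np.array(d["lo"]), hi=np.array(d["hi"]))

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "Normalizer":
        return cls.from_json(Path(path).read_text())


def fit_normalizer(corpus, percentiles: tuple[float, float] | None = (0.1, 99.9),
                   ) -> Normalizer:
    """Fit per-channel [0, 1] bounds on a corpus of FeatureTimeseries.

    ``percentiles=None`` uses the raw (nan-aware) min/max instead of the
    robust default.  Binary channels are pinned to (0, 1); NaN entries are
    excluded from fitting.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus must be non-empty")
    stacked = np.concatenate(
        [ts.values if isinstance(ts, FeatureTimeseries) else np.asarray(ts)
         for ts in corpus], axis=1)
    lo = np.empty(N_FEATURES)
    hi = np.empty(N_FEATURES)
    for ch in range(N_FEATURES):
        col = stacked[ch]
        col = col[np.isfinite(col)]
        if col.size == 0:
            lo[ch], hi[ch] = 0.0, 0.0
            continue
        if percentiles is None:
            lo[ch], hi[ch] = col.min(), col.max()
        else:
            lo[ch], hi[ch] = np.percentile(col, percentiles)
    for ch in BINARY_CHANNELS:
        lo[ch], hi[ch] = 0.0, 1.0
    return Normalizer(lo=lo, hi=hi)


def apply_normalizer(series: FeatureTimeseries, norm: Normalizer,
                     ) -> FeatureTimeseries:
    """Return a normalized copy of a feature timeseries."""
    if series.values.shape[0] != N_FEATURES:
        raise ValueError("channel count mismatch")
    return FeatureTimeseries(values=norm.transform(series.values),
                             cell_id=series.cell_id, dt=series.dt)


def extract_training_sample(series: FeatureTimeseries, horizon_H: int,
                            rng: np.random.Generator) -> ForecastSample:
    """Draw a random (past, future) split from one normalized timeseries.

    The past length P is uniform over [36, min(144, T - H)] and the split
    index uniform over the positions that leave P past and H future points.
    Raises SampleTooShort when T < 36 + H so the caller can resample.
    """
    if horizon_H not in HORIZONS:
        raise ValueError(f"horizon must be one of {HORIZONS}")
    T = series.T
    p_cap = min(P_MAX, T - horizon_H)
    if p_cap < P_MIN:
        raise SampleTooShort(f"series of length {T} too short for H={horizon_H}")
    P = int(rng.integers(P_MIN, p_cap + 1))
    split = int(rng.integers(P, T - horizon_H + 1))
    vals = series.values
    return ForecastSample(
        past=vals[:, split - P:split].copy(),
        future_stims=vals[CH_STIM, split:split + horizon_H].copy(),
        future_fluo=vals[CH_FLUO, split:split + horizon_H].copy(),
        split_index=split,
        cell_id=series.cell_id)


def mask_feature(sample: ForecastSample, channel) -> ForecastSample:
    """Return a copy with the given past channel(s) zeroed out.

    Accepts a single index or an iterable of indices (e.g. both
    fluorescence channels, or all 8 to blind the model completely).
    """
    channels = np.atleast_1d(np.asarray(channel, dtype=int))
    if np.any((channels < 0) | (channels >= N_FEATURES)):
        raise ValueError("channel index out of range")
    past = sample.past.copy()
    past[channels, :] = 0.0
    return ForecastSample(past=past, future_stims=sample.future_stims.copy(),
                          future_fluo=sample.future_fluo.copy(),
                          split_index=sample.split_index, cell_id=sample.cell_id)


def truncate_past(sample: ForecastSample, keep: int) -> ForecastSample:
    """Return a copy keeping only the most recent ``keep`` past timepoints."""
    if keep <= 0:
        raise ValueError("keep must be positive")
    keep = min(keep, sample.P)
    return ForecastSample(past=sample.past[:, -keep:].copy(),
                          future_stims=sample.future_stims.copy(),
                          future_fluo=sample.future_fluo.copy(),
                          split_index=sample.split_index, cell_id=sample.cell_id)


# -- dataset container ----------------------------------------------------

@dataclass
class Dataset:
    """A batch of cells as a (n_cells, 8, T) array plus per-cell metadata."""

    values: np.ndarray
    manifest: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != N_FEATURES:
            raise ValueError("values must be (n_cells, 8, T)")
        if self.manifest is None:
            self.manifest = pd.DataFrame(
                {"cell_id": [f"cell{i:05d}" for i in range(len(self.values))]})

    def __len__(self) -> int:
        return self.values.shape[0]

    def series(self, i: int) -> FeatureTimeseries:
        return FeatureTimeseries(values=self.values[i],
                                 cell_id=str(self.manifest["cell_id"].iloc[i]))

    def __iter__(self):
        return (self.series(i) for i in range(len(self)))


#: container layout version written into every manifest
CONTAINER_VERSION = 1


def save_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as ``<path>.npz`` (arrays) + ``<path>.csv`` (manifest)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path.with_suffix(".npz"), values=dataset.values,
                        version=np.array([CONTAINER_VERSION]))
    dataset.manifest.to_csv(path.with_suffix(".csv"), index=False)


def load_dataset(path) -> Dataset:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as f:
        values = f["values"]
    manifest = pd.read_csv(path.with_suffix(".csv"))
    return Dataset(values=values, manifest=manifest)
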