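"""Construction and assignment of per-cell control objectives.

Objectives are target fluorescence trajectories on the 5-minute grid:
constants, sinewaves (optionally with position-dependent phase delays, as
in concentric-wave patterns over a pixel grid), or stacks of grayscale
movie frames where each pixel's intensity becomes one cell's objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ObjectiveTrack", "MovieObjectiveSet", "constant_objective",
           "sinewave_objective", "movie_objectives", "objective_derivative",
           "load_frames"]

DT_MIN = 5.0

#: default intensity->fluorescence mapping band (a.u.), bracketing the
#: 800/1200/1800 a.u. setpoints used in constant-objective experiments
DEFAULT_LO_AU = 400.0
DEFAULT_HI_AU = 2000.0


@dataclass
class ObjectiveTrack:
    """Per-cell target fluorescence trajectory in arbitrary units."""

    values: np.ndarray
    cell_id: str = ""
    start_time_h: float = 3.0  # control onset (equilibration before)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("objective values must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.values)

    def segment(self, t: int, H: int) -> np.ndarray:
        """Horizon slice starting at step t, holding the last value if short."""
        seg = self.values[t:t + H]
        if len(seg) < H:
            pad = seg[-1] if len(seg) else self.values[-1]
            seg = np.concatenate([seg, np.full(H - len(seg), pad)])
        return seg


def constant_objective(level: float, T: int, cell_id: str = "") -> ObjectiveTrack:
    """Constant setpoint objective (e.g. 800, 1200 or 1800 a.u.)."""
    return ObjectiveTrack(values=np.full(T, float(level)), cell_id=cell_id)


def sinewave_objective(amplitude: float, period_h: float, phase: float,
                       offset: float, T: int, dt: float = DT_MIN,
                       cell_id: str = "") -> ObjectiveTrack:
    """Sinewave objective: offset + amplitude * sin(2π t dt / period + phase).

    ``period_h`` is in hours; ``offset >= amplitude`` is required so the
    target never goes negative.
    """
    if period_h <= 0:
        raise ValueError("period must be positive")
    if offset < amplitude:
        raise ValueError("offset must be >= amplitude (non-negative targets)")
    t = np.arange(T) * dt / 60.0  # hours
    values = offset + amplitude * np.sin(2.0 * np.pi * t / period_h + phase)
    return ObjectiveTrack(values=values, cell_id=cell_id)


@dataclass
class MovieObjectiveSet:
    """Grayscale frame stack whose pixels become per-cell objectives.

    ``frames`` is (F, H, W) with intensities in [0, 255]; the affine map
    [0, 255] -> [lo_au, hi_au] converts intensity to target fluorescence.
    ``frame_interval_min`` is the movie's own frame spacing; tracks are
    resampled to the 5-minute grid by nearest-frame hold.
    """

    frames: np.ndarray
    lo_au: float = DEFAULT_LO_AU
    hi_au: float = DEFAULT_HI_AU
    frame_interval_min: float = DT_MIN
    permutation: np.ndarray | None = None  # persisted shuffle for de-shuffling

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] == 0:
            raise ValueError("frames must be a non-empty (F, H, W) stack")
        if not self.hi_au > self.lo_au:
            raise ValueError("intensity mapping must be increasing")

    @property
    def n_pixels(self) -> int:
        return self.frames.shape[1] * self.frames.shape[2]

    def intensity_to_au(self, intensity: np.ndarray) -> np.ndarray:
        return self.lo_au + (self.hi_au - self.lo_au) * \
            np.asarray(intensity, dtype=float) / 255.0

    def au_to_intensity(self, au: np.ndarray) -> np.ndarray:
        return 255.0 * (np.asarray(au, dtype=float) - self.lo_au) / \
            (self.hi_au - self.lo_au)


def movie_objectives(movie: MovieObjectiveSet, n_cells: int, T: int,
                     rng: np.random.Generator | None = None,
                     offset: int = 0) -> list[ObjectiveTrack]:
    """Assign shuffled pixel trajectories to ``n_cells`` cells.

    Pixels are shuffled once (the permutation is persisted on the movie set
    so results can be de-shuffled back into frame order); ``offset`` selects
    which slice of the shuffled pixel list this batch covers, so several
    experiments can partition one movie.  Frame intensities are resampled
    to the 5-minute grid by nearest-frame hold and mapped affinely to a.u.
    """
    F, Hpix, Wpix = movie.frames.shape
    n_pixels = movie.n_pixels
    if n_cells <= 0 or offset + n_cells > n_pixels:
        raise ValueError(f"cannot assign {n_cells} cells at offset {offset} "
                         f"from {n_pixels} pixels")
    if movie.permutation is None:
        if rng is None:
            rng = np.random.default_rng(0)
        movie.permutation = rng.permutation(n_pixels)
    flat = movie.frames.reshape(F, n_pixels)
    # nearest-frame hold onto the 5-min grid
    t_grid = np.arange(T) * DT_MIN
    frame_idx = np.clip(np.round(t_grid / movie.frame_interval_min).astype(int),
                        0, F - 1)
    tracks = []
    for k in range(n_cells):
        pix = int(movie.permutation[offset + k])
        intensity = flat[frame_idx, pix]
        tracks.append(ObjectiveTrack(values=movie.intensity_to_au(intensity),
                                     cell_id=f"px{pix:05d}"))
    return tracks


def load_frames(paths) -> np.ndarray:
    """Read grayscale PNG/PGM frames into an (F, H, W) stack in [0, 255]."""
    import imageio.v3 as iio
    frames = []
    for p in paths:
        img = np.asarray(iio.imread(p), dtype=float)
        if img.ndim == 3:  # collapse RGB(A) to luminance
            img = img[..., :3].mean(axis=2)
        frames.append(img)
    if not frames:
        raise ValueError("no frames given")
    return np.stack(frames)


def objective_derivative(track, dt: float = DT_MIN) -> np.ndarray:
    """Finite-difference time derivative of an objective in a.u./h.

    Central differences in the interior (second-order accurate), one-sided
    at the edges; output stays aligned with the track.
    """
    values = track.values if isinstance(track, ObjectiveTrack) \
        else np.asarray(track, dtype=float)
    if len(values) < 2:
        raise ValueError("track must have at least 2 points")
    return np.gradient(values, dt / 60.0)
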