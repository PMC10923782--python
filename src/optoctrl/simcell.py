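"""Stochastic simulator of optogenetically actuated mother-machine cells.

The simulated plant stands in for live *E. coli* carrying a green/red
light-switchable expression system (CcaSR-like) growing in mother-machine
chambers.  It emits, every 5 minutes, the same 8 feature channels that a
real-time microscopy pipeline would extract, so that forecasters and
controllers built on top of it face qualitatively realistic data:
minutes-scale activation kinetics, dilution-dominated decay, bursty
production noise, growth and division, cell-to-cell rate heterogeneity,
aging, death, filamentation, and measurement glitches.

Model (per cell)::

    da/dt = k_on * u * (1 - a) - k_off * (1 - u) * a          promoter activation
    dη    = -η/τ dt + σ_η sqrt(2 dt/τ) dW                      OU production noise
    dg/dt = β_cell β0 (leak + (1-leak) a) max(0, 1+η)
            - (γ_m + µ_inst) g                                 concentration
    µ_inst = µ_cell µ0 exp(-k_age · age) / 60                  per-minute growth
    dA/dt = µ_inst A ; A >= A_div -> A/2 (g unchanged)         growth & division

`u` is the binary light input (1 = green/activating, 0 = red/repressing).
Fluorescence decay is dominated by dilution (γ_m + µ), matching systems
where the reporter is stable and loss is mostly growth-driven.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimParams", "CellState", "sample_cell", "step_cell", "simulate_chamber",
           "ChamberBatch"]

#: number of emitted feature channels
N_FEATURES = 8

# channel indices, in acquisition order
CH_STIM = 0
CH_FLUO = 1
CH_AREA = 2
CH_CHAMBER_MEAN = 3
CH_CHAMBER_SD = 4
CH_NCELLS = 5
CH_NEIGHBOR_STIM = 6
CH_SHARPNESS = 7


@dataclass(frozen=True)
class SimParams:
    """Plant parameters.

    Defaults are tuned so that the all-green steady state is ~2500 a.u.
    and the all-red (leaky) state is ~150 a.u., bracketing the 800-1800
    a.u. objective band used in control experiments.
    """

    k_on: float = 0.2        # activation rate under green light (1/min)
    k_off: float = 0.1       # deactivation rate under red light (1/min)
    beta0: float = 85.0      # maximal production rate (a.u./min)
    leak: float = 0.06       # basal production fraction
    gamma_m: float = 0.01    # maturation/degradation rate (1/min)
    mu0: float = 1.4         # baseline specific growth rate (1/h)
    k_age: float = 0.02      # aging decay rate of growth (1/h)
    A_birth: float = 1.5     # birth area (µm²)
    A_div: float = 3.0       # division area (µm²)
    cv_cell: float = 0.2     # CV of per-cell log-normal rate multipliers
    sigma_eta: float = 0.3   # production noise magnitude
    tau_eta: float = 30.0    # production noise correlation time (min)
    sigma_meas: float = 0.05  # relative fluorescence measurement noise
    p_death: float = 5e-4    # per-measurement-step death probability
    p_fil: float = 1e-3      # per-measurement-step filamentation probability
    p_glitch: float = 0.01   # per-step probability of a sharpness spike artifact
    px_area: float = 0.0044  # area of one pixel (µm²)
    dt_sim: float = 0.5      # integration substep (min)
    dt_meas: float = 5.0     # measurement interval (min)
    n_chamber_max: int = 8   # chamber capacity (cells)
    fil_duration_mean: float = 120.0  # mean filamentation duration (min)

    def __post_init__(self) -> None:
        vals = [self.k_on, self.k_off, self.beta0, self.gamma_m, self.mu0,
                self.k_age, self.sigma_eta, self.tau_eta, self.sigma_meas,
                self.p_death, self.p_fil, self.p_glitch, self.cv_cell]
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("all rates must be finite and non-negative")
        if not 0.0 <= self.leak <= 1.0:
            raise ValueError("leak must be in [0, 1]")
        if not self.A_birth < self.A_div:
            raise ValueError("A_birth must be < A_div")
        if self.px_area <= 0:
            raise ValueError("px_area must be positive")
        n_sub = self.dt_meas / self.dt_sim
        if abs(n_sub - round(n_sub)) > 1e-9 or n_sub < 1:
            raise ValueError("dt_sim must divide dt_meas")

    @property
    def n_substeps(self) -> int:
        return int(round(self.dt_meas / self.dt_sim))


MODE_GROWING = 0
MODE_FILAMENTING = 1
MODE_DEAD = 2


@dataclass
class CellState:
    """State of one simulated mother cell (scalar view of the batch state)."""

    a: float                 # promoter activation in [0, 1]
    g: float                 # fluorophore concentration (a.u.)
    eta: float               # production-noise state
    A: float                 # cell area (µm²)
    age: float               # time since trace start (h)
    mode: int                # MODE_GROWING / MODE_FILAMENTING / MODE_DEAD
    beta_cell: float         # per-cell production multiplier
    mu_cell: float           # per-cell growth multiplier
    n_chamber: int = 1
    fil_until: float = 0.0   # filamentation end time (h since start)

    def validate(self) -> None:
        if not (0.0 <= self.a <= 1.0 and self.g >= 0 and self.A > 0
                and self.n_chamber >= 1):
            raise ValueError("invalid cell state")


class ChamberBatch:
    """Vectorized state of ``n`` independent mother cells.

    All per-cell quantities are flat arrays; `step` advances every cell by
    one measurement interval given a per-cell light bit.  The scalar API
    (`sample_cell`, `step_cell`) wraps a batch of size one.
    """

    def __init__(self, params: SimParams, n: int, rng: np.random.Generator):
        self.params = params
        self.n = n
        self.rng = rng
        p = params
        sigma_ln = np.sqrt(np.log1p(p.cv_cell ** 2))
        # log-normal with median 1 and the stated CV
        self.beta_cell = np.exp(rng.normal(0.0, sigma_ln, n)) if sigma_ln > 0 \
            else np.ones(n)
        self.mu_cell = np.exp(rng.normal(0.0, sigma_ln, n)) if sigma_ln > 0 \
            else np.ones(n)
        self.a = np.zeros(n)
        self.eta = np.zeros(n)
        self.A = rng.uniform(p.A_birth, p.A_div, n)
        self.age = np.zeros(n)
        self.mode = np.full(n, MODE_GROWING, dtype=np.int64)
        self.n_chamber = np.ones(n, dtype=np.int64)
        self.fil_until = np.zeros(n)
        mu_inst = self.mu_cell * p.mu0 / 60.0
        self.g = p.leak * self.beta_cell * p.beta0 / (p.gamma_m + mu_inst)

    # -- dynamics ---------------------------------------------------------

    def _mu_inst(self) -> np.ndarray:
        """Per-minute instantaneous growth rate, zero when dead."""
        p = self.params
        mu = self.mu_cell * p.mu0 * np.exp(-p.k_age * self.age) / 60.0
        return np.where(self.mode == MODE_DEAD, 0.0, mu)

    def step(self, light: np.ndarray) -> None:
        """Advance all cells by one dt_meas interval (Euler-Maruyama)."""
        p = self.params
        u = np.asarray(light, dtype=float)
        if u.shape != (self.n,):
            raise ValueError(f"light must have shape ({self.n},)")
        dt = p.dt_sim
        for _ in range(p.n_substeps):
            mu_inst = self._mu_inst()
            dead = self.mode == MODE_DEAD
            # promoter activation (frozen in dead cells)
            da = (p.k_on * u * (1.0 - self.a) - p.k_off * (1.0 - u) * self.a) * dt
            self.a = np.clip(np.where(dead, self.a, self.a + da), 0.0, 1.0)
            # OU production noise
            if p.sigma_eta > 0:
                noise = self.rng.standard_normal(self.n)
                self.eta = (self.eta - (self.eta / p.tau_eta) * dt
                            + p.sigma_eta * np.sqrt(2.0 * dt / p.tau_eta) * noise)
            prod = (self.beta_cell * p.beta0
                    * (p.leak + (1.0 - p.leak) * self.a)
                    * np.maximum(0.0, 1.0 + self.eta))
            prod = np.where(dead, 0.0, prod)
            dg = (prod - (p.gamma_m + mu_inst) * self.g) * dt
            self.g = np.maximum(0.0, self.g + dg)
            # exponential area growth; frozen when dead
            self.A = self.A * np.exp(mu_inst * dt)
            # division halves area, concentration unchanged
            can_divide = (self.mode == MODE_GROWING) & (self.A >= p.A_div)
            if np.any(can_divide):
                self.A = np.where(can_divide, self.A / 2.0, self.A)
                self.n_chamber = np.where(
                    can_divide,
                    np.minimum(self.n_chamber + 1, p.n_chamber_max),
                    self.n_chamber)
            self.age = self.age + dt / 60.0
        # rare-event transitions, sampled once per measurement step
        alive = self.mode != MODE_DEAD
        if p.p_death > 0:
            dies = alive & (self.rng.random(self.n) < p.p_death)
            self.mode = np.where(dies, MODE_DEAD, self.mode)
        if p.p_fil > 0:
            fil = (self.mode == MODE_GROWING) & (self.rng.random(self.n) < p.p_fil)
            if np.any(fil):
                dur_h = self.rng.exponential(p.fil_duration_mean / 60.0, self.n)
                self.fil_until = np.where(fil, self.age + dur_h, self.fil_until)
                self.mode = np.where(fil, MODE_FILAMENTING, self.mode)
        recover = (self.mode == MODE_FILAMENTING) & (self.age >= self.fil_until)
        self.mode = np.where(recover, MODE_GROWING, self.mode)

    # -- measurement ------------------------------------------------------

    def measure(self, light: np.ndarray, neighbor_light: np.ndarray) -> np.ndarray:
        """Emit the 8 feature channels for every cell: (n, 8) array."""
        p = self.params
        rng = self.rng
        out = np.empty((self.n, N_FEATURES))
        out[:, CH_STIM] = light
        fluo = self.g * (1.0 + rng.normal(0.0, p.sigma_meas, self.n)) \
            if p.sigma_meas > 0 else self.g.copy()
        out[:, CH_FLUO] = np.maximum(0.0, fluo)
        out[:, CH_AREA] = self.A / p.px_area
        # chamber statistics are mother-derived surrogates (no daughter lineage)
        ch_mean = out[:, CH_FLUO] * (1.0 + rng.normal(0.0, 0.05, self.n))
        out[:, CH_CHAMBER_MEAN] = np.maximum(0.0, ch_mean)
        out[:, CH_CHAMBER_SD] = out[:, CH_CHAMBER_MEAN] * \
            np.abs(rng.normal(0.15, 0.05, self.n))
        out[:, CH_NCELLS] = self.n_chamber
        out[:, CH_NEIGHBOR_STIM] = neighbor_light
        sharp = 1.0 + rng.normal(0.0, 0.02, self.n)
        if p.p_glitch > 0:
            spikes = rng.random(self.n) < p.p_glitch
            sharp = np.where(spikes, sharp + rng.exponential(2.0, self.n), sharp)
        out[:, CH_SHARPNESS] = sharp
        return out

    # -- scalar interop ---------------------------------------------------

    def get_state(self, i: int) -> CellState:
        return CellState(
            a=float(self.a[i]), g=float(self.g[i]), eta=float(self.eta[i]),
            A=float(self.A[i]), age=float(self.age[i]), mode=int(self.mode[i]),
            beta_cell=float(self.beta_cell[i]), mu_cell=float(self.mu_cell[i]),
            n_chamber=int(self.n_chamber[i]), fil_until=float(self.fil_until[i]))

    def set_state(self, i: int, s: CellState) -> None:
        self.a[i] = s.a
        self.g[i] = s.g
        self.eta[i] = s.eta
        self.A[i] = s.A
        self.age[i] = s.age
        self.mode[i] = s.mode
        self.beta_cell[i] = s.beta_cell
        self.mu_cell[i] = s.mu_cell
        self.n_chamber[i] = s.n_chamber
        self.fil_until[i] = s.fil_until


def sample_cell(params: SimParams, rng_seed: int) -> CellState:
    """Draw the initial state of a fresh mother cell.

    Per-cell production and growth multipliers are log-normal with median 1
    and coefficient of variation ``params.cv_cell``; the initial
    fluorescence sits at the red-light (leaky) steady state.
    """
    rng = np.random.default_rng(rng_seed)
    batch = ChamberBatch(params, 1, rng)
    return batch.get_state(0)


def step_cell(state: CellState, light: int, params: SimParams,
              rng: np.random.Generator) -> CellState:
    """Advance one cell by one measurement interval (dt_meas)."""
    if light not in (0, 1):
        raise ValueError("light must be 0 or 1")
    state.validate()
    batch = ChamberBatch.__new__(ChamberBatch)
    batch.params = params
    batch.n = 1
    batch.rng = rng
    for name in ("a", "g", "eta", "A", "age", "fil_until",
                 "beta_cell", "mu_cell"):
        setattr(batch, name, np.array([getattr(state, name)], dtype=float))
    batch.mode = np.array([state.mode], dtype=np.int64)
    batch.n_chamber = np.array([state.n_chamber], dtype=np.int64)
    batch.step(np.array([float(light)]))
    return batch.get_state(0)


def simulate_chamber(params: SimParams, stims: np.ndarray, T: int,
                     rng_seed: int) -> np.ndarray:
    """Simulate one mother cell for ``T`` measurement intervals.

    Returns the (8, T) feature array.  ``stims`` supplies the applied light
    bit per interval (length >= T); the neighbor-chamber stimulation channel
    is an independent binarized random walk.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    stims = np.asarray(stims)
    if len(stims) < T:
        raise ValueError("stims must cover at least T intervals")
    rng = np.random.default_rng(rng_seed)
    batch = ChamberBatch(params, 1, rng)
    # independent neighbor stimulation sequence (same random-walk design)
    walk = np.cumsum(rng.standard_normal(T))
    neighbor = (walk > 0).astype(float)
    out = np.empty((N_FEATURES, T))
    for t in range(T):
        batch.step(np.array([float(stims[t])]))
        row = batch.measure(np.array([float(stims[t])]),
                            np.array([neighbor[t]]))[0]
        out[:, t] = row
    return out
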