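"""Trajectory generation: Euler--Maruyama, Gillespie SSA, chemical Langevin.

Seeding contract
----------------
Every ensemble member ``i`` draws its noise from
``numpy.random.SeedSequence(entropy=base_seed, spawn_key=(i,))``, so members
are independent, order-independent and individually reproducible.  Batched
fast paths (:func:`toy_ensemble`, :func:`cle_ensemble`) consume noise in the
same per-member chunked order as the single-trajectory integrators and
therefore produce bit-identical trajectories.

The chemical Langevin integrator uses per-reaction noise amplitudes
``sqrt(a_j)`` (diffusion matrix ``S diag(a) S^T``), the convention consistent
with the SSA increment covariance.  Coordinates are clamped at zero after
each step; clamp events are counted in the trajectory metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from tslandscape.models import (
    DEV_LABELS,
    TOY_LABELS,
    DevParams,
    ReactionNetwork,
    ToyParams,
    dev_network,
    toy_drift,
)

__all__ = [
    "IntegrationError",
    "ParameterSchedule",
    "SimConfig",
    "Trajectory",
    "Ensemble",
    "member_seed",
    "euler_maruyama",
    "ssa_gillespie",
    "cle_integrate",
    "run_ensemble",
    "toy_ensemble",
    "cle_ensemble",
    "sample_box",
    "toy_em_drift",
]

#: number of integrator steps per pre-generated noise block
_CHUNK = 4096


class IntegrationError(RuntimeError):
    """Raised when an integrator produces a non-finite state."""


@dataclass(frozen=True)
class ParameterSchedule:
    """Time course of a single controlled parameter.

    Modes: ``constant`` (value ``start`` forever), ``linear`` (ramp from
    ``start`` to ``end`` over ``duration``, then held at ``end``) and ``step``
    (``start`` before ``duration``, ``end`` after).
    """

    name: str
    mode: str = "constant"
    start: float = 0.0
    end: Optional[float] = None
    duration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "linear", "step"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.mode != "constant":
            if self.end is None or self.duration is None:
                raise ValueError(f"{self.mode} schedule needs end and duration")
            if self.duration <= 0:
                raise ValueError("schedule duration must be positive")
        if not np.isfinite(self.start):
            raise ValueError("schedule start must be finite")

    @classmethod
    def constant(cls, name: str, value: float) -> "ParameterSchedule":
        return cls(name=name, mode="constant", start=value)

    @classmethod
    def linear(cls, name: str, start: float, end: float, duration: float) -> "ParameterSchedule":
        return cls(name=name, mode="linear", start=start, end=end, duration=duration)

    @classmethod
    def step(cls, name: str, start: float, end: float, at: float) -> "ParameterSchedule":
        return cls(name=name, mode="step", start=start, end=end, duration=at)

    def value(self, t):
        t = np.asarray(t, dtype=float)
        if self.mode == "constant":
            return np.broadcast_to(np.float64(self.start), t.shape)[()] + 0.0
        if self.mode == "step":
            return np.where(t < self.duration, self.start, self.end)[()] + 0.0
        frac = np.clip(t / self.duration, 0.0, 1.0)
        return (self.start + (self.end - self.start) * frac)[()] + 0.0


@dataclass(frozen=True)
class SimConfig:
    """Simulation horizon, integrator step, output grid and RNG seed."""

    t_end: float
    dt: float = 1e-3
    record_interval: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.dt <= self.record_interval <= self.t_end):
            raise ValueError(
                f"need 0 < dt <= record_interval <= t_end, got "
                f"dt={self.dt}, record_interval={self.record_interval}, t_end={self.t_end}"
            )
        ratio = self.record_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9 * ratio:
            raise ValueError("record_interval must be an integer multiple of dt")

    @property
    def steps_per_record(self) -> int:
        return int(round(self.record_interval / self.dt))

    @property
    def n_records(self) -> int:
        return int(round(self.t_end / self.record_interval))

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_records + 1) * self.record_interval


@dataclass
class Trajectory:
    """A single recorded sample path on a fixed output grid."""

    times: np.ndarray
    states: np.ndarray
    labels: tuple
    model_id: str
    seed: int
    schedule: Optional[ParameterSchedule] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (len(self.times), len(self.labels)):
            raise ValueError("states must have shape (n_times, n_labels)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def column(self, label: str) -> np.ndarray:
        return self.states[:, self.labels.index(label)]


@dataclass
class Ensemble:
    """Trajectories on a common time grid with per-member seeds."""

    times: np.ndarray
    states: np.ndarray  # (n_members, n_times, n_species)
    labels: tuple
    model_id: str
    base_seed: int
    member_seeds: np.ndarray
    schedule: Optional[ParameterSchedule] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 3 or self.states.shape[1] != len(self.times):
            raise ValueError("states must have shape (n, n_times, d)")

    @property
    def n_members(self) -> int:
        return self.states.shape[0]

    def member(self, i: int) -> Trajectory:
        return Trajectory(
            times=self.times,
            states=self.states[i],
            labels=self.labels,
            model_id=self.model_id,
            seed=int(self.member_seeds[i]),
            schedule=self.schedule,
        )

    def column(self, label: str) -> np.ndarray:
        return self.states[:, :, self.labels.index(label)]


def member_seed(base_seed: int, index: int) -> np.random.SeedSequence:
    """Seed sequence for ensemble member ``index`` derived from ``base_seed``."""
    return np.random.SeedSequence(entropy=base_seed, spawn_key=(index,))


def _rng_for(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# Euler--Maruyama
# --------------------------------------------------------------------------

def toy_em_drift(params: ToyParams) -> Callable:
    """Drift closure ``f(x, beta)`` for the toy SDE; ``beta=None`` uses params."""

    def drift(x, beta=None):
        p = params if beta is None else params.replace(beta=float(beta))
        return toy_drift(x, p)

    return drift


def _em_batch(drift, sigma, x0s, schedule, config, rngs, labels):
    """Vectorized fixed-step EM over a batch; one RNG per member.

    Noise is pre-generated per member in blocks of ``_CHUNK`` steps so that a
    batch of size one is bit-identical to any larger batch.
    """
    n, d = x0s.shape
    n_steps = config.n_records * config.steps_per_record
    sqdt = math.sqrt(config.dt)
    x = x0s.copy()
    out = np.empty((n, config.n_records + 1, d))
    out[:, 0] = x
    rec = 0
    step = 0
    while step < n_steps:
        block = min(_CHUNK, n_steps - step)
        noise = np.empty((n, block, d))
        for i, rng in enumerate(rngs):
            noise[i] = rng.standard_normal((block, d))
        for j in range(block):
            t = (step + j) * config.dt
            u = None if schedule is None else schedule.value(t)
            x = x + drift(x, u) * config.dt + sigma * sqdt * noise[:, j]
            if (step + j + 1) % config.steps_per_record == 0:
                rec += 1
                out[:, rec] = x
        if not np.all(np.isfinite(x)):
            bad = np.nonzero(~np.isfinite(x).all(axis=1))[0][0]
            raise IntegrationError(
                f"non-finite state in member {bad} at step <= {step + block}"
            )
        step += block
    return config.time_grid(), out


def euler_maruyama(
    drift: Callable,
    sigma: float,
    x0,
    schedule: Optional[ParameterSchedule],
    config: SimConfig,
    labels: tuple = TOY_LABELS,
    model_id: str = "toy",
) -> Trajectory:
    """Fixed-step Euler--Maruyama integration of ``dX = f(X,u) dt + sigma dW``.

    ``drift(x, u)`` must accept a batch of states ``(n, d)`` and the scheduled
    parameter value ``u`` (``None`` when no schedule is given).  With
    ``sigma = 0`` this is explicit Euler for the ODE.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    rng = _rng_for(config.seed)
    times, out = _em_batch(drift, sigma, x0[None, :], schedule, config, [rng], labels)
    return Trajectory(
        times=times, states=out[0], labels=labels, model_id=model_id,
        seed=config.seed, schedule=schedule,
    )


# --------------------------------------------------------------------------
# Gillespie SSA
# --------------------------------------------------------------------------

def _dev_scalar_propensities(p: DevParams):
    """Scalar-float propensity evaluator for the SSA hot loop."""
    k0, k1, k2, k3, k4, k5 = p.k0, p.k1, p.k2, p.k3, p.k4, p.k5
    k6, k7, k8, k9, k10 = p.k6, p.k7, p.k8, p.k9, p.k10
    k11, k12, k13, k14, kd = p.k11, p.k12, p.k13, p.k14, p.kd

    def props(N, O, F, G, L):
        a1 = (k0 * O * (k1 + k2 * N * N + k0 * O + k3 * L)) / (
            1.0 + k0 * O * (k2 * N * N + k0 * O + k3 * L + k4 * F * F) + k5 * O * G * G
        )
        a2 = (k6 + k7 * O) / (1.0 + k7 * O + k8 * G * G)
        a3 = (k9 + k10 * O) / (1.0 + k10 * O)
        a4 = (k11 + k12 * G * G + k14 * O) / (
            1.0 + k12 * G * G + k13 * N * N + k14 * O
        )
        return (a1, a2, a3, a4, kd * N, kd * O, kd * F, kd * G)

    return props


def ssa_gillespie(
    network: ReactionNetwork,
    x0,
    schedule: Optional[ParameterSchedule],
    config: SimConfig,
    model_id: str = "dev",
) -> Trajectory:
    """Exact stochastic simulation of a birth--death network.

    A time-varying control (the LIF schedule) is frozen on a sub-grid of
    width <= 1% of the ramp duration; within each sub-interval the SSA is
    exact.  All-zero propensities leave the state constant until the horizon.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0) or np.any(np.abs(x0 - np.round(x0)) > 1e-9):
        raise ValueError("SSA initial state must be non-negative integers")
    if isinstance(network.params, DevParams):
        scalar_props = _dev_scalar_propensities(network.params)
        base_L = network.params.L
    else:
        if schedule is not None:
            raise ValueError("schedules require a DevParams-backed network")
        generic = network.propensities

        def scalar_props(N, O, F, G, L):  # pragma: no cover - generic fallback
            return tuple(generic(np.array([N, O, F, G])))

        base_L = None

    rng = _rng_for(config.seed)
    exp = rng.exponential
    uni = rng.random

    varying = schedule is not None and schedule.mode != "constant"
    sub = schedule.duration / 100.0 if varying else config.t_end

    N, O, F, G = (float(v) for v in x0)
    t = 0.0
    grid = config.time_grid()
    out = np.empty((len(grid), 4))
    out[0] = (N, O, F, G)
    rec = 1
    while t < config.t_end:
        if varying and t < schedule.duration:
            t_block = min(t + sub, config.t_end)
        else:
            # control constant from here on: one exact block to the horizon
            t_block = config.t_end
        L = base_L if schedule is None else float(schedule.value(t))
        while True:
            a = scalar_props(N, O, F, G, L)
            a0 = a[0] + a[1] + a[2] + a[3] + a[4] + a[5] + a[6] + a[7]
            if a0 <= 0.0:
                t_next = t_block
            else:
                t_next = t + exp(1.0 / a0)
            if t_next >= t_block:
                t = t_block
                break
            # grid points strictly before the event see the pre-event state
            while rec < len(grid) and grid[rec] < t_next:
                out[rec] = (N, O, F, G)
                rec += 1
            t = t_next
            r = uni() * a0
            acc = 0.0
            for j in range(8):
                acc += a[j]
                if r < acc:
                    break
            if j == 0:
                N += 1
            elif j == 1:
                O += 1
            elif j == 2:
                F += 1
            elif j == 3:
                G += 1
            elif j == 4:
                N -= 1
            elif j == 5:
                O -= 1
            elif j == 6:
                F -= 1
            else:
                G -= 1
            if N < 0 or O < 0 or F < 0 or G < 0:
                raise IntegrationError("SSA produced a negative copy number")
            while rec < len(grid) and grid[rec] <= t:
                out[rec] = (N, O, F, G)  # grid point coinciding with the event
                rec += 1
        while rec < len(grid) and grid[rec] <= t + 1e-12:
            out[rec] = (N, O, F, G)
            rec += 1
    while rec < len(grid):
        out[rec] = (N, O, F, G)
        rec += 1
    return Trajectory(
        times=grid, states=out, labels=DEV_LABELS, model_id=model_id,
        seed=config.seed, schedule=schedule,
    )


# --------------------------------------------------------------------------
# Chemical Langevin
# --------------------------------------------------------------------------

def _cle_batch(params, x0s, schedule, config, rngs, noise_scale=1.0):
    S = np.zeros((4, 8))
    for i in range(4):
        S[i, i] = 1.0
        S[i, i + 4] = -1.0
    from tslandscape.models import dev_propensities

    n, d = x0s.shape
    n_steps = config.n_records * config.steps_per_record
    sqdt = math.sqrt(config.dt)
    x = x0s.copy()
    out = np.empty((n, config.n_records + 1, d))
    out[:, 0] = x
    clamps = 0
    rec = 0
    step = 0
    while step < n_steps:
        block = min(_CHUNK, n_steps - step)
        noise = np.empty((n, block, 8))
        for i, rng in enumerate(rngs):
            noise[i] = rng.standard_normal((block, 8))
        for j in range(block):
            t = (step + j) * config.dt
            p = params if schedule is None else params.replace(L=float(schedule.value(t)))
            a = dev_propensities(x, p)
            incr = (a[:, :4] - a[:, 4:]) * config.dt \
                + noise_scale * (np.sqrt(a) * noise[:, j] * sqdt) @ S.T
            x = x + incr
            neg = x < 0
            clamps += int(neg.sum())
            np.clip(x, 0.0, None, out=x)
            if (step + j + 1) % config.steps_per_record == 0:
                rec += 1
                out[:, rec] = x
        if not np.all(np.isfinite(x)):
            raise IntegrationError(f"non-finite CLE state at step <= {step + block}")
        step += block
    return config.time_grid(), out, clamps


def cle_integrate(
    network: ReactionNetwork,
    x0,
    schedule: Optional[ParameterSchedule],
    config: SimConfig,
    model_id: str = "dev-cle",
    noise_scale: float = 1.0,
) -> Trajectory:
    """Euler--Maruyama integration of the chemical Langevin approximation.

    Drift ``S a``; per-reaction noise amplitude ``sqrt(a_j)`` (scaled by
    ``noise_scale``; 0 recovers the deterministic rate equations).  States
    are clamped at zero after each step (clamp count in ``meta['clamps']``).
    """
    if not isinstance(network.params, DevParams):
        raise ValueError("cle_integrate requires a DevParams-backed network")
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("CLE initial state must be non-negative")
    rng = _rng_for(config.seed)
    times, out, clamps = _cle_batch(network.params, x0[None, :], schedule, config,
                                    [rng], noise_scale=noise_scale)
    return Trajectory(
        times=times, states=out[0], labels=DEV_LABELS, model_id=model_id,
        seed=config.seed, schedule=schedule, meta={"clamps": clamps},
    )


# --------------------------------------------------------------------------
# Ensembles and initial-condition sampling
# --------------------------------------------------------------------------

def _resolve_x0(x0, n, base_seed):
    """Per-member initial states: fixed vector, (n,d) array, or sampler."""
    if callable(x0):
        rng = _rng_for(np.random.SeedSequence(entropy=base_seed, spawn_key=(0x1C,)))
        x0s = np.asarray(x0(rng, n), dtype=float)
    else:
        x0s = np.asarray(x0, dtype=float)
        if x0s.ndim == 1:
            x0s = np.tile(x0s, (n, 1))
    if x0s.shape[0] != n:
        raise ValueError(f"expected {n} initial states, got {x0s.shape[0]}")
    return x0s


def run_ensemble(
    simulate_one: Callable[..., Trajectory],
    x0,
    schedule: Optional[ParameterSchedule],
    config: SimConfig,
    n: int,
    base_seed: int,
    model_id: str = "model",
) -> Ensemble:
    """Run ``n`` independent trajectories with derived per-member seeds.

    ``simulate_one(x0, schedule, config)`` is invoked once per member with a
    config whose seed is the member's derived :func:`member_seed`.  Member
    failures are re-raised with the member index and seed attached.
    """
    if n < 2:
        raise ValueError("an ensemble needs n >= 2 members")
    x0s = _resolve_x0(x0, n, base_seed)
    states = None
    seeds = np.empty(n, dtype=np.int64)
    times = None
    labels = None
    for i in range(n):
        seq = member_seed(base_seed, i)
        seed_i = int(seq.generate_state(1)[0])
        seeds[i] = seed_i
        cfg = SimConfig(
            t_end=config.t_end, dt=config.dt,
            record_interval=config.record_interval, seed=seed_i,
        )
        try:
            traj = simulate_one(x0s[i], schedule, cfg)
        except Exception as err:
            raise RuntimeError(
                f"ensemble member {i} (seed {seed_i}) failed: {err}"
            ) from err
        if states is None:
            times = traj.times
            labels = traj.labels
            states = np.empty((n, len(times), len(labels)))
        states[i] = traj.states
    return Ensemble(
        times=times, states=states, labels=labels, model_id=model_id,
        base_seed=base_seed, member_seeds=seeds, schedule=schedule,
    )


def _member_rngs(base_seed, n):
    rngs = []
    seeds = np.empty(n, dtype=np.int64)
    for i in range(n):
        seq = member_seed(base_seed, i)
        seeds[i] = int(seq.generate_state(1)[0])
        rngs.append(_rng_for(seeds[i]))
    return rngs, seeds


def toy_ensemble(
    params: ToyParams,
    x0,
    schedule: Optional[ParameterSchedule],
    config: SimConfig,
    n: int,
    base_seed: int,
    drift: Optional[Callable] = None,
    burn_in: float = 0.0,
) -> Ensemble:
    """Batched EM ensemble for the toy SDE (bit-identical to the loop path).

    ``burn_in`` integrates the ensemble at the schedule's initial parameter
    value for the given duration before t = 0, so ensembles start from an
    equilibrated cloud rather than a point mass.
    """
    if n < 2:
        raise ValueError("an ensemble needs n >= 2 members")
    x0s = _resolve_x0(x0, n, base_seed)
    rngs, seeds = _member_rngs(base_seed, n)
    f = drift if drift is not None else toy_em_drift(params)
    if burn_in > 0:
        pre_cfg = SimConfig(t_end=burn_in, dt=config.dt, record_interval=burn_in, seed=0)
        pre_sched = None
        if schedule is not None:
            pre_sched = ParameterSchedule.constant(schedule.name, float(schedule.value(0.0)))
        _, pre = _em_batch(f, params.sigma, x0s, pre_sched, pre_cfg, rngs, TOY_LABELS)
        x0s = pre[:, -1]
    times, out = _em_batch(f, params.sigma, x0s, schedule, config, rngs, TOY_LABELS)
    return Ensemble(
        times=times, states=out, labels=TOY_LABELS, model_id="toy",
        base_seed=base_seed, member_seeds=seeds, schedule=schedule,
        meta={"burn_in": burn_in},
    )


def cle_ensemble(
    params: DevParams,
    x0,
    schedule: Optional[ParameterSchedule],
    config: SimConfig,
    n: int,
    base_seed: int,
) -> Ensemble:
    """Batched chemical-Langevin ensemble (same seeding contract as above)."""
    if n < 2:
        raise ValueError("an ensemble needs n >= 2 members")
    x0s = _resolve_x0(x0, n, base_seed)
    rngs, seeds = _member_rngs(base_seed, n)
    times, out, clamps = _cle_batch(params, x0s, schedule, config, rngs)
    return Ensemble(
        times=times, states=out, labels=DEV_LABELS, model_id="dev-cle",
        base_seed=base_seed, member_seeds=seeds, schedule=schedule,
        meta={"clamps": clamps},
    )


def sample_box(ranges, n: int, seed, integer: bool = False) -> np.ndarray:
    """Uniform samples from an axis-aligned box.

    ``ranges`` is a sequence of ``(low, high)`` pairs, one per coordinate.
    With ``integer=True`` samples are rounded to the nearest integer (for SSA
    initial conditions).
    """
    ranges = [tuple(map(float, r)) for r in ranges]
    for lo, hi in ranges:
        if lo > hi:
            raise ValueError(f"inverted range ({lo}, {hi})")
    rng = _rng_for(seed)
    cols = [rng.uniform(lo, hi, size=n) for lo, hi in ranges]
    out = np.column_stack(cols)
    if integer:
        out = np.round(out)
    return out
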