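"""Canonical-ensemble propagation of walkers at fixed (lambda, gamma).

The default propagator is a Metropolis random-walk Monte Carlo sampler whose
stationary distribution is exactly exp(-beta U); a BAOAB-discretized Langevin
integrator is provided for dynamical realism but carries O(dt^2) bias and is
not the reference path. Each walker owns a seeded RNG stream derived from the
master seed, so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .models import ModelSystem, _wrap_angles

__all__ = [
    "WalkerState",
    "SampleRecord",
    "SampleChunk",
    "MetropolisSampler",
    "LangevinSampler",
    "PropagationError",
    "PHYSICAL",
    "DUMMY",
]

PHYSICAL = "physical"
DUMMY = "dummy"


class PropagationError(RuntimeError):
    """Non-finite energy encountered during propagation."""


@dataclass
class WalkerState:
    """Complete state of one walker: the unit replica exchange swaps wholesale."""

    coords: np.ndarray
    lam_index: int = 0
    gamma_state: str = PHYSICAL
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    velocities: Optional[np.ndarray] = None
    step: int = 0  # cumulative propagation steps taken by this walker

    @property
    def gamma(self) -> float:
        return 1.0 if self.gamma_state == PHYSICAL else 0.0

    def copy(self) -> "WalkerState":
        return WalkerState(
            coords=self.coords.copy(),
            lam_index=self.lam_index,
            gamma_state=self.gamma_state,
            rng=self.rng,
            velocities=None if self.velocities is None else self.velocities.copy(),
            step=self.step,
        )


class SampleRecord(NamedTuple):
    step: int
    lam_index: int
    gamma_state: str
    dudl_value: float
    u_value: float


@dataclass
class SampleChunk:
    """A contiguous run of samples at fixed (window, gamma-state)."""

    steps: np.ndarray
    lam_index: int
    gamma_state: str
    dudl: np.ndarray
    u: np.ndarray

    def records(self) -> list[SampleRecord]:
        return [SampleRecord(int(s), self.lam_index, self.gamma_state, float(d), float(u))
                for s, d, u in zip(self.steps, self.dudl, self.u)]


class MetropolisSampler:
    """Random-walk Metropolis Monte Carlo with exact Boltzmann stationarity.

    Proposals are isotropic Gaussian displacements of scale ``step_size``;
    acceptance is min(1, exp(-beta dU)). One sample (dU/dlambda and U) is
    recorded every ``record_interval`` steps.
    """

    name = "metropolis"

    def __init__(self, beta: float = 1.0, step_size: float = 0.5,
                 record_interval: int = 1):
        if beta <= 0:
            raise ValueError("beta must be positive")
        if step_size <= 0:
            raise ValueError("step_size must be positive")
        if record_interval < 1:
            raise ValueError("record_interval must be >= 1")
        self.beta = float(beta)
        self.step_size = float(step_size)
        self.record_interval = int(record_interval)
        self.n_accepted = 0
        self.n_attempted = 0

    def propagate(self, state: WalkerState, model: ModelSystem, n_steps: int,
                  lam: float, gamma: float | None = None,
                  gamma_follows_lambda: bool = False) -> SampleChunk:
        """Advance ``n_steps``; mutates ``state`` in place, returns the samples."""
        if n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if gamma is None:
            gamma = state.gamma
        x = model._check_coords(state.coords)
        model._check_domain(lam, "lam")
        model._check_domain(gamma, "gamma")
        rec = self.record_interval
        n_rec = n_steps // rec
        dudl_out = np.empty(n_rec)
        u_out = np.empty(n_rec)
        if n_steps == 0:
            return SampleChunk(np.empty(0, dtype=np.int64), state.lam_index,
                               state.gamma_state, dudl_out, u_out)

        rng = state.rng
        disp = rng.normal(scale=self.step_size, size=(n_steps, x.size))
        logu = np.log(rng.random(n_steps))
        beta = self.beta
        periodic = model.periodic
        energy = model._energy
        dudl = model._dudl
        u_cur = energy(x, lam, gamma)
        if not math.isfinite(u_cur):
            raise PropagationError(
                f"non-finite energy at step {state.step} (before propagation)")
        n_acc = 0
        j = 0
        for t in range(n_steps):
            xp = x + disp[t]
            if periodic:
                xp = _wrap_angles(xp)
            up = energy(xp, lam, gamma)
            if not math.isfinite(up):
                raise PropagationError(
                    f"non-finite energy at step {state.step + t + 1}")
            if logu[t] <= -beta * (up - u_cur):
                x = xp
                u_cur = up
                n_acc += 1
            if (t + 1) % rec == 0:
                d = dudl(x, lam, gamma)
                if gamma_follows_lambda:
                    d += model._scaled_torsion_energy(x)
                dudl_out[j] = d
                u_out[j] = u_cur
                j += 1
        steps = state.step + rec * np.arange(1, n_rec + 1, dtype=np.int64)
        state.coords = x
        state.step += n_steps
        self.n_accepted += n_acc
        self.n_attempted += n_steps
        return SampleChunk(steps, state.lam_index, state.gamma_state,
                           dudl_out, u_out)

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_attempted if self.n_attempted else math.nan


class LangevinSampler:
    """BAOAB-splitting Langevin integrator (approximate; O(dt^2) bias).

    Provided for dynamical realism; the Metropolis sampler is the reference
    path because its stationary distribution is exact.
    """

    name = "langevin"

    def __init__(self, beta: float = 1.0, dt: float = 0.05,
                 friction: float = 1.0, record_interval: int = 1):
        if beta <= 0 or dt <= 0 or friction <= 0:
            raise ValueError("beta, dt and friction must be positive")
        if record_interval < 1:
            raise ValueError("record_interval must be >= 1")
        self.beta = float(beta)
        self.dt = float(dt)
        self.friction = float(friction)
        self.record_interval = int(record_interval)

    def propagate(self, state: WalkerState, model: ModelSystem, n_steps: int,
                  lam: float, gamma: float | None = None,
                  gamma_follows_lambda: bool = False) -> SampleChunk:
        if n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if gamma is None:
            gamma = state.gamma
        x = model._check_coords(state.coords).copy()
        model._check_domain(lam, "lam")
        model._check_domain(gamma, "gamma")
        rng = state.rng
        if state.velocities is None:
            state.velocities = rng.normal(scale=1.0 / math.sqrt(self.beta),
                                          size=x.size)
        v = state.velocities.copy()
        dt = self.dt
        c1 = math.exp(-self.friction * dt)
        c2 = math.sqrt((1.0 - c1 * c1) / self.beta)  # unit mass
        rec = self.record_interval
        n_rec = n_steps // rec
        dudl_out = np.empty(n_rec)
        u_out = np.empty(n_rec)
        noise = rng.normal(size=(n_steps, x.size))
        f = -model._gradient(x, lam, gamma)
        j = 0
        for t in range(n_steps):
            v += 0.5 * dt * f
            x += 0.5 * dt * v
            v = c1 * v + c2 * noise[t]
            x += 0.5 * dt * v
            if model.periodic:
                x = _wrap_angles(x)
            f = -model._gradient(x, lam, gamma)
            v += 0.5 * dt * f
            if (t + 1) % rec == 0:
                u_cur = model._energy(x, lam, gamma)
                if not math.isfinite(u_cur):
                    raise PropagationError(
                        f"non-finite energy at step {state.step + t + 1}")
                d = model._dudl(x, lam, gamma)
                if gamma_follows_lambda:
                    d += model._scaled_torsion_energy(x)
                dudl_out[j] = d
                u_out[j] = u_cur
                j += 1
        steps = state.step + rec * np.arange(1, n_rec + 1, dtype=np.int64)
        state.coords = x
        state.velocities = v
        state.step += n_steps
        return SampleChunk(steps, state.lam_index, state.gamma_state,
                           dudl_out, u_out)


def make_rng_streams(master_seed: int, n_streams: int) -> list[np.random.Generator]:
    """Independent per-replica RNG streams derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [np.random.default_rng(child) for child in ss.spawn(n_streams)]
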