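"""Serial tempering along the alchemical coordinate.

A single walker alternates configurational sampling at fixed lambda with
heat-bath Monte Carlo jumps between lambda windows, biased by per-window
free-energy offsets F_i so that, once the bias has converged, every window
is visited with equal probability (the flat-histogram design goal).

The bias is the negative running integral of the mean generalized force
<dU/dlambda>, accumulated by composite Simpson quadrature on the uniform
lambda grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .models import ModelSystem
from .sampler import SampleChunk, WalkerState

__all__ = [
    "LambdaGrid",
    "BiasProfile",
    "sequential_scan",
    "build_bias_simpson",
    "jump_log_weights",
    "heat_bath_probabilities",
    "heat_bath_jump",
    "ConfigurationError",
]

log = logging.getLogger(__name__)

#: probabilities below this are treated as exactly zero
_PROB_FLOOR = 1e-300


class ConfigurationError(ValueError):
    """Invalid grid / engine configuration."""


@dataclass(frozen=True)
class LambdaGrid:
    """Uniformly spaced alchemical windows covering [0, 1]."""

    n_windows: int = 101

    def __post_init__(self):
        if self.n_windows < 2:
            raise ConfigurationError("need at least 2 lambda windows")

    @property
    def delta_lambda(self) -> float:
        return 1.0 / (self.n_windows - 1)

    @property
    def values(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_windows)


@dataclass
class BiasProfile:
    """Per-window bias free energies F_i (kT), gauge-fixed at F_0 = 0."""

    f_values: np.ndarray
    source: str = "prescan"

    def __post_init__(self):
        self.f_values = np.asarray(self.f_values, dtype=float)
        if not np.isfinite(self.f_values).all():
            raise ConfigurationError("bias profile contains non-finite entries")

    @classmethod
    def zeros(cls, n_windows: int) -> "BiasProfile":
        return cls(np.zeros(n_windows), source="flat")


def sequential_scan(model: ModelSystem, grid: LambdaGrid, sampler,
                    state: WalkerState, steps_per_window: int,
                    tracker=None, gamma_follows_lambda: bool = False,
                    ) -> tuple[np.ndarray, np.ndarray, list[SampleChunk]]:
    """Phase 1: visit windows 0..n-1 in order, once each, sampling at each.

    Returns per-window mean dU/dlambda, per-window recorded sample counts,
    and the sample chunks (so the scan data enter the running statistics).
    """
    if steps_per_window < 1:
        raise ConfigurationError("steps_per_window must be >= 1")
    n = grid.n_windows
    lam_values = grid.values
    means = np.empty(n)
    counts = np.empty(n, dtype=np.int64)
    chunks: list[SampleChunk] = []
    for i in range(n):
        state.lam_index = i
        gamma = lam_values[i] if gamma_follows_lambda else state.gamma
        try:
            chunk = sampler.propagate(state, model, steps_per_window,
                                      lam_values[i], gamma,
                                      gamma_follows_lambda=gamma_follows_lambda)
        except Exception as exc:
            raise type(exc)(f"window {i}: {exc}") from exc
        means[i] = chunk.dudl.mean() if chunk.dudl.size else np.nan
        counts[i] = chunk.dudl.size
        chunks.append(chunk)
        if tracker is not None and chunk.gamma_state == "physical":
            tracker.update_batch(i, chunk.dudl)
    return means, counts, chunks


def build_bias_simpson(dudl_means: np.ndarray, grid: LambdaGrid) -> BiasProfile:
    """Bias as the negative Simpson-rule running integral of <dU/dlambda>.

    F_0 = 0 (gauge); F_1 closes the two-point start by the trapezoid rule;
    F_i = F_{i-2} - (dl/3)(y_{i-2} + 4 y_{i-1} + y_i) for i >= 2.
    """
    y = np.asarray(dudl_means, dtype=float)
    if y.shape != (grid.n_windows,):
        raise ConfigurationError(
            f"means vector length {y.size} != n_windows {grid.n_windows}")
    if grid.n_windows < 3:
        raise ConfigurationError("Simpson bias needs at least 3 windows")
    if not np.isfinite(y).all():
        raise ConfigurationError("dU/dlambda means contain non-finite entries")
    dl = grid.delta_lambda
    f = np.empty_like(y)
    f[0] = 0.0
    f[1] = -0.5 * dl * (y[0] + y[1])
    for i in range(2, y.size):
        f[i] = f[i - 2] - dl / 3.0 * (y[i - 2] + 4.0 * y[i - 1] + y[i])
    return BiasProfile(f, source="running-update")


def jump_log_weights(state: WalkerState, model: ModelSystem, grid: LambdaGrid,
                     bias: BiasProfile, beta: float = 1.0,
                     gamma_follows_lambda: bool = False) -> np.ndarray:
    """Log-probability of each candidate window given the frozen coordinates.

    logP(lam_j) = -beta [U(r, lam_j) - U(r, lam_i) + F_j - F_i]; the entry
    at the current window i is exactly zero.
    """
    i = state.lam_index
    if not 0 <= i < grid.n_windows:
        raise ConfigurationError(f"current window {i} outside grid")
    if gamma_follows_lambda:
        u_all = np.array([model.potential_energy(state.coords, l, l)
                          for l in grid.values])
    else:
        u_all = model.potential_energy_grid(state.coords, grid.values,
                                            state.gamma)
    logw = -beta * ((u_all - u_all[i]) + (bias.f_values - bias.f_values[i]))
    bad = ~np.isfinite(logw)
    if bad.any():
        log.warning("non-finite jump weights at windows %s; set to -inf",
                    np.nonzero(bad)[0].tolist())
        logw[bad] = -np.inf
    return logw


def heat_bath_probabilities(log_weights: np.ndarray, current_index: int,
                            target_weights: np.ndarray | None = None,
                            ) -> np.ndarray:
    """Normalized jump probabilities over candidates k != current.

    Optionally multiplies by the variance-adaptive ratio
    P_target(j)/P_target(i) before renormalizing. Computed with
    max-subtraction for overflow safety; the entry at ``current_index``
    is 0 (the printed heat-bath formula excludes the current state).
    """
    logw = np.asarray(log_weights, dtype=float).copy()
    n = logw.size
    if n < 2:
        raise ConfigurationError("need at least 2 windows to jump")
    if not 0 <= current_index < n:
        raise ConfigurationError("current_index outside the weight vector")
    if target_weights is not None:
        t = np.asarray(target_weights, dtype=float)
        if t[current_index] <= 0:
            raise AssertionError(
                "zero target probability at the current window; "
                "the floor rule should make this impossible")
        with np.errstate(divide="ignore"):
            logw = logw + np.log(t) - np.log(t[current_index])
    logw[current_index] = -np.inf
    m = logw.max()
    if not np.isfinite(m):
        return np.zeros(n)
    p = np.exp(logw - m)
    p[p < _PROB_FLOOR] = 0.0
    total = p.sum()
    if total <= 0.0:
        return np.zeros(n)
    return p / total


def heat_bath_jump(log_weights: np.ndarray, current_index: int,
                   rng: np.random.Generator,
                   target_weights: np.ndarray | None = None) -> int:
    """Sample the next window from the heat-bath distribution (forced move).

    If every candidate weight is -inf the jump is declined and the current
    index returned unchanged.
    """
    p = heat_bath_probabilities(log_weights, current_index, target_weights)
    total = p.sum()
    if total <= 0.0:
        log.warning("all candidate jump weights vanished; jump declined at "
                    "window %d", current_index)
        return current_index
    # inverse-CDF draw; p sums to 1 by construction
    idx = int(np.searchsorted(np.cumsum(p), rng.random(), side="right"))
    return min(idx, p.size - 1)
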