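"""Replica exchange and physical/dummy Hamiltonian exchange.

Two exchange moves live here:

* **Replica exchange (RE)** between concurrently running serial-tempering
  simulations: a Metropolis swap of the entire walker state (coordinates,
  velocities, window index) between a pair of replicas, accepted on the
  true potential energies only — no bias terms enter the criterion.
* **Hamiltonian exchange with torsion scaling (ACES)**: each walker carries
  a gamma-state label, physical (gamma = 1) or dummy (gamma = 0, torsional
  barriers removed); a Metropolis flip of that label at fixed coordinates
  lets conformational diversity harvested in the barrier-free state flow
  into the physical ensemble. Free energies are integrated along the
  physical coordinate only, so dummy-state samples are flagged and excluded
  downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .models import ModelSystem
from .sampler import DUMMY, PHYSICAL, WalkerState
from .st_engine import ConfigurationError, LambdaGrid

__all__ = [
    "ReplicaEnsemble",
    "replica_exchange_attempt",
    "pair_schedule",
    "aces_exchange_attempt",
]

log = logging.getLogger(__name__)


@dataclass
class PairCounter:
    attempts: int = 0
    accepts: int = 0

    @property
    def acceptance_rate(self) -> float:
        return self.accepts / self.attempts if self.attempts else math.nan


@dataclass
class ReplicaEnsemble:
    """Bookkeeping for a set of concurrently running replicas."""

    replicas: list[WalkerState]
    pairing_scheme: str = "fixed"
    exchange_interval: int = 100
    counters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.exchange_interval < 1:
            raise ConfigurationError("exchange interval must be >= 1")

    def counter(self, pair: tuple[int, int]) -> PairCounter:
        return self.counters.setdefault(pair, PairCounter())

    @property
    def acceptance_rates(self) -> dict:
        return {pair: c.acceptance_rate for pair, c in sorted(self.counters.items())}


def replica_exchange_attempt(state_m: WalkerState, state_n: WalkerState,
                             model: ModelSystem, grid: LambdaGrid,
                             beta: float, rng: np.random.Generator,
                             swap: str = "full",
                             ) -> tuple[WalkerState, WalkerState, bool]:
    """Metropolis exchange between two replicas.

    Acceptance min(1, exp(-beta dU)) with
    dU = U(r_n, lam_m) + U(r_m, lam_n) - U(r_m, lam_m) - U(r_n, lam_n),
    evaluated on the true potential energies (each walker keeps its own
    gamma-state). ``swap="full"`` exchanges the entire states (coordinates,
    velocities, window index) as the serial-tempering RE does;
    ``swap="coords"`` exchanges configurations only, leaving each window
    slot in place (the fixed-ladder Hamiltonian exchange used by the
    reference TI runner). Non-finite cross energies reject the attempt.
    """
    lam = grid.values
    lm, ln = lam[state_m.lam_index], lam[state_n.lam_index]
    u_mm = model.potential_energy(state_m.coords, lm, state_m.gamma)
    u_nn = model.potential_energy(state_n.coords, ln, state_n.gamma)
    u_nm = model.potential_energy(state_n.coords, lm, state_n.gamma)
    u_mn = model.potential_energy(state_m.coords, ln, state_m.gamma)
    du = u_nm + u_mn - u_mm - u_nn
    if not math.isfinite(du):
        log.warning("non-finite exchange energy between windows %d and %d; "
                    "attempt rejected", state_m.lam_index, state_n.lam_index)
        return state_m, state_n, False
    accepted = du <= 0.0 or rng.random() < math.exp(-beta * du)
    if accepted:
        if swap == "full":
            # whole states swap; each replica slot keeps its own RNG stream
            state_m.coords, state_n.coords = state_n.coords, state_m.coords
            state_m.velocities, state_n.velocities = \
                state_n.velocities, state_m.velocities
            state_m.lam_index, state_n.lam_index = \
                state_n.lam_index, state_m.lam_index
            state_m.gamma_state, state_n.gamma_state = \
                state_n.gamma_state, state_m.gamma_state
        elif swap == "coords":
            state_m.coords, state_n.coords = state_n.coords, state_m.coords
            state_m.velocities, state_n.velocities = \
                state_n.velocities, state_m.velocities
        else:
            raise ConfigurationError(f"unknown swap mode {swap!r}")
    return state_m, state_n, accepted


def pair_schedule(n_replicas: int, round_index: int = 0,
                  scheme: str = "fixed") -> list[tuple[int, int]]:
    """Disjoint replica pairs for one exchange round.

    "fixed" pairs (0,1),(2,3),... every round; "alternating" interleaves
    (1,2),(3,4),... on odd rounds so swaps can percolate along the ensemble.
    """
    if n_replicas < 2:
        raise ConfigurationError("replica exchange needs >= 2 replicas")
    if scheme == "fixed":
        start = 0
    elif scheme == "alternating":
        start = round_index % 2
    else:
        raise ConfigurationError(f"unknown pairing scheme {scheme!r}")
    return [(i, i + 1) for i in range(start, n_replicas - 1, 2)]


def aces_exchange_attempt(state: WalkerState, model: ModelSystem,
                          grid: LambdaGrid, beta: float,
                          rng: np.random.Generator,
                          ) -> tuple[WalkerState, bool]:
    """Metropolis flip of the gamma-state (physical <-> dummy) at fixed r.

    dU = U(r, lam, gamma_new) - U(r, lam, gamma_old); removing torsional
    energy (physical -> dummy away from a minimum) is always accepted,
    reinstating it atop a barrier is suppressed by exp(-beta dU).
    """
    if not model.has_torsions:
        raise ConfigurationError(
            f"model {model.name!r} has no torsions to scale; "
            "ACES requires a torsional model")
    lam = grid.values[state.lam_index]
    new_state = DUMMY if state.gamma_state == PHYSICAL else PHYSICAL
    gamma_new = 1.0 if new_state == PHYSICAL else 0.0
    u_old = model.potential_energy(state.coords, lam, state.gamma)
    u_new = model.potential_energy(state.coords, lam, gamma_new)
    du = u_new - u_old
    if not math.isfinite(du):
        log.warning("non-finite gamma-flip energy; attempt rejected")
        return state, False
    accepted = du <= 0.0 or rng.random() < math.exp(-beta * du)
    if accepted:
        state.gamma_state = new_state
    return state, accepted
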