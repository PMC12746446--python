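"""Analytic model systems for alchemical free energy calculations.

Each model exposes a reduced-unit potential energy ``U(r, lambda, gamma)``
(in kT at beta = 1), its alchemical derivative dU/dlambda, and — where a
closed form exists — the exact Helmholtz free energy difference between
lambda states, which serves as the oracle for every downstream estimator.

The alchemical coordinate ``lam`` in [0, 1] interpolates between end-state
Hamiltonians; the enhanced-sampling coordinate ``gamma`` in [0, 1] scales
selected torsional terms (gamma = 0 removes the barriers entirely, the
"dummy" state; gamma = 1 is the physical Hamiltonian).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.integrate import quad

__all__ = [
    "ModelSystem",
    "HarmonicOscillator",
    "ChargingToy",
    "TorsionChain",
    "build_model",
    "MODEL_REGISTRY",
]


class ModelError(ValueError):
    """Invalid model input (dimension mismatch or out-of-domain parameter)."""


class AnalyticUnavailable(Exception):
    """Raised when a model has no closed-form free energy oracle."""


def _wrap_angles(x: np.ndarray) -> np.ndarray:
    """Wrap periodic coordinates to (-pi, pi]."""
    return np.pi - np.mod(np.pi - x, 2.0 * np.pi)


class ModelSystem:
    """Base class: a pluggable Hamiltonian U(r, lambda, gamma).

    Subclasses implement the unchecked kernels ``_energy`` / ``_dudl`` (and
    optionally vectorized-over-lambda ``_energy_grid``); the public methods
    validate inputs. Hot loops may call the kernels directly after a single
    up-front validation.
    """

    name: str = "model"
    dimension: int = 1
    periodic: bool = False
    has_analytic_dg: bool = False
    has_torsions: bool = False

    # -- public validated surface -------------------------------------

    def potential_energy(self, coords, lam: float, gamma: float = 1.0) -> float:
        coords = self._check_coords(coords)
        self._check_domain(lam, "lam")
        self._check_domain(gamma, "gamma")
        return float(self._energy(coords, lam, gamma))

    def dudl(self, coords, lam: float, gamma: float = 1.0,
             gamma_follows_lambda: bool = False) -> float:
        """dU/dlambda at fixed coordinates.

        With the two-state (physical/dummy) scheme gamma is held fixed and
        does not contribute. Under the direct mapping gamma(lambda) = lambda
        the scaled torsional energy rides lambda and its derivative is added
        (``gamma_follows_lambda=True``).
        """
        coords = self._check_coords(coords)
        self._check_domain(lam, "lam")
        self._check_domain(gamma, "gamma")
        val = float(self._dudl(coords, lam, gamma))
        if gamma_follows_lambda:
            val += float(self._scaled_torsion_energy(coords))
        return val

    def analytic_dg(self, lam_a: float, lam_b: float, beta: float = 1.0) -> float:
        """Exact free energy difference G(lam_b) - G(lam_a) in kT."""
        if not self.has_analytic_dg:
            raise AnalyticUnavailable(f"model {self.name!r} has no analytic dG")
        self._check_domain(lam_a, "lam_a")
        self._check_domain(lam_b, "lam_b")
        return self._analytic_g(lam_b, beta) - self._analytic_g(lam_a, beta)

    def potential_energy_grid(self, coords, lam_values: np.ndarray,
                              gamma: float = 1.0) -> np.ndarray:
        """U(r, lambda_k, gamma) for every lambda on a grid (vectorized)."""
        coords = self._check_coords(coords)
        self._check_domain(gamma, "gamma")
        return self._energy_grid(coords, np.asarray(lam_values, dtype=float), gamma)

    def initial_coords(self) -> np.ndarray:
        return np.zeros(self.dimension)

    # -- kernels --------------------------------------------------------

    def _energy(self, coords: np.ndarray, lam: float, gamma: float) -> float:
        raise NotImplementedError

    def _dudl(self, coords: np.ndarray, lam: float, gamma: float) -> float:
        raise NotImplementedError

    def _gradient(self, coords: np.ndarray, lam: float, gamma: float) -> np.ndarray:
        # generic centered finite difference; subclasses override analytically
        h = 1e-6
        g = np.empty_like(coords)
        for i in range(coords.size):
            xp = coords.copy(); xp[i] += h
            xm = coords.copy(); xm[i] -= h
            g[i] = (self._energy(xp, lam, gamma) - self._energy(xm, lam, gamma)) / (2 * h)
        return g

    def _energy_grid(self, coords: np.ndarray, lam_values: np.ndarray,
                     gamma: float) -> np.ndarray:
        return np.array([self._energy(coords, l, gamma) for l in lam_values])

    def _scaled_torsion_energy(self, coords: np.ndarray) -> float:
        """Unscaled sum of the gamma-subject torsional terms (0 if none)."""
        return 0.0

    def _analytic_g(self, lam: float, beta: float) -> float:
        raise AnalyticUnavailable(self.name)

    # -- validation -----------------------------------------------------

    def _check_coords(self, coords) -> np.ndarray:
        coords = np.atleast_1d(np.asarray(coords, dtype=float))
        if coords.shape != (self.dimension,):
            raise ModelError(
                f"model {self.name!r} expects {self.dimension} coordinate(s), "
                f"got shape {coords.shape}")
        return coords

    @staticmethod
    def _check_domain(value: float, label: str) -> None:
        if not 0.0 <= value <= 1.0:
            raise ModelError(f"{label} = {value} outside [0, 1]")


class HarmonicOscillator(ModelSystem):
    """lambda-coupled harmonic well: U = 1/2 k(lam) |x|^2.

    k(lam) = (1 - lam) k0 + lam k1. The partition function is Gaussian, so
    beta G(lam) = (d/2) ln k(lam) up to a lambda-independent constant, and
    dG(0 -> 1) = d/(2 beta) ln(k1/k0).
    """

    name = "harmonic"
    has_analytic_dg = True

    def __init__(self, k0: float = 1.0, k1: float = 4.0, dimension: int = 1):
        if k0 <= 0 or k1 <= 0:
            raise ModelError("spring constants must be positive")
        self.k0 = float(k0)
        self.k1 = float(k1)
        self.dimension = int(dimension)

    def spring(self, lam: float) -> float:
        return (1.0 - lam) * self.k0 + lam * self.k1

    def _energy(self, coords, lam, gamma):
        return 0.5 * self.spring(lam) * float(coords @ coords)

    def _dudl(self, coords, lam, gamma):
        return 0.5 * (self.k1 - self.k0) * float(coords @ coords)

    def _gradient(self, coords, lam, gamma):
        return self.spring(lam) * coords

    def _energy_grid(self, coords, lam_values, gamma):
        k = (1.0 - lam_values) * self.k0 + lam_values * self.k1
        return 0.5 * k * float(coords @ coords)

    def _analytic_g(self, lam, beta):
        return self.dimension / (2.0 * beta) * math.log(self.spring(lam))

    # closed-form conditional moments of dU/dlambda under the Boltzmann
    # distribution at fixed lambda — oracles for scan/bias/VAR tests
    def analytic_dudl_mean(self, lam: float, beta: float = 1.0) -> float:
        return self.dimension * (self.k1 - self.k0) / (2.0 * beta * self.spring(lam))

    def analytic_dudl_var(self, lam: float, beta: float = 1.0) -> float:
        k = self.spring(lam)
        return self.dimension * (self.k1 - self.k0) ** 2 / (2.0 * beta ** 2 * k ** 2)


class ChargingToy(ModelSystem):
    """Heterogeneous-variance charging toy: U = 1/2 k(lam) x^2 + lam c x.

    A 1-D particle whose spring stiffens with lambda while a linear
    "charging" field switches on. Completing the square gives the exact
    free energy beta G(lam) = 1/2 ln k(lam) - beta lam^2 c^2 / (2 k(lam))
    (constants dropped), and Var(dU/dlambda) varies strongly along lambda,
    which is what the variance-adaptive component feeds on.
    """

    name = "charging"
    dimension = 1
    has_analytic_dg = True

    def __init__(self, k0: float = 1.0, k1: float = 4.0, c: float = 2.0):
        if k0 <= 0 or k1 <= 0:
            raise ModelError("spring constants must be positive")
        self.k0 = float(k0)
        self.k1 = float(k1)
        self.c = float(c)

    def spring(self, lam: float) -> float:
        return (1.0 - lam) * self.k0 + lam * self.k1

    def _energy(self, coords, lam, gamma):
        x = float(coords[0])
        return 0.5 * self.spring(lam) * x * x + lam * self.c * x

    def _dudl(self, coords, lam, gamma):
        x = float(coords[0])
        return 0.5 * (self.k1 - self.k0) * x * x + self.c * x

    def _gradient(self, coords, lam, gamma):
        return self.spring(lam) * coords + lam * self.c

    def _energy_grid(self, coords, lam_values, gamma):
        x = float(coords[0])
        k = (1.0 - lam_values) * self.k0 + lam_values * self.k1
        return 0.5 * k * x * x + lam_values * self.c * x

    def _analytic_g(self, lam, beta):
        k = self.spring(lam)
        return 0.5 * math.log(k) / beta - beta * lam ** 2 * self.c ** 2 / (2.0 * k)

    def analytic_dudl_mean(self, lam: float, beta: float = 1.0) -> float:
        k = self.spring(lam)
        mu = -lam * self.c / k          # Gaussian mean of x
        s2 = 1.0 / (beta * k)           # Gaussian variance of x
        dk = 0.5 * (self.k1 - self.k0)
        return dk * (s2 + mu * mu) + self.c * mu

    def analytic_dudl_var(self, lam: float, beta: float = 1.0) -> float:
        k = self.spring(lam)
        mu = -lam * self.c / k
        s2 = 1.0 / (beta * k)
        dk = 0.5 * (self.k1 - self.k0)
        # dU/dl = dk x^2 + c x with Gaussian x
        var_x2 = 2.0 * s2 ** 2 + 4.0 * mu ** 2 * s2
        cov_x2_x = 2.0 * mu * s2
        return dk ** 2 * var_x2 + self.c ** 2 * s2 + 2.0 * dk * self.c * cov_x2_x


class TorsionChain(ModelSystem):
    """Chain of torsion angles with gamma-scalable cosine barriers.

    U = sum_j g_j (V_j/2)(1 + cos(n_j theta_j - delta_j))
        + 1/2 k(lam) s^2,        s = sum_j cos(theta_j)

    where g_j = gamma for the angles listed in ``scaled`` and 1 otherwise
    (selective torsion scaling: one index emulates sACES, several emulate
    mACES). The collective coordinate s couples the angles to lambda so
    dU/dlambda is nontrivial; with multiplicity n_j = 2 and phase pi the
    single-angle chain is a symmetric double well (minima at 0 and pi,
    barrier V_j at +-pi/2) — the kinetic-trap testbed for enhanced sampling.
    The single-angle chain has a deterministic quadrature oracle for dG.
    """

    name = "torsion"
    periodic = True
    has_torsions = True

    def __init__(self, torsions: Sequence[tuple] = ((10.0, 2, math.pi),),
                 scaled: Sequence[int] | None = None,
                 k0: float = 1.0, k1: float = 1.0):
        self.torsions = [(float(v), int(n), float(d)) for v, n, d in torsions]
        self.dimension = len(self.torsions)
        if self.dimension == 0:
            raise ModelError("torsion chain needs at least one angle")
        self.scaled = tuple(range(self.dimension)) if scaled is None else tuple(scaled)
        if any(j < 0 or j >= self.dimension for j in self.scaled):
            raise ModelError("scaled torsion index out of range")
        if k0 < 0 or k1 < 0:  # zero switches the collective coupling off
            raise ModelError("spring constants must be nonnegative")
        self.k0 = float(k0)
        self.k1 = float(k1)
        self.has_analytic_dg = self.dimension == 1

    def spring(self, lam: float) -> float:
        return (1.0 - lam) * self.k0 + lam * self.k1

    def _torsion_terms(self, coords) -> np.ndarray:
        out = np.empty(self.dimension)
        for j, (v, n, d) in enumerate(self.torsions):
            out[j] = 0.5 * v * (1.0 + math.cos(n * float(coords[j]) - d))
        return out

    def _energy(self, coords, lam, gamma):
        terms = self._torsion_terms(coords)
        scale = np.ones(self.dimension)
        scale[list(self.scaled)] = gamma
        s = float(np.cos(coords).sum())
        return float(terms @ scale) + 0.5 * self.spring(lam) * s * s

    def _dudl(self, coords, lam, gamma):
        s = float(np.cos(coords).sum())
        return 0.5 * (self.k1 - self.k0) * s * s

    def _scaled_torsion_energy(self, coords):
        terms = self._torsion_terms(coords)
        return float(terms[list(self.scaled)].sum())

    def _gradient(self, coords, lam, gamma):
        g = np.empty(self.dimension)
        s = float(np.cos(coords).sum())
        k = self.spring(lam)
        for j, (v, n, d) in enumerate(self.torsions):
            gj = gamma if j in self.scaled else 1.0
            g[j] = (-0.5 * gj * v * n * math.sin(n * float(coords[j]) - d)
                    - k * s * math.sin(float(coords[j])))
        return g

    def _energy_grid(self, coords, lam_values, gamma):
        terms = self._torsion_terms(coords)
        scale = np.ones(self.dimension)
        scale[list(self.scaled)] = gamma
        s = float(np.cos(coords).sum())
        k = (1.0 - lam_values) * self.k0 + lam_values * self.k1
        return float(terms @ scale) + 0.5 * k * s * s

    def _analytic_g(self, lam, beta):
        if self.dimension != 1:
            raise AnalyticUnavailable("torsion chain oracle is 1-D only")
        v, n, d = self.torsions[0]
        k = self.spring(lam)

        def boltz(theta):  # physical state, gamma = 1
            u = 0.5 * v * (1.0 + math.cos(n * theta - d)) \
                + 0.5 * k * math.cos(theta) ** 2
            return math.exp(-beta * u)

        z, _ = quad(boltz, -math.pi, math.pi, limit=200)
        return -math.log(z) / beta

    def initial_coords(self) -> np.ndarray:
        return np.zeros(self.dimension)


MODEL_REGISTRY = {
    "harmonic": HarmonicOscillator,
    "charging": ChargingToy,
    "torsion": TorsionChain,
}


def build_model(name: str, params: dict | None = None) -> ModelSystem:
    """Instantiate a registered model system by name."""
    try:
        cls = MODEL_REGISTRY[name]
    except KeyError:
        raise ModelError(f"unknown model {name!r}; "
                         f"known: {sorted(MODEL_REGISTRY)}") from None
    return cls(**(params or {}))
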