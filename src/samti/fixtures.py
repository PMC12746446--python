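"""Synthetic dU/dlambda time-series generators with known ground truth.

These generators produce the deterministic inputs for the diagnostics
stack: i.i.d. series (g = 1), AR(1) series with statistical inefficiency
g = (1 + phi)/(1 - phi), and a set of replicate means in which half the
replicates are trapped in one well of a bimodal observable — a positive
control that must trip the sampling-quality flag.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["generate_fixture", "ar1_series"]


def ar1_series(phi: float, n: int, rng: np.random.Generator,
               sigma: float = 1.0, mu: float = 0.0) -> np.ndarray:
    """Stationary AR(1): X_t = mu + phi (X_{t-1} - mu) + eps_t.

    Innovations are scaled so the marginal standard deviation is ``sigma``;
    the integrated autocorrelation gives g = (1 + phi)/(1 - phi).
    """
    if not abs(phi) < 1:
        raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
    if n < 1:
        raise ValueError("need at least one sample")
    eps = rng.normal(scale=sigma * np.sqrt(1.0 - phi * phi), size=n)
    x = np.empty(n)
    x[0] = rng.normal(scale=sigma)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return mu + x


def generate_fixture(kind: str, params: dict | None = None, seed: int = 0,
                     path=None) -> pd.DataFrame:
    """Deterministic synthetic series for stand-alone diagnostic analysis.

    kinds:
      ``iid``                  — white noise; columns (step, dudl);
                                 truth: g = 1, SE = sigma/sqrt(N).
      ``ar1``                  — AR(1) with coefficient phi; truth:
                                 g = (1+phi)/(1-phi).
      ``dual_well_replicates`` — per-replicate series where ``n_trapped``
                                 replicates sample only the +separation/2
                                 well and the rest mix both wells; truth:
                                 quality ratio far above 2 (severe flag).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "iid":
        n = int(params.pop("n", 100_000))
        sigma = float(params.pop("sigma", 1.0))
        mu = float(params.pop("mu", 0.0))
        _reject_extras(kind, params)
        frame = pd.DataFrame({"step": np.arange(n),
                              "dudl": rng.normal(mu, sigma, size=n)})
    elif kind == "ar1":
        n = int(params.pop("n", 100_000))
        phi = float(params.pop("phi", 0.9))
        sigma = float(params.pop("sigma", 1.0))
        mu = float(params.pop("mu", 0.0))
        _reject_extras(kind, params)
        frame = pd.DataFrame({"step": np.arange(n),
                              "dudl": ar1_series(phi, n, rng, sigma, mu)})
    elif kind == "dual_well_replicates":
        n = int(params.pop("n", 2000))
        n_replicates = int(params.pop("n_replicates", 8))
        n_trapped = int(params.pop("n_trapped", 4))
        separation = float(params.pop("separation", 10.0))
        sigma = float(params.pop("sigma", 1.0))
        _reject_extras(kind, params)
        if not 0 <= n_trapped <= n_replicates:
            raise ValueError("n_trapped must be within the replicate count")
        parts = []
        for r in range(n_replicates):
            if r < n_trapped:  # stuck in the upper well the whole run
                centers = np.full(n, separation / 2.0)
            else:              # hops freely between the two wells
                centers = separation * (rng.random(n) < 0.5) - separation / 2.0
            parts.append(pd.DataFrame({
                "replica": r, "step": np.arange(n),
                "dudl": centers + rng.normal(scale=sigma, size=n)}))
        frame = pd.concat(parts, ignore_index=True)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if path is not None:
        frame.to_csv(Path(path), index=False)
    return frame


def _reject_extras(kind: str, params: dict) -> None:
    if params:
        raise ValueError(f"unknown {kind} fixture parameters: "
                         f"{sorted(params)}")
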