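"""Variance-adaptive resampling along the alchemical coordinate.

Tracks the running per-window variance of dU/dlambda, turns it into
variance-proportional target visitation probabilities (with a minimum-
probability floor so no window starves), re-weights the serial-tempering
jump probabilities toward those targets, and allocates a fixed sampling
budget across windows to minimize the propagated variance of the
thermodynamic-integration estimate.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = [
    "VarianceTracker",
    "target_probabilities",
    "apply_var_weight",
    "ti_variance",
    "neyman_allocation",
]

log = logging.getLogger(__name__)


class VarianceTracker:
    """Per-window running count / mean / variance of dU/dlambda.

    Welford one-pass updates; the reported variance is the population form
    <x^2> - <x>^2 (sum of squared deviations divided by the count).
    """

    def __init__(self, n_windows: int):
        if n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        self.n_windows = int(n_windows)
        self.counts = np.zeros(n_windows, dtype=np.int64)
        self.means = np.zeros(n_windows)
        self.m2 = np.zeros(n_windows)  # running sum of squared deviations

    def update(self, window: int, value: float) -> None:
        self._check_window(window)
        n = self.counts[window] + 1
        delta = value - self.means[window]
        self.means[window] += delta / n
        self.m2[window] += delta * (value - self.means[window])
        self.counts[window] = n

    def update_batch(self, window: int, values: np.ndarray) -> None:
        """Chan-style parallel merge of a chunk of samples into one window."""
        self._check_window(window)
        values = np.asarray(values, dtype=float)
        nb = values.size
        if nb == 0:
            return
        mb = values.mean()
        m2b = float(((values - mb) ** 2).sum())
        na = int(self.counts[window])
        if na == 0:
            self.counts[window] = nb
            self.means[window] = mb
            self.m2[window] = m2b
            return
        delta = mb - self.means[window]
        n = na + nb
        self.means[window] += delta * nb / n
        self.m2[window] += m2b + delta * delta * na * nb / n
        self.counts[window] = n

    @property
    def variances(self) -> np.ndarray:
        """Population variances; zero where a window has no samples."""
        out = np.zeros(self.n_windows)
        mask = self.counts > 0
        out[mask] = self.m2[mask] / self.counts[mask]
        return out

    def _check_window(self, window: int) -> None:
        if not 0 <= window < self.n_windows:
            raise IndexError(f"window {window} outside [0, {self.n_windows})")


def target_probabilities(tracker: VarianceTracker,
                         floor_fraction: float = 0.1,
                         min_samples: int = 10) -> np.ndarray:
    """Variance-proportional target visitation probabilities with a floor.

    Two-step rule: (1) P_i proportional to Var_i; (2) lift every entry to at
    least ``floor_fraction`` of the pre-renormalization maximum, then
    renormalize to sum to 1. Windows with fewer than ``min_samples`` samples
    have untrusted variance and inherit the mean variance of trusted windows;
    if every variance is zero a uniform vector is returned.
    """
    var = tracker.variances.copy()
    trusted = tracker.counts >= min_samples
    if trusted.any() and not trusted.all():
        var[~trusted] = var[trusted].mean()
    total = var.sum()
    n = var.size
    if total <= 0.0:
        log.info("all variances zero; falling back to uniform targets")
        return np.full(n, 1.0 / n)
    p = var / total
    p = np.maximum(p, floor_fraction * p.max())
    return p / p.sum()


def apply_var_weight(base_probabilities: np.ndarray, targets: np.ndarray,
                     current_index: int) -> np.ndarray:
    """Variance-weighted jump probabilities.

    P'(i -> j) = P(i -> j) * P_target(j) / P_target(i), renormalized over
    candidates so the output is again a probability vector. A zero base
    probability stays zero.
    """
    base = np.asarray(base_probabilities, dtype=float)
    t = np.asarray(targets, dtype=float)
    if base.shape != t.shape:
        raise ValueError("base and target vectors must have equal length")
    if t[current_index] <= 0.0:
        raise AssertionError(
            "zero target at the current window — the floor rule is broken")
    p = base * (t / t[current_index])
    total = p.sum()
    if total <= 0.0:
        return np.zeros_like(p)
    return p / total


def ti_variance(delta_lambdas: np.ndarray, n_samples: np.ndarray,
                variances: np.ndarray, squared_spacing: bool = False) -> float:
    """Total variance of the TI estimate: sum_i (dl_i / N_i) sigma_i^2.

    The first-power spacing is the printed error-propagation form and is the
    allocation objective; ``squared_spacing=True`` selects the dl_i^2
    delta-method variant. Every window must hold at least one sample.
    """
    dl = np.asarray(delta_lambdas, dtype=float)
    n = np.asarray(n_samples, dtype=float)
    s2 = np.asarray(variances, dtype=float)
    if not (dl.shape == n.shape == s2.shape):
        raise ValueError("delta_lambdas, n_samples, variances must align")
    empty = np.nonzero(n < 1)[0]
    if empty.size:
        raise ValueError(f"unsampled window(s): {empty.tolist()}")
    w = dl ** 2 if squared_spacing else dl
    return float(np.sum(w * s2 / n))


def neyman_allocation(variances: np.ndarray, delta_lambdas: np.ndarray,
                      total_samples: int, rule: str = "neyman") -> np.ndarray:
    """Allocate a fixed sampling budget across windows.

    rule="neyman"   — N_i proportional to sqrt(dl_i) * sigma_i, the true
                      minimizer of sum dl_i sigma_i^2 / N_i (Cauchy-Schwarz);
                      strictly beats uniform allocation whenever the
                      dl_i sigma_i^2 are heterogeneous.
    rule="variance" — N_i proportional to dl_i * sigma_i^2, the equalized-
                      contribution heuristic (each window contributes the
                      same dl_i sigma_i^2 / N_i).

    Every window receives at least one sample; fractional shares are rounded
    by largest remainder so the allocation sums exactly to ``total_samples``.
    All-zero variances yield a uniform allocation.
    """
    s2 = np.asarray(variances, dtype=float)
    dl = np.asarray(delta_lambdas, dtype=float)
    if s2.shape != dl.shape:
        raise ValueError("variances and delta_lambdas must align")
    if (s2 < 0).any():
        raise ValueError("variances must be nonnegative")
    k = s2.size
    if total_samples < k:
        raise ValueError("total_samples must cover at least one per window")
    if rule == "neyman":
        weights = np.sqrt(dl * s2)
    elif rule == "variance":
        weights = dl * s2
    else:
        raise ValueError(f"unknown allocation rule {rule!r}")
    if weights.sum() <= 0.0:
        weights = np.ones(k)
    ideal = total_samples * weights / weights.sum()
    alloc = np.maximum(1, np.floor(ideal).astype(np.int64))
    diff = int(total_samples - alloc.sum())
    if diff > 0:
        remainders = ideal - np.floor(ideal)
        for idx in np.argsort(-remainders)[:diff]:
            alloc[idx] += 1
    elif diff < 0:
        # floors at 1 can overshoot; shave from the smallest remainders
        order = np.argsort(ideal - np.floor(ideal))
        for idx in order:
            if diff == 0:
                break
            if alloc[idx] > 1:
                alloc[idx] -= 1
                diff += 1
        while diff < 0:  # pathological: shave the largest allocations
            idx = int(np.argmax(alloc))
            alloc[idx] -= 1
            diff += 1
    return alloc
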