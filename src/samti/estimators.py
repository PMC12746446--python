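"""Free-energy estimation and sampling-quality diagnostics.

Thermodynamic integration of per-window mean generalized forces, plus the
statistical stack used to judge whether the sampling can be trusted:
autocorrelation, statistical inefficiency g, effective sample size N_eff,
sampling efficiency eta = 1/g, per-run standard errors, the spread of
replicate means, and the sampling-quality ratio that flags trapped
replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson, trapezoid

from .st_engine import LambdaGrid

__all__ = [
    "TIResult",
    "DiagnosticsReport",
    "ti_integrate",
    "quadrature_weights",
    "ti_standard_error",
    "autocorrelation",
    "statistical_inefficiency",
    "effective_samples",
    "standard_error",
    "replicate_spread",
    "sampling_quality",
    "apply_burn_in",
]

log = logging.getLogger(__name__)

#: sampling-quality thresholds: ratio <= 2 ok, <= 5 warning, > 5 severe
QUALITY_WARNING = 2.0
QUALITY_SEVERE = 5.0


class ZeroVarianceError(ValueError):
    """Series has no variance; autocorrelation diagnostics are undefined."""


@dataclass
class TIResult:
    """Thermodynamic-integration estimate and its per-window ingredients."""

    dg: float
    per_window_means: np.ndarray
    per_window_variances: np.ndarray
    per_window_counts: np.ndarray
    rule: str
    burn_in_fraction: float = 0.0


@dataclass
class DiagnosticsReport:
    """Per-window and cross-replicate sampling diagnostics."""

    g: np.ndarray                    # statistical inefficiency per window
    n_eff: np.ndarray
    eta: np.ndarray
    se: np.ndarray                   # per-window standard errors
    replicate_means: np.ndarray      # per-replicate observable means A_i
    sigma_across: float              # std of replicate means (n-1 form)
    mean_se: float                   # <SE> over replicates
    quality_ratio: float
    flag: str = "ok"
    extra: dict = field(default_factory=dict)


def apply_burn_in(values: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    """Discard the leading ``fraction`` of a time-ordered stream."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("burn-in fraction must be in [0, 1)")
    values = np.asarray(values)
    return values[int(np.floor(fraction * values.shape[0])):]


def quadrature_weights(n_points: int, delta: float, rule: str = "simpson"
                       ) -> np.ndarray:
    """Composite quadrature weights on a uniform grid.

    Simpson requires an odd number of points; with an even count the last
    panel falls back to the trapezoid rule (logged).
    """
    if n_points < 2:
        raise ValueError("need at least 2 quadrature points")
    if rule == "trapezoid":
        w = np.full(n_points, delta)
        w[0] = w[-1] = 0.5 * delta
        return w
    if rule != "simpson":
        raise ValueError(f"unknown quadrature rule {rule!r}")
    if n_points == 2:
        log.warning("Simpson needs >= 3 points; using trapezoid")
        return quadrature_weights(n_points, delta, "trapezoid")
    w = np.zeros(n_points)
    n_simpson = n_points if n_points % 2 == 1 else n_points - 1
    w[0:n_simpson:2] = 2.0 * delta / 3.0
    w[1:n_simpson:2] = 4.0 * delta / 3.0
    w[0] = w[n_simpson - 1] = delta / 3.0
    if n_simpson != n_points:
        log.warning("even window count: trapezoid fallback on the last panel")
        w[-2] += 0.5 * delta
        w[-1] += 0.5 * delta
    return w


def ti_integrate(per_window_means: np.ndarray, grid: LambdaGrid,
                 rule: str = "simpson",
                 per_window_variances: np.ndarray | None = None,
                 per_window_counts: np.ndarray | None = None,
                 burn_in_fraction: float = 0.0) -> TIResult:
    """Free energy difference dG = integral of <dU/dlambda> over [0, 1]."""
    y = np.asarray(per_window_means, dtype=float)
    if y.shape != (grid.n_windows,):
        raise ValueError("means vector length must equal n_windows")
    if not np.isfinite(y).all():
        raise ValueError("per-window means contain non-finite entries "
                         "(unsampled window?)")
    x = grid.values
    if rule == "simpson":
        if grid.n_windows % 2 == 0:
            log.warning("even window count: trapezoid fallback on last panel")
            dg = float(simpson(y[:-1], x=x[:-1])) + \
                0.5 * grid.delta_lambda * (y[-2] + y[-1])
        else:
            dg = float(simpson(y, x=x))
    elif rule == "trapezoid":
        dg = float(trapezoid(y, x=x))
    else:
        raise ValueError(f"unknown quadrature rule {rule!r}")
    n = grid.n_windows
    var = (np.zeros(n) if per_window_variances is None
           else np.asarray(per_window_variances, dtype=float))
    cnt = (np.ones(n, dtype=np.int64) if per_window_counts is None
           else np.asarray(per_window_counts))
    if (cnt < 1).any():
        raise ValueError(
            f"window(s) without samples: {np.nonzero(cnt < 1)[0].tolist()}")
    return TIResult(dg, y, var, cnt, rule, burn_in_fraction)


def ti_standard_error(per_window_variances: np.ndarray,
                      per_window_n_eff: np.ndarray, grid: LambdaGrid,
                      rule: str = "simpson") -> float:
    """Propagated standard error of the TI estimate.

    Delta-method propagation through the quadrature: Var(dG) =
    sum_i w_i^2 sigma_i^2 / N_eff,i with w_i the composite quadrature
    weights; correlation within each window enters through N_eff.
    """
    s2 = np.asarray(per_window_variances, dtype=float)
    neff = np.asarray(per_window_n_eff, dtype=float)
    if s2.shape != (grid.n_windows,) or neff.shape != (grid.n_windows,):
        raise ValueError("variance / N_eff vectors must match the grid")
    if (neff <= 0).any():
        raise ValueError("N_eff must be positive at every window")
    w = quadrature_weights(grid.n_windows, grid.delta_lambda, rule)
    return float(np.sqrt(np.sum(w ** 2 * s2 / neff)))


def autocorrelation(series: np.ndarray, lag: int) -> float:
    """Normalized autocorrelation rho_k = Cov(X_t, X_{t+k}) / Var(X_t).

    Biased (population) covariance estimator with the overall series mean.
    """
    x = np.asarray(series, dtype=float)
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if x.size <= lag:
        raise ValueError("series shorter than the requested lag")
    mu = x.mean()
    var = float(np.mean((x - mu) ** 2))
    if var <= 0.0:
        raise ZeroVarianceError("constant series has no autocorrelation")
    if lag == 0:
        return 1.0
    d = x - mu
    return float(np.dot(d[:-lag], d[lag:]) / x.size / var)


def statistical_inefficiency(series: np.ndarray) -> float:
    """g = 1 + 2 sum_k rho_k, truncated at the first lag with rho_k <= 0.

    The factor by which autocorrelation reduces the information content of
    the series; floored at 1.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples for g")
    mu = x.mean()
    d = x - mu
    var = float(np.mean(d * d))
    if var <= 0.0:
        raise ZeroVarianceError("constant series has no statistical "
                                "inefficiency")
    n = x.size
    acc = 0.0
    for k in range(1, n):
        rho = float(np.dot(d[:-k], d[k:]) / n / var)
        if rho <= 0.0:
            break
        acc += rho
    return max(1.0, 1.0 + 2.0 * acc)


def effective_samples(series: np.ndarray) -> tuple[float, float]:
    """(N_eff, eta): effective sample size N/g and efficiency 1/g."""
    x = np.asarray(series, dtype=float)
    g = statistical_inefficiency(x)
    return x.size / g, 1.0 / g


def standard_error(series: np.ndarray) -> float:
    """SE = sample standard deviation / sqrt(N_eff)."""
    x = np.asarray(series, dtype=float)
    n_eff, _ = effective_samples(x)
    return float(np.std(x, ddof=1) / np.sqrt(n_eff))


def replicate_spread(replicate_means: np.ndarray) -> float:
    """Standard deviation (n-1 form) of per-replicate mean values."""
    a = np.asarray(replicate_means, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 replicate means")
    return float(np.std(a, ddof=1))


def sampling_quality(sigma_across: float, mean_se: float) -> tuple[float, str]:
    """Ratio of across-replicate spread to mean within-run SE, with a flag.

    Near 1 indicates every replicate explores the same ensemble; > 2 flags
    incomplete conformational sampling, > 5 severe trapping.
    """
    if mean_se <= 0.0:
        raise ValueError("mean standard error must be positive")
    ratio = float(sigma_across / mean_se)
    if ratio <= QUALITY_WARNING:
        flag = "ok"
    elif ratio <= QUALITY_SEVERE:
        flag = "warning"
    else:
        flag = "severe"
    return ratio, flag
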