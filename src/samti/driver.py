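"""Run orchestration: the master loop, reference baselines, and reports.

``run_samti`` executes the full adaptive loop — preliminary sequential scan,
bias and variance initialization, replica launch, then cycles of
propagation, biased lambda jumps, statistics updates, bias rebuilds and
exchange attempts — and returns a ``RunReport`` with the pooled free-energy
estimate and the complete diagnostic stack. ``run_reference_ti`` provides
the conventional fixed-window baselines (21W and 21W+RE) under the same
budget accounting.

Component toggles (VAR / RE / ACES) are independent; every method label of
the benchmark matrix (ST, ST+VAR, ST+RE, ST+VAR+RE, 21W, 21W+RE, with
optional sACES/mACES) is reachable from configuration alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from .exchange import (ReplicaEnsemble, aces_exchange_attempt, pair_schedule,
                       replica_exchange_attempt)
from .models import ModelSystem, build_model
from .sampler import (DUMMY, PHYSICAL, LangevinSampler, MetropolisSampler,
                      WalkerState)
from .st_engine import (BiasProfile, ConfigurationError, LambdaGrid,
                        build_bias_simpson, heat_bath_jump, jump_log_weights,
                        sequential_scan)
from .var_adapt import VarianceTracker, target_probabilities

__all__ = ["RunConfig", "RunReport", "run_samti", "run_reference_ti"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Complete configuration of a run; every field has a reproducible default.

    Defaults mirror the standard operating point: 101 windows, jump and
    exchange attempts every 100 steps, 8 replicas, 10% burn-in.
    """

    model: str = "harmonic"
    model_params: dict = field(default_factory=dict)
    beta: float = 1.0
    n_windows: int = 101
    sampler: str = "metropolis"
    step_size: float = 0.5
    record_interval: int = 1
    var_enabled: bool = False
    re_enabled: bool = False
    aces_enabled: bool = False
    aces_torsions: list | None = None     # scaled torsion indices (sACES: 1)
    gamma_mode: str = "two-state"         # or "direct" (gamma rides lambda)
    n_replicas: int = 8
    jump_interval: int = 100
    exchange_interval: int = 100
    adaptation_interval: int = 10_000
    total_steps: int = 1_000_000
    prescan_steps_per_window: int = 100
    burn_in_fraction: float = 0.10
    neighbor_jumps: bool = False          # restrict jumps to adjacent windows
    allocation_rule: str = "neyman"
    var_floor_fraction: float = 0.1
    var_min_samples: int = 10
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if self.n_windows < 3:
            raise ConfigurationError("need at least 3 windows")
        if min(self.jump_interval, self.exchange_interval,
               self.adaptation_interval, self.record_interval) < 1:
            raise ConfigurationError("all intervals must be >= 1")
        if not 0.0 <= self.burn_in_fraction <= 0.5:
            raise ConfigurationError("burn-in fraction must be in [0, 0.5]")
        if self.n_replicas < 1:
            raise ConfigurationError("need at least 1 replica")
        if self.re_enabled and self.n_replicas < 2:
            raise ConfigurationError("replica exchange needs >= 2 replicas")
        if self.total_steps < self.n_replicas:
            raise ConfigurationError("total_steps too small for the replicas")
        if self.gamma_mode not in ("two-state", "direct"):
            raise ConfigurationError(f"unknown gamma mode {self.gamma_mode!r}")
        if self.sampler not in ("metropolis", "langevin"):
            raise ConfigurationError(f"unknown sampler {self.sampler!r}")
        per_rep = self.total_steps // self.n_replicas
        if self.n_windows * self.prescan_steps_per_window > per_rep:
            raise ConfigurationError(
                "prescan exceeds the per-replica step budget")

    @property
    def method_label(self) -> str:
        label = "ST"
        if self.var_enabled:
            label += "+VAR"
        if self.re_enabled:
            label += "+RE"
        if self.aces_enabled:
            n_scaled = len(self.aces_torsions or [])
            label += " (sACES)" if n_scaled <= 1 else " (mACES)"
        return label

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    """Everything a run produces, bit-reproducible for a given config + seed."""

    method: str
    seed: int
    dg: float                         # pooled estimate (mean of replicate dGs)
    sigma_replicates: float           # spread of per-replicate dG estimates
    per_replica_dg: list
    ti: est.TIResult                  # pooled per-window statistics
    diagnostics: est.DiagnosticsReport
    visitation: np.ndarray            # post-jump window occupancy counts
    exchange_rates: dict
    jump_stats: dict
    aces_stats: dict
    config: dict
    samples: list = field(default_factory=list, repr=False)

    def samples_frame(self) -> pd.DataFrame:
        """Per-sample table: replica, step, lam_index, gamma_state, dudl, u."""
        parts = []
        for r, arrays in enumerate(self.samples):
            step, window, phys, dudl, u = arrays
            parts.append(pd.DataFrame({
                "replica": r, "step": step, "lam_index": window,
                "gamma_state": np.where(phys, PHYSICAL, DUMMY),
                "dudl": dudl, "u": u}))
        return pd.concat(parts, ignore_index=True)

    def summary_dict(self) -> dict:
        d = self.diagnostics
        return {
            "method": self.method,
            "seed": self.seed,
            "dg": self.dg,
            "sigma_replicates": self.sigma_replicates,
            "per_replica_dg": list(map(float, self.per_replica_dg)),
            "mean_se": d.mean_se,
            "quality_ratio": d.quality_ratio,
            "quality_flag": d.flag,
            "visitation": self.visitation.tolist(),
            "exchange_rates": {f"{a}-{b}": r
                               for (a, b), r in self.exchange_rates.items()},
            "jump_stats": self.jump_stats,
            "aces_stats": self.aces_stats,
            "config": self.config,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.summary_dict(), indent=2))


def _make_sampler(config: RunConfig):
    if config.sampler == "metropolis":
        return MetropolisSampler(config.beta, config.step_size,
                                 config.record_interval)
    return LangevinSampler(config.beta, dt=config.step_size,
                           record_interval=config.record_interval)


def _build_aces_model(config: RunConfig) -> ModelSystem:
    params = dict(config.model_params)
    if config.aces_enabled and config.aces_torsions is not None:
        params.setdefault("scaled", list(config.aces_torsions))
    model = build_model(config.model, params)
    if config.aces_enabled and not model.has_torsions:
        raise ConfigurationError(
            f"ACES enabled but model {model.name!r} has no torsions")
    return model


def _concat_chunks(chunks) -> tuple[np.ndarray, ...]:
    step = np.concatenate([c.steps for c in chunks])
    window = np.concatenate([np.full(c.steps.size, c.lam_index, dtype=np.int32)
                             for c in chunks])
    phys = np.concatenate([np.full(c.steps.size, c.gamma_state == PHYSICAL)
                           for c in chunks])
    dudl = np.concatenate([c.dudl for c in chunks])
    u = np.concatenate([c.u for c in chunks])
    return step, window, phys, dudl, u


def _per_window_stats(window: np.ndarray, dudl: np.ndarray, n_windows: int):
    """Counts, means and population variances of dudl grouped by window."""
    counts = np.bincount(window, minlength=n_windows)
    sums = np.bincount(window, weights=dudl, minlength=n_windows)
    means = np.divide(sums, counts, out=np.full(n_windows, np.nan),
                      where=counts > 0)
    sq = np.bincount(window, weights=dudl ** 2, minlength=n_windows)
    ex2 = np.divide(sq, counts, out=np.full(n_windows, np.nan),
                    where=counts > 0)
    variances = np.where(counts > 0, ex2 - means ** 2, np.nan)
    return counts, means, np.maximum(variances, 0.0)


def _window_inefficiencies(window: np.ndarray, dudl: np.ndarray,
                           counts: np.ndarray, max_series: int = 5000
                           ) -> np.ndarray:
    """Per-window statistical inefficiency g (1 where it cannot be estimated).

    Long window series are thinned to at most ``max_series`` points before
    the lag scan to bound the cost; thinning by stride s divides g by about
    s, so the estimate is rescaled accordingly (and floored at 1).
    """
    n_windows = counts.size
    g = np.ones(n_windows)
    order = np.argsort(window, kind="stable")  # stable keeps time order
    sorted_dudl = dudl[order]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    for i in range(n_windows):
        series = sorted_dudl[offsets[i]:offsets[i + 1]]
        if series.size < 10 or np.var(series) <= 0:
            continue
        stride = max(1, series.size // max_series)
        try:
            g_thin = est.statistical_inefficiency(series[::stride])
        except est.ZeroVarianceError:
            continue
        g[i] = max(1.0, g_thin * stride) if stride > 1 else g_thin
    return g


def _replica_ti(counts, means, variances, g, grid: LambdaGrid,
                fallback_means: np.ndarray | None):
    """Per-replicate TI estimate and propagated SE; fill unvisited windows."""
    means = means.copy()
    variances = variances.copy()
    counts = counts.copy()
    missing = counts == 0
    if missing.any():
        if fallback_means is None or not np.isfinite(
                fallback_means[missing]).all():
            raise ConfigurationError(
                f"window(s) never sampled: {np.nonzero(missing)[0].tolist()}")
        log.warning("replica missing %d window(s); filled from pooled means",
                    int(missing.sum()))
        means[missing] = fallback_means[missing]
        variances[missing] = 0.0
        counts[missing] = 1
    ti = est.ti_integrate(means, grid, "simpson", variances, counts)
    n_eff = np.maximum(counts / g, 1.0)
    safe_var = np.where(np.isfinite(variances), variances, 0.0)
    se = est.ti_standard_error(safe_var, n_eff, grid, "simpson")
    return ti, se, n_eff


def run_samti(config: RunConfig, keep_samples: bool = True) -> RunReport:
    """Execute the complete adaptive master loop and report the results."""
    config.validate()
    model = _build_aces_model(config)
    grid = LambdaGrid(config.n_windows)
    n_rep = config.n_replicas
    gamma_follows = config.aces_enabled and config.gamma_mode == "direct"
    two_state_aces = config.aces_enabled and config.gamma_mode == "two-state"

    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(c) for c in ss.spawn(n_rep)]

    base = config.total_steps // n_rep
    extra = config.total_steps % n_rep
    budgets = [base + (1 if r < extra else 0) for r in range(n_rep)]

    samplers = [_make_sampler(config) for _ in range(n_rep)]
    trackers = [VarianceTracker(grid.n_windows) for _ in range(n_rep)]
    states, biases, targets, all_chunks = [], [], [], []
    visitation = np.zeros(grid.n_windows, dtype=np.int64)
    jump_attempts = jump_moves = 0
    aces_attempts = aces_accepts = 0
    ensemble = ReplicaEnsemble([], exchange_interval=config.exchange_interval)

    # --- initialization + preliminary scan per replica -----------------
    for r in range(n_rep):
        start = 0 if n_rep == 1 else round(r * (grid.n_windows - 1) / (n_rep - 1))
        state = WalkerState(model.initial_coords(), lam_index=start, rng=rngs[r])
        means, _, chunks = sequential_scan(
            model, grid, samplers[r], state, config.prescan_steps_per_window,
            tracker=trackers[r], gamma_follows_lambda=gamma_follows)
        state.lam_index = start
        states.append(state)
        biases.append(build_bias_simpson(means, grid))
        targets.append(target_probabilities(
            trackers[r], config.var_floor_fraction, config.var_min_samples)
            if config.var_enabled else None)
        all_chunks.append(chunks)
    ensemble.replicas = states

    # --- main loop: rounds of jump_interval steps per replica ----------
    remaining = [b - grid.n_windows * config.prescan_steps_per_window
                 for b in budgets]
    exchange_every = max(1, config.exchange_interval // config.jump_interval)
    adapt_every = max(1, config.adaptation_interval // config.jump_interval)
    round_idx = 0
    while any(rem > 0 for rem in remaining):
        round_idx += 1
        for r in range(n_rep):
            if remaining[r] <= 0:
                continue
            n = min(config.jump_interval, remaining[r])
            state = states[r]
            lam = grid.values[state.lam_index]
            gamma = lam if gamma_follows else state.gamma
            chunk = samplers[r].propagate(state, model, n, lam, gamma,
                                          gamma_follows_lambda=gamma_follows)
            remaining[r] -= n
            all_chunks[r].append(chunk)
            if chunk.gamma_state == PHYSICAL:
                trackers[r].update_batch(state.lam_index, chunk.dudl)
            if n == config.jump_interval:  # full cycle: attempt a lambda jump
                logw = jump_log_weights(state, model, grid, biases[r],
                                        config.beta, gamma_follows)
                if config.neighbor_jumps:
                    mask = np.full(grid.n_windows, -np.inf)
                    i = state.lam_index
                    for j in (i - 1, i + 1):
                        if 0 <= j < grid.n_windows:
                            mask[j] = logw[j]
                    logw = mask
                new = heat_bath_jump(logw, state.lam_index, state.rng,
                                     targets[r])
                jump_attempts += 1
                if new != state.lam_index:
                    jump_moves += 1
                state.lam_index = new
                visitation[new] += 1
        if round_idx % adapt_every == 0:
            for r in range(n_rep):
                biases[r] = build_bias_simpson(trackers[r].means, grid)
                if config.var_enabled:
                    targets[r] = target_probabilities(
                        trackers[r], config.var_floor_fraction,
                        config.var_min_samples)
        if round_idx % exchange_every == 0:
            if two_state_aces:  # gamma flips first, then replica swaps
                for r in range(n_rep):
                    _, acc = aces_exchange_attempt(states[r], model, grid,
                                                   config.beta, states[r].rng)
                    aces_attempts += 1
                    aces_accepts += int(acc)
            if config.re_enabled:
                for (a, b) in pair_schedule(n_rep, round_idx, "fixed"):
                    counter = ensemble.counter((a, b))
                    _, _, acc = replica_exchange_attempt(
                        states[a], states[b], model, grid, config.beta,
                        states[a].rng, swap="full")
                    counter.attempts += 1
                    counter.accepts += int(acc)

    return _finalize(config, model, grid, all_chunks, visitation,
                     ensemble.acceptance_rates,
                     {"attempts": jump_attempts, "moves": jump_moves},
                     {"attempts": aces_attempts, "accepts": aces_accepts},
                     keep_samples)


def run_reference_ti(config: RunConfig, n_windows: int = 21,
                     with_exchange: bool = False,
                     keep_samples: bool = True) -> RunReport:
    """Conventional fixed-window TI baseline (21W / 21W+RE).

    Each of ``config.n_replicas`` replicate runs places one walker per
    window with equal per-window budgets; with exchange enabled, neighbor
    configuration swaps along the window ladder are attempted every
    ``exchange_interval`` steps with alternating pairing.
    """
    config.validate()
    model = _build_aces_model(config)
    grid = LambdaGrid(n_windows)
    n_rep = config.n_replicas
    ss = np.random.SeedSequence(config.seed)
    rep_seeds = ss.spawn(n_rep)

    base = config.total_steps // n_rep
    extra = config.total_steps % n_rep
    all_chunks = [[] for _ in range(n_rep)]
    exch_rates: dict = {}
    visitation = np.zeros(n_windows, dtype=np.int64)

    for r in range(n_rep):
        budget = base + (1 if r < extra else 0)
        per_window = budget // n_windows
        if per_window < 1:
            raise ConfigurationError("budget too small for the window count")
        leftovers = budget - per_window * n_windows
        rngs = [np.random.default_rng(c) for c in rep_seeds[r].spawn(n_windows)]
        walkers = [WalkerState(model.initial_coords(), lam_index=i, rng=rngs[i])
                   for i in range(n_windows)]
        sampler = _make_sampler(config)
        steps_left = [per_window + (1 if i < leftovers else 0)
                      for i in range(n_windows)]
        ensemble = ReplicaEnsemble(walkers,
                                   exchange_interval=config.exchange_interval)
        round_idx = 0
        while any(s > 0 for s in steps_left):
            round_idx += 1
            for i, w in enumerate(walkers):
                n = min(config.exchange_interval, steps_left[i])
                if n <= 0:
                    continue
                chunk = sampler.propagate(w, model, n,
                                          grid.values[w.lam_index], w.gamma)
                # window slot i records its own series regardless of swaps
                chunk.lam_index = i
                all_chunks[r].append(chunk)
                steps_left[i] -= n
                visitation[i] += chunk.dudl.size
            if with_exchange:
                for (a, b) in pair_schedule(n_windows, round_idx,
                                            "alternating"):
                    counter = ensemble.counter((a, b))
                    _, _, acc = replica_exchange_attempt(
                        walkers[a], walkers[b], model, grid, config.beta,
                        walkers[a].rng, swap="coords")
                    counter.attempts += 1
                    counter.accepts += int(acc)
        for pair, c in ensemble.counters.items():
            agg = exch_rates.setdefault(pair, [0, 0])
            agg[0] += c.attempts
            agg[1] += c.accepts
    rates = {pair: (a[1] / a[0] if a[0] else math.nan)
             for pair, a in exch_rates.items()}
    label = f"{n_windows}W+RE" if with_exchange else f"{n_windows}W"
    return _finalize(config, model, grid, all_chunks, visitation, rates,
                     {"attempts": 0, "moves": 0},
                     {"attempts": 0, "accepts": 0},
                     keep_samples, method=label)


def _finalize(config, model, grid, all_chunks, visitation, exchange_rates,
              jump_stats, aces_stats, keep_samples, method=None) -> RunReport:
    """Burn-in, per-replicate estimation, pooling, and diagnostics."""
    n_rep = len(all_chunks)
    arrays = []
    for chunks in all_chunks:
        step, window, phys, dudl, u = _concat_chunks(chunks)
        keep = slice(int(np.floor(config.burn_in_fraction * step.size)), None)
        arrays.append((step[keep], window[keep], phys[keep],
                       dudl[keep], u[keep]))

    # pooled per-window statistics over physical-state samples only
    pool_w = np.concatenate([a[1][a[2]] for a in arrays])
    pool_d = np.concatenate([a[3][a[2]] for a in arrays])
    counts, means, variances = _per_window_stats(pool_w, pool_d,
                                                 grid.n_windows)
    if (counts == 0).any():
        raise ConfigurationError(
            "window(s) without any physical samples after burn-in: "
            f"{np.nonzero(counts == 0)[0].tolist()}")
    pooled_ti = est.ti_integrate(means, grid, "simpson", variances, counts,
                                 burn_in_fraction=config.burn_in_fraction)

    per_dg, per_se, g_acc, neff_acc = [], [], [], []
    for step, window, phys, dudl, u in arrays:
        w_r, d_r = window[phys], dudl[phys]
        c_r, m_r, v_r = _per_window_stats(w_r, d_r, grid.n_windows)
        g_r = _window_inefficiencies(w_r, d_r, c_r)
        ti_r, se_r, neff_r = _replica_ti(c_r, m_r, v_r, g_r, grid, means)
        per_dg.append(ti_r.dg)
        per_se.append(se_r)
        g_acc.append(g_r)
        neff_acc.append(neff_r)

    per_dg = np.asarray(per_dg)
    dg = float(per_dg.mean())
    sigma = est.replicate_spread(per_dg) if n_rep >= 2 else math.nan
    mean_se = float(np.mean(per_se))
    if n_rep >= 2 and mean_se > 0:
        ratio, flag = est.sampling_quality(sigma, mean_se)
    else:
        ratio, flag = math.nan, "ok"
    g_mean = np.mean(np.vstack(g_acc), axis=0)
    n_eff_total = np.sum(np.vstack(neff_acc), axis=0)
    diag = est.DiagnosticsReport(
        g=g_mean, n_eff=n_eff_total, eta=1.0 / g_mean,
        se=np.sqrt(np.divide(variances, np.maximum(n_eff_total, 1.0))),
        replicate_means=per_dg, sigma_across=float(sigma),
        mean_se=mean_se, quality_ratio=float(ratio), flag=flag)

    report = RunReport(
        method=method or config.method_label,
        seed=config.seed, dg=dg, sigma_replicates=float(sigma),
        per_replica_dg=per_dg.tolist(), ti=pooled_ti, diagnostics=diag,
        visitation=visitation, exchange_rates=exchange_rates,
        jump_stats=jump_stats, aces_stats=aces_stats,
        config=dataclasses.asdict(config),
        samples=arrays if keep_samples else [])
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / f"report_{report.method.replace(' ', '')}.json")
        if keep_samples:
            report.samples_frame().to_csv(out / "samples.csv", index=False)
    return report
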