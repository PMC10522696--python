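"""Population reliability analysis (PRA): Monte-Carlo winner-take-all selection.

The selection statistic assumes one neural population per search item. Each
simulated trial draws, with replacement, ``pop_size`` trial-level multiunit
responses per alternative (one oddball alternative, ``n_items - 1`` distractor
alternatives), sums them within alternative, and scores the alternative with
the largest summed response at every timepoint (ties broken uniformly at
random). Repeating ``n_sims`` times yields the percent of simulations in which
the oddball wins -- the selection-frequency surface over time x population
size. Chance for a 6-item array is 16.67%; an empirical chance window from the
pre-stimulus baseline calibrates when crossings are reliable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, WindowError

log = logging.getLogger(__name__)

DEFAULT_POP_SIZES = (1, 9, 49, 131, 225, 250)
DEFAULT_N_SIMS = 1000


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class ResponsePool:
    """Trial-level response pools for one analysis condition.

    ``oddball`` is (n_trials, n_time); ``distractor`` is either a single pool
    reused for every distractor alternative or a list of per-alternative pools
    (length n_items - 1). Rows are empirically measured trial-level multiunit
    time courses (z-units).
    """

    oddball: np.ndarray
    distractor: np.ndarray | list[np.ndarray]
    time_ms: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.oddball = np.atleast_2d(np.asarray(self.oddball, dtype=float))
        if isinstance(self.distractor, list):
            self.distractor = [np.atleast_2d(np.asarray(d, dtype=float))
                               for d in self.distractor]
        else:
            self.distractor = np.atleast_2d(np.asarray(self.distractor, dtype=float))
        dists = self.distractor if isinstance(self.distractor, list) else [self.distractor]
        for pool in [self.oddball] + dists:
            if pool.shape[0] == 0:
                raise ConfigurationError("empty response pool")
            if pool.shape[1] != self.oddball.shape[1]:
                raise ConfigurationError("pools must share the time axis")

    def distractor_pools(self, n_items: int) -> list[np.ndarray]:
        if isinstance(self.distractor, list):
            if len(self.distractor) != n_items - 1:
                raise ConfigurationError(
                    f"need {n_items - 1} distractor pools, got {len(self.distractor)}")
            return self.distractor
        return [self.distractor] * (n_items - 1)

    def restrict_time(self, tmask: np.ndarray) -> "ResponsePool":
        dist = ([d[:, tmask] for d in self.distractor]
                if isinstance(self.distractor, list) else self.distractor[:, tmask])
        tm = self.time_ms[tmask] if self.time_ms is not None else None
        return ResponsePool(self.oddball[:, tmask], dist, time_ms=tm, meta=self.meta)


@dataclass
class SelectionResult:
    """Selection-frequency surface with chance calibration."""

    freq: np.ndarray  # (n_time, n_pop_sizes), percent oddball selected
    pop_sizes: tuple[int, ...]
    n_sims: int
    n_items: int
    time_ms: np.ndarray | None = None
    chance_window: tuple[float, float] | None = None
    freq_all: np.ndarray | None = None  # (n_items, n_time, n_pop_sizes)

    @property
    def chance(self) -> float:
        return 100.0 / self.n_items

    @property
    def selection_vs_chance(self) -> np.ndarray:
        """Signed selection frequency relative to chance (percentage points)."""
        return self.freq - self.chance


def _population_sums(pool: np.ndarray, pop_size: int, n_sims: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Summed responses of ``n_sims`` random populations drawn with replacement."""
    n = pool.shape[0]
    idx = rng.integers(0, n, size=(n_sims, pop_size))
    counts = np.zeros((n_sims, n))
    np.add.at(counts, (np.arange(n_sims)[:, None], idx), 1.0)
    return counts @ pool  # (n_sims, n_time)


def _winners(pools: list[np.ndarray], pop_size: int, n_sims: int,
             rng: np.random.Generator) -> np.ndarray:
    """Winning alternative per (sim, timepoint); index 0 is the oddball."""
    sums = np.stack([_population_sums(p, pop_size, n_sims, rng) for p in pools])
    mx = sums.max(axis=0)
    key = rng.random(sums.shape)  # uniform tie-break among exact maxima
    return np.argmax(np.where(sums == mx, key, -1.0), axis=0)


def simulate_selection(pool: ResponsePool, n_items: int = 6,
                       pop_sizes: tuple[int, ...] = DEFAULT_POP_SIZES,
                       n_sims: int = DEFAULT_N_SIMS,
                       seed: int | np.random.Generator | None = 0,
                       keep_all: bool = False) -> SelectionResult:
    """Monte-Carlo winner-take-all selection frequency over time x population size."""
    if n_items < 2:
        raise ConfigurationError("n_items must be >= 2")
    rng = _as_rng(seed)
    pools = [pool.oddball] + pool.distractor_pools(n_items)
    for p in pools:
        if max(pop_sizes) > p.shape[0]:
            log.info("pop_size %d exceeds pool size %d; sampling with replacement",
                     max(pop_sizes), p.shape[0])
            break
    n_time = pool.oddball.shape[1]
    freq = np.empty((n_time, len(pop_sizes)))
    freq_all = np.empty((n_items, n_time, len(pop_sizes))) if keep_all else None
    for j, p in enumerate(pop_sizes):
        w = _winners(pools, p, n_sims, rng)
        freq[:, j] = 100.0 * (w == 0).mean(axis=0)
        if keep_all:
            for a in range(n_items):
                freq_all[a, :, j] = 100.0 * (w == a).mean(axis=0)
    return SelectionResult(freq=freq, pop_sizes=tuple(pop_sizes), n_sims=n_sims,
                           n_items=n_items, time_ms=pool.time_ms, freq_all=freq_all)


def chance_window(pool: ResponsePool, baseline_mask: np.ndarray, n_items: int = 6,
                  pop_sizes: tuple[int, ...] = DEFAULT_POP_SIZES,
                  n_sims: int = DEFAULT_N_SIMS,
                  seed: int | np.random.Generator | None = 0,
                  ci: float = 99.0) -> tuple[float, float]:
    """Empirical chance interval of the selection frequency from the baseline.

    Runs the selection simulation restricted to pre-stimulus timepoints and
    returns the (100-ci)/2 and 100-(100-ci)/2 percentiles of the pooled
    frequencies across time and population size (99% interval by default).
    """
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    if baseline_mask.sum() < 10:
        raise WindowError("baseline window must contain at least 10 samples")
    res = simulate_selection(pool.restrict_time(baseline_mask), n_items=n_items,
                             pop_sizes=pop_sizes, n_sims=n_sims, seed=seed)
    tail = (100.0 - ci) / 2.0
    lo, hi = np.percentile(res.freq.ravel(), [tail, 100.0 - tail])
    return float(lo), float(hi)


def selection_time(result: SelectionResult, threshold: float | None = None,
                   sustain_ms: float = 5.0) -> dict[int, float | None]:
    """First sustained post-stimulus crossing above the chance window, per pop size.

    A crossing counts only if the frequency stays above threshold for at least
    ``sustain_ms`` consecutive samples; returns None where no reliable
    crossing exists.
    """
    if threshold is None:
        if result.chance_window is None:
            raise ConfigurationError("chance window not set and no threshold given")
        threshold = result.chance_window[1]
    if result.time_ms is None:
        raise ConfigurationError("result carries no time axis")
    t = result.time_ms
    dt = float(np.median(np.diff(t)))
    m = max(1, int(round(sustain_ms / dt)))
    post = t >= 0.0
    out: dict[int, float | None] = {}
    for j, p in enumerate(result.pop_sizes):
        above = (result.freq[:, j] > threshold) & post
        kernel = np.ones(m)
        runs = np.convolve(above.astype(float), kernel, mode="valid") >= m - 0.5
        idx = np.flatnonzero(runs)
        out[p] = float(t[idx[0]]) if idx.size else None
    return out


def depth_resolved_selection(pools_by_depth: dict[int, ResponsePool | None],
                             n_items: int = 6, pop_sizes: tuple[int, ...] = (250,),
                             n_sims: int = DEFAULT_N_SIMS, seed: int = 0
                             ) -> dict[int, SelectionResult | None]:
    """Selection frequency per aligned cortical depth (missing depths -> None).

    Each depth gets its own seed derived from (seed, depth), so relabeling
    depths permutes the outputs exactly.
    """
    out: dict[int, SelectionResult | None] = {}
    for depth, pool in pools_by_depth.items():
        rng = np.random.default_rng([int(seed), int(depth)])
        out[depth] = (None if pool is None else
                      simulate_selection(pool, n_items=n_items, pop_sizes=pop_sizes,
                                         n_sims=n_sims, seed=rng))
    return out


def within_trial_selection(pool: ResponsePool, n_items: int = 6,
                           n_sims: int = DEFAULT_N_SIMS,
                           seed: int | np.random.Generator | None = 0
                           ) -> SelectionResult:
    """PRA with preserved population structure.

    Each pool row must be the combined (summed) multiunit response of one
    cortical column on one trial, so a draw is a single column-trial and the
    independence of population samples is preserved (population size 1 draw
    per alternative).
    """
    return simulate_selection(pool, n_items=n_items, pop_sizes=(1,),
                              n_sims=n_sims, seed=seed)


def error_trial_selection(pool: ResponsePool, n_items: int = 6,
                          pop_sizes: tuple[int, ...] = DEFAULT_POP_SIZES,
                          n_sims: int = DEFAULT_N_SIMS,
                          seed: int | np.random.Generator | None = 0,
                          min_trials: int = 50) -> SelectionResult:
    """Selection on incorrect trials; the oddball pool comes from error trials
    and the distractor pool from the errantly fixated item.

    Use ``result.selection_vs_chance``: negative values indicate systematic
    selection of the chosen distractor over the oddball. An alternative signed
    metric (oddball-minus-distractor frequency) can be derived from
    ``freq_all`` which this variant always retains.
    """
    n_min = min(p.shape[0] for p in [pool.oddball] + pool.distractor_pools(n_items))
    if n_min < min_trials:
        log.warning("only %d error trials per condition (< %d): wide Monte-Carlo error",
                    n_min, min_trials)
    return simulate_selection(pool, n_items=n_items, pop_sizes=pop_sizes,
                              n_sims=n_sims, seed=seed, keep_all=True)


@dataclass
class BaselineBiasResult:
    freqs_a: np.ndarray
    freqs_b: np.ndarray
    t_stat: float
    p_value: float


def baseline_selection_frequencies(pool: ResponsePool, baseline_mask: np.ndarray,
                                   n_items: int = 6, pop_size: int = 250,
                                   n_sims: int = DEFAULT_N_SIMS,
                                   seed: int | np.random.Generator | None = 0
                                   ) -> np.ndarray:
    """Per-simulation oddball selection frequency (%) over the baseline window."""
    rng = _as_rng(seed)
    sub = pool.restrict_time(np.asarray(baseline_mask, dtype=bool))
    pools = [sub.oddball] + sub.distractor_pools(n_items)
    w = _winners(pools, pop_size, n_sims, rng)
    return 100.0 * (w == 0).mean(axis=1)


def baseline_bias(freqs_a: np.ndarray, freqs_b: np.ndarray) -> BaselineBiasResult:
    """Two-sample t test comparing per-sim baseline selection frequencies."""
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("need at least 2 values per group")
    t, p = stats.ttest_ind(a, b)
    return BaselineBiasResult(a, b, float(t), float(p))


def feature_selectivity(red: np.ndarray, green: np.ndarray, n_draw: int = 100,
                        n_sims: int = DEFAULT_N_SIMS,
                        seed: int | np.random.Generator | None = 0) -> float:
    """Two-alternative reliability: percent of simulations where red beats green.

    ``red`` and ``green`` are per-trial scalar responses of one multiunit
    (e.g. the 60-160 ms post-display average). Each simulation sums ``n_draw``
    draws (with replacement) per color and compares the sums; exact ties count
    half. 50% = unselective.
    """
    rng = _as_rng(seed)
    red = np.asarray(red, dtype=float).ravel()
    green = np.asarray(green, dtype=float).ravel()
    if red.size < n_draw or green.size < n_draw:
        log.info("fewer than %d trials per color; sampling with replacement", n_draw)
    r = red[rng.integers(0, red.size, (n_sims, n_draw))].sum(axis=1)
    g = green[rng.integers(0, green.size, (n_sims, n_draw))].sum(axis=1)
    return float(100.0 * ((r > g).mean() + 0.5 * (r == g).mean()))


def adjacency_conditioned_selection(pools_by_geometry: dict[str, ResponsePool],
                                    n_items: int = 6,
                                    pop_sizes: tuple[int, ...] = DEFAULT_POP_SIZES,
                                    n_sims: int = DEFAULT_N_SIMS,
                                    seed: int | np.random.Generator | None = 0
                                    ) -> dict[str, SelectionResult]:
    """Selection with distractor pools restricted by array geometry.

    Keys are geometry labels (e.g. ``adjacent``, ``opposite``); each value is a
    :class:`ResponsePool` whose distractor pool contains only trials where the
    RF distractor had that position relative to the target.
    """
    if not pools_by_geometry:
        raise ConfigurationError("geometry labels missing")
    rng = _as_rng(seed)
    return {g: simulate_selection(p, n_items=n_items, pop_sizes=pop_sizes,
                                  n_sims=n_sims, seed=rng)
            for g, p in pools_by_geometry.items()}


def pools_from_session(responses: np.ndarray, oddball_trials: np.ndarray,
                       distractor_trials: np.ndarray,
                       channels: np.ndarray | list[int] | None = None,
                       time_ms: np.ndarray | None = None, **meta) -> ResponsePool:
    """Build a pseudo-population pool from (channel, time, trial) responses.

    Every channel x trial combination contributes one trial-level time course;
    NaN rows (flagged channel-trials) are dropped.
    """
    x = np.asarray(responses, dtype=float)
    if channels is not None:
        x = x[np.asarray(channels, dtype=int)]

    def _rows(trial_mask: np.ndarray) -> np.ndarray:
        sub = x[:, :, np.asarray(trial_mask)]
        rows = np.moveaxis(sub, 1, 2).reshape(-1, x.shape[1])
        keep = ~np.isnan(rows).any(axis=1)
        return rows[keep]

    return ResponsePool(_rows(oddball_trials), _rows(distractor_trials),
                        time_ms=time_ms, meta=meta)
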