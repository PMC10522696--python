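"""Synthetic laminar pop-out search sessions with known ground truth.

The generator emulates a 32-channel laminar probe (0.1 mm spacing) in a
color-singleton search task with 6 items: a visually evoked multiunit
transient with ~58 ms onset latency, a granular-layer current sink in the
local field potential, target-vs-distractor response modulation whose
single-trial amplitude S drives reaction time through a power law
RT = alpha + beta * S**r + noise, block-structured color priming with tonic
baseline shifts in color-preferring columns, and a minority of error trials
in which the receptive-field distractor carries the oddball-like boost plus a
small pre-stimulus bias.

Everything is reproducible bit-for-bit from the configured seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SessionRecording
from .errors import ConfigurationError

FOREPERIOD_RANGE_MS = (750.0, 1250.0)


@dataclass
class SimConfig:
    """Geometry and size of a simulated session."""

    n_channels: int = 32
    channel_spacing_mm: float = 0.1
    sample_rate_hz: float = 1000.0
    n_trials: int = 400
    n_items: int = 6
    block_length_range: tuple[int, int] = (5, 15)
    t_pre_ms: float = 100.0
    t_post_ms: float = 400.0
    rf_position: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_items < 2:
            raise ConfigurationError("n_items must be >= 2")
        if self.n_channels < 3:
            raise ConfigurationError("need at least 3 channels")
        lo, hi = self.block_length_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("invalid block_length_range")
        if self.t_pre_ms < 100.0:
            raise ConfigurationError("t_pre_ms must be >= 100 ms")
        if not (0 <= self.rf_position < self.n_items):
            raise ConfigurationError("rf_position outside the array")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")


@dataclass
class GroundTruth:
    """Generative parameters (the quantities the analysis tries to recover).

    alpha, beta, r parameterize RT = alpha + beta * S**r (+ truncated Gaussian
    noise, floor 100 ms) with S the trial-level oddball feedforward amplitude.
    ``sink_channels`` is the inclusive channel range of the granular input
    sink; its deepest channel is the laminar alignment marker.
    ``priming_baseline_shift`` (z-units) is added tonically to the column when
    the column's preferred color is the current target and priming has built
    up (2nd trial of a block onward).
    """

    alpha: float = 120.0
    beta: float = 120.0
    r: float = -0.7
    latency_ms: float = 58.0
    sink_channels: tuple[int, int] = (14, 18)
    column_color_pref: str = "red"
    error_rate: float = 0.1
    priming_baseline_shift: float = 0.0
    oddball_gain: float = 1.0
    distractor_gain: float = 0.6
    adjacent_suppression: float = 0.0
    error_baseline_bias: float = 0.2
    s_sigma: float = 0.3
    rt_noise_sd: float = 20.0
    rt_floor_ms: float = 100.0
    mua_noise_sd: float = 0.5
    lfp_noise_sd: float = 0.3
    lfp_noise_tau_ms: float = 20.0
    lfp_spatial_sd_ch: float = 2.0
    csd_sink_amplitude: float = 30.0
    latency_jitter_ms: float = 2.0
    boost_channels: Sequence[int] | None = None

    def validate(self, cfg: SimConfig) -> None:
        if not (0.0 <= self.error_rate <= 1.0):
            raise ConfigurationError("error_rate must lie in [0, 1]")
        lo, hi = self.sink_channels
        if not (0 < lo <= hi < cfg.n_channels - 1):
            raise ConfigurationError("sink_channels outside probe interior")
        if self.latency_ms <= 0:
            raise ConfigurationError("latency_ms must be positive")
        if self.column_color_pref not in ("red", "green"):
            raise ConfigurationError("column_color_pref must be red or green")


def generate_foreperiods(n: int, seed: int | np.random.Generator = 0,
                         scale_ms: float = 200.0) -> np.ndarray:
    """Fixation-to-array delays from a nonaging foreperiod schedule.

    Delays are 750 ms plus an exponential waiting time (scale ``scale_ms``)
    right-censored at 1250 ms, so the hazard of stimulus onset is flat across
    the interior of the support and the residual mass sits at the maximum.
    """
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = FOREPERIOD_RANGE_MS
    delays = lo + rng.exponential(scale_ms, size=n)
    return np.minimum(delays, hi)


def _block_structure(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Block indices, within-block position, and alternating target color."""
    lo, hi = cfg.block_length_range
    colors = ["red", "green"]
    start = int(rng.integers(0, 2))
    rows: list[tuple[int, int, str]] = []
    block = 0
    while len(rows) < cfg.n_trials:
        length = int(rng.integers(lo, hi + 1))
        color = colors[(start + block) % 2]
        for i in range(length):
            rows.append((block, i + 1, color))
            if len(rows) == cfg.n_trials:
                break
        block += 1
    return pd.DataFrame(rows, columns=["block_index", "trial_in_block", "target_color"])


def _ring_geometry(target_position: np.ndarray, rf_position: int, n_items: int) -> np.ndarray:
    """Geometry of the RF item relative to the target on the stimulus ring."""
    d = np.abs(target_position - rf_position)
    d = np.minimum(d, n_items - d)
    geom = np.where(d == 0, "target", np.where(d == 1, "adjacent", "other"))
    if n_items % 2 == 0:
        geom = np.where(d == n_items // 2, "opposite", geom)
    return geom.astype(object)


def generate_trial_table(cfg: SimConfig, truth: GroundTruth,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Behavioral trial table: blocks, positions, outcomes, latent S, RT."""
    cfg.validate()
    truth.validate(cfg)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    tbl = _block_structure(cfg, rng)
    n = cfg.n_trials
    tbl.insert(0, "trial_id", np.arange(n))
    tbl.insert(1, "session_id", f"sim-{cfg.seed}")
    tbl["target_position"] = rng.integers(0, cfg.n_items, size=n)
    rf_item = np.where(tbl["target_position"].to_numpy() == cfg.rf_position,
                       "target", "distractor")
    tbl["rf_item"] = rf_item
    tbl["rf_geometry"] = _ring_geometry(tbl["target_position"].to_numpy(),
                                        cfg.rf_position, cfg.n_items)
    tbl["correct"] = rng.random(n) >= truth.error_rate

    # Errors saccade to the RF distractor whenever the RF holds one.
    chosen = tbl["target_position"].to_numpy().copy()
    err = ~tbl["correct"].to_numpy()
    rf_is_distractor = err & (rf_item == "distractor")
    chosen[rf_is_distractor] = cfg.rf_position
    other_err = err & ~rf_is_distractor
    if other_err.any():
        offs = rng.integers(1, cfg.n_items, size=int(other_err.sum()))
        chosen[other_err] = (chosen[other_err] + offs) % cfg.n_items
    tbl["chosen_position"] = chosen

    # Latent oddball feedforward amplitude and the RT it produces.
    s = rng.lognormal(mean=0.0, sigma=truth.s_sigma, size=n) * truth.oddball_gain
    rt = truth.alpha + truth.beta * s ** truth.r
    if truth.rt_noise_sd > 0:
        a = (truth.rt_floor_ms - rt) / truth.rt_noise_sd
        rt = stats.truncnorm.rvs(a, np.inf, loc=rt, scale=truth.rt_noise_sd,
                                 random_state=rng)
    tbl["s_amp"] = s
    tbl["rt_ms"] = rt
    tbl["foreperiod_ms"] = generate_foreperiods(n, rng)
    return tbl


def _evoked_template(time_ms: np.ndarray, latency_ms: float) -> np.ndarray:
    """Difference-of-gamma transient: 0 before ``latency_ms``, peak 1 ~30 ms later."""
    tau = time_ms - latency_ms
    g1 = stats.gamma.pdf(tau, a=3.0, scale=10.0)
    g2 = stats.gamma.pdf(tau, a=5.0, scale=16.0)
    w = g1 - 0.6 * g2
    peak = np.max(w)
    return w / peak if peak > 0 else w


def _ou_noise(shape: tuple[int, ...], sd: float, tau_ms: float, dt_ms: float,
              rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck noise along the second (time) axis."""
    if sd == 0:
        return np.zeros(shape)
    c, t, k = shape
    a = np.exp(-dt_ms / tau_ms)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    out = np.empty(shape)
    out[:, 0, :] = rng.normal(0.0, sd, size=(c, k))
    eps = rng.normal(0.0, innov_sd, size=(c, t - 1, k))
    for i in range(1, t):
        out[:, i, :] = a * out[:, i - 1, :] + eps[:, i - 1, :]
    return out


def _sink_lfp_profile(cfg: SimConfig, truth: GroundTruth, sigma_s_per_m: float = 0.4
                      ) -> np.ndarray:
    """Depth profile whose second spatial difference yields the granular sink.

    A unit-amplitude sink (CSD = -1) spans ``sink_channels`` with balancing
    sources at the flanks; the voltage profile is recovered by double
    cumulative summation so the forward CSD operator reproduces the target
    pattern exactly (up to probe edges).
    """
    c = cfg.n_channels
    lo, hi = truth.sink_channels
    csd_target = np.zeros(c)
    csd_target[lo:hi + 1] = -1.0
    flank = (hi - lo + 1) / 2.0
    csd_target[lo - 1] = flank
    if hi + 1 < c:
        csd_target[hi + 1] = flank
    z = cfg.channel_spacing_mm
    # CSD(d) = -sigma * (x[d-1] + x[d+1] - 2 x[d]) / z**2  =>  second difference
    f = -csd_target * z * z / sigma_s_per_m
    x = np.zeros(c)
    for d in range(1, c - 1):
        x[d + 1] = 2.0 * x[d] - x[d - 1] + f[d]
    return x


def generate_session(cfg: SimConfig, truth: GroundTruth) -> SessionRecording:
    """Simulate a full laminar session (LFP + MUA envelopes + trial table)."""
    cfg.validate()
    truth.validate(cfg)
    rng = np.random.default_rng(cfg.seed)
    trials = generate_trial_table(cfg, truth, rng)
    n = cfg.n_trials
    dt = 1000.0 / cfg.sample_rate_hz
    time_ms = np.arange(-cfg.t_pre_ms, cfg.t_post_ms + dt / 2, dt)
    t = time_ms.size
    c = cfg.n_channels

    if truth.boost_channels is None:
        signal_channels = np.arange(c)
    else:
        signal_channels = np.asarray(list(truth.boost_channels), dtype=int)
        if signal_channels.size and not (
                (signal_channels >= 0).all() and (signal_channels < c).all()):
            raise ConfigurationError("boost_channels outside probe")

    rf_target = trials["rf_item"].to_numpy() == "target"
    correct = trials["correct"].to_numpy()
    err_rf = (~correct) & (
        trials["chosen_position"].to_numpy() == cfg.rf_position) & ~rf_target

    # Evoked envelope amplitude of the RF column on each trial. On error
    # trials attention is captured by the chosen distractor: that population
    # gets the oddball-like boost while the unattended oddball responds like
    # a distractor.
    s = trials["s_amp"].to_numpy()
    d_amp = truth.distractor_gain * rng.lognormal(0.0, truth.s_sigma, size=n)
    adj = trials["rf_geometry"].to_numpy() == "adjacent"
    d_amp = d_amp * np.where(adj, 1.0 - truth.adjacent_suppression, 1.0)
    boost = rng.lognormal(0.0, truth.s_sigma, size=n) * truth.oddball_gain
    amp = np.where(rf_target & correct, s, d_amp)
    amp = np.where(err_rf, boost, amp)

    # Tonic (whole-trial) offsets: priming shift + errant pre-stimulus bias.
    primed_pref = (trials["target_color"].to_numpy() == truth.column_color_pref) & (
        trials["trial_in_block"].to_numpy() >= 2)
    tonic = np.where(primed_pref, truth.priming_baseline_shift, 0.0)
    tonic = tonic + np.where(err_rf, truth.error_baseline_bias, 0.0)

    lat = truth.latency_ms + (
        rng.uniform(-truth.latency_jitter_ms, truth.latency_jitter_ms, size=n)
        if truth.latency_jitter_ms > 0 else np.zeros(n))
    templates = np.stack([_evoked_template(time_ms, li) for li in lat], axis=-1)  # (t, n)

    mua = (rng.normal(0.0, truth.mua_noise_sd, size=(c, t, n))
           if truth.mua_noise_sd > 0 else np.zeros((c, t, n)))
    evoked = templates[None, :, :] * amp[None, None, :] + tonic[None, None, :]
    mask = np.zeros(c, dtype=bool)
    mask[signal_channels] = True
    mua[mask] += evoked

    # LFP: spatially smooth OU noise (volume conduction) plus a granular sink
    # whose magnitude tracks the envelope amplitude.
    lfp = _ou_noise((c, t, n), truth.lfp_noise_sd, truth.lfp_noise_tau_ms, dt, rng)
    if truth.lfp_spatial_sd_ch > 0:
        offs = np.arange(-3 * int(np.ceil(truth.lfp_spatial_sd_ch)),
                         3 * int(np.ceil(truth.lfp_spatial_sd_ch)) + 1)
        kern = np.exp(-0.5 * (offs / truth.lfp_spatial_sd_ch) ** 2)
        kern /= kern.sum()
        from scipy import ndimage
        lfp = ndimage.convolve1d(lfp, kern, axis=0, mode="nearest")
    profile = _sink_lfp_profile(cfg, truth)
    sink_amp = truth.csd_sink_amplitude * amp
    lfp += profile[:, None, None] * templates[None, :, :] * sink_amp[None, None, :]

    meta = {
        "synthetic": True,
        "seed": cfg.seed,
        "ground_truth": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                         for k, v in vars(truth).items()},
        "config": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in vars(cfg).items()},
    }
    return SessionRecording(lfp=lfp, mua=mua, sample_rate_hz=cfg.sample_rate_hz,
                            time_ms=time_ms, channel_spacing_mm=cfg.channel_spacing_mm,
                            trials=trials, meta=meta)


def simulate_column_baselines(n_columns: int = 12, n_units: int = 15,
                              n_blocks: int = 40, shift: float = 0.0,
                              unit_sd: float = 1.0,
                              block_length_range: tuple[int, int] = (5, 15),
                              seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Pre-stimulus baseline activity of color-preferring columns across blocks.

    Lightweight counterpart of :func:`generate_session` for the priming
    baseline analysis: half the columns prefer red, half green; when the
    block's target color matches the column preference and priming has built
    up (trial_in_block >= 2), the column baseline is elevated by ``shift``
    z-units. Each row is one column x trial with the baseline averaged over
    ``n_units`` units.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = block_length_range
    rows = []
    for col in range(n_columns):
        pref = "red" if col % 2 == 0 else "green"
        start = int(rng.integers(0, 2))
        trial = 0
        for b in range(n_blocks):
            color = ["red", "green"][(start + b) % 2]
            for i in range(int(rng.integers(lo, hi + 1))):
                base = rng.normal(0.0, unit_sd / np.sqrt(n_units))
                if color == pref and i + 1 >= 2:
                    base += shift
                rows.append((f"col{col}", pref, trial, b, i + 1, color, base))
                trial += 1
    return pd.DataFrame(rows, columns=["column_id", "pref_color", "trial_id",
                                       "block_index", "trial_in_block",
                                       "target_color", "baseline"])
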