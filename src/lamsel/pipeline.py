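"""End-to-end pipeline: simulate -> preprocess -> align -> pra -> fit-rt -> priming -> report.

Each stage consumes the session container and the shared configuration,
logs its seed and parameters, and writes diffable CSV/JSON artifacts (plus
PNG figures) into the output directory. Stage failures halt the run with a
stage-tagged error message.
"""
from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, preprocess, reliability, rtmodel, synthetic
from .containers import SessionRecording
from .errors import ConfigurationError, LamselError
from .session_io import read_session, write_session

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "align", "pra", "fit-rt", "priming", "report")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "simulate": {
        "n_trials": 1200,
        "n_channels": 32,
        "alpha": 120.0,
        "beta": 120.0,
        "r": -0.7,
        "error_rate": 0.1,
        "priming_baseline_shift": 0.0,
    },
    "preprocess": {"conductivity": preprocess.DEFAULT_CONDUCTIVITY},
    "pra": {"pop_sizes": list(reliability.DEFAULT_POP_SIZES), "n_sims": 1000},
    "fit_rt": {
        "scheme": "fine",
        "pop_size": 250,
        "sims_per_bin": 250,
        "exponent_sign": -1,
        "mcmc": {"chains": 4, "warmup": 400, "samples": 1600, "thin": 2},
    },
    "priming": {"n_columns": 12, "n_units": 15, "n_blocks": 40, "shift": 0.5},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def simulate_stage(cfg: dict, seed: int) -> SessionRecording:
    sim = cfg["simulate"]
    sim_cfg = synthetic.SimConfig(n_trials=int(sim["n_trials"]),
                                  n_channels=int(sim["n_channels"]), seed=seed)
    truth = synthetic.GroundTruth(
        alpha=float(sim["alpha"]), beta=float(sim["beta"]), r=float(sim["r"]),
        error_rate=float(sim["error_rate"]),
        priming_baseline_shift=float(sim["priming_baseline_shift"]))
    log.info("simulate: %d trials, seed %d", sim_cfg.n_trials, seed)
    return synthetic.generate_session(sim_cfg, truth)


def preprocess_stage(rec: SessionRecording, cfg: dict):
    z = preprocess.baseline_normalize(rec.mua, rec.time_ms, mode="zscore")
    csd = preprocess.compute_csd(rec.lfp, rec.channel_spacing_mm,
                                 sigma=cfg["preprocess"]["conductivity"])
    return z, csd


def align_stage(rec: SessionRecording, csd) -> preprocess.LaminarAlignment:
    align = preprocess.find_granular_sink(csd, rec.time_ms)
    log.info("align: marker channel %d, sink onset %.0f ms",
             align.marker_channel, align.onset_ms)
    return align


def session_pools(rec: SessionRecording, z: np.ndarray,
                  channels=None, trials_mask=None) -> reliability.ResponsePool:
    """Oddball/distractor pools from correct trials of a session."""
    correct = rec.trials["correct"].to_numpy(dtype=bool)
    keep = correct if trials_mask is None else (correct & np.asarray(trials_mask))
    rf = rec.trials["rf_item"].to_numpy()
    return reliability.pools_from_session(
        z, oddball_trials=keep & (rf == "target"),
        distractor_trials=keep & (rf == "distractor"),
        channels=channels, time_ms=rec.time_ms)


def pra_stage(rec: SessionRecording, z: np.ndarray, cfg: dict, seed: int
              ) -> tuple[pd.DataFrame, dict]:
    pcfg = cfg["pra"]
    pop_sizes = tuple(int(p) for p in pcfg["pop_sizes"])
    n_sims = int(pcfg["n_sims"])
    pool = session_pools(rec, z)
    lo, hi = reliability.chance_window(pool, rec.baseline_mask(),
                                       pop_sizes=pop_sizes, n_sims=n_sims, seed=seed)
    res = reliability.simulate_selection(pool, pop_sizes=pop_sizes, n_sims=n_sims,
                                         seed=seed + 1)
    res.chance_window = (lo, hi)
    times = reliability.selection_time(res)
    tidy = pd.DataFrame({
        "time_ms": np.repeat(res.time_ms, len(pop_sizes)),
        "pop_size": np.tile(pop_sizes, res.freq.shape[0]),
        "freq_pct": res.freq.ravel(),
        "chance_lo": lo,
        "chance_hi": hi,
    })
    meta = {"chance_window": [lo, hi], "n_sims": n_sims, "seed": seed,
            "selection_time_ms": {str(k): v for k, v in times.items()}}
    return tidy, meta


def binned_pools_builder(rec: SessionRecording, z: np.ndarray):
    """Callable mapping a binned trial table to regression pools per RT bin."""

    def build(binned: pd.DataFrame) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        tid = rec.trials["trial_id"].to_numpy()
        for b, g in binned.groupby("rt_bin", sort=True):
            mask = np.isin(tid, g["trial_id"].to_numpy())
            sub = z[:, :, mask]
            rows = np.moveaxis(sub, 1, 2).reshape(-1, z.shape[1])
            rts = np.tile(g["rt_ms"].to_numpy(dtype=float), z.shape[0])
            keep = ~np.isnan(rows).any(axis=1)
            out[int(b)] = (rows[keep], rts[keep])
        return out

    return build


def fit_rt_stage(rec: SessionRecording, z: np.ndarray, cfg: dict, seed: int):
    fcfg = cfg["fit_rt"]
    correct = rec.trials[rec.trials["correct"]]
    oddball = correct[correct["rf_item"] == "target"]
    binned = behavior.rank_and_bin_rts(oddball, scheme=fcfg["scheme"])
    if fcfg["scheme"] == "fine":
        binned = binned[binned["rt_bin_used"]]
    # Feedforward window from the mean oddball population response.
    rf = rec.trials["rf_item"].to_numpy() == "target"
    mean_resp = np.nanmean(z[:, :, rf & rec.trials["correct"].to_numpy(dtype=bool)],
                           axis=(0, 2))
    window = rtmodel.find_feedforward_window(mean_resp, rec.time_ms)
    pools = binned_pools_builder(rec, z)(binned)
    table = rtmodel.build_regression_table(
        pools, rec.time_ms, window.window, pop_size=int(fcfg["pop_size"]),
        sims_per_bin=int(fcfg["sims_per_bin"]), seed=seed)
    mcmc = rtmodel.MCMCConfig(**fcfg["mcmc"])
    fit = rtmodel.fit_power_model(table, mcmc=mcmc,
                                  exponent_sign=int(fcfg["exponent_sign"]), seed=seed)
    return window, table, fit


def priming_stage(rec: SessionRecording, cfg: dict, seed: int) -> dict:
    pcfg = cfg["priming"]
    trials = rec.trials.copy()
    trials["priming"] = behavior.label_priming(trials)
    correct = trials[trials["correct"]]
    rt_by_rep = correct.groupby(correct["trial_in_block"].clip(upper=8))[
        "rt_ms"].median()
    cols = synthetic.simulate_column_baselines(
        n_columns=int(pcfg["n_columns"]), n_units=int(pcfg["n_units"]),
        n_blocks=int(pcfg["n_blocks"]), shift=float(pcfg["shift"]), seed=seed)
    per_col, t, p = behavior.priming_baseline_effect(cols)
    return {"rt_median_by_repetition": {int(k): float(v)
                                        for k, v in rt_by_rep.items()},
            "baseline_effect_t": t, "baseline_effect_p": p,
            "per_column": per_col.to_dict(orient="list"), "seed": seed}


def _plots(out: Path, tidy: pd.DataFrame, table: pd.DataFrame, fit, rec, csd):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    # Selection surface.
    fig, ax = plt.subplots(figsize=(6, 4))
    piv = tidy.pivot_table(index="pop_size", columns="time_ms", values="freq_pct")
    im = ax.imshow(piv.to_numpy(), aspect="auto", origin="lower",
                   extent=[piv.columns.min(), piv.columns.max(), 0, len(piv.index)])
    ax.set_yticks(np.arange(len(piv.index)) + 0.5, piv.index)
    ax.set_xlabel("time (ms)"); ax.set_ylabel("population size")
    fig.colorbar(im, label="oddball selection (%)")
    p = out / "selection_surface.png"; fig.savefig(p, dpi=100); plt.close(fig)
    written.append(p)
    # RT vs response with credible band.
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(table["spk"], table["rt_ms"], ".", ms=2, alpha=0.3, color="k")
    xs = np.linspace(table["spk"].min(), table["spk"].max(), 100)
    xs_s = xs / fit.scale["x_scale"]
    d = fit.draws.sample(min(len(fit.draws), 400), random_state=0)
    curves = (d["alpha"].to_numpy()[:, None]
              + d["beta"].to_numpy()[:, None]
              * xs_s[None, :] ** (fit.exponent_sign * d["r"].to_numpy()[:, None]))
    curves = curves * fit.scale["y_scale"]
    lo, med, hi = np.percentile(curves, [5.5, 50, 94.5], axis=0)
    ax.fill_between(xs, lo, hi, color="m", alpha=0.3)
    ax.plot(xs, med, "m-")
    ax.set_xlabel("population feedforward response"); ax.set_ylabel("RT (ms)")
    p = out / "rt_vs_response.png"; fig.savefig(p, dpi=100); plt.close(fig)
    written.append(p)
    # Laminar oddball-distractor CSD difference map.
    rf = rec.trials["rf_item"].to_numpy() == "target"
    valid = csd.valid_channels
    diff = np.full(csd.values.shape[:2], np.nan)
    diff[valid] = (csd.values[valid][:, :, rf].mean(axis=2)
                   - csd.values[valid][:, :, ~rf].mean(axis=2))
    fig, ax = plt.subplots(figsize=(6, 4))
    lim = np.nanmax(np.abs(diff))
    ax.imshow(diff, aspect="auto", cmap="PiYG", vmin=-lim, vmax=lim,
              extent=[rec.time_ms[0], rec.time_ms[-1], rec.n_channels, 0])
    ax.set_xlabel("time (ms)"); ax.set_ylabel("channel (superficial at top)")
    p = out / "csd_difference.png"; fig.savefig(p, dpi=100); plt.close(fig)
    written.append(p)
    return [str(w) for w in written]


def run_pipeline(config: dict | None = None, out_dir: str | Path = "lamsel_out",
                 session_path: str | Path | None = None) -> dict:
    """Execute the configured stages in order and return the report dict."""
    cfg = _merge(DEFAULT_CONFIG, config)
    unknown = [s for s in cfg["stages"] if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {unknown}")
    stages = [s for s in STAGES if s in cfg["stages"]]
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg, "artifacts": [], "stages_run": stages}

    rec = z = csd = align = None
    tidy = table = fit = window = None
    current = "setup"
    try:
        current = "simulate"
        if "simulate" in stages:
            rec = simulate_stage(cfg, seed)
            path = out / "session.h5"
            write_session(rec, path)
            report["artifacts"].append(str(path))
        elif session_path is not None:
            rec = read_session(session_path)
        else:
            raise ConfigurationError("no simulate stage and no session_path given")

        current = "preprocess"
        if "preprocess" in stages:
            z, csd = preprocess_stage(rec, cfg)
        current = "align"
        if "align" in stages:
            align = align_stage(rec, csd)
            report["alignment"] = {"marker_channel": align.marker_channel,
                                   "onset_ms": align.onset_ms}
        current = "pra"
        if "pra" in stages:
            tidy, meta = pra_stage(rec, z, cfg, seed + 10)
            path = out / "selection.csv"
            tidy.to_csv(path, index=False)
            (out / "selection_meta.json").write_text(json.dumps(meta, indent=2))
            report["artifacts"] += [str(path), str(out / "selection_meta.json")]
            report["pra"] = meta
        current = "fit-rt"
        if "fit-rt" in stages:
            window, table, fit = fit_rt_stage(rec, z, cfg, seed + 20)
            fit.draws.to_csv(out / "posterior_draws.csv", index=False)
            summary = {"window_ms": list(window.window),
                       "medians": fit.medians,
                       "ci89": {k: list(v) for k, v in fit.ci89.items()},
                       "r2": fit.r2, "diagnostics": fit.diagnostics,
                       "exponent_sign": fit.exponent_sign, "reliable": fit.reliable}
            (out / "power_fit.json").write_text(json.dumps(summary, indent=2))
            report["artifacts"] += [str(out / "posterior_draws.csv"),
                                    str(out / "power_fit.json")]
            report["fit_rt"] = summary
        current = "priming"
        if "priming" in stages:
            pr = priming_stage(rec, cfg, seed + 30)
            (out / "priming.json").write_text(json.dumps(pr, indent=2))
            report["artifacts"].append(str(out / "priming.json"))
            report["priming"] = {k: pr[k] for k in
                                 ("baseline_effect_t", "baseline_effect_p")}
        current = "report"
        if "report" in stages:
            if tidy is not None and fit is not None:
                report["artifacts"] += _plots(out, tidy, table, fit, rec, csd)
            path = out / "report.json"
            path.write_text(json.dumps(report, indent=2, default=str))
            report["artifacts"].append(str(path))
    except LamselError:
        raise
    except Exception as exc:  # tag the failing stage for the operator
        raise LamselError(f"stage '{current}' failed: {exc}") from exc
    return report
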