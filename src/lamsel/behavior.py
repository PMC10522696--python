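"""Reaction-time ranking/binning, accuracy summaries, and priming analyses.

RT ranking is done within session so every session contributes equally to each
bin. Two schemes are used: a coarse quartile split (4 bins) and a fine
25-bin split where the slowest bin is dropped as outliers. Priming of pop-out
is labeled from the position of a trial within its target-color block: the
first trial after a color switch is not primed; trials from the k-th
repetition onward (default k=3) are primed; the remainder are excluded as
transitional.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

log = logging.getLogger(__name__)

SCHEMES = {"quartile": 4, "fine": 25}


def rank_and_bin_rts(trials: pd.DataFrame, scheme: str = "quartile",
                     rt_col: str = "rt_ms", session_col: str = "session_id"
                     ) -> pd.DataFrame:
    """Within-session percentile ranks and equal-percentile RT bins.

    Returns a copy of ``trials`` with columns ``rt_rank_pct`` (percentile of
    the trial's RT within its session, stable tie order), ``rt_bin`` (1-based)
    and ``rt_bin_used`` (False only for the slowest fine bin, which is
    excluded as outliers). Pass correct trials only.
    """
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    n_bins = SCHEMES[scheme]
    out = trials.copy()
    out["rt_rank_pct"] = np.nan
    out["rt_bin"] = -1
    for _, idx in out.groupby(session_col, sort=False).groups.items():
        rts = out.loc[idx, rt_col].to_numpy(dtype=float)
        n = rts.size
        if n < n_bins:
            raise ConfigurationError(
                f"session with {n} trials cannot fill {n_bins} bins")
        ranks = stats.rankdata(rts, method="ordinal")  # stable ties
        pct = ranks / n
        out.loc[idx, "rt_rank_pct"] = 100.0 * pct
        out.loc[idx, "rt_bin"] = np.ceil(pct * n_bins - 1e-9).astype(int)
    out["rt_bin_used"] = (out["rt_bin"] < n_bins) if scheme == "fine" else True
    return out


def accuracy_summary(trials: pd.DataFrame, session_col: str = "session_id"
                     ) -> pd.DataFrame:
    """Per-session accuracy and RT statistics (RT over correct trials)."""
    if len(trials) == 0:
        raise ConfigurationError("empty trial table")
    rows = []
    for sid, g in trials.groupby(session_col, sort=False):
        correct = g["correct"].to_numpy(dtype=bool)
        rts = g.loc[g["correct"], "rt_ms"].to_numpy(dtype=float)
        rows.append((sid, len(g), 100.0 * correct.mean(),
                     float(np.mean(rts)) if rts.size else np.nan,
                     float(np.median(rts)) if rts.size else np.nan))
    return pd.DataFrame(rows, columns=["session_id", "n_trials", "accuracy_pct",
                                       "rt_mean_ms", "rt_median_ms"])


def rt_cdf_by_bin(trials: pd.DataFrame, bin_col: str = "rt_bin"
                  ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Empirical RT CDF (sorted RTs, cumulative fraction) per RT bin."""
    out = {}
    for b, g in trials.groupby(bin_col, sort=True):
        rts = np.sort(g["rt_ms"].to_numpy(dtype=float))
        out[int(b)] = (rts, np.arange(1, rts.size + 1) / rts.size)
    return out


def label_priming(trials: pd.DataFrame, k: int = 3) -> pd.Series:
    """Per-trial priming label from within-block position.

    Trial 1 of a block (immediately after a target-color switch) is
    ``not_primed``; trials at repetition >= ``k`` are ``primed``; trials in
    between are ``excluded``. A pure function of ``trial_in_block``.
    """
    if "trial_in_block" not in trials:
        raise ConfigurationError("missing block index (trial_in_block)")
    tib = trials["trial_in_block"].to_numpy()
    lab = np.where(tib == 1, "not_primed", np.where(tib >= k, "primed", "excluded"))
    return pd.Series(lab, index=trials.index, name="priming")


def priming_baseline_effect(column_baselines: pd.DataFrame, k: int = 3
                            ) -> tuple[pd.DataFrame, float, float]:
    """Baseline modulation of feature columns by target relevance and priming.

    ``column_baselines`` needs columns ``column_id``, ``pref_color``,
    ``target_color``, ``trial_in_block`` and ``baseline`` (raw, not
    baseline-corrected, pre-stimulus spiking). For each column and priming
    condition the difference mean(baseline | target = preferred color) -
    mean(baseline | target = non-preferred) is computed; a paired two-sided
    t test compares primed vs not-primed differences across columns.

    Returns (per-column table, t statistic, p value).
    """
    req = {"column_id", "pref_color", "target_color", "trial_in_block", "baseline"}
    missing = req - set(column_baselines.columns)
    if missing:
        raise ConfigurationError(f"missing columns: {sorted(missing)}")
    df = column_baselines.copy()
    df["priming"] = label_priming(df, k=k)
    rows = []
    for col, g in df.groupby("column_id", sort=False):
        pref = g["pref_color"].iloc[0]
        diffs = {}
        for cond in ("not_primed", "primed"):
            sub = g[g["priming"] == cond]
            on = sub.loc[sub["target_color"] == pref, "baseline"]
            off = sub.loc[sub["target_color"] != pref, "baseline"]
            diffs[cond] = (on.mean() - off.mean()
                           if len(on) and len(off) else np.nan)
        rows.append((col, pref, diffs["not_primed"], diffs["primed"]))
    per_col = pd.DataFrame(rows, columns=["column_id", "pref_color",
                                          "diff_not_primed", "diff_primed"])
    ok = per_col.dropna()
    if len(ok) < 2:
        raise ConfigurationError("need >= 2 columns with both priming conditions")
    t, p = stats.ttest_rel(ok["diff_primed"], ok["diff_not_primed"])
    return per_col, float(t), float(p)


def not_primed_model_check(trials: pd.DataFrame, pool_builder, fit_fn,
                           scheme: str = "fine", k: int = 3, **fit_kwargs):
    """Refit the RT power model on not-primed trials only.

    ``pool_builder(binned_trials)`` must return the ``binned_pools`` mapping
    consumed by :func:`lamsel.rtmodel.build_regression_table`-based fitting;
    ``fit_fn(binned_pools, **fit_kwargs)`` performs table construction + fit.
    RT percentiles are re-ranked within the not-primed subset, so when every
    block has length 1 the subset equals the full set and the fit is
    identical.
    """
    lab = label_priming(trials, k=k)
    subset = trials[lab == "not_primed"]
    if len(subset) == 0:
        raise ConfigurationError("not-primed subset is empty")
    binned = rank_and_bin_rts(subset, scheme=scheme)
    if scheme == "fine":
        binned = binned[binned["rt_bin_used"]]
    log.info("not-primed model check on %d of %d trials", len(subset), len(trials))
    return fit_fn(pool_builder(binned), **fit_kwargs)
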