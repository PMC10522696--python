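import itertools
import logging
import math
import warnings

import numpy as np
import pytest

import lamsel as L


def exact_win_probability(odd_vals, dist_vals, n_items, pop_size):
    """Brute-force enumeration of the oddball win probability at one timepoint.

    Enumerates every ordered draw combination for the summed population
    response of each alternative; ties split uniformly among the tied maxima.
    Independent oracle for the Monte-Carlo selection statistic.
    """
    def sum_dist(vals):
        out = {}
        for comb in itertools.product(vals, repeat=pop_size):
            s = sum(comb)
            out[s] = out.get(s, 0.0) + 1.0 / len(vals) ** pop_size
        return out

    odd = sum_dist(odd_vals)
    dist = sum_dist(dist_vals)
    n_d = n_items - 1
    p_win = 0.0
    for s, ps in odd.items():
        p_lt = sum(p for v, p in dist.items() if v < s)
        p_eq = sum(p for v, p in dist.items() if v == s)
        for k in range(n_d + 1):
            p_win += ps * (math.comb(n_d, k) * p_eq ** k
                           * p_lt ** (n_d - k) / (k + 1))
    return 100.0 * p_win

warnings.filterwarnings("ignore", category=FutureWarning)
logging.getLogger("lamsel").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_session():
    """A 200-trial synthetic session with default ground truth."""
    cfg = L.SimConfig(n_trials=200, seed=1)
    truth = L.GroundTruth()
    return L.generate_session(cfg, truth), cfg, truth


@pytest.fixture(scope="session")
def zscored(small_session):
    rec, _, _ = small_session
    return L.baseline_normalize(rec.mua, rec.time_ms, mode="zscore")


@pytest.fixture(scope="session")
def aligned(small_session):
    rec, _, _ = small_session
    csd = L.compute_csd(rec.lfp, rec.channel_spacing_mm)
    align = L.find_granular_sink(csd, rec.time_ms)
    return csd, align
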