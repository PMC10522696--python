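"""In-memory containers for laminar session recordings.

A session holds two channel x time x trial arrays (local field potential and
multiunit envelope), sampling metadata, and a per-trial behavior table. Time is
expressed in milliseconds relative to stimulus (search array) onset; channel 0
is the most superficial contact.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Columns every trial table must provide.
TRIAL_COLUMNS = (
    "trial_id",
    "session_id",
    "block_index",
    "trial_in_block",
    "target_color",
    "target_position",
    "rf_item",
    "rf_geometry",
    "correct",
    "chosen_position",
    "rt_ms",
)


@dataclass
class SessionRecording:
    """A laminar recording session.

    Parameters
    ----------
    lfp, mua : ndarray, shape (n_channels, n_time, n_trials)
        Local field potential (volts, arbitrary scale) and multiunit envelope.
    sample_rate_hz : float
        Sampling rate of the time axis.
    time_ms : ndarray, shape (n_time,)
        Time in ms relative to stimulus onset (0 = onset).
    channel_spacing_mm : float
        Inter-contact distance of the linear probe.
    trials : pandas.DataFrame
        One row per trial; see :data:`TRIAL_COLUMNS`.
    meta : dict
        Free-form metadata (generator ground truth, seeds, units).
    """

    lfp: np.ndarray
    mua: np.ndarray
    sample_rate_hz: float
    time_ms: np.ndarray
    channel_spacing_mm: float
    trials: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=float)
        self.mua = np.asarray(self.mua, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.lfp.shape != self.mua.shape:
            raise ConfigurationError(
                f"lfp shape {self.lfp.shape} != mua shape {self.mua.shape}"
            )
        if self.lfp.ndim != 3:
            raise ConfigurationError("lfp/mua must be (channels, time, trials)")
        if self.lfp.shape[1] != self.time_ms.size:
            raise ConfigurationError("time axis length mismatch")
        if self.lfp.shape[2] != len(self.trials):
            raise ConfigurationError("trial count mismatch between arrays and table")
        if self.time_ms[0] > -100.0:
            raise ConfigurationError("recording must include >=100 ms pre-stimulus")

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[2]

    @property
    def time_zero(self) -> int:
        """Index of the first sample at or after stimulus onset."""
        return int(np.searchsorted(self.time_ms, 0.0))

    def baseline_mask(self, duration_ms: float = 100.0) -> np.ndarray:
        """Boolean time mask for the pre-stimulus baseline window."""
        return (self.time_ms >= -duration_ms) & (self.time_ms < 0.0)
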