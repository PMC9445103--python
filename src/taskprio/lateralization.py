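"""Hemispheric alpha-power asymmetry relative to the retro-cue direction.

For each mirror electrode pair the raw power of the member ipsilateral to
the retro-cued side and of the contralateral member is averaged across
trials, and the lateralization index

    (ipsilateral - contralateral) / (ipsilateral + contralateral)

is formed per pair, frequency and time point.  Positive values mean weaker
contralateral alpha, i.e. attention directed toward the cued memory item.
Trials are drawn so that retro-cue direction and number-task response side
are balanced (each of the four cells truncated to the minimum cell count).
The pooled curve averages the 17 posterior pairs and wavelet frequencies
8-15 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import montage
from ._utils import window_mask
from .containers import TFRSet

POOLED_BAND_HZ = (8.0, 15.0)


def draw_balanced_trials(metadata: pd.DataFrame, seed: int = 0) -> np.ndarray:
    """Positional trial indices balanced over retro-cue side x response side.

    Every cell is randomly truncated to the smallest cell count; an empty
    cell is an error.
    """
    rng = np.random.default_rng(seed)
    cue = metadata["retrocue_side"].to_numpy()
    resp = metadata["response_side"].to_numpy()
    cells = {}
    for c in ("left", "right"):
        for r in ("left", "right"):
            cells[(c, r)] = np.flatnonzero((cue == c) & (resp == r))
    m = min(len(v) for v in cells.values())
    if m == 0:
        empty = [k for k, v in cells.items() if len(v) == 0]
        raise ValueError(f"empty retro-cue x response cells: {empty}")
    keep = np.concatenate([
        rng.choice(v, size=m, replace=False) for v in cells.values()
    ])
    return np.sort(keep)


@dataclass
class LateralizationResult:
    """Index per pair x frequency x time, plus the axes needed to pool."""

    index: np.ndarray
    pairs: list[tuple[str, str]]
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    n_trials_used: int

    def pooled_timecourse(self, band_hz: tuple[float, float] = POOLED_BAND_HZ) -> np.ndarray:
        """Average over all pairs and the wavelet centers inside ``band_hz``
        (endpoints inclusive); returns one value per time point."""
        fmask = (self.freqs_hz >= band_hz[0]) & (self.freqs_hz <= band_hz[1])
        if not fmask.any():
            raise ValueError(f"no wavelet frequencies inside {band_hz}")
        return self.index[:, fmask].mean(axis=(0, 1))

    def pooled_window_mean(self, window_ms, band_hz=POOLED_BAND_HZ) -> float:
        curve = self.pooled_timecourse(band_hz)
        return float(curve[window_mask(self.times_ms, window_ms)].mean())


def lateralization_index(
    raw_tfr: TFRSet,
    metadata: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    trials: np.ndarray | None = None,
) -> LateralizationResult:
    """Lateralization index from raw (linear) power.

    ``trials`` (e.g. from :func:`draw_balanced_trials`) selects the trial
    subset; trial averaging happens before the index is formed, separately
    for ipsi- and contralateral pair members.
    """
    if raw_tfr.is_db:
        raise ValueError("lateralization index requires raw power, not dB")
    pairs = montage.POSTERIOR_PAIRS if pairs is None else pairs
    pair_idx = montage.pair_indices(raw_tfr.channel_names, pairs)
    if trials is None:
        trials = np.arange(raw_tfr.n_trials)
    cue = metadata["retrocue_side"].to_numpy()[trials]
    power = raw_tfr.power[trials]  # (trials, ch, f, t)

    left = power[:, pair_idx[:, 0]]   # left-hemisphere pair members
    right = power[:, pair_idx[:, 1]]
    cue_left = (cue == "left")[:, None, None, None]
    ipsi = np.where(cue_left, left, right).mean(0)
    contra = np.where(cue_left, right, left).mean(0)

    with np.errstate(invalid="ignore", divide="ignore"):
        index = (ipsi - contra) / (ipsi + contra)
    index = np.where(ipsi + contra == 0, 0.0, index)
    return LateralizationResult(
        index=index,
        pairs=list(pairs),
        freqs_hz=raw_tfr.freqs_hz,
        times_ms=raw_tfr.times_ms,
        n_trials_used=len(trials),
    )
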