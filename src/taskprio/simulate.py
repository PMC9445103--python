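"""Synthetic data for the cued dual-task (task-prioritization) paradigm.

Each simulated trial nests a number classification task (NCT) inside the
retention interval of a retro-cued working memory task (WMT).  A relevance
cue at trial start marks one task as important; feedback at trial end
weights the important task's score three times as strongly (maximum 75
points cued vs 25 points un-cued).

The EEG generator emits "clean", epoched data at 200 Hz (preprocessing is
out of scope): 1/f background noise per channel plus additive, band-limited
oscillatory bursts carrying the condition contrasts, a lateralized posterior
alpha component that follows the retro-cue side, and classification-type
specific scalp patterns during the number task.  Identical seed and effect
specification give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

from . import montage
from .containers import EpochSet

#: trial-event onsets in ms relative to relevance-cue onset
EVENT_ONSETS_MS: dict[str, float] = {
    "relevance_cue": 0.0,       # 500 ms on screen
    "memory_items": 3000.0,     # 400 ms
    "classification_cue": 5600.0,   # 200 ms
    "classification_digit": 6800.0,  # 200 ms
    "retro_cue": 9600.0,        # 200 ms
    "wm_target": 10800.0,
}

#: stimulus durations in ms (wm_target stays until response)
EVENT_DURATIONS_MS: dict[str, float] = {
    "relevance_cue": 500.0,
    "memory_items": 400.0,
    "classification_cue": 200.0,
    "classification_digit": 200.0,
    "retro_cue": 200.0,
}

NCT_RT_WINDOW_MS = (200.0, 1800.0)  # registration window after digit onset
MAX_POINTS_CUED = 75.0
MAX_POINTS_UNCUED = 25.0

TASKS = ("NCT", "WMT")
SIDES = ("left", "right")
CLASSIFICATION_TYPES = ("odd_even", "smaller_bigger")


# --------------------------------------------------------------------------
# trial schedule
# --------------------------------------------------------------------------

def make_schedule(n_blocks: int, trials_per_block: int, seed: int) -> pd.DataFrame:
    """Balanced, block-randomized trial schedule.

    Within every block each level of important task, retro-cue side and
    classification type appears equally often and every pairwise
    co-occurrence is balanced.  This requires ``trials_per_block`` divisible
    by 4; when it is also divisible by 8 all triple cells are equal, and for
    the study's 60-trial blocks (60/8 = 7.5) the triple cells alternate
    between 7 and 8 trials in an XOR pattern that keeps all pairwise margins
    exact, flipped on alternating blocks.  Response side is split as evenly
    as possible within each factor cell.  Returns one row per trial; the
    fixed event onsets are attached as ``schedule.attrs["event_onsets_ms"]``.
    """
    if trials_per_block % 4:
        raise ValueError(
            f"trials_per_block={trials_per_block} not divisible by 4: factor "
            "levels and pairwise co-occurrences cannot be balanced"
        )
    rng = np.random.default_rng(seed)
    reps = trials_per_block // 8
    half = (trials_per_block % 8) // 4  # 0 or 1 extra trial in half the cells
    rows = []
    for block in range(n_blocks):
        cells = []
        for i, task in enumerate(TASKS):
            for j, cue in enumerate(SIDES):
                for k, ctype in enumerate(CLASSIFICATION_TYPES):
                    n_cell = reps + (half if (i ^ j ^ k) == block % 2 else 0)
                    resp = list(SIDES) * (n_cell // 2)
                    if n_cell % 2:
                        resp.append(rng.choice(SIDES))
                    rng.shuffle(resp)
                    cells += [
                        {"block": block, "important_task": task,
                         "retrocue_side": cue, "classification_type": ctype,
                         "response_side": r}
                        for r in resp
                    ]
        order = rng.permutation(len(cells))
        rows += [cells[i] for i in order]
    schedule = pd.DataFrame(rows)
    schedule.insert(0, "trial_index", np.arange(len(schedule)))
    schedule.attrs["event_onsets_ms"] = dict(EVENT_ONSETS_MS)
    return schedule


# --------------------------------------------------------------------------
# feedback scores
# --------------------------------------------------------------------------

def feedback_nct(rt_ms: float | None, correct: bool, cued: bool) -> float:
    """Number-classification feedback points.

    The full score (75 cued / 25 un-cued) is awarded for responses within
    200-400 ms of digit onset; points then fall linearly to zero at the
    1800 ms registration deadline.  Missing or incorrect answers score zero.
    """
    mx = MAX_POINTS_CUED if cued else MAX_POINTS_UNCUED
    if rt_ms is None or (isinstance(rt_ms, float) and np.isnan(rt_ms)):
        return 0.0
    lo, hi = NCT_RT_WINDOW_MS
    if not lo <= rt_ms <= hi:
        raise ValueError(f"rt_ms={rt_ms} outside registration window {NCT_RT_WINDOW_MS}")
    if not correct:
        return 0.0
    if rt_ms <= 400.0:
        return mx
    return mx - mx / (1800.0 - 400.0) * (rt_ms - 400.0)


def feedback_wmt(deviation_deg: float | None, cued: bool) -> float:
    """Working-memory feedback points: linear from the maximum at 0 degrees
    of angular deviation down to zero at 45 degrees; zero beyond, zero when
    missing."""
    mx = MAX_POINTS_CUED if cued else MAX_POINTS_UNCUED
    if deviation_deg is None or (isinstance(deviation_deg, float) and np.isnan(deviation_deg)):
        return 0.0
    if deviation_deg < 0:
        raise ValueError(f"deviation_deg={deviation_deg} must be nonnegative")
    if deviation_deg >= 45.0:
        return 0.0
    return mx - mx / 45.0 * deviation_deg


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

@dataclass
class BehaviorParams:
    """Per-condition behavioral distribution parameters.

    Defaults are the printed condition means/SDs of the study population;
    RTs are drawn log-normal (moment-matched) and truncated to the
    registration windows, angular deviations truncated-normal on [0, 180].
    Keys: condition in which the *respective* task was important or not.
    """

    nct_rt_mean_ms: dict = field(default_factory=lambda: {"NCT": 537.00, "WMT": 562.86})
    nct_rt_sd_ms: dict = field(default_factory=lambda: {"NCT": 114.13, "WMT": 119.61})
    nct_error_rate: dict = field(default_factory=lambda: {"NCT": 0.0856, "WMT": 0.0866})
    wmt_rt_mean_ms: dict = field(default_factory=lambda: {"NCT": 1292.68, "WMT": 1368.91})
    wmt_rt_sd_ms: dict = field(default_factory=lambda: {"NCT": 267.38, "WMT": 300.92})
    deviation_mean_deg: dict = field(default_factory=lambda: {"NCT": 13.48, "WMT": 11.77})
    deviation_sd_deg: dict = field(default_factory=lambda: {"NCT": 5.23, "WMT": 4.07})


def _lognormal_truncated(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    out = rng.lognormal(mu, np.sqrt(sigma2), size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.lognormal(mu, np.sqrt(sigma2), bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _normal_truncated(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def simulate_behavior(
    schedule: pd.DataFrame,
    params: BehaviorParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample per-trial behavioral outcomes and feedback scores."""
    params = params or BehaviorParams()
    rng = np.random.default_rng(seed)
    n = len(schedule)
    task = schedule["important_task"].to_numpy()

    rt_nct = np.empty(n)
    correct = np.empty(n, dtype=bool)
    rt_wmt = np.empty(n)
    dev = np.empty(n)
    for cond in TASKS:
        m = task == cond
        rt_nct[m] = _lognormal_truncated(
            rng, params.nct_rt_mean_ms[cond], params.nct_rt_sd_ms[cond],
            *NCT_RT_WINDOW_MS, m.sum())
        correct[m] = rng.random(m.sum()) >= params.nct_error_rate[cond]
        rt_wmt[m] = _lognormal_truncated(
            rng, params.wmt_rt_mean_ms[cond], params.wmt_rt_sd_ms[cond],
            200.0, 4500.0, m.sum())
        dev[m] = _normal_truncated(
            rng, params.deviation_mean_deg[cond], params.deviation_sd_deg[cond],
            0.0, 180.0, m.sum())

    nct_cued = task == "NCT"
    fp_nct = np.array([
        feedback_nct(r, c, q) for r, c, q in zip(rt_nct, correct, nct_cued)
    ])
    fp_wmt = np.array([
        feedback_wmt(d, q) for d, q in zip(dev, ~nct_cued)
    ])
    return pd.DataFrame({
        "rt_nct_ms": rt_nct,
        "correct_nct": correct,
        "rt_wmt_ms": rt_wmt,
        "deviation_deg": dev,
        "fp_nct": fp_nct,
        "fp_wmt": fp_wmt,
        "fp_total": fp_nct + fp_wmt,
    }, index=schedule.index)


# --------------------------------------------------------------------------
# EEG effect specification
# --------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Background model: 1/f power-law noise plus white sensor noise."""

    exponent: float = 1.0
    sd_uv: float = 10.0
    white_sd_uv: float = 1.0


@dataclass
class BandEffect:
    """Additive oscillatory burst (random phase per trial).

    ``condition`` restricts the burst to trials where metadata column equals
    the given level (e.g. ``("important_task", "NCT")``); ``None`` applies
    it to every trial.  ``channels=None`` means all channels.
    """

    freq_hz: float
    window_ms: tuple[float, float]
    amplitude_uv: float
    channels: list[str] | None = None
    condition: tuple[str, str] | None = None


@dataclass
class LateralizedAlphaEffect:
    """Posterior alpha-band burst with hemispheric amplitude asymmetry.

    The asymmetry is parameterized directly as the target lateralization
    index ``index`` of the burst's band power: the member of each electrode
    pair ipsilateral to the retro-cued side receives amplitude
    ``A*sqrt(1+index)`` and the contralateral member ``A*sqrt(1-index)``.
    One carrier oscillation per 1 Hz step spans ``band_hz`` (random phases
    per trial and carrier) so that *every* wavelet pooled over the band sees
    the same asymmetry, and ``amplitude_uv`` (per carrier) is chosen large
    relative to the background so the burst dominates the band power and the
    measured pooled index approaches ``index``.
    """

    index: float = 0.02
    band_hz: tuple[float, float] = (8.0, 15.0)
    window_ms: tuple[float, float] = (
        EVENT_ONSETS_MS["retro_cue"], EVENT_ONSETS_MS["wm_target"])
    amplitude_uv: float = 25.0
    pairs: list[tuple[str, str]] | None = None  # None -> posterior cluster

    @property
    def carrier_freqs_hz(self) -> np.ndarray:
        return np.arange(self.band_hz[0], self.band_hz[1] + 0.5)


@dataclass
class DecodingEffect:
    """Classification-type-specific scalp patterns during the number task.

    One fixed random unit-norm 64-channel pattern per class drives a
    phase-locked broadband (ERP-like) component, and a second pattern per
    class modulates the amplitude of a 10 Hz oscillation so that both
    broadband-voltage and alpha-power features are linearly separable.
    """

    window_ms: tuple[float, float] = (5600.0, 8000.0)
    erp_amplitude_uv: float = 2.0
    alpha_amplitude_uv: float = 4.0
    alpha_freq_hz: float = 10.0
    label_column: str = "classification_type"


@dataclass
class EffectSpec:
    """Full planted-effect specification; the seed fully determines output."""

    band_effects: list[BandEffect] = field(default_factory=list)
    lateralized_alpha: LateralizedAlphaEffect | None = None
    decoding: DecodingEffect | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0


def default_effect_spec(seed: int = 0) -> EffectSpec:
    """Effect layout emulating the study's observed phenomena: theta/beta
    enhancement for NCT-important trials around the relevance cue and during
    the retention interval, an alpha increase for WMT-important trials
    during number-task performance, retro-cue-locked posterior alpha
    lateralization, and classification-type patterns in the number-task
    window."""
    return EffectSpec(
        band_effects=[
            BandEffect(5.0, (-150.0, 1000.0), 3.0, condition=("important_task", "NCT")),
            BandEffect(13.0, (-150.0, 1000.0), 2.0, condition=("important_task", "NCT")),
            BandEffect(5.0, (3000.0, 5600.0), 3.0, condition=("important_task", "NCT")),
            BandEffect(10.0, (5600.0, 7800.0), 3.0, condition=("important_task", "WMT")),
        ],
        lateralized_alpha=LateralizedAlphaEffect(),
        decoding=DecodingEffect(),
        seed=seed,
    )


def null_effect_spec(seed: int = 0) -> EffectSpec:
    """Pure-background spec: no planted effects of any kind."""
    return EffectSpec(seed=seed)


# --------------------------------------------------------------------------
# EEG generation
# --------------------------------------------------------------------------

def _one_over_f_noise(rng, n_traces, n_samples, sfreq, model: NoiseModel):
    """1/f-shaped Gaussian noise, per-trace SD normalized to model.sd_uv."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-model.exponent / 2.0)
    shape[0] = 0.0  # no DC
    white = rng.standard_normal((n_traces, n_samples))
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * shape, n=n_samples, axis=-1)
    shaped /= shaped.std(axis=-1, keepdims=True)
    out = shaped * model.sd_uv
    if model.white_sd_uv > 0:
        out += rng.standard_normal((n_traces, n_samples)) * model.white_sd_uv
    return out


def _burst_envelope(times_ms, window_ms):
    lo, hi = window_ms
    if hi <= lo:
        raise ValueError(f"effect window {window_ms} is empty")
    if lo < times_ms[0] or hi > times_ms[-1]:
        raise ValueError(f"effect window {window_ms} outside epoch span")
    env = np.zeros_like(times_ms)
    m = (times_ms >= lo) & (times_ms <= hi)
    env[m] = tukey(int(m.sum()), alpha=0.25)
    return env


def _channel_idx(names, channels):
    if channels is None:
        return np.arange(len(names))
    lookup = {n: i for i, n in enumerate(names)}
    bad = [c for c in channels if c not in lookup]
    if bad:
        raise KeyError(f"unknown channel labels in effect spec: {bad}")
    return np.array([lookup[c] for c in channels])


def simulate_epochs(
    schedule: pd.DataFrame,
    spec: EffectSpec,
    sfreq: float = 200.0,
    tmin_ms: float = -3700.0,
    tmax_ms: float = 13700.0,
    channel_names: list[str] | None = None,
) -> EpochSet:
    """Generate epoched synthetic EEG with the planted effects of ``spec``.

    The default epoch spans -3700 to +13700 ms around the relevance cue so
    that 700 ms can be trimmed at each side after wavelet convolution.
    """
    names = channel_names if channel_names is not None else montage.channel_names()
    n_ch = len(names)
    n_tr = len(schedule)
    dt = 1000.0 / sfreq
    times = np.arange(tmin_ms, tmax_ms + dt / 2, dt)
    n_s = len(times)
    rng = np.random.default_rng(spec.seed)

    data = np.empty((n_tr, n_ch, n_s), dtype=np.float32)
    chunk = max(1, int(2e7 // n_s))  # bound FFT workspace
    for lo in range(0, n_tr * n_ch, chunk):
        hi = min(lo + chunk, n_tr * n_ch)
        data.reshape(-1, n_s)[lo:hi] = _one_over_f_noise(
            rng, hi - lo, n_s, sfreq, spec.noise)

    t_sec = times / 1000.0

    for eff in spec.band_effects:
        if eff.amplitude_uv < 0:
            raise ValueError("effect amplitudes must be nonnegative")
        env = _burst_envelope(times, eff.window_ms)
        ch = _channel_idx(names, eff.channels)
        if eff.condition is None:
            trials = np.arange(n_tr)
        else:
            col, level = eff.condition
            trials = np.flatnonzero(schedule[col].to_numpy() == level)
        phases = rng.uniform(0, 2 * np.pi, n_tr)  # drawn for all trials: keeps
        # the RNG stream independent of the condition labels
        for tr in trials:
            data[tr, ch] += (
                eff.amplitude_uv * env * np.cos(2 * np.pi * eff.freq_hz * t_sec + phases[tr])
            ).astype(np.float32)

    lat = spec.lateralized_alpha
    if lat is not None:
        if not -1.0 < lat.index < 1.0:
            raise ValueError("lateralization index must lie in (-1, 1)")
        pairs = lat.pairs if lat.pairs is not None else montage.POSTERIOR_PAIRS
        idx = montage.pair_indices(names, pairs)
        env = _burst_envelope(times, lat.window_ms)
        amp_hi = lat.amplitude_uv * np.sqrt(1.0 + lat.index)
        amp_lo = lat.amplitude_uv * np.sqrt(1.0 - lat.index)
        carriers = lat.carrier_freqs_hz
        phases = rng.uniform(0, 2 * np.pi, (n_tr, len(carriers)))
        cue = schedule["retrocue_side"].to_numpy()
        for tr in range(n_tr):
            wave = (env * np.cos(
                2 * np.pi * carriers[:, None] * t_sec[None, :] + phases[tr][:, None]
            ).sum(0)).astype(np.float32)
            ipsi, contra = (idx[:, 0], idx[:, 1]) if cue[tr] == "left" else (idx[:, 1], idx[:, 0])
            data[tr, ipsi] += amp_hi * wave
            data[tr, contra] += amp_lo * wave

    dec = spec.decoding
    if dec is not None:
        env = _burst_envelope(times, dec.window_ms)
        labels = schedule[dec.label_column].to_numpy()
        classes = sorted(pd.unique(labels))
        erp_patterns = {}
        alpha_weights = {}
        for c in classes:  # one fixed random pattern per class and feature kind
            p = rng.standard_normal(n_ch)
            erp_patterns[c] = p / np.linalg.norm(p)
            q = rng.standard_normal(n_ch)
            alpha_weights[c] = np.clip(1.0 + q / np.linalg.norm(q) * np.sqrt(n_ch) * 0.5, 0.0, None)
        phases = rng.uniform(0, 2 * np.pi, n_tr)
        for tr in range(n_tr):
            c = labels[tr]
            data[tr] += (dec.erp_amplitude_uv * erp_patterns[c][:, None] * env).astype(np.float32)
            wave = env * np.cos(2 * np.pi * dec.alpha_freq_hz * t_sec + phases[tr])
            data[tr] += (dec.alpha_amplitude_uv * alpha_weights[c][:, None] * wave).astype(np.float32)

    return EpochSet(data=data, sfreq=sfreq, times_ms=times,
                    channel_names=list(names), metadata=schedule.copy())


def simulate_subject(
    seed: int,
    n_blocks: int = 10,
    trials_per_block: int = 60,
    spec: EffectSpec | None = None,
    behavior_params: BehaviorParams | None = None,
    **epoch_kwargs,
) -> EpochSet:
    """Schedule + behavior + EEG for one synthetic participant."""
    from ._utils import derive_seed

    spec = default_effect_spec(derive_seed(seed, "eeg")) if spec is None else replace(
        spec, seed=derive_seed(seed, "eeg"))
    schedule = make_schedule(n_blocks, trials_per_block, derive_seed(seed, "schedule"))
    behavior = simulate_behavior(schedule, behavior_params, derive_seed(seed, "behavior"))
    metadata = pd.concat([schedule, behavior], axis=1)
    metadata.attrs = schedule.attrs
    return simulate_epochs(metadata, spec, **epoch_kwargs)
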