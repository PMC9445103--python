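"""Complex Morlet wavelet time-frequency decomposition.

Wavelets are parameterized by their full width at half maximum (FWHM): 19
center frequencies linearly spaced 2-20 Hz with temporal FWHM interpolated
linearly from 1000 ms (2 Hz) to 200 ms (20 Hz).  The spectral FWHM follows
from the Gaussian time-frequency reciprocity FWHM_t * FWHM_f = 4*ln(2)/pi
(~0.88 Hz at 2 Hz, ~4.4 Hz at 20 Hz).  Wavelets are unit-energy normalized;
power is the squared magnitude of the complex convolution, edge-trimmed by
700 ms at each side, and optionally decibel-normalized against the
condition-pooled mean power from 700 to 200 ms before the relevance cue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from ._utils import window_mask
from .containers import EpochSet, TFRSet

#: Gaussian reciprocity constant: FWHM_t[s] * FWHM_f[Hz] (amplitude spectra)
FWHM_PRODUCT = 4.0 * np.log(2.0) / np.pi

DEFAULT_FREQS_HZ = np.linspace(2.0, 20.0, 19)
FWHM_MS_ENDPOINTS = ((2.0, 1000.0), (20.0, 200.0))
BASELINE_WINDOW_MS = (-700.0, -200.0)
EDGE_TRIM_MS = 700.0


@dataclass
class WaveletBank:
    """Morlet wavelet family: center frequencies with temporal and spectral
    FWHM per wavelet (reciprocity-consistent) at a given sampling rate."""

    freqs_hz: np.ndarray
    fwhm_ms: np.ndarray
    fwhm_hz: np.ndarray
    sfreq: float

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.fwhm_ms = np.asarray(self.fwhm_ms, dtype=float)
        self.fwhm_hz = np.asarray(self.fwhm_hz, dtype=float)
        if not (np.diff(self.freqs_hz) > 0).all():
            raise ValueError("frequencies must be strictly increasing")
        prod = self.fwhm_ms / 1000.0 * self.fwhm_hz
        if not np.allclose(prod, FWHM_PRODUCT, rtol=1e-6):
            raise ValueError("fwhm_ms and fwhm_hz violate Gaussian reciprocity")

    def kernel(self, i: int) -> np.ndarray:
        """Unit-energy complex Morlet kernel for wavelet ``i`` (length >= 8
        temporal SDs, odd)."""
        sigma_s = self.fwhm_ms[i] / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        half = int(np.ceil(4.0 * sigma_s * self.sfreq))
        t = np.arange(-half, half + 1) / self.sfreq
        w = np.exp(2j * np.pi * self.freqs_hz[i] * t) * np.exp(-(t**2) / (2 * sigma_s**2))
        return w / np.sqrt(np.sum(np.abs(w) ** 2))


def build_wavelets(sfreq: float, freqs_hz: np.ndarray | None = None) -> WaveletBank:
    """Construct the wavelet bank (default: 19 wavelets, 2-20 Hz).

    Temporal FWHM is interpolated linearly in frequency between 1000 ms at
    2 Hz and 200 ms at 20 Hz; spectral FWHM follows from reciprocity.
    """
    freqs = DEFAULT_FREQS_HZ if freqs_hz is None else np.asarray(freqs_hz, dtype=float)
    if sfreq < 2.0 * freqs.max():
        raise ValueError(
            f"sfreq={sfreq} Hz below Nyquist limit for {freqs.max()} Hz wavelets")
    (f0, w0), (f1, w1) = FWHM_MS_ENDPOINTS
    fwhm_ms = w0 + (freqs - f0) * (w1 - w0) / (f1 - f0)
    if (fwhm_ms <= 0).any():
        raise ValueError("temporal FWHM interpolation went nonpositive")
    fwhm_hz = FWHM_PRODUCT / (fwhm_ms / 1000.0)
    return WaveletBank(freqs_hz=freqs, fwhm_ms=fwhm_ms, fwhm_hz=fwhm_hz, sfreq=sfreq)


def decompose(
    epochs: EpochSet,
    bank: WaveletBank | None = None,
    channels: list[str] | None = None,
) -> TFRSet:
    """Raw (linear) power per trial/channel/frequency with edge trimming.

    Convolution runs in the frequency domain with 'same' alignment; the
    first and last 700 ms of each epoch are deleted afterwards.
    """
    bank = bank if bank is not None else build_wavelets(epochs.sfreq)
    if not np.isclose(bank.sfreq, epochs.sfreq):
        raise ValueError("wavelet bank sampling rate differs from epochs")
    times = epochs.times_ms
    keep = (times >= times[0] + EDGE_TRIM_MS) & (times <= times[-1] - EDGE_TRIM_MS)
    if keep.sum() < 1:
        raise ValueError("epoch too short for 700 ms edge trimming")

    if channels is None:
        ch_idx = np.arange(len(epochs.channel_names))
        ch_names = list(epochs.channel_names)
    else:
        lookup = {n: i for i, n in enumerate(epochs.channel_names)}
        missing = [c for c in channels if c not in lookup]
        if missing:
            raise KeyError(f"channels not in epochs: {missing}")
        ch_idx = np.array([lookup[c] for c in channels])
        ch_names = list(channels)

    data = epochs.data[:, ch_idx]
    n_tr, n_ch, n_s = data.shape
    kernels = [bank.kernel(i) for i in range(len(bank.freqs_hz))]
    max_len = max(len(k) for k in kernels)
    nfft = next_fast_len(n_s + max_len - 1)
    spectra = [fft(k, nfft) for k in kernels]

    power = np.empty((n_tr, n_ch, len(kernels), int(keep.sum())), dtype=np.float32)
    chunk = max(1, int(4e7 // (n_ch * nfft)))
    for lo in range(0, n_tr, chunk):
        hi = min(lo + chunk, n_tr)
        x = fft(data[lo:hi].astype(np.float64), nfft, axis=-1)
        for fi, (k, wf) in enumerate(zip(kernels, spectra)):
            start = (len(k) - 1) // 2
            conv = ifft(x * wf, axis=-1)[..., start:start + n_s]
            power[lo:hi, :, fi] = (np.abs(conv[..., keep]) ** 2).astype(np.float32)

    return TFRSet(
        power=power,
        freqs_hz=bank.freqs_hz,
        times_ms=times[keep],
        sfreq=epochs.sfreq,
        channel_names=ch_names,
        is_db=False,
        metadata=epochs.metadata.copy(),
    )


def db_baseline(
    tfr: TFRSet,
    trial_mask: np.ndarray | None = None,
    baseline_window_ms: tuple[float, float] = BASELINE_WINDOW_MS,
) -> TFRSet:
    """Decibel normalization against a condition-unspecific baseline.

    The baseline B(channel, freq) is the mean raw power across *all* trials
    in ``trial_mask`` (default: every trial, i.e. both conditions pooled)
    and across the baseline window; output is 10*log10(P/B).
    """
    if tfr.is_db:
        raise ValueError("input is already decibel-scaled")
    tmask = window_mask(tfr.times_ms, baseline_window_ms)
    trials = slice(None) if trial_mask is None else np.asarray(trial_mask)
    base = tfr.power[trials][..., tmask].mean(axis=(0, -1))  # (ch, freq)
    if (base <= 0).any():
        bad = [(tfr.channel_names[c], float(tfr.freqs_hz[f]))
               for c, f in zip(*np.nonzero(base <= 0))]
        raise ZeroDivisionError(f"zero baseline power at (channel, freq): {bad[:10]}")
    db = 10.0 * np.log10(tfr.power / base[None, :, :, None])
    return TFRSet(
        power=db.astype(np.float32),
        freqs_hz=tfr.freqs_hz,
        times_ms=tfr.times_ms,
        sfreq=tfr.sfreq,
        channel_names=tfr.channel_names,
        is_db=True,
        baseline=base,
        baseline_window_ms=baseline_window_ms,
        metadata=None if tfr.metadata is None else tfr.metadata.copy(),
    )


def invert_db(tfr: TFRSet) -> TFRSet:
    """Recover raw power from a dB-scaled TFRSet using its stored baseline."""
    if not tfr.is_db:
        raise ValueError("input is not decibel-scaled")
    if tfr.baseline is None:
        raise ValueError("no stored baseline to invert with")
    raw = tfr.baseline[None, :, :, None] * 10.0 ** (tfr.power / 10.0)
    return TFRSet(
        power=raw,
        freqs_hz=tfr.freqs_hz,
        times_ms=tfr.times_ms,
        sfreq=tfr.sfreq,
        channel_names=tfr.channel_names,
        is_db=False,
        metadata=None if tfr.metadata is None else tfr.metadata.copy(),
    )


def condition_mean_db(tfr_db: TFRSet, metadata, column: str, level: str) -> np.ndarray:
    """Mean dB power over the trials of one condition: (channels, freqs, times)."""
    mask = (metadata[column] == level).to_numpy()
    if not mask.any():
        raise ValueError(f"no trials with {column} == {level}")
    return np.asarray(tfr_db.power[mask].mean(0))
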