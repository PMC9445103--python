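"""Small shared helpers: seeding and window/index arithmetic."""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from a global seed and a stage name."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % MAX_SEED


def window_mask(times_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    lo, hi = window_ms
    if hi < lo:
        raise ValueError(f"window end {hi} before start {lo}")
    mask = (times_ms >= lo) & (times_ms <= hi)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    return mask


def bin_downsample(x: np.ndarray, factor: int, axis: int = -1) -> np.ndarray:
    """Downsample by averaging non-overlapping bins along ``axis``."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    x = np.moveaxis(x, axis, -1)
    n = (x.shape[-1] // factor) * factor
    x = x[..., :n].reshape(*x.shape[:-1], n // factor, factor).mean(-1)
    return np.moveaxis(x, -1, axis)


def moving_average(x: np.ndarray, n_points: int, axis: int = -1) -> np.ndarray:
    """Centered moving average with edge-truncated windows."""
    if n_points % 2 != 1:
        raise ValueError("n_points must be odd")
    half = n_points // 2
    x = np.moveaxis(x, axis, -1)
    csum = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x], axis=-1), axis=-1)
    n = x.shape[-1]
    out = np.empty_like(x, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[..., i] = (csum[..., hi] - csum[..., lo]) / (hi - lo)
    return np.moveaxis(out, -1, axis)
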