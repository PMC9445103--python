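"""In-memory containers for epoched EEG and time-frequency power.

Both containers serialize to a directory holding one ``.npy`` array, a JSON
sidecar with axes and provenance, and (for epochs) a CSV trial-metadata
table, so every pipeline stage can run from serialized upstream output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import bin_downsample


@dataclass
class EpochSet:
    """Epoched multichannel EEG: trials x channels x samples (microvolts).

    ``times_ms`` is relative to relevance-cue onset and must be uniform at
    1/sfreq; ``metadata`` has one row per trial.
    """

    data: np.ndarray
    sfreq: float
    times_ms: np.ndarray
    channel_names: list[str]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_tr, n_ch, n_s = self.data.shape
        if len(self.metadata) != n_tr:
            raise ValueError(f"metadata rows ({len(self.metadata)}) != trials ({n_tr})")
        if len(self.channel_names) != n_ch:
            raise ValueError("channel_names length mismatch")
        if len(self.times_ms) != n_s:
            raise ValueError("times_ms length mismatch")
        step = np.diff(self.times_ms)
        if not (step > 0).all() or not np.allclose(step, 1000.0 / self.sfreq, atol=1e-6):
            raise ValueError("times_ms must increase uniformly at 1/sfreq")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.save(out / "epochs.npy", self.data.astype(np.float32))
        self.metadata.to_csv(out / "metadata.csv", index=False)
        sidecar = {
            "kind": "EpochSet",
            "sfreq": self.sfreq,
            "times_ms": self.times_ms.tolist(),
            "channel_names": list(self.channel_names),
            "shape": list(self.data.shape),
        }
        (out / "epochs.json").write_text(json.dumps(sidecar, indent=1))
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "EpochSet":
        in_dir = Path(in_dir)
        sidecar = json.loads((in_dir / "epochs.json").read_text())
        return cls(
            data=np.load(in_dir / "epochs.npy"),
            sfreq=sidecar["sfreq"],
            times_ms=np.array(sidecar["times_ms"]),
            channel_names=sidecar["channel_names"],
            metadata=pd.read_csv(in_dir / "metadata.csv"),
        )


@dataclass
class TFRSet:
    """Time-frequency power: (trials | 1) x channels x freqs x samples.

    ``is_db`` flags decibel-normalized arrays; ``baseline`` stores the
    per-channel/frequency raw baseline power used for the dB conversion so
    the transform is invertible.
    """

    power: np.ndarray
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    sfreq: float
    channel_names: list[str]
    is_db: bool = False
    baseline: np.ndarray | None = None
    baseline_window_ms: tuple[float, float] | None = None
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.power.ndim != 4:
            raise ValueError("power must be trials x channels x freqs x samples")
        _, n_ch, n_f, n_s = self.power.shape
        if n_ch != len(self.channel_names) or n_f != len(self.freqs_hz):
            raise ValueError("axis labels do not match power shape")
        if n_s != len(self.times_ms):
            raise ValueError("times_ms length mismatch")
        if not self.is_db and self.power.size and float(self.power.min()) < 0:
            raise ValueError("raw (linear) power must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def average(self) -> "TFRSet":
        """Trial-averaged copy (leading axis of length 1)."""
        return TFRSet(
            power=self.power.mean(0, keepdims=True),
            freqs_hz=self.freqs_hz,
            times_ms=self.times_ms,
            sfreq=self.sfreq,
            channel_names=self.channel_names,
            is_db=self.is_db,
            baseline=self.baseline,
            baseline_window_ms=self.baseline_window_ms,
        )

    def downsample_time(self, target_sfreq: float) -> "TFRSet":
        """Reduce the time axis by non-overlapping bin averaging."""
        factor = int(round(self.sfreq / target_sfreq))
        if factor < 1 or not np.isclose(self.sfreq / factor, target_sfreq):
            raise ValueError(f"{target_sfreq} Hz does not divide {self.sfreq} Hz")
        return TFRSet(
            power=bin_downsample(self.power, factor, axis=-1),
            freqs_hz=self.freqs_hz,
            times_ms=bin_downsample(self.times_ms, factor),
            sfreq=target_sfreq,
            channel_names=self.channel_names,
            is_db=self.is_db,
            baseline=self.baseline,
            baseline_window_ms=self.baseline_window_ms,
            metadata=self.metadata,
        )

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.save(out / "tfr.npy", self.power.astype(np.float32))
        if self.baseline is not None:
            np.save(out / "baseline.npy", self.baseline)
        if self.metadata is not None:
            self.metadata.to_csv(out / "metadata.csv", index=False)
        sidecar = {
            "kind": "TFRSet",
            "sfreq": self.sfreq,
            "freqs_hz": self.freqs_hz.tolist(),
            "times_ms": self.times_ms.tolist(),
            "channel_names": list(self.channel_names),
            "is_db": self.is_db,
            "baseline_window_ms": self.baseline_window_ms,
            "shape": list(self.power.shape),
        }
        (out / "tfr.json").write_text(json.dumps(sidecar, indent=1))
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "TFRSet":
        in_dir = Path(in_dir)
        sidecar = json.loads((in_dir / "tfr.json").read_text())
        baseline = None
        if (in_dir / "baseline.npy").exists():
            baseline = np.load(in_dir / "baseline.npy")
        metadata = None
        if (in_dir / "metadata.csv").exists():
            metadata = pd.read_csv(in_dir / "metadata.csv")
        bw = sidecar["baseline_window_ms"]
        return cls(
            power=np.load(in_dir / "tfr.npy"),
            freqs_hz=np.array(sidecar["freqs_hz"]),
            times_ms=np.array(sidecar["times_ms"]),
            sfreq=sidecar["sfreq"],
            channel_names=sidecar["channel_names"],
            is_db=sidecar["is_db"],
            baseline=baseline,
            baseline_window_ms=tuple(bw) if bw else None,
            metadata=metadata,
        )
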