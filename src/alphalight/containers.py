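"""On-disk and in-memory containers for epoched EEG and trial tables.

The epoch container is deliberately simple: a directory holding a
``manifest.json`` with shape/timing metadata and a ``data.bin`` of 32-bit
little-endian floats laid out trial-major ``[trial][channel][sample]``.
Trial tables are plain CSV with a fixed column order so that every stage
of the pipeline (and external tools) can round-trip them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Fixed column order of the trial-table CSV.
TRIAL_COLUMNS = [
    "session_id",
    "participant_id",
    "condition_order",
    "light_condition",
    "trial_number",
    "delay_s",
    "quadrant",
    "hemifield",
    "vertical_field",
    "direction",
    "responded",
    "rt_ms",
]

LIGHT_LEVELS = ("low", "medium", "high")
QUADRANTS = ("UL", "UR", "LL", "LR")


@dataclass
class EpochSet:
    """Epoched multi-channel voltages around target onset.

    Attributes
    ----------
    voltages : ndarray, shape (n_trials, n_channels, n_samples)
        Voltage in microvolts.
    fs : float
        Sampling rate in Hz.
    t_start_ms : float
        Time of the first sample relative to target onset (ms).
    channel_labels : list of str
        10-10 electrode names, unique.
    baseline_window_ms : tuple or None
        Baseline interval already subtracted, or None.
    """

    voltages: np.ndarray
    fs: float
    t_start_ms: float
    channel_labels: list[str]
    baseline_window_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.voltages.ndim != 3:
            raise ValueError("voltages must be trials x channels x samples")
        if len(self.channel_labels) != self.voltages.shape[1]:
            raise ValueError("channel_labels length does not match voltages")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_trials(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to target onset."""
        step = 1000.0 / self.fs
        return self.t_start_ms + step * np.arange(self.n_samples)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label: {label!r}") from None

    def copy(self) -> "EpochSet":
        return replace(self, voltages=self.voltages.copy(),
                       channel_labels=list(self.channel_labels))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        data = np.ascontiguousarray(self.voltages, dtype="<f4")
        manifest = {
            "n_trials": int(self.n_trials),
            "n_channels": int(len(self.channel_labels)),
            "n_samples": int(self.n_samples),
            "fs_hz": float(self.fs),
            "t_start_ms": float(self.t_start_ms),
            "channel_labels": list(self.channel_labels),
            "units": "uV",
            "dtype": "float32",
            "byte_order": "little",
            "layout": "trial_channel_sample",
            "baseline_window_ms": (list(self.baseline_window_ms)
                                   if self.baseline_window_ms else None),
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        data.tofile(path / "data.bin")

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        shape = (manifest["n_trials"], manifest["n_channels"],
                 manifest["n_samples"])
        data = np.fromfile(path / "data.bin", dtype="<f4").reshape(shape)
        bw = manifest.get("baseline_window_ms")
        return cls(
            voltages=data,
            fs=manifest["fs_hz"],
            t_start_ms=manifest["t_start_ms"],
            channel_labels=list(manifest["channel_labels"]),
            baseline_window_ms=tuple(bw) if bw else None,
        )


@dataclass
class AlphaSeries:
    """Rectified-and-smoothed alpha-band envelope on a trimmed time grid.

    ``values`` has shape (n_trials, n_channels, n_windows); entries are
    non-negative envelope amplitudes in microvolts. ``grid_times_ms`` are
    the centres of the 100 ms smoothing windows.
    """

    values: np.ndarray
    grid_times_ms: np.ndarray
    channel_labels: list[str]
    band_hz: tuple[float, float] = (8.0, 13.0)
    win_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be trials x channels x windows")
        if self.values.shape[2] != len(self.grid_times_ms):
            raise ValueError("grid length mismatch")
        if self.values.shape[1] != len(self.channel_labels):
            raise ValueError("channel label mismatch")

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label: {label!r}") from None

    def window_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Boolean mask of grid windows lying fully inside ``window_ms``.

        A grid point at centre c represents the half-open window
        [c - win/2, c + win/2); it is included when that extent fits
        inside the requested interval.
        """
        half = self.win_ms / 2.0
        lo, hi = window_ms
        g = np.asarray(self.grid_times_ms, dtype=float)
        mask = (g - half >= lo - 1e-9) & (g + half <= hi + 1e-9)
        if not mask.any():
            raise ValueError(f"no envelope windows inside {window_ms}")
        return mask

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        data = np.ascontiguousarray(self.values, dtype="<f4")
        manifest = {
            "n_trials": int(self.values.shape[0]),
            "n_channels": int(self.values.shape[1]),
            "n_samples": int(self.values.shape[2]),
            "grid_times_ms": [float(t) for t in self.grid_times_ms],
            "channel_labels": list(self.channel_labels),
            "band_hz": list(self.band_hz),
            "win_ms": float(self.win_ms),
            "units": "uV",
            "dtype": "float32",
            "byte_order": "little",
            "layout": "trial_channel_sample",
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        data.tofile(path / "data.bin")

    @classmethod
    def load(cls, path: str | Path) -> "AlphaSeries":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        shape = (manifest["n_trials"], manifest["n_channels"],
                 manifest["n_samples"])
        data = np.fromfile(path / "data.bin", dtype="<f4").reshape(shape)
        return cls(
            values=data,
            grid_times_ms=np.asarray(manifest["grid_times_ms"], dtype=float),
            channel_labels=list(manifest["channel_labels"]),
            band_hz=tuple(manifest["band_hz"]),
            win_ms=manifest["win_ms"],
        )


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table CSV with the canonical leading column order."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    extra = [c for c in trials.columns if c not in TRIAL_COLUMNS]
    trials[TRIAL_COLUMNS + extra].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if df["responded"].dtype != bool:
        df["responded"] = df["responded"].astype(str).str.lower().isin(
            ("true", "1"))
    return df
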