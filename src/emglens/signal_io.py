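"""Data model and preprocessing for multi-channel sEMG recordings.

A recording is a ``channels x samples`` matrix sampled at a fixed rate
(default 10 channels at 1 kHz).  Recordings are band-pass filtered,
segmented into fixed-length windows (default 151 samples with a stride of
51, i.e. 100 samples of overlap), and split into train/validation/test
sets by recording *cycle*.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "Window",
    "WindowedDataset",
    "PreprocessConfig",
    "DEFAULT_SPLIT",
    "bandpass_filter",
    "segment",
    "preprocess",
    "load_dataset",
    "save_dataset",
    "FormatError",
]

#: Default cycle -> role assignment: cycles 1-3 train, 4 validation, 5-8 test.
DEFAULT_SPLIT: dict[int, str] = {1: "train", 2: "train", 3: "train", 4: "val",
                                 5: "test", 6: "test", 7: "test", 8: "test"}


class FormatError(ValueError):
    """Raised when an on-disk dataset violates the expected layout."""


@dataclass(frozen=True)
class Recording:
    """One continuous multi-channel acquisition of a single gesture hold."""

    signal: np.ndarray  # (channels, samples)
    fs: float
    participant: int
    gesture: int
    cycle: int

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2:
            raise ValueError("signal must be a 2-D (channels x samples) array")
        object.__setattr__(self, "signal", sig)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class Window:
    """A fixed-length slice of a recording, carrying its metadata."""

    data: np.ndarray  # (channels, window_len)
    participant: int
    gesture: int
    cycle: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))


@dataclass
class WindowedDataset:
    """Windows plus the cycle->role split used for train/val/test."""

    windows: list[Window]
    split: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_SPLIT))

    def __len__(self) -> int:
        return len(self.windows)

    def roles(self) -> list[str]:
        return [self.split.get(w.cycle, "test") for w in self.windows]

    def subset(self, role: str) -> "WindowedDataset":
        """Windows whose cycle maps to ``role`` (one of train/val/test)."""
        keep = [w for w in self.windows if self.split.get(w.cycle, "test") == role]
        return WindowedDataset(keep, dict(self.split))

    def participants(self) -> list[int]:
        return sorted({w.participant for w in self.windows})

    def for_participant(self, participant: int) -> "WindowedDataset":
        keep = [w for w in self.windows if w.participant == participant]
        return WindowedDataset(keep, dict(self.split))

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Stack into ``(X, gesture, participant, cycle)`` arrays.

        ``X`` has shape ``(n_windows, channels, window_len)``.
        """
        if not self.windows:
            raise ValueError("empty dataset")
        X = np.stack([w.data for w in self.windows])
        y = np.array([w.gesture for w in self.windows])
        p = np.array([w.participant for w in self.windows])
        c = np.array([w.cycle for w in self.windows])
        return X, y, p, c


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering + segmentation settings applied when loading recordings."""

    fs: float = 1000.0
    low_hz: float = 20.0
    high_hz: float = 495.0
    order: int = 4
    window_len: int = 151
    stride: int = 51
    zero_phase: bool = False
    #: If True, segment the raw recording first and filter each window
    #: individually; the default filters the whole recording to avoid
    #: filter transients inside every short window.
    filter_per_window: bool = False
    n_channels: int = 10
    n_classes: int = 11


def bandpass_filter(signal: np.ndarray, fs: float = 1000.0, low: float = 20.0,
                    high: float = 495.0, order: int = 4,
                    zero_phase: bool = False) -> np.ndarray:
    """Per-channel Butterworth band-pass filter.

    Parameters
    ----------
    signal:
        ``(channels, samples)`` matrix; a 1-D array is treated as a single
        channel.
    zero_phase:
        Apply the filter forward-backward (``filtfilt``).  The default is a
        causal (forward-only) pass, matching real-time use.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= fs / 2:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {fs / 2} Hz")
    if x.shape[1] <= 3 * order:
        raise ValueError("signal too short for the filter order")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        out = sps.sosfiltfilt(sos, x, axis=1)
    else:
        out = sps.sosfilt(sos, x, axis=1)
    if signal.ndim == 1:
        return out[0]
    return np.asarray(out)


def segment(recording: Recording, window_len: int = 151, stride: int = 51) -> list[Window]:
    """Slide a half-open ``[start, start + window_len)`` frame over the recording.

    Produces ``floor((S - window_len) / stride) + 1`` windows; a recording
    shorter than one window yields an empty list.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    S = recording.n_samples
    if S < window_len:
        return []
    n = (S - window_len) // stride + 1
    return [
        Window(
            data=recording.signal[:, i * stride:i * stride + window_len].copy(),
            participant=recording.participant,
            gesture=recording.gesture,
            cycle=recording.cycle,
        )
        for i in range(n)
    ]


def preprocess(recordings: Iterable[Recording],
               config: PreprocessConfig = PreprocessConfig(),
               split: Mapping[int, str] | None = None) -> WindowedDataset:
    """Filter and segment recordings into a :class:`WindowedDataset`."""
    windows: list[Window] = []
    for rec in recordings:
        if config.filter_per_window:
            for w in segment(rec, config.window_len, config.stride):
                filtered = bandpass_filter(w.data, config.fs, config.low_hz,
                                           config.high_hz, config.order,
                                           config.zero_phase)
                windows.append(replace(w, data=filtered))
        else:
            filtered = bandpass_filter(rec.signal, config.fs, config.low_hz,
                                       config.high_hz, config.order,
                                       config.zero_phase)
            rec_f = Recording(filtered, rec.fs, rec.participant, rec.gesture, rec.cycle)
            windows.extend(segment(rec_f, config.window_len, config.stride))
    sp = dict(split) if split is not None else dict(DEFAULT_SPLIT)
    return WindowedDataset(windows, sp)


def read_recording(path: str | Path, participant: int, gesture: int, cycle: int,
                   fs: float = 1000.0, n_channels: int | None = None) -> Recording:
    """Read one delimited-text signal file (one row per channel)."""
    sig = np.loadtxt(path, delimiter=",", ndmin=2)
    if n_channels is not None and sig.shape[0] != n_channels:
        raise FormatError(
            f"{path}: expected {n_channels} channels, found {sig.shape[0]}")
    return Recording(sig, fs, participant, gesture, cycle)


def load_dataset(manifest_path: str | Path,
                 config: PreprocessConfig = PreprocessConfig(),
                 split: Mapping[int, str] | None = None) -> WindowedDataset:
    """Load a manifest of signal files and preprocess into windows.

    The manifest is JSON: ``{"recordings": [{"file", "participant",
    "gesture", "cycle"}, ...]}`` with file paths relative to the manifest.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    entries = manifest.get("recordings")
    if entries is None:
        raise FormatError("manifest missing 'recordings' list")
    recordings = []
    for e in entries:
        gesture = int(e["gesture"])
        if not 0 <= gesture < config.n_classes:
            raise FormatError(f"unknown gesture id {gesture}")
        recordings.append(read_recording(
            manifest_path.parent / e["file"], int(e["participant"]), gesture,
            int(e["cycle"]), fs=config.fs, n_channels=config.n_channels))
    return preprocess(recordings, config, split)


def save_dataset(dataset: WindowedDataset, path: str | Path) -> None:
    """Persist a windowed dataset as text: a JSON header + one CSV of windows.

    Each CSV row is one window flattened row-major (channel-by-channel).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "split": {str(k): v for k, v in dataset.split.items()},
        "windows": [
            {"participant": w.participant, "gesture": w.gesture, "cycle": w.cycle,
             "shape": list(w.data.shape)}
            for w in dataset.windows
        ],
    }
    with open(path / "dataset.json", "w") as fh:
        json.dump(meta, fh)
    flat = np.stack([w.data.ravel() for w in dataset.windows]) if dataset.windows \
        else np.zeros((0, 0))
    np.savetxt(path / "windows.csv", flat, delimiter=",")


def load_saved_dataset(path: str | Path) -> WindowedDataset:
    """Inverse of :func:`save_dataset`."""
    path = Path(path)
    with open(path / "dataset.json") as fh:
        meta = json.load(fh)
    flat = np.loadtxt(path / "windows.csv", delimiter=",", ndmin=2)
    windows = []
    for row, info in zip(flat, meta["windows"]):
        shape = tuple(info["shape"])
        windows.append(Window(row.reshape(shape), int(info["participant"]),
                              int(info["gesture"]), int(info["cycle"])))
    split = {int(k): v for k, v in meta["split"].items()}
    return WindowedDataset(windows, split)
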