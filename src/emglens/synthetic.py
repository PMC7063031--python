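"""Synthetic multi-domain sEMG generator.

Emulates the structure of a multi-participant armband dataset: ``P``
participants x ``G`` gestures x fixed-rate 10-channel cycles.  Each
channel carries band-limited (20-450 Hz) Gaussian noise whose amplitude is
modulated by a gesture-specific activation profile over the circular
channel axis.  Participants differ by a circular channel rotation, a
per-channel gain and an additive noise floor, giving controlled domain
shift between participants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .signal_io import (PreprocessConfig, Recording, Window, WindowedDataset,
                        preprocess)

__all__ = ["SynthConfig", "generate_recordings", "generate_dataset",
           "generate_noise_window", "write_dataset_files"]


@dataclass(frozen=True)
class SynthConfig:
    participants: int = 8
    gestures: int = 5
    channels: int = 10
    fs: float = 1000.0
    cycle_duration: float = 5.0  # seconds of signal per (gesture, cycle)
    cycles: int = 8              # first half train, second half test
    amplitude: float = 450.0     # baseline RMS-ish scale of active channels
    #: width (in channels) of the Gaussian activation bump of each gesture
    bump_width: float = 0.8
    #: ratio of resting to active channel amplitude
    rest_level: float = 0.12
    #: participant armband rotation, in channels: drawn uniformly from
    #: [0, max_rotation].  Fractional rotations shift the activation bump
    #: continuously around the circular channel axis; with G gestures
    #: spaced C/G channels apart, rotations at multiples of the spacing
    #: would alias one gesture onto another, so the default stays below it.
    max_rotation: float = 3.0
    #: per-channel gain drawn log-uniformly from [1/gain_span, gain_span]
    gain_span: float = 3.0
    #: participant-wide global gain drawn log-uniformly from
    #: [1/participant_gain_span, participant_gain_span]
    participant_gain_span: float = 4.0
    #: additive broadband noise floor SD, as a fraction of `amplitude`
    noise_floor: tuple[float, float] = (0.05, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.participants < 2 or self.gestures < 2:
            raise ValueError("need at least 2 participants and 2 gestures")
        if self.cycles % 2 != 0:
            raise ValueError("cycles must be even (half train, half test)")

    def split(self) -> dict[int, str]:
        """Cycle->role map: first half train (last train cycle = val), rest test."""
        half = self.cycles // 2
        sp: dict[int, str] = {}
        for c in range(1, self.cycles + 1):
            if c < half:
                sp[c] = "train"
            elif c == half:
                sp[c] = "val"
            else:
                sp[c] = "test"
        return sp


def _bandlimit(x: np.ndarray, fs: float) -> np.ndarray:
    """20-450 Hz band-pass used to give the noise carrier an EMG-like spectrum."""
    sos = sps.butter(4, [20.0, min(450.0, 0.49 * fs)], btype="bandpass",
                     fs=fs, output="sos")
    return np.asarray(sps.sosfiltfilt(sos, x, axis=-1))


def gesture_profile(gesture: int, config: SynthConfig,
                    rotation: float = 0.0) -> np.ndarray:
    """Per-channel activation envelope of a gesture.

    A Gaussian bump over the circular channel axis centred at the gesture's
    assigned channel (shifted by the participant's armband ``rotation``),
    on top of a low resting level.
    """
    C = config.channels
    # irregular spacing: no armband rotation can map one gesture's bump
    # exactly onto another's, keeping classes identifiable across domains
    jitter = (0.0, 0.65, -0.45, 0.35, -0.75, 0.55, -0.25, 0.15, -0.6, 0.4)
    center = (gesture * C) / config.gestures + jitter[gesture % 10] + rotation
    ch = np.arange(C, dtype=float)
    # circular distance between channel index and the bump centre
    d = np.minimum(np.abs(ch - center) % C, C - np.abs(ch - center) % C)
    bump = np.exp(-0.5 * (d / config.bump_width) ** 2)
    return config.rest_level + (1.0 - config.rest_level) * bump


def _participant_domain(rng: np.random.Generator, config: SynthConfig):
    rotation = float(rng.uniform(0.0, config.max_rotation))
    log_span = np.log(config.gain_span)
    gains = np.exp(rng.uniform(-log_span, log_span, size=config.channels))
    g_span = np.log(config.participant_gain_span)
    gains *= np.exp(rng.uniform(-g_span, g_span))
    lo, hi = config.noise_floor
    noise_sd = float(rng.uniform(lo, hi)) * config.amplitude
    return rotation, gains, noise_sd


def generate_recordings(config: SynthConfig = SynthConfig()) -> list[Recording]:
    """All ``P x G x cycles`` recordings, deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    S = int(round(config.cycle_duration * config.fs))
    recordings: list[Recording] = []
    for p in range(config.participants):
        rotation, gains, noise_sd = _participant_domain(rng, config)
        for g in range(config.gestures):
            profile = gesture_profile(g, config, rotation)
            for cyc in range(1, config.cycles + 1):
                carrier = _bandlimit(
                    rng.standard_normal((config.channels, S)), config.fs)
                sig = config.amplitude * profile[:, None] * carrier
                if noise_sd > 0:
                    sig = sig + noise_sd * _bandlimit(
                        rng.standard_normal((config.channels, S)), config.fs)
                sig = gains[:, None] * sig
                recordings.append(Recording(sig, config.fs, p, g, cyc))
    return recordings


def generate_dataset(config: SynthConfig = SynthConfig(),
                     preprocess_config: PreprocessConfig | None = None) -> WindowedDataset:
    """Generate recordings and run the standard preprocessing pipeline."""
    if preprocess_config is None:
        preprocess_config = PreprocessConfig(fs=config.fs,
                                             n_channels=config.channels,
                                             n_classes=max(11, config.gestures))
    return preprocess(generate_recordings(config), preprocess_config,
                      split=config.split())


def generate_noise_window(sigma: float = 450.0, seed: int = 0,
                          channels: int = 10, window_len: int = 151) -> Window:
    """A pure iid-Gaussian window (mean 0, SD ``sigma``); gesture label -1."""
    rng = np.random.default_rng(seed)
    data = sigma * rng.standard_normal((channels, window_len))
    return Window(data, participant=-1, gesture=-1, cycle=0)


def write_dataset_files(config: SynthConfig, out_dir: str | Path) -> Path:
    """Emit raw recordings as CSV files plus a JSON manifest.

    The output is the exact on-disk layout :func:`emglens.signal_io.load_dataset`
    consumes; returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in generate_recordings(config):
        name = f"p{rec.participant}_g{rec.gesture}_c{rec.cycle}.csv"
        np.savetxt(out_dir / name, rec.signal, delimiter=",")
        entries.append({"file": name, "participant": rec.participant,
                        "gesture": rec.gesture, "cycle": rec.cycle})
    manifest = out_dir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"fs": config.fs, "recordings": entries}, fh)
    return manifest
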