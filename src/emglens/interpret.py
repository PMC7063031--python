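"""Saliency for EMG windows: guided backpropagation, Grad-CAM and their
fusion (Guided Grad-CAM), plus a Gaussian-noise probe.

All saliency is computed in eval mode (dropout off, stored BN statistics)
and the four steps are:

1. seed the output gradient with 1 at the requested class logit;
2. guided backpropagation to the input (negative activations and negative
   backward gradients zeroed at every activation layer);
3. Grad-CAM at the last block's post-activation maps: weight each map by
   the global average pool of its class gradient, sum, rectify;
4. broadcast the Grad-CAM map along the time axis and multiply point-wise
   with the guided-backpropagation map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .convnet import SHARED_BANK, ConvNet
from .signal_io import Window
from .synthetic import generate_noise_window

__all__ = ["SaliencyMap", "guided_backprop", "grad_cam", "guided_grad_cam",
           "noise_probe"]


@dataclass(frozen=True)
class SaliencyMap:
    """Non-negative relevance per input sample for one (window, class) pair."""

    relevance: np.ndarray  # (channels, samples), elementwise >= 0
    gesture: int
    window: Window | None = None

    def __post_init__(self) -> None:
        if np.min(self.relevance) < 0:
            raise ValueError("saliency must be non-negative")

    @property
    def max_magnitude(self) -> float:
        return float(np.max(self.relevance))


def _window_data(window) -> np.ndarray:
    return window.data if isinstance(window, Window) else np.asarray(window)


def _resolve_stats(model: ConvNet, bank_key, stats):
    if stats is not None:
        return stats
    if bank_key in model.bn_banks:
        return model.get_bank(bank_key)
    if SHARED_BANK in model.bn_banks:
        return model.get_bank(SHARED_BANK)
    if model.bn_banks:
        return model.mean_bank()
    return model._fresh_stats()


def _seed_gradient(model: ConvNet, gesture: int) -> np.ndarray:
    n_classes = model.config.n_classes
    if not 0 <= gesture < n_classes:
        raise ValueError(f"class {gesture} out of range 0..{n_classes - 1}")
    seed = np.zeros((1, n_classes))
    seed[0, gesture] = 1.0
    return seed


def guided_backprop(model: ConvNet, window, gesture: int, bank_key=None,
                    stats=None) -> np.ndarray:
    """Guided-backpropagation map of shape (channels, samples); >= 0."""
    x = _window_data(window)
    stats = _resolve_stats(model, bank_key, stats)
    model.forward(x, stats=stats, train=False, cache=True)
    dx = model.backward(_seed_gradient(model, gesture), accumulate=False,
                        guided=True)
    return np.maximum(np.asarray(dx[0], dtype=float), 0.0)


def grad_cam(model: ConvNet, window, gesture: int, block: int | None = None,
             bank_key=None, stats=None) -> np.ndarray:
    """Class-activation map at a block's post-activation maps.

    Each of the block's feature maps is weighted by the spatial average of
    the class-logit gradient with respect to that map; the weighted sum is
    rectified.  Output shape is the block's spatial map shape
    (channels x time length; 10x1 at the default final block).
    """
    cfg = model.config
    if block is None:
        block = cfg.n_blocks
    if not 1 <= block <= cfg.n_blocks:
        raise ValueError(f"block {block} out of range 1..{cfg.n_blocks}")
    x = _window_data(window)
    stats = _resolve_stats(model, bank_key, stats)
    collect: list[np.ndarray] = []
    model.forward(x, stats=stats, train=False, cache=True, collect=collect)
    d_maps = model.backward(_seed_gradient(model, gesture), accumulate=False,
                            stop_block=block)  # (1, maps, R, T)
    fmaps = collect[block - 1][0]               # (maps, R, T)
    weights = d_maps[0].mean(axis=(1, 2))       # global average pool per map
    cam = np.tensordot(weights, fmaps, axes=(0, 0))
    return np.maximum(np.asarray(cam, dtype=float), 0.0)


def guided_grad_cam(model: ConvNet, window, gesture: int, bank_key=None,
                    stats=None) -> SaliencyMap:
    """Fuse Grad-CAM (broadcast along time) with guided backpropagation."""
    gbp = guided_backprop(model, window, gesture, bank_key, stats)
    cam = grad_cam(model, window, gesture, bank_key=bank_key, stats=stats)
    # final-block maps have time length 1: broadcast each channel's CAM
    # value along the full time axis before fusing
    cam_per_channel = cam.mean(axis=1)  # (channels,)
    fused = gbp * cam_per_channel[:, None]
    w = window if isinstance(window, Window) else None
    return SaliencyMap(fused, gesture, w)


def noise_probe(model: ConvNet, sigma: float = 450.0,
                classes: list[int] | None = None, seed: int = 0,
                bank_key=None, stats=None) -> dict[int, float]:
    """Maximum Guided Grad-CAM magnitude per class on a pure-noise window.

    Compares how strongly the network 'finds' each gesture in an input
    where no gesture is present.
    """
    if classes is None:
        classes = list(range(model.config.n_classes))
    window = generate_noise_window(sigma=sigma, seed=seed,
                                   channels=model.config.input_shape[0],
                                   window_len=model.config.input_shape[1])
    out: dict[int, float] = {}
    for c in classes:
        sal = guided_grad_cam(model, window, c, bank_key, stats)
        out[c] = sal.max_magnitude
    return out
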