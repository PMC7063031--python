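"""Channel-independent ConvNet for 10x151 sEMG windows, in pure NumPy.

The network is six *blocks* (convolution with 1x26 kernels -> batch
normalization -> leaky ReLU -> dropout) followed by two fully-connected
heads on the flattened final block output: an 11-class gesture head and a
2-output domain head.  Kernels have height 1, so the 10 electrode-channel
rows are never mixed; valid padding at stride 1 shrinks the time axis by
25 per block (151 -> 126 -> 101 -> 76 -> 51 -> 26 -> 1).

Batch-normalization scale/shift parameters are shared weights, while the
running mean/variance statistics are kept in per-participant *banks* so
the same weights can be evaluated under different participants' feature
statistics.

Forward and backward passes are implemented by hand; gradients are exact
(verified against finite differences in the test suite), which also makes
gradient-reversal and guided-backpropagation straightforward to express.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .handcrafted import FeatureTable
from .signal_io import WindowedDataset

__all__ = ["ArchitectureConfig", "ConvNet", "build_model",
           "count_parameters", "extract_learned_features",
           "learned_feature_names", "SHARED_BANK"]

#: bank key used by standard (non-ADANN) training
SHARED_BANK = "__shared__"

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class ArchitectureConfig:
    n_blocks: int = 6
    feature_maps: int = 64
    kernel_time: int = 26
    leaky_slope: float = 0.1
    dropout: float = 0.35
    n_classes: int = 11
    n_domain_outputs: int = 2
    input_shape: tuple[int, int] = (10, 151)  # (channels, samples)

    def __post_init__(self) -> None:
        if self.final_time_len < 1:
            raise ValueError(
                f"{self.n_blocks} blocks of 1x{self.kernel_time} kernels do not "
                f"fit a {self.input_shape[1]}-sample input")

    @property
    def final_time_len(self) -> int:
        return self.input_shape[1] - self.n_blocks * (self.kernel_time - 1)

    def time_len_after(self, block: int) -> int:
        return self.input_shape[1] - block * (self.kernel_time - 1)

    @property
    def head_in(self) -> int:
        return self.feature_maps * self.input_shape[0] * self.final_time_len


# ---------------------------------------------------------------------------
# layers


class _Layer:
    """Base: trainable layers expose aligned ``params`` / ``grads`` lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def zero_grad(self) -> None:
        for g in self.grads():
            g[...] = 0.0


class Conv1xK(_Layer):
    """Valid-padding stride-1 convolution along the time axis only.

    Activations use a channels-last layout ``(B, R, T, C)`` so the im2col
    matrix is a contiguous copy and the convolution is a single GEMM.  The
    ``R`` electrode rows are processed independently (kernel height 1).
    The kernel is stored as ``(K, Cin, Cout)``.
    """

    def __init__(self, in_maps: int, out_maps: int, k: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        fan_in = in_maps * k
        self.W = (rng.standard_normal((k, in_maps, out_maps))
                  * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(out_maps, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    @property
    def k(self) -> int:
        return self.W.shape[0]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        sw = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
        # (B, R, t', C, K) -> (B, R, t', K, C); each (K, C) block is
        # contiguous in the source, so this copy is memcpy-like
        cols = np.ascontiguousarray(sw.transpose(0, 1, 2, 4, 3))
        return cols.reshape(-1, k * x.shape[3])

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        B, R, T, Cin = x.shape
        k = self.k
        t_out = T - k + 1
        cols = self._im2col(x, k)
        out = cols @ self.W.reshape(k * Cin, -1)
        out += self.b
        if cache:
            self._cols = cols
            self._x_shape = x.shape
        return out.reshape(B, R, t_out, -1)

    def backward(self, d_out: np.ndarray, accumulate: bool = True,
                 need_input_grad: bool = True) -> np.ndarray | None:
        assert self._cols is not None, "forward(cache=True) must precede backward"
        B, R, T, Cin = self._x_shape
        k = self.k
        t_out = d_out.shape[2]
        d2 = d_out.reshape(-1, d_out.shape[3])
        if accumulate:
            self.gb += d2.sum(axis=0)
            self.gW += (self._cols.T @ d2).reshape(self.W.shape)
        if not need_input_grad:
            return None
        # input gradient = full correlation of d_out with the flipped kernel,
        # expressed as a second im2col + GEMM
        cout = d_out.shape[3]
        pad = np.zeros((B, R, T + k - 1, cout), dtype=d_out.dtype)
        pad[:, :, k - 1:k - 1 + t_out, :] = d_out
        cols2 = self._im2col(pad, k)
        w_rev = self.W[::-1].transpose(0, 2, 1).reshape(k * cout, Cin)
        return (cols2 @ w_rev).reshape(B, R, T, Cin)


class BatchNormMaps(_Layer):
    """Batch norm over feature maps: statistics pooled over (batch, row, time).

    Activations are channels-last ``(B, R, T, C)``; statistics are per map
    (last axis).  Running statistics live *outside* the layer, in
    per-participant banks; the caller passes the relevant ``(mean, var)``
    pair for eval mode and receives updated statistics when
    ``update_stats`` is set.
    """

    def __init__(self, n_maps: int, dtype=np.float32) -> None:
        self.gamma = np.ones(n_maps, dtype=dtype)
        self.beta = np.zeros(n_maps, dtype=dtype)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self._cache: tuple | None = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def forward(self, x: np.ndarray, stats: tuple[np.ndarray, np.ndarray],
                train: bool, update_stats: bool = False, cache: bool = True
                ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
        mean_run, var_run = stats
        if train:
            mu = x.mean(axis=(0, 1, 2))
            var = np.maximum((x * x).mean(axis=(0, 1, 2)) - mu * mu, 0.0)
        else:
            mu, var = mean_run, var_run
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu) * inv_std
        out = self.gamma * xhat + self.beta
        if cache:
            self._cache = (x.shape, xhat, inv_std, train)
        new_stats = stats
        if train and update_stats:
            new_stats = ((1 - _BN_MOMENTUM) * mean_run + _BN_MOMENTUM * mu,
                         (1 - _BN_MOMENTUM) * var_run + _BN_MOMENTUM * var)
        return out, new_stats

    def backward(self, d_out: np.ndarray, accumulate: bool = True) -> np.ndarray:
        x_shape, xhat, inv_std, train = self._cache
        if accumulate:
            self.ggamma += np.sum(d_out * xhat, axis=(0, 1, 2))
            self.gbeta += np.sum(d_out, axis=(0, 1, 2))
        if not train:
            return d_out * (self.gamma * inv_std)
        m = x_shape[0] * x_shape[1] * x_shape[2]
        dxhat = d_out * self.gamma
        sum_dxhat = dxhat.sum(axis=(0, 1, 2))
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 1, 2))
        dx = (inv_std / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        return dx


class LeakyReLU(_Layer):
    def __init__(self, slope: float = 0.1) -> None:
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        mask = x > 0
        out = np.where(mask, x, self.slope * x)
        if cache:
            self._mask = mask
        return out

    def backward(self, d_out: np.ndarray, guided: bool = False) -> np.ndarray:
        mask = self._mask
        if guided:
            # guided backprop: zero gradient where the activation was
            # negative OR where the incoming gradient is negative
            return d_out * mask * (d_out > 0)
        return np.where(mask, d_out, self.slope * d_out)


class Dropout(_Layer):
    def __init__(self, p: float) -> None:
        self.p = p
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator | None = None,
                cache: bool = True) -> np.ndarray:
        if not train or self.p <= 0:
            if cache:
                self._mask = None
            return x
        assert rng is not None, "dropout in train mode needs an rng"
        u = rng.random(x.shape, dtype=np.float32 if x.dtype == np.float32
                       else np.float64)
        mask = ((u >= self.p) / (1.0 - self.p)).astype(x.dtype)
        if cache:
            self._mask = mask
        return x * mask

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return d_out
        return d_out * self._mask


class Linear(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.W = (rng.standard_normal((n_out, n_in))
                  * np.sqrt(2.0 / n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        if cache:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, d_out: np.ndarray, accumulate: bool = True) -> np.ndarray:
        if accumulate:
            self.gW += d_out.T @ self._x
            self.gb += d_out.sum(axis=0)
        return d_out @ self.W


# ---------------------------------------------------------------------------
# model


class ConvNet:
    """Shared weights plus a bank of per-participant BN running statistics."""

    def __init__(self, config: ArchitectureConfig = ArchitectureConfig(),
                 seed: int = 0, dtype=np.float32) -> None:
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.blocks: list[dict] = []
        in_maps = 1
        for _ in range(config.n_blocks):
            self.blocks.append({
                "conv": Conv1xK(in_maps, config.feature_maps, config.kernel_time,
                                rng, dtype),
                "bn": BatchNormMaps(config.feature_maps, dtype),
                "act": LeakyReLU(config.leaky_slope),
                "drop": Dropout(config.dropout),
            })
            in_maps = config.feature_maps
        self.gesture_head = Linear(config.head_in, config.n_classes, rng, dtype)
        self.domain_head = Linear(config.head_in, config.n_domain_outputs, rng, dtype)
        #: participant id (or :data:`SHARED_BANK`) -> per-block (mean, var)
        self.bn_banks: dict[object, list[tuple[np.ndarray, np.ndarray]]] = {}

    # -- parameters ---------------------------------------------------------

    def layers(self) -> list[_Layer]:
        out: list[_Layer] = []
        for blk in self.blocks:
            out.extend([blk["conv"], blk["bn"]])
        out.extend([self.gesture_head, self.domain_head])
        return out

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers() for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers() for g in layer.grads()]

    def zero_grad(self) -> None:
        for layer in self.layers():
            layer.zero_grad()

    # -- BN banks -----------------------------------------------------------

    def _fresh_stats(self) -> list[tuple[np.ndarray, np.ndarray]]:
        m = self.config.feature_maps
        return [(np.zeros(m, dtype=self.dtype), np.ones(m, dtype=self.dtype))
                for _ in range(self.config.n_blocks)]

    def get_bank(self, key, create: bool = False) -> list[tuple[np.ndarray, np.ndarray]]:
        if key not in self.bn_banks:
            if not create:
                raise KeyError(
                    f"no BN statistics stored for participant {key!r}; train on "
                    "this participant first or choose an adaptation policy")
            self.bn_banks[key] = self._fresh_stats()
        return self.bn_banks[key]

    def mean_bank(self, keys: Iterable[object] | None = None
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Element-wise average of stored banks (used as a fallback for
        unseen participants when no adaptation is allowed)."""
        keys = list(keys) if keys is not None else list(self.bn_banks)
        if not keys:
            raise ValueError("no BN banks stored")
        banks = [self.get_bank(k) for k in keys]
        out = []
        for b in range(self.config.n_blocks):
            out.append((np.mean([bk[b][0] for bk in banks], axis=0),
                        np.mean([bk[b][1] for bk in banks], axis=0)))
        return out

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, bank_key=SHARED_BANK, train: bool = False,
                rng: np.random.Generator | None = None,
                update_stats: bool = False, cache: bool = False,
                stats: list | None = None,
                collect: list | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Run the network; returns ``(gesture_logits, domain_logits)``.

        ``x`` is ``(B, channels, samples)`` or a single window.  ``stats``
        overrides the bank lookup with an explicit list of per-block BN
        statistics.  If ``collect`` is a list, the post-activation output of
        every block is appended to it.
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        h = x[:, :, :, None]  # channels-last (B, R, T, C=1)
        if stats is None:
            bank = self.get_bank(bank_key, create=train)
        else:
            bank = stats
        for b, blk in enumerate(self.blocks):
            h = blk["conv"].forward(h, cache=cache)
            h, new_stats = blk["bn"].forward(h, bank[b], train=train,
                                             update_stats=update_stats,
                                             cache=cache)
            if train and update_stats and stats is None:
                bank[b] = new_stats
            h = blk["act"].forward(h, cache=cache)
            if collect is not None:
                # expose activations map-first: (B, C, R, T)
                collect.append(h.transpose(0, 3, 1, 2))
            h = blk["drop"].forward(h, train=train, rng=rng, cache=cache)
        self._feat_shape = h.shape
        # flatten in the documented (map, channel-row, time) order
        flat = h.transpose(0, 3, 1, 2).reshape(h.shape[0], -1)
        return self.gesture_head.forward(flat, cache=cache), \
            self.domain_head.forward(flat, cache=cache)

    def backward(self, d_class: np.ndarray | None,
                 d_domain: np.ndarray | None = None,
                 domain_scale: float = 1.0, accumulate: bool = True,
                 guided: bool = False, stop_block: int = 0) -> np.ndarray:
        """Backpropagate logit gradients; returns the input-space gradient.

        ``domain_scale`` multiplies the domain-head gradient where it joins
        the shared representation (gradient reversal uses ``-lambda``).
        ``stop_block`` > 0 stops after reaching that block's post-activation
        output (used by Grad-CAM) and returns the gradient there.
        """
        d_flat = np.zeros((self._feat_shape[0],
                           self.gesture_head.W.shape[1]), dtype=self.dtype)
        if d_class is not None:
            d_flat += self.gesture_head.backward(np.asarray(d_class, self.dtype),
                                                 accumulate=accumulate)
        if d_domain is not None:
            d_flat += domain_scale * self.domain_head.backward(
                np.asarray(d_domain, self.dtype), accumulate=accumulate)
        B, R, T, C = self._feat_shape
        # undo the (map, channel-row, time) flatten order
        dh = d_flat.reshape(B, C, R, T).transpose(0, 2, 3, 1)
        for b in range(self.config.n_blocks - 1, -1, -1):
            blk = self.blocks[b]
            dh = blk["drop"].backward(dh)
            if stop_block and b + 1 == stop_block:
                # gradient w.r.t. the block's post-activation maps, map-first
                return dh.transpose(0, 3, 1, 2)
            dh = blk["act"].backward(dh, guided=guided)
            dh = blk["bn"].backward(dh, accumulate=accumulate)
            # during training the input-space gradient of block 1 is unused
            need_dx = b > 0 or not accumulate
            dh = blk["conv"].backward(dh, accumulate=accumulate,
                                      need_input_grad=need_dx)
        return dh[:, :, :, 0] if dh is not None else None

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint: config as JSON sidecar + weights/banks in one .npz."""
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.params()):
            arrays[f"param_{i}"] = p
        bank_keys = []
        for key, bank in self.bn_banks.items():
            bank_keys.append(str(key))
            for b, (m, v) in enumerate(bank):
                arrays[f"bank_{key}_mean_{b}"] = m
                arrays[f"bank_{key}_var_{b}"] = v
        np.savez(path, **arrays)
        cfg = {"version": 1,
               "config": self.config.__dict__ | {"input_shape": list(self.config.input_shape)},
               "bank_keys": bank_keys}
        with open(str(path) + ".json", "w") as fh:
            json.dump(cfg, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ConvNet":
        path = Path(path)
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        cdict = dict(meta["config"])
        cdict["input_shape"] = tuple(cdict["input_shape"])
        model = cls(ArchitectureConfig(**cdict))
        npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
        if not npz_path.exists():
            npz_path = path
        data = np.load(npz_path)
        for i, p in enumerate(model.params()):
            p[...] = data[f"param_{i}"]
        for key in meta["bank_keys"]:
            try:
                bank_key: object = int(key)
            except ValueError:
                bank_key = key
            bank = []
            for b in range(model.config.n_blocks):
                bank.append((data[f"bank_{key}_mean_{b}"],
                             data[f"bank_{key}_var_{b}"]))
            model.bn_banks[bank_key] = bank
        return model


def build_model(config: ArchitectureConfig = ArchitectureConfig(),
                seed: int = 0, dtype=np.float32) -> ConvNet:
    return ConvNet(config, seed=seed, dtype=dtype)


def count_parameters(model: ConvNet) -> int:
    """Brute-force sum of element counts over all trainable tensors."""
    return int(sum(p.size for p in model.params()))


def parameter_breakdown(model: ConvNet) -> dict[str, int]:
    out: dict[str, int] = {}
    for b, blk in enumerate(model.blocks, start=1):
        out[f"block{b}"] = sum(p.size for p in blk["conv"].params()) + \
            sum(p.size for p in blk["bn"].params())
    out["gesture_head"] = sum(p.size for p in model.gesture_head.params())
    out["domain_head"] = sum(p.size for p in model.domain_head.params())
    return out


def learned_feature_names(config: ArchitectureConfig = ArchitectureConfig()
                          ) -> list[str]:
    """All learned-feature identifiers: ``B<block>F<map>``."""
    return [f"B{b}F{i + 1}" for b in range(1, config.n_blocks + 1)
            for i in range(config.feature_maps)]


def extract_learned_features(model: ConvNet, dataset: WindowedDataset,
                             blocks: Sequence[int] | None = None,
                             bank_policy: str = "own",
                             batch_size: int = 256) -> FeatureTable:
    """Channel-wise time-averaged post-activation maps as a feature table.

    For every requested block, each of the feature maps is averaged along
    the time axis per channel row, yielding ``feature_maps`` scalars per
    channel per window.  ``bank_policy`` selects the BN statistics:
    ``"own"`` (each window's participant bank, created as fresh statistics
    if absent), ``"shared"`` or ``"mean"``.
    """
    cfg = model.config
    if blocks is None:
        blocks = list(range(1, cfg.n_blocks + 1))
    for b in blocks:
        if not 1 <= b <= cfg.n_blocks:
            raise ValueError(f"block {b} out of range 1..{cfg.n_blocks}")
    X, y, p, c = dataset.arrays()
    n = X.shape[0]
    values = np.zeros((n, cfg.input_shape[0], len(blocks) * cfg.feature_maps))
    for participant in np.unique(p):
        idx = np.where(p == participant)[0]
        if bank_policy == "own":
            stats = model.bn_banks.get(int(participant))
            if stats is None:
                stats = model._fresh_stats()
        elif bank_policy == "shared":
            stats = model.get_bank(SHARED_BANK)
        elif bank_policy == "mean":
            stats = model.mean_bank()
        else:
            raise ValueError(f"unknown bank_policy {bank_policy!r}")
        for lo in range(0, len(idx), batch_size):
            sel = idx[lo:lo + batch_size]
            collect: list[np.ndarray] = []
            model.forward(X[sel], stats=stats, train=False, collect=collect)
            for j, b in enumerate(blocks):
                # (B, maps, R, T) -> time average -> (B, R, maps)
                avg = collect[b - 1].mean(axis=3).transpose(0, 2, 1)
                values[sel, :, j * cfg.feature_maps:(j + 1) * cfg.feature_maps] = avg
    names = [f"B{b}F{i + 1}" for b in blocks for i in range(cfg.feature_maps)]
    labels = [f"B{b}" for b in blocks for _ in range(cfg.feature_maps)]
    meta = pd.DataFrame({"participant": p, "gesture": y, "cycle": c})
    return FeatureTable(values, names, labels, meta)
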