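"""Training loops: standard aggregate training and multi-domain adversarial
training with per-participant batch-normalization statistics.

The adversarial procedure treats every participant as a *domain*.  Each
epoch visits every participant as the *source*; every source batch (domain
label 0) is paired with a *target* batch drawn from one uniformly random
other participant (domain label 1).  The two batches are fed consecutively,
each under its own participant's BN statistics; running statistics are
updated only on source batches.  Both heads use cross-entropy and the
total loss is ``Ly + lambda * Ld``; the domain-head gradient is multiplied
by a negative constant (default -1) where it re-enters the shared trunk,
pushing the shared weights toward domain-invariant features.  Target
batches contribute only to the domain loss (their gesture labels are never
used).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .convnet import SHARED_BANK, ArchitectureConfig, ConvNet, build_model
from .signal_io import WindowedDataset

__all__ = ["TrainConfig", "TrainResult", "Adam", "train_standard",
           "train_adann", "evaluate_cross_subject", "adapt_bn",
           "compare_training_methods", "domain_gap_experiment"]


@dataclass
class TrainConfig:
    lr: float = 0.0404709
    batch_size: int = 512
    lambda_domain: float = 0.1
    #: ramp the domain-loss weight linearly from 0 over this many epochs
    #: (0 disables the warmup); stabilizes the adversarial game early on
    lambda_warmup_epochs: int = 0
    reversal_constant: float = -1.0
    anneal_factor: float = 5.0
    patience: int = 15
    #: stop after this many consecutive annealings without a new best val loss
    early_stop_annealings: int = 2
    max_epochs: int = 500
    seed: int = 0


@dataclass
class TrainResult:
    model: ConvNet
    history: pd.DataFrame
    best_val_loss: float


class Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def softmax_xent(logits: np.ndarray, labels: np.ndarray
                 ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -float(np.mean(np.log(np.maximum(probs[np.arange(n), labels], 1e-30))))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class _Annealer:
    """Learning-rate annealing with patience + early stopping after a fixed
    number of consecutive annealings that produced no new best loss."""

    def __init__(self, optimizer: Adam, config: TrainConfig) -> None:
        self.opt = optimizer
        self.cfg = config
        self.best = np.inf
        self.bad_epochs = 0
        self.fruitless_anneals = 0

    def update(self, val_loss: float) -> bool:
        """Record a validation loss; returns True if training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.bad_epochs = 0
            self.fruitless_anneals = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.cfg.patience:
            self.opt.lr /= self.cfg.anneal_factor
            self.bad_epochs = 0
            self.fruitless_anneals += 1
        return self.fruitless_anneals >= self.cfg.early_stop_annealings


def _val_loss_shared(model: ConvNet, Xv, yv, batch_size: int) -> float:
    losses, weights = [], []
    for lo in range(0, len(Xv), batch_size):
        logits, _ = model.forward(Xv[lo:lo + batch_size], bank_key=SHARED_BANK)
        loss, _ = softmax_xent(logits, yv[lo:lo + batch_size])
        losses.append(loss)
        weights.append(len(yv[lo:lo + batch_size]))
    return float(np.average(losses, weights=weights))


def train_standard(model: ConvNet, dataset: WindowedDataset,
                   config: TrainConfig = TrainConfig()) -> TrainResult:
    """Aggregate all participants' training windows and minimize the gesture
    cross-entropy with a single shared BN bank."""
    train = dataset.subset("train")
    val = dataset.subset("val")
    if len(train) == 0 or len(val) == 0:
        raise ValueError("dataset needs nonempty train and val splits")
    X, y, _, _ = train.arrays()
    Xv, yv, _, _ = val.arrays()
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), config.lr)
    annealer = _Annealer(opt, config)
    model.get_bank(SHARED_BANK, create=True)
    rows = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(X))
        epoch_loss, nb = 0.0, 0
        for lo in range(0, len(X), config.batch_size):
            sel = order[lo:lo + config.batch_size]
            model.zero_grad()
            logits, _ = model.forward(X[sel], bank_key=SHARED_BANK, train=True,
                                      rng=rng, update_stats=True, cache=True)
            loss, dlogits = softmax_xent(logits, y[sel])
            model.backward(dlogits)
            opt.step(model.grads())
            epoch_loss += loss
            nb += 1
        val_loss = _val_loss_shared(model, Xv, yv, config.batch_size)
        rows.append({"epoch": epoch, "train_loss": epoch_loss / max(nb, 1),
                     "val_loss": val_loss, "lr": opt.lr})
        if annealer.update(val_loss):
            break
    history = pd.DataFrame(rows)
    return TrainResult(model, history, annealer.best)


def _participant_arrays(dataset: WindowedDataset):
    X, y, p, _ = dataset.arrays()
    return {int(pp): (X[p == pp], y[p == pp]) for pp in np.unique(p)}


def _val_loss_per_participant(model: ConvNet, val_by_p: Mapping[int, tuple],
                              batch_size: int) -> float:
    losses = []
    for participant, (Xv, yv) in val_by_p.items():
        sub = []
        for lo in range(0, len(Xv), batch_size):
            logits, _ = model.forward(Xv[lo:lo + batch_size], bank_key=participant)
            loss, _ = softmax_xent(logits, yv[lo:lo + batch_size])
            sub.append(loss)
        losses.append(np.mean(sub))
    return float(np.mean(losses))


def train_adann(model: ConvNet, dataset: WindowedDataset,
                config: TrainConfig = TrainConfig(),
                refresh_stats: bool = True) -> TrainResult:
    """Multi-domain adversarial training with per-participant BN statistics.

    With ``refresh_stats`` (default), each participant's running BN
    statistics are recomputed exactly from their training windows under the
    final weights, replacing the momentum-based running estimates (which
    converge slowly when a participant contributes few batches per epoch).
    """
    train = dataset.subset("train")
    val = dataset.subset("val")
    if len(train) == 0 or len(val) == 0:
        raise ValueError("dataset needs nonempty train and val splits")
    by_p = _participant_arrays(train)
    val_by_p = _participant_arrays(val)
    participants = sorted(by_p)
    if len(participants) < 2:
        warnings.warn("single participant: falling back to standard training",
                      stacklevel=2)
        return train_standard(model, dataset, config)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), config.lr)
    annealer = _Annealer(opt, config)
    for p in participants:
        model.get_bank(p, create=True)
    lam = config.lambda_domain
    rows = []
    for epoch in range(config.max_epochs):
        # the domain head always trains at full strength; the reversed
        # gradient into the shared trunk ramps up over the warmup epochs
        ramp = 1.0
        if config.lambda_warmup_epochs > 0:
            ramp = min(1.0, (epoch + 1) / config.lambda_warmup_epochs)
        reversal = config.reversal_constant * ramp
        epoch_ly, epoch_ld, nb = 0.0, 0.0, 0
        # one shuffled pass over every participant's batches, interleaved
        # across participants so consecutive updates mix domains
        plan: list[tuple[int, np.ndarray]] = []
        for source in rng.permutation(participants):
            source = int(source)
            order = rng.permutation(len(by_p[source][0]))
            plan.extend((source, order[lo:lo + config.batch_size])
                        for lo in range(0, len(order), config.batch_size))
        for source, sel in (plan[i] for i in rng.permutation(len(plan))):
            Xs_all, ys_all = by_p[source]
            Xs, ys = Xs_all[sel], ys_all[sel]
            target = int(rng.choice([p for p in participants if p != source]))
            Xt_all, _ = by_p[target]
            tsel = rng.choice(len(Xt_all), size=min(len(Xt_all), len(sel)),
                              replace=False)
            Xt = Xt_all[tsel]

            model.zero_grad()
            # source batch: domain label 0; BN stats of the source
            # participant, running statistics updated
            logits, dlogits_dom = model.forward(
                Xs, bank_key=source, train=True, rng=rng,
                update_stats=True, cache=True)
            ly, d_class = softmax_xent(logits, ys)
            ld_s, d_dom = softmax_xent(dlogits_dom,
                                       np.zeros(len(Xs), dtype=int))
            model.backward(d_class,
                           d_domain=lam * d_dom if lam else None,
                           domain_scale=reversal)
            # target batch: domain label 1; BN stats of the target
            # participant, running statistics NOT updated; gesture
            # labels unused
            _, logits_dom_t = model.forward(
                Xt, bank_key=target, train=True, rng=rng,
                update_stats=False, cache=True)
            ld_t, d_dom_t = softmax_xent(logits_dom_t,
                                         np.ones(len(Xt), dtype=int))
            if lam:
                model.backward(None, d_domain=lam * d_dom_t,
                               domain_scale=reversal)
            opt.step(model.grads())
            epoch_ly += ly
            epoch_ld += 0.5 * (ld_s + ld_t)
            nb += 1
        val_loss = _val_loss_per_participant(model, val_by_p, config.batch_size)
        rows.append({"epoch": epoch, "train_loss": epoch_ly / max(nb, 1),
                     "domain_loss": epoch_ld / max(nb, 1),
                     "val_loss": val_loss, "lr": opt.lr})
        if annealer.update(val_loss):
            break
    if refresh_stats:
        for p in participants:
            adapt_bn(model, by_p[p][0], p, config.batch_size)
    history = pd.DataFrame(rows)
    return TrainResult(model, history, annealer.best)


# ---------------------------------------------------------------------------
# evaluation


def adapt_bn(model: ConvNet, X: np.ndarray, key, batch_size: int = 256) -> None:
    """AdaBN: recompute BN running statistics for ``key`` from unlabeled
    windows, leaving all weights untouched.

    Statistics are exact per block: each block's input distribution is
    computed under the already-adapted statistics of the preceding blocks.
    """
    cfg = model.config
    stats = model._fresh_stats()
    for b in range(cfg.n_blocks):
        s = np.zeros(cfg.feature_maps)
        sq = np.zeros(cfg.feature_maps)
        count = 0
        for lo in range(0, len(X), batch_size):
            # channels-last activations (B, R, T, C)
            h = np.asarray(X[lo:lo + batch_size], dtype=model.dtype)[..., None]
            for bb in range(b):
                blk = model.blocks[bb]
                h = blk["conv"].forward(h, cache=False)
                h, _ = blk["bn"].forward(h, stats[bb], train=False, cache=False)
                h = blk["act"].forward(h, cache=False)
            h = model.blocks[b]["conv"].forward(h, cache=False)
            s += h.sum(axis=(0, 1, 2))
            sq += (h.astype(np.float64) ** 2).sum(axis=(0, 1, 2))
            count += h.shape[0] * h.shape[1] * h.shape[2]
        mean = s / count
        var = np.maximum(sq / count - mean ** 2, 0.0)
        stats[b] = (mean.astype(model.dtype), var.astype(model.dtype))
    model.bn_banks[key] = stats


def predict(model: ConvNet, X: np.ndarray, stats, batch_size: int = 256
            ) -> np.ndarray:
    preds = []
    for lo in range(0, len(X), batch_size):
        logits, _ = model.forward(X[lo:lo + batch_size], stats=stats)
        preds.append(np.argmax(logits, axis=1))
    return np.concatenate(preds)


def evaluate_cross_subject(model: ConvNet, test_dataset: WindowedDataset,
                           adaptation: str = "adabn",
                           batch_size: int = 256) -> dict[int, float]:
    """Per-participant accuracy on held-out participants, never updating
    weights.

    ``adaptation="adabn"`` recomputes BN statistics from each test
    participant's unlabeled windows; ``"none"`` evaluates under the average
    of the stored training banks.
    """
    by_p = _participant_arrays(test_dataset)
    out: dict[int, float] = {}
    for participant, (X, y) in by_p.items():
        if adaptation == "adabn":
            key = ("__adapt__", participant)
            adapt_bn(model, X, key, batch_size)
            stats = model.bn_banks.pop(key)
        elif adaptation == "none":
            stats = model.mean_bank(
                [k for k in model.bn_banks if not isinstance(k, tuple)])
        else:
            raise ValueError(f"unknown adaptation {adaptation!r}")
        preds = predict(model, X, stats, batch_size)
        out[participant] = float(np.mean(preds == y))
    return out


def compare_training_methods(acc_a: Sequence[float], acc_b: Sequence[float]
                             ) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank p-value (two-sided) and Cohen's d.

    ``d`` is the mean paired difference divided by the pooled standard
    deviation of the two samples.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D paired samples")
    if len(a) < 5:
        raise ValueError("need at least 5 paired observations")
    diffs = a - b
    if np.allclose(diffs, 0.0):
        return 1.0, 0.0
    res = sstats.wilcoxon(a, b, alternative="two-sided")
    pooled = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
    d = float(np.mean(diffs) / pooled) if pooled > 0 else 0.0
    return float(res.pvalue), d


# ---------------------------------------------------------------------------
# leave-one-domain-out property experiment


def domain_gap_experiment(seeds: Sequence[int] = (0, 1, 2),
                          synth_kwargs: dict | None = None,
                          arch: ArchitectureConfig | None = None,
                          train_kwargs: dict | None = None,
                          adaptation: Mapping[str, str] | None = None,
                          folds: Sequence[int] | None = None) -> dict:
    """Leave-one-domain-out comparison of adversarial vs. standard training
    on the synthetic multi-domain generator.

    For every seed and every held-out participant, both methods are trained
    on the remaining participants and evaluated on the held-out
    participant's test windows.  Each method is evaluated under its own
    protocol: conventionally trained models use their trained (shared) BN
    statistics with no participant-specific adaptation, while the
    adversarial model — whose per-participant statistic banks cannot cover
    an unseen arm — recomputes statistics from the held-out participant's
    unlabeled windows (the AdaBN policy); override via ``adaptation``.
    Returns per-method mean accuracies and the mean gap (adversarial minus
    standard) in accuracy points.
    """
    from .synthetic import SynthConfig, generate_dataset

    synth_kwargs = dict(synth_kwargs or {})
    arch = arch or ArchitectureConfig(n_blocks=3, feature_maps=8)
    train_kwargs = dict(train_kwargs or {})
    adaptation = dict(adaptation or {"adann": "adabn", "standard": "none"})
    results = {"adann": [], "standard": []}
    for seed in seeds:
        cfg = SynthConfig(**{"seed": seed, **synth_kwargs})
        dataset = generate_dataset(cfg)
        X, y, p, c = dataset.arrays()
        for held_out in (folds if folds is not None
                         else range(cfg.participants)):
            keep = [w for w in dataset.windows if w.participant != held_out]
            train_ds = WindowedDataset(keep, dict(dataset.split))
            test_ds = WindowedDataset(
                [w for w in dataset.windows
                 if w.participant == held_out
                 and dataset.split.get(w.cycle) == "test"],
                dict(dataset.split))
            for method in ("adann", "standard"):
                model = build_model(arch, seed=seed * 17 + held_out)
                tc = TrainConfig(**{"seed": seed * 31 + held_out, **train_kwargs})
                if method == "adann":
                    train_adann(model, train_ds, tc)
                else:
                    train_standard(model, train_ds, tc)
                acc = evaluate_cross_subject(model, test_ds,
                                             adaptation[method])
                results[method].append(acc[held_out])
    mean_adann = float(np.mean(results["adann"]))
    mean_standard = float(np.mean(results["standard"]))
    return {
        "adann_accuracies": results["adann"],
        "standard_accuracies": results["standard"],
        "mean_adann": mean_adann,
        "mean_standard": mean_standard,
        "gap_points": 100.0 * (mean_adann - mean_standard),
    }
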