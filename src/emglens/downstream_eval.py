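"""Reference evaluations of feature quality.

Two probes are provided:

- :func:`lda_eval` trains a linear discriminant analysis classifier in a
  cross-subject framework (fit on training cycles, tested on test cycles)
  on a single feature or a whole feature group/block.  A single
  handcrafted feature enters as its 10 per-channel values; a single
  learned feature is reduced to the first principal component of its 10
  channel values.
- :func:`regression_probe` freezes a trained network and fits a linear
  regression head from a block's post-activation maps (first channel row
  only) to a handcrafted feature's first-channel value, repeated with
  random restarts, reporting the mean test MSE across repetitions and
  participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .convnet import ConvNet, SHARED_BANK
from .handcrafted import GROUPS, FeatureTable
from .signal_io import WindowedDataset

__all__ = ["EvalResult", "RegressionResult", "lda_eval", "regression_probe"]


@dataclass
class EvalResult:
    target: str               # feature or group/block id
    accuracy: float
    confusion: np.ndarray     # (n_classes, n_classes); rows true, cols predicted
    used_shrinkage: bool = False


@dataclass
class RegressionResult:
    block: int
    feature: str
    repetitions: int
    mean_mse: float
    per_participant_mse: dict[int, float] = field(default_factory=dict)


def _roles(table: FeatureTable, split: dict[int, str]) -> np.ndarray:
    return np.array([split.get(int(c), "test") for c in table.meta["cycle"]])

def _confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    return cm


def _fit_lda(Xtr, ytr):
    """LDA with a shrinkage fallback when the within-class covariance is
    singular / features are collinear."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        lda = LinearDiscriminantAnalysis()
        lda.fit(Xtr, ytr)
        collinear = any("collinear" in str(w.message).lower() for w in caught)
    if collinear:
        warnings.warn("within-class covariance singular; refitting LDA with "
                      "lsqr solver and automatic shrinkage", stacklevel=2)
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(Xtr, ytr)
        return lda, True
    return lda, False


def lda_eval(table: FeatureTable, split: dict[int, str],
             feature: str | None = None, group: str | None = None,
             mode: str = "auto", n_classes: int | None = None,
             train_roles: tuple[str, ...] = ("train", "val")) -> EvalResult:
    """Cross-subject LDA accuracy of one feature or one feature group.

    ``mode`` controls how a single feature enters the classifier:
    ``"channels"`` uses the 10 per-channel values, ``"pc1"`` the first
    principal component over channels (fit on the training rows); with
    ``"auto"``, handcrafted features (group label in the five functional
    groups) use channels and learned features use pc1.
    """
    if (feature is None) == (group is None):
        raise ValueError("pass exactly one of feature=... or group=...")
    roles = _roles(table, split)
    tr = np.isin(roles, train_roles)
    te = roles == "test"
    if not tr.any() or not te.any():
        raise ValueError("need nonempty train and test rows")
    y = table.meta["gesture"].to_numpy()
    if n_classes is None:
        n_classes = int(y.max()) + 1

    if feature is not None:
        j = table.feature_names.index(feature)
        vals = table.values[:, :, j]  # (windows, channels)
        if mode == "auto":
            mode = "channels" if table.feature_labels[j] in GROUPS else "pc1"
        if mode == "channels":
            X = vals
        elif mode == "pc1":
            pca = PCA(n_components=1)
            pca.fit(vals[tr])
            X = pca.transform(vals)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        target = feature
    else:
        cols = [j for j, lab in enumerate(table.feature_labels) if lab == group]
        if not cols:
            raise ValueError(f"no features labeled {group!r}")
        X = table.values[:, :, cols].reshape(table.n_windows, -1)
        target = group

    lda, used_shrinkage = _fit_lda(X[tr], y[tr])
    pred = lda.predict(X[te])
    acc = float(np.mean(pred == y[te]))
    cm = _confusion(y[te], pred, n_classes)
    return EvalResult(target, acc, cm, used_shrinkage)


# ---------------------------------------------------------------------------
# regression probe


def _block_first_channel_features(model: ConvNet, X: np.ndarray, block: int,
                                  stats, batch_size: int = 256) -> np.ndarray:
    """Flattened first-channel slice of a block's post-activation maps."""
    outs = []
    for lo in range(0, len(X), batch_size):
        collect: list[np.ndarray] = []
        model.forward(X[lo:lo + batch_size], stats=stats, train=False,
                      collect=collect)
        maps = collect[block - 1]          # (B, maps, R, T)
        outs.append(maps[:, :, 0, :].reshape(maps.shape[0], -1))
    return np.concatenate(outs).astype(np.float64)


def _linear_sgd(Xtr, ytr, rng: np.random.Generator, epochs: int = 60,
                batch_size: int = 64, lr: float = 1e-2) -> tuple[np.ndarray, float]:
    """Mini-batch Adam on MSE for a single-output linear head."""
    n, d = Xtr.shape
    # small random restarts: near-zero init keeps early iterates sensible
    # in the heavily over-parameterized regime (d >> n)
    w = rng.standard_normal(d) * (0.01 / np.sqrt(d))
    b = 0.0
    mw = np.zeros(d); vw = np.zeros(d); mb = vb = 0.0
    t = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            sel = order[lo:lo + batch_size]
            err = Xtr[sel] @ w + b - ytr[sel]
            gw = 2.0 * Xtr[sel].T @ err / len(sel)
            gb = 2.0 * float(np.mean(err))
            t += 1
            mw = 0.9 * mw + 0.1 * gw; vw = 0.999 * vw + 0.001 * gw * gw
            mb = 0.9 * mb + 0.1 * gb; vb = 0.999 * vb + 0.001 * gb * gb
            w -= lr * (mw / (1 - 0.9 ** t)) / (np.sqrt(vw / (1 - 0.999 ** t)) + 1e-8)
            b -= lr * (mb / (1 - 0.9 ** t)) / (np.sqrt(vb / (1 - 0.999 ** t)) + 1e-8)
    return w, b


def regression_probe(model: ConvNet, block: int, feature: str,
                     table: FeatureTable, dataset: WindowedDataset,
                     reps: int = 20, seed: int = 0,
                     strict_phase_pca: bool = False,
                     epochs: int = 60) -> RegressionResult:
    """Predict a handcrafted feature from a frozen block's learned maps.

    The regression head sees the flattened first-channel slice of the
    block's post-activation maps; the target is the feature's first-channel
    value (first principal component for multi-output methods), z-scored on
    training statistics.  Trained ``reps`` times per participant with
    random restarts; reports the mean test MSE.
    """
    cfg = model.config
    if not 1 <= block <= cfg.n_blocks:
        raise ValueError(f"block {block} out of range 1..{cfg.n_blocks}")
    if not model.bn_banks:
        warnings.warn("probing an untrained model (no BN banks stored)",
                      stacklevel=2)
    X, y, p, c = dataset.arrays()
    roles = np.array([dataset.split.get(int(cc), "test") for cc in c])
    # target values: the named method's outputs on channel 0
    cols = [j for j, n in enumerate(table.feature_names)
            if n == feature or (n.startswith(feature) and
                                n[len(feature):].isdigit())]
    if not cols:
        raise ValueError(f"feature {feature!r} not in table")
    rng = np.random.default_rng(seed)
    per_p: dict[int, float] = {}
    for participant in np.unique(p):
        mask = p == participant
        tr = mask & np.isin(roles, ("train", "val"))
        te = mask & (roles == "test")
        if not tr.any() or not te.any():
            continue
        stats = model.bn_banks.get(int(participant))
        if stats is None:
            stats = (model.bn_banks.get(SHARED_BANK) or model._fresh_stats())
        feats_tr = _block_first_channel_features(model, X[tr], block, stats)
        feats_te = _block_first_channel_features(model, X[te], block, stats)
        targ = table.values[:, 0, :][:, cols]  # first channel, method outputs
        if len(cols) > 1:
            pca = PCA(n_components=1)
            if strict_phase_pca:
                t_tr = PCA(n_components=1).fit_transform(targ[tr])[:, 0]
                t_te = PCA(n_components=1).fit_transform(targ[te])[:, 0]
            else:
                pca.fit(targ[tr])
                t_tr = pca.transform(targ[tr])[:, 0]
                t_te = pca.transform(targ[te])[:, 0]
        else:
            t_tr, t_te = targ[tr, 0], targ[te, 0]
        mu, sd = np.mean(t_tr), max(np.std(t_tr), 1e-12)
        t_tr = (t_tr - mu) / sd
        t_te = (t_te - mu) / sd
        # standardize inputs on train stats for stable SGD; features that
        # are constant on the training windows carry no usable signal and
        # would explode under standardization, so they are zeroed instead
        fmu = feats_tr.mean(axis=0)
        fsd = feats_tr.std(axis=0)
        dead = fsd < 1e-8 * max(1.0, float(fsd.max()))
        fsd = np.where(dead, 1.0, fsd)
        feats_tr = (feats_tr - fmu) / fsd
        feats_te = (feats_te - fmu) / fsd
        feats_tr[:, dead] = 0.0
        feats_te[:, dead] = 0.0
        mses = []
        for _ in range(reps):
            w, b = _linear_sgd(feats_tr, t_tr, rng, epochs=epochs)
            mses.append(float(np.mean((feats_te @ w + b - t_te) ** 2)))
        per_p[int(participant)] = float(np.mean(mses))
    if not per_p:
        raise ValueError("no participant had both train and test windows")
    return RegressionResult(block, feature, reps,
                            float(np.mean(list(per_p.values()))), per_p)
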