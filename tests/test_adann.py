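import numpy as np
import pytest

from emglens.adann import (Adam, TrainConfig, _Annealer, adapt_bn,
                           compare_training_methods, evaluate_cross_subject,
                           softmax_xent, train_adann, train_standard)
from emglens.convnet import ArchitectureConfig, ConvNet, build_model
from emglens.signal_io import Window, WindowedDataset
from emglens.synthetic import SynthConfig, generate_dataset


def _toy_dataset(seed=0, participants=2, gestures=2, n_per=12):
    """Linearly separable toy windows: gesture g has mean level g * 30."""
    rng = np.random.default_rng(seed)
    windows = []
    for p in range(participants):
        for g in range(gestures):
            for cycle in (1, 2):
                for _ in range(n_per):
                    data = rng.standard_normal((10, 151)) + 30.0 * g
                    windows.append(Window(data, p, g, cycle))
    return WindowedDataset(windows, {1: "train", 2: "val"})


TINY = ArchitectureConfig(n_blocks=1, feature_maps=4, n_classes=2)
#: dropout-free variant for gradient-identity tests (no rng needed)
TINY_DET = ArchitectureConfig(n_blocks=1, feature_maps=4, n_classes=2,
                              dropout=0.0)


class TestTrainStandard:
    def test_loss_decreases_on_separable_toy(self):
        ds = _toy_dataset()
        model = build_model(TINY, seed=0)
        res = train_standard(model, ds, TrainConfig(lr=1e-3, batch_size=32,
                                                    max_epochs=4, seed=0))
        assert res.history["train_loss"].iloc[-1] < \
            res.history["train_loss"].iloc[0]

    def test_fixed_seed_bitwise_determinism(self):
        losses = []
        for _ in range(2):
            ds = _toy_dataset()
            model = build_model(TINY, seed=1)
            res = train_standard(model, ds, TrainConfig(lr=1e-3, batch_size=32,
                                                        max_epochs=3, seed=5))
            losses.append(res.history["val_loss"].iloc[-1])
        assert losses[0] == losses[1]

    def test_empty_split_rejected(self):
        ds = _toy_dataset()
        ds.split = {1: "train", 2: "train"}  # no val cycles
        with pytest.raises(ValueError):
            train_standard(build_model(TINY, seed=0), ds, TrainConfig())


class TestTrainAdann:
    def test_single_participant_falls_back(self):
        ds = _toy_dataset(participants=1)
        model = build_model(TINY, seed=0)
        with pytest.warns(UserWarning, match="single participant"):
            res = train_adann(model, ds, TrainConfig(lr=1e-3, batch_size=32,
                                                     max_epochs=1, seed=0))
        assert "domain_loss" not in res.history.columns

    def test_lambda_zero_leaves_domain_head_untouched(self):
        ds = _toy_dataset()
        model = build_model(TINY, seed=2)
        w0 = model.domain_head.W.copy()
        b0 = model.domain_head.b.copy()
        train_adann(model, ds, TrainConfig(lr=1e-3, batch_size=32,
                                           max_epochs=2, seed=2,
                                           lambda_domain=0.0))
        np.testing.assert_array_equal(model.domain_head.W, w0)
        np.testing.assert_array_equal(model.domain_head.b, b0)

    def test_reversal_negates_trunk_gradient_only(self):
        """Direct-computation oracle for the gradient-reversal unit."""
        model = build_model(TINY_DET, seed=3, dtype=np.float64)
        model.get_bank("p", create=True)
        rng = np.random.default_rng(4)
        X = rng.standard_normal((6, 10, 151))
        trunk_grads = {}
        head_grads = {}
        for scale in (1.0, -1.0):
            model.zero_grad()
            _, dom = model.forward(X, bank_key="p", train=True, cache=True)
            _, gd = softmax_xent(dom, np.zeros(6, dtype=int))
            model.backward(None, d_domain=gd, domain_scale=scale)
            trunk_grads[scale] = [g.copy() for layer in
                                  [blk["conv"] for blk in model.blocks]
                                  for g in layer.grads()]
            head_grads[scale] = [g.copy() for g in model.domain_head.grads()]
        for g_plus, g_minus in zip(trunk_grads[1.0], trunk_grads[-1.0]):
            np.testing.assert_allclose(g_minus, -g_plus, rtol=1e-10)
        for g_plus, g_minus in zip(head_grads[1.0], head_grads[-1.0]):
            np.testing.assert_allclose(g_minus, g_plus, rtol=1e-10)

    def test_every_participant_gets_a_bank(self):
        ds = _toy_dataset(participants=3)
        model = build_model(TINY, seed=0)
        train_adann(model, ds, TrainConfig(lr=1e-3, batch_size=64,
                                           max_epochs=1, seed=0))
        assert {0, 1, 2} <= set(model.bn_banks)


class TestBNIsolation:
    def test_update_stats_touches_only_the_active_bank(self):
        model = build_model(TINY, seed=0)
        rng = np.random.default_rng(0)
        model.get_bank("a", create=True)
        model.get_bank("b", create=True)
        snap_b = [(m.copy(), v.copy()) for m, v in model.get_bank("b")]
        model.forward(rng.standard_normal((4, 10, 151)), bank_key="a",
                      train=True, rng=rng, update_stats=True)
        for (m0, v0), (m1, v1) in zip(snap_b, model.get_bank("b")):
            np.testing.assert_array_equal(m0, m1)
            np.testing.assert_array_equal(v0, v1)
        # and the active bank did change
        fresh = model._fresh_stats()
        changed = any(not np.array_equal(m, fm)
                      for (m, _), (fm, _) in zip(model.get_bank("a"), fresh))
        assert changed

    def test_train_mode_without_update_leaves_bank(self):
        model = build_model(TINY, seed=0)
        rng = np.random.default_rng(1)
        model.get_bank("a", create=True)
        snap = [(m.copy(), v.copy()) for m, v in model.get_bank("a")]
        model.forward(rng.standard_normal((4, 10, 151)), bank_key="a",
                      train=True, rng=rng, update_stats=False)
        for (m0, v0), (m1, v1) in zip(snap, model.get_bank("a")):
            np.testing.assert_array_equal(m0, m1)


class _PerfectStub(ConvNet):
    """Reads the gesture id planted as the window's constant level."""

    def forward(self, x, bank_key=None, stats=None, **kw):
        x = np.atleast_3d(np.asarray(x))
        level = np.round(x.mean(axis=(1, 2))).astype(int)
        logits = np.zeros((len(level), self.config.n_classes))
        logits[np.arange(len(level)), np.clip(level, 0, None)] = 10.0
        return logits, np.zeros((len(level), 2))


def _planted_dataset(permute=False, seed=0):
    rng = np.random.default_rng(seed)
    windows = []
    for g in range(2):
        for _ in range(30):
            label = int(rng.integers(0, 2)) if permute else g
            windows.append(Window(np.full((10, 151), float(g)), 0, label, 5))
    return WindowedDataset(windows, {5: "test"})


class TestEvaluateCrossSubject:
    def test_perfect_stub_scores_one(self):
        stub = _PerfectStub(TINY, seed=0)
        stub.get_bank("__shared__", create=True)
        acc = evaluate_cross_subject(stub, _planted_dataset(), "none")
        assert acc[0] == 1.0

    def test_label_permuted_near_chance(self):
        stub = _PerfectStub(TINY, seed=0)
        stub.get_bank("__shared__", create=True)
        acc = evaluate_cross_subject(stub, _planted_dataset(permute=True),
                                     "none")
        assert abs(acc[0] - 0.5) < 0.25

    def test_adabn_beats_none_on_scaled_domain(self, trained_tiny_model,
                                               small_dataset):
        # a synthetic 'new arm': participant 0's test windows scaled 6x
        shifted = WindowedDataset(
            [Window(w.data * 6.0, 99, w.gesture, w.cycle)
             for w in small_dataset.windows
             if w.participant == 0 and small_dataset.split[w.cycle] == "test"],
            dict(small_dataset.split))
        acc_ada = evaluate_cross_subject(trained_tiny_model, shifted, "adabn")
        acc_none = evaluate_cross_subject(trained_tiny_model, shifted, "none")
        assert acc_ada[99] >= acc_none[99]

    def test_unknown_adaptation_rejected(self, trained_tiny_model,
                                         small_dataset):
        with pytest.raises(ValueError):
            evaluate_cross_subject(trained_tiny_model, small_dataset, "magic")


class TestAnnealer:
    def test_two_fruitless_annealings_stop_training(self):
        cfg = TrainConfig(lr=1.0, patience=2, anneal_factor=5.0)
        opt = Adam([np.zeros(1)], cfg.lr)
        ann = _Annealer(opt, cfg)
        assert not ann.update(1.0)   # new best
        stops = [ann.update(2.0) for _ in range(6)]
        # epochs 1,2 bad; epoch 3 anneals (1st); 4,5 bad; 6 anneals (2nd) -> stop
        assert stops == [False, False, False, False, False, True]
        assert opt.lr == pytest.approx(1.0 / 25.0)

    def test_new_best_resets_fruitless_count(self):
        cfg = TrainConfig(lr=1.0, patience=1, anneal_factor=2.0)
        opt = Adam([np.zeros(1)], cfg.lr)
        ann = _Annealer(opt, cfg)
        ann.update(1.0)
        ann.update(2.0)
        assert not ann.update(2.0)   # first annealing
        assert not ann.update(0.5)   # new best: reset
        ann.update(2.0)
        assert not ann.update(2.0)   # annealing again, count restarted at 1


class TestCompareTrainingMethods:
    def test_identical_vectors(self):
        p, d = compare_training_methods([0.5] * 6, [0.5] * 6)
        assert d == 0.0
        assert p == 1.0

    def test_constant_shift_n22_significant(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.4, 0.8, size=22)
        p, d = compare_training_methods(base + 0.01, base)
        assert p < 0.001
        assert d > 0

    def test_six_pair_exact_enumeration_oracle(self):
        a = np.array([0.71, 0.64, 0.80, 0.55, 0.62, 0.90])
        b = np.array([0.65, 0.60, 0.70, 0.58, 0.52, 0.85])
        p, _ = compare_training_methods(a, b)
        # enumerate all 2^6 sign assignments of the ranked |differences|
        diffs = a - b
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        t_obs = ranks[diffs > 0].sum()
        total = ranks.sum()
        null = []
        for mask in range(64):
            signs = [(mask >> i) & 1 for i in range(6)]
            null.append(sum(r for r, s in zip(ranks, signs) if s))
        null = np.array(null)
        lo, hi = min(t_obs, total - t_obs), max(t_obs, total - t_obs)
        p_exact = (np.mean(null <= lo) + np.mean(null >= hi))
        assert p == pytest.approx(p_exact, rel=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            compare_training_methods([1, 2, 3], [1, 2, 2])


class TestAdaptBN:
    def test_adapted_stats_match_direct_computation_block1(self,
                                                           trained_tiny_model):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 10, 151)) * 30
        adapt_bn(trained_tiny_model, X, "tmp")
        stats = trained_tiny_model.bn_banks.pop("tmp")
        h = trained_tiny_model.blocks[0]["conv"].forward(
            np.asarray(X, dtype=trained_tiny_model.dtype)[..., None],
            cache=False)
        np.testing.assert_allclose(stats[0][0], h.mean(axis=(0, 1, 2)),
                                   rtol=1e-4, atol=1e-5)
        np.testing.assert_allclose(stats[0][1], h.var(axis=(0, 1, 2)),
                                   rtol=1e-3, atol=1e-3)
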