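"""Split protocol, metrics, early stopping and paired-training tests."""

import numpy as np
import pytest

from enkit.errors import ConfigurationError
from enkit.models import ModelSpec, build_model
from enkit.simulate import EpochSet
from enkit.train_eval import (EarlyStopper, TrainConfig, compare_enk,
                              derive_seed, evaluate, f1_scores, mse_score,
                              stratified_split, train)


def _labelled(labels, n_channels=2, n_samples=8):
    labels = np.asarray(labels)
    rng = np.random.default_rng(0)
    return EpochSet(
        data=rng.standard_normal((len(labels), n_channels, n_samples)),
        labels=labels, sampling_rate=64,
        channel_names=[f"ch{i}" for i in range(n_channels)],
        class_names=[f"c{i}" for i in range(int(labels.max()) + 1)],
        provenance={})


class TestStratifiedSplit:
    def test_exact_on_divisible(self):
        es = _labelled([0] * 5 + [1] * 5)
        tr, va, te = stratified_split(es, (0.6, 0.2, 0.2), seed=1)
        assert (tr.n_epochs, va.n_epochs, te.n_epochs) == (6, 2, 2)
        for part in (tr, va, te):
            counts = np.bincount(part.labels, minlength=2)
            assert counts[0] == counts[1]

    def test_partition_law(self):
        es = _labelled([0] * 9 + [1] * 13)
        tr, va, te = stratified_split(es, seed=3)
        # reconstruct membership via data rows (indices are not exposed)
        seen = np.concatenate([p.data[:, 0, 0] for p in (tr, va, te)])
        assert len(seen) == es.n_epochs
        assert set(np.round(seen, 12)) == set(np.round(es.data[:, 0, 0], 12))

    def test_floor_allocation_remainder_to_train(self):
        es = _labelled([0] * 7 + [1] * 7)
        tr, va, te = stratified_split(es, (0.6, 0.2, 0.2), seed=0)
        assert (tr.n_epochs, va.n_epochs, te.n_epochs) == (10, 2, 2)

    def test_class_too_small_named(self):
        es = _labelled([0] * 10 + [1] * 3)
        with pytest.raises(ConfigurationError, match="class 1"):
            stratified_split(es, (0.6, 0.2, 0.2), seed=0)

    def test_determinism_and_stratification_property(self):
        """100 random label vectors: per-class proportions preserved to
        within one epoch; identical seeds give identical partitions."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_classes = int(rng.integers(2, 5))
            counts = rng.integers(5, 30, size=n_classes)
            labels = np.repeat(np.arange(n_classes), counts)
            es = _labelled(labels)
            seed = int(rng.integers(0, 2 ** 31))
            tr, va, te = stratified_split(es, (0.6, 0.2, 0.2), seed=seed)
            tr2, va2, te2 = stratified_split(es, (0.6, 0.2, 0.2), seed=seed)
            np.testing.assert_array_equal(tr.data, tr2.data)
            np.testing.assert_array_equal(te.labels, te2.labels)
            for c in range(n_classes):
                n_c = counts[c]
                assert np.sum(va.labels == c) == int(np.floor(0.2 * n_c))
                assert np.sum(te.labels == c) == int(np.floor(0.2 * n_c))

    def test_bad_fractions(self):
        with pytest.raises(ConfigurationError, match="sum to 1"):
            stratified_split(_labelled([0] * 5 + [1] * 5), (0.5, 0.2, 0.2))


class TestMetrics:
    def test_mse_toy_case(self):
        probs = np.array([[0.8, 0.2]])
        assert mse_score(probs, np.array([0]), 2) == pytest.approx(0.04)

    def test_binary_f1_closed_form(self):
        # TP=1, FP=1, FN=0 -> F1 = 2/3
        y_true = np.array([1, 0])
        y_pred = np.array([1, 1])
        _, f1 = f1_scores(y_true, y_pred, 2)
        assert f1 == pytest.approx(2 / 3)

    def test_exhaustive_2x2_tables(self):
        """All confusion tables with cell counts <= 3 against the closed
        form 2TP/(2TP+FP+FN)."""
        for tp in range(4):
            for fp in range(4):
                for fn in range(4):
                    for tn in range(4):
                        if tp + fp + fn + tn == 0:
                            continue
                        y_true = np.array([1] * tp + [0] * fp + [1] * fn + [0] * tn)
                        y_pred = np.array([1] * tp + [1] * fp + [0] * fn + [0] * tn)
                        per_class, f1 = f1_scores(y_true, y_pred, 2)
                        denom = 2 * tp + fp + fn
                        expected = 2 * tp / denom if denom else 0.0
                        assert f1 == pytest.approx(expected), (tp, fp, fn, tn)
                        # mirror table for the negative class
                        neg = 2 * tn / (2 * tn + fn + fp) if (2 * tn + fn + fp) else 0.0
                        assert per_class[0] == pytest.approx(neg)

    def test_weighted_f1_weighting_arithmetic(self):
        # per-class F1 (1.0, 0.5, 0.0) with supports (2, 1, 1) -> 0.625
        per_class = [1.0, 0.5, 0.0]
        support = [2, 1, 1]
        weighted = sum(f * s for f, s in zip(per_class, support)) / sum(support)
        assert weighted == pytest.approx(0.625)

    def test_matches_sklearn(self):
        """Cross-check binary and weighted multiclass F1 against sklearn."""
        from sklearn.metrics import f1_score

        rng = np.random.default_rng(7)
        for n_classes in (2, 3, 4):
            for _ in range(20):
                n = int(rng.integers(4, 40))
                y_true = rng.integers(0, n_classes, size=n)
                y_pred = rng.integers(0, n_classes, size=n)
                per_class, mine = f1_scores(y_true, y_pred, n_classes)
                if n_classes == 2:
                    ref = f1_score(y_true, y_pred, pos_label=1, zero_division=0)
                else:
                    ref = f1_score(y_true, y_pred, average="weighted",
                                   labels=np.arange(n_classes), zero_division=0)
                assert mine == pytest.approx(ref, abs=1e-12)

    def test_absent_class_warns(self, tiny_epochs):
        spec = ModelSpec(architecture="eegnet", n_channels=4, n_samples=64,
                         n_classes=2)
        model = build_model(spec, 0)
        only_one = tiny_epochs.subset(np.flatnonzero(tiny_epochs.labels == 1)[:4])
        rep = evaluate(model, only_one)
        assert any("class 0" in w for w in rep.warnings)


class TestEarlyStopping:
    def test_monotone_increase_stops_at_patience_plus_one(self):
        stopper = EarlyStopper(patience=20)
        stopped_at = None
        for epoch, loss in enumerate(np.arange(1.0, 100.0), start=1):
            if stopper.update(epoch, float(loss)):
                stopped_at = epoch
                break
        assert stopped_at == 21
        assert stopper.best_epoch == 1

    def test_improvement_resets_patience(self):
        stopper = EarlyStopper(patience=3)
        losses = [5.0, 4.0, 4.5, 4.6, 3.9, 4.1, 4.2, 4.3]
        stops = [stopper.update(i, lo) for i, lo in enumerate(losses, 1)]
        assert stops == [False] * 7 + [True]
        assert stopper.best_epoch == 5


def _fast_cfg(seed=0, **kw):
    base = dict(max_epochs=6, patience=3, batch_size=8, seed=seed)
    base.update(kw)
    return TrainConfig(**base)


class TestTrain:
    @pytest.fixture(scope="class")
    def splits(self, tiny_epochs):
        return stratified_split(tiny_epochs, seed=1)

    def _model(self, seed=2):
        return build_model(ModelSpec(architecture="eegnet", n_channels=4,
                                     n_samples=64, n_classes=2, scale=0.5),
                           init_seed=seed)

    def test_loss_decreases_on_separable_task(self, splits):
        tr, va, _ = splits
        model, hist = train(self._model(), tr, va, _fast_cfg())
        assert hist.val_loss[hist.best_epoch - 1] == min(hist.val_loss)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_best_weights_restored(self, splits):
        from enkit.train_eval import _val_loss
        tr, va, _ = splits
        model, hist = train(self._model(), tr, va, _fast_cfg())
        assert _val_loss(model, va) == pytest.approx(min(hist.val_loss), rel=1e-9)

    def test_deterministic_histories(self, splits):
        tr, va, _ = splits
        _, h1 = train(self._model(seed=4), tr, va, _fast_cfg(seed=9))
        _, h2 = train(self._model(seed=4), tr, va, _fast_cfg(seed=9))
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss
        assert h1.best_epoch == h2.best_epoch

    def test_history_csv(self, splits, tmp_path):
        tr, va, _ = splits
        _, hist = train(self._model(), tr, va, _fast_cfg())
        hist.to_csv(tmp_path / "h.csv")
        lines = (tmp_path / "h.csv").read_text().strip().splitlines()
        assert lines[0] == "epoch,train_loss,val_loss"
        assert len(lines) == hist.n_epochs + 1


class TestCompareEnk:
    def test_paired_reports(self, tiny_epochs):
        spec = ModelSpec(architecture="eegnet", n_channels=4, n_samples=64,
                         n_classes=2, scale=0.5)
        rep = compare_enk(spec, tiny_epochs, _fast_cfg(seed=3))
        assert rep.off.config_hash == rep.on.config_hash
        assert rep.off.enk_enabled is False and rep.on.enk_enabled is True
        assert rep.off.n_test == rep.on.n_test
        assert rep.delta_f1 == pytest.approx(rep.on.f1 - rep.off.f1)
        assert rep.delta_mse == pytest.approx(rep.on.mse - rep.off.mse)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(batch_size=32), dict(batch_size=1), dict(dropout=0.1),
        dict(split=(0.5, 0.2, 0.2)), dict(patience=300)])
    def test_invalid(self, kw):
        with pytest.raises(ConfigurationError):
            TrainConfig(**kw)

    def test_derive_seed_stable_and_bounded(self):
        a = derive_seed(7, "split")
        assert a == derive_seed(7, "split")
        assert a != derive_seed(7, "init")
        assert 0 <= a < 2 ** 31
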