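import numpy as np
import pytest

from apnealite.archspec import PAPER_MODEL_IDS, make_paper_fusion, make_paper_spec
from apnealite.complexity import count_params
from apnealite.netbuild import (
    TrainConfig,
    build,
    fuse,
    load_weights,
    save_weights,
    train,
)
from conftest import random_small_spec


def _separable_toy(rng, n=96, length=32):
    """Two classes separated by a mean shift — linearly separable."""
    y = (np.arange(n) % 2).astype(np.int8)
    x = rng.normal(0, 0.5, (n, length)).astype(np.float32) + y[:, None] * 2.0
    return x, y


class TestBuild:
    @pytest.mark.parametrize("model_id", PAPER_MODEL_IDS)
    def test_parameter_count_matches_analytic(self, model_id):
        spec = make_paper_spec(model_id)
        total, trainable, frozen = build(spec, seed=0).parameter_count()
        analytic = count_params(spec)
        assert (total, trainable, frozen) == (
            analytic.total, analytic.trainable, analytic.non_trainable)

    def test_randomized_specs_match_analytic(self, rng):
        for _ in range(10):
            spec = random_small_spec(rng)
            assert build(spec, seed=3).parameter_count()[0] == count_params(spec).total

    def test_same_seed_identical_weights(self):
        spec = make_paper_spec("dsc_spo2")
        w1 = build(spec, seed=42).all_weights()
        w2 = build(spec, seed=42).all_weights()
        assert all(np.array_equal(a, b) for a, b in zip(w1, w2))

    def test_different_seed_different_weights(self):
        spec = make_paper_spec("dsc_spo2")
        w1 = build(spec, seed=1).all_weights()
        w2 = build(spec, seed=2).all_weights()
        assert any(not np.array_equal(a, b) for a, b in zip(w1, w2))

    def test_softmax_normalization_on_zero_and_random_input(self, rng):
        model = build(make_paper_spec("dsc_spo2"), seed=0)
        for x in (np.zeros((3, 128)), rng.normal(size=(5, 128))):
            p = model.predict_proba(x)
            assert p.shape == (x.shape[0], 2)
            assert np.all(p >= 0)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_input_width_mismatch_rejected(self):
        model = build(make_paper_spec("dsc_spo2"), seed=0)
        with pytest.raises(ValueError, match="does not match"):
            model.predict_proba(np.zeros((2, 96)))


class TestFuse:
    @pytest.fixture
    def branches(self):
        return (build(make_paper_spec("dsc_ecg"), seed=1),
                build(make_paper_spec("dsc_spo2"), seed=2))

    def test_fusion_parameter_counts(self, branches):
        model = fuse(*branches, freeze_branches=True, seed=3)
        assert model.parameter_count()[0] == 11_563
        assert model.trainable_parameter_count() == 2730 * 2 + 2

    def test_sc_fusion_parameter_count(self):
        a = build(make_paper_spec("sc_ecg"), seed=1)
        b = build(make_paper_spec("sc_spo2"), seed=2)
        assert fuse(a, b).parameter_count()[0] == count_params(make_paper_fusion("sc")).total

    def test_branch_features_equal_standalone_flatten(self, branches, rng):
        """Weight copy: fused branches reproduce the standalone flatten outputs."""
        model = fuse(*branches, freeze_branches=True, seed=3)
        xe = rng.normal(size=(4, 1200, 1)).astype(np.float32)
        xs = rng.normal(size=(4, 128, 1)).astype(np.float32)
        fa = model._run(model.branch_a, xe, training=False)
        # standalone: run the ECG model up to its flatten layer
        standalone = branches[0]
        x = xe
        for layer in standalone.layers[:-2]:  # stop before dropout+dense
            x = layer.forward(x, training=False)
        np.testing.assert_array_equal(fa, x)
        assert model._run(model.branch_b, xs, training=False).shape == (4, 480)

    def test_fusion_rejects_fusion_input(self, branches):
        model = fuse(*branches)
        with pytest.raises(ValueError):
            fuse(model, branches[1])

    def test_frozen_branches_unchanged_by_training(self, branches, rng):
        model = fuse(*branches, freeze_branches=True, seed=3)
        before = [w.copy() for l in model.branch_a + model.branch_b for w in l.params()]
        xe = rng.normal(size=(32, 1200)).astype(np.float32)
        xs = rng.normal(size=(32, 128)).astype(np.float32)
        y = (np.arange(32) % 2).astype(np.int8)
        cfg = TrainConfig(max_epochs=2, batch_size=16, seed=0)
        train(model, (xe, xs), y, (xe[:8], xs[:8]), y[:8], cfg)
        after = [w for l in model.branch_a + model.branch_b for w in l.params()]
        assert all(np.array_equal(a, b) for a, b in zip(before, after))


class TestTrain:
    def test_history_length_one_epoch(self, tiny_spec, rng):
        x, y = _separable_toy(rng)
        model = build(tiny_spec, seed=0)
        _, hist = train(model, x, y, x[:16], y[:16],
                        TrainConfig(max_epochs=1, batch_size=16, seed=0))
        assert len(hist.train_loss) == 1
        assert len(hist.val_loss) == 1

    def test_loss_decreases_on_separable_data(self, tiny_spec, rng):
        x, y = _separable_toy(rng, n=128)
        model = build(tiny_spec, seed=0)
        _, hist = train(model, x, y, x[:32], y[:32],
                        TrainConfig(max_epochs=8, batch_size=16, seed=0))
        assert hist.train_loss[-1] <= hist.train_loss[0]
        assert hist.val_accuracy[-1] >= 0.75

    def test_training_is_deterministic(self, tiny_spec, rng):
        x, y = _separable_toy(rng)
        runs = []
        for _ in range(2):
            model = build(tiny_spec, seed=7)
            _, hist = train(model, x, y, x[:16], y[:16],
                            TrainConfig(max_epochs=3, batch_size=16, seed=7))
            runs.append((tuple(hist.train_loss), tuple(hist.val_loss)))
        assert runs[0] == runs[1]

    def test_empty_sets_rejected(self, tiny_spec):
        model = build(tiny_spec, seed=0)
        empty = np.zeros((0, 32), np.float32)
        with pytest.raises(ValueError, match="non-empty"):
            train(model, empty, np.zeros(0), empty, np.zeros(0))

    def test_mismatched_labels_rejected(self, tiny_spec, rng):
        x, y = _separable_toy(rng)
        model = build(tiny_spec, seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            train(model, x, y[:-1], x[:8], y[:8])


class TestCheckpoint:
    def test_round_trip(self, tiny_spec, tmp_path, rng):
        model = build(tiny_spec, seed=5)
        x = rng.normal(size=(3, 32)).astype(np.float32)
        ref = model.predict_proba(x)
        path = tmp_path / "ckpt.npz"
        save_weights(model, str(path))
        fresh = load_weights(build(tiny_spec, seed=99), str(path))
        np.testing.assert_array_equal(fresh.predict_proba(x), ref)

    def test_architecture_mismatch_rejected(self, tiny_spec, tmp_path):
        model = build(tiny_spec, seed=0)
        path = tmp_path / "ckpt.npz"
        save_weights(model, str(path))
        other = build(make_paper_spec("dsc_spo2"), seed=0)
        with pytest.raises(ValueError, match="does not match"):
            load_weights(other, str(path))
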