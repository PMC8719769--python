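"""Training objective: class balancing, weighted loss, gradients, protocol."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from davsnet.model import DavsNet
from davsnet.training import (
    Adam,
    ClassWeights,
    TrainingConfig,
    TrainingDiverged,
    leave_one_out_splits,
    median_frequency_weights,
    train,
    weighted_cross_entropy,
)


class TestMedianFrequencyWeights:
    def test_balanced_classes_unit_weights(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[:2] = 1  # exactly half vessel
        w = median_frequency_weights([mask])
        assert w.vessel == w.background == 1.0

    def test_hand_computed_example(self):
        """10 pixels, 2 vessels: freqs (0.2, 0.8), median 0.5 -> (2.5, 0.625)."""
        mask = np.zeros((2, 5), dtype=np.uint8)
        mask[0, :2] = 1
        w = median_frequency_weights([mask])
        assert w.vessel == pytest.approx(2.5)
        assert w.background == pytest.approx(0.625)

    def test_invariant_to_mask_duplication_and_scaling(self):
        mask = np.zeros((2, 5), dtype=np.uint8)
        mask[0, :2] = 1
        w1 = median_frequency_weights([mask])
        w2 = median_frequency_weights([mask] * 7)
        w3 = median_frequency_weights([np.kron(mask, np.ones((3, 3), dtype=np.uint8))])
        assert (w1.vessel, w1.background) == (w2.vessel, w2.background)
        assert w1.vessel == pytest.approx(w3.vessel)
        assert w1.background == pytest.approx(w3.background)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="vessel"):
            median_frequency_weights([np.zeros((4, 4), dtype=np.uint8)])

    def test_weights_must_be_positive_finite(self):
        with pytest.raises(ValueError):
            ClassWeights(vessel=0.0, background=1.0)
        with pytest.raises(ValueError):
            ClassWeights(vessel=1.0, background=math.inf)


class TestWeightedCrossEntropy:
    def test_perfect_one_hot_prediction_zero_loss(self):
        target = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        probs = np.stack([target, 1 - target], axis=-1).astype(float)
        assert weighted_cross_entropy(probs, target, ClassWeights(2.0, 0.5)) == 0.0

    def test_uniform_prediction_ln2(self):
        probs = np.full((3, 3, 2), 0.5)
        target = (np.arange(9).reshape(3, 3) % 2).astype(np.uint8)
        loss = weighted_cross_entropy(probs, target, ClassWeights(1.0, 1.0))
        assert loss == pytest.approx(math.log(2.0))

    def test_2x2_mixed_weights_matches_per_pixel_expansion(self):
        """Brute-force per-pixel sum on a 2x2 toy map."""
        probs = np.array(
            [[[0.9, 0.1], [0.3, 0.7]], [[0.6, 0.4], [0.2, 0.8]]]
        )
        target = np.array([[1, 0], [1, 0]], dtype=np.uint8)
        w = ClassWeights(2.5, 0.625)
        expected = -(
            2.5 * math.log(0.9)
            + 0.625 * math.log(0.7)
            + 2.5 * math.log(0.6)
            + 0.625 * math.log(0.8)
        ) / 4.0
        assert weighted_cross_entropy(probs, target, w) == pytest.approx(expected, rel=1e-12)

    def test_zero_probability_guarded_finite(self):
        probs = np.zeros((1, 1, 2))
        probs[..., 1] = 1.0
        target = np.ones((1, 1), dtype=np.uint8)  # vessel predicted with p=0
        loss = weighted_cross_entropy(probs, target, ClassWeights(1.0, 1.0))
        assert math.isfinite(loss) and loss > 20  # -log(1e-12)

    def test_fov_restriction_ignores_outside_pixels(self):
        probs = np.full((2, 2, 2), 0.5)
        probs[0, 0] = (1.0, 0.0)
        target = np.array([[1, 1], [1, 1]], dtype=np.uint8)
        fov = np.array([[1, 0], [0, 0]], dtype=np.uint8)
        assert weighted_cross_entropy(probs, target, ClassWeights(1, 1), fov=fov) == 0.0


class TestLeaveOneOut:
    def test_two_samples(self):
        plan = leave_one_out_splits(["a", "b"])
        assert list(plan) == [(("b",), ("a",)), (("a",), ("b",))]

    def test_twenty_samples_protocol(self):
        ids = [f"im{i:02d}" for i in range(20)]
        plan = leave_one_out_splits(ids)
        assert len(plan) == 20
        for tr, held in plan:
            assert len(tr) == 19 and len(held) == 1
            assert set(tr) | set(held) == set(ids)
            assert not set(tr) & set(held)

    @given(n=st.integers(min_value=2, max_value=30))
    @settings(deadline=None, max_examples=29)
    def test_coverage_property(self, n):
        ids = list(range(n))
        plan = leave_one_out_splits(ids)
        held = [h for _, (h,) in plan]
        assert sorted(held) == ids

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            leave_one_out_splits(["only"])


def _loss_of(model, xb, yb, weights):
    acts, _ = model.runtime.forward(model.params, {"input": xb.copy()}, training=True)
    return weighted_cross_entropy(acts["softmax"], yb, weights)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic loss gradient vs central differences on a tiny model,
        relative tolerance 1e-4 (absolute floor for near-zero gradients,
        e.g. conv biases immediately normalised away by batch norm)."""
        rng = np.random.default_rng(3)
        xb = rng.random((1, 8, 8, 3))
        yb = (rng.random((1, 8, 8)) < 0.3).astype(np.uint8)
        model = DavsNet(input_shape=(8, 8), seed=2, dtype=np.float64)
        w = ClassWeights(2.0, 0.7)

        acts, idx = model.runtime.forward(model.params, {"input": xb}, training=True)
        probs = acts["softmax"]
        onehot = np.stack([yb == 1, yb == 0], axis=-1).astype(float)
        w_pix = np.where(yb == 1, w.vessel, w.background)[..., None]
        dlogits = w_pix * (probs - onehot) / yb.size
        grads = model.runtime.backward(model.params, {model.LOGIT_LAYER: dlogits}, acts, idx)

        sampler = np.random.default_rng(9)
        checked = 0
        for lname, garrs in grads.items():
            for pname, g in garrs.items():
                flat = model.params[lname][pname].reshape(-1)
                gflat = g.reshape(-1)
                for _ in range(2):
                    i = sampler.integers(flat.size)
                    eps, old = 1e-6, flat[i]
                    flat[i] = old + eps
                    lp = _loss_of(model, xb, yb, w)
                    flat[i] = old - eps
                    lm = _loss_of(model, xb, yb, w)
                    flat[i] = old
                    fd = (lp - lm) / (2 * eps)
                    assert abs(fd - gflat[i]) <= 1e-4 * max(abs(fd), abs(gflat[i])) + 1e-8, (
                        lname,
                        pname,
                        fd,
                        gflat[i],
                    )
                    checked += 1
        assert checked >= 100


@pytest.fixture(scope="module")
def tiny_training_set():
    from davsnet.synthetic import generate_sample

    samples = [generate_sample(size=(16, 16), seed=s,
                               params=_loose_params()) for s in range(3)]
    images = np.stack([s.image for s in samples])
    masks = np.stack([s.vessel_mask for s in samples])
    fovs = np.stack([s.fov_mask for s in samples])
    return images, masks, fovs


def _loose_params():
    from davsnet.synthetic import GeneratorParams

    # small canvases need a wide tolerance band for the vessel fraction
    return GeneratorParams(vessel_fraction_range=(0.005, 0.4), branch_depth=3)


class TestTrainLoop:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, tiny_training_set):
        images, masks, fovs = tiny_training_set
        model = DavsNet(input_shape=(16, 16), seed=0)
        before = {
            ln: {pn: arr.copy() for pn, arr in arrs.items() if pn in ("weight", "bias", "gamma", "beta")}
            for ln, arrs in model.params.items()
        }
        train(model, images, masks, fovs=fovs,
              config=TrainingConfig(learning_rate=0.0, batch_size=3, epochs=2, seed=0))
        for ln, arrs in before.items():
            for pn, arr in arrs.items():
                np.testing.assert_array_equal(model.params[ln][pn], arr)

    def test_same_seed_identical_loss_history(self, tiny_training_set):
        images, masks, fovs = tiny_training_set
        cfg = TrainingConfig(batch_size=2, epochs=2, seed=11)
        h1 = DavsNet(input_shape=(16, 16), seed=5).fit(images, masks, fovs=fovs, config=cfg).history
        h2 = DavsNet(input_shape=(16, 16), seed=5).fit(images, masks, fovs=fovs, config=cfg).history
        assert h1 == h2
        assert len(h1) == 4  # 2 epochs x ceil(3/2) iterations

    def test_loss_history_and_log_written(self, tiny_training_set, tmp_path):
        images, masks, fovs = tiny_training_set
        model = DavsNet(input_shape=(16, 16), seed=0)
        res = train(model, images, masks, fovs=fovs,
                    config=TrainingConfig(batch_size=3, epochs=3, seed=0))
        assert [it for it, _, _ in res.history] == [1, 2, 3]
        assert all(math.isfinite(l) for _, l, _ in res.history)
        log = tmp_path / "loss.csv"
        res.write_loss_log(log)
        lines = log.read_text().strip().splitlines()
        assert lines[0] == "iteration,loss,learning_rate"
        assert len(lines) == 4
        assert "iterations" in res.summary()

    def test_non_finite_loss_aborts(self, tiny_training_set):
        images, masks, fovs = tiny_training_set
        model = DavsNet(input_shape=(16, 16), seed=0)
        # corrupt a weight so the logits (and thus the loss path) go non-finite
        model.params["EDB1-C1"]["weight"][...] = np.nan
        with pytest.raises(TrainingDiverged):
            train(model, images, masks, config=TrainingConfig(batch_size=3, seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainingConfig(first_moment_decay=1.5)

    def test_adam_zero_gradient_noop(self):
        cfg = TrainingConfig(learning_rate=1e-2)
        opt = Adam(cfg)
        params = {"l": {"weight": np.ones(3, dtype=np.float32)}}
        opt.step(params, {"l": {"weight": np.zeros(3)}})
        np.testing.assert_array_equal(params["l"]["weight"], 1.0)
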