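"""CNN architecture arithmetic, training behavior, gradients, Grad-CAM."""

import numpy as np
import pytest

from poredelay.cnn import (
    CLASS_NAMES,
    CnnSpec,
    ModelHandle,
    TrainConfig,
    _backward,
    _forward,
    _init_params,
    _pool_forward,
    _softmax,
    grad_cam,
    predict,
    resolution_sweep,
    train,
)
from poredelay.errors import ConfigurationError, DataError, TrainingError
from poredelay.images import render_dataset, render_image
from poredelay.sim import generate_dataset


class TestSpecArithmetic:
    def test_parameter_count_at_56(self):
        # conv1 (5*5+1)*16 + conv2 (16*25+1)*32 + fc1 (32*11^2+1)*64 + fc2 65*2
        spec = CnnSpec(input_resolution=56)
        assert spec.spatial_sizes() == (52, 26, 22, 11)
        expected = 26 * 16 + 401 * 32 + (32 * 121 + 1) * 64 + 65 * 2
        assert spec.n_parameters == expected == 261_250

    def test_too_small_resolution_rejected(self):
        with pytest.raises(ConfigurationError):
            CnnSpec(input_resolution=12).validate()


class TestTraining:
    def test_learns_above_majority_baseline(self, trained_model_28):
        hist = trained_model_28.train_history
        assert hist[-1]["train_acc"] > 0.5
        assert hist[-1]["val_acc"] > 0.9

    def test_norm_constants_stored(self, trained_model_28):
        assert trained_model_28.norm_sd > 0
        assert 0.0 < trained_model_28.norm_mean < 1.0

    def test_single_class_rejected(self, sim_cfg):
        evs = generate_dataset(sim_cfg, 0, 20, seed=400)
        x, _ = render_dataset(evs, 28)
        with pytest.raises(DataError):
            train(x, ["non_delayed"] * 20, x, ["non_delayed"] * 20,
                  CnnSpec(input_resolution=28), TrainConfig(epochs_max=1))

    def test_seeded_training_reproducible(self, sim_cfg):
        evs = generate_dataset(sim_cfg, 30, 30, seed=401)
        val = generate_dataset(sim_cfg, 10, 10, seed=402)
        x, _ = render_dataset(evs, 28)
        xv, _ = render_dataset(val, 28)
        labels = [e.label for e in evs]
        vlabels = [e.label for e in val]
        cfgt = TrainConfig(epochs_max=2, seed=3)
        spec = CnnSpec(input_resolution=28)
        m1 = train(x, labels, xv, vlabels, spec, cfgt)
        m2 = train(x, labels, xv, vlabels, spec, cfgt)
        _, c1 = predict(m1, xv)
        _, c2 = predict(m2, xv)
        np.testing.assert_array_equal(c1, c2)

    def test_permuted_labels_learn_nothing(self, sim_cfg):
        """Null control: shuffled labels give chance-level validation accuracy."""
        evs = generate_dataset(sim_cfg, 60, 60, seed=403)
        val = generate_dataset(sim_cfg, 20, 20, seed=404)
        x, _ = render_dataset(evs, 28)
        xv, _ = render_dataset(val, 28)
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.permutation([0, 1] * 60)
            yv = rng.permutation([0, 1] * 20)
            m = train(x, y, xv, yv, CnnSpec(input_resolution=28),
                      TrainConfig(epochs_max=2, seed=seed))
            _, c = predict(m, xv)
            accs.append(np.mean(c == yv))
        assert 0.4 <= np.mean(accs) <= 0.6


class TestPredict:
    def test_probabilities_sum_to_one(self, trained_model_28, blind_events_small):
        x, _ = render_dataset(blind_events_small[:20], 28)
        probs, classes = predict(trained_model_28, x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert set(classes) <= {0, 1}

    def test_duplicate_image_identical(self, trained_model_28, blind_events_small):
        x, _ = render_dataset(blind_events_small[:1], 28)
        both = np.concatenate([x, x])
        probs, _ = predict(trained_model_28, both)
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_accuracy_on_small_blind_set(self, trained_model_28, blind_events_small):
        x, _ = render_dataset(blind_events_small, 28)
        _, classes = predict(trained_model_28, x)
        acc = np.mean(
            [CLASS_NAMES[c] == e.label for c, e in zip(classes, blind_events_small)]
        )
        assert acc >= 0.95

    def test_resolution_mismatch_rejected(self, trained_model_28, blind_events_small):
        x, _ = render_dataset(blind_events_small[:2], 56)
        with pytest.raises(DataError):
            predict(trained_model_28, x)

    def test_untrained_model_rejected(self):
        handle = ModelHandle(CnnSpec(), {}, [], 0.0, 1.0)
        with pytest.raises(TrainingError):
            predict(handle, np.zeros((1, 56, 56)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        spec = CnnSpec(conv_filters=(2, 2), fc_units=8, input_resolution=28)
        rng = np.random.default_rng(0)
        params = {k: v.astype(np.float64) for k, v in _init_params(spec, rng).items()}
        x = rng.normal(0, 1, (3, 1, 28, 28))
        y = np.array([0, 1, 0])

        def loss(p):
            logits, _ = _forward(p, x, spec)
            pr = _softmax(logits)
            return -np.log(pr[np.arange(3), y]).mean()

        logits, cache = _forward(params, x, spec, keep_cache=True)
        pr = _softmax(logits)
        dl = pr.copy()
        dl[np.arange(3), y] -= 1
        dl /= 3
        grads = _backward(dl, cache, params, spec)
        eps = 1e-6
        for key in params:
            flat = params[key].ravel()
            for i in rng.choice(flat.size, min(4, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss(params)
                flat[i] = old - eps
                lm = loss(params)
                flat[i] = old
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grads[key].ravel()[i]) < 1e-3

    def test_gradcam_channel_gradients_match_finite_differences(self):
        """Grad-CAM's dLogit/dA on a 2-filter toy model vs central differences
        (entries participating in non-tied pooling decisions)."""
        spec = CnnSpec(conv_filters=(2, 2), fc_units=8, input_resolution=28)
        rng = np.random.default_rng(0)
        params = {k: v.astype(np.float64) for k, v in _init_params(spec, rng).items()}
        x = rng.normal(0, 1, (1, 1, 28, 28))
        _, cache = _forward(params, x, spec, keep_cache=True)
        dlog = np.zeros((1, 2))
        dlog[0, 0] = 1.0
        dA = _backward(dlog, cache, params, spec, upto_conv2=True)
        A = cache["r2"].copy()

        def logit(Anew):
            p2, _ = _pool_forward(Anew, spec.pool_size)
            flat = p2.reshape(1, -1)
            h = np.maximum(flat @ params["Wf1"] + params["bf1"], 0)
            return (h @ params["Wf2"] + params["bf2"])[0, 0]

        checked = 0
        h2, w2 = A.shape[2], A.shape[3]
        for f in range(2):
            for i in range(0, h2 - h2 % 2, 2):
                for j in range(0, w2 - w2 % 2, 2):
                    bi, bj = i // 2 * 2, j // 2 * 2
                    block = np.sort(A[0, f, bi : bi + 2, bj : bj + 2].ravel())[::-1]
                    v = A[0, f, i, j]
                    strict_max = v == block[0] and v - block[1] > 1e-4
                    strictly_below = block[0] - v > 1e-4
                    if not (strict_max or strictly_below):
                        continue
                    old = v
                    A[0, f, i, j] = old + 1e-5
                    lp = logit(A)
                    A[0, f, i, j] = old - 1e-5
                    lm = logit(A)
                    A[0, f, i, j] = old
                    assert abs((lp - lm) / 2e-5 - dA[0, f, i, j]) < 1e-3
                    checked += 1
        assert checked > 20


class TestGradCam:
    def test_heatmap_contract(self, trained_model_28, blind_events_small):
        img = render_image(blind_events_small[0], 28)
        sal = grad_cam(trained_model_28, img, target_class=0)
        assert sal.heatmap.shape == (28, 28)
        assert sal.heatmap.min() >= 0.0
        assert sal.heatmap.max() == pytest.approx(1.0)

    def test_delay_saliency_concentrates_in_tail_region(
        self, trained_model_28, sim_cfg
    ):
        """On correctly-classified delayed events, saliency mass in the
        columns covering fractional positions [0.7, 1.0] exceeds the uniform
        30% share on average."""
        events = generate_dataset(sim_cfg, 100, 0, seed=405)
        x, _ = render_dataset(events, 28)
        _, classes = predict(trained_model_28, x)
        fracs = []
        for ev, img, cls in zip(events, x, classes):
            if cls != 0:
                continue
            sal = grad_cam(trained_model_28, img, target_class=0)
            total = sal.heatmap.sum()
            if total == 0:
                continue
            cut = int(0.7 * 28)
            fracs.append(sal.heatmap[:, cut:].sum() / total)
        assert len(fracs) >= 50
        assert np.mean(fracs) > 0.30

    def test_degenerate_gradients_flagged(self, trained_model_28):
        broken = ModelHandle(
            spec=trained_model_28.spec,
            params={k: v.copy() for k, v in trained_model_28.params.items()},
            train_history=[],
            norm_mean=trained_model_28.norm_mean,
            norm_sd=trained_model_28.norm_sd,
        )
        broken.params["Wf2"] = broken.params["Wf2"].copy()
        broken.params["Wf2"][:, 0] = 0.0  # class-0 logit becomes constant
        sal = grad_cam(broken, np.zeros((28, 28), dtype=np.float32), 0)
        assert sal.degenerate and not sal.heatmap.any()

    def test_invalid_class_rejected(self, trained_model_28):
        with pytest.raises(ConfigurationError):
            grad_cam(trained_model_28, np.zeros((28, 28)), 2)


class TestModelIO:
    def test_save_load_round_trip(self, trained_model_28, blind_events_small, tmp_path):
        path = tmp_path / "model.npz"
        trained_model_28.save(path)
        back = ModelHandle.load(path)
        assert back.spec == trained_model_28.spec
        x, _ = render_dataset(blind_events_small[:10], 28)
        p1, _ = predict(trained_model_28, x)
        p2, _ = predict(back, x)
        np.testing.assert_array_equal(p1, p2)


class TestResolutionSweep:
    def test_two_resolution_sweep(self, sim_cfg):
        tr = generate_dataset(sim_cfg, 40, 40, seed=406)
        va = generate_dataset(sim_cfg, 15, 15, seed=407)
        te = generate_dataset(sim_cfg, 25, 25, seed=408)
        metrics, radar = resolution_sweep(
            tr, va, te, (28, 56),
            cfg=TrainConfig(epochs_max=2, seed=1),
        )
        assert list(metrics.index) == [28, 56]
        for col in radar.columns:
            vals = radar[col].dropna()
            if len(vals):
                assert vals.min() == 0.0 and vals.max() == 1.0

    def test_single_resolution_rejected(self, sim_cfg):
        with pytest.raises(DataError):
            resolution_sweep([], [], [], (56,))

    def test_six_resolution_sweep_smoke(self, sim_cfg):
        """The full published resolution grid runs end to end (1-epoch smoke)."""
        tr = generate_dataset(sim_cfg, 30, 30, seed=409)
        va = generate_dataset(sim_cfg, 10, 10, seed=410)
        te = generate_dataset(sim_cfg, 10, 10, seed=411)
        metrics, radar = resolution_sweep(
            tr, va, te, (28, 56, 70, 84, 112, 140),
            cfg=TrainConfig(epochs_max=1, seed=2),
        )
        assert list(metrics.index) == [28, 56, 70, 84, 112, 140]
        assert len(metrics) == 6 and set(metrics.columns) == {
            "accuracy", "precision", "recall", "f1", "mcc", "auc",
        }
        assert radar.shape == metrics.shape
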