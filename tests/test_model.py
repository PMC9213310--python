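"""Network mechanics: shapes, gradients, training loop, tiling, CV folds."""

import numpy as np
import pytest

from bonesct.model import (NetworkConfig, TrainConfig, TrainedModel,
                           build_network, loocv, predict_volume, prepare_case,
                           train)
from bonesct.phantom import PhantomSpec, make_cohort
from bonesct.preprocess import denormalize_ct, normalize_mr

TINY = NetworkConfig(levels=2, base_filters=4, patch_size=8)


def _tiny_trained_shell(net, cfg=TINY):
    return TrainedModel(net, cfg, TrainConfig())


class TestArchitecture:
    def test_forward_shape_contract(self):
        net = build_network(NetworkConfig(levels=3, base_filters=8,
                                          patch_size=24), seed=0)
        x = np.zeros((1, 2, 24, 24, 24), dtype=np.float32)
        assert net.forward(x).shape == (1, 1, 24, 24, 24)

    def test_zeroed_head_gives_zero_output(self, rng):
        net = build_network(TINY, seed=0)
        net.head.W.value[...] = 0.0
        net.head.b.value[...] = 0.0
        x = rng.standard_normal((2, 2, 8, 8, 8)).astype(np.float32)
        assert np.abs(net.forward(x)).max() == 0.0

    def test_parameter_count_monotone_in_width(self):
        counts = [build_network(NetworkConfig(levels=2, base_filters=b,
                                              patch_size=8), seed=0).n_parameters
                  for b in (2, 4, 8)]
        assert counts[0] < counts[1] < counts[2]

    def test_incompatible_patch_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(levels=4, patch_size=12)

    def test_init_deterministic(self):
        a = build_network(TINY, seed=5).get_weights()
        b = build_network(TINY, seed=5).get_weights()
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa, wb)


class TestGradients:
    def test_backprop_matches_central_differences(self):
        """The hand-written backward pass is checked against numerical
        gradients of the L1 objective on a double-precision tiny net."""
        net = build_network(NetworkConfig(levels=3, base_filters=2,
                                          patch_size=8), seed=0,
                            dtype=np.float64)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 2, 8, 8, 8))
        t = rng.standard_normal((2, 1, 8, 8, 8))

        def loss():
            y = net.forward(x)
            return float(np.mean(np.abs(y - t))), y

        _, y = loss()
        net.zero_grad()
        net.backward(np.sign(y - t) / y.size)
        eps = 1e-6
        pick = np.random.default_rng(2)
        for p in net.parameters():
            flat = p.value.reshape(-1)
            grad = p.grad.reshape(-1)
            for idx in pick.choice(flat.size, size=min(3, flat.size),
                                   replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = loss()
                flat[idx] = orig - eps
                lm, _ = loss()
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                denom = max(1e-8, abs(numeric) + abs(grad[idx]))
                assert abs(numeric - grad[idx]) / denom < 1e-4


def _mini_cohort(n=3, shape=(32, 32, 28), seed=21):
    return make_cohort(n, PhantomSpec(shape=shape), seed=seed)


class TestTraining:
    def test_zero_learning_rate_keeps_weights(self):
        cohort = _mini_cohort(2)
        prepared = [prepare_case(c) for c in cohort]
        net = build_network(TINY, seed=1)
        before = net.get_weights()
        train(net, [prepared[0]], prepared[1],
              TrainConfig(learning_rate=0.0, epochs=1, patches_per_volume=4,
                          batch_size=2, augment=False, seed=0))
        for w0, w1 in zip(before, net.get_weights()):
            np.testing.assert_array_equal(w0, w1)

    def test_identical_seeds_identical_logs(self):
        cohort = _mini_cohort(2)
        prepared = [prepare_case(c) for c in cohort]
        logs = []
        for _ in range(2):
            net = build_network(TINY, seed=3)
            tm = train(net, [prepared[0]], prepared[1],
                       TrainConfig(learning_rate=1e-3, epochs=2,
                                   patches_per_volume=4, batch_size=2,
                                   augment=False, seed=9))
            logs.append(tm.log)
        assert logs[0] == logs[1]

    def test_empty_training_set_rejected(self):
        cohort = _mini_cohort(2)
        prepared = [prepare_case(c) for c in cohort]
        net = build_network(TINY, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(net, [], prepared[0], TrainConfig())

    def test_overfit_single_phantom(self):
        """In the overfit regime (one case, many passes) the desk-scale
        net drives the training L1 below 0.05 on the normalized scale —
        comfortably above the phantom's own noise floor (~0.01)."""
        cohort = _mini_cohort(2, shape=(32, 32, 28), seed=6)
        prepared = [prepare_case(c) for c in cohort]
        net = build_network(NetworkConfig(levels=3, base_filters=8,
                                          patch_size=24), seed=2)
        tm = train(net, [prepared[0]], prepared[0],
                   TrainConfig(learning_rate=3e-3, epochs=25,
                               patches_per_volume=16, batch_size=4,
                               augment=False, seed=4))
        assert tm.log[-1][1] < 0.05


class TestPredictVolume:
    def test_constant_model_tiles_exactly(self):
        """Uniform overlap averaging must preserve a constant network
        output to 1e-6 HU across the whole tiled volume."""
        net = build_network(TINY, seed=0)
        net.head.W.value[...] = 0.0
        net.head.b.value[...] = 0.25
        tm = _tiny_trained_shell(net)
        vol = np.random.default_rng(0).uniform(0.1, 1.0, (20, 14, 11))
        mr = normalize_mr(vol)
        sct = predict_volume(tm, mr, mr)
        expected = denormalize_ct(np.array(0.25))
        assert np.max(np.abs(sct - expected)) < 1e-6

    def test_single_patch_volume_equals_forward(self):
        net = build_network(TINY, seed=1)
        vol = np.random.default_rng(1).uniform(0.1, 1.0, (8, 8, 8))
        mr = normalize_mr(vol)
        tm = _tiny_trained_shell(net)
        sct = predict_volume(tm, mr, mr)
        x = np.stack([mr.values, mr.values])[None].astype(np.float32)
        direct = denormalize_ct(net.forward(x)[0, 0].astype(np.float64))
        np.testing.assert_allclose(sct, np.clip(direct, -1024, 3071), atol=2e-3)

    def test_volume_smaller_than_patch_rejected(self):
        net = build_network(TINY, seed=0)
        tm = _tiny_trained_shell(net)
        vol = np.random.default_rng(0).uniform(0.1, 1.0, (6, 6, 6))
        mr = normalize_mr(vol)
        with pytest.raises(ValueError, match="smaller"):
            predict_volume(tm, mr, mr)

    def test_output_within_hu_range(self):
        net = build_network(TINY, seed=2)
        tm = _tiny_trained_shell(net)
        vol = np.random.default_rng(2).uniform(0.1, 1.0, (10, 10, 10))
        mr = normalize_mr(vol)
        sct = predict_volume(tm, mr, mr)
        assert sct.min() >= -1024.0 and sct.max() <= 3071.0


class TestSerialization:
    def test_round_trip_bit_identical_predictions(self, tmp_path):
        net = build_network(TINY, seed=7)
        tm = _tiny_trained_shell(net)
        path = tmp_path / "model.npz"
        tm.save(path)
        back = TrainedModel.load(path)
        x = np.random.default_rng(3).standard_normal((1, 2, 8, 8, 8)
                                                     ).astype(np.float32)
        np.testing.assert_array_equal(tm.network.forward(x),
                                      back.network.forward(x))
        assert back.net_cfg == tm.net_cfg


class TestLOOCV:
    @pytest.fixture(scope="class")
    def tiny_cv(self):
        cohort = _mini_cohort(3, shape=(28, 28, 26), seed=31)
        cfg = NetworkConfig(levels=2, base_filters=4, patch_size=24)
        tc = TrainConfig(learning_rate=1e-3, epochs=1, patches_per_volume=4,
                         batch_size=2, augment=False, seed=13)
        return cohort, loocv(cohort, cfg, tc)

    def test_every_case_tested_once(self, tiny_cv):
        cohort, cv = tiny_cv
        tested = [f.test_case_id for f in cv.folds]
        assert sorted(tested) == sorted(c.case_id for c in cohort)

    def test_no_fold_leaks_its_test_case(self, tiny_cv):
        _, cv = tiny_cv
        for f in cv.folds:
            assert f.test_case_id not in f.train_case_ids
            assert f.test_case_id != f.validation_case_id
            assert f.validation_case_id not in f.train_case_ids

    def test_fold_sizes_smallest_legal_cohort(self, tiny_cv):
        _, cv = tiny_cv
        for f in cv.folds:
            assert len(f.train_case_ids) == 1

    def test_two_reports_per_fold(self, tiny_cv):
        _, cv = tiny_cv
        assert len(cv.reports) == 2 * len(cv.folds)
        regions = {r.region for r in cv.reports}
        assert regions == {"bone", "lesion"}

    def test_too_small_cohort_rejected(self):
        cohort = _mini_cohort(2)
        with pytest.raises(ValueError, match="3"):
            loocv(cohort, TINY, TrainConfig())
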