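"""Input encoding, fold plans and training mechanics of the predictor."""

import numpy as np
import pytest

from hepajac.nn import Adam, UNet3D, mse_loss
from hepajac.phantom import CohortConfig, generate_cohort
from hepajac.predictor import (
    TrainingConfig,
    encode_inputs,
    make_folds,
    predict_map,
    train_fold,
)


@pytest.fixture(scope="module")
def tiny_cohort():
    return generate_cohort(12, 5, CohortConfig(shape=(40, 40, 32), spacing=(4.5, 4.5, 5.5)))


@pytest.fixture(scope="module")
def encoded(tiny_cohort):
    return {
        c.case_id: encode_inputs(c, grid_shape=(32, 32, 16), margins_vox=(3, 3, 2))
        for c in tiny_cohort
    }


class TestEncoding:
    def test_hu_window_endpoints_and_midpoint(self, tiny_cohort):
        case = tiny_cohort[0]
        case.pre_ct.values[0, 0, 0] = -1000.0
        case.pre_ct.values[0, 0, 1] = 500.0
        case.pre_ct.values[0, 0, 2] = -250.0
        s = encode_inputs(case, grid_shape=(32, 32, 16), margins_vox=(3, 3, 2))
        assert s.channels[0].min() >= 0.0 and s.channels[0].max() <= 1.0
        # direct check of the window mapping itself
        ct = np.array([-1000.0, 500.0, -250.0])
        np.testing.assert_allclose(np.clip((ct + 1000) / 1500, 0, 1), [0.0, 1.0, 0.5])

    def test_dose_channel_is_eqd2_over_100(self, encoded, tiny_cohort):
        case = tiny_cohort[1]
        s = encoded[case.case_id]
        inside = s.liver
        # channel 2 should track EQD2/100 wherever the resampled dose is smooth
        assert s.channels[1].max() == pytest.approx(case.eqd2.values.max() / 100.0, rel=0.05)

    def test_contour_time_channel(self, encoded, tiny_cohort):
        case = tiny_cohort[2]
        s = encoded[case.case_id]
        outside = ~s.liver
        assert np.all(s.channels[2][outside] == -1.0)
        inside = s.liver
        expect = s.channels[1][inside] * 100.0 / (case.t_days * 100.0)
        np.testing.assert_allclose(s.channels[2][inside], expect, atol=1e-6)

    def test_target_zero_outside_liver(self, encoded):
        for s in encoded.values():
            assert np.all(s.target[~s.liver] == 0.0)

    def test_crop_roundtrip_fidelity(self, encoded, tiny_cohort):
        """Mapping the encoded target back to the planning grid loses only
        resampling detail: voxel-wise r >= 0.98 against the original map."""
        from scipy.stats import pearsonr

        from hepajac.grids import Grid3D, resample_to

        case = tiny_cohort[3]
        s = encode_inputs(case, grid_shape=(48, 48, 24), margins_vox=(3, 3, 2))
        crop_grid = Grid3D(s.target.astype(float), s.grid.spacing, s.grid.origin)
        back = resample_to(crop_grid, case.labels.geometry, "linear")
        liver = case.labels.liver_mask()
        r = pearsonr(back.values[liver], case.truth_dv.values[liver]).statistic
        assert r >= 0.98


class TestFolds:
    def test_disjoint_cover(self, tiny_cohort):
        plan = make_folds(tiny_cohort, k=4, seed=3)
        all_test = sorted(cid for f in plan.folds for cid in f["test_ids"])
        assert all_test == sorted(c.case_id for c in tiny_cohort)

    def test_no_leakage(self, tiny_cohort):
        plan = make_folds(tiny_cohort, k=4, seed=3)
        for f in plan.folds:
            assert not set(f["test_ids"]) & set(f["train_ids"])
            assert not set(f["test_ids"]) & set(f["val_ids"])
            assert not set(f["train_ids"]) & set(f["val_ids"])

    def test_deterministic(self, tiny_cohort):
        assert make_folds(tiny_cohort, k=4, seed=9).folds == make_folds(tiny_cohort, k=4, seed=9).folds

    def test_stratification_spread(self, tiny_cohort):
        plan = make_folds(tiny_cohort, k=4, seed=3)
        counts = {t: sum(1 for c in tiny_cohort if c.cancer_type == t) for t in set(c.cancer_type for c in tiny_cohort)}
        for f in plan.folds:
            for t, n in counts.items():
                in_fold = sum(
                    1 for cid in f["test_ids"]
                    if next(c for c in tiny_cohort if c.case_id == cid).cancer_type == t
                )
                assert abs(in_fold - n / 4) <= 1


class TestTraining:
    def test_validation_keep_k_rule(self):
        # mean of the 16 smallest of MSEs 1..18 is 8.5
        mses = list(range(1, 19))
        keep = int(round(16 / 18 * len(mses)))
        assert np.mean(sorted(mses)[:keep]) == pytest.approx(8.5)

    def test_constant_zero_targets_learned(self, encoded):
        ids = list(encoded)[:6]
        samples = {
            cid: type(encoded[cid])(
                case_id=cid,
                channels=encoded[cid].channels,
                target=np.zeros_like(encoded[cid].target),
                liver=encoded[cid].liver,
                crop=encoded[cid].crop,
                grid=encoded[cid].grid,
            )
            for cid in ids
        }
        fold = {"train_ids": ids[:4], "val_ids": ids[4:], "test_ids": []}
        cfg = TrainingConfig.desk(seed=1, max_epochs=12)
        cfg = type(cfg)(**{**cfg.__dict__, "grid_shape": (32, 32, 16)})
        model, hist = train_fold(fold, samples, cfg)
        val = [mse_loss(model.forward(samples[c].channels)[0], samples[c].target)[0] for c in ids[4:]]
        assert np.mean(val) < 1e-3

    def test_two_epoch_determinism(self, encoded):
        ids = list(encoded)
        fold = {"train_ids": ids[:4], "val_ids": ids[4:6], "test_ids": ids[6:8]}
        cfg = TrainingConfig.desk(seed=11, max_epochs=2)
        cfg = type(cfg)(**{**cfg.__dict__, "grid_shape": (32, 32, 16)})
        _, h1 = train_fold(fold, encoded, cfg, fold_seed=0)
        _, h2 = train_fold(fold, encoded, cfg, fold_seed=0)
        assert h1.equals(h2)

    def test_checkpoint_metric_non_increasing(self, encoded):
        ids = list(encoded)
        fold = {"train_ids": ids[:5], "val_ids": ids[5:8], "test_ids": []}
        cfg = TrainingConfig.desk(seed=2, max_epochs=6)
        cfg = type(cfg)(**{**cfg.__dict__, "grid_shape": (32, 32, 16)})
        _, hist = train_fold(fold, encoded, cfg)
        saved = hist[hist.improved].val_metric.to_numpy()
        assert np.all(np.diff(saved) <= 0)

    def test_prediction_zero_outside_liver(self, encoded, tiny_cohort):
        case = tiny_cohort[0]
        model = UNet3D(base=4, dropout=0.0, seed=0)
        out = predict_map(model, encoded[case.case_id], case)
        assert np.all(out.values[~case.labels.liver_mask()] == 0.0)


class TestNN:
    def test_adam_reduces_quadratic(self):
        p = [np.array([5.0])]
        opt = Adam(p, lr=0.1)
        for _ in range(200):
            opt.step([2 * p[0]])
        assert abs(p[0][0]) < 0.1

    def test_forward_shapes(self):
        net = UNet3D(base=4, dropout=0.0, seed=0)
        y = net.forward(np.zeros((3, 16, 16, 8), np.float32))
        assert y.shape == (1, 16, 16, 8)

    def test_gradient_matches_finite_differences(self):
        net = UNet3D(base=2, dropout=0.0, seed=3)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 8, 8, 4)).astype(np.float32)
        t = rng.standard_normal((8, 8, 4)).astype(np.float32)
        pred = net.forward(x, train=True)
        _, d = mse_loss(pred[0], t)
        net.zero_grad()
        net.backward(d[None])
        params, grads = net.parameters(), net.gradients()
        for pi in (0, 4, 10):
            idx = tuple(rng.integers(0, s) for s in params[pi].shape)
            eps = 1e-3
            old = params[pi][idx]
            params[pi][idx] = old + eps
            l1, _ = mse_loss(net.forward(x)[0], t)
            params[pi][idx] = old - eps
            l2, _ = mse_loss(net.forward(x)[0], t)
            params[pi][idx] = old
            assert grads[pi][idx] == pytest.approx((l1 - l2) / (2 * eps), abs=2e-4)
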