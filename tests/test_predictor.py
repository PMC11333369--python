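"""Feedforward network: loss, training protocol, transfer, inference."""

import numpy as np
import pytest

from exoassist import evaluation as ev
from exoassist import gait_synth as gs
from exoassist import predictor as pr
from exoassist.errors import ConfigurationError, DomainError


def synthetic_dataset(subject_range, n_cycles=160, seed_base=1000,
                      offset_sd=(0.08, 2.0, 2.0, 2.0), noise=True):
    """Targets = smooth function of features + per-subject offset + noise."""
    cfg = gs.PopulationConfig(seed=3)
    rng = np.random.default_rng(42 + min(subject_range))
    feats, targs, speeds = [], [], []
    for si in subject_range:
        subj = gs.sample_subject(cfg, si)
        off = rng.normal(0.0, offset_sd)
        for ci in range(n_cycles):
            speed = cfg.speed_grid[ci % 14]
            cyc = gs.generate_cycle(subj, speed, 0.03,
                                    seed_base + si * 500 + ci)
            u = (speed - 0.5) / 1.3
            target = np.array([
                0.45 + 0.55 * u + 0.002 * (subj.mass - 68.5) + off[0],
                55.0 - 7.0 * u + off[1],
                38.0 + 40.0 * (subj.calf_length - 0.42) - 1.5 * u + off[2],
                65.0 - 10.0 * u + off[3]])
            if noise:
                target = target + rng.normal(0.0, [0.01, 0.3, 0.2, 0.3])
            feats.append(pr.feature_vector(subj, cyc))
            targs.append(target)
            speeds.append(speed)
    return np.array(feats), np.array(targs), np.array(speeds)


class TestL1Loss:
    def test_examples(self):
        y = np.array([[1.0, 2.0, 3.0, 4.0]])
        yhat = np.array([[1.0, 1.0, 3.0, 5.0]])
        assert pr.l1_loss(y, y) == 0.0
        assert pr.l1_loss(y, yhat) == pytest.approx(2.0)

    def test_homogeneous_in_residual(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(10, 4))
        r = rng.normal(size=(10, 4))
        assert pr.l1_loss(y, y + 2 * r) == pytest.approx(
            2 * pr.l1_loss(y, y + r), rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(DomainError):
            pr.l1_loss(np.zeros((3, 4)), np.zeros((2, 4)))


class TestTrain:
    def test_learnable_mapping_reduces_validation_loss(self):
        # clean smooth mapping: no subject offsets, no target noise
        x, y, _ = synthetic_dataset(range(8), n_cycles=150, noise=False,
                                    offset_sd=(0.0, 0.0, 0.0, 0.0))
        model = pr.train(x, y, pr.TrainingConfig(epochs=120, seed=0))
        hist = model.history["val_loss"]
        assert min(hist) < 0.10 * hist[0]

    def test_parameter_recovery_r2_above_0_9_at_n6000(self):
        """Targets that are a smooth function of features plus mild noise are
        recovered with R^2 > 0.9 per feature on a held-out split."""
        x, y, _ = synthetic_dataset(range(40), n_cycles=168,
                                    offset_sd=(0.0, 0.0, 0.0, 0.0))
        x_test, y_test = x[6000:6720], y[6000:6720]
        model = pr.train(x[:6000], y[:6000],
                         pr.TrainingConfig(epochs=120, seed=0))
        pred, _ = pr.predict(model, x_test)
        r2 = ev.per_feature_r2(y_test, pred)
        assert all(v > 0.9 for v in r2.values()), r2

    def test_deterministic_under_seed(self):
        x, y, _ = synthetic_dataset(range(3), n_cycles=60)
        cfg = pr.TrainingConfig(epochs=8, seed=5)
        h1 = pr.train(x, y, cfg).history["train_loss"]
        h2 = pr.train(x, y, cfg).history["train_loss"]
        assert h1 == h2

    def test_patience_zero_stops_at_first_non_improvement(self):
        x, y, _ = synthetic_dataset(range(3), n_cycles=60)
        model = pr.train(x, y, pr.TrainingConfig(epochs=100, patience=0,
                                                 seed=0))
        hist = model.history["val_loss"]
        assert len(hist) < 100
        # every epoch before the stop improved on the best so far
        best = np.minimum.accumulate(hist)
        assert np.all(np.diff(best[:-1]) < 0)

    def test_best_so_far_validation_loss_monotone(self):
        x, y, _ = synthetic_dataset(range(4), n_cycles=80)
        model = pr.train(x, y, pr.TrainingConfig(epochs=30, seed=1))
        best = np.minimum.accumulate(model.history["val_loss"])
        assert np.all(np.diff(best) <= 0)

    def test_too_small_dataset_rejected(self):
        with pytest.raises(DomainError):
            pr.train(np.zeros((10, 13)), np.zeros((10, 4)))

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            pr.TrainingConfig(validation_fraction=0.0)


@pytest.fixture(scope="module")
def trained():
    x, y, _ = synthetic_dataset(range(10), n_cycles=150)
    model = pr.train(x, y, pr.TrainingConfig(epochs=100, seed=0))
    xt, yt, st = synthetic_dataset(range(10, 12), n_cycles=150,
                                   seed_base=90000)
    return model, xt, yt, st


class TestTransfer:
    def test_transfer_improves_held_out_r2(self, trained):
        model, xt, yt, st = trained
        extreme = np.isclose(st, 0.5) | np.isclose(st, 1.8)
        tuned = pr.transfer(model, xt[extreme], yt[extreme], st[extreme])
        before, _ = pr.predict(model, xt[~extreme])
        after, _ = pr.predict(tuned, xt[~extreme])
        r2b = ev.per_feature_r2(yt[~extreme], before)
        r2a = ev.per_feature_r2(yt[~extreme], after)
        assert np.mean(list(r2a.values())) > np.mean(list(r2b.values()))
        improved = sum(r2a[k] >= r2b[k] for k in r2a)
        assert improved >= 3

    def test_zero_epochs_leaves_model_unchanged(self, trained):
        model, xt, yt, st = trained
        extreme = np.isclose(st, 0.5) | np.isclose(st, 1.8)
        same = pr.transfer(model, xt[extreme], yt[extreme], st[extreme],
                           epochs=0)
        p0, _ = pr.predict(model, xt[:5])
        p1, _ = pr.predict(same, xt[:5])
        assert np.array_equal(p0, p1)

    def test_non_extreme_speeds_rejected(self, trained):
        model, xt, yt, st = trained
        with pytest.raises(DomainError):
            pr.transfer(model, xt[:4], yt[:4], np.array([0.5, 1.0, 1.8, 1.8]))
        with pytest.raises(DomainError):
            pr.transfer(model, xt[:0], yt[:0], st[:0])


@pytest.fixture(scope="module")
def model():
    x, y, _ = synthetic_dataset(range(4), n_cycles=80)
    return pr.train(x, y, pr.TrainingConfig(epochs=20, seed=2))


class TestPredict:
    def test_four_outputs_and_pure_function(self, model):
        x, _, _ = synthetic_dataset(range(1), n_cycles=3)
        p1, _ = pr.predict(model, x[0])
        p2, _ = pr.predict(model, x[0])
        assert p1.shape == (1, 4)
        assert np.array_equal(p1, p2)

    def test_times_ordered_and_clipped(self, model):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 13)) * 50.0  # wild inputs
        params, _ = pr.predict(model, x)
        t2, t1, t3 = params[:, 1], params[:, 2], params[:, 3]
        assert np.all((t1 <= t2) & (t2 <= t3))
        assert np.all((params[:, 1:] >= 0) & (params[:, 1:] <= 100))

    def test_predicted_profiles_are_valid(self, model):
        x, _, _ = synthetic_dataset(range(1), n_cycles=5)
        for p in pr.predicted_profiles(model, x):
            assert 0 <= p.start_time < p.peak_time < p.end_time <= 100

    def test_wrong_feature_count_rejected(self, model):
        with pytest.raises(DomainError):
            pr.predict(model, np.zeros(12))

    def test_save_load_roundtrip(self, model, tmp_path):
        path = tmp_path / "model.json"
        pr.save_model(model, path)
        loaded = pr.load_model(path)
        x, _, _ = synthetic_dataset(range(1), n_cycles=3)
        a, _ = pr.predict(model, x)
        b, _ = pr.predict(loaded, x)
        assert np.allclose(a, b, atol=1e-12)
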