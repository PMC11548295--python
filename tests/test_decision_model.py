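"""CNN-GRU classifier: gradients, training contracts, tuning plumbing."""

import numpy as np
import pytest

from anklestage import decision_model as dm
from anklestage import augmentation as aug
from anklestage import pipeline as pl
from anklestage import synthetic_data as sd


def _toy_windows(n=8, W=20, n_classes=5, seed=0):
    """Well-separated toy windows: class k has mean level k."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % n_classes
    X = rng.normal(size=(n, W, 6)) * 0.1 + y[:, None, None]
    return X, y.astype(np.int64)


class TestBuildModel:
    def test_seeded_init_is_identical(self):
        a = dm.build_model(dm.ModelSpec(), dm.CONTROL_HP, seed=3)
        b = dm.build_model(dm.ModelSpec(), dm.CONTROL_HP, seed=3)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_more_hidden_units_more_parameters(self):
        small = dm.build_model(dm.ModelSpec(), dm.Hyperparameters(hidden_units=10))
        big = dm.build_model(dm.ModelSpec(), dm.Hyperparameters(hidden_units=30))
        assert big.n_parameters > small.n_parameters

    def test_forward_shape_contract(self):
        model = dm.build_model(dm.ModelSpec(), dm.CONTROL_HP, seed=0)
        X, _ = _toy_windows(n=4, W=50)
        logits, _ = model.forward(X)
        assert logits.shape == (4, 5)

    def test_hidden_units_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            dm.Hyperparameters(hidden_units=31)
        with pytest.raises(ValueError):
            dm.Hyperparameters(hidden_units=9)


class TestGradients:
    def test_numerical_gradient_check(self):
        """Analytic backprop agrees with central finite differences."""
        spec = dm.ModelSpec(window=12, conv_filters=(3, 4), n_classes=3)
        model = dm.build_model(spec, dm.Hyperparameters(hidden_units=10,
                                                        l2_coefficient=1e-3), seed=1)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 12, 6))
        y = np.array([0, 1, 2, 1, 0])
        _, grads = model.loss_and_grads(X, y)
        eps = 1e-6
        for name in ("W1", "b2", "Wx", "Wh", "bh", "Wo", "bo"):
            p = model.params[name]
            for _ in range(4):
                idx = tuple(rng.integers(s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = model.loss_and_grads(X, y)
                p[idx] = orig - eps
                lm, _ = model.loss_and_grads(X, y)
                p[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)


class TestTrain:
    def test_overfits_a_tiny_batch(self):
        X, y = _toy_windows(n=8, W=20)
        model = dm.build_model(dm.ModelSpec(window=20), dm.CONTROL_HP, seed=0)
        dm.train(model, X, y, cfg=dm.TrainConfig(epochs=200, seed=0))
        labels, _ = dm.predict(model, X)
        assert np.mean(labels == y) == 1.0

    def test_loss_history_length_equals_epochs(self):
        X, y = _toy_windows()
        model = dm.build_model(dm.ModelSpec(window=20), dm.CONTROL_HP, seed=0)
        out = dm.train(model, X, y, cfg=dm.TrainConfig(epochs=7, seed=0))
        assert len(out["loss"]) == 7

    def test_stronger_l2_shrinks_weights(self):
        X, y = _toy_windows(n=16, W=20)
        norms = {}
        for l2 in (1e-5, 1e-2):
            model = dm.build_model(dm.ModelSpec(window=20),
                                   dm.Hyperparameters(l2_coefficient=l2), seed=0)
            dm.train(model, X, y, cfg=dm.TrainConfig(epochs=60, seed=0))
            norms[l2] = model.weight_norm()
        assert norms[1e-5] > norms[1e-2]

    def test_empty_train_set_rejected(self):
        model = dm.build_model(dm.ModelSpec(window=20), dm.CONTROL_HP)
        with pytest.raises(ValueError):
            dm.train(model, np.zeros((0, 20, 6)), np.zeros(0, dtype=int))


class TestPredict:
    def test_prediction_deterministic(self):
        X, y = _toy_windows()
        model = dm.build_model(dm.ModelSpec(window=20), dm.CONTROL_HP, seed=0)
        dm.train(model, X, y, cfg=dm.TrainConfig(epochs=10, seed=0))
        a, pa = dm.predict(model, X)
        b, pb = dm.predict(model, X)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(pa, pb)

    def test_scores_are_probabilities(self):
        X, _ = _toy_windows()
        model = dm.build_model(dm.ModelSpec(window=20), dm.CONTROL_HP, seed=0)
        _, probs = dm.predict(model, X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_shape_mismatch_rejected(self):
        model = dm.build_model(dm.ModelSpec(window=20), dm.CONTROL_HP)
        with pytest.raises(ValueError):
            dm.predict(model, np.zeros((3, 20, 5)))


class TestFitnessAndTune:
    def test_decode_position_rounds_and_clips(self):
        hp = dm.decode_position([0.2, 22.6, 1e-6])
        assert hp.learning_rate == pytest.approx(0.1)  # clipped to ub
        assert hp.hidden_units == 23
        assert hp.l2_coefficient == pytest.approx(1e-5)  # clipped to lb

    def test_fitness_in_unit_interval_and_deterministic(self):
        X, y = _toy_windows(n=30, W=20)
        splits = dm.DataSplits(X[:20], y[:20], X[20:], y[20:])
        cfg = dm.TrainConfig(epochs=5, fitness_epochs=5, seed=1)
        pos = np.array([1e-2, 12.0, 1e-4])
        f1 = dm.fitness_fobj(pos, splits, cfg, dm.ModelSpec(window=20))
        f2 = dm.fitness_fobj(pos, splits, cfg, dm.ModelSpec(window=20))
        assert 0.0 <= f1 <= 1.0
        assert f1 == f2

    def test_fitness_near_zero_on_separable_data(self):
        X, y = _toy_windows(n=40, W=20)
        splits = dm.DataSplits(X[:30], y[:30], X[30:], y[30:])
        cfg = dm.TrainConfig(epochs=5, fitness_epochs=40, seed=1)
        for pos in ([1e-2, 12.0, 1e-4], [5e-3, 20.0, 1e-3]):
            assert dm.fitness_fobj(np.array(pos), splits, cfg,
                                   dm.ModelSpec(window=20)) <= 0.2

    def test_woa_tune_respects_bounds_and_trace(self):
        from anklestage.optimizers import WoaConfig
        X, y = _toy_windows(n=30, W=20)
        splits = dm.DataSplits(X[:20], y[:20], X[20:], y[20:])
        cfg = dm.TrainConfig(epochs=5, fitness_epochs=3, seed=1)
        hp, run = dm.woa_tune(splits, WoaConfig(n_agents=3, max_iteration=2, seed=1),
                              cfg, dm.ModelSpec(window=20))
        assert 10 <= hp.hidden_units <= 30
        assert 1e-4 <= hp.learning_rate <= 1e-1
        assert 1e-5 <= hp.l2_coefficient <= 1e-2
        assert np.all(np.diff(run.trace) <= 0)


def test_accuracy_non_decreasing_with_profile_separation(profiles):
    """Parameter-recovery surrogate: wider-separated stage profiles are
    easier to classify (3-point monotonicity, non-strict)."""
    from dataclasses import replace

    def squeeze(factor):
        # pull all stage means toward the stage-III centre by `factor`
        centre = profiles[2]
        out = []
        for p in profiles:
            out.append(replace(
                p,
                arom_mean=centre.arom_mean + factor * (p.arom_mean - centre.arom_mean),
                angvel_mean=centre.angvel_mean + factor * (p.angvel_mean - centre.angvel_mean),
                jerk_mean=max(centre.jerk_mean + factor * (p.jerk_mean - centre.jerk_mean), 1.0),
                eval_score_mean=centre.eval_score_mean
                + factor * (p.eval_score_mean - centre.eval_score_mean),
                completion_mean=centre.completion_mean
                + factor * (p.completion_mean - centre.completion_mean),
                tc_rate=centre.tc_rate + factor * (p.tc_rate - centre.tc_rate),
            ))
        # squeezing can break strict ordering only at factor=0; keep > 0
        return out

    accs = []
    counts = {s: 6 for s in ("I", "II", "III", "IV", "V")}
    for factor in (0.05, 0.3, 1.0):
        profs = squeeze(factor)
        cycles = sd.generate_dataset(profs, counts, 6.0, seed=2)
        cfg = pl.RunConfig(seed=2, n_cycles_per_stage=counts, duration_s=6.0,
                           stride=50, tune=False)
        splits, _ = pl.make_splits(cycles, cfg, stride=50)
        model = dm.build_model(dm.ModelSpec(), dm.CONTROL_HP, seed=2)
        dm.train(model, splits.X_train, splits.y_train,
                 cfg=dm.TrainConfig(epochs=40, seed=2))
        yp, _ = dm.predict(model, splits.X_test)
        accs.append(float(np.mean(yp == splits.y_test)))
    assert accs[0] <= accs[1] + 0.05 <= accs[2] + 0.10
    assert accs[2] >= accs[0]
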