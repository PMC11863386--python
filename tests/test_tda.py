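"""Discriminant-CV loss, gradients, training and evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from preorg.errors import BatchError, ConfigError
from preorg.surrogate import default_stage_specs, generate_state_ensembles
from preorg.features import switch_normalize
from preorg.tda import (
    CVModel,
    MLPSpec,
    TDATargets,
    TrainConfig,
    evaluate_cv,
    tda_loss,
    tda_loss_and_output_grad,
    train_cv,
    _MLP,
)


def _brute_force_loss(groups, targets):
    total = 0.0
    for g, mu_t, sd_t in zip(groups, targets.centers, targets.sigmas):
        g = np.asarray(g, float)
        mu = sum(g) / len(g)
        sd = np.sqrt(sum((v - mu) ** 2 for v in g) / len(g))
        total += (mu - mu_t) ** 2 + targets.alpha * (sd - sd_t) ** 2
    return total


class TestTDALoss:
    def test_zero_at_exact_targets(self, rng):
        targets = TDATargets()
        groups = []
        for mu, sd in zip(targets.centers, targets.sigmas):
            g = rng.normal(size=200)
            g = (g - g.mean()) / g.std() * sd + mu  # match moments exactly
            groups.append(g)
        assert tda_loss(groups, targets) == pytest.approx(0.0, abs=1e-20)

    def test_single_class_unit_offset(self):
        # one class at mean 1 vs target 0 with sd on target: loss = 1
        targets = TDATargets(centers=(0.0,), sigmas=(0.3,), alpha=1.0)
        g = np.array([1.0 - 0.3, 1.0 + 0.3])  # mean 1, sd 0.3
        assert tda_loss([g], targets) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        targets = TDATargets(alpha=0.7)
        for _ in range(20):
            groups = [rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 2), size=rng.integers(2, 40))
                      for _ in range(3)]
            assert tda_loss(groups, targets) == pytest.approx(
                _brute_force_loss(groups, targets), rel=1e-12
            )

    def test_permutation_invariance(self, rng):
        targets = TDATargets()
        groups = [rng.normal(c, 1.0, 30) for c in targets.centers]
        shuffled = [rng.permutation(g) for g in groups]
        assert tda_loss(groups, targets) == pytest.approx(tda_loss(shuffled, targets))

    def test_small_class_rejected(self):
        targets = TDATargets(centers=(0.0,), sigmas=(1.0,))
        with pytest.raises(BatchError):
            tda_loss([np.array([1.0])], targets)

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=20))
    @settings(max_examples=100, derandomize=True)
    def test_non_negative(self, values):
        targets = TDATargets(centers=(0.0,), sigmas=(0.5,))
        assert tda_loss([np.asarray(values)], targets) >= 0.0


class TestGradients:
    def test_output_gradient_matches_finite_difference(self, rng):
        targets = TDATargets()
        values = rng.normal(0, 5, 30)
        labels = np.repeat([0, 1, 2], 10)
        _, grad = tda_loss_and_output_grad(values, labels, targets)
        h = 1e-6
        for i in range(0, 30, 7):
            vp, vm = values.copy(), values.copy()
            vp[i] += h
            vm[i] -= h
            lp, _ = tda_loss_and_output_grad(vp, labels, targets)
            lm, _ = tda_loss_and_output_grad(vm, labels, targets)
            assert grad[i] == pytest.approx((lp - lm) / (2 * h), rel=1e-4, abs=1e-8)

    def test_parameter_gradients_match_finite_difference(self, rng):
        """Backprop through a random small net agrees with finite differences."""
        spec = MLPSpec((4, 6, 1), seed=11)
        net = _MLP(spec, np.random.default_rng(11))
        targets = TDATargets(centers=(-1.0, 0.0, 1.0), sigmas=(0.3, 0.3, 0.3))
        x = rng.normal(size=(18, 4))
        y = np.repeat([0, 1, 2], 6)
        out, acts = net.forward(x, cache=True)
        _, dout = tda_loss_and_output_grad(out.ravel(), y, targets)
        gw, gb, _ = net.backward(acts, dout[:, None])
        h = 1e-6
        for layer in range(2):
            w = net.weights[layer]
            for idx in [(0, 0), (w.shape[0] - 1, w.shape[1] - 1)]:
                orig = w[idx]
                w[idx] = orig + h
                lp, _ = tda_loss_and_output_grad(net.forward(x).ravel(), y, targets)
                w[idx] = orig - h
                lm, _ = tda_loss_and_output_grad(net.forward(x).ravel(), y, targets)
                w[idx] = orig
                fd = (lp - lm) / (2 * h)
                assert gw[layer][idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_input_gradient_matches_finite_difference(self, rng):
        spec = MLPSpec((3, 5, 1), seed=2)
        model = _train_tiny(rng, spec)
        x = rng.normal(size=(4, 3))
        g = model.input_gradient(x)
        h = 1e-6
        for j in range(3):
            xp, xm = x.copy(), x.copy()
            xp[:, j] += h
            xm[:, j] -= h
            fd = (model.evaluate(xp) - model.evaluate(xm)) / (2 * h)
            assert np.allclose(g[:, j], fd, rtol=1e-4, atol=1e-7)


def _train_tiny(rng, spec=None):
    spec = spec or MLPSpec((3, 5, 1), seed=2)
    x = np.vstack([rng.normal(c, 0.3, size=(40, 3)) for c in (-2.0, 0.0, 2.0)])
    y = np.repeat([0, 1, 2], 40)
    return train_cv(x, y, spec, TDATargets(), TrainConfig(max_epochs=400))


class TestTraining:
    def test_separable_three_state_data_converges(self, rng):
        """Per-class CV means land within 0.5 of (-10, 0, 10)."""
        x = np.vstack([rng.normal(c, 0.2, size=(300, 1)) for c in (1.0, 2.0, 3.0)])
        y = np.repeat([0, 1, 2], 300)
        model = train_cv(x, y, MLPSpec((1, 8, 1), seed=0), TDATargets())
        _, summary = evaluate_cv(model, x, y)
        means = summary.sort_values("class_index")["mean"].to_numpy()
        assert np.all(np.abs(means - np.array([-10.0, 0.0, 10.0])) < 0.5)
        assert np.all(np.diff(means) > 0)  # class-order consistency

    def test_shuffled_labels_plateau_far_above_separable(self, rng):
        x = np.vstack([rng.normal(c, 0.2, size=(100, 1)) for c in (1.0, 2.0, 3.0)])
        y = np.repeat([0, 1, 2], 100)
        good = train_cv(x, y, MLPSpec((1, 8, 1), seed=0), TDATargets())
        y_shuffled = np.random.default_rng(0).permutation(y)
        with pytest.warns(RuntimeWarning):
            bad = train_cv(
                x, y_shuffled, MLPSpec((1, 8, 1), seed=0), TDATargets(),
                TrainConfig(max_epochs=600, patience=100),
            )
        assert bad.final_validation_loss > 50 * good.final_validation_loss

    def test_training_deterministic(self, rng):
        a = _train_tiny(np.random.default_rng(5))
        b = _train_tiny(np.random.default_rng(5))
        assert a.history == b.history
        assert all(np.array_equal(w1, w2) for w1, w2 in zip(a.net.weights, b.net.weights))

    def test_config_errors(self, rng):
        x = rng.normal(size=(30, 2))
        y = np.repeat([0, 1, 2], 10)
        with pytest.raises(ConfigError):
            train_cv(x, y, MLPSpec((3, 4, 1)), TDATargets())  # dim mismatch
        with pytest.raises(ConfigError):
            train_cv(x, np.zeros(30, dtype=int), MLPSpec((2, 4, 1)), TDATargets())


class TestEvaluate:
    def test_summaries_equal_brute_force(self, rng):
        model = _train_tiny(rng)
        x = rng.normal(size=(60, 3))
        labels = rng.integers(0, 3, 60)
        values, summary = evaluate_cv(model, x, labels)
        for _, row in summary.iterrows():
            g = values[labels == row["class_index"]]
            assert row["mean"] == pytest.approx(g.mean())
            assert row["sd"] == pytest.approx(g.std())

    def test_evaluation_pure(self, rng):
        model = _train_tiny(rng)
        x = rng.normal(size=(10, 3))
        assert np.array_equal(model.evaluate(x), model.evaluate(x))

    def test_save_load_roundtrip(self, rng, tmp_path):
        model = _train_tiny(rng)
        path = tmp_path / "cv.json"
        model.save(path)
        again = CVModel.load(path)
        x = rng.normal(size=(20, 3))
        assert np.allclose(model.evaluate(x), again.evaluate(x))
        assert again.status == model.status


def test_pipeline_feature_dimension_consistency():
    """36-dim switch-normalized ensembles train the 36-input network."""
    specs = default_stage_specs(36)
    df = generate_state_ensembles(specs, 40, seed=0)
    x = switch_normalize(df[[f"feat_{i}" for i in range(36)]].to_numpy(), 4.0)
    y = df["class_index"].to_numpy()
    model = train_cv(x, y, MLPSpec((36, 72, 36, 1), seed=0), TDATargets(),
                     TrainConfig(max_epochs=30, patience=30))
    assert model.spec.layer_widths[0] == x.shape[1] == 36
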