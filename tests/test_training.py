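import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ictalnet.dataset import kfold_plan, subject_split
from ictalnet.models import ModelSpec, build_model
from ictalnet.training import (
    FocalLossParams,
    TrainConfig,
    cross_validate,
    focal_loss,
    focal_loss_with_grad,
    train_fold,
)


class TestFocalLoss:
    def test_perfect_prediction_gives_zero_loss(self):
        assert focal_loss(np.array([1.0 - 1e-9]), np.array([1])) < 1e-6

    def test_gamma_zero_alpha_one_is_plain_cross_entropy(self):
        p = np.linspace(0.05, 0.95, 19)
        y = np.ones_like(p, dtype=int)
        params = FocalLossParams(alpha=1.0, gamma=0.0)
        for pi in p:
            assert focal_loss(np.array([pi]), np.array([1]), params) == pytest.approx(
                -np.log(pi)
            )

    def test_gamma_zero_equals_alpha_weighted_cross_entropy_on_grid(self):
        params = FocalLossParams(alpha=0.6, gamma=0.0)
        for pi in np.linspace(0.05, 0.95, 10):
            for y in (0, 1):
                expected = -(0.6 if y else 0.4) * np.log(pi if y else 1 - pi)
                got = focal_loss(np.array([pi]), np.array([y]), params)
                assert got == pytest.approx(expected)

    def test_hand_evaluated_reference_value(self):
        # p=0.5, y=1, alpha=0.6, gamma=2: 0.6 * 0.25 * ln 2
        got = focal_loss(np.array([0.5]), np.array([1]), FocalLossParams(0.6, 2.0))
        assert got == pytest.approx(0.6 * 0.25 * np.log(2), rel=1e-9)
        assert got == pytest.approx(0.10397, abs=1e-5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(gamma=st.floats(0.0, 4.0), alpha=st.floats(0.1, 0.9))
    def test_monotone_decreasing_in_p_t(self, gamma, alpha):
        params = FocalLossParams(alpha, gamma)
        p = np.linspace(0.02, 0.98, 40)
        losses = [focal_loss(np.array([pi]), np.array([1]), params) for pi in p]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_logit_form_matches_probability_form(self):
        rng = np.random.default_rng(0)
        logits = rng.standard_normal((50, 2)).astype(np.float32)
        y = rng.integers(0, 2, 50)
        params = FocalLossParams(0.6, 2.0)
        loss, _ = focal_loss_with_grad(logits, y, params)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        assert loss == pytest.approx(focal_loss(p[:, 1], y, params), rel=1e-6)

    def test_logit_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((6, 2)).astype(np.float64)
        y = np.array([0, 1, 1, 0, 1, 0])
        params = FocalLossParams(0.6, 2.0)
        _, grad = focal_loss_with_grad(logits, y, params)
        for i in range(6):
            for j in range(2):
                eps = 1e-5
                lp = focal_loss_with_grad(
                    logits + eps * np.eye(6)[:, [i]] @ np.eye(2)[[j]], y, params)[0]
                lm = focal_loss_with_grad(
                    logits - eps * np.eye(6)[:, [i]] @ np.eye(2)[[j]], y, params)[0]
                assert (lp - lm) / (2 * eps) == pytest.approx(grad[i, j], abs=1e-5)


def separable_dataset(n=40, seed=0):
    """Two well-separated Gaussian classes as tiny (1, 4, 8) maps."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    x = rng.standard_normal((n, 1, 4, 8)).astype(np.float32)
    x[y == 1] += 2.5
    return x, y


class TestTrainFold:
    def small_spec(self):
        return ModelSpec(architecture="shallow_convnet", in_channels=1,
                         input_hw=(4, 8), dropout_rate=0.2)

    def frozen_spec(self):
        # batch-norm-free stack: with a vanishing learning rate the float32
        # weights (and hence the validation loss) are exactly constant
        return ModelSpec(architecture="alexnet_baseline", in_channels=1,
                         input_hw=(4, 8), dropout_rate=0.2)

    def test_early_stop_after_patience_epochs_without_improvement(self):
        x, y = separable_dataset(20)
        model = build_model(self.frozen_spec(), seed=0)
        cfg = TrainConfig(lr=1e-15, weight_decay=1e-15, epochs=20, patience=8, seed=0)
        _, hist = train_fold(model, (x, y), (x.copy(), y.copy()), cfg)
        assert hist["epoch"][-1] == 9  # 1 best epoch + 8 stagnant epochs

    def test_seeded_determinism(self):
        x, y = separable_dataset(24, seed=3)
        cfg = TrainConfig(epochs=3, patience=3, seed=5, batch_size=8)
        runs = []
        for _ in range(2):
            model = build_model(self.small_spec(), seed=1)
            _, hist = train_fold(model, (x[:16], y[:16]), (x[16:], y[16:]), cfg)
            runs.append(hist["val_loss"])
        assert runs[0] == runs[1]

    def test_separable_data_is_fit_perfectly_within_20_epochs(self):
        from sklearn.linear_model import LogisticRegression

        x, y = separable_dataset(40, seed=1)
        # independent oracle: a logistic fit separates the same data
        oracle = LogisticRegression().fit(x.reshape(40, -1), y)
        assert oracle.score(x.reshape(40, -1), y) == 1.0
        # a mean-shifted task needs a sign-preserving stack (the shallow
        # net's square-law features are invariant to x -> -x)
        model = build_model(ModelSpec(architecture="eegnet_se", in_channels=1,
                                      input_hw=(4, 8), dropout_rate=0.2), seed=0)
        cfg = TrainConfig(lr=5e-3, epochs=20, patience=20, batch_size=8, seed=0)
        model, _ = train_fold(model, (x, y), (x, y), cfg)
        pred = model.predict_proba(x)[:, 1] >= 0.5
        assert (pred == y).mean() == 1.0

    def test_lr_decays_by_factor_on_plateau(self):
        x, y = separable_dataset(20)
        model = build_model(self.frozen_spec(), seed=0)
        cfg = TrainConfig(lr=1e-15, weight_decay=1e-15, epochs=20, patience=8,
                          lr_decay_factor=0.3, lr_plateau_patience=3, seed=0)
        _, hist = train_fold(model, (x, y), (x, y), cfg)
        lrs = hist["lr"]
        assert lrs[-1] < lrs[0]
        assert min(lrs) == pytest.approx(lrs[0] * 0.3 ** 2, rel=1e-6)

    def test_empty_subset_raises(self):
        x, y = separable_dataset(10)
        model = build_model(self.small_spec(), seed=0)
        with pytest.raises(ValueError):
            train_fold(model, (x[:0], y[:0]), (x, y), TrainConfig(seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=5, patience=9)
        with pytest.raises(ValueError):
            FocalLossParams(alpha=1.5)
        with pytest.raises(ValueError):
            FocalLossParams(gamma=-1)


@pytest.fixture(scope="module")
def cv_results(stft_dataset):
    spec = ModelSpec(architecture="shallow_convnet", in_channels=4,
                     input_hw=(129, 39))
    cfg = TrainConfig(epochs=3, patience=3, seed=2, batch_size=16)
    plan = kfold_plan(len(stft_dataset), 5, seed=42)
    return cross_validate(stft_dataset, spec, cfg, plan), plan


class TestCrossValidate:

    def test_one_result_per_fold(self, cv_results):
        results, _ = cv_results
        assert len(results) == 5
        assert [r.fold for r in results] == list(range(5))

    def test_every_item_tested_exactly_once(self, cv_results, stft_dataset):
        results, _ = cv_results
        tested = np.concatenate([r.test_indices for r in results])
        assert sorted(tested.tolist()) == list(range(len(stft_dataset)))

    def test_thresholds_stay_inside_search_band(self, cv_results):
        results, _ = cv_results
        for r in results:
            assert 0.3 <= r.threshold <= 0.7

    def test_metrics_recomputable_from_counts(self, cv_results):
        results, _ = cv_results
        for r in results:
            c = r.counts
            assert r.metrics.accuracy == pytest.approx((c.tp + c.tn) / c.total)

    def test_subject_independent_mode_respects_partition(self, stft_dataset):
        spec = ModelSpec(architecture="shallow_convnet", in_channels=4,
                         input_hw=(129, 39))
        cfg = TrainConfig(epochs=2, patience=2, seed=0, batch_size=16)
        plan = subject_split(stft_dataset, n_train_subjects=16, seed=0)
        results = cross_validate(stft_dataset, spec, cfg, plan)
        assert len(results) == 1
        test_subj = {stft_dataset.subject_ids[i] for i in results[0].test_indices}
        assert test_subj <= plan.test_subjects
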