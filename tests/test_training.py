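"""Loss, clipping, Adam, learning-rate schedule, early stopping, training loop."""

import math

import numpy as np
import pytest

import premscore as pm
from premscore import EarlyStopper, TrainConfig, adam_update, clip_gradients, \
    learning_rate, nll_l2_loss
from premscore.errors import ConfigError
from premscore.nn.optim import OptimizerState


# ---------------------------------------------------------------------------
# loss


def test_perfect_predictions_give_zero_loss():
    probs = np.eye(5)[[0, 3, 2]]
    assert nll_l2_loss(probs, [0, 3, 2]) == pytest.approx(0.0, abs=1e-9)


def test_uniform_five_class_probabilities_give_ln5():
    probs = np.full((4, 5), 0.2)
    assert nll_l2_loss(probs, [0, 1, 2, 3]) == pytest.approx(math.log(5), rel=1e-12)


def test_l2_penalty_direct_evaluation():
    # single weight w = 2, lambda = 0.1, N_b = 1, perfect probabilities
    probs = np.array([[1.0, 0.0]])
    loss = nll_l2_loss(probs, [0], weights=[np.array([2.0])], l2_lambda=0.1)
    assert loss == pytest.approx(0.1 * 4 / 2, rel=1e-12)


def test_loss_survives_zero_probability_via_clamping():
    probs = np.array([[0.0, 1.0]])
    assert np.isfinite(nll_l2_loss(probs, [0]))


# ---------------------------------------------------------------------------
# gradient clipping


def test_norm_at_threshold_unchanged():
    g = np.array([0.06, 0.08])  # norm exactly 0.1
    assert np.array_equal(clip_gradients(g, 0.1), g)


def test_norm_above_threshold_rescaled():
    g = np.array([0.12, 0.16])  # norm 0.2
    assert np.allclose(clip_gradients(g, 0.1), [0.06, 0.08])


def test_zero_gradient_stays_zero():
    assert np.array_equal(clip_gradients(np.zeros(3), 0.1), np.zeros(3))


def test_clipping_is_global_over_a_parameter_list():
    gs = clip_gradients([np.array([0.12]), np.array([0.16])], 0.1)
    assert np.allclose(gs[0], 0.06) and np.allclose(gs[1], 0.08)


# ---------------------------------------------------------------------------
# Adam


def test_zero_gradient_leaves_weight_unchanged():
    w = np.array([1.0, -2.0])
    state = OptimizerState.zeros_like(w)
    w2, state2 = adam_update(w, np.zeros(2), state, eta=0.1)
    assert np.array_equal(w2, w)
    assert state2.t == 1


def test_first_step_moves_by_eta_times_sign():
    w = np.array([1.0])
    w2, _ = adam_update(w, np.array([0.01]), OptimizerState.zeros_like(w),
                        eta=1e-3)
    # bias correction makes m_hat = g, v_hat = g^2, so the step is ~ eta * sign(g)
    assert w2[0] == pytest.approx(1.0 - 1e-3, rel=1e-4)


def test_constant_gradient_keeps_unit_scaled_steps():
    w = np.array([0.0])
    state = OptimizerState.zeros_like(w)
    g = np.array([0.05])
    w1, state = adam_update(w, g, state, eta=1e-3)
    w2, state = adam_update(w1, g, state, eta=1e-3)
    assert (w1 - w2)[0] == pytest.approx(1e-3, rel=1e-3)


def test_adam_matches_textbook_oracle():
    """Independent step-by-step Adam recurrence on random instances."""
    rng = np.random.default_rng(0)
    for _ in range(5):
        n = rng.integers(1, 6)
        w = rng.standard_normal(n)
        state = OptimizerState.zeros_like(w)
        m = np.zeros(n)
        v = np.zeros(n)
        beta1, beta2, eps, eta = 0.9, 0.999, 1e-8, 3e-4
        w_ref = w.copy()
        for t in range(1, 8):
            g = rng.standard_normal(n)
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g**2
            w_ref = w_ref - eta * (m / (1 - beta1**t)) / (
                np.sqrt(v / (1 - beta2**t)) + eps)
            w, state = adam_update(w, g, state, eta, beta1, beta2, eps)
            assert np.allclose(w, w_ref, atol=1e-10)


# ---------------------------------------------------------------------------
# learning-rate protocol


def test_learning_rate_protocol_values():
    cfg = TrainConfig()  # N_b = 256
    assert learning_rate(1, cfg) == pytest.approx(2.56e-5, rel=1e-12)
    assert learning_rate(12, cfg) == pytest.approx(2.56e-4, rel=1e-12)
    assert learning_rate(22, cfg) == pytest.approx(2.56e-4 * math.exp(-0.6),
                                                   rel=1e-12)


def test_warmup_is_linear():
    cfg = TrainConfig()
    etas = np.array([learning_rate(i, cfg) for i in range(1, 13)])
    assert np.allclose(np.diff(etas), etas[1] - etas[0], rtol=1e-9)


def test_cooldown_is_exponential():
    cfg = TrainConfig()
    e13, e14 = learning_rate(13, cfg), learning_rate(14, cfg)
    assert e14 / e13 == pytest.approx(math.exp(-0.06), rel=1e-12)


def test_epochs_are_one_based():
    with pytest.raises(ConfigError):
        learning_rate(0, TrainConfig())


# ---------------------------------------------------------------------------
# early stopping


def test_scripted_sequence_stops_after_five_flat_epochs():
    stopper = EarlyStopper(min_epochs=1, max_epochs=50, patience=5)
    scores = [0.5, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6]
    stopped_at = None
    for epoch, f1 in enumerate(scores, start=1):
        if stopper.update(epoch, f1):
            stopped_at = epoch
            break
    assert stopped_at == 7  # best at epoch 2, then 5 non-improving epochs
    assert stopper.best_epoch == 2


def test_monotonic_improvement_runs_to_max_epochs():
    stopper = EarlyStopper(min_epochs=1, max_epochs=10, patience=3)
    for epoch in range(1, 11):
        stop = stopper.update(epoch, epoch / 10.0)
        assert stop == (epoch == 10)
    assert stopper.best_epoch == 10


def test_minimum_epoch_floor_delays_stopping():
    stopper = EarlyStopper(min_epochs=12, max_epochs=50, patience=5)
    stops = [stopper.update(e, 1.0 - e / 100) for e in range(1, 13)]
    assert not any(stops[:-1])
    assert stops[-1]  # worsening from the start: stop exactly at epoch 12


# ---------------------------------------------------------------------------
# training loop


def _tiny_setup(seed=0, n_epochs=120):
    hyp = pm.generate_hypnogram(pm.DEFAULT_HYPNOGRAM_MODEL, n_epochs, seed=seed)
    rec = pm.generate_recording(hyp, pm.DEFAULT_SIGNAL_MODELS, fs=128.0,
                                seed=seed + 1)
    windows = pm.make_windows(pm.preprocess_recording(rec), hyp)
    X, y = pm.windows_to_array(windows)
    cfg = pm.ModelConfig(n_kernels=6, num_classes=5, p_dropout=0.2)
    return windows, X, y, cfg


def test_loss_decreases_over_first_epochs():
    windows, X, y, cfg = _tiny_setup(n_epochs=200)
    net = pm.build_network(cfg, rng=0, classes=np.arange(5))
    # small batches and a stronger per-sample rate so the tiny fixture
    # accumulates enough gradient steps within a few epochs
    tcfg = TrainConfig(min_epochs=1, max_epochs=8, batch_size=64, seed=0,
                       lr_start_per_sample=1e-6, lr_peak_per_sample=1e-5)
    _, hist = pm.train(net, windows, X, y, tcfg)
    assert hist["train_loss"].iloc[-2:].mean() < hist["train_loss"].iloc[0]
    assert hist["val_macro_f1"].iloc[-1] > hist["val_macro_f1"].iloc[0]


def test_training_is_reproducible_with_fixed_seed():
    windows, X, y, cfg = _tiny_setup()
    tcfg = TrainConfig(min_epochs=1, max_epochs=2, batch_size=64, seed=3)
    runs = []
    for _ in range(2):
        net = pm.build_network(cfg, rng=1, classes=np.arange(5))
        net, hist = pm.train(net, windows, X, y, tcfg,
                             augment_params=pm.AugmentationParams(a_a=0.5, a_s=0.5))
        runs.append((hist, net.get_weights()))
    (h1, w1), (h2, w2) = runs
    assert h1.equals(h2)
    assert all(np.array_equal(a, b) for a, b in zip(w1, w2))


def test_empty_sets_rejected():
    windows, X, y, cfg = _tiny_setup()
    net = pm.build_network(cfg, rng=0, classes=np.arange(5))
    with pytest.raises(pm.errors.DataError):
        pm.train(net, [], X, y, TrainConfig())
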