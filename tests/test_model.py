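"""Network architecture: dimensional bookkeeping, probabilities, gradients."""

import numpy as np
import pytest

import premscore.nn.layers as nnl
import premscore.nn.network as nnn
from premscore import ModelConfig, SleepNet, build_network, conv_output_lengths
from premscore.errors import ConfigError
from premscore.nn.layers import Conv1d, Linear, softmax


def tiny_cfg(**kw):
    base = dict(n_kernels=4, kernel_len=3, n_conv_layers=2, stride_pattern=(1, 2),
                p_dropout=0.0, fc_hidden=6, num_classes=3, input_len=20)
    base.update(kw)
    return ModelConfig(**base)


# ---------------------------------------------------------------------------
# convolution arithmetic


def test_valid_convolution_chain_on_default_input():
    lengths = conv_output_lengths(1920, 5, (1, 2, 1, 2, 1, 2, 1, 2))
    assert lengths == [1916, 956, 952, 474, 470, 233, 229, 113]


def test_flatten_width_is_113_times_96():
    assert ModelConfig().flatten_width == 113 * 96 == 10848


def test_single_position_convolution():
    assert conv_output_lengths(5, 5, [1]) == [1]


def test_chain_shorter_than_kernel_rejected():
    with pytest.raises(ConfigError):
        conv_output_lengths(16, 5, (2, 2, 2, 2))


def test_only_valid_convolutions_reproduce_the_published_feature_count():
    """'Same' padding would give 1920 / 16 = 120 positions; valid convolution
    with the alternating stride pattern gives 113."""
    same_padding_length = 1920
    for stride in (1, 2, 1, 2, 1, 2, 1, 2):
        same_padding_length = int(np.ceil(same_padding_length / stride))
    assert same_padding_length == 120
    assert conv_output_lengths(1920, 5, (1, 2, 1, 2, 1, 2, 1, 2))[-1] == 113


# ---------------------------------------------------------------------------
# construction


@pytest.mark.parametrize("num_classes", [3, 5])
def test_output_layer_width_matches_stage_set(num_classes):
    net = build_network(ModelConfig(num_classes=num_classes), rng=0)
    out_layer = [l for l in net.layers if isinstance(l, Linear)][-1]
    assert out_layer.W.value.shape == (80, num_classes)


def test_conv_depths_one_then_n_kernels():
    net = build_network(ModelConfig(), rng=0)
    convs = [l for l in net.layers if isinstance(l, Conv1d)]
    assert len(convs) == 8
    assert convs[0].W.value.shape == (96, 1, 5)
    for c in convs[1:]:
        assert c.W.value.shape == (96, 96, 5)
    assert [c.stride for c in convs] == [1, 2, 1, 2, 1, 2, 1, 2]


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        ModelConfig(num_classes=4)
    with pytest.raises(ConfigError):
        ModelConfig(stride_pattern=(1, 2))
    with pytest.raises(ConfigError):
        ModelConfig(p_dropout=1.0)


# ---------------------------------------------------------------------------
# prediction contracts


def test_probabilities_form_a_simplex():
    net = build_network(tiny_cfg(), rng=0)
    X = np.random.default_rng(0).standard_normal((7, 20)).astype(np.float32)
    probs, pred = net.predict(X)
    assert probs.shape == (7, 3)
    assert (probs >= 0).all()
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert set(pred) <= set(net.classes_)


def test_repeated_input_gives_identical_rows_in_inference_mode():
    net = build_network(tiny_cfg(p_dropout=0.5), rng=0)  # dropout must be off
    x = np.random.default_rng(1).standard_normal(20).astype(np.float32)
    X = np.tile(x, (5, 1))
    probs, _ = net.predict(X)
    # rows agree to float32 round-off (BLAS may vary accumulation per row)
    assert np.allclose(probs, np.tile(probs[0], (5, 1)), atol=1e-6)


def test_zeroed_output_layer_gives_uniform_probabilities_and_first_class():
    net = build_network(tiny_cfg(), rng=0, classes=np.array([0, 1, 3]))
    out_layer = [l for l in net.layers if isinstance(l, Linear)][-1]
    out_layer.W.value[...] = 0.0
    out_layer.b.value[...] = 0.0
    X = np.random.default_rng(2).standard_normal((4, 20)).astype(np.float32)
    probs, pred = net.predict(X)
    assert np.allclose(probs, 1.0 / 3.0, atol=1e-6)
    assert (pred == 0).all()  # argmax tie-break: lowest class index


def test_batch_permutation_equivariance():
    net = build_network(tiny_cfg(), rng=3)
    X = np.random.default_rng(4).standard_normal((10, 20)).astype(np.float32)
    perm = np.random.default_rng(5).permutation(10)
    probs, _ = net.predict(X)
    probs_perm, _ = net.predict(X[perm])
    assert np.allclose(probs[perm], probs_perm, atol=1e-6)


def test_wrong_input_length_rejected():
    net = build_network(tiny_cfg(), rng=0)
    with pytest.raises(ConfigError):
        net.forward(np.zeros((2, 21), dtype=np.float32))


def test_default_forward_pass_completes_on_a_full_batch():
    import time

    net = build_network(ModelConfig(), rng=0)
    X = np.random.default_rng(0).standard_normal((256, 1920)).astype(np.float32)
    start = time.time()
    logits = net.forward(X)
    assert logits.shape == (256, 5)
    assert time.time() - start < 60.0


# ---------------------------------------------------------------------------
# gradients


def test_backprop_matches_numerical_gradients():
    """Central-difference check of every layer type, run in float64."""
    old = nnl.DTYPE
    nnl.DTYPE = np.float64
    nnn.DTYPE = np.float64
    try:
        net = SleepNet(tiny_cfg(), rng=0)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((5, 20))
        y = np.array([0, 1, 2, 1, 0])

        def loss():
            p = softmax(net.forward(X, train=True))
            return -np.mean(np.log(p[np.arange(5), y]))

        p = softmax(net.forward(X, train=True))
        d = p.copy()
        d[np.arange(5), y] -= 1
        net.backward(d / 5)
        for prm in net.params():
            grad = prm.grad.copy()
            flat = prm.value.reshape(-1)
            for i in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                eps, orig = 1e-6, flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grad.reshape(-1)[i]
                assert abs(num - ana) <= 1e-5 * (abs(num) + abs(ana)) + 1e-7, prm.name
    finally:
        nnl.DTYPE = old
        nnn.DTYPE = old


def test_checkpoint_round_trip(tmp_path):
    net = build_network(tiny_cfg(), rng=7, classes=np.array([0, 1, 3]))
    X = np.random.default_rng(8).standard_normal((6, 20)).astype(np.float32)
    probs, _ = net.predict(X)
    path = net.save(tmp_path / "model.npz")
    back = SleepNet.load(path)
    probs2, _ = back.predict(X)
    assert np.allclose(probs, probs2, atol=1e-6)
    assert np.array_equal(back.classes_, net.classes_)
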