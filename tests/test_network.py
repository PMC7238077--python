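import numpy as np
import pytest

from phideid.corpus import LabeledDocument
from phideid.encoders import EmbeddingTable
from phideid.network import (
    LstmParams,
    NetworkConfig,
    ParameterVector,
    bilstm,
    forward,
    gradient,
    init_parameters,
    load_checkpoint,
    loss,
    loss_and_gradient,
    lstm_step,
    parameter_length,
    predict_labels,
    save_checkpoint,
    token_embedding,
)


def zero_lstm(hidden, input_dim):
    shape = (hidden, input_dim + hidden)
    z = lambda *s: np.zeros(s)
    return LstmParams(z(*shape), z(*shape), z(*shape), z(hidden), z(hidden), z(hidden))


def random_lstm(hidden, input_dim, seed):
    rng = np.random.default_rng(seed)
    shape = (hidden, input_dim + hidden)
    m = lambda: rng.normal(0, 0.4, size=shape)
    v = lambda: rng.normal(0, 0.2, size=hidden)
    return LstmParams(m(), m(), m(), v(), v(), v())


# ---------------------------------------------------------------- cell


def test_lstm_step_zero_params_zero_state():
    params = zero_lstm(3, 2)
    h, c = lstm_step(np.array([1.5, -2.0]), np.zeros(3), np.zeros(3), params)
    assert np.array_equal(h, np.zeros(3))
    assert np.array_equal(c, np.zeros(3))


def test_lstm_step_scalar_hand_computed():
    # zero weights, c_prev = 1: i = sigma(1), c = sigma(1), h = 0.5*tanh(c)
    params = zero_lstm(1, 1)
    h, c = lstm_step(np.array([7.0]), np.zeros(1), np.ones(1), params)
    sig1 = 1.0 / (1.0 + np.exp(-1.0))
    assert c[0] == pytest.approx(sig1, abs=1e-12)  # ~0.731059
    assert h[0] == pytest.approx(0.5 * np.tanh(sig1), abs=1e-12)  # ~0.311856


def test_lstm_step_shape_errors():
    params = zero_lstm(3, 2)
    with pytest.raises(ValueError):
        lstm_step(np.zeros(2), np.zeros(4), np.zeros(3), params)
    with pytest.raises(ValueError):
        lstm_step(np.zeros(5), np.zeros(3), np.zeros(3), params)


def test_lstm_params_validation():
    with pytest.raises(ValueError):
        LstmParams(
            np.zeros((2, 5)), np.zeros((2, 4)), np.zeros((2, 5)),
            np.zeros(2), np.zeros(2), np.zeros(2),
        )


# ---------------------------------------------------------------- bilstm


def test_bilstm_single_element_last_equals_full():
    f, b = random_lstm(3, 2, 0), random_lstm(3, 2, 1)
    x = [np.array([0.3, -0.7])]
    last = bilstm(x, f, b, mode="last")
    full = bilstm(x, f, b, mode="full")
    assert np.allclose(last, full[0])


def test_bilstm_zero_params_zero_output():
    f = b = zero_lstm(4, 3)
    out = bilstm([np.ones(3)] * 5, f, b, mode="last")
    assert out.shape == (8,)
    assert np.array_equal(out, np.zeros(8))


def test_bilstm_reversal_swaps_directions():
    rng = np.random.default_rng(7)
    f, b = random_lstm(3, 2, 2), random_lstm(3, 2, 3)
    xs = [rng.normal(size=2) for _ in range(6)]
    out = bilstm(xs, f, b, mode="last")
    out_rev = bilstm(xs[::-1], b, f, mode="last")
    assert np.allclose(out_rev, np.concatenate([out[3:], out[:3]]))


def test_bilstm_rejects_empty_sequence():
    f = b = zero_lstm(2, 2)
    with pytest.raises(ValueError):
        bilstm([], f, b)


# ---------------------------------------------------------------- embedding


def test_token_embedding_is_556_at_study_dimensions():
    config = NetworkConfig()
    assert config.e_dim == 556
    assert config.d_dim == 200
    table = EmbeddingTable(dim=300, vectors={})
    f = b = zero_lstm(config.char_hidden, config.char_onehot_dim)
    e = token_embedding("unseen-token", table, f, b)
    assert e.shape == (556,)
    assert np.array_equal(e, np.zeros(556))  # OOV word + zero char params


def test_token_embedding_reproducible():
    table = EmbeddingTable(dim=4, vectors={})
    f, b = random_lstm(3, 128, 4), random_lstm(3, 128, 5)
    e1 = token_embedding("MR123456", table, f, b)
    e2 = token_embedding("MR123456", table, f, b)
    assert np.array_equal(e1, e2)
    assert e1.shape == (4 + 6,)
    assert np.any(e1 != 0.0)


# ---------------------------------------------------------------- forward


def doc(tokens, labels):
    return LabeledDocument("d", "p", tuple(tokens), tuple(labels))


def test_forward_rows_are_distributions(tiny_config, tiny_table, tiny_params):
    d = doc(["alpha", "912", "Beta"], ["non-PHI", "date", "patient"])
    out = forward(d, tiny_params, tiny_table)
    assert out.probabilities.shape == (3, 29)
    assert np.all(out.probabilities >= 0)
    assert np.allclose(out.probabilities.sum(axis=1), 1.0, atol=1e-9)


def test_forward_zero_params_uniform(tiny_config, tiny_table):
    p0 = ParameterVector(np.zeros(parameter_length(tiny_config)), tiny_config)
    d = doc(["alpha", "beta"], ["non-PHI", "non-PHI"])
    out = forward(d, p0, tiny_table)
    assert np.allclose(out.probabilities, 1.0 / 29)


def test_predict_tie_break_lowest_index(tiny_config, tiny_table, scheme):
    p0 = ParameterVector(np.zeros(parameter_length(tiny_config)), tiny_config)
    d = doc(["alpha", "beta"], ["non-PHI", "non-PHI"])
    labels = predict_labels(d, p0, tiny_table, scheme)
    assert labels == [scheme.labels[0]] * 2


def test_forward_matches_primitive_composition(tiny_config, tiny_table, tiny_params):
    """The batched kernels must agree with the lstm_step/bilstm reference path."""
    d = doc(["alpha", "MR123456", "912", "zz"], ["non-PHI"] * 4)
    out = forward(d, tiny_params, tiny_table, return_diagnostics=True)
    cf = tiny_params.lstm_params("char_fwd")
    cb = tiny_params.lstm_params("char_bwd")
    e_ref = np.stack([token_embedding(t, tiny_table, cf, cb) for t in d.tokens])
    assert np.allclose(out.embeddings, e_ref, atol=1e-12)
    lf = tiny_params.lstm_params("label_fwd")
    lb = tiny_params.lstm_params("label_bwd")
    d_ref = bilstm(list(e_ref), lf, lb, mode="full")
    assert np.allclose(out.states, d_ref, atol=1e-12)
    l_ref = np.tanh(d_ref @ tiny_params.view("W_1").T + tiny_params.view("b_1"))
    logits = l_ref @ tiny_params.view("W_2").T + tiny_params.view("b_2")
    a_ref = np.exp(logits - logits.max(axis=1, keepdims=True))
    a_ref /= a_ref.sum(axis=1, keepdims=True)
    assert np.allclose(out.probabilities, a_ref, atol=1e-12)


def test_token_order_matters(tiny_config, tiny_table, tiny_params):
    d1 = doc(["alpha", "912", "beta"], ["non-PHI"] * 3)
    d2 = doc(["beta", "912", "alpha"], ["non-PHI"] * 3)
    a1 = forward(d1, tiny_params, tiny_table).probabilities
    a2 = forward(d2, tiny_params, tiny_table).probabilities
    assert not np.allclose(a1[1], a2[1])


# ---------------------------------------------------------------- loss/grad


def test_loss_uniform_closed_form(tiny_config, tiny_table):
    p0 = ParameterVector(np.zeros(parameter_length(tiny_config)), tiny_config)
    for n in (1, 4):
        d = doc(["alpha"] * n, ["date"] * n)
        assert loss(p0, d, tiny_table) == pytest.approx(n * np.log(29), rel=1e-12)


def test_loss_nonnegative_random(tiny_config, tiny_table, tiny_params, scheme):
    rng = np.random.default_rng(0)
    for _ in range(5):
        n = int(rng.integers(1, 6))
        d = doc(
            [["alpha", "beta", "912"][int(rng.integers(3))] for _ in range(n)],
            [scheme.labels[int(rng.integers(29))] for _ in range(n)],
        )
        assert loss(tiny_params, d, tiny_table) >= 0.0


def test_gradient_matches_finite_differences_spot(tiny_config, tiny_table, tiny_params):
    d = doc(["alpha", "912"], ["non-PHI", "date"])
    val, g = loss_and_gradient(tiny_params, d, tiny_table, dropout_seed=5)
    rng = np.random.default_rng(1)
    eps = 1e-5
    p = tiny_params
    for j in rng.choice(len(p), size=120, replace=False):
        p.values[j] += eps
        lp = loss(p, d, tiny_table, dropout_seed=5)
        p.values[j] -= 2 * eps
        lm = loss(p, d, tiny_table, dropout_seed=5)
        p.values[j] += eps
        fd = (lp - lm) / (2 * eps)
        assert abs(fd - g[j]) / max(abs(fd), abs(g[j]), 1e-3) < 1e-4


def test_gradient_bitwise_deterministic(tiny_config, tiny_table, tiny_params):
    d = doc(["alpha", "912", "beta"], ["non-PHI", "date", "non-PHI"])
    g1 = gradient(tiny_params, d, tiny_table, dropout_seed=9)
    g2 = gradient(tiny_params, d, tiny_table, dropout_seed=9)
    assert np.array_equal(g1, g2)


def test_single_sgd_step_decreases_loss(tiny_config, tiny_table, scheme):
    """Descent property: a small step along -grad reduces the loss."""
    improved = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        p = init_parameters(tiny_config, seed)
        n = int(rng.integers(2, 6))
        d = doc(
            [["alpha", "beta", "912", "MRx"][int(rng.integers(4))] for _ in range(n)],
            [scheme.labels[int(rng.integers(29))] for _ in range(n)],
        )
        before, g = loss_and_gradient(p, d, tiny_table)
        p.values -= 0.01 * g
        after = loss(p, d, tiny_table)
        improved += after < before
    assert improved == 20


def test_dropout_changes_training_loss_only(tiny_config, tiny_table, tiny_params):
    d = doc(["alpha", "beta", "912"], ["non-PHI", "non-PHI", "date"])
    l_inf = loss(tiny_params, d, tiny_table, dropout_seed=None)
    l_tr1 = loss(tiny_params, d, tiny_table, dropout_seed=1)
    l_tr2 = loss(tiny_params, d, tiny_table, dropout_seed=2)
    assert l_inf != l_tr1 and l_tr1 != l_tr2
    assert loss(tiny_params, d, tiny_table, dropout_seed=1) == l_tr1


# ---------------------------------------------------------------- params


def test_init_parameters_contract(tiny_config):
    a = init_parameters(tiny_config, 12)
    b = init_parameters(tiny_config, 12)
    c = init_parameters(tiny_config, 13)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)
    assert len(a) == parameter_length(tiny_config)
    assert np.all(np.abs(a.values) < 1.0)
    for name in ("char_fwd.b_i", "label_bwd.b_o", "b_1", "b_2"):
        assert np.array_equal(a.view(name), np.zeros_like(a.view(name)))


def test_index_map_disjoint_and_covering(tiny_config):
    p = init_parameters(tiny_config, 0)
    spans = sorted(p.index_map.values())
    assert spans[0][0] == 0
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 == s2
    assert spans[-1][1] == len(p)


def test_stacked_views_alias_named_blocks(tiny_config):
    p = init_parameters(tiny_config, 5)
    W, b = p._stacked(p.values, "char_fwd")
    h = tiny_config.char_hidden
    assert np.array_equal(W[:h], p.view("char_fwd.W_i"))
    assert np.array_equal(W[h : 2 * h], p.view("char_fwd.W_c"))
    assert np.array_equal(W[2 * h :], p.view("char_fwd.W_o"))
    assert np.array_equal(b[:h], p.view("char_fwd.b_i"))


def test_checkpoint_round_trip(tmp_path, tiny_config, tiny_table, tiny_params, scheme):
    d = doc(["alpha", "912"], ["non-PHI", "date"])
    path = tmp_path / "ckpt.json"
    save_checkpoint(path, tiny_params, scheme)
    p2, scheme2 = load_checkpoint(path)
    assert np.array_equal(p2.values, tiny_params.values)
    assert scheme2.labels == scheme.labels
    assert predict_labels(d, p2, tiny_table, scheme2) == predict_labels(
        d, tiny_params, tiny_table, scheme
    )
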