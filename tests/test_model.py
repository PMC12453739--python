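"""Network blocks against brute-force oracles and their algebraic identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dilinet.autograd import Tensor
from dilinet.model import (DiliClassifier, MHAParams, ModelConfig, SEParams,
                           multi_head_attention, multi_head_attention_with_weights,
                           pool_tokens, se_recalibrate, sinusoidal_encoding, to_tokens)


# ------------------------------------------------------------------- oracles
def mha_oracle(x: np.ndarray, p: MHAParams) -> np.ndarray:
    """Head-by-head loop: softmax((XWq)(XWk)^T/sqrt(dk))(XWv), concat, project."""
    heads = []
    for i in range(p.h):
        sl = slice(i * p.d_k, (i + 1) * p.d_k)
        q, k, v = x @ p.w_q[:, sl], x @ p.w_k[:, sl], x @ p.w_v[:, sl]
        scores = q @ k.T / math.sqrt(p.d_k)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        heads.append(a @ v)
    return np.hstack(heads) @ p.w_o


def se_oracle(f: np.ndarray, p: SEParams) -> np.ndarray:
    hidden = np.maximum(p.w1 @ f, 0.0)
    s = 1.0 / (1.0 + np.exp(-(p.w2 @ hidden)))
    return s * f


def random_mha_params(rng, d_model, h):
    d_k = d_model // h
    return MHAParams(h, d_k, *(rng.normal(size=(d_model, d_model)) for _ in range(3)),
                     rng.normal(size=(d_model, d_model)))


# ------------------------------------------------------------------ attention
class TestMultiHeadAttention:
    def test_zero_query_key_gives_uniform_mixing(self):
        # softmax of all-zero scores is uniform: every row is the token mean
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 4))
        p = MHAParams(1, 4, np.zeros((4, 4)), np.zeros((4, 4)), np.eye(4), np.eye(4))
        out = multi_head_attention(x, p)
        assert np.allclose(out, np.tile(x.mean(axis=0), (5, 1)), atol=1e-12)

    def test_single_token_attends_to_itself(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 6))
        p = random_mha_params(rng, 6, 2)
        heads = [x @ p.w_v[:, i * 3:(i + 1) * 3] for i in range(2)]
        assert np.allclose(multi_head_attention(x, p), np.hstack(heads) @ p.w_o, atol=1e-12)

    def test_two_token_hand_computation(self):
        x = np.array([[1.0, 0.0], [0.0, 2.0]])
        p = MHAParams(1, 2, np.eye(2), np.eye(2), np.eye(2), np.eye(2))
        scores = x @ x.T / math.sqrt(2)
        e = np.exp(scores)
        a = e / e.sum(axis=1, keepdims=True)
        assert np.allclose(multi_head_attention(x, p), a @ x, atol=1e-9)

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        max_err = 0.0
        for _ in range(120):
            h = int(rng.choice([1, 2, 4]))
            n = int(rng.integers(2, 7))
            x = rng.normal(size=(n, 8))
            p = random_mha_params(rng, 8, h)
            out, weights = multi_head_attention_with_weights(x, p)
            max_err = max(max_err, np.abs(out - mha_oracle(x, p)).max())
            assert np.allclose(weights.sum(axis=-1), 1.0, atol=1e-9)
            assert (weights >= 0).all() and (weights <= 1).all()
        assert max_err < 1e-6

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        x = rng.normal(size=(n, 8))
        p = random_mha_params(rng, 8, 2)
        perm = rng.permutation(n)
        assert np.allclose(multi_head_attention(x[perm], p),
                           multi_head_attention(x, p)[perm], atol=1e-9)

    def test_nonfinite_params_rejected(self):
        w = np.full((4, 4), np.nan)
        with pytest.raises(ValueError):
            MHAParams(1, 4, w, w, w, w)


# -------------------------------------------------------------------- SE gate
class TestSqueezeExcitation:
    def test_zero_weights_give_half_gates(self):
        f = np.arange(4.0)
        p = SEParams(4, 2, np.zeros((2, 4)), np.zeros((4, 2)))
        out, gates = se_recalibrate(f, p)
        assert np.allclose(gates, 0.5) and np.allclose(out, 0.5 * f)

    def test_zero_input_stays_zero(self):
        rng = np.random.default_rng(3)
        p = SEParams(8, 4, rng.normal(size=(2, 8)), rng.normal(size=(8, 2)))
        out, _ = se_recalibrate(np.zeros(8), p)
        assert np.allclose(out, 0.0)

    def test_matches_bruteforce_oracle_and_attenuates(self):
        rng = np.random.default_rng(7)
        max_err = 0.0
        for _ in range(120):
            c, r = 4, 2
            # small weights keep the sigmoid away from float saturation
            p = SEParams(c, r, 0.5 * rng.normal(size=(c // r, c)), 0.5 * rng.normal(size=(c, c // r)))
            f = rng.normal(size=c)
            out, gates = se_recalibrate(f, p)
            max_err = max(max_err, np.abs(out - se_oracle(f, p)).max())
            assert ((gates > 0) & (gates < 1)).all()
            assert (np.abs(out) <= np.abs(f) + 1e-12).all()
        assert max_err < 1e-6

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            SEParams(6, 4, np.zeros((1, 6)), np.zeros((6, 1)))


# ---------------------------------------------------------------- token plumbing
class TestTokenBridge:
    def test_reshape_is_row_major(self):
        v = np.arange(1.0, 257.0)
        tokens = to_tokens(v)
        assert tokens.shape == (8, 32)
        assert np.array_equal(tokens[0], v[:32])

    def test_round_trip_without_pe(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=256)
        assert np.array_equal(to_tokens(v).ravel(), v)

    def test_pe_is_additive_and_matches_reference_formula(self):
        v = np.random.default_rng(1).normal(size=256)
        delta = to_tokens(v, positional_encoding=True) - to_tokens(v)
        ref = np.zeros((8, 32))
        for pos in range(8):
            for i in range(16):
                angle = pos / 10000 ** (2 * i / 32)
                ref[pos, 2 * i] = math.sin(angle)
                ref[pos, 2 * i + 1] = math.cos(angle)
        assert np.allclose(delta, ref, atol=1e-12)
        assert np.allclose(sinusoidal_encoding(8, 32), ref, atol=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            to_tokens(np.zeros(100))

    def test_pooling_is_column_mean(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 32))
        brute = np.array([x[:, j].sum() / 8 for j in range(32)])
        assert np.allclose(pool_tokens(x), brute, atol=1e-12)
        same = np.tile(x[0], (8, 1))
        assert np.allclose(pool_tokens(same), x[0])
        with pytest.raises(ValueError):
            pool_tokens(np.zeros((0, 32)))


# ------------------------------------------------------------------ assembly
@pytest.fixture()
def small_inputs():
    rng = np.random.default_rng(5)
    return (rng.random((6, 128)) < 0.3).astype(float)


class TestAssembledNetwork:
    def test_logit_shape_probability_range_and_determinism(self, small_inputs):
        model = DiliClassifier(ModelConfig(), np.random.default_rng(0))
        logits = model.forward_logit(small_inputs)
        assert logits.shape == (6,) and np.isfinite(logits).all()
        assert np.array_equal(logits, model.forward_logit(small_inputs))
        probs = model.predict_proba(small_inputs)
        assert ((probs > 0) & (probs < 1)).all()
        assert np.allclose(probs, 1 / (1 + np.exp(-logits)))

    def test_sigmoid_closed_forms(self):
        model = DiliClassifier(ModelConfig(), np.random.default_rng(0))
        # zero every contribution to the head -> logit = output bias -> set to 0 and 1
        for name, t in model._named_tensors().items():
            t.data[...] = 0.0
        model.out.b.data[...] = 0.0
        x = np.zeros((1, 128))
        assert model.predict_proba(x)[0] == pytest.approx(0.5)
        model.out.b.data[...] = 1.0
        assert model.predict_proba(x)[0] == pytest.approx(0.731059, abs=1e-6)

    def test_probability_monotone_in_logit(self):
        z = np.linspace(-8, 8, 33)
        p = 1 / (1 + np.exp(-z))
        assert (np.diff(p) > 0).all()

    def test_expansion_output_length_and_leaky_slope(self):
        model = DiliClassifier(ModelConfig(), np.random.default_rng(0))
        x = (np.random.default_rng(1).random((3, 128)) < 0.3).astype(float)
        assert model.expand_features(x).shape == (3, 256)
        # hand-set weights; make both BatchNorms exact identities in eval mode
        for fc, bn in ((model.fc1, model.bn1), (model.fc2, model.bn2)):
            fc.w.data[...] = 0.0
            fc.b.data[...] = 0.0
            bn.running_mean[...] = 0.0
            bn.running_var[...] = 1.0 - bn.eps
        model.fc1.b.data[0] = -1.0   # pre-activation -1 -> LeakyReLU -> -0.01
        model.fc2.w.data[...] = np.eye(256)
        out = model.expand_features(np.zeros((1, 128)))
        # block 1 emits -0.01 at coordinate 0; block 2's LeakyReLU maps it to -1e-4
        assert out[0, 0] == pytest.approx(-1e-4, rel=1e-9)
        assert np.allclose(out[0, 1:], 0.0)

    def test_leaky_relu_primitive_slope(self):
        assert Tensor(np.array([-1.0])).leaky_relu(0.01).data[0] == -0.01

    def test_encoder_layer_composes_from_exposed_sub_operations(self):
        model = DiliClassifier(ModelConfig(), np.random.default_rng(4))
        x = np.random.default_rng(6).normal(size=(8, 32))

        def layer_norm(v, gamma, beta, eps=1e-5):
            mu = v.mean(axis=-1, keepdims=True)
            var = ((v - mu) ** 2).mean(axis=-1, keepdims=True)
            return (v - mu) / np.sqrt(var + eps) * gamma + beta

        attn = multi_head_attention(x, model.mha_params())
        x1 = layer_norm(x + attn, model.ln1.gamma.data, model.ln1.beta.data)
        ffn = np.maximum(x1 @ model.ffn1.w.data + model.ffn1.b.data, 0.0) @ model.ffn2.w.data + model.ffn2.b.data
        expected = layer_norm(x1 + ffn, model.ln2.gamma.data, model.ln2.beta.data)
        assert np.allclose(model.encode_tokens(x), expected, atol=1e-9)
        assert model.encode_tokens(x).shape == (8, 32)

    def test_zeroed_se_gate_yields_half_residue(self, small_inputs):
        """With SE weights zeroed the gate is 0.5 everywhere, so the output
        head must see 1.5*m + skip(x)."""
        model = DiliClassifier(ModelConfig(), np.random.default_rng(9))
        model.se_w1.data[...] = 0.0
        model.se_w2.data[...] = 0.0
        logits = model.forward_logit(small_inputs)
        # recompute m through the exposed stages
        v = model.expand_features(small_inputs)
        tokens = v.reshape(-1, 8, 32) + model.pe
        pooled = pool_tokens(model.encode_tokens(tokens))
        post = pooled @ model.post.w.data + model.post.b.data
        norm = ((post - model.bn3.running_mean) / np.sqrt(model.bn3.running_var + model.bn3.eps)
                * model.bn3.gamma.data + model.bn3.beta.data)
        m = np.where(norm > 0, norm, 0.01 * norm)
        skip = small_inputs @ model.skip.w.data + model.skip.b.data
        expected = (1.5 * m + skip) @ model.out.w.data + model.out.b.data
        assert np.allclose(logits, expected.ravel(), atol=1e-9)
        assert np.allclose(model.last_gates, 0.5)

    def test_input_width_validated(self):
        model = DiliClassifier(ModelConfig(), np.random.default_rng(0))
        with pytest.raises(ValueError):
            model.forward_logit(np.zeros((2, 64)))

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            ModelConfig(n_tokens=7)
        with pytest.raises(ValueError):
            ModelConfig(n_heads=5)
        with pytest.raises(ValueError):
            ModelConfig(dropout_expansion=1.0)
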