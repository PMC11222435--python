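import numpy as np
import pytest

from squigmeth import autograd as ag
from squigmeth import model as M
from squigmeth.autograd import Tensor


def tiny_config(**kw):
    defaults = dict(latent=8, heads=2, n_enc=1, n_dec=1, d_ff=16, window=7,
                    block_width=5, codebook_size=4, dropout=0.0)
    defaults.update(kw)
    return M.ModelConfig(**defaults)


def pe_oracle(s, r, q, f, mode):
    """Scalar-loop evaluation of the positional-encoding definition."""
    P = np.zeros((s, f))
    for i in range(s):
        for j in range(f):
            if mode == "reference":
                pt = 10000.0 ** (-4.0 * (j // 4) / f)
                if j % 4 == 0:
                    P[i, j] = np.cos(i * pt)
                elif j % 4 == 1:
                    P[i, j] = np.sin(i * pt)
                elif j % 4 == 2:
                    P[i, j] = np.cos(r[i] * pt)
                else:
                    P[i, j] = np.cos(q[i] * pt)
            else:
                pt = 10000.0 ** (-2.0 * (j // 2) / f)
                P[i, j] = np.cos(i * pt) if j % 2 == 0 else np.sin(i * pt)
    return P


class TestPositionalEncoding:
    def test_origin_is_one_in_both_modes(self):
        r = q = np.zeros(3, dtype=int)
        for mode in ("reference", "basecall"):
            cfg = tiny_config(mode=mode)
            P = M.positional_encoding(3, r, q, cfg)
            assert P[0, 0] == pytest.approx(1.0)

    def test_fourth_column_is_cos_of_query_index(self):
        # j=3: floor(3/4)=0 so pt(3)=1 and the entry is cos(q_i)
        cfg = tiny_config(mode="reference")
        r = np.array([0, 2, 5])
        q = np.array([1, 3, 4])
        P = M.positional_encoding(3, r, q, cfg)
        assert np.allclose(P[:, 3], np.cos(q.astype(float)))

    @pytest.mark.parametrize("mode", ["reference", "basecall"])
    def test_matches_scalar_oracle(self, mode):
        rng = np.random.default_rng(0)
        cfg = tiny_config(mode=mode)
        s = 7
        r = np.sort(rng.integers(0, 7, s))
        q = np.sort(rng.integers(0, 7, s))
        P = M.positional_encoding(s, r if mode == "reference" else None,
                                  q if mode == "reference" else None, cfg)
        assert np.allclose(P, pe_oracle(s, r, q, cfg.latent, mode), atol=1e-12)

    def test_reference_mode_requires_indices(self):
        with pytest.raises(ValueError):
            M.positional_encoding(3, None, None, tiny_config(mode="reference"))


def identity_attention_params(f):
    eye = np.eye(f)
    return {
        "a.wq": ag.parameter(eye.copy()),
        "a.wk": ag.parameter(eye.copy()),
        "a.wv": ag.parameter(eye.copy()),
        "a.wo": ag.parameter(eye.copy()),
    }


def mha_oracle(x_k, x_q, x_v, params, prefix, H, mask=None):
    """Explicit per-head attention loop (single unbatched instance)."""
    f = x_k.shape[-1]
    d = f // H
    wq, wk, wv = (params[f"{prefix}.{n}"].data for n in ("wq", "wk", "wv"))
    heads = []
    for h in range(H):
        sl = slice(h * d, (h + 1) * d)
        Q = x_q @ wq[:, sl]
        K = x_k @ wk[:, sl]
        V = x_v @ wv[:, sl]
        scores = Q @ K.T / np.sqrt(d)
        if mask is not None:
            scores = scores + np.where(mask, 0.0, -1e9)
        w = np.exp(scores - scores.max(axis=-1, keepdims=True))
        w /= w.sum(axis=-1, keepdims=True)
        heads.append(w @ V)
    return np.concatenate(heads, axis=-1) @ params[f"{prefix}.wo"].data


class TestMultiHeadAttention:
    def test_single_key_returns_value_row(self):
        f = 4
        params = identity_attention_params(f)
        v = np.array([[1.0, -2.0, 0.5, 3.0]])
        out = M.multi_head_attention(Tensor(v), Tensor(v), Tensor(v), params, "a", 1)
        assert np.allclose(out.data, v)

    def test_two_identical_keys_average_values(self):
        f = 4
        params = identity_attention_params(f)
        k = np.ones((2, f))
        v = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])
        q = np.ones((1, f))
        out = M.multi_head_attention(Tensor(k), Tensor(q), Tensor(v), params, "a", 1)
        assert np.allclose(out.data, v.mean(axis=0, keepdims=True))

    @pytest.mark.parametrize("H", [1, 2, 4])
    def test_matches_per_head_oracle(self, H):
        rng = np.random.default_rng(H)
        f, n = 8, 5
        params = {f"a.{p}": ag.parameter(rng.normal(size=(f, f)))
                  for p in ("wq", "wk", "wv", "wo")}
        x = rng.normal(size=(n, f))
        out = M.multi_head_attention(Tensor(x), Tensor(x), Tensor(x), params, "a", H)
        assert np.allclose(out.data, mha_oracle(x, x, x, params, "a", H), atol=1e-10)

    def test_masked_keys_get_zero_weight(self):
        rng = np.random.default_rng(5)
        f = 4
        params = identity_attention_params(f)
        k = rng.normal(size=(3, f))
        k[2] = 1e3  # would dominate if not masked
        mask = np.array([True, True, False])
        out = M.multi_head_attention(
            Tensor(k), Tensor(k[:1]), Tensor(k), params, "a", 1, mask=mask
        )
        oracle = mha_oracle(k, k[:1], k, params, "a", 1, mask=mask)
        assert np.allclose(out.data, oracle)
        # attention restricted to the two unmasked rows
        w0 = np.exp(k[:1] @ k[:2].T / 2)
        w0 /= w0.sum()
        assert np.allclose(out.data, w0 @ k[:2], atol=1e-6)


class TestEncoder:
    def test_zero_layers_is_projection_plus_encoding(self):
        cfg = tiny_config(n_enc=0)
        params = M.init_params(cfg, seed=0)
        rng = np.random.default_rng(0)
        blocks = rng.normal(size=(4, cfg.block_width))
        pos = M.positional_encoding(4, np.arange(4), np.arange(4), cfg)
        local, enc = M.encode_signal(Tensor(blocks), pos, params, cfg)
        assert np.allclose(local.data, blocks @ params["w_signal"].data)
        assert np.allclose(enc.data, local.data + pos)

    def test_permutation_equivariance(self):
        cfg = tiny_config(n_enc=2)
        params = M.init_params(cfg, seed=1)
        rng = np.random.default_rng(1)
        s = 6
        blocks = rng.normal(size=(s, cfg.block_width))
        r = np.sort(rng.integers(0, 7, s))
        q = np.sort(rng.integers(0, 7, s))
        pos = M.positional_encoding(s, r, q, cfg)
        # permuting rows of (blocks + matching positional encoding rows)
        perm = rng.permutation(s)
        _, enc = M.encode_signal(Tensor(blocks), pos, params, cfg)
        _, enc_p = M.encode_signal(Tensor(blocks[perm]), pos[perm], params, cfg)
        assert np.allclose(enc.data[perm], enc_p.data, atol=1e-10)

    def test_batch_independence(self):
        cfg = tiny_config(n_enc=2)
        params = M.init_params(cfg, seed=2)
        rng = np.random.default_rng(2)
        blocks = rng.normal(size=(1, 5, cfg.block_width))
        pos = M.positional_encoding(5, np.arange(5), np.arange(5), cfg)[None]
        _, single = M.encode_signal(Tensor(blocks), pos, params, cfg)
        doubled = np.concatenate([blocks, blocks])
        _, double = M.encode_signal(Tensor(doubled), np.concatenate([pos, pos]), params, cfg)
        assert np.allclose(double.data[0], single.data[0])
        assert np.allclose(double.data[0], double.data[1])

    def test_identity_residual_stream_with_zero_weights(self):
        """With every projection zeroed the Pre-LN network is the identity."""
        cfg = tiny_config(n_enc=2, n_dec=1)
        params = M.init_params(cfg, seed=3)
        for name, p in params.items():
            if "ln" not in name:
                p.data = np.zeros_like(p.data)
        rng = np.random.default_rng(3)
        blocks = rng.normal(size=(4, cfg.block_width))
        pos = M.positional_encoding(4, np.arange(4), np.arange(4), cfg)
        local, enc = M.encode_signal(Tensor(blocks), pos, params, cfg)
        assert np.allclose(enc.data, local.data + pos)  # residual path only


class TestDecoder:
    def test_zero_layers_is_embedding_plus_encoding(self):
        cfg = tiny_config(n_dec=0)
        params = M.init_params(cfg, seed=4)
        tokens = np.array([0, 1, 2, 3, 4, 5, 1])
        enc = Tensor(np.zeros((3, cfg.latent)))
        dec = M.embed_and_decode(tokens, enc, params, cfg)
        expected = params["embed"].data[tokens] + M.sequence_positional_encoding(7, cfg.latent)
        assert np.allclose(dec.data, expected)

    def test_mask_token_uses_mask_embedding_row(self):
        cfg = tiny_config(n_dec=0)
        params = M.init_params(cfg, seed=5)
        tokens = np.array([0, 1, 5, 3, 0, 1, 2])
        dec = M.embed_and_decode(tokens, Tensor(np.zeros((2, cfg.latent))), params, cfg)
        pe = M.sequence_positional_encoding(7, cfg.latent)
        assert np.allclose(dec.data[2], params["embed"].data[5] + pe[2])

    def test_out_of_vocabulary_rejected(self):
        cfg = tiny_config()
        params = M.init_params(cfg, seed=0)
        with pytest.raises(ValueError):
            M.embed_and_decode(np.array([0, 6, 1, 2, 3, 0, 1]),
                               Tensor(np.zeros((2, cfg.latent))), params, cfg)

    def test_matches_reference_layer_loop(self):
        """Full decoder layer agrees with a straightforward re-implementation."""
        cfg = tiny_config(n_dec=1, n_enc=0)
        params = M.init_params(cfg, seed=6)
        rng = np.random.default_rng(6)
        tokens = rng.integers(0, 6, cfg.window)
        enc = rng.normal(size=(5, cfg.latent))
        got = M.embed_and_decode(tokens, Tensor(enc), params, cfg).data

        def ln(x, g, b, eps=1e-5):
            mu = x.mean(-1, keepdims=True)
            v = x.var(-1, keepdims=True)
            return (x - mu) / np.sqrt(v + eps) * g + b

        x = params["embed"].data[tokens] + M.sequence_positional_encoding(
            cfg.window, cfg.latent
        )
        h = ln(x, params["dec0.ln1.g"].data, params["dec0.ln1.b"].data)
        x = x + mha_oracle(h, h, h, params, "dec0.self", cfg.heads)
        h = ln(x, params["dec0.ln2.g"].data, params["dec0.ln2.b"].data)
        x = x + mha_oracle(enc, h, enc, params, "dec0.cross", cfg.heads)
        h = ln(x, params["dec0.ln3.g"].data, params["dec0.ln3.b"].data)
        from scipy.special import erf

        a = h @ params["dec0.ffn.w_in"].data + params["dec0.ffn.b_in"].data
        gelu = a * 0.5 * (1 + erf(a / np.sqrt(2)))
        x = x + gelu @ params["dec0.ffn.w_out"].data + params["dec0.ffn.b_out"].data
        assert np.allclose(got, x, atol=1e-10)


class TestPredictionHead:
    def test_zero_head_gives_probability_half(self):
        cfg = tiny_config()
        params = M.init_params(cfg, seed=7)
        params["mod_head.w"].data[:] = 0.0
        params["mod_head.b"].data[:] = 0.0
        rng = np.random.default_rng(7)
        dec = Tensor(rng.normal(size=(3, cfg.window, cfg.latent)))
        z = M.predict_modification(dec, params, cfg)
        assert np.allclose(z.data, 0.0)
        assert np.allclose(1 / (1 + np.exp(-z.data)), 0.5)

    def test_central_row_selected_for_standard_window(self):
        cfg = tiny_config(window=31)
        params = M.init_params(cfg, seed=8)
        rng = np.random.default_rng(8)
        dec = rng.normal(size=(31, cfg.latent))
        z = M.predict_modification(Tensor(dec), params, cfg)
        expected = dec[15] @ params["mod_head.w"].data + params["mod_head.b"].data
        assert np.allclose(z.data, expected)

    def test_non_central_token_irrelevant_without_decoder_layers(self):
        cfg = tiny_config(n_dec=0)
        params = M.init_params(cfg, seed=9)
        tokens = np.array([0, 1, 2, 1, 2, 3, 0])
        enc = Tensor(np.zeros((2, cfg.latent)))
        z1 = M.predict_modification(M.embed_and_decode(tokens, enc, params, cfg), params, cfg)
        tokens2 = tokens.copy()
        tokens2[0] = 3
        z2 = M.predict_modification(M.embed_and_decode(tokens2, enc, params, cfg), params, cfg)
        assert np.allclose(z1.data, z2.data)


class TestForwardBatch:
    def test_deterministic_inference(self, small_examples):
        from squigmeth.training import pad_batch, _stack_pos_enc

        cfg = tiny_config(window=15, n_enc=1, n_dec=1)
        params = M.init_params(cfg, seed=10)
        blocks, r, q, tokens, valid = pad_batch(small_examples[:8], cfg)
        pos = _stack_pos_enc(r, q, cfg)
        out1 = M.forward_batch(params, cfg, blocks, pos, tokens, valid)
        out2 = M.forward_batch(params, cfg, blocks, pos, tokens, valid)
        assert np.array_equal(out1["mod_logit"].data, out2["mod_logit"].data)

    def test_decoder_bypass_uses_pooled_signal(self, small_examples):
        from squigmeth.training import pad_batch, _stack_pos_enc

        cfg = tiny_config(window=15, n_enc=1, n_dec=1, use_decoder=False)
        params = M.init_params(cfg, seed=11)
        blocks, r, q, tokens, valid = pad_batch(small_examples[:4], cfg)
        pos = _stack_pos_enc(r, q, cfg)
        out = M.forward_batch(params, cfg, blocks, pos, tokens, valid)
        assert "decoded" not in out
        assert out["mod_logit"].data.shape == (4,)


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        cfg = tiny_config()
        params = M.init_params(cfg, seed=12)
        path = tmp_path / "model.npz"
        M.save_checkpoint(params, cfg, path)
        loaded, cfg2 = M.load_checkpoint(path)
        assert cfg2 == cfg
        assert set(loaded) == set(params)
        for k in params:
            assert np.array_equal(loaded[k].data, params[k].data)
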