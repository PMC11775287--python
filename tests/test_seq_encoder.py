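"""Sequence encoder: embedding, group enhancement, BiLSTM, link attention."""

import numpy as np
import pytest

from dualdta.drug_io import tokenize_smiles
from dualdta.nn import BiLSTM, Tensor
from dualdta.seq_encoder import (
    EncoderConfig,
    GroupEnhance,
    LinkAttention,
    SeqEncoder,
    pad_batch,
    seq_forward,
)
from dualdta.target_io import tokenize_protein
from dualdta.vocab import drug_vocabulary, protein_vocabulary


def brute_force_gem(x, mask, groups, eps, w, b):
    """Independent re-implementation of group enhancement with plain loops."""
    batch, length, dim = x.shape
    dg = dim // groups
    out = np.zeros_like(x)
    for s in range(batch):
        valid = np.where(mask[s])[0]
        for g in range(groups):
            xg = x[s, :, g * dg : (g + 1) * dg]
            t = np.array([xg[l] @ (xg[l].mean() * np.ones(dg)) for l in range(length)])
            mean = t[valid].mean()
            std = np.sqrt(((t[valid] - mean) ** 2).mean())
            tn = (t - mean) / (std + eps)
            gate = 1 / (1 + np.exp(-(w[g] * tn + b[g])))
            out[s, :, g * dg : (g + 1) * dg] = xg * gate[:, None]
    return out


def brute_force_link_attention(x, mask, weight, bias):
    """Independent masked softmax pooling with explicit loops."""
    length, dim = x.shape
    heads = weight.shape[1]
    scores = x @ weight + bias  # (L, H)
    attn = np.zeros((heads, length))
    for h in range(heads):
        m = mask[h] if mask.ndim == 2 else mask
        e = np.where(m, scores[:, h], -np.inf)
        e = np.exp(e - e[m].max())
        attn[h] = e / e.sum()
    return attn @ x, attn


class TestEncoderConfig:
    def test_rejects_indivisible_groups(self):
        with pytest.raises(ValueError):
            EncoderConfig(embed_dim=30, gem_groups=4)

    def test_rejects_nonpositive_epsilon(self):
        with pytest.raises(ValueError):
            EncoderConfig(gem_epsilon=0.0)


class TestEmbedding:
    def test_deterministic_and_shaped(self):
        enc = SeqEncoder(EncoderConfig(embed_dim=16, gem_groups=2, heads=2, lstm_layers=1), seed=0)
        ids = np.array([[3, 4, 5, 1]])
        a = enc.target_enc.embedding(ids).data
        b = enc.target_enc.embedding(ids).data
        np.testing.assert_array_equal(a, b)
        assert a.shape == (1, 4, 16)

    def test_identity_fc_reproduces_table_rows(self):
        enc = SeqEncoder(EncoderConfig(embed_dim=16, gem_groups=2, heads=2, lstm_layers=1), seed=0)
        ent = enc.target_enc
        ent.fc.weight.data = np.eye(16)
        ent.fc.bias.data = np.zeros(16)
        ids = np.array([[7, 2]])
        out = ent.fc(ent.embedding(ids)).data
        np.testing.assert_allclose(out[0, 0], ent.embedding.weight.data[7])
        np.testing.assert_allclose(out[0, 1], ent.embedding.weight.data[2])

    def test_out_of_vocab_id_rejected(self):
        enc = SeqEncoder(EncoderConfig(embed_dim=16, gem_groups=2, heads=2, lstm_layers=1), seed=0)
        with pytest.raises(ValueError):
            enc.target_enc.embedding(np.array([[10_000]]))


class TestGroupEnhance:
    def test_shape_preserved(self, rng):
        gem = GroupEnhance(12, 3, 1e-5)
        x = Tensor(rng.normal(size=(2, 7, 12)))
        mask = np.ones((2, 7), dtype=bool)
        assert gem(x, mask).shape == (2, 7, 12)

    def test_constant_input_degenerate_std_is_finite(self):
        gem = GroupEnhance(8, 2, 1e-5)
        x = Tensor(np.ones((1, 5, 8)))
        out = gem(x, np.ones((1, 5), dtype=bool)).data
        assert np.all(np.isfinite(out))

    def test_matches_brute_force_reimplementation(self, rng):
        gem = GroupEnhance(6, 1, 1e-5)
        gem.weight.data = rng.normal(size=1)
        gem.bias.data = rng.normal(size=1)
        x = rng.normal(size=(1, 3, 6))
        mask = np.ones((1, 3), dtype=bool)
        got = gem(Tensor(x), mask).data
        want = brute_force_gem(x, mask, 1, 1e-5, gem.weight.data, gem.bias.data)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_matches_brute_force_with_groups_and_padding(self, rng):
        gem = GroupEnhance(8, 4, 1e-5)
        gem.weight.data = rng.normal(size=4)
        gem.bias.data = rng.normal(size=4)
        x = rng.normal(size=(2, 6, 8))
        mask = np.ones((2, 6), dtype=bool)
        mask[1, 4:] = False
        got = gem(Tensor(x), mask).data
        want = brute_force_gem(x, mask, 4, 1e-5, gem.weight.data, gem.bias.data)
        np.testing.assert_allclose(got[mask], want[mask], atol=1e-6)

    def test_zero_length_rejected(self):
        gem = GroupEnhance(8, 2, 1e-5)
        with pytest.raises(ValueError):
            gem(Tensor(np.zeros((1, 0, 8))), np.zeros((1, 0), dtype=bool))


class TestBiLSTM:
    def test_direction_reversal_property(self, rng):
        """The backward direction on x equals the forward direction on the
        reversed sequence (read back in reverse), when both share weights."""
        lstm = BiLSTM(6, 8, rng)
        state = lstm.fwd.state_dict()
        lstm.bwd.load_state_dict(state)
        x = rng.normal(size=(1, 9, 6))
        mask = np.ones((1, 9), dtype=bool)
        out = lstm(Tensor(x), mask).data
        fwd_half, bwd_half = out[..., :4], out[..., 4:]
        out_rev = lstm(Tensor(x[:, ::-1]), mask).data
        np.testing.assert_allclose(bwd_half, out_rev[:, ::-1][..., :4], atol=1e-12)

    def test_single_step_sequence(self, rng):
        lstm = BiLSTM(4, 6, rng)
        out = lstm(Tensor(rng.normal(size=(2, 1, 4))), np.ones((2, 1), dtype=bool))
        assert out.shape == (2, 1, 6)
        assert np.all(np.isfinite(out.data))

    def test_output_width_independent_of_length(self, rng):
        lstm = BiLSTM(4, 6, rng)
        for length in (1, 3, 11):
            out = lstm(
                Tensor(rng.normal(size=(1, length, 4))),
                np.ones((1, length), dtype=bool),
            )
            assert out.shape[2] == 6


class TestLinkAttention:
    def test_single_unmasked_position_gets_weight_one(self, rng):
        attn = LinkAttention(8, 3, rng)
        x = Tensor(rng.normal(size=(5, 8)))
        mask = np.zeros(5, dtype=bool)
        mask[2] = True
        pooled, weights = attn(x, mask)
        np.testing.assert_array_equal(weights.data[:, 2], 1.0)
        assert np.all(weights.data[:, [0, 1, 3, 4]] == 0.0)
        for h in range(3):
            np.testing.assert_allclose(pooled.data[h], x.data[2])

    def test_uniform_scores_give_uniform_weights(self, rng):
        attn = LinkAttention(8, 2, rng)
        attn.query.weight.data[:] = 0.0
        attn.query.bias.data[:] = 0.0
        mask = np.array([True, True, True, False])
        _, weights = attn(Tensor(rng.normal(size=(4, 8))), mask)
        np.testing.assert_allclose(weights.data[:, :3], 1 / 3)
        assert np.all(weights.data[:, 3] == 0.0)

    def test_matches_brute_force(self, rng):
        attn = LinkAttention(5, 2, rng)
        x = rng.normal(size=(4, 5))
        mask = np.array([[True, True, False, True], [True, False, True, True]])
        pooled, weights = attn(Tensor(x), mask)
        want_pooled, want_attn = brute_force_link_attention(
            x, mask, attn.query.weight.data, attn.query.bias.data
        )
        np.testing.assert_allclose(weights.data, want_attn, atol=1e-6)
        np.testing.assert_allclose(pooled.data, want_pooled, atol=1e-6)

    def test_fully_masked_head_rejected(self, rng):
        attn = LinkAttention(5, 2, rng)
        mask = np.array([[True, True], [False, False]])
        with pytest.raises(ValueError, match="masked"):
            attn(Tensor(rng.normal(size=(2, 5))), mask)

    def test_masked_positions_get_zero_gradient(self, rng):
        attn = LinkAttention(5, 2, rng)
        x = Tensor(rng.normal(size=(1, 4, 5)), requires_grad=True)
        mask = np.array([[True, False, True, False]])
        pooled, _ = attn(x, mask)
        pooled.sum().backward()
        assert np.all(x.grad[0, 1] == 0.0)
        assert np.all(x.grad[0, 3] == 0.0)
        assert np.any(x.grad[0, 0] != 0.0)


class TestSeqForward:
    @pytest.fixture(scope="class")
    def encoder(self):
        return SeqEncoder(
            EncoderConfig(embed_dim=16, lstm_layers=1, heads=2, gem_groups=2, dropout=0.0),
            seed=1,
        ).eval()

    @pytest.fixture(scope="class")
    def tokens(self):
        return tokenize_smiles("CCOc1ccccc1"), tokenize_protein("MKVLWAALLVT")

    def test_out_seq_width_is_three_h_d(self, encoder, tokens):
        drug, target = tokens
        out = seq_forward(encoder, drug, target)
        assert out.out_seq.shape == (1, 3 * 2 * 16)

    def test_attention_rows_sum_to_one_and_masked_exactly_zero(self, encoder, tokens):
        drug, target = tokens
        d_ids, d_mask, d_eos = pad_batch([drug], drug_vocabulary().pad_id, 20)
        t_ids, t_mask, t_eos = pad_batch([target], protein_vocabulary().pad_id, 20)
        out = encoder(t_ids, t_mask, d_ids, d_mask, t_eos, d_eos)
        for attn, mask in (
            (out.attn_target, t_mask),
            (out.attn_drug, d_mask),
            (out.attn_cat, np.concatenate([t_mask, d_mask], axis=1)),
        ):
            sums = attn.data.sum(axis=2)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)
            assert np.all(attn.data[:, :, ~mask[0]] == 0.0)

    def test_zero_ffn_weights_make_pure_residual(self, tokens):
        encoder = SeqEncoder(
            EncoderConfig(embed_dim=16, lstm_layers=1, heads=2, gem_groups=2, dropout=0.0),
            seed=2,
        ).eval()
        encoder.ffn.weight.data[:] = 0.0
        encoder.ffn.bias.data[:] = 0.0
        drug, target = tokens
        out = seq_forward(encoder, drug, target)
        b = 1
        r_seq = np.concatenate(
            [
                out.pooled_target.data.reshape(b, -1),
                out.pooled_drug.data.reshape(b, -1),
                out.pooled_cat.data.reshape(b, -1),
            ],
            axis=1,
        )
        np.testing.assert_allclose(out.out_seq.data, r_seq, atol=1e-12)

    def test_padding_invariance_of_out_seq_and_attention(self, encoder, tokens):
        drug, target = tokens
        d_ids, d_mask, d_eos = pad_batch([drug], drug_vocabulary().pad_id)
        t_ids, t_mask, t_eos = pad_batch([target], protein_vocabulary().pad_id)
        base = encoder(t_ids, t_mask, d_ids, d_mask, t_eos, d_eos)

        def pad(arr, n, fill):
            return np.concatenate(
                [arr, np.full((1, n), fill, dtype=arr.dtype)], axis=1
            )

        t_ids2 = pad(t_ids, 6, protein_vocabulary().pad_id)
        d_ids2 = pad(d_ids, 4, drug_vocabulary().pad_id)
        t_mask2, d_mask2 = pad(t_mask, 6, False), pad(d_mask, 4, False)
        padded = encoder(t_ids2, t_mask2, d_ids2, d_mask2, t_eos, d_eos)
        np.testing.assert_allclose(padded.out_seq.data, base.out_seq.data, atol=1e-5)
        lt, ld = t_ids.shape[1], d_ids.shape[1]
        np.testing.assert_allclose(
            padded.attn_target.data[:, :, :lt], base.attn_target.data, atol=1e-5
        )
        np.testing.assert_allclose(
            padded.attn_drug.data[:, :, :ld], base.attn_drug.data, atol=1e-5
        )
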