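"""Core network: causality, masking, loss arithmetic, gradients, training."""

import numpy as np
import pytest

from halosynth.network import (HALOConfig, HALONetwork, build_fine_masks,
                               check_fine_masks, masked_bce_loss,
                               record_log_likelihood, train_network)
from halosynth.records import encode_record
from halosynth.vocab import build_vocabulary

from conftest import toy_record


def random_batch(net, B=3, L=5, density=0.3, seed=0):
    rng = np.random.default_rng(seed)
    C = net.n_codes
    R = (rng.random((B, L, C)) < density).astype(float)
    R[:, 0, :] = 0.0
    R[:, 0, -2] = 1.0  # start position in the tiny vocab layout
    valid = np.ones((B, L))
    return R, valid


class TestMasks:
    def test_mask_structure(self):
        masks = build_fine_masks(n_emb=4, n_codes=6, n_layers=3)
        check_fine_masks(masks, 4)
        # hidden layers: non-strict upper triangle
        assert masks[0][2, 2] == 1 and masks[0][3, 7] == 1 and masks[0][7, 3] == 0
        # final layer: strict within the code block, embedding diag kept
        assert masks[-1][5, 5] == 0 and masks[-1][3, 3] == 1
        # embedding inputs always reach code outputs
        assert np.all(masks[-1][:4, 4:] == 1)

    def test_check_rejects_violations(self):
        masks = build_fine_masks(4, 6, 2)
        masks[1][9, 9] = 1.0  # self-connection at the output layer
        with pytest.raises(ValueError):
            check_fine_masks(masks, 4)

    def test_masked_entries_stay_zero_through_training(self, tiny_net):
        R, valid = random_batch(tiny_net, B=6, L=5)
        train_network(tiny_net, R, valid, epochs=3, batch_size=3, lr=1e-3,
                      seed=0)
        for n, mask in enumerate(tiny_net.fine_masks):
            w = tiny_net.params[f"fine{n}.W"]
            assert np.all(w[mask == 0] == 0)


class TestVisitHistories:
    def test_output_shape(self, tiny_net):
        R, _ = random_batch(tiny_net, B=2, L=5)
        H = tiny_net.visit_histories(R)
        assert H.shape == (2, 5, tiny_net.config.n_emb)

    def test_causality_under_perturbation(self, tiny_net):
        rng = np.random.default_rng(2)
        R, _ = random_batch(tiny_net, B=1, L=5)
        H = tiny_net.visit_histories(R)
        for _ in range(50):
            t = rng.integers(1, 5)
            j = rng.integers(0, tiny_net.n_codes)
            R2 = R.copy()
            R2[0, t, j] = 1.0 - R2[0, t, j]
            H2 = tiny_net.visit_histories(R2)
            np.testing.assert_array_equal(H[0, :t], H2[0, :t])

    def test_zero_weights_reduce_to_normalized_embeddings(self, tiny_vocab,
                                                          tiny_config):
        net = HALONetwork(tiny_config, len(tiny_vocab),
                          rng=np.random.default_rng(1))
        for k in net.params:
            if ".W" in k and k.startswith("blk"):
                net.params[k][:] = 0.0
        R, _ = random_batch(net, B=1, L=4)
        H = net.visit_histories(R)
        # with all block weights zero the residual stream is the embedding;
        # the final layernorm standardizes it (unit gain, zero shift)
        x = R[0] @ net.params["We"] + net.params["Wp"][:4]
        xc = x - x.mean(-1, keepdims=True)
        expected = xc / np.sqrt((xc ** 2).mean(-1, keepdims=True) + 1e-5)
        np.testing.assert_allclose(H[0], expected, atol=1e-10)


class TestCodeProbabilities:
    def test_zero_fine_weights_give_half(self, tiny_net):
        for n in range(tiny_net.config.N):
            tiny_net.params[f"fine{n}.W"][:] = 0.0
            tiny_net.params[f"fine{n}.b"][:] = 0.0
        R, _ = random_batch(tiny_net, B=2, L=5)
        O = tiny_net.forward(R)
        np.testing.assert_allclose(O, 0.5)

    def test_output_shape_is_rows_minus_one(self, tiny_net):
        R, _ = random_batch(tiny_net, B=2, L=5)
        assert tiny_net.forward(R).shape == (2, 4, tiny_net.n_codes)

    def test_probabilities_in_unit_interval(self, tiny_net):
        R, _ = random_batch(tiny_net, B=2, L=5)
        O = tiny_net.forward(R)
        assert np.all((O > 0) & (O < 1))

    def test_forward_is_deterministic_in_eval_mode(self, tiny_net):
        R, _ = random_batch(tiny_net)
        np.testing.assert_array_equal(tiny_net.forward(R), tiny_net.forward(R))

    def test_autoregressive_no_leak_exhaustive(self, tiny_net):
        """O[t, i] must be invariant to any future bit: same row with
        column >= i, or any later row.  Exhaustive over a 12-code vocab."""
        C = tiny_net.n_codes
        L = 5
        R, _ = random_batch(tiny_net, B=1, L=L, seed=4)
        O = tiny_net.forward(R)[0]
        for t in range(1, L):  # flip bits of record row t
            for j in range(C):
                R2 = R.copy()
                R2[0, t, j] = 1.0 - R2[0, t, j]
                O2 = tiny_net.forward(R2)[0]
                # earlier target rows are untouched
                np.testing.assert_array_equal(O[: t - 1], O2[: t - 1])
                # same target row: only outputs strictly after j may change
                np.testing.assert_array_equal(O[t - 1, : j + 1],
                                              O2[t - 1, : j + 1])

    def test_coarse_variant_ignores_own_row(self, tiny_vocab):
        cfg = HALOConfig(M=1, N=2, n_emb=8, n_heads=2, max_T=4,
                         dropout=0.0, coarse=True)
        net = HALONetwork(cfg, len(tiny_vocab), rng=np.random.default_rng(0))
        R, _ = random_batch(net, B=1, L=5)
        O = net.forward(R)[0]
        for t in range(1, 5):
            for j in range(net.n_codes):
                R2 = R.copy()
                R2[0, t, j] = 1.0 - R2[0, t, j]
                O2 = net.forward(R2)[0]
                np.testing.assert_array_equal(O[t - 1], O2[t - 1])


class TestMaskedBCELoss:
    def test_perfect_prediction_at_clip_floor(self):
        t = np.array([[[1.0, 0.0, 1.0]]])
        loss = masked_bce_loss(t, t, np.ones((1, 1)), eps=1e-12)
        assert 0 <= loss <= 1e-11

    def test_half_probability_closed_form(self):
        O = np.full((1, 1, 1), 0.5)
        t = np.ones((1, 1, 1))
        assert np.isclose(masked_bce_loss(O, t, np.ones((1, 1))), np.log(2))

    def test_hand_computed_toy(self):
        O = np.array([[[0.9, 0.2, 0.5], [0.4, 0.8, 0.1]]])
        t = np.array([[[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]]])
        by_hand = -(np.log(0.9) + np.log(0.8) + np.log(0.5)
                    + np.log(0.6) + np.log(0.8) + np.log(0.9)) / 6
        assert np.isclose(masked_bce_loss(O, t, np.ones((1, 2))), by_hand,
                          atol=1e-12)

    def test_padded_rows_do_not_contribute(self):
        O = np.array([[[0.9, 0.1], [0.123, 0.456]]])
        t = np.array([[[1.0, 0.0], [1.0, 1.0]]])
        mask = np.array([[1.0, 0.0]])
        expected = -(np.log(0.9) + np.log(0.9)) / 2
        assert np.isclose(masked_bce_loss(O, t, mask), expected)

    def test_no_valid_rows_rejected(self):
        with pytest.raises(ValueError):
            masked_bce_loss(np.ones((1, 1, 1)) * 0.5, np.ones((1, 1, 1)),
                            np.zeros((1, 1)))


class TestLogLikelihood:
    def test_uniform_model_closed_form(self, tiny_vocab, tiny_config):
        net = HALONetwork(tiny_config, len(tiny_vocab),
                          rng=np.random.default_rng(0))
        for n in range(net.config.N):
            net.params[f"fine{n}.W"][:] = 0.0
            net.params[f"fine{n}.b"][:] = 0.0
        m = encode_record(toy_record(), tiny_vocab, max_T=4)
        lp = record_log_likelihood(net, m)
        n_positions = (m.T + 2) * len(tiny_vocab)  # valid non-start rows
        assert np.isclose(lp, n_positions * np.log(0.5))

    def test_sequential_reveal_matches_batched(self, tiny_net, tiny_vocab):
        """Chain rule: revealing codes one at a time and accumulating
        conditional log-probabilities equals the one-pass likelihood."""
        m = encode_record(toy_record(), tiny_vocab, max_T=4)
        batched = record_log_likelihood(tiny_net, m)

        C = tiny_net.n_codes
        bits = m.bits.astype(float)
        L_valid = m.T + 3
        total = 0.0
        for t in range(1, L_valid):  # target rows (start row never a target)
            for i in range(C):
                partial = bits.copy()
                partial[t, i:] = 0.0  # codes >= i of row t not yet revealed
                partial[t + 1:, :] = 0.0  # future rows unknown
                O = tiny_net.forward(partial[None])[0]
                p = np.clip(O[t - 1, i], 1e-12, 1 - 1e-12)
                total += np.log(p) if bits[t, i] else np.log1p(-p)
        assert np.isclose(batched, total, atol=1e-9)

    def test_same_input_same_value(self, tiny_net, tiny_vocab):
        m = encode_record(toy_record(), tiny_vocab, max_T=4)
        assert record_log_likelihood(tiny_net, m) == record_log_likelihood(
            tiny_net, m)


class TestGradients:
    @pytest.mark.parametrize("coarse", [False, True])
    def test_analytic_matches_numerical(self, tiny_vocab, coarse):
        cfg = HALOConfig(M=1, N=2, n_emb=8, n_heads=2, max_T=4,
                         dropout=0.0, coarse=coarse)
        net = HALONetwork(cfg, len(tiny_vocab), rng=np.random.default_rng(0))
        R, valid = random_batch(net, B=2, L=5)
        valid[1, 4] = 0
        R[1, 4] = 0
        _, grads = net.loss_and_grads(R, valid)
        check_rng = np.random.default_rng(1)
        for k, v in net.params.items():
            flat = v.ravel()
            for i in check_rng.choice(flat.size, size=min(4, flat.size),
                                      replace=False):
                orig = flat[i]
                h = 1e-5 * max(1.0, abs(orig))
                flat[i] = orig + h
                lp, _ = net.loss_and_grads(R, valid)
                flat[i] = orig - h
                lm, _ = net.loss_and_grads(R, valid)
                flat[i] = orig
                assert np.isclose((lp - lm) / (2 * h), grads[k].ravel()[i],
                                  atol=1e-7), k


class TestTraining:
    def test_single_record_memorization(self, tiny_vocab):
        cfg = HALOConfig(M=1, N=2, n_emb=8, n_heads=2, max_T=4, dropout=0.0)
        net = HALONetwork(cfg, len(tiny_vocab), rng=np.random.default_rng(0))
        m = encode_record(toy_record(), tiny_vocab, max_T=4)
        R = m.bits[None].astype(float)
        valid = m.valid_rows[None].astype(float)
        trace = train_network(net, R, valid, epochs=400, batch_size=1,
                              lr=1e-2, seed=0)
        assert trace[-1] < 0.02  # close to the clipping floor

    def test_loss_decreases_on_cohort(self, tiny_net):
        R, valid = random_batch(tiny_net, B=12, L=5, seed=7)
        trace = train_network(tiny_net, R, valid, epochs=5, batch_size=4,
                              lr=1e-3, seed=0)
        assert trace[-1] < trace[0]

    def test_same_seed_identical_parameters(self, tiny_vocab, tiny_config):
        results = []
        for _ in range(2):
            net = HALONetwork(tiny_config, len(tiny_vocab),
                              rng=np.random.default_rng(5))
            R, valid = random_batch(net, B=8, L=5, seed=3)
            train_network(net, R, valid, epochs=2, batch_size=4, lr=1e-3,
                          seed=9)
            results.append({k: v.copy() for k, v in net.params.items()})
        for k in results[0]:
            np.testing.assert_array_equal(results[0][k], results[1][k])

    def test_likelihood_improves_with_training(self, tiny_vocab, tiny_config):
        net = HALONetwork(tiny_config, len(tiny_vocab),
                          rng=np.random.default_rng(0))
        R, valid = random_batch(net, B=16, L=5, seed=11)
        before = net.log_likelihoods(R, valid).mean()
        train_network(net, R, valid, epochs=10, batch_size=8, lr=1e-3, seed=0)
        after = net.log_likelihoods(R, valid).mean()
        assert after > before
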