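"""The convolutional MIL-ensemble predictor against brute-force oracles."""

import numpy as np
import pytest

from tcrmil.cme_model import (
    CMEConfig,
    bag_loss,
    bag_score,
    conv_feature_maps,
    forward_binary,
    forward_binary_batch,
    forward_multiclass,
    init_params,
    load_checkpoint,
    one_max_pool,
    save_checkpoint,
    sequence_loss,
    sequence_score,
    sigmoid,
)
from tcrmil.embedding import MiniEncoder, pad_and_stack, tokenize


def small_config(**kw):
    defaults = dict(embed_dim=8, k=4, Lmax=24, dropout_rate=0.0)
    defaults.update(kw)
    return CMEConfig(**defaults)


class TestSigmoid:
    def test_fixed_points_and_symmetry(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(50.0) == pytest.approx(1.0)
        assert sigmoid(1.0) + sigmoid(-1.0) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing_into_open_interval(self, rng):
        x = np.sort(rng.normal(scale=3, size=50))
        y = sigmoid(x)
        assert np.all(np.diff(y) > 0)
        assert np.all((y > 0) & (y < 1))


class TestConvFeatureMaps:
    def test_worked_example_feature_counts(self, rng):
        """A 10-residue sequence yields 9/8/7 positions for kernels 2/3/4."""
        cfg = small_config()
        params = init_params(cfg, 0)
        E = rng.normal(size=(24, 8))
        maps = conv_feature_maps(E, cfg, params, true_len=10)
        sizes = [len(m) for m in maps]
        assert sizes == [9, 9, 9, 8, 8, 7]

    def test_valid_convolution_length_law(self, rng):
        """positions = span - kernel + 1, against a sliding-window oracle."""
        cfg = small_config()
        params = init_params(cfg, 1)
        for span in (10, 15, 24):
            E = rng.normal(size=(24, 8))
            maps = conv_feature_maps(E, cfg, params, true_len=span)
            i = 0
            for s, f in zip(cfg.kernel_sizes, cfg.filters_per_size):
                for _ in range(f):
                    assert len(maps[i]) == span - s + 1
                    i += 1

    def test_matches_window_dot_oracle(self, rng):
        cfg = small_config()
        params = init_params(cfg, 2)
        E = rng.normal(size=(24, 8))
        maps = conv_feature_maps(E, cfg, params, true_len=12)
        # oracle: explicit per-position window inner products
        W, b = params.conv_W[0], params.conv_b[0]  # first kernel size (s=2)
        for p in range(11):
            want = sigmoid(float((E[p : p + 2] * W[0]).sum()) + b[0])
            assert maps[0][p] == pytest.approx(want, abs=1e-12)

    def test_zero_embedding_zero_bias_gives_half(self):
        cfg = small_config()
        params = init_params(cfg, 0)
        for W in params.conv_W:
            W[:] = W  # weights irrelevant on zero input
        maps = conv_feature_maps(np.zeros((24, 8)), cfg, params, true_len=10)
        for m in maps:
            assert m == pytest.approx(np.full_like(m, 0.5))

    def test_kernel_longer_than_sequence_rejected(self):
        cfg = small_config()
        params = init_params(cfg, 0)
        with pytest.raises(ValueError):
            conv_feature_maps(np.zeros((24, 8)), cfg, params, true_len=3)


class TestOneMaxPool:
    def test_simple_and_constant_maps(self):
        assert one_max_pool([0.1, 0.9, 0.4]) == 0.9
        assert one_max_pool([0.3, 0.3]) == 0.3

    def test_matches_linear_scan_oracle(self, rng):
        for _ in range(100):
            v = rng.normal(size=rng.integers(1, 30))
            best = v[0]
            for x in v[1:]:
                if x > best:
                    best = x
            assert one_max_pool(v) == best

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            one_max_pool([])


class TestSequenceScore:
    def test_zero_weights_give_half(self):
        cfg = small_config()
        params = init_params(cfg, 0)
        params.w_seq[:] = 0.0
        assert sequence_score(np.ones(6), params) == 0.5

    def test_matches_direct_formula(self, rng):
        cfg = small_config()
        params = init_params(cfg, 3)
        for _ in range(100):
            p = rng.normal(size=6)
            want = 1.0 / (1.0 + np.exp(-(p @ params.w_seq + params.b_seq)))
            assert sequence_score(p, params) == pytest.approx(want, abs=1e-12)

    def test_dropout_is_training_only_noise(self, rng):
        cfg = small_config()
        params = init_params(cfg, 3)
        p = rng.normal(size=6)
        eval_score = sequence_score(p, params)
        drop = sequence_score(p, params, dropout_rate=0.99, rng=np.random.default_rng(0))
        assert drop != eval_score


class TestLosses:
    def test_half_probability_costs_ln2(self):
        assert sequence_loss(0.5, 1) == pytest.approx(np.log(2))
        assert bag_loss(0.5, 0) == pytest.approx(np.log(2))

    def test_loss_vanishes_as_prediction_approaches_label(self):
        assert sequence_loss(1 - 1e-9, 1) < 1e-6
        assert bag_loss(1e-9, 0) < 1e-6

    def test_exact_zero_one_clamped_finite(self):
        assert np.isfinite(sequence_loss(0.0, 1))
        assert np.isfinite(bag_loss(1.0, 0))

    def test_matches_elementwise_oracle(self, rng):
        for _ in range(100):
            p = float(rng.uniform(0.01, 0.99))
            y = int(rng.integers(0, 2))
            want = -(y * np.log(p) + (1 - y) * np.log(1 - p))
            assert sequence_loss(p, y) == pytest.approx(want, abs=1e-12)


class TestBagScore:
    def test_zero_heads_give_half(self):
        cfg = small_config()
        params = init_params(cfg, 0)
        params.head_W[:] = 0.0
        params.head_b[:] = 0.0
        y = np.array([0.2, 0.8, 0.5, 0.9])
        assert bag_score(y, np.ones(4, bool), params) == 0.5

    def test_identical_heads_equal_single_head(self, rng):
        cfg = small_config(n_heads=5)
        params = init_params(cfg, 1)
        params.head_W[:] = params.head_W[0]
        params.head_b[:] = params.head_b[0]
        y = rng.uniform(size=4)
        single = sigmoid(float(params.head_W[0] @ y + params.head_b[0]))
        assert bag_score(y, np.ones(4, bool), params) == pytest.approx(single, abs=1e-12)

    def test_matches_loop_and_average_oracle(self, rng):
        cfg = small_config(n_heads=3)
        params = init_params(cfg, 2)
        for _ in range(100):
            y = rng.uniform(size=4)
            zs = [float(params.head_W[j] @ y + params.head_b[j]) for j in range(3)]
            want = 1.0 / (1.0 + np.exp(-np.mean(zs)))
            assert bag_score(y, np.ones(4, bool), params) == pytest.approx(want, abs=1e-12)

    def test_mean_aggregator_is_plain_average(self, rng):
        cfg = small_config()
        params = init_params(cfg, 0)
        y = np.array([0.2, 0.4, 0.6, 0.0])
        mask = np.array([True, True, True, False])
        assert bag_score(y, mask, params, aggregator="mean") == pytest.approx(0.4)

    def test_all_masked_bag_rejected(self):
        cfg = small_config()
        params = init_params(cfg, 0)
        with pytest.raises(ValueError):
            bag_score(np.zeros(4), np.zeros(4, bool), params)


class TestForwardBinary:
    def _embedded_bag(self, seqs, k=4):
        enc = MiniEncoder(embed_dim=8, seed=0)
        return pad_and_stack([enc.embed(tokenize(s)) for s in seqs], k=k)

    def test_identical_instances_get_identical_scores(self):
        bag = self._embedded_bag(["CASSGTEQFF"] * 4)
        cfg = small_config()
        params = init_params(cfg, 1)
        _, yh = forward_binary(bag, cfg, params)
        assert np.allclose(yh, yh[0])

    def test_equals_composition_of_atomic_ops(self):
        """Pipeline output == composing conv/pool/score/aggregate by hand."""
        seqs = ["CASSGTEQFF", "CASSLAPGATNEKLFF", "CAAAAAAAAF"]
        bag = self._embedded_bag(seqs, k=4)
        cfg = small_config()
        params = init_params(cfg, 5)
        Y, yh = forward_binary(bag, cfg, params)
        manual = np.zeros(4)
        for i, s in enumerate(seqs):
            maps = conv_feature_maps(bag.tensor[i], cfg, params, true_len=bag.lengths[i])
            pooled = np.array([one_max_pool(m) for m in maps])
            manual[i] = sequence_score(pooled, params)
        want = bag_score(manual, bag.mask, params)
        assert yh[:3] == pytest.approx(manual[:3], abs=1e-10)
        assert yh[3] == 0.0  # masked slot contributes zero
        assert Y == pytest.approx(want, abs=1e-10)

    def test_masked_slot_embedding_is_irrelevant(self, rng):
        bag = self._embedded_bag(["CASSGTEQFF", "CAAAAAAAAF"], k=4)
        cfg = small_config()
        params = init_params(cfg, 2)
        Y1, _ = forward_binary(bag, cfg, params)
        bag.tensor[3] = rng.normal(size=bag.tensor[3].shape)  # masked slot
        Y2, _ = forward_binary(bag, cfg, params)
        assert Y1 == Y2

    def test_monotone_in_sequence_scores_under_nonneg_heads(self, rng):
        cfg = small_config(n_heads=2)
        params = init_params(cfg, 3)
        params.head_W = np.abs(params.head_W)
        y = rng.uniform(size=4)
        base = bag_score(y, np.ones(4, bool), params)
        y2 = y.copy()
        y2[1] += 0.1
        assert bag_score(y2, np.ones(4, bool), params) >= base

    def test_scores_strictly_inside_unit_interval(self, rng):
        bag = self._embedded_bag(["CASSGTEQFF", "CASSLAPGATNEKLFF"], k=4)
        cfg = small_config()
        for seed in range(5):
            params = init_params(cfg, seed)
            Y, yh = forward_binary(bag, cfg, params)
            assert 0.0 < Y < 1.0
            assert np.all((yh[bag.mask] > 0) & (yh[bag.mask] < 1))


class TestForwardMulticlass:
    def _bag(self):
        enc = MiniEncoder(embed_dim=8, seed=0)
        return pad_and_stack(
            [enc.embed(tokenize(s)) for s in ("CASSGTEQFF", "CAAAAAAAAF")], k=4
        )

    def test_identical_heads_tie_broken_to_lowest_class(self):
        cfg = small_config(task="multiclass", n_classes=3)
        params = init_params(cfg, 0)
        params.w_seq[:] = 0.0
        params.b_seq[:] = 0.0
        params.head_W[:] = 0.0
        params.head_b[:] = 0.0
        decision, scores = forward_multiclass(self._bag(), cfg, params)
        assert np.all(scores == scores[0])
        assert decision == 0

    def test_dominant_class_head_wins(self):
        cfg = small_config(task="multiclass", n_classes=3)
        params = init_params(cfg, 1)
        params.head_b[:, 2] += 100.0
        decision, _ = forward_multiclass(self._bag(), cfg, params)
        assert decision == 2

    def test_argmax_agrees_with_exhaustive_comparison(self, rng):
        cfg = small_config(task="multiclass", n_classes=4)
        bag = self._bag()
        for seed in range(10):
            params = init_params(cfg, seed)
            decision, scores = forward_multiclass(bag, cfg, params)
            best = 0
            for c in range(1, 4):
                if scores[c] > scores[best]:
                    best = c
            assert decision == best


class TestCheckpoint:
    def test_round_trip_preserves_config_and_weights(self, tmp_path):
        cfg = small_config(n_heads=3)
        params = init_params(cfg, 9)
        path = tmp_path / "model.npz"
        save_checkpoint(path, cfg, params, fingerprint={"backend": "mini_encoder"}, seed=9)
        cfg2, params2, meta = load_checkpoint(path)
        assert cfg2 == cfg
        assert meta["seed"] == 9
        assert meta["embedding_fingerprint"]["backend"] == "mini_encoder"
        for (_, a), (_, b) in zip(params.leaves(), params2.leaves()):
            assert np.array_equal(a, b)

    def test_loaded_model_predicts_identically(self, tmp_path):
        enc = MiniEncoder(embed_dim=8, seed=0)
        bag = pad_and_stack([enc.embed(tokenize("CASSGTEQFF"))], k=4)
        cfg = small_config()
        params = init_params(cfg, 4)
        Y1, _ = forward_binary(bag, cfg, params)
        save_checkpoint(tmp_path / "m.npz", cfg, params)
        cfg2, params2, _ = load_checkpoint(tmp_path / "m.npz")
        Y2, _ = forward_binary(bag, cfg2, params2)
        assert Y1 == Y2
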