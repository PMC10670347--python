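"""Cross-fusion arithmetic, head isolation, the probability septet, and the
threshold majority vote."""

import itertools

import numpy as np
import pytest

import hilofuse as hf
from hilofuse.fusion_model import (
    FUSION_PAIRS,
    FeatureBundle,
    FusionHeads,
    VoteConfig,
    cross_fuse,
    majority_vote,
    sigmoid,
    validate_septet,
)


def make_bundle(n=1, hi=32, lo=512, rng=None):
    rng = rng or np.random.default_rng(0)
    return FeatureBundle(
        s_high=rng.standard_normal((n, hi)),
        s_low=rng.standard_normal((n, lo)),
        f_high=rng.standard_normal((n, hi)),
        f_low=rng.standard_normal((n, lo)),
        fc_logit=rng.standard_normal(n),
    )


class TestCrossFuse:
    def test_paper_scale_fused_lengths(self):
        fused = cross_fuse(make_bundle())
        assert [f.shape[1] for f in fused] == [64, 1024, 544, 544, 544, 544]

    def test_zero_bundle_zero_vectors(self):
        z = FeatureBundle(*(np.zeros((1, d)) for d in (4, 6, 4, 6)),
                          fc_logit=np.zeros(1))
        assert all(np.all(f == 0) for f in cross_fuse(z))

    def test_one_hot_parents_recoverable(self):
        """Each fused vector is exactly the concatenation of its two parents."""
        feats = {
            "s_high": np.eye(4)[[0]], "s_low": np.eye(6)[[1]],
            "f_high": np.eye(4)[[2]], "f_low": np.eye(6)[[3]],
        }
        bundle = FeatureBundle(fc_logit=np.zeros(1), **feats)
        for (a, b), fused in zip(FUSION_PAIRS, cross_fuse(bundle)):
            np.testing.assert_array_equal(
                fused, np.concatenate([feats[a], feats[b]], axis=1))

    def test_pair_order_covers_hh_ll_and_hl(self):
        assert FUSION_PAIRS[0] == ("s_high", "f_high")   # HH
        assert FUSION_PAIRS[1] == ("s_low", "f_low")     # LL
        hl = set(FUSION_PAIRS[2:])
        assert hl == {("s_high", "s_low"), ("f_high", "f_low"),
                      ("s_high", "f_low"), ("s_low", "f_high")}


class TestFusionHeads:
    def test_zero_input_logits_equal_biases(self, rng):
        heads = FusionHeads([3, 5], rng)
        heads.heads[0].bias.value[...] = 0.7
        heads.heads[1].bias.value[...] = -0.2
        out = heads.forward([np.zeros((2, 3), dtype=np.float32),
                             np.zeros((2, 5), dtype=np.float32)])
        np.testing.assert_allclose(out, [[0.7, -0.2]] * 2, atol=1e-7)

    def test_dot_product_oracle(self, rng):
        heads = FusionHeads([4], rng)
        x = rng.standard_normal((3, 4)).astype(np.float32)
        w = heads.heads[0].weight.value[:, 0]
        b = heads.heads[0].bias.value[0]
        expected = x @ w + b
        np.testing.assert_allclose(heads.forward([x])[:, 0], expected, rtol=1e-6)

    def test_head_isolation(self, rng):
        heads = FusionHeads([3, 3, 3], rng)
        base = [rng.standard_normal((1, 3)).astype(np.float32) for _ in range(3)]
        ref = heads.forward(base)
        perturbed = [f.copy() for f in base]
        perturbed[1] += 1.0
        out = heads.forward(perturbed)
        assert np.allclose(out[:, [0, 2]], ref[:, [0, 2]])
        assert not np.allclose(out[:, 1], ref[:, 1])

    def test_length_mismatch_rejected(self, rng):
        heads = FusionHeads([3], rng)
        with pytest.raises(ValueError, match="length"):
            heads.forward([np.zeros((1, 4), dtype=np.float32)])


class TestForward:
    def test_subject_probabilities_in_range_and_deterministic(
            self, tiny_cohort, tiny_cfg):
        model = hf.FusionModel(tiny_cfg, seed=9).eval()
        rec = tiny_cohort.records[0]
        probs, label = hf.forward_subject(rec, model)
        assert probs.shape == (7,)
        assert np.all(np.isfinite(probs))
        assert np.all((probs >= 0) & (probs <= 1))
        assert label in (0, 1)
        probs2, _ = hf.forward_subject(rec, model)
        np.testing.assert_array_equal(probs, probs2)

    def test_sigmoid_of_zero_logit(self):
        assert sigmoid(np.zeros(1))[0] == 0.5


class TestMajorityVote:
    def test_matches_popcount_oracle_on_all_128_patterns(self):
        for bits in itertools.product([0, 1], repeat=7):
            probs = [0.9 if b else 0.1 for b in bits]
            expected = int(sum(bits) >= 4)
            assert majority_vote(probs, 0.5) == expected

    def test_spec_examples(self):
        assert majority_vote([0.9, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1]) == 1
        assert majority_vote([0.1] * 7) == 0

    def test_permutation_invariant_and_monotone(self, rng):
        p = rng.random(7)
        base = majority_vote(p)
        for _ in range(10):
            assert majority_vote(rng.permutation(p)) == base
        # raising any probability never flips 1 -> 0
        if base == 1:
            for k in range(7):
                q = p.copy()
                q[k] = min(1.0, q[k] + 0.3)
                assert majority_vote(q) == 1

    def test_probability_at_threshold_is_negative_vote(self):
        # exactly at the threshold: strict '>' means the vote is 0
        probs = [0.5, 0.5, 0.5, 0.5, 0.9, 0.9, 0.9]
        assert majority_vote(probs, 0.5) == 0

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([1.2, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])

    def test_even_voter_tie_breaks_to_hc(self):
        assert majority_vote([0.9, 0.1], 0.5) == 0

    def test_vote_config_validation(self):
        with pytest.raises(ValueError):
            VoteConfig(threshold=1.0)
        assert VoteConfig().threshold == 0.5

    def test_validate_septet_rejects_wrong_length(self):
        with pytest.raises(ValueError, match="7"):
            validate_septet([0.5] * 6)


class TestCheckpoint:
    def test_round_trip_bit_identical(self, smoke_model, tmp_path):
        from hilofuse.train_eval import prepare_arrays

        model, _, subset = smoke_model
        path = tmp_path / "ckpt.npz"
        hf.save_checkpoint(model, path)
        loaded = hf.load_checkpoint(path)
        smri, fam, fc, _ = prepare_arrays(subset[:4])
        np.testing.assert_array_equal(
            model.predict_proba(smri, fam, fc),
            loaded.predict_proba(smri, fam, fc))

    def test_version_tag_enforced(self, smoke_model, tmp_path):
        import json
        model, _, _ = smoke_model
        path = tmp_path / "ckpt.npz"
        state = model.state_dict()
        np.savez(path, __meta__=np.array(json.dumps(
            {"version": "bogus", "config": model.cfg.to_dict()})), **state)
        with pytest.raises(ValueError, match="version"):
            hf.load_checkpoint(path)
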