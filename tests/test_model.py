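"""Channel-replacement interaction, backbone structure, fusion head,
losses and end-to-end gradients of the three-branch classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peelnet.model import (
    FusionConfig,
    InteractionConfig,
    MultiStreamClassifier,
    SingleStreamClassifier,
    classification_loss,
    interaction_forward,
    interaction_reverse,
    replace_channels,
    sample_channel_indices,
)
from peelnet.nn.layers import Backbone, BackboneConfig


def _maps(rng, n=2, c=10, h=4, w=4, count=3):
    return [rng.normal(0, 1, (n, c, h, w)) for _ in range(count)]


class TestReplaceChannels:
    def test_empty_index_set_is_identity(self):
        rng = np.random.default_rng(0)
        t, s, _ = _maps(rng)
        out = replace_channels(t, s, np.array([], dtype=int))
        np.testing.assert_array_equal(out, t)

    def test_all_channels_gives_source(self):
        rng = np.random.default_rng(1)
        t, s, _ = _maps(rng)
        out = replace_channels(t, s, np.arange(10))
        np.testing.assert_array_equal(out, s)

    def test_selected_channels_verified_elementwise(self):
        rng = np.random.default_rng(2)
        t = rng.normal(0, 1, (4, 3, 3))
        s = rng.normal(0, 1, (4, 3, 3))
        out = replace_channels(t, s, np.array([1, 3]))
        for ch in range(4):
            expected = s if ch in (1, 3) else t
            for i in range(3):
                for j in range(3):
                    assert out[ch, i, j] == expected[ch, i, j]

    def test_inputs_unmodified(self):
        rng = np.random.default_rng(3)
        t, s, _ = _maps(rng)
        t0, s0 = t.copy(), s.copy()
        replace_channels(t, s, np.array([0, 5]))
        np.testing.assert_array_equal(t, t0)
        np.testing.assert_array_equal(s, s0)

    def test_shape_mismatch_and_bad_indices_raise(self):
        rng = np.random.default_rng(4)
        t = rng.normal(0, 1, (2, 4, 4, 4))
        with pytest.raises(ValueError):
            replace_channels(t, rng.normal(0, 1, (2, 5, 4, 4)), np.array([0]))
        s = rng.normal(0, 1, (2, 4, 4, 4))
        with pytest.raises(ValueError):
            replace_channels(t, s, np.array([0, 0]))
        with pytest.raises(ValueError):
            replace_channels(t, s, np.array([4]))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_untouched_channels_exactly_preserved(self, seed):
        rng = np.random.default_rng(seed)
        c = int(rng.integers(2, 16))
        t = rng.normal(0, 1, (2, c, 3, 3))
        s = rng.normal(0, 1, (2, c, 3, 3))
        k = int(rng.integers(0, c + 1))
        idx = rng.choice(c, size=k, replace=False)
        out = replace_channels(t, s, idx)
        untouched = np.setdiff1d(np.arange(c), idx)
        np.testing.assert_array_equal(out[:, untouched], t[:, untouched])
        np.testing.assert_array_equal(out[:, idx.astype(int)], s[:, idx.astype(int)])


class TestSampleChannelIndices:
    def test_ten_percent_of_512_is_51(self):
        idx = sample_channel_indices(512, 0.10, np.random.default_rng(0))
        assert len(idx) == 51
        assert len(np.unique(idx)) == 51
        assert idx.min() >= 0 and idx.max() < 512

    def test_zero_ratio_empty(self):
        assert len(sample_channel_indices(64, 0.0, np.random.default_rng(0))) == 0

    def test_fixed_seed_reproducible(self):
        a = sample_channel_indices(100, 0.25, np.random.default_rng(7))
        b = sample_channel_indices(100, 0.25, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_bad_ratio_raises(self):
        with pytest.raises(ValueError):
            sample_channel_indices(10, 1.5, np.random.default_rng(0))


class TestInteraction:
    def test_inactive_config_passes_through(self):
        rng = np.random.default_rng(0)
        f, e, a = _maps(rng)
        cfg = InteractionConfig(active=False)
        e2, a2, idx = interaction_forward(f, e, a, cfg, rng)
        np.testing.assert_array_equal(e2, e)
        np.testing.assert_array_equal(a2, a)
        assert len(idx) == 0

    def test_identical_maps_unchanged(self):
        rng = np.random.default_rng(1)
        f = rng.normal(0, 1, (2, 10, 4, 4))
        e2, a2, _ = interaction_forward(f, f.copy(), f.copy(), InteractionConfig(), rng)
        np.testing.assert_array_equal(e2, f)
        np.testing.assert_array_equal(a2, f)

    def test_forward_matches_manual_replacement_with_logged_indices(self):
        rng = np.random.default_rng(2)
        f, e, a = _maps(rng)
        cfg = InteractionConfig(forward_ratio=0.3)
        e2, a2, idx = interaction_forward(f, e, a, cfg, np.random.default_rng(5))
        # Re-draw the same seeded stream to recover the index set.
        idx2 = sample_channel_indices(10, 0.3, np.random.default_rng(5))
        np.testing.assert_array_equal(idx, idx2)
        np.testing.assert_array_equal(e2, replace_channels(e, f, idx2))
        np.testing.assert_array_equal(a2, replace_channels(a, f, idx2))

    def test_reverse_zero_ratio_is_identity(self):
        rng = np.random.default_rng(3)
        f, e, a = _maps(rng)
        cfg = InteractionConfig(reverse_ratio=0.0)
        f2, ie, ia = interaction_reverse(f, e, a, cfg, rng)
        np.testing.assert_array_equal(f2, f)

    def test_reverse_identical_sources_is_identity(self):
        rng = np.random.default_rng(4)
        f = rng.normal(0, 1, (2, 10, 4, 4))
        f2, _, _ = interaction_reverse(f, f.copy(), f.copy(), InteractionConfig(), rng)
        np.testing.assert_array_equal(f2, f)

    def test_reverse_changed_channel_count_with_disjoint_sets(self):
        c = 40
        rng_data = np.random.default_rng(6)
        f = rng_data.normal(0, 1, (1, c, 2, 2))
        e = rng_data.normal(0, 1, (1, c, 2, 2))
        a = rng_data.normal(0, 1, (1, c, 2, 2))
        cfg = InteractionConfig(reverse_ratio=0.05)
        # Find a draw seed whose two 5% sets are disjoint, then count.
        for seed in range(50):
            r = np.random.default_rng(seed)
            f2, idx_e, idx_a = interaction_reverse(f, e, a, cfg, r)
            if len(np.intersect1d(idx_e, idx_a)) == 0:
                changed = np.flatnonzero(np.any(f2 != f, axis=(0, 2, 3)))
                assert len(changed) == 2 * int(np.floor(0.05 * c))
                return
        pytest.fail("no disjoint draw found")

    def test_interaction_values_come_from_inputs_only(self):
        # Pure copy property: every value in E' occurs in E or F.
        rng = np.random.default_rng(8)
        f, e, a = _maps(rng)
        e2, a2, _ = interaction_forward(f, e, a, InteractionConfig(forward_ratio=0.4), rng)
        pool = set(np.concatenate([e.ravel(), f.ravel()]).tolist())
        assert set(e2.ravel().tolist()) <= pool


class TestBackboneStructure:
    def test_standard50_stage4_map_is_2048_at_7x7(self):
        cfg = BackboneConfig.standard50()
        bb = Backbone(cfg)
        params = {}
        bb.init(params, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(0, 1, (1, 3, 224, 224)).astype(np.float32)
        h, _ = bb.forward_stem(params, x)
        h, _ = bb.forward_stages(params, h, 1, 4)
        assert h.shape == (1, 2048, 7, 7)

    def test_standard50_stage_channels(self):
        cfg = BackboneConfig.standard50()
        assert [cfg.stage_channels(s) for s in (1, 2, 3, 4)] == [256, 512, 1024, 2048]

    def test_reduced_variant_channels_and_pooling(self):
        cfg = BackboneConfig.reduced()
        bb = Backbone(cfg)
        params = {}
        bb.init(params, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(0, 1, (2, 3, 64, 64)).astype(np.float32)
        h, _ = bb.forward_stem(params, x)
        for stage in (1, 2, 3, 4):
            h, _ = bb.forward_stages(params, h, stage, stage)
            assert h.shape[1] == cfg.stage_channels(stage)
        assert h.shape == (2, 64, 4, 4)

    def test_deterministic_forward(self, micro_model, micro_batch):
        p = micro_model.init_params(0)
        x, _ = micro_batch
        a = micro_model.predict_proba(p, x)
        b = micro_model.predict_proba(p, x)
        np.testing.assert_array_equal(a, b)


class TestFusionHead:
    def test_fused_vector_length_1536(self):
        model = MultiStreamClassifier(backbone=BackboneConfig.standard50())
        p = model.init_fusion_params(0)
        rng = np.random.default_rng(0)
        maps = {b: rng.normal(0, 1, (2, 2048, 2, 2)).astype(np.float32) for b in ("full", "exocarp", "albedo")}
        fused = model.fuse_features(p, maps)
        assert fused.shape == (2, 1536)

    def test_probabilities_sum_to_one(self, micro_model, micro_batch):
        p = micro_model.init_params(0)
        probs = micro_model.predict_proba(p, micro_batch[0])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_zero_head_gives_uniform(self, micro_model):
        p = micro_model.init_fusion_params(0)
        p["head.w"][:] = 0
        p["head.b"][:] = 0
        rng = np.random.default_rng(1)
        maps = {b: rng.normal(0, 1, (3, 5, 2, 2)).astype(np.float32) for b in ("full", "exocarp", "albedo")}
        probs = micro_model.fuse_and_classify(p, maps)
        np.testing.assert_allclose(probs, 0.25, atol=1e-7)

    def test_channel_mismatch_raises(self, micro_model):
        p = micro_model.init_fusion_params(0)
        maps = {b: np.zeros((1, 7, 2, 2), dtype=np.float32) for b in ("full", "exocarp", "albedo")}
        with pytest.raises(ValueError):
            micro_model.fuse_and_classify(p, maps)


class TestClassificationLoss:
    def test_certain_correct_prediction_is_zero(self):
        assert classification_loss(np.array([0, 1, 0, 0.0]), np.array([0, 1, 0, 0])) == 0.0

    def test_uniform_is_log4(self):
        loss = classification_loss(np.full(4, 0.25), np.array([0, 0, 1, 0]))
        assert loss == pytest.approx(np.log(4), rel=1e-12)

    def test_matches_hand_computation(self):
        p = np.array([0.7, 0.2, 0.05, 0.05])
        y = np.array([0, 1, 0, 0])
        assert classification_loss(p, y) == pytest.approx(-np.log(0.2), rel=1e-12)

    def test_zero_probability_floored(self):
        loss = classification_loss(np.array([1.0, 0, 0, 0]), np.array([0, 1, 0, 0]))
        assert np.isfinite(loss)


class TestMultiStreamGradients:
    def test_gradients_finite_and_match_finite_differences(self, micro_model, micro_batch):
        p = {k: v.astype(np.float64) for k, v in micro_model.init_params(0).items()}
        x, y = micro_batch
        x64 = tuple(a.astype(np.float64) for a in x)
        loss, grads = micro_model.loss_and_grad(p, (x64, y))
        assert np.isfinite(loss)
        assert all(np.all(np.isfinite(g)) for g in grads.values())
        rng = np.random.default_rng(2)
        eps = 1e-6
        for key in rng.choice(sorted(p.keys()), size=6, replace=False):
            i = rng.integers(p[key].size)
            q = {k: v.copy() for k, v in p.items()}
            q[key].flat[i] += eps
            lp, _ = micro_model.loss_and_grad(q, (x64, y))
            q[key].flat[i] -= 2 * eps
            lm, _ = micro_model.loss_and_grad(q, (x64, y))
            num = (lp - lm) / (2 * eps)
            ana = grads[key].flat[i]
            assert num == pytest.approx(ana, rel=1e-3, abs=1e-7)

    def test_interaction_toggle_changes_only_via_replaced_channels(self, micro_backbone, micro_batch):
        # With ratios 0 the interacting model equals the non-interacting one.
        x, y = micro_batch
        on = MultiStreamClassifier(
            backbone=micro_backbone,
            interaction=InteractionConfig(forward_ratio=0.0, reverse_ratio=0.0),
            fusion=FusionConfig(compress_dim=6, n_classes=4),
        )
        off = MultiStreamClassifier(
            backbone=micro_backbone,
            interaction=InteractionConfig(active=False),
            fusion=FusionConfig(compress_dim=6, n_classes=4),
        )
        p = on.init_params(0)
        np.testing.assert_array_equal(on.predict_proba(p, x), off.predict_proba(p, x))

    def test_whole_branch_reduces_to_single_stream_baseline(self, micro_backbone, micro_batch):
        # Copying the single-stream weights into the whole-image branch (and
        # its auxiliary head) reproduces the baseline's logits exactly.
        x, y = micro_batch
        single = SingleStreamClassifier(backbone=micro_backbone)
        ps = single.init_params(0)
        multi = MultiStreamClassifier(
            backbone=micro_backbone,
            interaction=InteractionConfig(active=False),
            fusion=FusionConfig(compress_dim=6, n_classes=4),
        )
        pm = multi.init_params(1)
        for k, v in ps.items():
            if k.startswith("bb."):
                pm["full." + k[3:]] = v.copy()
            elif k.startswith("head."):
                pm["aux.full." + k[5:]] = v.copy()
        single_logits, _ = single._forward(ps, x[0])
        _, aux = multi.forward_logits(pm, x)
        np.testing.assert_allclose(aux["full"], single_logits, rtol=1e-5, atol=1e-6)
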