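"""Architecture table conformance, compound scaling, weight archives, and
training behavior of the scalable network."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ictal2d as it
from ictal2d.network import (
    SCALING_TABLE,
    Network,
    baseline_spec,
    round_filters,
    round_repeats,
    save_weights,
    load_pretrained,
    predict_logits,
    spec_for_level,
    tiny_spec,
)

# operator, expansion, kernel, in_resolution, channels, layers, stride
BASELINE_TABLE = [
    ("plain_conv", 1, 3, 224, 32, 1, 2),
    ("mbconv", 1, 3, 112, 16, 1, 1),
    ("mbconv", 6, 3, 112, 24, 2, 2),
    ("mbconv", 6, 5, 56, 40, 2, 2),
    ("mbconv", 6, 3, 28, 80, 3, 2),
    ("mbconv", 6, 5, 14, 112, 3, 1),
    ("mbconv", 6, 5, 14, 192, 4, 2),
    ("mbconv", 6, 3, 7, 320, 1, 1),
    ("plain_conv", 1, 1, 7, 1280, 1, 1),
]


class TestBaselineSpec:
    def test_all_nine_stages_match_the_architecture_table(self):
        stages = baseline_spec()
        assert len(stages) == 9
        for st, (op, exp, k, res, ch, layers, stride) in zip(
            stages, BASELINE_TABLE
        ):
            assert (st.operator, st.kernel, st.in_resolution,
                    st.out_channels, st.layers, st.stride_first) == (
                op, k, res, ch, layers, stride)
            if op == "mbconv":
                assert st.expansion == exp

    def test_stage_seven_row(self):
        st = baseline_spec()[6]
        assert (st.operator, st.expansion, st.kernel, st.out_channels,
                st.layers) == ("mbconv", 6, 5, 192, 4)

    def test_total_mbconv_repeats(self):
        assert sum(st.layers for st in baseline_spec()[1:8]) == 16


class TestScaling:
    def test_level_zero_is_identity_on_the_baseline(self):
        spec = spec_for_level(0)
        for scaled, base in zip(spec.stages, baseline_spec()):
            assert scaled == base
        assert spec.feature_dim == 1280
        assert spec.input_resolution == 224

    def test_level3_depth_rule(self):
        # width 1.2, depth 1.4: stage 5 has ceil(3 x 1.4) = 5 layers
        spec = spec_for_level(3)
        assert spec.stages[4].layers == 5

    def test_level4_table_row(self):
        cfg = it.ScalingConfig.from_level(4)
        assert cfg.input_resolution == 380
        assert cfg.depth_coefficient == 1.8
        assert cfg.width_coefficient == 1.4

    def test_scaling_table_levels(self):
        assert SCALING_TABLE == {
            0: (224, 1.0, 1.0), 1: (240, 1.0, 1.1), 2: (260, 1.1, 1.2),
            3: (300, 1.2, 1.4), 4: (380, 1.4, 1.8), 5: (456, 1.6, 2.2),
            6: (528, 1.8, 2.6), 7: (600, 2.0, 3.1),
        }

    def test_mismatched_level_settings_rejected(self):
        with pytest.raises(ValueError, match="scaling table"):
            it.ScalingConfig(level=2, input_resolution=224,
                             width_coefficient=1.1, depth_coefficient=1.2)

    def test_sub_unit_coefficients_rejected_without_optin(self):
        cfg = it.ScalingConfig(level=None, input_resolution=64,
                               width_coefficient=0.5, depth_coefficient=0.5)
        with pytest.raises(ValueError, match="tiny"):
            it.scale_spec(baseline_spec(), cfg)

    def test_feature_dim_follows_width_rounding(self):
        assert spec_for_level(2).feature_dim == round_filters(1280, 1.1) == 1408

    def test_round_filters_is_idempotent_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            c = rng.integers(8, 2048)
            w = rng.uniform(0.3, 2.5)
            r = round_filters(c, w)
            assert r % 8 == 0
            assert r >= 0.9 * c * w
            assert round_filters(r, 1.0) == r

    @given(c=st.integers(1, 4096),
           w=st.floats(0.25, 3.0, allow_nan=False))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_round_filters_never_undershoots_90pct(self, c, w):
        r = round_filters(c, w)
        assert r % 8 == 0
        assert r >= 0.9 * c * w
        assert round_filters(r, 1.0) == r

    def test_round_repeats_is_ceiling(self):
        assert round_repeats(3, 1.4) == 5
        assert round_repeats(1, 1.0) == 1
        assert round_repeats(4, 1.8) == 8

    def test_parameter_count_nondecreasing_over_levels(self):
        counts = [
            it.build_network(spec_for_level(lv), seed=0).parameter_count()
            for lv in range(5)
        ]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestBuiltNetwork:
    def test_level0_logits_and_depth_feature_dimensions(self):
        net = it.build_network(spec_for_level(0), seed=0)
        x = np.zeros((2, 3, 224, 224), dtype=np.float32)
        feats = it.extract_depth_features(net, x)
        assert feats.shape == (2, 1280)
        assert predict_logits(net, x).shape == (2, 2)

    def test_level0_stage_output_sizes_follow_the_table(self):
        net = it.build_network(spec_for_level(0), seed=0)
        assert net.stage_output_sizes() == [112, 112, 56, 28, 14, 14, 7, 7]

    def test_forward_is_finite_and_deterministic(self, tiny_net):
        x = np.zeros((2, 3, 64, 64), dtype=np.float32)
        a = predict_logits(tiny_net, x)
        b = predict_logits(tiny_net, x)
        assert np.all(np.isfinite(a))
        np.testing.assert_array_equal(a, b)

    def test_identical_inputs_give_identical_feature_rows(self, tiny_net):
        rng = np.random.default_rng(1)
        row = rng.normal(size=(3, 64, 64)).astype(np.float32)
        batch = np.stack([row, row, row])
        feats = it.extract_depth_features(tiny_net, batch)
        np.testing.assert_array_equal(feats[0], feats[1])

    def test_resolution_mismatch_names_expected_resolution(self, tiny_net):
        with pytest.raises(ValueError, match="64"):
            it.extract_depth_features(
                tiny_net, np.zeros((1, 3, 32, 32), dtype=np.float32)
            )

    def test_same_seed_builds_identical_networks(self):
        a = it.build_network(tiny_spec(), seed=3)
        b = it.build_network(tiny_spec(), seed=3)
        for (na, pa), (nb, pb) in zip(a.named_parameters(),
                                      b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)


class TestWeightArchives:
    def test_round_trip_skips_nothing(self, tmp_path, tiny_net):
        path = tmp_path / "w.npz"
        save_weights(tiny_net, path)
        other = it.build_network(tiny_spec(), seed=99)
        other, skipped = load_pretrained(other, path)
        assert skipped == []
        x = np.random.default_rng(0).normal(size=(2, 3, 64, 64)).astype(
            np.float32)
        np.testing.assert_allclose(predict_logits(other, x),
                                   predict_logits(tiny_net, x), atol=1e-6)

    def test_foreign_head_skips_exactly_the_head(self, tmp_path):
        donor = it.build_network(tiny_spec(num_classes=1000), seed=0)
        path = tmp_path / "imagenet_like.npz"
        save_weights(donor, path)
        net = it.build_network(tiny_spec(num_classes=2), seed=1)
        net, skipped = load_pretrained(net, path)
        assert set(skipped) == {"fc.weight", "fc.bias"}

    def test_wrong_level_archive_fails_strict(self, tmp_path, tiny_net):
        path = tmp_path / "tiny.npz"
        save_weights(tiny_net, path)
        net0 = it.build_network(spec_for_level(0), seed=0)
        with pytest.raises(ValueError, match="does not match"):
            load_pretrained(net0, path, strict=True)

    def test_backbone_transfer_preserves_features(self, tmp_path, tiny_net):
        """Loading a 1000-class archive transfers the backbone: depth
        features match the donor even though the head is reinitialized."""
        donor = it.build_network(tiny_spec(num_classes=1000), seed=5)
        path = tmp_path / "donor.npz"
        save_weights(donor, path)
        net = it.build_network(tiny_spec(num_classes=2), seed=6)
        net, _ = load_pretrained(net, path)
        x = np.random.default_rng(2).normal(size=(2, 3, 64, 64)).astype(
            np.float32)
        np.testing.assert_allclose(
            it.extract_depth_features(net, x),
            it.extract_depth_features(donor, x), atol=1e-6)


class TestTraining:
    @staticmethod
    def toy_data(n=8, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 3, 64, 64)).astype(np.float32)
        y = np.arange(n) % 2
        return x, y

    def test_one_epoch_smoke(self, ):
        net = it.build_network(tiny_spec(), seed=0)
        x, y = self.toy_data()
        net, history = it.train(net, (x, y), (x, y),
                                it.TrainConfig(epochs=1, seed=0))
        assert len(history) == 1
        assert np.isfinite(history[0].train_loss)

    def test_same_seed_gives_identical_history(self):
        x, y = self.toy_data(12)
        runs = []
        for _ in range(2):
            net = it.build_network(tiny_spec(), seed=1)
            _, history = it.train(net, (x, y), (x, y),
                                  it.TrainConfig(epochs=2, seed=1))
            runs.append([(h.train_loss, h.val_accuracy) for h in history])
        assert runs[0] == runs[1]

    def test_empty_training_set_is_an_error(self):
        net = it.build_network(tiny_spec(), seed=0)
        empty = (np.zeros((0, 3, 64, 64), dtype=np.float32), np.zeros(0, int))
        with pytest.raises(ValueError, match="empty"):
            it.train(net, empty, empty)

    def test_frozen_backbone_only_updates_head(self):
        net = it.build_network(tiny_spec(), seed=2)
        before = {n: p.data.copy() for n, p in net.named_parameters()}
        x, y = self.toy_data(8, seed=3)
        net, _ = it.train(net, (x, y), (x, y),
                          it.TrainConfig(epochs=1, seed=2,
                                         freeze_backbone=True))
        changed = {n for n, p in net.named_parameters()
                   if not np.array_equal(p.data, before[n])}
        assert changed <= {"fc.weight", "fc.bias"}
        assert changed
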