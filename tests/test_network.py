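import numpy as np
import pytest

from blastoseg.network import (
    LayerSpec,
    TensorShape,
    aggregate,
    build_network,
    canonical_spec,
    count_parameters,
    infer_shapes,
    layer_output_shape,
    predict,
)

# Canonical per-layer output sizes at 400x400x1 input (height, width, channels).
EXPECTED_SHAPES = [
    ("Input-Conv", (200, 200, 16)),
    *[(f"S8-DWSC-{i}", (25, 25, 32)) for i in range(1, 9)],
    ("S8-Conv-S", (25, 25, 32)),
    ("S8-Tconv-A", (50, 50, 32)),
    ("S8-Tconv-B", (100, 100, 32)),
    ("S8-Tconv-C", (200, 200, 32)),
    ("S2-Conv-S", (100, 100, 32)),
    ("S2-Conv-A", (100, 100, 64)),
    ("S2-Conv-B", (100, 100, 64)),
    ("S2-Pool", (50, 50, 64)),
    ("S2-Conv-C", (50, 50, 128)),
    ("S2-Conv-D", (50, 50, 256)),
    ("S2-DWSC-1", (50, 50, 256)),
    ("S2-DWSC-2", (50, 50, 256)),
    ("S2-Tconv-A", (100, 100, 128)),
    ("S2-Tconv-B", (200, 200, 64)),
    ("S4-Conv-S", (50, 50, 32)),
    ("S4-Conv-A", (50, 50, 64)),
    ("S4-Conv-B", (50, 50, 128)),
    ("S4-DWSC-A-1", (50, 50, 128)),
    ("S4-DWSC-A-2", (50, 50, 128)),
    ("S4-DWSC-B-1", (50, 50, 64)),
    ("S4-DWSC-B-2", (50, 50, 64)),
    ("S4-Tconv-A", (100, 100, 128)),
    ("S4-Tconv-B", (200, 200, 64)),
    ("FBB-Conv-A", (200, 200, 32)),
    ("FBB-Conv-B", (200, 200, 64)),
    ("FBB-Conv-C", (200, 200, 64)),
    ("FBB-Conv-D", (200, 200, 128)),
    ("Feature-Aggregation", (200, 200, 288)),
    ("US-Conv-A", (200, 200, 256)),
    ("US-Conv-B", (200, 200, 128)),
    ("US-Conv-C", (200, 200, 64)),
    ("US-Tconv-A", (400, 400, 32)),
    ("Class-Mask-Conv", (400, 400, 5)),
]


class TestCanonicalSpec:
    def test_aggregation_operand_channels(self):
        spec = canonical_spec(with_fbb=True)
        assert tuple(spec.blocks[n][-1].out_channels for n in spec.branch_names) == (
            32, 64, 64, 128,
        )
        spec = canonical_spec(with_fbb=False)
        assert tuple(spec.blocks[n][-1].out_channels for n in spec.branch_names) == (32, 64, 64)
        assert "fbb" not in spec.blocks
        assert spec.blocks["upsampling"][0].in_channels == 160

    def test_every_layer_but_the_head_has_bn_relu(self):
        spec = canonical_spec(with_fbb=True)
        for block, layers in spec.blocks.items():
            for layer in layers:
                if layer.kind == "classhead":
                    assert not layer.bn_relu
                elif layer.kind != "maxpool":
                    assert layer.bn_relu, layer.name

    def test_exactly_one_pooling_layer_in_the_whole_network(self):
        spec = canonical_spec(with_fbb=True)
        pools = [l for layers in spec.blocks.values() for l in layers if l.kind == "maxpool"]
        assert len(pools) == 1
        assert pools[0].name == "S2-Pool"

    def test_spec_json_round_trip(self, tmp_path):
        import json

        from blastoseg.network import NetworkSpec

        spec = canonical_spec(True)
        spec.to_json(tmp_path / "spec.json")
        back = NetworkSpec.from_dict(json.loads((tmp_path / "spec.json").read_text()))
        assert back == spec


class TestShapeInference:
    def test_full_table_conformance(self):
        shapes = dict(
            (name, (s.height, s.width, s.channels))
            for name, s in infer_shapes(canonical_spec(True))
        )
        for name, expected in EXPECTED_SHAPES:
            assert shapes[name] == expected, name
        assert len(shapes) == len(EXPECTED_SHAPES)

    def test_aggregation_without_fbb_is_160_channels(self):
        shapes = dict(infer_shapes(canonical_spec(False)))
        assert shapes["Feature-Aggregation"] == TensorShape(200, 200, 160)

    def test_fbb_preserves_200x200_throughout(self):
        shapes = dict(infer_shapes(canonical_spec(True)))
        for name in ("FBB-Conv-A", "FBB-Conv-B", "FBB-Conv-C", "FBB-Conv-D"):
            assert (shapes[name].height, shapes[name].width) == (200, 200)

    @pytest.mark.parametrize("side", [48, 64, 400])
    def test_output_size_equals_input_for_sides_divisible_by_16(self, side):
        shapes = infer_shapes(canonical_spec(True), TensorShape(side, side, 1))
        name, out = shapes[-1]
        assert name == "Class-Mask-Conv"
        assert (out.height, out.width, out.channels) == (side, side, 5)

    def test_side_not_divisible_by_16_fails_at_aggregation_naming_operands(self):
        with pytest.raises(ValueError, match="scale8.*scale2|aggregation"):
            infer_shapes(canonical_spec(True), TensorShape(40, 40, 1))

    def test_entry_convolution_shapes(self):
        fi = TensorShape(200, 200, 16)
        s8 = LayerSpec("e8", "conv", 16, 32, stride=8, dilation=8)
        s4 = LayerSpec("e4", "conv", 16, 32, stride=4, dilation=4)
        assert layer_output_shape(fi, s8) == TensorShape(25, 25, 32)
        assert layer_output_shape(fi, s4) == TensorShape(50, 50, 32)
        tconv = LayerSpec("t", "tconv", 32, 32, kernel=2, stride=2)
        assert layer_output_shape(TensorShape(25, 25, 32), tconv) == TensorShape(50, 50, 32)

    def test_channel_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="channels"):
            layer_output_shape(TensorShape(10, 10, 7), LayerSpec("c", "conv", 3, 8))


class TestParameterCount:
    def test_class_head_count(self):
        counts = count_parameters(canonical_spec(True)).as_dict()
        assert counts["Class-Mask-Conv"] == 32 * 5 + 5  # 1x1 conv + bias, no BN

    def test_dwsc_count_decomposition(self):
        counts = count_parameters(canonical_spec(True)).as_dict()
        # depthwise 3x3x32 (+bias) + pointwise 32->32 (+bias) + BN affine
        assert counts["S8-DWSC-1"] == (288 + 32) + (1024 + 32) + 64
        weights_only = 288 + 1024
        assert weights_only == 1312

    def test_totals_and_fbb_difference_decomposition(self):
        with_fbb = count_parameters(canonical_spec(True))
        without = count_parameters(canonical_spec(False))
        assert with_fbb.total == 2_152_037
        assert without.total == 1_722_629
        # the difference is exactly the FBB layers plus the widened US-Conv-A
        fbb_layers = sum(
            n for name, n in with_fbb.per_layer if name.startswith("FBB-")
        )
        us_a_wide = dict(with_fbb.per_layer)["US-Conv-A"]
        us_a_narrow = dict(without.per_layer)["US-Conv-A"]
        assert with_fbb.total - without.total == fbb_layers + (us_a_wide - us_a_narrow)
        assert us_a_wide - us_a_narrow == 9 * (288 - 160) * 256

    def test_total_equals_per_layer_sum(self):
        pc = count_parameters(canonical_spec(True))
        assert pc.total == sum(n for _, n in pc.per_layer)


class TestBuildNetwork:
    def test_built_parameter_count_matches_spec_count(self):
        for with_fbb in (True, False):
            spec = canonical_spec(with_fbb)
            net = build_network(spec, seed=0)
            assert net.num_parameters() == count_parameters(spec).total

    def test_same_seed_identical_weights_different_seed_not(self):
        a = build_network(canonical_spec(True), seed=3)
        b = build_network(canonical_spec(True), seed=3)
        c = build_network(canonical_spec(True), seed=4)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)
        assert any(
            not np.array_equal(pa.value, pc.value)
            for pa, pc in zip(a.parameters(), c.parameters())
        )

    def test_forward_full_resolution_returns_five_score_maps(self):
        net = build_network(canonical_spec(True), seed=0)
        scores = net.forward(np.random.default_rng(0).random((1, 1, 400, 400)))
        assert scores.shape == (1, 5, 400, 400)
        assert np.isfinite(scores).all()

    def test_branch_outputs_recorded_at_aggregation_resolution(self):
        net = build_network(canonical_spec(True), seed=0)
        net.forward(np.zeros((1, 1, 48, 48), dtype=np.float32))
        blocks = net.last_blocks
        assert blocks.FS8.shape == (1, 32, 24, 24)
        assert blocks.FS2.shape == (1, 64, 24, 24)
        assert blocks.FS4.shape == (1, 64, 24, 24)
        assert blocks.FBB.shape == (1, 128, 24, 24)
        assert blocks.SA.shape == (1, 288, 24, 24)

    def test_state_dict_round_trip(self, tmp_path):
        from blastoseg.network import Network

        net = build_network(canonical_spec(False), seed=1)
        net.save(tmp_path / "ckpt.npz")
        back = Network.load(tmp_path / "ckpt.npz", canonical_spec(False))
        x = np.random.default_rng(2).random((1, 1, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), back.forward(x))


class TestAggregate:
    def test_channels_add_in_fixed_order(self, rng):
        f1 = rng.random((1, 32, 8, 8))
        f2 = rng.random((1, 64, 8, 8))
        f3 = rng.random((1, 64, 8, 8))
        f4 = rng.random((1, 128, 8, 8))
        sa = aggregate(f1, f2, f3, f4)
        assert sa.shape == (1, 288, 8, 8)
        np.testing.assert_array_equal(sa[:, :32], f1)
        np.testing.assert_array_equal(sa[:, 160:], f4)
        assert aggregate(f1, f2, f3).shape == (1, 160, 8, 8)

    def test_single_operand_is_identity(self, rng):
        f = rng.random((1, 16, 4, 4))
        np.testing.assert_array_equal(aggregate(f), f)

    def test_spatial_mismatch_is_hard_error(self, rng):
        with pytest.raises(ValueError, match="spatial mismatch"):
            aggregate(rng.random((1, 8, 4, 4)), rng.random((1, 8, 6, 6)))


class TestPredict:
    def test_masks_partition_the_frame(self, small_phantom):
        net = build_network(canonical_spec(True), seed=0)
        label_map, masks = predict(net, small_phantom.image)
        assert label_map.shape == small_phantom.image.shape
        assert masks.shape == (5, 48, 48)
        np.testing.assert_array_equal(masks.sum(axis=0), np.ones((48, 48), dtype=np.uint8))

    def test_ties_resolve_to_lowest_class_index(self):
        scores = np.zeros((5, 4, 4))
        assert (scores.argmax(axis=0) == 0).all()  # convention used by predict

    def test_channel_maximal_everywhere_gives_single_class(self, monkeypatch):
        net = build_network(canonical_spec(True), seed=0)
        scores = np.zeros((1, 5, 16, 16), dtype=np.float32)
        scores[:, 4] = 10.0
        monkeypatch.setattr(net, "forward", lambda x, training=False: scores)
        label_map, masks = predict(net, np.zeros((16, 16)))
        assert (label_map == 4).all()
        assert masks[4].all() and not masks[:4].any()

    def test_non_2d_input_rejected(self):
        net = build_network(canonical_spec(True), seed=0)
        with pytest.raises(ValueError, match="2-D"):
            predict(net, np.zeros((1, 48, 48)))
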