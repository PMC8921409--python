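"""Cascade architectures, shape propagation and ROI transforms."""

import numpy as np
import pytest

from spinealign.geometry import Point2D
from spinealign.models import (ArchError, ArchSpec, build_model, compose,
                               crop_with_transform, first_order_arch,
                               map_to_global, map_to_local, propagate_shapes,
                               resize_transform, scaled_arch,
                               second_order_arch, third_order_arch,
                               NetworkModel, OUTPUT_UNITS, RoiTransform)

# the published layer tables, one (layer name, output shape) row per layer
FIRST_ORDER_TABLE = [
    ("Conv1", (1612, 532, 8)), ("Max-pooling 1", (403, 133, 8)),
    ("Conv2", (397, 127, 16)), ("Max-pooling 2", (132, 42, 16)),
    ("Conv3", (126, 36, 16)), ("Max-pooling 3", (63, 18, 16)),
    ("Conv4", (59, 14, 32)), ("Max-pooling 4", (29, 7, 32)),
    ("Conv5", (27, 5, 32)), ("Dropout", (27, 5, 32)), ("ReLU", (27, 5, 32)),
    ("FC1", (256,)), ("FC2", (128,)), ("Output", (2,)),
]
SECOND_ORDER_TABLE = [
    ("Conv1", (492, 242, 8)), ("Max-pooling 1", (164, 81, 8)),
    ("Conv2", (158, 75, 16)), ("Max-pooling 2", (79, 37, 16)),
    ("Conv3", (73, 31, 16)), ("Max-pooling 3", (36, 15, 16)),
    ("Conv4", (32, 11, 32)), ("Max-pooling 4", (16, 5, 32)),
    ("Conv5", (14, 3, 32)), ("Dropout", (14, 3, 32)), ("ReLU", (14, 3, 32)),
    ("FC1", (256,)), ("FC2", (90,)), ("Output", (6,)),
]
THIRD_ORDER_TABLE = [
    ("Conv1", (142, 142, 8)), ("Max-pooling 1", (71, 71, 8)),
    ("Conv2", (65, 65, 8)), ("Max-pooling 2", (32, 32, 8)),
    ("Conv3", (28, 28, 16)), ("Max-pooling 3", (14, 14, 16)),
    ("Conv4", (12, 12, 16)), ("Max-pooling 4", (6, 6, 16)),
    ("Conv5", (6, 6, 32)), ("Dropout", (6, 6, 32)), ("ReLU", (6, 6, 32)),
    ("FC1", (256,)), ("FC2", (90,)), ("Output", (8,)),
]


class TestPropagateShapes:
    @pytest.mark.parametrize("arch, table", [
        (first_order_arch(), FIRST_ORDER_TABLE),
        (second_order_arch(6), SECOND_ORDER_TABLE),
        (third_order_arch(8), THIRD_ORDER_TABLE),
    ], ids=["first", "second", "third"])
    def test_full_table_equality(self, arch, table):
        got = propagate_shapes(arch)
        assert got == [shape for _, shape in table]

    def test_output_dimensionalities(self):
        assert {k: v for k, v in OUTPUT_UNITS.items()} == {
            "first_cervical": 2, "first_lumbar": 2, "first_femoral": 2,
            "second_cervical": 6, "second_lumbar": 4,
            "third_c1": 4, "third_c2": 8, "third_t1": 8,
            "third_l1": 4, "third_s1": 8, "third_femoral": 2,
        }

    def test_non_positive_dimension_named(self):
        with pytest.raises(ArchError, match="layer"):
            propagate_shapes(first_order_arch(input_shape=(40, 40)))

    def test_scaled_arch_reproduces_native_at_native_size(self):
        native = propagate_shapes(first_order_arch())
        scaled = propagate_shapes(scaled_arch("first_order", (1620, 540)))
        assert native == scaled

    @pytest.mark.parametrize("order, shape", [
        ("first_order", (162, 54)), ("second_order", (125, 63)),
        ("third_order", (38, 38)),
    ])
    def test_scaled_arch_keeps_five_convs_positive(self, order, shape):
        arch = scaled_arch(order, shape, kernel_scale=0.5, relu_convs=True)
        shapes = propagate_shapes(arch)
        assert all(all(d >= 1 for d in s) for s in shapes)
        assert sum(l.kind == "conv" for l in arch.layers) == 5

    def test_arch_json_roundtrip(self):
        arch = second_order_arch(4)
        assert ArchSpec.from_json(arch.to_json()) == arch


class TestBuildModel:
    def test_zero_image_returns_head_bias(self):
        # with the zero-initialized output head, a zero input must map to the
        # bias vector of the head (feed-forward sanity of Y = f(wX + b))
        arch = scaled_arch("third_order", (38, 38), output_units=8)
        model = build_model(arch, seed=0)
        out = model.predict(np.zeros((1, 38, 38, 1), dtype=np.float32))
        np.testing.assert_allclose(out[0], model.net.layers[-1].params["b"])
        model.net.layers[-1].params["b"][:] = 0.25
        out = model.predict(np.zeros((2, 38, 38, 1), dtype=np.float32))
        np.testing.assert_allclose(out, 0.25)

    def test_deterministic_initialization(self):
        arch = scaled_arch("third_order", (38, 38), output_units=2)
        a = build_model(arch, seed=5)
        b = build_model(arch, seed=5)
        for (la, k), (lb, _) in zip(a.net.parameters(), b.net.parameters()):
            np.testing.assert_array_equal(la.params[k], lb.params[k])

    def test_invalid_output_units(self):
        with pytest.raises(ArchError):
            build_model(third_order_arch(8), output_units=0)

    def test_save_load_roundtrip(self, tmp_path, rng):
        arch = scaled_arch("third_order", (38, 38), output_units=4,
                           relu_convs=True)
        model = build_model(arch, seed=3)
        x = rng.normal(size=(2, 38, 38, 1)).astype(np.float32)
        before = model.predict(x)
        model.save(tmp_path / "m.npz")
        loaded = NetworkModel.load(tmp_path / "m.npz")
        np.testing.assert_allclose(loaded.predict(x), before, rtol=1e-6)


class TestRoiTransforms:
    def test_crop_origin_and_mapping(self):
        img = np.arange(500 * 600, dtype=np.float32).reshape(500, 600)
        crop, t = crop_with_transform(img, Point2D(200, 300), (150, 150))
        assert crop.shape == (150, 150)
        assert (t.origin.x, t.origin.y) == (125, 225)
        g = map_to_global(Point2D(10, 10), t)
        assert (g.x, g.y) == (135, 235)
        np.testing.assert_array_equal(crop, img[225:375, 125:275])

    def test_crop_zero_pads_at_border(self):
        img = np.ones((300, 300), dtype=np.float32)
        crop, t = crop_with_transform(img, Point2D(10, 10), (150, 150))
        assert crop.shape == (150, 150)
        assert crop[0, 0] == 0.0          # padded corner
        assert crop[140, 140] == 1.0      # inside original image
        # mapping still exact: local (75, 75) is the crop centre = (10, 10)
        g = map_to_global(Point2D(75, 75), t)
        assert (g.x, g.y) == (10, 10)

    def test_center_outside_image_rejected(self):
        img = np.zeros((100, 100))
        with pytest.raises(ValueError, match="outside"):
            crop_with_transform(img, Point2D(150, 50), (30, 30))

    def test_local_global_roundtrip(self, rng):
        t = RoiTransform(Point2D(125, 225), (0.5, 0.25))
        for _ in range(100):
            p = Point2D(float(rng.uniform(-50, 400)), float(rng.uniform(-50, 400)))
            q = map_to_global(map_to_local(p, t), t)
            assert q.x == pytest.approx(p.x, abs=1e-9)
            assert q.y == pytest.approx(p.y, abs=1e-9)

    def test_composition_associative(self, rng):
        ts = [RoiTransform(Point2D(float(rng.uniform(-20, 20)),
                                   float(rng.uniform(-20, 20))),
                           (float(rng.uniform(0.5, 2)), float(rng.uniform(0.5, 2))))
              for _ in range(3)]
        left = compose(compose(ts[0], ts[1]), ts[2])
        right = compose(ts[0], compose(ts[1], ts[2]))
        p = Point2D(3.7, -2.2)
        a, b = map_to_global(p, left), map_to_global(p, right)
        assert a.x == pytest.approx(b.x, abs=1e-9)
        assert a.y == pytest.approx(b.y, abs=1e-9)
        # and composition equals sequential application
        seq = map_to_global(map_to_global(map_to_global(p, ts[2]), ts[1]), ts[0])
        assert a.x == pytest.approx(seq.x, abs=1e-9)

    def test_resize_transform_roundtrip_under_rescaling(self):
        t = resize_transform((810, 270), (162, 54))
        p = Point2D(100.0, 600.0)
        q = map_to_global(map_to_local(p, t), t)
        assert abs(q.x - p.x) < 0.5 and abs(q.y - p.y) < 0.5

    def test_identity_transform(self):
        t = RoiTransform(Point2D(0, 0))
        p = Point2D(12.5, 7.25)
        assert map_to_global(p, t) == p
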