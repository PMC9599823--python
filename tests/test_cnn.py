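"""Output-size arithmetic, shape chains vs actual forward passes, streams."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gcndecode as g
from gcndecode.cnn import (
    InfeasibleArchitectureError,
    LayerSpec,
    default9_layers,
    depth_sweep_layers,
)
from gcndecode.rois import ROI_NAMES

from conftest import TINY_GRID, TINY_LAYERS


class TestOutputSize:
    @pytest.mark.parametrize(
        "I,P,D,K,S,expected",
        [
            (64, 0, 1, 5, 1, 60),
            (4, 0, 1, 3, 2, 1),
            (46, 0, 1, 3, 2, 22),
            (50, 0, 1, 3, 1, 48),
            (10, 2, 1, 3, 1, 12),   # padding exercised even though unused by default
            (10, 0, 2, 3, 1, 6),    # dilation widens the effective kernel
        ],
    )
    def test_formula(self, I, P, D, K, S, expected):
        assert g.output_size(I, P, D, K, S) == expected

    def test_collapse_raises(self):
        with pytest.raises(InfeasibleArchitectureError):
            g.output_size(2, 0, 1, 3, 1)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            g.output_size(0, 0, 1, 3, 1)


class TestShapeChain:
    def test_default9_collapses_to_unit_grid(self):
        chain = g.shape_chain(g.StreamConfig())
        assert [c[0] for c in chain] == [50, 48, 46, 22, 20, 18, 8, 6, 4, 1]
        assert [c[1] for c in chain] == [64, 60, 56, 27, 23, 19, 9, 5, 3, 1]
        assert [c[2] for c in chain] == [64, 60, 56, 27, 23, 19, 9, 5, 3, 1]
        assert chain[-1] == (1, 1, 1)

    def test_depth_after_first_pool_is_22(self):
        chain = g.shape_chain(g.StreamConfig())
        assert chain[3][0] == 22  # layers C1, C2, S1 applied

    def test_infeasible_grid_raises_naming_layer(self):
        with pytest.raises(InfeasibleArchitectureError, match="layer"):
            g.shape_chain(g.StreamConfig(), input_extents=(8, 8, 8))

    def test_matches_forward_pass_small_config(self, rng):
        # 2 conv + 1 pool on a (10, 12, 12) input
        layers = [
            LayerSpec("conv3d", (3, 3, 3), (1, 1, 1), 4),
            LayerSpec("conv3d", (3, 3, 3), (1, 1, 1), 4),
            LayerSpec("maxpool3d", (3, 3, 3), (2, 2, 2)),
        ]
        cfg = g.StreamConfig(layers=layers, input_grid=(10, 12, 12))
        stream = g.build_stream(cfg)
        x = rng.normal(size=(2, 3, 10, 12, 12))
        observed = [s[2:] for s in stream.layer_output_shapes(x)]
        assert observed == g.shape_chain(cfg)[1:]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_forward_pass_random_configs(self, data):
        grid = tuple(data.draw(st.integers(7, 14), label=f"g{i}") for i in range(3))
        n_layers = data.draw(st.integers(1, 3), label="n_layers")
        layers, extents = [], grid
        for li in range(n_layers):
            kind = data.draw(st.sampled_from(["conv3d", "maxpool3d"]), label=f"k{li}")
            kernel = tuple(
                data.draw(st.integers(1, min(3, e)), label=f"ker{li}{ax}")
                for ax, e in enumerate(extents)
            )
            if kind == "conv3d":
                layers.append(LayerSpec(kind, kernel, (1, 1, 1), 4))
                extents = tuple(e - k + 1 for e, k in zip(extents, kernel))
            else:
                layers.append(LayerSpec(kind, kernel, (2, 2, 2)))
                extents = tuple((e - k) // 2 + 1 for e, k in zip(extents, kernel))
        cfg = g.StreamConfig(layers=layers, input_grid=grid)
        stream = g.build_stream(cfg)
        x = np.random.default_rng(0).normal(size=(1, 3) + grid)
        observed = [s[2:] for s in stream.layer_output_shapes(x)]
        assert observed == g.shape_chain(cfg)[1:]

    @pytest.mark.parametrize("n_layers", [6, 7, 8, 9, 10, 11])
    def test_depth_sweep_presets_feasible(self, n_layers):
        specs = depth_sweep_layers(n_layers)
        n_conv = sum(1 for s in specs if s.kind == "conv3d")
        n_pool = len(specs) - n_conv
        assert len(specs) == n_layers
        assert (n_conv, n_pool) == {
            6: (3, 3), 7: (4, 3), 8: (5, 3), 9: (6, 3), 10: (6, 4), 11: (7, 4)
        }[n_layers]
        chain = g.shape_chain(g.StreamConfig(layers=specs))
        assert min(chain[-1]) >= 1

    def test_default9_channel_schedule(self):
        convs = [s for s in default9_layers() if s.kind == "conv3d"]
        assert [c.out_channels for c in convs] == [16, 16, 32, 64, 64, 8]
        assert [c.kernel for c in convs] == [(3, 5, 5)] * 5 + [(3, 3, 3)]


class TestBuildStream:
    def test_forward_on_zeros_finite(self, tiny_stream_config):
        stream = g.build_stream(tiny_stream_config)
        out = stream.forward(np.zeros((1, 3) + TINY_GRID))
        assert out.shape == (1, stream.out_features)
        assert np.isfinite(out).all()

    def test_same_seed_identical_parameters(self, tiny_stream_config):
        a = g.build_stream(tiny_stream_config)
        b = g.build_stream(tiny_stream_config)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_feature_width_propagates(self):
        cfg = g.StreamConfig(layers="small", feature_width=4,
                             input_grid=(10, 12, 12))
        stream = g.build_stream(cfg)
        out = stream.forward(np.zeros((2, 3, 10, 12, 12)))
        assert out.shape == (2, 4)

    def test_infeasible_config_raises_before_training(self):
        with pytest.raises(InfeasibleArchitectureError):
            g.build_stream(g.StreamConfig(input_grid=(10, 10, 10)))

    def test_gradient_reaches_first_conv(self, tiny_stream_config, rng):
        from gcndecode import nn

        stream = g.build_stream(tiny_stream_config)
        params = stream.params()
        before = [p.value.copy() for p in params]
        opt = nn.Adam(params, lr=0.01)
        x = rng.normal(size=(4, 3) + TINY_GRID)
        out = stream.forward(x, training=True)
        loss, gy = nn.cross_entropy_loss(out, np.zeros(4, dtype=int))
        opt.zero_grad()
        stream.backward(gy)
        opt.step()
        first_conv = params[0]
        assert not np.allclose(first_conv.value, before[0])


class TestFeatureMatrix:
    def test_eleven_by_width_matrix(self, template, tiny_stream_config, rng):
        streams = g.build_streams(tiny_stream_config)
        scan = rng.normal(size=(3,) + TINY_GRID)
        fm = g.extract_feature_matrix(streams, scan, template)
        assert fm.shape == (11, streams[0].out_features)

    def test_stream_count_mismatch(self, template, tiny_stream_config, rng):
        streams = g.build_streams(tiny_stream_config)[:5]
        with pytest.raises(ValueError, match="streams"):
            g.extract_feature_matrix(streams, rng.normal(size=(3,) + TINY_GRID),
                                     template)

    def test_shared_weights_give_equal_rows_on_uniform_scan(
        self, template, tiny_stream_config
    ):
        cfg = g.StreamConfig(layers=TINY_LAYERS, feature_width=4,
                             input_grid=TINY_GRID, shared_weights=True)
        streams = g.build_streams(cfg)
        fm = g.extract_feature_matrix(streams, np.zeros((3,) + TINY_GRID), template)
        for r in range(1, 11):
            np.testing.assert_allclose(fm[r], fm[0])

    def test_row_permutation_oracle(self, template, tiny_stream_config, rng):
        streams = g.build_streams(tiny_stream_config)
        scan = rng.normal(size=(3,) + TINY_GRID)
        fm = g.extract_feature_matrix(streams, scan, template)
        for r, name in enumerate(ROI_NAMES):
            masked = g.apply_mask(scan, name, template)
            row = streams[r].forward(masked[None])[0]
            np.testing.assert_allclose(fm[r], row)

    def test_masking_locality(self, template, tiny_stream_config, rng):
        streams = g.build_streams(tiny_stream_config)
        scan = rng.normal(size=(3,) + TINY_GRID)
        fm_before = g.extract_feature_matrix(streams, scan, template)
        outside = np.argwhere(
            (template.masks["V1d"] == 0) & (template.masks["HVC"] == 0)
        )[0]
        bumped = scan.copy()
        bumped[(slice(None),) + tuple(outside)] += 100.0
        fm_after = g.extract_feature_matrix(streams, bumped, template)
        np.testing.assert_allclose(fm_after[0], fm_before[0])
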