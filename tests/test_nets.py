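"""Architecture parsing, shape contracts, and analytic parameter-count oracles."""

import numpy as np
import pytest

from vstain import nets


# ------------------------------------------------------------------ parsing
def test_printed_generator_spec_expands_to_12_layers():
    spec = nets.parse_arch_spec(nets.GENERATOR_128, dims=2)
    assert spec.n_layers == 12  # 1 + 2 + 6 residuals + 2 + 1
    kinds = [t.kind for t in spec.tokens]
    assert kinds == ["c7s1", "d", "d"] + ["R"] * 6 + ["u", "u", "c7s1"]


def test_large_patch_generator_has_9_residuals():
    spec = nets.parse_arch_spec(nets.GENERATOR_256, dims=2)
    assert spec.n_layers == 15
    assert sum(1 for t in spec.tokens if t.kind == "R") == 9


def test_discriminator_spec_with_unicode_separators():
    spec = nets.parse_arch_spec("C64 ‐ C128 ‐ C256 ‐ C512 ‐ F1", dims=2)
    assert spec.n_layers == 5
    assert [t.k for t in spec.tokens] == [64, 128, 256, 512, 1]


def test_unknown_token_reports_position():
    with pytest.raises(nets.ArchParseError, match="x9q"):
        nets.parse_arch_spec("c7s1-64, x9q, u64", dims=2)


def test_spec_round_trips_through_string():
    spec = nets.parse_arch_spec(nets.GENERATOR_128, dims=2)
    again = nets.parse_arch_spec(spec.to_string(), dims=2)
    assert again.tokens == spec.tokens


# ----------------------------------------------------- analytic count oracle
def _analytic_param_count(tokens, dims, in_ch, out_ch):
    """Independent hand formula: conv k^d*cin*cout + cout biases, IN 2c affine."""
    kd = lambda k: k ** dims
    total = 0
    ch = in_ch
    for i, (kind, k) in enumerate(tokens):
        last = i == len(tokens) - 1
        if kind == "c7s1":
            co = out_ch if last else k
            total += kd(7) * ch * co + co
            if not last:
                total += 2 * co
            ch = co
        elif kind == "d":
            total += kd(3) * ch * k + k + 2 * k
            ch = k
        elif kind == "R":
            total += 2 * (kd(3) * k * k + k) + 2 * (2 * k)
        elif kind == "u":
            total += kd(3) * ch * k + k + 2 * k
            ch = k
        elif kind == "C":
            total += kd(4) * ch * k + k + 2 * k
            ch = k
        elif kind == "F":
            total += kd(4) * ch * k + k
            ch = k
    return total


@pytest.mark.parametrize("spec_str,dims", [
    ("c7s1-2, d4, R4 (x1), u2, c7s1-1", 2),
    ("c7s1-2, d3, u2, c7s1-1", 3),
    ("c7s1-4, d8, d16, R16 (x2), u8, u4, c7s1-1", 2),
])
def test_generator_parameter_counts_match_hand_formula(spec_str, dims):
    spec = nets.parse_arch_spec(spec_str, dims=dims, in_channels=1, out_channels=1)
    handle = nets.build_generator(spec)
    expected = _analytic_param_count([(t.kind, t.k) for t in spec.tokens], dims, 1, 1)
    assert handle.n_parameters == expected


def test_discriminator_parameter_count_matches_hand_formula():
    spec = nets.parse_arch_spec("C3 - F1", dims=2, in_channels=1)
    handle = nets.build_discriminator(spec)
    expected = _analytic_param_count([(t.kind, t.k) for t in spec.tokens], 2, 1, 1)
    assert handle.n_parameters == expected


# ------------------------------------------------------------ shape contracts
def test_generator_preserves_shape_2d():
    spec = nets.parse_arch_spec("c7s1-4, d8, d16, R16 (x1), u8, u4, c7s1-1", dims=2)
    g = nets.build_generator(spec)
    out = g(np.zeros((48, 48), np.float32))
    assert out.shape == (48, 48)
    assert out.min() >= -1.0 and out.max() <= 1.0


def test_generator_preserves_shape_3d():
    spec = nets.parse_arch_spec("c7s1-2, d4, R4 (x1), u2, c7s1-1", dims=3)
    g = nets.build_generator(spec)
    assert g(np.zeros((16, 16, 16), np.float32)).shape == (16, 16, 16)


def test_generator_rejects_indivisible_input():
    spec = nets.parse_arch_spec("c7s1-2, d4, d8, R8 (x1), u4, u2, c7s1-1", dims=2)
    g = nets.build_generator(spec)
    with pytest.raises(ValueError, match="divisible"):
        g(np.zeros((18, 18), np.float32))


def test_2d_and_3d_builds_share_layer_sequence():
    """The 3D build is the 2D build with convolutions swapped to 3D."""
    s2 = nets.parse_arch_spec("c7s1-2, d4, R4 (x1), u2, c7s1-1", dims=2)
    s3 = nets.parse_arch_spec("c7s1-2, d4, R4 (x1), u2, c7s1-1", dims=3)
    g2, g3 = nets.build_generator(s2), nets.build_generator(s3)
    names2 = [type(m).__name__ for m in g2.module.layers]
    names3 = [type(m).__name__ for m in g3.module.layers]
    assert names2 == names3
    for m2, m3 in zip(g2.module.layers, g3.module.layers):
        if hasattr(m2, "weight"):
            assert m2.weight.data.shape[:2] == m3.weight.data.shape[:2]
            assert m2.weight.data.ndim + 1 == m3.weight.data.ndim


def _disc_out_edge(n, n_c_blocks):
    """Closed-form shape recurrence: stride-2 4x4 pad-1 convs then one stride-1."""
    for _ in range(n_c_blocks):
        n = (n + 2 - 4) // 2 + 1
    return n + 2 - 4 + 1


def test_discriminator_score_map_shape_closed_form():
    spec = nets.parse_arch_spec(nets.DISCRIMINATOR, dims=2)
    d = nets.build_discriminator(spec)
    out = d(np.zeros((1, 1, 128, 128), np.float32))
    edge = _disc_out_edge(128, 4)
    assert out.shape == (1, 1, edge, edge)


def test_discriminator_3d_and_single_channel_output():
    spec = nets.parse_arch_spec("C4 - C8 - F1", dims=3)
    d = nets.build_discriminator(spec)
    out = d(np.zeros((1, 1, 16, 16, 16), np.float32))
    assert out.shape[1] == 1 and out.ndim == 5
    assert all(o < 16 for o in out.shape[2:])


def test_discriminator_requires_final_f_token():
    spec = nets.parse_arch_spec("C4 - C8", dims=2)
    with pytest.raises(nets.ArchParseError, match="F token"):
        nets.build_discriminator(spec)


# ------------------------------------------------------------------- U-Net
def test_unet_preserves_shape_and_range():
    u = nets.build_unet(2, depth=2, base_filters=4)
    out = u(np.zeros((32, 32), np.float32))
    assert out.shape == (32, 32)
    assert out.min() >= -1.0 and out.max() <= 1.0


def test_unet_rejects_indivisible_input():
    u = nets.build_unet(2, depth=3, base_filters=2)
    with pytest.raises(ValueError, match="divisible"):
        u(np.zeros((20, 20), np.float32))


def test_unet_depth1_parameter_count_matches_hand_formula():
    u = nets.build_unet(2, depth=1, base_filters=2, seed=0)
    base = 2
    # encoder block: two 3x3 convs (1->2, 2->2) each + IN
    enc = (9 * 1 * 2 + 2 + 4) + (9 * 2 * 2 + 2 + 4)
    down = 9 * 2 * 2 + 2
    bottle = (9 * 2 * 4 + 4 + 8) + (9 * 4 * 4 + 4 + 8)
    up = 9 * 4 * 2 + 2
    dec = (9 * 4 * 2 + 2 + 4) + (9 * 2 * 2 + 2 + 4)  # concat doubles input
    final = 1 * 2 * 1 + 1
    assert u.n_parameters == enc + down + bottle + up + dec + final


def test_unet_skip_concatenation_doubles_decoder_input():
    u = nets.build_unet(2, depth=2, base_filters=4)
    for level, dec_block in enumerate(u.module.dec):
        first_conv = dec_block.layers[0]
        out_ch = first_conv.weight.data.shape[0]
        assert first_conv.weight.data.shape[1] == 2 * out_ch


# -------------------------------------------------------------- checkpoints
def test_checkpoint_round_trip(tmp_path, rng):
    spec = nets.parse_arch_spec("c7s1-2, d4, R4 (x1), u2, c7s1-1", dims=2)
    g = nets.build_generator(spec, seed=1)
    x = rng.normal(size=(16, 16)).astype(np.float32)
    before = g(x)
    nets.save_checkpoint(g, tmp_path / "g.npz")
    loaded = nets.load_checkpoint(tmp_path / "g.npz")
    np.testing.assert_allclose(loaded(x), before, atol=1e-6)
    assert loaded.spec.source == spec.source
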