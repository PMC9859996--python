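"""Architecture structure, shape contracts, gating and checkpointing."""

from dataclasses import replace

import numpy as np
import pytest

from busgate.model import (GatedDenseUNet, NetworkConfig, Prediction,
                           build_baseline, build_network, load_checkpoint,
                           predict, save_checkpoint)

TINY = NetworkConfig(input_size=16, growth_rate=2, initial_channels=4,
                     bottleneck_factor=2, seed=0)


@pytest.fixture(scope="module")
def tiny_net():
    return build_network(TINY)


def test_reference_block_counts():
    """Encoder dense blocks hold 3/4/8/12 conv blocks; decoder 8/4/3."""
    net = build_network(NetworkConfig(input_size=16, growth_rate=2,
                                      initial_channels=4, seed=1))
    assert [len(db.blocks) for db in net.encoder_blocks] == [3, 4, 8, 12]
    assert [len(db.blocks) for db in net.decoder_blocks] == [8, 4, 3]
    assert len(net.transitions_down) == 3
    assert len(net.transitions_up) == 3


def test_dense_channel_arithmetic(tiny_net):
    """Every dense block satisfies C_out = C_in + m * growth_rate."""
    g = TINY.growth_rate
    for db in tiny_net.encoder_blocks + tiny_net.decoder_blocks:
        assert db.out_channels == db.in_channels + len(db.blocks) * g
        # introspect actual conv shapes: each block's 3x3 conv emits g
        for blk in db.blocks:
            assert blk.conv2.weight.shape[-1] == g


def test_forward_shape_contract(tiny_net):
    x = np.random.default_rng(0).normal(0, 1, (2, 16, 16)).astype(np.float32)
    cls_logit, seg_logit = tiny_net.forward(x)
    assert cls_logit.shape == (2,)
    assert seg_logit.shape == (2, 16, 16)


@pytest.mark.parametrize("size", [16, 24, 32])
def test_segmentation_resolution_matches_input(size):
    cfg = NetworkConfig(input_size=size, growth_rate=2, initial_channels=4,
                        encoder_block_sizes=(1, 1, 1, 1),
                        decoder_block_sizes=(1, 1, 1), seed=0)
    net = build_network(cfg)
    x = np.zeros((1, size, size), dtype=np.float32)
    _, seg = net.forward(x)
    assert seg.shape == (1, size, size)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        NetworkConfig(input_size=60).validate()  # not divisible by 8
    with pytest.raises(ValueError):
        NetworkConfig(encoder_block_sizes=(3, 4, 8)).validate()
    with pytest.raises(ValueError):
        NetworkConfig(growth_rate=0).validate()
    with pytest.raises(ValueError):
        NetworkConfig(cls_threshold=1.5).validate()
    net = build_network(TINY)
    with pytest.raises(ValueError):
        net.forward(np.zeros((1, 24, 24), dtype=np.float32))


def test_gating_forces_empty_mask(tiny_net):
    """Any image judged normal yields an all-zero mask."""
    x = np.random.default_rng(1).normal(0, 1, (3, 16, 16)).astype(np.float32)
    cfg_gate_all = replace(TINY, cls_threshold=1.0)
    preds = predict(tiny_net, x, cfg_gate_all)
    for p in preds:
        assert p.gated
        assert p.mask.sum() == 0
    # threshold 0: gate never fires; mask equals thresholded prob map
    cfg_open = replace(TINY, cls_threshold=0.0)
    preds = predict(tiny_net, x, cfg_open)
    for p in preds:
        assert not p.gated
        np.testing.assert_array_equal(
            p.mask, (p.prob_map >= cfg_open.seg_threshold).astype(np.uint8))


def test_zero_initialized_heads_predict_half():
    """With zeroed final layers, sigmoid outputs are exactly 0.5."""
    net = build_network(TINY)
    net.cls_head.fc.weight.data[...] = 0.0
    net.cls_head.fc.bias.data[...] = 0.0
    net.final_conv.weight.data[...] = 0.0
    net.final_conv.bias.data[...] = 0.0
    x = np.random.default_rng(2).normal(0, 1, (1, 16, 16)).astype(np.float32)
    preds = predict(net, x)
    assert preds[0].p_abnormal == 0.5
    np.testing.assert_array_equal(preds[0].prob_map, 0.5)


def test_baseline_has_no_classifier_and_never_gates():
    base = build_baseline(TINY)
    cls_logit, seg = base.forward(np.zeros((2, 16, 16), dtype=np.float32))
    assert cls_logit is None
    assert seg.shape == (2, 16, 16)
    preds = predict(base, np.zeros((2, 16, 16), dtype=np.float32))
    assert all(not p.gated for p in preds)
    full = build_network(TINY)
    n_base = sum(p.data.size for p in base.parameters())
    n_full = sum(p.data.size for p in full.parameters())
    assert n_base < n_full
    # shared layers have identical shapes under the same seed/config
    base_state = base.named_state()
    full_state = full.named_state()
    for k, v in base_state.items():
        assert full_state[k].shape == v.shape


def test_inference_is_deterministic(tiny_net):
    x = np.random.default_rng(3).normal(0, 1, (2, 16, 16)).astype(np.float32)
    p1 = predict(tiny_net, x)
    p2 = predict(tiny_net, x)
    for a, b in zip(p1, p2):
        assert a.p_abnormal == b.p_abnormal
        np.testing.assert_array_equal(a.prob_map, b.prob_map)


def test_checkpoint_roundtrip(tmp_path, tiny_net):
    x = np.random.default_rng(4).normal(0, 1, (1, 16, 16)).astype(np.float32)
    ref = predict(tiny_net, x)[0]
    path = save_checkpoint(tiny_net, tmp_path / "ck.npz")
    loaded = load_checkpoint(path)
    assert loaded.config == tiny_net.config
    out = predict(loaded, x)[0]
    assert out.p_abnormal == ref.p_abnormal
    np.testing.assert_array_equal(out.prob_map, ref.prob_map)


def test_config_yaml_roundtrip():
    cfg = NetworkConfig(input_size=64, growth_rate=6, upsample_mode="nearest")
    assert NetworkConfig.from_yaml(cfg.to_yaml()) == cfg


def test_prediction_invariants():
    with pytest.raises(ValueError):
        Prediction(p_abnormal=1.2, prob_map=np.zeros((2, 2)),
                   mask=np.zeros((2, 2), dtype=np.uint8), gated=False)
    with pytest.raises(ValueError):
        Prediction(p_abnormal=0.3, prob_map=np.zeros((2, 2)),
                   mask=np.ones((2, 2), dtype=np.uint8), gated=True)
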