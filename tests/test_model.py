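"""Architecture contracts of the dual-stream network."""

import numpy as np
import pytest

from cxrprior.model import DualStreamModel, ModelConfig, ModelConfigError


def test_descriptor_reports_streams_kernels_and_pools():
    cfg = ModelConfig(input_size=128, filters_per_block=(16, 32, 64),
                      embedding_len=8, n_classes=2)
    model = DualStreamModel(cfg, seed=0)
    desc = model.describe()
    for stream, kernel in zip(desc["streams"], (3, 5)):
        assert stream["n_conv"] == 6
        assert stream["n_pool"] == 3
        convs = [l for l in stream["layers"] if l["kind"] == "conv"]
        assert all(c["kernel"] == kernel for c in convs)
    # 128 / 2^3 = 16 per stream after the three poolings
    assert cfg.feature_map_size == 16
    assert desc["f_total_len"] == 2 * 16 * 16 * 64


def test_f_total_is_concatenation(tiny_model):
    rng = np.random.default_rng(0)
    x = rng.random((3, 32, 32)).astype(np.float32)
    _, bank = tiny_model.forward(x)
    assert bank.f_total.shape[1] == bank.f_s1.shape[1] + bank.f_s2.shape[1]
    np.testing.assert_array_equal(bank.f_total[:, : bank.f_s1.shape[1]], bank.f_s1)


def test_param_count_is_config_determined():
    """Golden regression: the default desk-scale config's parameter count."""
    cfg = ModelConfig(input_size=32, filters_per_block=(4, 8, 8), n_classes=2)
    a = DualStreamModel(cfg, seed=0)
    b = DualStreamModel(cfg, seed=99)
    assert a.param_count() == b.param_count() == 12568


def test_inference_deterministic_and_scores_nonnegative(tiny_model):
    rng = np.random.default_rng(1)
    x = rng.random((2, 32, 32)).astype(np.float32)
    e1, _ = tiny_model.forward(x)
    e2, _ = tiny_model.forward(x)
    np.testing.assert_array_equal(e1.scores, e2.scores)
    assert (e1.scores >= 0).all()
    assert (e1.scores < 1).all()


def test_both_streams_feed_the_head(tiny_model):
    """Ablation probe: zeroing the stream-2 half of F_total changes the
    head output, so the concatenation is genuinely consumed."""
    rng = np.random.default_rng(2)
    x = rng.random((1, 32, 32)).astype(np.float32)
    emb, bank = tiny_model.forward(x)
    half = bank.f_s1.shape[1]
    ablated = bank.f_total.copy()
    ablated[:, half:] = 0.0
    out = tiny_model.head.forward(ablated, train=False)
    full = tiny_model.head.forward(bank.f_total, train=False)
    assert not np.allclose(out, full)


def test_concatenation_equivariance(tiny_model):
    """Swapping (F_S1, F_S2) together with the head's weight halves leaves
    the output unchanged."""
    rng = np.random.default_rng(3)
    x = rng.random((2, 32, 32)).astype(np.float32)
    _, bank = tiny_model.forward(x)
    half = bank.f_s1.shape[1]
    w = tiny_model.head.W.value
    swapped_w = np.concatenate([w[half:], w[:half]], axis=0)
    swapped_f = np.concatenate([bank.f_s2, bank.f_s1], axis=1)
    np.testing.assert_allclose(
        swapped_f @ swapped_w, bank.f_total @ w, rtol=1e-5, atol=1e-6
    )


def test_swap_head_preserves_backbone(tiny_model):
    before = tiny_model.backbone_checksum()
    head_before = tiny_model.head_checksum()
    tiny_model.swap_head(4, task_kind="single", seed=5)
    assert tiny_model.backbone_checksum() == before
    assert tiny_model.head_checksum() != head_before
    emb, _ = tiny_model.forward(np.zeros((1, 32, 32), dtype=np.float32))
    assert emb.scores.shape == (1, 4)


def test_swap_same_count_fresh_seed_changes_head_only(tiny_model):
    before = tiny_model.backbone_checksum()
    h0 = tiny_model.head_checksum()
    tiny_model.swap_head(2, seed=123)
    assert tiny_model.head_checksum() != h0
    assert tiny_model.backbone_checksum() == before


def test_gradient_reaches_every_block():
    """After one backward pass, every block of both streams accumulates a
    nonzero parameter gradient (no dead stream)."""
    cfg = ModelConfig(input_size=32, filters_per_block=(4, 8, 8), n_classes=2,
                      dropout_rate=0.0)
    model = DualStreamModel(cfg, seed=0)
    rng = np.random.default_rng(4)
    x = rng.random((4, 32, 32)).astype(np.float32)
    emb, _ = model.forward(x, train=True)
    model.backward(np.ones_like(emb.vectors))
    for stream in (model.stream1, model.stream2):
        convs = [l for l in stream if l.kind == "conv"]
        assert len(convs) == 6
        for conv in convs:
            assert np.abs(conv.W.grad).max() > 0


def test_shape_mismatch_names_expected_size(tiny_model):
    with pytest.raises(ValueError, match="32"):
        tiny_model.forward(np.zeros((1, 16, 16)))


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(input_size=100),                      # not divisible by 8
        dict(kernel_s1=3, kernel_s2=3),            # identical kernels
        dict(blocks_per_stream=2),
        dict(filters_per_block=(8, 16)),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ModelConfigError):
        base = dict(input_size=32, filters_per_block=(4, 8, 8))
        ModelConfig(**{**base, **kwargs}).validate()


def test_checkpoint_round_trip(tmp_path, tiny_model):
    rng = np.random.default_rng(5)
    x = rng.random((2, 32, 32)).astype(np.float32)
    before, _ = tiny_model.forward(x)
    path = tiny_model.save(tmp_path / "model.npz")
    loaded = DualStreamModel.load(path)
    after, _ = loaded.forward(x)
    np.testing.assert_array_equal(before.scores, after.scores)
    assert loaded.cfg == tiny_model.cfg
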