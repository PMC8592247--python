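"""Grad-CAM maps, the 3x3 zone grid and zone-attention profiles."""

import numpy as np
import pytest

from cxrprior.attention import (
    ZONE_NAMES,
    _zone_vector,
    cam_from_activations,
    grad_cam,
    overlay,
    zone_partition,
    zone_profile,
)
from cxrprior.model import DualStreamModel, ModelConfig
from cxrprior.phantom import ImageRecord
from cxrprior.training import PhaseConfig, run_phase
from cxrprior.preprocess import DatasetVersion

# ---------------------------------------------------------------------------
# Zone grid


def test_exact_division_300():
    grid = zone_partition(300)
    for r0, r1, c0, c1 in grid.bounds.values():
        assert (r1 - r0, c1 - c0) == (100, 100)


def test_remainder_bands_on_128():
    grid = zone_partition(128)
    # 128 // 3 = 42, so bands are 42 / 42 / 44
    assert grid.bounds["Z11"] == (0, 42, 0, 42)
    assert grid.bounds["Z22"] == (42, 84, 42, 84)
    assert grid.bounds["Z33"] == (84, 128, 84, 128)


@pytest.mark.parametrize("size", [3, 4, 5, 7, 32, 33, 64, 100])
def test_partition_property(size):
    grid = zone_partition(size)
    cover = np.zeros((size, size), dtype=int)
    for sl in grid.masks().values():
        cover[sl] += 1
    assert (cover == 1).all()
    assert len(grid.bounds) == 9


def test_too_small_image_rejected():
    with pytest.raises(ValueError, match="at least 3x3"):
        zone_partition(2)


# ---------------------------------------------------------------------------
# Grad-CAM arithmetic


def test_cam_hand_computed():
    a1 = np.array([[1.0, 2.0], [3.0, 4.0]])
    a2 = np.array([[0.0, 1.0], [0.0, -1.0]])
    g1 = np.full((2, 2), 0.5)       # weight = 0.5
    g2 = np.array([[1.0, -1.0], [2.0, -2.0]])  # mean = 0
    cam = cam_from_activations(np.stack([a1, a2]), np.stack([g1, g2]))
    np.testing.assert_allclose(cam, 0.5 * a1)


def test_constant_gradient_yields_that_weight():
    a = np.ones((1, 3, 3))
    g = np.full((1, 3, 3), 2.5)
    np.testing.assert_allclose(cam_from_activations(a, g), np.full((3, 3), 2.5))


def test_zero_gradients_zero_map():
    a = np.random.default_rng(0).random((4, 3, 3))
    cam = cam_from_activations(a, np.zeros_like(a))
    np.testing.assert_array_equal(cam, 0.0)


def test_negative_combination_rectified():
    a = np.ones((1, 2, 2))
    g = np.full((1, 2, 2), -1.0)
    np.testing.assert_array_equal(cam_from_activations(a, g), 0.0)


def test_grad_cam_shapes_and_nonnegativity(tiny_model):
    rng = np.random.default_rng(0)
    img = rng.random((32, 32)).astype(np.float32)
    cam = grad_cam(tiny_model, img, class_index=1)
    assert cam.upsampled.shape == (32, 32)
    assert (cam.raw >= 0).all() and (cam.upsampled >= -1e-12).all()
    assert cam.z == cam.raw.size
    with pytest.raises(ValueError, match="class_index"):
        grad_cam(tiny_model, img, class_index=7)


# ---------------------------------------------------------------------------
# Zone profiles


def test_uniform_map_gives_equal_ninths():
    grid = zone_partition(30)
    vec = _zone_vector(np.full((30, 30), 0.7), grid)
    np.testing.assert_allclose(vec, 1.0 / 9.0)


def test_zone_vector_sums_to_one():
    rng = np.random.default_rng(1)
    grid = zone_partition(32)
    vec = _zone_vector(rng.random((32, 32)), grid)
    assert vec.sum() == pytest.approx(1.0, abs=1e-9)


def _patch_records(n, seed, patch=True):
    """Binary phantom stand-ins: class 1 images carry a bright patch in the
    top-left ninth (Z11), class 0 images do not."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        has = i % 2 == 1
        img = (rng.random((32, 32)) * 40 + 30).astype(np.uint8)
        if has and patch:
            img[2:8, 2:8] = 230
        recs.append(
            ImageRecord(
                image_id=f"p{i}.png", pixels=img,
                gender="Male" if has else "Female", age_years=40,
                role="train" if i < int(0.8 * n) else "test",
            )
        )
    return recs


def test_planted_feature_attracts_attention():
    """A classifier whose positive class is defined by a bright Z11 patch
    must put the largest profile fraction on Z11."""
    recs = _patch_records(80, seed=0)
    version = DatasetVersion(tag="Ver_ORG", records=recs)
    # no per-image standardization: the patch moves the global mean, and
    # standardizing would turn every background pixel into class signal
    cfg = ModelConfig(input_size=32, filters_per_block=(4, 8, 8), n_classes=2,
                      dropout_rate=0.0, standardize_input=False)
    model = DualStreamModel(cfg, seed=0)
    run_phase(
        PhaseConfig(task="gender", dataset_version="Ver_ORG", epochs=10,
                    batch_size=16),
        version, model, seed=0,
    )
    profile = zone_profile(model, version.subset("test"), "Male", task="gender")
    assert not profile.empty
    assert profile.fractions["Z11"] == max(profile.fractions.values())
    assert sum(profile.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_profile_empty_when_nothing_correct(tiny_model):
    recs = _patch_records(10, seed=1)
    # untrained model rarely classifies; force emptiness with an impossible class
    profile = zone_profile(tiny_model, [r for r in recs if r.gender == "Male"][:0],
                           "Male", task="gender")
    assert profile.empty
    assert profile.n_images == 0


# ---------------------------------------------------------------------------
# Overlay


def test_overlay_zero_map_returns_grayscale_rgb():
    img = (np.arange(64, dtype=np.uint8).reshape(8, 8) * 3)
    out = overlay(img, np.zeros((8, 8)))
    assert out.shape == (8, 8, 3)
    for c in range(3):
        np.testing.assert_array_equal(out[..., c], img)


def test_overlay_saturated_map_blends_at_alpha():
    img = np.full((4, 4), 100, dtype=np.uint8)
    out = overlay(img, np.ones((4, 4)), alpha=0.4)
    from matplotlib import cm

    expected = 0.6 * (100 / 255.0) + 0.4 * np.array(cm.jet(1.0)[:3])
    np.testing.assert_allclose(out[0, 0] / 255.0, expected, atol=1 / 255.0)


def test_overlay_deterministic_and_shape_checked():
    rng = np.random.default_rng(2)
    img = (rng.random((16, 16)) * 255).astype(np.uint8)
    m = rng.random((16, 16))
    assert overlay(img, m).tobytes() == overlay(img, m).tobytes()
    with pytest.raises(ValueError, match="shape"):
        overlay(img, np.zeros((8, 8)))
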