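"""NMF compression, CLAHE enhancement, augmentation and splitting."""

import numpy as np
import pytest

from cxrprior.phantom import ImageRecord
from cxrprior.preprocess import (
    CLAHEConfig,
    NMFConfig,
    PreprocessConfigError,
    augment_balance,
    clahe_enhance,
    make_version_nmf,
    make_version_org,
    max_admissible_kappa,
    n_tiles,
    nmf_compress,
    split_dataset,
)

# ---------------------------------------------------------------------------
# NMF


def test_rank1_matrix_recovered_exactly():
    v = np.outer([1.0, 2.0, 3.0], [4.0, 5.0])
    res = nmf_compress(v, NMFConfig(kappa=1, max_iter=200, tol=0.0))
    assert res.objective_value < 1e-6
    assert (res.W >= 0).all() and (res.H >= 0).all()


def test_kappa_bound_64x64():
    assert max_admissible_kappa((64, 64)) == 31
    with pytest.raises(PreprocessConfigError, match=r"n\*m/\(n\+m\)"):
        nmf_compress(np.ones((64, 64)), NMFConfig(kappa=32))
    # kappa = 31 is admissible
    NMFConfig(kappa=31).validate_for((64, 64))


@pytest.mark.parametrize("objective", ["frobenius", "log_form"])
@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_objective_monotone_nonincreasing(objective, seed):
    rng = np.random.default_rng(seed)
    v = rng.random((20, 20)) * 50
    res = nmf_compress(
        v, NMFConfig(kappa=4, max_iter=60, tol=0.0, objective=objective, seed=seed)
    )
    diffs = np.diff(res.objective_trace)
    assert (diffs <= 1e-8 * max(1.0, res.objective_trace[0])).all()


def test_rank_nesting_reduces_error():
    """A richer factorization fits at least as well as rank 1, comparing
    rank 1 against the largest admissible rank under the kappa bound."""
    rng = np.random.default_rng(9)
    v = rng.random((16, 12)) * 100
    k_max = max_admissible_kappa(v.shape)
    lo = nmf_compress(v, NMFConfig(kappa=1, max_iter=300, tol=0.0, seed=0))
    hi = nmf_compress(v, NMFConfig(kappa=k_max, max_iter=300, tol=0.0, seed=0))
    assert hi.objective_value <= lo.objective_value + 1e-6


def test_matches_reference_mu_solver():
    """Independent route: sklearn's multiplicative-update NMF reaches the
    same Frobenius error ballpark on the same matrix."""
    from sklearn.decomposition import NMF as SkNMF

    rng = np.random.default_rng(0)
    v = rng.random((15, 12)) * 100
    mine = nmf_compress(v, NMFConfig(kappa=3, max_iter=500, tol=0.0, seed=1))
    sk = SkNMF(n_components=3, solver="mu", max_iter=2000, init="random",
               random_state=1).fit(v)
    ref = np.linalg.norm(v - sk.transform(v) @ sk.components_)
    assert mine.objective_value == pytest.approx(ref, rel=0.05)


def test_negative_pixels_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        nmf_compress(np.array([[1.0, -2.0], [3.0, 4.0]]), NMFConfig(kappa=1))


def test_reconstruction_is_8bit_low_rank():
    rng = np.random.default_rng(1)
    v = (rng.random((32, 32)) * 255).astype(np.uint8)
    res = nmf_compress(v, NMFConfig(kappa=3, max_iter=100))
    assert res.reconstruction.dtype == np.uint8
    assert np.linalg.matrix_rank(res.W @ res.H) <= 3


# ---------------------------------------------------------------------------
# CLAHE


def test_tile_count_512_with_8x8_grid():
    assert n_tiles((512, 512), CLAHEConfig(nt=(8, 8))) == 64


def test_constant_image_stays_constant():
    img = np.full((64, 64), 77, dtype=np.uint8)
    out = clahe_enhance(img, CLAHEConfig(nt=(4, 4)))
    assert out.shape == img.shape and out.dtype == np.uint8
    assert len(np.unique(out)) == 1


def test_entropy_not_decreased_on_low_contrast_gradient():
    img = (np.linspace(100, 140, 64)[None, :] * np.ones((64, 1))).astype(np.uint8)

    def entropy(im):
        p = np.bincount(im.ravel(), minlength=256) / im.size
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    out = clahe_enhance(img, CLAHEConfig(nt=(4, 4)))
    assert entropy(out) >= entropy(img)


def test_double_application_stable_in_distribution():
    """Re-equalizing an already-equalized image barely moves its gray-level
    distribution (16-bin histogram L1 distance below 0.5; a regression
    tolerance, not a theorem)."""
    rng = np.random.default_rng(0)
    img = (rng.random((64, 64)) * 50 + 80).astype(np.uint8)
    once = clahe_enhance(img, CLAHEConfig(nt=(4, 4)))
    twice = clahe_enhance(once, CLAHEConfig(nt=(4, 4)))
    h1, _ = np.histogram(once, bins=16, range=(0, 256))
    h2, _ = np.histogram(twice, bins=16, range=(0, 256))
    assert np.abs(h1 / h1.sum() - h2 / h2.sum()).sum() < 0.5


def test_oversized_tile_grid_rejected():
    with pytest.raises(PreprocessConfigError, match="exceeds"):
        clahe_enhance(np.zeros((16, 16), dtype=np.uint8), CLAHEConfig(nt=(32, 32)))


def test_odd_size_padded_and_cropped_back():
    rng = np.random.default_rng(2)
    img = (rng.random((50, 37)) * 255).astype(np.uint8)
    out = clahe_enhance(img, CLAHEConfig(nt=(3, 3)))
    assert out.shape == img.shape


# ---------------------------------------------------------------------------
# Dataset versions


def test_ver_nmf_same_ids_different_pixels(small_records):
    subset = small_records[:10]
    ver = make_version_nmf(subset, NMFConfig(kappa=6, max_iter=50),
                           CLAHEConfig(nt=(4, 4)))
    assert ver.tag == "Ver_NMF"
    assert [r.image_id for r in ver.records] == [r.image_id for r in subset]
    assert all(
        (a.pixels != b.pixels).any() for a, b in zip(ver.records, subset)
    )
    # labels and roles untouched
    for a, b in zip(ver.records, subset):
        assert (a.gender, a.age_years, a.diseases, a.role) == (
            b.gender, b.age_years, b.diseases, b.role
        )


def test_ver_nmf_empty():
    assert make_version_nmf([], NMFConfig(kappa=2)).records == []


def test_batch_independence(small_records):
    one = make_version_nmf(small_records[3:4], NMFConfig(kappa=6, max_iter=50),
                           CLAHEConfig(nt=(4, 4)))
    batch = make_version_nmf(small_records[:10], NMFConfig(kappa=6, max_iter=50),
                             CLAHEConfig(nt=(4, 4)))
    assert one.records[0].pixels.tobytes() == batch.records[3].pixels.tobytes()


def test_per_image_errors_carry_image_id(small_records):
    bad = small_records[0].replace(pixels=np.zeros((7, 7), dtype=np.uint8))
    with pytest.raises(PreprocessConfigError, match=bad.image_id):
        make_version_nmf([bad], NMFConfig(kappa=30), CLAHEConfig())


def test_versions_label_isomorphic(small_records):
    split = split_dataset(small_records, seed=0, by="gender")
    org = make_version_org(split)
    nmf = make_version_nmf(split, NMFConfig(kappa=6, max_iter=30),
                           CLAHEConfig(nt=(4, 4)))
    assert org.ids() == nmf.ids()
    for a, b in zip(org.records, nmf.records):
        assert (a.diseases, a.gender, a.age_bin, a.role) == (
            b.diseases, b.gender, b.age_bin, b.role
        )


# ---------------------------------------------------------------------------
# Augmentation


def _gender_counts(records):
    import collections

    return collections.Counter(r.gender for r in records)


def test_balanced_input_is_noop(small_records):
    males = [r for r in small_records if r.gender == "Male"][:5]
    females = [r for r in small_records if r.gender == "Female"][:5]
    out = augment_balance(males + females, by="gender", seed=0)
    assert out == males + females


def test_minority_oversampled_to_majority(small_records):
    males = [r for r in small_records if r.gender == "Male"][:10]
    females = [r for r in small_records if r.gender == "Female"][:4]
    out = augment_balance(males + females, by="gender", seed=0)
    counts = _gender_counts(out)
    assert counts["Male"] == 10 and counts["Female"] == 10
    # originals retained
    assert all(r in out for r in males + females)


def test_rotation_angles_within_limits(small_records):
    males = [r for r in small_records if r.gender == "Male"][:10]
    females = [r for r in small_records if r.gender == "Female"][:2]
    out = augment_balance(males + females, max_angle_deg=30.0, by="gender", seed=3)
    angles = [r.meta["rotation_deg"] for r in out if "rotation_deg" in r.meta]
    assert len(angles) == 8
    assert all(-30.0 <= a <= 30.0 for a in angles)
    # derived ids are unique and reference the source
    ids = [r.image_id for r in out]
    assert len(set(ids)) == len(ids)


def test_missing_class_reported(small_records):
    males = [r for r in small_records if r.gender == "Male"][:3]
    with pytest.raises(ValueError, match="Female"):
        augment_balance(males, by="gender", classes=["Male", "Female"])


# ---------------------------------------------------------------------------
# Splitting


def _mk(i, gender="Male"):
    return ImageRecord(
        image_id=f"r{i}.png", pixels=np.zeros((8, 8), np.uint8),
        gender=gender, age_years=30,
    )


def test_split_80_10_10_single_class():
    recs = [_mk(i) for i in range(1000)]
    out = split_dataset(recs, seed=0, by="gender")
    roles = [r.role for r in out]
    assert roles.count("train") == 800
    assert roles.count("val") == 100
    assert roles.count("test") == 100


def test_split_two_classes_of_five_totals_8_1_1():
    recs = [_mk(i, "Male") for i in range(5)] + [_mk(i + 5, "Female") for i in range(5)]
    out = split_dataset(recs, seed=1, by="gender")
    roles = [r.role for r in out]
    assert roles.count("train") == 8
    assert roles.count("val") == 1 and roles.count("test") == 1
    for g in ("Male", "Female"):
        cls = [r.role for r in out if r.gender == g]
        assert cls.count("train") == 4
        assert sorted([cls.count("val"), cls.count("test")]) == [0, 1]


def test_split_deterministic():
    recs = [_mk(i, "Male" if i % 3 else "Female") for i in range(60)]
    a = split_dataset(recs, seed=1, by="gender")
    b = split_dataset(recs, seed=1, by="gender")
    assert [r.role for r in a] == [r.role for r in b]
    c = split_dataset(recs, seed=2, by="gender")
    assert [r.role for r in a] != [r.role for r in c]


def test_tiny_stratum_all_to_train():
    recs = [_mk(0, "Male"), _mk(1, "Male"), _mk(2, "Female")]
    with pytest.warns(UserWarning, match="train"):
        out = split_dataset(recs, seed=0, by="gender")
    assert all(r.role == "train" for r in out)


def test_bad_fractions_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        split_dataset([_mk(0)], fractions=(0.5, 0.2, 0.2))
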