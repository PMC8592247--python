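"""Sequential training protocol: phases, chaining, determinism, leakage."""

import numpy as np
import pytest

from cxrprior import training
from cxrprior.model import DualStreamModel, ModelConfig
from cxrprior.phantom import PhantomConfig, generate_phantom
from cxrprior.preprocess import (
    CLAHEConfig,
    NMFConfig,
    make_version_nmf,
    make_version_org,
    split_dataset,
)
from cxrprior.training import (
    PhaseConfig,
    VARIANTS,
    VariantError,
    parse_variant,
    run_phase,
    run_protocol,
)

MC = ModelConfig(input_size=32, filters_per_block=(4, 8, 8), n_classes=2)


@pytest.fixture(scope="module")
def gender_versions():
    cfg = PhantomConfig(image_size=32, n_subjects=120, disease_blob_radius=2.0,
                        gender_geometry_effect=0.4, disease_prevalence=0.0, seed=9)
    recs = split_dataset(generate_phantom(cfg), seed=9, by="gender")
    return {
        "Ver_ORG": make_version_org(recs),
        "Ver_NMF": make_version_nmf(recs, NMFConfig(kappa=8, max_iter=60),
                                    CLAHEConfig(nt=(4, 4))),
    }


# ---------------------------------------------------------------------------
# Variant parsing


def test_variant_chains_decode():
    assert parse_variant("DD_ORG") == [("disease", "Ver_ORG")]
    assert parse_variant("GD_NMF => DD_ORG") == [
        ("gender", "Ver_NMF"), ("disease", "Ver_ORG")
    ]
    assert parse_variant("GD_NMF=>AD_NMF=>DD_ORG") == [
        ("gender", "Ver_NMF"), ("age", "Ver_NMF"), ("disease", "Ver_ORG")
    ]


def test_unknown_variant_lists_valid_names():
    with pytest.raises(VariantError) as exc:
        parse_variant("DD_NMF => GD_ORG")
    for name in VARIANTS:
        assert name in str(exc.value)


# ---------------------------------------------------------------------------
# run_phase


def test_zero_epochs_leaves_model_at_init(gender_versions):
    model = DualStreamModel(MC, seed=1)
    before = model.backbone_checksum(), model.head_checksum()
    res = run_phase(
        PhaseConfig(task="gender", dataset_version="Ver_NMF", epochs=0),
        gender_versions["Ver_NMF"], model, seed=0,
    )
    assert res.log.empty
    assert (model.backbone_checksum(), model.head_checksum()) == before


def test_one_epoch_logs_finite_loss(gender_versions):
    model = DualStreamModel(MC, seed=1)
    res = run_phase(
        PhaseConfig(task="gender", dataset_version="Ver_NMF", epochs=1),
        gender_versions["Ver_NMF"], model, seed=0,
    )
    assert len(res.log) == 1
    assert np.isfinite(res.log.loc[0, "train_loss"])
    assert {"train_acc", "val_loss", "val_acc"} <= set(res.log.columns)


def test_gender_task_beats_majority_baseline(gender_versions):
    """With a 0.4 geometry effect the gender phase must do better than
    always predicting the majority class."""
    model = DualStreamModel(MC, seed=1)
    res = run_phase(
        PhaseConfig(task="gender", dataset_version="Ver_NMF", epochs=10),
        gender_versions["Ver_NMF"], model, seed=0,
    )
    assert res.log["val_acc"].max() > 0.5


def test_version_task_mismatch_mentions_naming(gender_versions):
    model = DualStreamModel(MC, seed=1)
    with pytest.raises(ValueError, match="GD/AD/DD"):
        run_phase(
            PhaseConfig(task="gender", dataset_version="Ver_ORG", epochs=1),
            gender_versions["Ver_NMF"], model, seed=0,
        )


def test_head_class_count_checked(gender_versions):
    model = DualStreamModel(MC, seed=1)   # 2-class head
    with pytest.raises(ValueError, match="swap_head"):
        run_phase(
            PhaseConfig(task="age", dataset_version="Ver_NMF", epochs=1),
            gender_versions["Ver_NMF"], model, seed=0,
        )


# ---------------------------------------------------------------------------
# run_protocol


def test_single_variant_runs_one_phase(gender_versions):
    run = run_protocol("GD_ORG", gender_versions, seed=0, model_cfg=MC,
                       fast=True)
    assert len(run.phases) == 1
    assert run.phases[0].config.task == "gender"


def test_chain_passes_backbone_forward(gender_versions, monkeypatch):
    """Phase k+1 must start from exactly the backbone phase k ended with."""
    checksums = []
    original = training.run_phase

    def spy(cfg, data, model, seed=0, checkpoint_path=None):
        checksums.append(("start", model.backbone_checksum()))
        out = original(cfg, data, model, seed=seed, checkpoint_path=checkpoint_path)
        checksums.append(("end", model.backbone_checksum()))
        return out

    monkeypatch.setattr(training, "run_phase", spy)
    run_protocol("GD_NMF => AD_NMF", gender_versions, seed=0, model_cfg=MC,
                 fast=True)
    assert len(checksums) == 4
    # swap_head between phases must not touch the backbone
    assert checksums[1][1] == checksums[2][1]


def test_protocol_deterministic(gender_versions):
    runs = [
        run_protocol("GD_NMF", gender_versions, seed=3, model_cfg=MC, fast=True)
        for _ in range(2)
    ]
    a, b = (r.phases[0].log for r in runs)
    assert a.equals(b)
    assert runs[0].model.backbone_checksum() == runs[1].model.backbone_checksum()


def test_no_test_ids_in_training_batches(gender_versions):
    run = run_protocol("GD_NMF", gender_versions, seed=0, model_cfg=MC,
                       fast=True)
    test_ids = {r.image_id for r in gender_versions["Ver_NMF"].subset("test")}
    val_ids = {r.image_id for r in gender_versions["Ver_NMF"].subset("val")}
    trained = set(run.phases[0].trained_ids)
    assert trained
    assert not trained & test_ids
    assert not trained & val_ids


def test_missing_version_reported():
    with pytest.raises(VariantError, match="Ver_NMF"):
        run_protocol("GD_NMF", {}, seed=0, model_cfg=MC)
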