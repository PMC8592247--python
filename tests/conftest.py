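import numpy as np
import pytest

from cxrprior.model import DualStreamModel, ModelConfig
from cxrprior.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom_cfg() -> PhantomConfig:
    """Desk-scale phantom population shared across tests."""
    return PhantomConfig(
        image_size=32,
        n_subjects=60,
        disease_blob_radius=2.0,
        gender_geometry_effect=0.4,
        disease_prevalence=0.12,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_records(small_phantom_cfg):
    return generate_phantom(small_phantom_cfg)


@pytest.fixture()
def tiny_model() -> DualStreamModel:
    cfg = ModelConfig(input_size=32, filters_per_block=(4, 8, 8), n_classes=2)
    return DualStreamModel(cfg, seed=0)
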