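"""Grad-CAM zone-attention profiling for gender detection.

Trains a short gender phase on phantoms, then quantifies where the
model looks: the attention map of each correctly classified test image
is averaged inside the nine anatomical zones Z11..Z33 (3x3 grid, Z11 =
left shoulder, Z22 = central spine, Z21/Z23 = rib cage flanks).
Because the phantom's gender signal lives in the shoulder-band width,
the top-row zones should dominate.
"""

import warnings

import numpy as np

from cxrprior import (
    ModelConfig,
    PhantomConfig,
    generate_phantom,
    grad_cam,
    overlay,
    split_dataset,
    zone_profile,
)
from cxrprior.model import DualStreamModel
from cxrprior.preprocess import make_version_org
from cxrprior.training import PhaseConfig, run_phase

warnings.filterwarnings("ignore", category=UserWarning)

records = split_dataset(
    generate_phantom(
        PhantomConfig(image_size=32, n_subjects=200, disease_blob_radius=2.0,
                      gender_geometry_effect=0.5, disease_prevalence=0.0, seed=3)
    ),
    seed=3, by="gender",
)
version = make_version_org(records)
model = DualStreamModel(
    ModelConfig(input_size=32, filters_per_block=(6, 12, 24), n_classes=2),
    seed=3,
)
result = run_phase(
    PhaseConfig(task="gender", dataset_version="Ver_ORG", epochs=8),
    version, model, seed=3,
)
print(f"gender val accuracy: {result.log['val_acc'].max():.2f}")

test = version.subset("test")
for label in ("Male", "Female"):
    prof = zone_profile(model, test, label, task="gender")
    top = sorted(prof.fractions, key=prof.fractions.get, reverse=True)[:3]
    row = "  ".join(f"{z}={prof.fractions[z]:.2f}" for z in sorted(prof.fractions))
    print(f"{label:6s} (n={prof.n_images:2d}): {row}")
    print(f"        top zones: {top}")

# Render one overlay (RGB heatmap blend) to show the qualitative view.
img = test[0].pixels
cam = grad_cam(model, img.astype(np.float32) / 255.0, class_index=0)
rgb = overlay(img, cam.upsampled / max(cam.upsampled.max(), 1e-9))
print(f"\noverlay image: shape {rgb.shape}, dtype {rgb.dtype} "
      "(save with PIL.Image.fromarray to view)")
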