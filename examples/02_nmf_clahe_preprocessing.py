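"""NMF compression followed by CLAHE on one phantom.

Shows the two-stage preprocessing that builds the Ver_NMF dataset
version: a rank-kappa non-negative factorization whose reconstruction
suppresses small disease blobs, then contrast-limited adaptive
histogram equalization that amplifies the surviving anatomy edges.
"""

import numpy as np

from cxrprior import CLAHEConfig, NMFConfig, PhantomConfig, generate_phantom
from cxrprior.preprocess import clahe_enhance, max_admissible_kappa, nmf_compress

cfg = PhantomConfig(image_size=64, n_subjects=1, disease_blob_radius=4.0,
                    disease_prevalence=0.0, noise_sd=4.0, seed=1)
from cxrprior.phantom import _draw_subject, render_subject

rng = np.random.default_rng(0)
latents = _draw_subject(cfg, rng)
img, meta = render_subject(cfg, latents, rng, diseases=["Mass"])
print("image 64x64 with one 'Mass' blob planted in the left lung field")
print(f"admissible NMF rank bound: kappa < 64*64/(64+64) -> max {max_admissible_kappa(img.shape)}")

br, bc, radius = meta["blob_centers"]["Mass"]
rows, cols = np.ogrid[:64, :64]
disc = (rows - br) ** 2 + (cols - bc) ** 2 <= radius ** 2
ring = ((rows - br) ** 2 + (cols - bc) ** 2 <= (3 * radius) ** 2) & ~disc


def blob_contrast(image):
    """Mean gray inside the blob disc minus its surrounding ring."""
    return float(image[disc].mean() - image[ring].mean())


print(f"\nblob local contrast, original: {blob_contrast(img):5.1f} gray levels")
for kappa in (4, 6, 12):
    res = nmf_compress(img, NMFConfig(kappa=kappa, max_iter=200, tol=0.0, seed=0))
    monotone = bool((np.diff(res.objective_trace) <= 1e-8).all())
    print(f"  kappa={kappa:2d}: contrast {blob_contrast(res.reconstruction):5.1f}, "
          f"Frobenius residual {res.objective_value:7.1f}, monotone: {monotone}")

res = nmf_compress(img, NMFConfig(kappa=6, max_iter=200, seed=0))
enhanced = clahe_enhance(res.reconstruction, CLAHEConfig(nt=(4, 4), cl=2.0))
print(f"after CLAHE on the kappa=6 reconstruction: image std "
      f"{img.std():.1f} -> {enhanced.std():.1f} (contrast amplified)")
# Suppression is rank-dependent: the phantom's anatomy occupies ~5
# components, so only a rank budget near it (kappa ~4-5) starves this
# blob, while kappa >= 12 has rank to spare and reconstructs it fully.
# Across all 14 blob placements the effect is partial (see the methods
# note); CLAHE then amplifies whatever structure survives.
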