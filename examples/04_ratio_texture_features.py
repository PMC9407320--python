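"""Two-band ratio image and the 24-element MAM feature vector.

The ratio image K_782/999 divides the reflectance bands nearest 782 and
999.3 nm, cancelling the multiplicative shading field, and its GLCM texture
over the bruise region plus the three band means form the classifier input.
"""

import numpy as np

import hsibruise as hb
from hsibruise.pca import BandSelection
from hsibruise.texture import band_ratio, mam_features

cube, frames, truth = hb.generate_phantom(hb.PhantomConfig(grade="III", seed=2))
refl = hb.calibrate(cube, frames)
fruit = hb.make_fruit_mask(refl)

# illumination flattening: coefficient of variation on sound tissue
sound = truth.fruit_mask & ~truth.bruise_mask
ratio = band_ratio(refl, 782.0, 999.3, fruit)
ja = refl.data[:, :, hb.nearest_band(refl, 782.0)]
cov = lambda v: v.std() / abs(v.mean())
print(f"CoV on sound tissue: single band {cov(ja[sound]):.3f}, "
      f"ratio image {cov(ratio.values[sound]):.3f}")

verdict, seg = hb.triage(refl, fruit)
bands = BandSelection(np.array([782.0, 944.3, 999.3]), np.arange(3), source_pc=1)
fv = mam_features(refl, seg, bands, fruit)
for name, value in list(zip(fv.names(), fv.to_array()))[:9]:
    print(f"  {name:>16s} = {value:.4f}")
print(f"  ... ({len(fv.to_array())} features total)")
# The ratio image is far more uniform than a single band, so its mean gray
# and texture reflect the bruise, not the illumination.
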