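"""Generate a synthetic head CT slice with lesions and a low-dose copy.

The phantom is a head-shaped attenuation map in Hounsfield units: a
+1000 HU skull ring, ~35 HU parenchyma, ~8 HU ventricles and hypodense
ellipsoidal lesions.  The low-dose realization adds Gaussian noise of
known sigma — the ground truth every denoiser is scored against.
"""

import numpy as np

from strokeseg.core import NoiseModel
from strokeseg.phantoms import add_lowdose_noise, default_spec, make_head_phantom

spec = default_spec(seed=7, shape=(128, 128), n_lesions=2)
volume, mask = make_head_phantom(spec)
pair = add_lowdose_noise(volume, NoiseModel(sigma=25.0, seed=7))

brain = (volume.data > -200) & (volume.data < 300)
print(f"phantom shape {volume.shape}, spacing {volume.spacing} mm")
print(f"brain mean attenuation: {volume.data[brain].mean():6.1f} HU")
print(f"lesion voxels: {mask.volume_voxels()} "
      f"({100 * mask.volume_voxels() / mask.data.size:.1f}% of the slice)")
resid = pair.noisy.data - pair.clean.data
print(f"added noise: mean {resid.mean():+.2f} HU, std {resid.std():.2f} HU "
      f"(target sigma 25)")
# the lesion is hypodense: its mean sits below surrounding parenchyma
lesion_mean = volume.data[mask.data == 1].mean()
print(f"lesion mean {lesion_mean:.1f} HU vs parenchyma ~35 HU -> hypodense")
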