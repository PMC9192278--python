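"""Simulate a CT perfusion acquisition and recover CBF/CBV/MTT/TTP maps
by truncated-SVD deconvolution.

The forward model convolves a gamma-variate arterial input function with
an exponential residue per tissue class (20 frames over 45 s); the lesion
gets reduced flow and prolonged transit time.  Deconvolution inverts the
AIF Toeplitz system voxelwise with a relative singular-value cutoff.
"""

import numpy as np

from strokeseg.perfusion import DeconvolutionParams, perfusion_maps
from strokeseg.phantoms import (PerfusionParams, default_spec,
                                make_head_phantom, make_perfusion_series)

vol, mask = make_head_phantom(default_spec(seed=3, shape=(64, 64), n_lesions=1))
params = PerfusionParams(normal_cbf=60.0, normal_mtt=4.0,
                         lesion_cbf=20.0, lesion_mtt=8.0)
series = make_perfusion_series(vol, mask, params)
maps = perfusion_maps(series, DeconvolutionParams(truncation_fraction=0.05))

truth = series.truth_maps
for name, region in [("normal tissue", truth["cbf"] == 60.0),
                     ("ischemic lesion", truth["cbf"] == 20.0)]:
    print(f"{name}:")
    print(f"  CBF {maps.cbf[region].mean():6.1f} mL/100g/min "
          f"(truth {truth['cbf'][region].mean():.0f})")
    print(f"  CBV {maps.cbv[region].mean():6.2f} mL/100g "
          f"(truth {truth['cbv'][region].mean():.2f})")
    print(f"  MTT {maps.mtt[region].mean():6.1f} s "
          f"(truth {truth['mtt'][region].mean():.0f})")
    print(f"  TTP {maps.ttp[region].mean():6.1f} s")
print("\nThe lesion shows the ischemic signature: low CBF, prolonged MTT,")
print("delayed time-to-peak — the pattern read clinically to delineate stroke.")
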