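"""The four image-derived indicators: greenness, wetness, dryness, heat.

NDVI and the bare soil index are normalized differences; wetness is the
tasseled-cap third component; LST inverts the thermal radiance through the
single-channel atmospheric correction and the Planck function. Dryness runs
inverse to wetness — bare saline flats are dry, vegetated flats are moist.
"""

import numpy as np

from rseikit import SceneConfig, bare_soil_index, lst, make_scene, ndvi, wetness
from rseikit.indices import resample

scene = make_scene(SceneConfig(seed=5))
roles = scene.band_roles()

greenness = ndvi(roles["red"], roles["nir"])
wet = wetness(roles)
dry = bare_soil_index(roles)
heat = lst(scene.thermal_radiance, scene.lst_params)

for name, g in (("greenness", greenness), ("wetness", wet), ("dryness", dry)):
    print(f"{name:>9}: {np.nanmin(g.values):+.3f} .. {np.nanmax(g.values):+.3f}")
print(f"{'heat':>9}: {np.nanmin(heat.values):.2f} .. "
      f"{np.nanmax(heat.values):.2f} degC "
      f"(truth recovered to {np.abs(heat.values - scene.truth_lst.values).max():.1e})")

r = np.corrcoef(wet.values.ravel(), dry.values.ravel())[0, 1]
print(f"corr(wetness, dryness) = {r:+.2f} — the expected inverse relation")

# a 30 m thermal product resampled onto the 10 m optical grid
coarse = resample(heat, 30.0, "nearest")
fine = resample(coarse, 10.0, "bilinear")
print(f"30 m -> 10 m resample: {coarse.shape} -> {fine.shape}")
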