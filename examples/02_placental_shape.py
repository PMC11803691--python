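"""Placental shape metrics from the binary mask.

Builds placenta masks with growing boundary-perturbation amplitude and
prints the three mask-derived measures: volume (voxel count × voxel
volume), the morphology score (mean + SD of the distance-to-boundary map;
higher = bulkier, less uniformly shaped), and the maximum-thickness
estimate (twice the largest distance value).
"""

import dataclasses

from fetalt2star import PhantomSpec, morphology_metrics
from fetalt2star.synthetic import make_placenta_mask

print("amplitude_mm  volume_cm3  morphology  max_thickness_mm")
for amp in (0.0, 2.0, 4.0, 6.0, 8.0):
    spec = dataclasses.replace(PhantomSpec(), perturb_amplitude_mm=amp, seed=7)
    result = morphology_metrics(make_placenta_mask(spec))
    print(
        "%12.1f  %10.1f  %10.3f  %16.1f"
        % (amp, result.volume_mm3 / 1000.0, result.morphology_score, result.max_thickness_mm)
    )
print("\nthe morphology score rises strictly with the perturbation amplitude:")
print("bumpier boundaries and locally thicker lobes read as bulkier shapes.")
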