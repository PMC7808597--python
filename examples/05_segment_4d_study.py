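"""Segment a ten-phase 4D study and build the motion-encompassing PRV.

The heart is segmented once on the 0% phase by multi-atlas fusion, carried
to the other nine phases by intra-patient demons registration, and the PRV
is the union of all ten delineations.
"""

import heartseg as hs
from heartseg.pipeline import PipelineConfig

cohort = hs.make_cohort(4, seed=3)
motion = hs.MotionSpec(amplitude_mm=10.0)
target = hs.cases_from_cohort(cohort[:1], motion=motion)[0]
atlases = hs.cases_from_cohort(cohort[1:])

result = hs.run_single(target, atlases, PipelineConfig(mode="propagate"))
print("per-phase agreement with ground truth:")
for pid, phase, comp in result.comparisons:
    print(f"  {phase:>3}: DSC {comp.dsc:.3f}  MASD {comp.masd_mm:.2f} mm")
seg = result.segmentation
print(f"cost: {seg.log['n_fusions']} fusion + {seg.log['n_propagations']} propagations")
# The PRV row compares the union of the ten automatic delineations with the
# union of the ten ground-truth masks — the analogue of checking the
# motion-encompassing contour against one drawn on a MIP image.
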