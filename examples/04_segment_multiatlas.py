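"""Full multi-atlas segmentation of one target.

All atlases are registered to the target, discordant ones are rejected
against the majority-vote consensus, and the survivors are fused with local
intensity weighting.
"""

import heartseg as hs
from heartseg.pipeline import PipelineConfig

cohort = hs.make_cohort(5, seed=7)
cases = hs.cases_from_cohort(cohort)
target, atlas_cases = cases[0], cases[1:]

result = hs.run_single(target, atlas_cases, PipelineConfig())
fusion = result.segmentation.fusion_results["0%"]
print(f"atlases retained: {fusion.retained_ids}, rejected: {fusion.rejected_ids}")

(_pid, _phase, comp) = result.comparisons[0]
print(f"Heart_auto vs ground truth: DSC {comp.dsc:.3f}, "
      f"MASD {comp.masd_mm:.2f} mm, HD {comp.hd_mm:.1f} mm")
# DSC near 1 means near-perfect overlap; MASD around the voxel size (2.5 mm
# here) matches the surface agreement reported for clinically accepted
# automatic heart contours.
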