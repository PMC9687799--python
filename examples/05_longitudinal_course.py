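"""Follow per-subject TcB courses through a treatment-reversal time series.

Six subjects sampled at three timepoints under a treatment that reverses
the progression programs: TcB should decline, and the per-timepoint kernel
density of gene-shift values should drift toward lower activity.
"""

import numpy as np

import tcburden as tb

matrix, meta, truth, sets = tb.generate_longitudinal_reversal(seed=7)
course, density = tb.longitudinal_course(matrix, meta)

print("per-subject TcB course (timepoints:", ", ".join(meta.timepoint_order) + "):")
for subject, sub in course.groupby("subject_id"):
    vals = " -> ".join(f"{v:.2f}" for v in sub["tcb"])
    print(f"  {subject}: {vals}")

for tp, sub in density.groupby("timepoint", sort=False):
    mean_shift = np.trapezoid(sub["grid"] * sub["density"], sub["grid"])
    print(f"gene-shift density mean at {tp}: {mean_shift:.3f}")

# Every course is (nearly) non-increasing: treatment lowers the global
# transcriptomic burden. The density mean moving left confirms the whole
# transcriptome, scaled per gene to [0, 1], drifts to lower activity.
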