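"""Simulate one subject's four runs and watch activation focalise.

Across feedback runs the generator shrinks the stable "hand-area"
regions toward their cores and fades the transient early-training
regions — the widespread-to-focal trajectory that makes a statically
trained classifier go stale.
"""

import numpy as np

from nfdecode import Condition, simulate_subject

subject = simulate_subject(subject_id=0, seed=0)

print(f"grid {subject.config.grid_dims}, learning_rate "
      f"{subject.config.learning_rate:.3f}")
print("run  active LGO voxels  active RGO voxels")
for run in subject.runs:
    n_lgo = int(run.truth_masks[Condition.LGO].sum())
    n_rgo = int(run.truth_masks[Condition.RGO].sum())
    print(f"  {run.run_index}    {n_lgo:5d}             {n_rgo:5d}")

# The active-voxel counts shrink monotonically: a model trained on run 0
# relies on voxels that are no longer informative by run 3.
core = subject.runs[0].data[17, 12, 7]
print(f"run-0 hand-area voxel: mean {core.mean():.1f}, sd {core.std():.2f} "
      "(task modulation ~2% of baseline under AR(1) noise)")
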