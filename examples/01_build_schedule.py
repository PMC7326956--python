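"""Build the study's block schedule and inspect its label bookkeeping.

The default run is nine 30-s rest blocks bracketing eight 30-s task
blocks (4 imagined left-hand, 4 right-hand gripping/opening) at
TR 2.0 s — 255 volumes.
"""

from nfdecode import Condition, build_schedule

schedule = build_schedule(9, 4, 4, block_s=30.0, tr_s=2.0)

print(f"volumes per run : {schedule.n_volumes}")
print(f"blocks          : {[str(c) for c, _ in schedule.blocks]}")
counts = schedule.condition_counts()
print(f"volume counts   : REST={counts[Condition.REST]}, "
      f"LGO={counts[Condition.LGO]}, RGO={counts[Condition.RGO]}")

# Shifting labels by 2 volumes (4 s) models the hemodynamic delay: the
# BOLD response to a cue arrives roughly one HRF peak-time later.
shifted = schedule.with_shift(2).labels()
print(f"labels around first task onset (shift 2): "
      f"{[str(l) for l in shifted[13:19]]}")
# The printed counts are the TPV denominators: 60 task volumes per
# condition per run.
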