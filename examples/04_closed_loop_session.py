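"""One subject through the closed loop under both training strategies.

Run 0 trains the initial SVMs; runs 1-3 are classified volume-by-volume
(smooth, mask, incremental detrend, decide, drift-correct the decision,
move the robot arm).  The incremental strategy then retrains on each
newly completed run; the static strategy keeps the run-0 models.
"""

from nfdecode import (
    SessionConfig,
    incremental_session,
    session_metrics,
    simulate_subject,
    static_session,
)

subject = simulate_subject(subject_id=0, seed=0)
config = SessionConfig()  # 8-mm FWHM, c=1, 11-degree increments

inc = incremental_session(subject, config)
sta = static_session(subject, config)

print("TPV (%) per feedback run — task volumes correctly classified as task:")
for res in (inc, sta):
    m = session_metrics(res)
    piv = m.pivot_table(index="contrast", columns="run", values="value")
    print(f"\n{res.strategy}:")
    print(piv.round(1))

angles = inc.run_results[1].feedback_angles
print(f"\nrun-1 peak arm angle: {angles.max():.0f} deg "
      "(11 deg per correct volume, reset at block ends)")
# Expect: both strategies identical at run 1 (same run-0 models); by run 3
# the static TPVs drop sharply while incremental ones hold near ceiling.
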