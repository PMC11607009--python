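"""Simulate a tracked session and close the loop: FRE, FLE estimate, TRE.

Places the configured device under a random rigid patient pose, adds
isotropic localization noise (0.4 mm RMS) to every fiducial over ten
registration repeats, registers each repeat, and compares the measured
target registration error with the analytic prediction.
"""

from fidkit import (
    PhantomSpec,
    WheelConfiguration,
    evaluate_session,
    simulate_tracking_session,
)

spec = PhantomSpec(tracker_fle_rms_mm=0.4, seed=42)
configuration = WheelConfiguration(spec.geometry.wheel_ids, (5, 5, 8, 2))

session = simulate_tracking_session(spec, configuration, n_repeats=10)
report = evaluate_session(session, target_labels=spec.target_labels)

print(f"configuration (B, G, R, Y): {configuration.label()}")
print(f"N = {report.n_fiducials} fiducials, {session.n_repeats} repeats")
print(f"RMS FRE over repeats: {report.fre_rms:.3f} mm")
print(f"FLE estimated from FREs: {report.fle_est_rms:.3f} mm "
      f"(true {session.fle_rms:.3f} mm)")
print(report.to_frame().to_string(index=False,
                                  float_format=lambda x: f"{x:.3f}"))

# FLE_est^2 = N/(N-2) * mean(FRE^2) inverts the expected FRE deficit of the
# rigid fit; with only ten repeats it is a coarse but unbiased estimate.
# Measured TRE fluctuates around the predicted value for the same reason.
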