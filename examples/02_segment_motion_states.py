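"""Motion-state segmentation of a nanoscale transport trajectory.

Generates a synthetic axonal-transport trajectory (alternating directed and
stationary phases with 5 nm localization noise at 100 Hz), segments it with
the angle-autocorrelation pipeline, classifies active phases fast/slow via
the two-Gaussian velocity mixture, and prints the per-state breakdown.
"""

import numpy as np

import orbitrack as ot

rng = np.random.default_rng(7)
gt = ot.generate_state_trajectory(ot.StateParams(), 120.0, rng)
result = ot.analyze_trajectory(gt.times, gt.positions, rng)

accuracy = (result.active == (gt.states != "stationary")).mean()
print(f"trajectory: {gt.n_samples} samples, {len(result.phases)} active phases")
print(f"randomization threshold: {result.carpet.threshold:.2f} "
      "(reduced angle correlation above this = directed transport)")
print(f"binary active/stationary accuracy vs ground truth: {100 * accuracy:.1f}%")
if result.mixture and not result.mixture.degenerate:
    m = result.mixture
    print(f"velocity mixture: slow {m.mu1:.2f} um/s, fast {m.mu2:.2f} um/s, "
          f"class boundary {m.threshold:.2f} um/s")
for state in ("fast_antero", "slow_antero", "fast_retro", "slow_retro", "stationary"):
    frac = (result.labels == state).mean()
    print(f"  {state:12s} {100 * frac:5.1f}% of samples")
print("directed transport separates from pauses because step angles persist")
print("over the 64-sample correlation window only while motors are engaged.")
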