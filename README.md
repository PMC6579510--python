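# orbitrack

A desk-scale simulation and analysis toolkit for **3D orbital tracking** of
organelles in vivo — the feedback microscopy technique in which a focused
laser circles a fluorescent particle and the intensity modulation around the
orbit encodes the particle's offset, enabling nanometre localization at
100 Hz over tens of micrometres of axon.

The package is written for microscopists and quantitative biologists who
want to (a) understand and prototype the tracking method itself — sector
photon statistics, localization estimators, feedback behaviour — without a
microscope, and (b) run the downstream trajectory analyses used for axonal
mitochondrial transport: motion-state segmentation, fast/slow velocity
classification, pause/transition statistics, and colocalization against
stationary organelles seen in a parallel wide-field channel.

## The method in brief

**Localization.** One orbit yields photon counts in 16 angular sectors for
two detection planes placed symmetrically above and below the focal plane.
With the plane-summed counts expressed as a Fourier series
`I(φ) = a₀/2 + Σ (aₖ cos kφ + bₖ sin kφ)`, only the zero- and first-order
coefficients matter:

    φ       = atan2(b₁, a₁)
    Mod_xy  = √(a₁² + b₁²) / a₀          dr = r_orbit · f(Mod_xy)
    Mod_z   = (I₁ − I₂) / (I₁ + I₂)      dz = Δz · g(Mod_z)

The scaling functions `f` and `g` are tabulated from noiseless simulations
of the Gaussian-beam detection model and inverted by binary search with
linear interpolation. The feedback loop re-centers the orbit on every
estimate, falls back to an Archimedean spiral search when the count rate
drops below threshold, interleaves dark (unilluminated) orbits to limit
photobleaching, and hands the accumulated beam offset to the sample stage
once it exceeds 10 µm (long-range tracking).

**Trajectory analysis.** The lateral step angles φₜ = atan2(Δy, Δx) are
autocorrelated in a sliding 64-sample window; directed transport keeps
cos(φₜ − φₜ₋τ) near one while pauses collapse it to zero. The
active/stationary threshold is the mean + 5 std of the same statistic on a
sign-augmented, randomized copy of the angle array. Active phases are
classified fast/slow per direction by a maximum-likelihood two-Gaussian fit
of the phase velocities, with the class boundary at the midpoint of the two
centers.

**Wide-field colocalization.** Moving objects are removed from the 2 Hz
camera movie by the forward-difference rule `I_stat = I + min(I(t+10) − I(t), 0)`;
segment mean images (between stage-recentering events) are thresholded at
µ + 5σ inside a 51 × 11 px corridor around the mapped trajectory, and the
detected resting mitochondria are related to the tracked organelle's motion
states and per-100 nm crossing times.

## Worked example

```python
import numpy as np
import orbitrack as ot

rng = np.random.default_rng(7)
gt = ot.generate_state_trajectory(ot.StateParams(), 120.0, rng)
result = ot.analyze_trajectory(gt.times, gt.positions, rng)
```

Running `python examples/02_segment_motion_states.py` (the same code with
reporting) prints:

```
trajectory: 12001 samples, 22 active phases
randomization threshold: 0.51 (reduced angle correlation above this = directed transport)
binary active/stationary accuracy vs ground truth: 95.9%
velocity mixture: slow 0.37 um/s, fast 0.63 um/s, class boundary 0.50 um/s
  fast_antero    33.9% of samples
  slow_antero     1.1% of samples
  fast_retro      0.0% of samples
  slow_retro      0.7% of samples
  stationary     64.3% of samples
```

The trajectory was generated with fast anterograde speeds around
0.62 µm/s and slow speeds around 0.36 µm/s; the mixture fit recovers both
centers and the per-sample labels agree with the generating ground truth for
~96% of samples. The other example scripts demonstrate closed-loop tracking
precision (`01`), population/transition statistics (`03`), and the
wide-field roadblock analysis (`04`).

A thin CLI wraps the same functions for batch use:

```bash
orbitrack simulate --out run1 --seed 11 --widefield
orbitrack segment run1/trajectory.csv --out run1
orbitrack colocalize --trajectory run1/trajectory_labeled.csv \
    --movie run1/movie.tif --out run1
```

## Layout

| Module | Contents |
| --- | --- |
| `orbitrack.psf` | Gaussian-beam detection model, orbit photon-count simulation |
| `orbitrack.motion` | semi-Markov ground-truth transport generator |
| `orbitrack.lut` | calibration lookup tables f(r), g(z) |
| `orbitrack.tracking` | Fourier localization and the closed feedback loop |
| `orbitrack.segmentation` | angle autocorrelation, randomization threshold |
| `orbitrack.phases` | phase kinematics, two-Gaussian classification |
| `orbitrack.stats` | 10-subset state statistics, transition/pause analysis |
| `orbitrack.diagnostics` | kymographs, heartbeat-artifact QC |
| `orbitrack.scenes` / `orbitrack.widefield` | wide-field rendering and colocalization analysis |
| `orbitrack.io` / `orbitrack.config` / `orbitrack.cli` | tables, TIFF, configs, CLI |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
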