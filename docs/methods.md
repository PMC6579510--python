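# Methods

This note records the models behind `orbitrack`, the parameters that matter,
and the choices made where the published description of the technique leaves
the design open.

## Detection model and orbit simulation

Each detection volume is a 3D Gaussian: a point emitter at lateral distance
r from the beam and axial distance ζ from a detection plane contributes
`brightness · exp(−2r²/w_xy²) · exp(−2ζ²/w_z²)` expected photons per orbit.
The two planes sit at ±Δz/2 about the focal plane; an emitter above focus
gives I₁ > I₂, fixing the sign convention dz > 0 toward plane 1. No
astigmatism, aberrations or vectorial effects are modelled, and the camera
noise model for the wide-field channel is plain Poisson + Gaussian read
noise (no EM-gain register statistics).

Defaults: `w_xy = 300 nm`, `w_z = 700 nm`, `Δz = 1000 nm`, orbit radius
`r_orbit = 150 nm`, 16 sectors, 5 ms orbit period. The instrument's actual
beam geometry is not published; these values follow high-NA confocal
practice and give strictly monotone modulation curves over the tabulated
ranges (lateral 0–1.5 r_orbit, axial ±0.75 Δz). All are configurable.

Because the beam moves continuously, a sector's expected count is the mean
of the point response at 5 equally spaced arc positions within the sector
(error < 0.1% against dense quadrature at 16 sectors; verified by test).
Extended emitters are uniform lines of 33 midpoint-rule sub-emitters;
midpoint sampling matters — endpoint-inclusive sampling biases the line
integral by O(1/n) and was measured at −2 to −3% for 600–900 nm emitters.

Photon counts are Poisson draws around the sector means; `rng=None` returns
the noiseless means, which is how the lookup tables and all noiseless
oracles are produced. Background is spread uniformly over sectors and
planes. Bleaching is an exponential per-illuminated-orbit brightness decay.

## Localization and feedback

Localization uses the FFT of the plane-summed sector series with a
half-sector phase correction so that sector midpoints carry the angles. The
lookup tables store 256 nodes; retrieval is binary search + linear
interpolation, and modulations beyond the table are clamped and flagged
rather than extrapolated.

The feedback loop applies each estimate to the next orbit. With back-to-back
illuminated orbits the first sector of an orbit still circles the previous
center (the "on-the-fly" update bias); with dark orbits interleaved
(default 1-in-2, giving 100 Hz effective sampling) the update is clean.
Below the count threshold the tracker walks an Archimedean spiral (pitch =
one orbit radius per turn, 16 probes per turn, both configurable) from the
last tracked point and declares the particle lost beyond 5 µm. Long-range
recentering hands the full galvo offset of an axis to the stage when it
exceeds 10 µm, with fixed per-axis dead times (63 ms x, 35 ms y; the
published jitter of those times is not simulated), during which no records
are produced. Sample-fixed coordinates are always stage + galvo, so
positions are continuous across events by construction and verified by test.

A note on extended emitters: the single-orbit estimate of an emitter
extended *along* its displacement is multiplicatively shrunk (≈ −25% for a
300 nm line at 60 nm offset with the default geometry) because the Gaussian
excitation weights the near end more. The shrinkage is
displacement-independent, so the closed-loop fixed point is unbiased and
imposed trajectories are recovered — degradation becomes visible only for
emitters approaching ~1.2 µm, consistent with the published in vivo
validation. Symmetric (perpendicular) extensions localize like point
emitters to < 2% up to 200 nm.

## Ground-truth motion generator

Trajectories alternate stationary phases and directed phases along the axon
axis (x; anterograde = +x). Directed states are the four observed transport
states with truncated-normal speeds and durations parameterized from the
published population values (fast: 0.62 ± 0.09 and 0.76 ± 0.08 µm/s for
~2.5 s; slow: 0.36 ± 0.08 and 0.42 ± 0.11 µm/s for ~0.46 s). Pauses are
truncated-exponential (mean 2.5 s, minimum 0.5 s). A phase-level transition
matrix favours persistence and forbids fast↔fast direction reversals; fast
motion exists only in a trajectory's dominant direction.

Speeds are hierarchical: each trajectory draws its characteristic state
speed from the between-trajectory component (sd 0.08 µm/s) and phases
scatter around it with sd 0.04 µm/s, so the *population* spread matches the
published ±0.09 while *per-trajectory* velocity histograms are bimodal —
the feature the per-trajectory two-Gaussian classification protocol relies
on. Localization noise is i.i.d. Gaussian (5 nm lateral, 15 nm axial),
emulating the tracker's output at the stabilized ~500 photons/orbit.

What the generator does not emulate: correlated tracker noise, axial
transport structure (states are defined laterally), heartbeat and drift
artifacts (injected explicitly in the QC tests instead), photophysics
beyond exponential bleaching, and organelle shape changes over time. Tests
passing on this synthetic data therefore validate the *analysis chain*, not
the biology of any particular recording.

## Segmentation

Angles are computed on positions smoothed by a 5-point (50 ms) moving
average, then correlated with `Cor(t,τ) = mean cos(φ_s − φ_{s−τ})` over a
64-sample window, reduced by averaging lags 0.03–0.06 s (3–6 samples at
100 Hz). Labels are shifted back by half a window, and active runs shorter
than 150 ms (twice the recentering dead time) are relabelled stationary.
The null threshold is mean + 5 std of the reduced statistic computed on a
randomized, sign-augmented copy of the angle array (pooled over 10
shuffles; sign augmentation removes the bias a net travel direction would
impose on the null).

Two design points deserve emphasis:

* **Smoothing order.** Smoothing must precede the angle computation. At
  5 nm per-sample noise the per-step displacement of the slower states
  (3–4 nm) is below the step noise (~7 nm), the angle series is nearly
  isotropic, and segmentation accuracy collapses to ~73%. With 5-point
  pre-smoothing the step noise drops to ~1.4 nm, active-phase correlations
  approach one, the randomized threshold lands near 0.3, and accuracy under
  the validation conditions is ~98% (recomputed by `scripts/acceptance.py`).
* **Correlation functional.** The raw product Σ φ_s φ_{s−τ}/(n−τ) is
  direction-dependent (motion along +x has φ ≈ 0 and a near-zero product);
  the cosine-of-angle-difference form behaves identically for every travel
  direction and is the default. The raw-product mode is retained
  (`mode="raw-product"`) for comparison.

Known bias: phase boundaries are detected ~5 samples inside the true phase
at each end, so measured durations of ~0.5 s phases are ~10% short. The
acceptance suite leaves the corresponding population-duration check red
rather than compensating for it.

## Classification and statistics

Phase direction is the sign of the net x displacement; velocity is the net
lateral displacement over the duration (path length would be noise-inflated
at 100 Hz). The two-Gaussian fit is scikit-learn's ML EM with k-means
initialization and 10 restarts, per trajectory, on the dominant direction's
phase velocities; the other direction's phases are slow by construction. A
fit is degenerate when the fitted two-component density has no valley
between the centers (midpoint density ≥ 0.9 × the smaller center density);
a two-component fit of unimodal data produces exactly such valley-free
splits, while genuinely bimodal velocity samples dip well below. Degenerate
trajectories get all-slow labels and a warning.

Population values use the 10-subset procedure: random equal-size partition
(seeded), per-subset ML fits (Gaussian center for velocities, exponential
decay constant — the subset mean — for durations and displacements),
reported as mean ± std across subsets, which also supply the replicates for
two-sided t-tests. Per-orbit x displacements are fitted by a single
Gaussian directly. Pauses are the stationary gaps between consecutive
active phases (terminal stationary stretches are not pauses), classed by
their flanking speed states, with mono-exponential ML decays per class and
direction-change probabilities split at 20 s.

## Wide-field analysis

The movie cleaner implements `ΔI = I(t+lag) − I(t)` (lag 10 frames = 5 s at
2 Hz), keeps only negative differences, and adds them back; the final `lag`
frames have no forward difference and are dropped. Two intrinsic
properties: the negative-difference clamp rectifies pixel noise downward by
~0.4σ, and an object that lingers within a few pixels for longer than the
lag window is (correctly) kept as stationary — including the tracked
organelle itself during long pauses.

Segment mean images (one per interval between recentering events, the
post-final-event segment dropped) are smoothed with a 5 × 5 boxcar,
thresholded at the full-frame mean + 5σ, and masked to a 51 × 11 px
corridor around the trajectory (a dilated polyline with half-widths 25 and
5 px when the track is not x-aligned). Component centroids are
intensity-weighted over a window extended past the thresholded footprint;
lengths use the second moment along the axon deconvolved for the boxcar and
the optical blur (`psf_sigma`, default 200 nm), which keeps the estimate
near the physical extent instead of the threshold footprint (≤ 2 px error
at SNR ≥ 10 in the round-trip tests). Camera-to-stage mapping is a
second-order bivariate polynomial least-squares fit on ≥ 12 (normally 25)
control points; without control points an identity-times-pixel-size map is
used with a warning.

Occupancy classifies each sample by whether its x position falls within a
detected object's extent dilated by a 500 nm capture distance (the
published analysis states no number; 500 nm is of the order of the organelle
radius plus mapping error). Crossing times accumulate dwell time per 100 nm
bin per trajectory; 1 µm bins where a trajectory needs > 10 s are flagged
and the flagged fraction is pooled over both travel directions. Unvisited
bins are reported missing, not zero.

## Reproducibility

Every stochastic operation takes an explicit `numpy` Generator; the CLI and
`RunConfig` derive all stages from one seed and stamp outputs with the seed
and a config hash. Problem sizes in the test and acceptance runs — 20
trajectories × 60 s for segmentation accuracy, 43 trajectories × 120 s for
the population statistics, 28 s sinusoid runs, 8 random wide-field scenes —
were chosen as the smallest sets whose sampling error is comfortably below
the tolerances being checked.

## Known limitations

* The analysis assumes the axon is aligned with x; strongly curved axons
  would need a pre-straightening step that is out of scope.
* The heartbeat QC inspects only the lateral-perpendicular component.
* Axial motion is tracked but not used for state definitions.
* The deposited in vivo trajectory files can be ingested through
  `io.read_trajectory`'s column mapping, but no copy ships with the
  package, and their exact schema must be configured by the user.
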