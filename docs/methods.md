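# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `spvsim`, and what its synthetic stimuli and virtual
observer do and do not establish about real prosthetic vision.

## Coordinate system and units

One planar frame is shared by the visual field and the retinal surface:
right eye, x positive nasal, y positive superior, fovea at the origin.
Retinal distances are in µm, visual angles in degrees, related by a single
linear constant `um_per_degree` (default 280 µm/deg, configurable). The
literature quotes the same 10-electrode, 400-µm-pitch row both as "about
15°" and as 14.6°, which correspond to slightly different conversion
constants; we expose the constant rather than privilege either figure (the
default gives 14.3°). The temporal horizontal raphe is the ray y = 0, x < 0;
the optic-disc centre sits at (15°, 2°).

## Axon trajectories (traj-v1)

No closed-form axon trajectories are standard for simulation work beyond the
Jansonius spiral family, so we implement a Jansonius-style parameterization,
versioned `traj-v1` so results are reproducible across releases:

- bundles leave a 4°-radius disc rim at emission angle φ₀, measured from the
  nasal direction; the angle along a bundle grows as
  φ(r) = φ₀ + b·(r − 4)^c, with b and c smooth (tanh) functions of φ₀ that
  make papillomacular fibres (|φ₀| → 180°) nearly straight and arcuate
  fibres strongly curved; superior (φ₀ > 0) and inferior branches mirror
  each other with slightly different coefficients;
- bundles are truncated where |φ| reaches 180°, i.e. on the horizontal
  meridian through the disc — beyond the fovea this line is the temporal
  raphe, which axons never cross;
- paths are generated in a raphe-aligned frame (disc on the +x axis) and a
  nasal-only vertical shear (zero for x ≤ 0, smoothstep to +2° at the disc)
  places the disc at (15°, 2°) while keeping the raphe exactly on y = 0.

Defaults: 500 bundles, polylines resampled to ≤50 µm chords. Each
percept-grid sample acts as its own soma: its axon consists of the sample
point itself plus the nearest bundle walked back toward the disc, with the
attachment gap added to the arc length. Two consequences: (i) the λ→0 limit
reproduces the closed-form radial Gaussian exactly (the soma term carries no
quantization error), and (ii) attachment respects the raphe — temporal
samples may only attach within their own hemifield, so the percept is
discontinuous across the raphe, as the axon model requires.

Granularity: halving the path step (50→25 µm) changes the brightness field
by <0.01 for 99% of samples; a handful of foveal samples flip between
adjacent bundles (worst case ~0.12), which is bundle-count granularity, not
path-step error, and shrinks with `n_axons`.

## Spatial model evaluation

b_I = max over the path of Σ_e a_e·exp(−d_e²/2ρ² − d_soma²/2λ²). Amplitudes
weight the radial terms inside the path maximum; single-electrode percepts
are never combined linearly after the maximum, which is precisely the
nonlinearity the model exists to capture. Per (array, axon map, ρ, λ) we
precompute two Gaussian bases — sample-to-electrode (the soma term) and
bundle-point-to-electrode, the latter with per-sample path weights
exp(−d_soma²/2λ²) in CSR layout, pruned below 10⁻⁴ — so a frame costs one
matrix–vector product plus a segment maximum (~4 ms at the default 97×97
grid). Defaults ρ = 300 µm, λ = 1000 µm (realistic epiretinal values); the
percept grid spans ±12° at 0.25°/sample, which covers the array footprint
plus a 3ρ margin (enforced at configuration time).

## Temporal model

dn/dt = −τ_n·n + b_I; db/dt = −τ_b·b − α·n + b_I, with presets
(τ_n, τ_b, α) = (0.2, 5, 0.2) ("5Hz") and (0.2, 5, 0.25) ("20Hz"). τ_n and
τ_b are treated as rate coefficients exactly as the equations are written —
although quoted with units of seconds in the source literature — because
that reading yields fast brightness (1/τ_b = 0.2 s) and slow desensitization
(1/τ_n = 5 s) and makes the algebraic steady state b* = b_I(1 − α/τ_n)/τ_b
vanish for the 5Hz preset (complete fading, the phenomenon of interest); the
opposite reading would make desensitization faster than brightness and
produce a large sustained percept. For the 20Hz preset (α > τ_n) the
unclamped steady state is negative, so b is clamped to zero after every step.

Integration is forward Euler at the render period (1/90 s), updating n first
and using the updated n in the b step; this sequential variant is slightly
more accurate than the parallel one. Accuracy against the exact
(matrix-exponential, zero-order-hold) solution: ~0.1% of peak for slowly
varying input, ~1.1% for step onsets — the intrinsic first-order bound
max_k |(1−h)^k − e^(−hk)| ≈ 1.05% at h = τ_b/90 — and up to ~1.8% for
raster-pulsed input. The per-frame display applies a fixed configurable gain
(default 2.0) rather than per-frame autoscaling, which would mask fading.

## Raster scheduling

The clock counts render frames: the 44.4 ms group interval snaps to 4 frames
at 90 Hz (44.44 ms exactly), giving a 222 ms, 4.5 Hz cycle and a 22.5 Hz
group-event rate for 5 groups. The "fast" condition steps one group per
render frame (11.1 ms), i.e. 18 full cycles per second, and uses the 20Hz
temporal preset. The "four_group" condition keeps the 4.5 Hz-class cycle by
using a 55.6 ms interval (a true 5 Hz cycle would need 4.5 render frames,
which no frame clock can realize). The main 4.5 Hz condition is also
labelled "5 Hz" in rate-comparison contexts; the 44.4 ms interval is the
operative number.

Checkerboard construction: group of electrode (i, j) is (a·i + b·j) mod n,
with (a, b) found by exhaustive search over balanced assignments maximizing
the minimum within-group nearest-neighbour distance (certified optimum
√5 × pitch for 10×10/5; ties broken lexicographically), and the activation
order found by exhaustive search over the n! permutations minimizing the
apparent-motion consistency index (again lexicographic ties). Both searches
are tiny and certify optimality by enumeration.

Apparent-motion index: for each within-cycle group transition, each incoming
electrode contributes the displacement from its nearest outgoing electrode;
the index reports the mean displacement (µm) and the norm of the mean unit
displacement (0–1). The cycle-wrap transition is excluded — the jump from
the last group back to the first is an artifact of indexing, not perception.
The same exclusion applies to percept-level motion energy via the clip's
cycle metadata.

Random pattern: equal-size partitions drawn from a seeded generator, re-drawn
every `reshuffle_every` raster frames rounded to whole cycles (default: every
cycle), so each cycle remains a valid partition and every electrode fires
exactly once per cycle — the safety property rastering exists to provide.

## Stimuli, gaze, and the virtual observer

Optotypes are built on the 5×5 Sloan stroke grid (stroke = 1/5 letter
height), white on black, default 41.1° letter height on a 60° field; moving
bars are full-length, 10% of the field wide, crossing the field in the 5-s
clip, in 8 compass directions. Frames are converted to grayscale, resized to
200×200, and smoothed with a unit-sum 3×3 Gaussian (σ = 0.85 px — the kernel
size is prescribed, the σ is our binomial-like choice). Gaze traces add
isotropic Gaussian error to a fixation or pursuit target, scaled so the mean
radial error equals the 1.9° tracker figure (Rayleigh mean σ√(π/2)); >99% of
samples then fall within 5°, comfortably inside the reported 94%. Error is
drawn independently per sample; real tracker error is temporally correlated,
which matters only for analyses of gaze dynamics, not for the retinally
stabilized rendering tested here. Head movement is folded into the gaze
trace. The gaze-contingent shift is a nearest-pixel translation with zero
(dark-room) padding.

The template observer time-averages the percept and picks the template with
the highest normalized cross-correlation; templates are rendered under the
no-raster, temporal-off reference at the evaluation ρ/λ, so observer and
signal share the same spatial distortions and only the raster manipulation
differs between conditions. Ties (including all-zero percepts) resolve to
the fixed alphabetical/clockwise order. The motion observer takes the
centroid-based drift vector's nearest compass direction. Neither is fit to
human data: human odds ratios, learning curves, and difficulty ratings are
not reproduction targets, and virtual-observer accuracies should be read as
relative pattern comparisons, not predicted human performance.

A consequence worth knowing: at the default 41.1° letter size only the
central ~15° of a letter is visible to the fovea-centred array, so letters
differing only peripherally (C/D/O; E/F at the bottom) produce identical
percepts under fixation and the observer ceiling is well below 100% — the
simulator-level analogue of the letter-grouping confusions seen in humans.
Veridical-limit checks therefore use letters sized to the array's field.

## What the synthetic data do not show

The generator emulates the study's stimulus geometry, timing, and tracker
noise, not human vision: there is no perceptual learning, no head-movement
strategy, no scanning eye movements (fixation is the default), and the
observer is deterministic given its seed. Passing tests establish the
engine's internal correctness and the relative quality ordering of raster
patterns under this observer; they do not predict absolute human accuracy.

## Known limitations

- Axon trajectories are a generic spiral family, not per-patient fits; no
  optic-disc scotoma or electrode–retina distance effects.
- No pulse-level waveforms or charge-density accounting; amplitudes are
  abstract gray levels in [0, 1].
- Forward Euler at the render rate carries ~1% error at sharp input onsets
  (see above); applications needing tighter trajectories should integrate
  with the matrix-exponential propagator used in the tests.
- The letter task's template observer under fixation saturates below 100%
  at the default letter size for the geometric reasons above.
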