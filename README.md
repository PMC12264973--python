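# spvsim — raster-scheduled simulated prosthetic vision

Epiretinal implants cannot fire all electrodes at once: charge-density and
simultaneous-current limits force the array into *timing groups* ("raster
patterns") activated in rapid succession. `spvsim` is a simulator for
studying how the choice of raster pattern shapes what an implant user would
see. It renders gaze-contingent phosphene movies for a fovea-centred 10×10
epiretinal array (400 µm pitch, ≈15° field of view), runs eight-alternative
forced-choice letter and motion experiments with a virtual observer in place
of human participants, and scores raster patterns with quantitative
spacing/apparent-motion metrics.

It is aimed at researchers prototyping stimulation-scheduling strategies and
at psychophysicists who need a reproducible, scriptable stand-in for
virtual-patient experiments.

## The model

**Spatial (axon map).** Epiretinal stimulation excites retinal ganglion cell
axons, so phosphenes elongate along the axon trajectories. The instantaneous
brightness at percept location (r, θ) is

```
b_I(r, θ) = max_{p ∈ R(θ)}  Σ_e  a_e · exp( −d_e²/2ρ²  −  d_soma²/2λ² )
```

where `R(θ)` is the axon path terminating at (r, θ), `d_e` the distance from
path point `p` to electrode `e`, `d_soma` the arc length from `p` back to the
soma, `a_e ∈ [0, 1]` the electrode amplitude (the gray level at the electrode's
position in the processed input frame), and ρ, λ (µm) the radial-spread and
axonal-elongation scales (defaults 300 and 1000). The maximum over the path —
not a linear sum — captures the nonlinear merging and asymmetric brightness of
simultaneous multi-electrode stimulation. Axon trajectories follow a
documented Jansonius-style spiral family (see `docs/methods.md`).

**Temporal (coupled leaky integrators).** Per percept pixel,

```
dn/dt = −τ_n·n + b_I        db/dt = −τ_b·b − α·n + b_I
```

with desensitization `n(t)` and perceived brightness `b(t)`, integrated by
forward Euler at the 90 Hz render rate with `b` clamped non-negative. Presets
`"5Hz"` (τ_n = 0.2, τ_b = 5, α = 0.2) and `"20Hz"` (α = 0.25). Because
α ≥ τ_n, sustained stimulation fades to zero — the hallmark of epiretinal
percepts.

**Raster scheduling.** Four patterns partition the 100 electrodes into five
groups of 20, stepped every 44.4 ms (222 ms cycle, 4.5 Hz; 22.5 Hz
group-event rate): `horizontal` (row bands, top→bottom), `vertical` (column
bands, left→right), `checkerboard` (modular assignment certified by
exhaustive search to maximize within-group spacing — √5 × pitch ≈ 894 µm vs
400 µm for the band patterns — with an activation order minimizing coherent
apparent motion), and `random` (seeded re-partition every cycle).

## Worked example

Score the raster patterns and run a motion experiment:

```
$ spvsim schedule --pattern checkerboard --out sched.csv
checkerboard/5 groups: drift=(-75.0, 75.0) um, consistency=0.284 -> sched.csv

$ spvsim schedule --pattern horizontal --out sched_h.csv
horizontal/5 groups: drift=(0.0, -600.0) um, consistency=1.000 -> sched_h.csv
```

The horizontal raster's unit-displacement consistency of 1.000 means every
group-to-group transition pushes the percept the same way (600 µm downward
per step — a coherent apparent-motion artifact); the checkerboard's 0.284
means its activation order has no dominant direction.

```
$ spvsim experiment --condition no_raster --task motion --seed 1 --out exp/
accuracy: 0.958 (48 trials) -> exp/records.csv
```

Under the no-raster baseline the virtual observer discriminates the eight bar
directions near-perfectly; with the structured rasters, accuracy drops and the
confusion matrix (written to `exp/confusion.csv`) picks up errors biased
along the scan axis — the same apparent-motion bias that band rasters induce
in human observers. Percept movies can be rendered with `spvsim simulate`
(8-bit PNG frames plus a config echo that re-runs bit-identically).

From Python, the same pipeline is three calls:

```python
import spvsim
cfg  = spvsim.SimConfig.condition("main", pattern="checkerboard", seed=1)
sim  = spvsim.Simulator(cfg)
stim = spvsim.render_optotype("E")
gaze = spvsim.simulate_gaze(stim.duration_s, seed=1)
clip = sim.run(stim, gaze)          # (T, 97, 97) brightness frames
spvsim.motion_energy(clip)          # residual drift, deg/s
```

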