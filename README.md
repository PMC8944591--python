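# saccadeye

A simulator and analysis pipeline for **binocular mirror-symmetric
microsaccadic sampling** in *Drosophila* compound eyes — the active-sampling
mechanism by which light-driven photomechanical photoreceptor contractions
("microsaccades") move and narrow receptive fields in lock-step mirror
symmetry between the two eyes, turning object depth into an inter-eye
**time disparity** and enabling hyperacute (finer than the 4.5°
interommatidial angle) 3D vision.

The package is aimed at computational/visual neuroscientists who want to
simulate compound-eye active sampling end to end: eye geometry → synthetic
3D scenes → per-photoreceptor light → stochastic quantum-bump
phototransduction → depth/acuity readouts.

## The model in brief

* **Sampling matrix.** Two mirror-symmetric hexagonal ommatidial lattices
  (~880 lens units per eye, interommatidial angle Δφ = 4.5°), each
  ommatidium housing photoreceptors R1–R8 with circular-Gaussian receptive
  fields (FWHM 5.4°). Neural superposition pools the R1–R6 of six
  neighboring ommatidia plus the resident R7/R8 into one lamina cartridge,
  so a single frontal point at 25 mm falls inside ≥ 16 receptive fields
  across the two eyes. The eyes sit a baseline *k* = 0.4 mm apart and share
  a ~23.5°-wide binocular field.
* **Microsaccades.** A light increment contracts the photoreceptors along a
  hardwired axis that matches the forward-flight optic-flow direction:
  latency < 10 ms, fast phase completing in 40–50 ms, slow relaxation
  (< 1 s) on darkening. The contraction amplitude follows Michaelis–Menten
  saturation A(I) = A_max·I/(I + I50); the receptive field shifts opposite
  to the rhabdomere (lens inversion) and narrows in proportion.
* **Depth from time disparity.** A dot moving at angular velocity ω crosses
  the corresponding left/right receptive fields at times Δt apart; static
  triangulation gives Δt = 2·atan(k/2z)/ω, i.e. z = k / (2 tan(ω Δt/2)).
  The model measures Δt by cross-correlating the pooled left/right
  cartridge responses (quantum-bump transduction with photon noise),
  velocity-normalizes with a neighbor-correlation estimate of ω, and
  decodes depth through a calibration table built by forward simulation of
  the full closed-loop dynamics.

## Worked example

```python
import saccadeye as se

pair = se.build_eye_pair()
print("ommatidia per eye:", pair.right.n_ommatidia)
print("frontal coverage @25 mm:",
      se.coverage_count(pair, (0.0, 0.0), 25.0), "photoreceptors")

scene, control = se.make_hidden_dot_scene(dot_deg=0.98, stripe_deg=1.2)
print("hidden-dot contrast: %.2f%%" % se.static_contrast_metric(scene, control))

cal = se.build_calibration(pair)                     # noise-free forward model
print("delta-t vs depth:", cal.monotone_direction)
est = se.run_depth_trial(pair, z_mm=25.0, stochastic=True, seed=2,
                         calibration=cal)
print("z=25 mm trial: dt=%.2f ms, omega=%.1f deg/s, z_hat=%.1f mm (err %.1f%%)"
      % (est.delta_t_ms, est.omega_hat_dps, est.z_hat_mm, 100 * est.rel_error))
```

prints

```
ommatidia per eye: 879
frontal coverage @25 mm: 16 photoreceptors
hidden-dot contrast: 1.59%
delta-t vs depth: decreasing
z=25 mm trial: dt=29.48 ms, omega=47.6 deg/s, z_hat=24.4 mm (err 2.3%)
```

i.e. the immobile-eye ("old theory") analysis leaves a hidden 0.98° dot at
only ~1.6% of the stripe contrast — invisible to static sampling — while
one noisy binocular microsaccadic transit of a dot at 25 mm recovers its
depth to a few percent. `delta-t vs depth: decreasing` records the
empirical sign of the lag–depth relation in this model: closer objects
produce longer velocity-normalized lags.

Figure-level recipes run from the shell:

```
saccadeye list-experiments
saccadeye run fig6G_static --out results
saccadeye run fig5EF_depth --seed 1 --out results
```

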