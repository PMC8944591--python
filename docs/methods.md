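# Methods

This note documents the model behind `saccadeye`: what is simulated, the
parameter defaults and why, the numerical choices that matter, and what the
synthetic experiments do and do not show about real compound eyes.

## Eye geometry

Each eye is a hexagonal-row lattice of ommatidia on the viewing sphere:
rows of constant elevation spaced `row_aspect × Δφ` (default 0.95 × 4.5°),
within-row great-circle spacing exactly Δφ, alternate rows offset half a
step. The 0.95 row aspect keeps every lattice-neighbor separation within
10% of Δφ on the sphere (a true hexagonal aspect of √3/2 would put
vertically aligned neighbors 13% closer). The default field extents
(azimuth −13.5°…133° for the right eye, elevation ±87.7°) were sized once
so that a lattice row passes through azimuth 0 (giving exactly co-aligned
left/right frontal cartridges) and one eye carries ≈880 ommatidia (879
emerge). The left eye is the exact mirror image: azimuths negated, sub-RF
offsets and movement axes mirrored, so mirror symmetry is a construction
invariant rather than an approximation.

Per ommatidium, R1–R6 sub-receptive-fields sit on a regular hexagon of
radius 1.5° around the axis and R7/R8 share the central axis; ventral
ommatidia mirror the offsets about the eye equator. All receptive fields
are circular Gaussians with FWHM 5.4° (σ = FWHM/2.3548) unless stated
otherwise. Neural superposition is modeled by cartridges: each ommatidium's
cartridge pools the resident R7/R8 plus, from each of its (up to six)
lattice neighbors, the single R1–R6 whose RF center lies closest to the
cartridge axis — seven ommatidia per cartridge away from lattice edges.

The microsaccade movement axis of every ommatidium is set to the local
forward-translation optic-flow direction (receptive-field fast phase along
the flow; the rhabdomere moves opposite, and the ommatidial lens inverts
rhabdomere motion into RF motion). Near the frontal flow focus, where flow
is undefined, the axis falls back to the horizontal away-from-midline
direction. Measured direction maps can be loaded from CSV instead.

## Microsaccade kinematics

The contraction model is a first-order cascade with times in ms:

| parameter | default | meaning |
|---|---|---|
| `latency_ms` | 8 | onset latency (< 10 ms) |
| `tau_drive_ms` | 35 | low-pass "drive" filter on intensity |
| `tau_fast_ms` | 20 | rise toward the saturation target |
| `tau_slow_ms` | 300 | relaxation in darkness |
| `A_max_deg` | 2.0 | maximal RF displacement |
| `I50` | 0.1 | half-saturation of normalized luminance |
| `narrow_max` | 0.2 | maximal fractional FWHM reduction |
| `adapt_tau_ms` / depletion | 500 / 300 | amplitude-adaptation gain dynamics |

The Michaelis–Menten target A_max·d/(d + I50) is computed on the
low-pass-filtered drive d rather than raw intensity, so a 10-ms saturating
flash keeps contracting after light-off and peaks 40–50 ms from onset
(τ_drive and τ_fast were set once to place that peak at ~45 ms); the
offset then relaxes with τ_slow to < 5% within a second. Narrowing is
proportional to normalized offset — the simplest testable coupling of
"narrow and slide". Adaptation acts on amplitude only, as a gain that
depletes under sustained drive and recovers in dim light, making a second
flash 200 ms after the first strictly weaker. Intensities are normalized
luminance in [0, 1].

## Stimulus synthesis and rendering

Scenes are parametric: dots (angular diameter, 3D position on a
constant-depth sphere, azimuthal angular velocity), thin axial pins
(rendered as a short stack of depth-offset discs), and full-field vertical
square-wave gratings. Gratings use an even (cosine) convention — a white
stripe centered on the phase origin — which makes mirrored scenes
bit-identical under azimuth sign flip; together with the mirrored lattice
this gives *bit-exact* mirror equivariance of the whole deterministic
pipeline (a tested property).

Per frame (dt ≤ 1 ms), each photoreceptor's intensity is the scene
radiance integrated over its current (displaced, narrowed) Gaussian RF:
dots exactly via the offset disc–Gaussian mass (noncentral-χ² CDF with 2
degrees of freedom, planar small-angle approximation), gratings
analytically per Fourier harmonic with attenuation exp(−2π²n²σ²/λ²). Each
eye views the scene in perspective from (±k/2, 0, 0) mm, so a point
object's inter-eye azimuth difference equals 2·atan(k/2z) to machine
precision. In `microsaccadic` mode the loop is closed once per frame:
rendered ommatidial mean light drives the contraction state, which
displaces the RFs used for the next frame. `asynchronous` mode applies one
eye's state with a delay, `asymmetric` freezes one eye's RFs, `monocular`
zeroes one eye's channels.

Rendered light is a noise-free radiance rate by default; Poisson photon
sampling at the light stage is available but off, because photon noise
enters physically at absorption (the bump model below). Microsaccade
kinematics are therefore driven by mean light, and per-trial stochasticity
is photon noise plus bump latency jitter only.

## Phototransduction

The stochastic path is population-level quantum-bump integration per
photoreceptor: Poisson photon counts per time bin (default 1000
photons/ms at unit luminance ≈ 10⁶ photons/s, bright daylight), binomial
thinning by the tracked busy fraction of 30,000 microvilli, per-event
clipped-normal refractory periods (mean 25 ms, SD 8, min 5) and latencies
(10 ± 2 ms), a gamma-shaped bump kernel (order 3, time-to-peak 12 ms) and
Naka–Rushton saturation (half-saturation at 300 bumps/ms). Event latencies
and refractory draws are discretized to the time grid and scattered with
batched multinomials — statistically identical to independent per-event
draws, with exact delivered = lost + bumps bookkeeping. The 25-ms
effective refractory period is shorter than dark-adapted single-microvillus
estimates; it was chosen once so that transduction sits in a responsive,
light-adapted regime at the daylight photon rate (occupancy ≈ 0.45), the
operating point the depth experiments assume.

The deterministic surrogate is a *feedforward* divisive-adaptation
cascade: expected photon rate → low-pass (occupancy relaxation time at the
bright operating point) → steady-state occupancy → divisive gain → latency
shift + Gaussian jitter blur → bump kernel → Naka–Rushton. Because it is
built solely from LTI filters and memoryless nonlinearities it commutes
*exactly* with fractional-sample time shifts of its input — the property
the time-disparity measurements rest on (a feedback implementation of the
same mean field breaks sample-grid shift equivalence and measurably
corrupts sub-sample lag estimates). It matches the stochastic trial mean
within ~4% on flash stimuli (tested bound 10%).

The LMC/L2 stage is a sign-inverting band-pass (first-order high-pass
τ = 50 ms into low-pass τ = 10 ms), optionally averaging the six
superposed R1–R6 inputs of a cartridge before filtering.

## Depth inference

A trial simulates a dark dot (default: one dot of 3.9° diameter — the
dot size the behavioral scenes use; the classic two-dot 3.5°-apart scene
is available via `n_dots=2` with 1.7° dots) crossing the frontal field
left to right at 50°/s at depth z, with baseline k = 0.4 mm.

Channels pool the shared-axis central photoreceptors (R7/R8) of three
consecutive equatorial cartridges: the binocular channel is centered on
azimuth 0 (an azimuth-symmetric member set, so the mirrored right-eye
channel sees an exact time-shifted copy of the left channel), and the
velocity channel is the preceding disjoint cartridge block (centroids
13.5° apart). Measurement proceeds in two passes: a coarse velocity from
the unaligned pooled channels, then *motion-compensated member alignment*
— each member's response is advanced by its azimuthal offset divided by
the velocity estimate so all transits superimpose coherently — iterated
once, after which ω̂ = Δφ/lag and the binocular lag Δt come from the
aligned pooled waveforms. Alignment makes the cross-correlation peak
unimodal and pools noise without blurring the transit.

Lags are the argmax of the cross-correlation of *first differences*
(differencing removes the arbitrary response baseline exactly, so the
finite window adds no triangular bias), refined by parabolic
interpolation; a known 4.58-ms offset at 1-ms sampling is recovered to
well within ±0.1 ms. The first 150 ms are cropped before measuring, so the
shared stimulus-onset transient never enters the correlation (members are
cropped *before* alignment, so edge-hold interpolation only ever extends
the flat plateau). Channels whose cropped series vary by less than 10⁻³
response units (e.g. a zeroed eye whose only activity is spontaneous dark
bumps) raise an undefined-disparity error.

Decoding is calibrated by default: the noise-free forward model is run on
a geometric depth grid (2–450 mm, 15 points) and the velocity-normalized
product p = ω̂·Δt is interpolated monotonically (PCHIP, linear in p
against log z); measured products are clamped to the table range and
flagged. The closed form z = k/(2·tan(ωΔt/2)) is retained as the
documented static-triangulation baseline: in `static` mode (no
microsaccades) the measured Δt matches 2·atan(k/2z)/ω within 2% over
5–200 mm. In the full closed-loop model the microsaccades subtract a
roughly depth-independent ~7 ms from the geometric lag, so the calibrated
p(z) is strictly decreasing over 2–450 mm: **in this model, closer objects
give longer velocity-normalized lags** — the geometric ordering. The
code reports this direction rather than assuming either sign.

With the default noise model the Monte-Carlo error curve rises from ~6% at
25 mm through ~15% at 50 mm and ~30% at 100 mm to ~60% at 200 mm
(means over 100 trials): depth is reliable only in the near field and the
error exceeds 10% beyond ~100 mm, degrading monotonically with distance.
Ablations at 25 mm on paired seeds: monocular sampling fails on every
trial (no binocular disparity); a 20-ms inter-eye kinematic delay or
freezing one eye's receptive fields raises the mean error several-fold
above the mirror-symmetric control — asynchronous or asymmetric binocular
sampling degrades stereopsis even though both eyes still see the scene.

## Acuity analyses

**Static ("old theory") contrast.** Scenes are rasterized on a 0.05° grid
and convolved with a circular Gaussian RF; the metric is the peak absolute
convolved difference between the dot-bearing and control scenes, divided
by the control pattern's own peak-to-trough contrast. The stated "5.4°
half-width" is mapped to σ = half-width/2 = 2.7° for this metric (the
half-width read as the profile's 2σ full width); under that convention the
closed form 1 − exp(−r²/2σ²) for a 0.98° dot gives 1.63%, and the raster
computation returns 1.59% — the ~1.6% "invisible dot" figure. The common
FWHM reading (σ = 2.29°) would give 2.3% instead; the convention choice is
deliberate and local to this metric (rendering keeps σ = FWHM/2.3548).
The convolved stripe pattern itself retains essentially no contrast under
any such RF (~10⁻¹¹ of nominal), which is why the denominator is the
pattern contrast, not the convolved-control contrast.

**Grating resolvability.** A drifting square-wave grating appears out of
darkness and the pooled frontal-cartridge LMC response is analyzed after a
settle window. Signal is the stimulus-contrast-locked power at the
grating's temporal frequency: the deterministic response minus the
deterministic zero-contrast reference (cancelling onset/adaptation
transients exactly); the noise floor is the median broadband power of the
stochastic-minus-deterministic residual at the same seed. `resolvable`
means SNR ≥ 2 (configurable). Coarse gratings (9°) are resolvable in any
mode; for hyperacute 2° gratings the microsaccadic mode retains orders of
magnitude more stimulus-locked power than static sampling (tonic
narrowing and fast-phase sweeps), though both sit below the photon-noise
floor at these parameters.

**Optomotor correlator.** Hassenstein–Reichardt pairs (20-ms first-order
delay arm) on neighboring equatorial cartridge LMC signals, three pairs
per eye around |azimuth| ≈ 30°, summed over mirror-symmetric chains in
both eyes; positive output is syndirectional with the panorama's rotation.
The output is odd in yaw to machine precision. Coarse gratings (λ = 20°)
drive a positive (normal) response; the classic aliasing band
(Δφ < λ < 2Δφ) reverses it; and under microsaccadic sampling the sign
also reverses for a hyperacute λ = 3.0° grating where static sampling
stays positive (full parameter set: full-contrast square wave, 30°/s yaw,
20-ms delay, default kinetics) — reversal driven by the sampling dynamics
rather than spatial aliasing alone.

## What the synthetic data do and do not show

The generator reproduces the controlled laboratory situations the model
addresses: uniform backgrounds, single/paired dots at fixed depth and
velocity, ideal square-wave gratings, noise limited to photon shot noise
and bump timing jitter. It does not emulate natural-scene statistics,
extended textures, body/head movements, intraocular-muscle gaze shifts, or
receptor-to-receptor biophysical heterogeneity. Passing tests therefore
validate the internal consistency and qualitative predictions of the
sampling theory (mirror-symmetric disparity coding, its ablation, static
vs dynamic acuity), not quantitative performance on natural stimuli. The
absolute depth-error magnitudes depend on the reduced transduction model's
information rate and the small pooled channel (six central photoreceptors);
richer biophysical photoreceptor models and larger pooling would lower the
curve without changing its shape.

## Numerical conventions

Degrees everywhere; azimuth positive rightward, elevation positive dorsal;
eyes at (±k/2, 0, 0) mm with y forward. Time in ms, dt ≤ 1 ms
(forward-Euler state updates). Disparities are positive when the left eye
leads. Binocular-pair matching breaks ties by smaller |elevation| then
smaller ommatidium id. All randomness flows through numpy Generators
seeded per trial via `SeedSequence.spawn`; identical seeds give
bit-identical stochastic outputs.
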