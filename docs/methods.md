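# Methods

`sonoretina` implements the computational core of a phased-array ultrasound
retina prosthesis: a 16×16, 4.5 MHz, 0.75 mm-pitch transducer array placed
on the eye both images the eyeball and projects arbitrary acoustic pressure
patterns onto the retina, where radiation force activates the remaining
neurons.  The package covers five computations: plane-to-plane acoustic
propagation, hologram (drive) computation, imaging-based auto-alignment,
beam/pattern metrics and safety dosimetry, and the electrophysiological
readout chain — each exercisable on synthetic inputs with known ground
truth.

## Wave propagation

Fields are scalar complex pressures sampled on uniform transverse planes
(space in mm, frequency in MHz, sound speed in m/s; the wavenumber is
`km = 2π·f/(c/1000)` rad/mm).  Propagation uses the band-limited angular
spectrum method: the 2D FFT decomposes the field into plane waves
(analysis kernel `exp(−i(kx·x+ky·y))`), each component is multiplied by
`exp(i·dz·√(km²−kx²−ky²))`, and the inverse FFT resynthesizes the field at
`z+dz`.  Backpropagation conjugates the propagator and is the exact inverse
on the propagating band.  Evanescent components (`kx²+ky² > km²`) are zeroed
outright rather than decayed: every propagation distance of interest is
hundreds of wavelengths, where their decay is numerically total.

Two guards control sampling artifacts of finite apertures:

* **Band limit.**  With a source aperture of side `La` and a target window
  of side `Li` at distance `z`, spatial frequencies above
  `kc = π(La+Li)/(λ·√(z²+(La+Li)²/4))` cannot connect the two windows
  geometrically and only alias; they are zeroed, separably in `|kx|` and
  `|ky|`.  As `z→0` the cutoff tends to the full propagating band `2π/λ`.
* **Grid margin.**  Source grids are built with spacing `λ/4` and extent at
  least twice the aperture (`make_source_grid`), rounded to a power of two.
  The margin suppresses FFT wrap-around.  It is deliberately applied at
  grid-construction time rather than as a transient pad-crop inside the
  operator: pad-crop would discard energy spreading into the margin and
  break the exact propagate/backpropagate round trip, which the test suite
  checks to 1e−8.

The propagator is validated against an independent brute-force quadrature
of the first Rayleigh–Sommerfeld integral (`rs_oracle`,
`p = (1/2π)∬ p₀·(1/r − i·km)·(z/r)·e^{i·km·r}/r dA`, O(N·M), no FFT), which
itself is validated against the closed-form on-axis piston solution
`p(z) = e^{i·km·z} − (z/R)·e^{i·km·R}`.  Agreement between the spectral and
direct routes at focal-plane points is within 2% for focused pistons at
3–5.4 MHz on ≤256² grids; the 20 MHz transducer (whose λ/2-sampled aperture
needs a larger grid) is checked against the closed form at 1024²–2048².

Layered media (`propagate_layered`) chain the spectral propagator through
planar tissue slabs with per-layer wavenumber and attenuation and apply the
normal-incidence amplitude transmission `T = 2Z₂/(Z₁+Z₂)` at each interface.
Refraction at curved interfaces is out of scope (planar-layer
approximation).

## Holography

`DriveSolution.phase` stores a per-element **delay** in [0, 2π): the forward
model renders element *e* as `amplitude_e·exp(−i·phase_e)` and propagates
with the `exp(+i·z·kz)` propagator.  Under this convention the focusing law
is the familiar positive delay `km·√((xe−xf)²+(ye−yf)²+zf²)`, and the
tilt-compensation ramp `km(x·tanθx + y·tanθy)` adds directly to the element
delays.  Applying the ramp shifts the focal spot laterally by `z·tanθ`
(toward −x for positive θx under this sign convention), which is exactly
what re-aiming at a retina tilted by θ requires.

`decode_pattern` converts a target intensity image to pressure amplitude
(square root — neural activation is modeled on pressure magnitude),
embeds it at the target depth, backpropagates with the band limit, and
projects the hologram onto the array by averaging the complex field over
each element's active area (fill factor 0.9 of the 0.75 mm pitch;
averaging is the least-squares piston projection and empirically more
accurate than point sampling, which aliases the rapidly rotating phase at
outer elements).  Amplitudes are normalized to max 1 (shared voltage
ceiling) and kept continuous.  An optional alternate-projections refinement
(`iterations > 0`) is available but off by default; for the patterns tested
it changes the result negligibly.

Decoded single-point holograms match the geometric delay law to better than
0.1 rad on elements carrying ≥10% of the peak amplitude.  The residual
(~0.05–0.08 rad) is Gibbs ringing of the hard band-limit cutoff plus the
curvature of the spherical delay across a finite element; elements near the
aperture rim are strongly apodized by the band limit and their phases are
correspondingly less constrained, so phase-accuracy statements are
amplitude-weighted.

## Resolution metric

The spatial-resolution metric is the **half-power beamwidth**: the full
width at half maximum of the focal `|p|²` profile (equivalently the
distance between the `|p| = 1/√2` points), extracted through the peak with
10× spline upsampling and linear interpolation of the crossings.  This is
the convention under which the simulated focused pistons reproduce the
measured free-field values (simulated 84.7 µm vs 81 µm printed at 20 MHz;
548 vs 590 µm at 3 MHz) — the literal half-maximum of the pressure
magnitude is ≈1.4× wider for an F-number-1 focus (115.9 µm at 20 MHz, by
both the spectral and Rayleigh–Sommerfeld routes) and matches no printed
value.  `measure_fwhm` on an explicit profile measures the literal FWHM of
the samples given; on a field it defaults to the half-power width
(`quantity="pressure"` selects the literal |p| width).

The acuity rule `Snellen denominator = 4 × FWHM(µm)` (20/20 ↔ 5 µm
resolved on the retina, rounded to the nearest multiple of 20) is not a
standard optometric formula; it is reverse-engineered to reproduce both
printed pairs (115 µm → 20/460, 81 µm → 20/320) and documented as such.

Steering coverage declares a commanded target *covered* when the
synthesized peak lands within 0.25 mm and retains ≥50% of the on-axis
steered amplitude; the covered field of view is the largest centered square
whose targets are all covered.  Both thresholds are an operationalization
of "can stimulate" and are configurable.

## Eye model

The default layered eye for the distortion assay uses literature acoustic
properties: cornea (0.7 mm, c = 1586 m/s, ρ = 1076 kg/m³, 0.8 dB/cm/MHz),
lens (3.5 mm, 1641 m/s, 1090 kg/m³, 1.2 dB/cm/MHz), vitreous (to the retina
and beyond, 1532 m/s, 1005 kg/m³, 0.1 dB/cm/MHz).  Because the sound-speed
contrasts are a few percent, the dominant effect is a small axial focal
shift; the lateral half-power width changes by ≈0.1% at 4.5 MHz (< 4%),
measured at each condition's own axial peak plane (scan F ± 1.5 mm in
0.05 mm steps).

## B-mode phantom and auto-alignment

The phantom renders the eye as a sphere of radius 3.5 mm with its anterior
pole at a configurable depth (defaults give a 10 mm array-to-retina
distance).  Tilt (θx, θy) displaces the sphere center laterally by
`R·tanθ/√(1+tan²θx+tan²θy)` so that the anterior-surface normal on the
array axis makes exactly those angles with the axis.  Each slice shows
echogenic outer tissue, an anechoic interior (−10 dB), and a bright shell
on the outward side of the boundary; the interior→shell transition is an
analytic sigmoid in the signed distance to the sphere so the intensity
inflection — and hence the detected edge — sits on the sphere to sub-pixel
accuracy rather than at a pixel-quantized position.  Speckle is multi-look
multiplicative noise (mean-1 gamma, the average of K unit-exponential
intensity draws with K chosen so mean/std matches the requested SNR; K = 1
recovers fully developed exponential speckle), applied before 40 dB log
compression.  Pixels are 50 µm; nine slices span ±2 mm elevation.

What the phantom does *not* emulate: diffraction-limited point-spread
blurring and depth-dependent resolution, refraction and reverberation
artifacts, the lens and iris interfaces, and motion.  Passing alignment
tests therefore demonstrates the correctness of the edge-detection and
pose-fitting chain against known geometry, not performance on clinical
imagery.

Pose recovery: Canny edges (σ = 2 px, hysteresis at 40%/80% of the
99th-percentile gradient magnitude — the paper-style detector with
contrast-adaptive thresholds); per column, the strongest-gradient edge
above/below the anechoic interior's central row gives the anterior and
posterior arc points (sub-pixel via parabolic refinement of the gradient
peak), with grazing columns (chord < 70% of the widest chord) discarded.
Depth is a quadratic fit of the central slice's posterior points evaluated
on the axis.  Tilt comes from an algebraic least-squares sphere (quadric)
fit to all anterior points within 2.5 mm of the axis: the fitted center
(xc, yc) gives `tanθ = c_lateral/√(R²−xc²−yc²)`.  The quadric fit replaces
a small-window tangent-plane fit, whose slope is biased by surface
curvature; fitting the sphere uses the whole imaged cornea cap and is
unbiased by construction.  Across 20 seeded phantoms (tilts ±10°, retina
depth ≈ 9–11.5 mm, 10 dB speckle) recovery errors are ≤0.01 mm in depth and
≤0.04° in tilt, comfortably within the 0.2 mm / 1° targets.

## Dosimetry

`MI = NPP/√f` (MPa, MHz); `I_SPPA = NPP²/(2ρc)` (W/cm²);
`I_SPTA = I_SPPA × duty`.  The thermal index uses the standard small-
aperture soft-tissue form `TI = min(W, I_SPTA·1 cm²)·f / 210 mW·MHz`,
including the center-frequency factor; the beam power `W` is caller-
supplied, since the derating path from surface power to retinal power is a
property of the experiment, not of the formula, and no strict TI target is
asserted.  The radiation body force is `F = p²·α·f/(ρc²)` N/m³ with α in
Np·m⁻¹·MHz⁻¹ (helpers convert from dB·cm⁻¹·MHz⁻¹, 8.6859 dB/Np).

Threshold-vs-frequency fitting offers two power-law models in pressure
units: exponent fixed (default −1, inverse proportionality; −1/2 is what a
constant-radiation-force criterion predicts, since F ∝ p²f) and exponent
free (Levenberg–Marquardt from a log-space start).  RMSE is reported in
MPa.  Monte-Carlo recovery (8 frequencies, σ = 0.05 MPa, 200 replicates)
returns the true exponent within ±0.1 on average.

## MUA pipeline

Zero-phase 4th-order Butterworth filters throughout (the bands 500–7000 Hz
and 10–200 Hz are given; order and phase handling are our choice — forward-
backward filtering avoids latency shifts that would bias the peak search).
Amplitude = post-stimulus maximum of the enveloped signal per trial, then
averaged across trials (averaging after extraction preserves per-trial
traces).  The synthetic generator injects Tukey-windowed band-limited noise
bursts (default 800–3000 Hz, 60 ms, 30 ms latency) on a graded active-
channel mask over white noise; the default post-stimulus window is 200 ms
(unstated upstream; configurable).  The analytic envelope oracle uses the
rectified-mean identities (`2/π` for a sine carrier, `√(2/π)` for Gaussian
noise); oracle agreement is asserted with a sinusoidal carrier, where the
rectification harmonics fall above the envelope band — for a noise carrier
the rectified fluctuation spectrum overlaps 10–200 Hz and inflates the peak
statistic, so no tight bound is claimed there.

The activation map arranges the 56 channels as 7×8 at 0.35 mm (the true
layout's rectangular arrangement; exact shape configurable), zeroes listed
bad channels, and upsamples 4× per axis with separable modified-Akima
cubic interpolation (`makima`), which passes through the node values
exactly and bounds overshoot.  Map-vs-pattern similarity is SSIM (K1=0.01,
K2=0.03, 7×7 uniform window, dynamic range = joint max) after min-max
normalization, with the target resampled to the map grid.

## Problem sizes and determinism

Default problem sizes, chosen as the package's standard operating points:
2048² grids at λ/4 for the 20 MHz resolution simulation, 512² for the
4.5 MHz array (225 steered foci for the coverage map), 256² for the
distortion assay, nine 280×241 phantom slices, and 3–5 trial synthetic
recordings.  Every stochastic component (phantom speckle, synthetic
ephys, Monte-Carlo fits) draws from an explicit seed carried in its spec,
and repeated runs are bit-identical; the closed-loop demo writes a
byte-reproducible JSON report.

## Known limitations

Scalar, linear, monochromatic acoustics only (no nonlinearity, shear waves,
or transducer electrical modeling); rigid-piston elements with no
crosstalk; planar-layer eye (no refraction at curved interfaces); the
phantom and synthetic recordings validate algorithmic correctness, not
in vivo performance; absolute pressures are relative (no hydrophone
calibration), so dosimetry takes measured NPP as input rather than deriving
it from the field simulation.
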