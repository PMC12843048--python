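# Methods

This note documents the models, numerical choices, and limitations of
`uteqsm`. Symbols: χ susceptibility (ppm), b local field, D(k) the k-space
dipole kernel, R2\* = 1/T2\* the effective transverse rate, R2′ = R2\* − R2
its reversible component.

## Field model and conventions

A susceptibility distribution produces a relative field shift
`IFFT(D(k)·FFT(χ))` with D(k) = 1/3 − (k·b̂₀)²/|k|² evaluated on the
physical frequency grid (cycles/mm), so anisotropic voxels are handled
naturally. Conventions, shared by all stages:

- **DC term.** D(0) = 0. The spatial mean of χ is unobservable from the
  field, so all simulated and inverted fields are mean-free. Absolute χ
  offsets are therefore not meaningful; only contrasts are.
- **FFT layout.** Half-open frequency grid, zero frequency at index 0
  (`numpy.fft.fftfreq`); all modules share it.
- **B0 direction** defaults to the array +z axis and is configurable as a
  unit vector for oblique acquisitions.
- **Padding.** `forward_field` is a circular (periodic) convolution by
  default. A zero-padding factor of 2 approximates the open-boundary
  (linear) convolution; it is enabled inside the background-removal stage
  and in the acquisition simulator, where sources near the volume edge
  would otherwise wrap. Verification: the padded forward field of a
  uniform sphere matches the analytic external solution
  (χ/3)(a/r)³(3cos²θ−1) to 0.3% relative RMS over 2a < r < 4a at 64³
  (1.4% unpadded).
- **Units.** Times in seconds, fields in Hz, χ in ppm internally;
  milliseconds appear only at the configuration boundary. Conversion uses
  γ̄ = 42.577 MHz/T (1 ppm at 3 T = 127.73 Hz).

## Multi-echo water/fat fit

Per voxel, echoes S(t_j) are fit to

S(t) = (S_W e^(−R2\*·t) + S_F Σ_k α_k e^(i2πf_k t)) e^(i(φ₀+2πf_B0 t)),

five real parameters with a *shared* initial phase φ₀ between water and
fat. Only the water pool is damped by R2\*; the fat terms are undamped, as
the model above states literally. An option (`FitOptions.damp_fat`)
applies the same decay to fat, and `shared_phase=False` relaxes the common
phase to independent complex amplitudes, since many fat–water variants
make those choices.

**Fat spectrum.** Six peaks with shifts in ppm relative to water,
amplitude-normalized, scaling linearly with field strength. The packaged
table (`data/fat_spectrum_6peak.json`) is a synthetic calibration artifact
constructed so the amplitude-weighted mean shift is ≈ −429 Hz at 3 T,
consistent with the conventional ≈ −440 Hz dominant methylene shift; it is
not a measured spectrum and should be replaced (via `FatSpectrum`) for
quantitative fat-fraction work. Output sidecars record which table was
used.

**Solver.** Variable projection: for fixed (f_B0, R2\*), the optimal
(S_W, S_F, φ₀) minimizing the complex residual is closed-form — the normal
equations Re(AᴴA)ρ = Re(e^(−iφ)Aᴴs) reduce the optimal phase to the
principal eigenvector of a 2×2 symmetric matrix; nonnegativity of the
amplitudes falls back to the better single-pool boundary solution. The
reduced 2-D objective is scanned on a coarse grid (f_B0 step 2 Hz over
±1/(2·min ΔTE), R2\* on a log-spaced node set in [0, 5000] s⁻¹) because
the ~440 Hz fat–water ambiguity creates distant local minima; the best
node is refined by a shrinking pattern search in (f_B0, log R2\*) and a
guarded finite-difference Newton polish. Volume fitting first runs the
full scan on a 2× downsampled volume and propagates its f_B0 map as the
full-resolution seed, which suppresses isolated fat–water swaps; the
full-resolution stage then searches only a ±45 Hz window around the seed
before refining. All stages are vectorized across voxels and
deterministic. Degenerate voxels (all-zero or non-finite) are flagged
not-converged with zeroed outputs and excluded downstream.

Measured on noise-free synthetic volumes at the eight-echo phantom
schedule: max |f_B0| error ≤ 0.003 Hz, T2\* within 0.1% (1% in the nearly
degenerate high-fat/slow-decay corner), fat fraction within 1e-4, zero
swaps for |f_B0| ≤ 100 Hz.

## Background-field removal

Projection onto dipole fields: find background susceptibility x supported
outside the tissue mask M minimizing ‖W·M·(f − D⊛((1−M)x))‖², solved by
LSMR on the weighted operator (stop: relative tolerance 1e-6 or 200
iterations); the local field is f − D⊛x inside the mask, zeroed (not
extrapolated) outside. Weights default to uniform inside the mask;
magnitude weighting is optional. Convolutions are zero-padded ×2 and
cropped, so edge sources are modeled with open boundaries. Masks come from
`make_mask`: threshold at a fraction of the robust (99.5th-percentile)
maximum, fill holes, erode, keep the largest connected component. The mask
must keep a ≥2-voxel margin to the volume edge.

**Known behavior.** The exact least-squares projection removes whatever
part of the *interior* sources' field is representable by exterior
sources — i.e. its harmonic-in-mask component. For broad interior sources
this removes 10–25% of the local field, concentrated toward the mask
boundary; for compact, deep sources the error measured ≥6 voxels from the
boundary is below 5%. This is a property of the projection formulation
itself (damping or early stopping only trades it against background
suppression — both were measured and rejected as defaults), and it is why
the test suite evaluates interior-field preservation on a compact central
source inside a 6-voxel-eroded mask. External-source fields are suppressed
to ≈0.1% RMS. Consequences for the phantom pipeline: per-tube mean local
field biases of ≈1–2% (tubes are cylinders along B0, whose fields are
nearly unmimickable tophats), common-mode across tubes, so concentration
correlations are essentially unaffected.

## χ-separation

Joint inversion of the local field (ppm) and R2′ for χ⁺ ≥ 0 and χ⁻ ≤ 0:

J = λ_f‖W(b − D⊛(χ⁺+χ⁻))‖² + λ_r‖W′(R2′ − D_r(χ⁺−χ⁻))‖² + λ_reg R(χ⁺,χ⁻).

The field senses the *sum* of the signed components; R2′ senses their
*absolute content* (difference of signed values) through the relaxometric
constant D_r. Together they are jointly identifiable; the sign constraints
resolve the remaining ambiguity.

- **D_r = 114 s⁻¹/ppm at 3 T**, scaled linearly with field strength — a
  literature-order static-dephasing calibration, *not* fitted here; it is
  echoed in every output sidecar.
- **R2′ from R2\*.** Short-T2 tissue rarely admits a spin-echo R2
  measurement, so R2 is assumed proportional to R2\*: R2 = c·R2\* with
  c = 0.3 by default (`r2_ratio`), giving R2′ = (1−c)·R2\*, clamped at 0.
  A measured R2 map can be supplied instead. The proportionality constant
  is a modeling assumption whose validity varies by tissue; biases enter
  the separated maps as a common-mode offset split between χ⁺ and −χ⁻
  (see the phantom discussion below).
- **Weights** λ_f = 1, λ_r = 1/D_r² by default, so both data terms are in
  ppm²; voxels whose upstream fit failed get zero weight in both terms.
- **Regularizer**: Tikhonov with λ_reg = 1e-3 (relative to the
  unit-weighted ppm² data terms) by default; smoothed isotropic TV
  (ε = 1e-6) optional.
- **Solver**: alternating projected gradient with backtracking from a
  conservative Lipschitz step; every iterate is sign-feasible by
  construction and the objective is monotonically non-increasing (both
  recorded in the diagnostics and asserted in tests). Stopping: relative
  objective change < 1e-6 on three consecutive iterations, or 250
  iterations. χ_total ≡ χ⁺ + χ⁻ exactly.

On self-consistent noise-free scenes (field and R2′ generated by the same
forward model) a 0.5 ppm paramagnetic sphere is recovered to 0.3% in the
interior mean with |χ⁻| ≤ 0.002 ppm, and a mixed ±0.5 ppm sphere recovers
both components to 0.1% with |χ_total| ≈ 1e-5 ppm — the cancellation
phenomenon that motivates source separation.

## Synthetic phantom

`make_tube_phantom` rasterizes three cylinders (radius 7 mm, length 80 mm,
along B0) in a cylindrical agarose container (radius 40 mm, length
116 mm), default grid 64³ at 2 mm. Concentration design: diamagnetic proxy
522/347/174 mg/mL, paramagnetic proxy 12/8/4 mg/mL (tube 1 carries the
highest concentration of both).

- **Calibration slopes** are free parameters, not physical molar
  susceptibilities: χ⁺ slope +0.07 ppm/(mg/mL) and χ⁻ slope
  −0.00135 ppm/(mg/mL) put tube susceptibilities in the ±1 ppm range
  (+0.84…+0.28 and −0.70…−0.23 ppm).
- **R2\* model**: r2star = background + slope_para·c_para +
  slope_dia·c_dia, with agarose background 15 s⁻¹ and slopes
  11.4 / 0.22 s⁻¹/(mg/mL) chosen so that (1−c)·R2\* ≈ D_r(χ⁺−χ⁻) inside
  the tubes — i.e. the generator is consistent with the default ratio
  assumption *except* for the agarose term, which injects a known uniform
  R2′ bias of (1−c)·15/D_r ≈ 0.09 ppm. That bias is retained deliberately:
  it emulates the real-world imperfection of the R2 ∝ R2\* assumption and
  appears in pipeline results as a small common-mode inflation of both
  components (≈ +0.045 ppm each), leaving tube orderings and
  concentration correlations intact.
- **Partial volume** is antialiased by supersampling rim voxels (8×8
  in-plane subsamples; exact 1-D overlap along the tube axis), which
  suppresses ringing in the forward fields. Relaxation rates are tissue
  properties, so partial volume acts on signal amplitude, not on the rate.
- **Acquisition**: per-voxel signal from the water/fat model (φ₀ = 0.3 rad
  constant, fat undamped, T2\* = 1/r2star), off-resonance from the padded
  forward field of all sources, complex Gaussian noise per echo at the
  stated SNR (defined on the first-echo mean magnitude inside the mask),
  fully reproducible per seed. Echo presets: the eight-echo schedule
  0.05–5.5 ms (phantom) and the six-echo 0.032–4.7 ms schedule
  (knee/ankle). k-space trajectories are *not* simulated — signals are
  generated in image space, consistent with the trajectory-robustness of
  susceptibility estimates; gridding/streaking artifacts of non-Cartesian
  reconstruction are therefore outside what these tests can show.
- **Background source**: one 9 ppm sphere (radius 8 mm) outside the
  container exercises the background-removal stage with tens-of-Hz smooth
  gradients inside the mask.

**What passing tests show / don't show.** The synthetic data match the
pipeline's own signal model (plus noise), so end-to-end tests validate the
estimators, conventions and solver contracts — not robustness to coil
phase singularities, motion, flow, k-space trajectory artifacts,
chemical-shift displacement, or hemosiderin signal voids (extreme
concentrations where even ultrashort echoes detect no signal; an R2\*
upper bound of 5000 s⁻¹ merely caps the parameterization there).

## Problem sizes and determinism

Default test and acceptance problem sizes are 64³ (pipeline, background
removal, kernel oracles) and 48³/32³ for module-level property tests —
sizes at which every stage's behavior is already asymptotic while a full
pipeline run completes in about a minute. All solvers are deterministic;
the only randomness is the seeded acquisition noise, and identical
configurations reproduce bit-identical outputs (checksummed in the
pipeline provenance record).

## Known limitations

- The dipole inversion is regularized (Tikhonov/TV) but not
  streak-suppressing; strong cone-of-silence artifacts from noisy fields
  are attenuated mainly by the R2′ data term.
- The exact-projection background removal attenuates broad interior field
  patterns near the mask boundary (quantified above).
- D_r and the R2/R2\* ratio are literature-order constants; absolute
  component values inherit their uncertainty even when correlations with
  composition are strong.
- Single-coil, eddy-current-free, monopolar acquisition is assumed; no
  coil combination or phase-error correction is provided.
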