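# Methods

This note records the model, the parameters that matter, what the synthetic
data do and do not emulate, and the design choices made where the design was
genuinely open.  Every number quoted here is produced by the test suite, the
examples, or `scripts/acceptance.py`.

## Signal model and processing chain

A linear array of N elements (pitch p, center frequency f0, sampling rate
fs, speed of sound c) acquires a full STA data set: element i transmits a
spherical wave, all j receive, giving rf[i, j, t].  For an image point
(x, z) the two-way delay is (d_tx + d_rx)/c with Euclidean distances to the
element positions on z = 0; channel samples are read by linear
interpolation in time, out-of-window reads are zero-filled and counted.
Receive synthesis collapses j by weighted summation (rectangular or Hamming
taper; an f-number > 0 restricts |x_e − x| ≤ z/(2·f#), and the f-number rule
applies to the receive stage only — the adaptive stage always sees all N
transmit-synthesized entries).  Each receive-synthesized trace is converted
to its analytic signal along depth (one-sided spectrum doubling), so all
adaptive processing operates on complex data and the envelope is the
modulus of the beamformed output.  The formulas in the source literature
are written in real arithmetic and never state a Hilbert conversion; we
processed both conventions end to end and kept the analytic signal, which
is the standard choice for Hermitian covariance processing.  The choice is
consequential: real-RF processing roughly quintuples the MV beam width (see
"Known limitations").

Beamformers per pixel:

* **DAS** — apodized sum of the N transmit-synthesized entries.
* **MV (Capon)** — covariance from spatial smoothing (subarrays of length
  L) and temporal smoothing (2K+1 axial samples), diagonal loading
  ε = Δ·trace(R), Hermitian solve for w = R̂⁻¹a/(aᴴR̂⁻¹a) with a = 1, output
  averaged over the center vector's subarrays.  The batched image driver
  uses numpy's batched LU solve and is tested to 1e-10 against the
  per-pixel Cholesky path; a singular solve (never observed after loading)
  falls back to uniform weights and is counted.
* **ESBMV** — w_MV projected onto the eigenvectors of R̂ with λ ≥ γ·λ_max
  (ties inclusive, λ_max always kept).  When every eigenvalue passes, the
  projection short-circuits to w_MV exactly, so γ → 0 reproduces MV
  bit for bit.
* **GCF-MV** — MV multiplied by the generalized coherence factor: the
  fraction of aperture-spectrum energy in the 2·M0+1 bins k ∈ [−M0, M0]
  of the unitary DFT across the aperture.
* **CMSF-MV / CMSAW-MV** — MV multiplied by the mean-to-standard-deviation
  ratio (MSR) of a modified covariance matrix; see below.

## The CMSF / CMSAW chain

Per pixel: σ = population std of the aperture entries (complex deviations
enter via squared modulus); image-wide σ′ = σ^(−1/3) normalized by its
global maximum (σ clamped below at 1e-12·max σ); L′ = ⌊σ′·L_max⌋ clamped at
2; spatial-only smoothing over N−L′+1 subarrays; rotary averaging exactly
as the four-term form (R + JRᵀ + JRJ + RᵀJ)/4 — for Hermitian R this is
Hermitian (JRᵀ and RᵀJ are mutual adjoints) — with a `classic_fb` alternate
mode (R + JRᵀJ)/2 available; diagonal reducing R̂ − δ·diag(R̂); MSR over all
L′² entries, computed on real parts (the diagonal is real, off-diagonals
near-conjugate-symmetric; an all-|·| variant was measured to give
indistinguishable images).  A constant-matrix MSR returns a cap of 1e6 and
is counted; the all-zero matrix returns weight 0.  CMSAW replaces δ by
δ_ac = W_CF^σ′·δ_max (σ′ clamped ≥ 1e-6; W_CF = 0 maps to 0).  The σ′ map
is computed once, pooled over every region being imaged, and reused for
both L′ and δ_ac.  Weight maps are applied raw to the complex MV image; the
display normalization absorbs global scale.

The weighting works because the MSR of the reduced matrix separates signal
classes: a coherent vector gives the two-valued matrix whose MSR is
√(L′−1); incoherent noise gives a diagonal-dominant matrix with MSR
≈ 1/√(L′−1); strong off-axis (alternating-phase) clutter cancels under
rotary averaging and lands near 0 (`examples/02`).

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| L | N/2 | MV subarray length (study setting) |
| Δ | 0.1/L | diagonal loading scale; inflates trace by exactly 10% |
| 2K+1 | 9 | temporal smoothing samples |
| temporal stride | λ/4 (study), 1 (library) | spacing of the temporal samples on the image grid, see below |
| γ | 0.5 | ESBMV eigenvalue threshold |
| M0 | 1 | GCF low-frequency half-width |
| δ, δ_max | 1.0 | diagonal reducing (study setting) |
| L_max | N/4 (study), N/2 (library) | dynamic-subarray ceiling, see below |
| ASD exponent | 1/3 | σ′ = normalized σ^(−1/3) |
| gCNR bins | 256 | equal-width bins on the pooled envelope range |
| dynamic range | 60 dB | display log compression |

Two parameters are not fixed by the published description and were resolved
here; both are exposed in `BeamformerConfig`:

* **Temporal-smoothing stride.** "2K+1 axial imaging points" depends on the
  axial image sampling, which is never stated.  At RF-rate axial sampling
  (c/2fs ≈ 19 µm) nine adjacent rows span only 0.17 mm — a fraction of the
  0.39 mm pulse — and MV becomes far more aggressive than the published
  baseline behaves (background speckle SNR 1.31 instead of ≈ 1.8).  The
  study presets therefore space the nine temporal samples a quarter
  wavelength apart while keeping the display grid at RF rate, which
  reproduces the expected MV speckle statistics (sSNR 1.76–1.78).  The
  display grid itself must stay fine: coarsening it to λ/2 puts the axial
  carrier at Nyquist and aliases the envelope.
* **L_max.** With L_max = N/2 the CMSAW weight map on speckle is too noisy
  to smooth it (speckle sSNR 1.5 < DAS 1.8); at N/4 the weight
  anti-correlates with |Y_MV| (r ≈ −0.4) and the defining
  speckle-preservation property appears (sSNR 2.0–2.4 > DAS).  The study
  presets use N/4; the bare library default stays N/2.

## Synthetic data

The generator emulates a Field-II-style point-scatterer experiment.
Scatterer count = density × phantom volume / resolution-cell volume, with
the cell defined as (λ·z_mid/D) × elevation slab × c/(2B), B the −6 dB pulse
bandwidth; positions uniform in the slab (elevation collapsed to a 0.5 mm
band around y = 0), amplitudes N(0, 1) scaled per cyst sphere (0 anechoic),
point targets appended explicitly.  Echoes are Gaussian-enveloped cosines
(default 60% fractional bandwidth, tabulated at 16× fs and linearly
interpolated) at the exact two-way delays, with optional 1/(d_tx·d_rx)
spreading (default on); transmit/receive reciprocity is exact.  Additive
channel noise is white Gaussian with variance set from the mean power of
the nonzero signal support and the requested SNR in dB.  All randomness
flows through explicitly seeded generators; identical seeds give
bit-identical cubes.

The full study configuration is the 64-element, 0.24 mm pitch, 3.33 MHz,
40 MHz, 1540 m/s array with a 22×0.5×15 mm phantom at 40 scatterers per
cell (≈ 45,500 scatterers), three point targets at x = 0, z = 19/24/29 mm,
a 5 mm anechoic cyst at (−6, 24.5) mm, and 10 dB channel SNR.  Point-target
amplitude is 200 relative to unit-variance scatterers (≈ 30 dB above the
speckle envelope mean), chosen so the −6 dB crossings are measured on the
mainlobe rather than on speckle.  The toy variant (N = 32, 10 per cell, one
point, 4 mm cyst) runs end to end in a few seconds.

Not modeled: element directivity and subdivision, exact spatial impulse
responses, attenuation, nonlinear propagation, phase aberration.  Passing
tests therefore demonstrate the algorithmic chain under ideal focusing, not
performance on real channel data; recorded data can be loaded through the
HDF5 container or the MATLAB adapter in `stabeam.io`.

## Metrics and regions

Metrics operate on the pre-compression envelope and are all invariant to a
global gain.  Lateral FWHM takes the lateral profile through the peak's
axial row and interpolates the two −6 dB crossings linearly in dB (lateral
sampling 10–20 µm in the point regions).  CR = 20·log10(μ_cyst/μ_bck);
gCNR = 1 − Σ min of the two histogram masses on 256 equal-width bins over
the pooled range; sSNR = μ/σ (population).  The cyst ROI is the cyst circle
eroded by roughly one beamwidth; the background ROI sits at matched depth
on the mirrored side and is larger (a homogeneous region needs no erosion,
and more independent speckle cells stabilize sSNR).  Because the simulator
applies geometric spreading, the envelope carries a deterministic ~z⁻²
depth trend that display processing on a scanner removes; the evaluation
stage therefore applies two-way time-gain compensation (envelope ×
(z/z_mid)²) uniformly to every method before ROI statistics.  Beamforming
and the adaptive weights always see uncompensated data.  Region grids keep
an axial margin beyond the ROIs so analytic-signal edge transients stay out
of the statistics.

## Numerical choices and degenerate inputs

Linear time interpolation of channel data (fs ≫ f0); covariance symmetrized
before the solve; eigenvalue ties at γ·λ_max inclusive; temporal windows
shrink symmetrically at image edges instead of zero-padding (zero rows bias
R toward singularity); per-pixel operations are pure functions, so the
image loop order cannot change results.  Degenerate handling: zero-trace
covariance skips loading with a warning; singular solves fall back to
uniform weights; all-zero aperture vectors give CF = GCF = 0 and weight 0;
σ′ normalization refuses an all-zero σ map.  Pixel-failure counters
(out-of-window reads, singular solves, clamped L′, capped MSR) are carried
through to the run manifest; in the shipped study runs all are zero except
out-of-window reads at patch corners.

## Problem sizes

The acceptance script runs three seeded realizations of the full
64-element study; each simulates ≈ 45,500 scatterers into a 64×64×~2000
cube (~35 s) and beamforms three metric regions (cyst, background, point;
≈ 85,000 pixels total) with DAS, MV and CMSAW-MV (~15 s), for about two
minutes overall on one CPU.  The test suite uses the 32-element toy and
speckle phantoms (3,000–8,000 scatterers, ≈ 40,000 pixels) and runs in
about half a minute.

## Known limitations

* Under ideal focusing the complex-data MV super-resolves: the measured MV
  FWHM is ≈ 0.10 mm and CMSAW-MV ≈ 0.07 mm at 24 mm depth, a larger gain
  over DAS (0.68 mm, itself within 6% of the 0.886·λz/D diffraction value)
  than reported for Field II data.  Real-RF processing moves the same
  pipeline to MV 0.51 / CMSAW 0.39 mm, bracketing published values; the
  absolute FWHM of the adaptive methods is therefore the least transferable
  number this bench produces.
* The CR-versus-sSNR tradeoff in (δ, L_max) is sharper here than with Field
  II data: at the study L_max = N/4 the CMSAW contrast gain stops ~1.5 dB
  short of GCF-MV's, while larger L_max restores the contrast margin but
  destroys the speckle preservation.  No single setting achieves both
  margins in this simulator.
* gCNR on the anechoic cyst saturates near 0.99 for every well-suppressing
  method because the idealized cyst interior is almost empty; recorded
  phantoms show more overlap.
* The MSR weight maps inherit the L′ floor quantization; at very bright
  points the weight profile can develop sample-scale structure, which is
  why the acceptance script reports the FWHM median across seeds.
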