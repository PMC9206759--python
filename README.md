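# stabeam

Adaptive minimum-variance beamforming for synthetic-transmit-aperture (STA)
medical ultrasound, with covariance-matrix-based adaptive pixel weighting
(CMSF and CMSAW), the baselines it is compared against (DAS, MV, ESBMV,
GCF-MV), an in-repo Field-II-style channel-data simulator, and the standard
image-quality metrics (lateral FWHM, CR, gCNR, sSNR).

It is written for ultrasound beamforming researchers who want a compact,
tested reference implementation of the covariance-matrix
mean-to-standard-deviation weighting chain and a reproducible synthetic
test bench for it.

## The method

In STA imaging each element transmits alone while all N receive; after
delay compensation and receive-aperture synthesis every image point p has a
complex aperture vector x(p) of length N.  The Capon (minimum-variance)
beamformer forms

    w_MV = R̂⁻¹a / (aᴴR̂⁻¹a),   a = 1,   Y_MV = (1/(N−L+1)) Σ_l w_MVᴴ x_l,

with R estimated by spatial smoothing over length-L subarrays and temporal
smoothing over 2K+1 axial neighbors, and stabilized by diagonal loading
ε = Δ·trace(R).  MV sharpens the point response dramatically but does little
for contrast and roughens speckle.

The covariance-matrix statistical factor (CMSF) weights each MV pixel by
the mean-to-standard-deviation ratio (MSR) of a modified covariance matrix:

1. σ(p) = aperture amplitude standard deviation; σ′ = normalized σ^(−1/3)
   over the whole image; dynamic subarray length L′ = ⌊σ′·L_max⌋ (≥ 2);
2. spatial-only smoothing R over the N−L′+1 subarrays of x(p);
3. rotary averaging R̂ = (R + JRᵀ + JRJ + RᵀJ)/4 with J the exchange matrix;
4. diagonal reducing R̂ − δ·diag(R̂);
5. W_CMSF = E[R̂] / Std[R̂] over all L′² entries; Y = W_CMSF · Y_MV.

CMSAW replaces the constant δ with a per-pixel, coherence-driven value
δ_ac = W_CF^σ′ · δ_max (W_CF the coherence factor), which preserves speckle
texture while still crushing off-axis clutter and incoherent noise.

## Worked example

`python examples/01_simulate_and_beamform.py` simulates the 32-element toy
phantom (speckle slab, 4 mm anechoic cyst, one point target, 10 dB channel
SNR) and prints:

```
method,fwhm_mm,cr_db,gcnr,ssnr
das,1.209,-18.52,0.9065,1.715
mv,0.238,-16.75,0.8752,1.654
esbmv,0.2356,-24.41,0.898,1.568
gcf_mv,0.2357,-29.16,0.9168,1.263
cmsf_mv,0.119,-23.2,0.907,1.554
cmsaw_mv,0.1198,-25.75,0.9419,2.094
```

Reading it: DAS sits at the 1.2 mm diffraction limit with Rayleigh-like
speckle (sSNR ≈ 1.9); MV reaches 0.24 mm but loses contrast and speckle
quality; the CMSAW weighting halves the MV width again (0.12 mm), restores
9 dB of cyst contrast over MV, and is the only adaptive method whose
speckle SNR rises *above* DAS — the speckle-preservation property that
motivates the coherence-adaptive diagonal reducing.

The other examples show the weighting chain on canonical aperture vectors
(`02`), Rayleigh speckle statistics (`03`), and per-method point resolution
(`04`).  A thin CLI wraps the same pipeline:
`stabeam run --preset toy --seed 1 --out scratch/run1 --dump-weights`.

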