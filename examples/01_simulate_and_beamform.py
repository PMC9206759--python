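"""Simulate the toy STA phantom and beamform it with all six methods.

Builds a 32-element synthetic-transmit-aperture acquisition of a speckle
slab containing a point target and a 4 mm anechoic cyst, beamforms the
metric regions with DAS, MV, ESBMV, GCF-MV, CMSF-MV and CMSAW-MV, and
prints the image-quality table: lateral -6 dB FWHM (resolution, smaller is
better), contrast ratio CR in dB (more negative = darker cyst), gCNR in
[0, 1] (lesion detectability), and speckle SNR (~1.91 for Rayleigh speckle,
larger = smoother background).
"""

from stabeam.pipeline import RunConfig, run

result = run(RunConfig(preset="toy", rng_seed=1))
print(result.report.as_table())
print(
    "Reading the table: the adaptive weighting (cmsaw_mv) should combine\n"
    "the best resolution (smallest fwhm_mm), strong cyst contrast, and a\n"
    "speckle SNR above DAS — preserving tissue texture while rejecting\n"
    "clutter and noise."
)
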