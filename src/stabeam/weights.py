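"""Pixel-based adaptive weights: CF, GCF, and the CMSF / CMSAW chain.

The covariance-matrix statistical factor (CMSF) weights each MV pixel by the
mean-to-standard-deviation ratio (MSR) of a modified covariance matrix built
from the aperture vector in four steps:

1. a dynamic subarray length L' = floor(sigma' * L_max), where sigma' is the
   image-wide-normalized reciprocal amplitude standard deviation (ASD) of
   the aperture data, raised to the 1/3 power;
2. spatial smoothing over the N - L' + 1 sliding subarrays (no temporal term);
3. rotary averaging R_hat = (R + J R^T + J R J + R^T J) / 4 with J the
   exchange matrix;
4. diagonal reducing R_hat - delta * diag(R_hat), emphasizing the
   off-diagonal coherence structure.

CMSAW replaces the constant delta by an adaptive per-pixel value
delta_ac = W_CF^sigma' * delta_max driven by the coherence factor, which
preserves speckle while still suppressing incoherent noise.  Coherent
mainlobe signals keep moderate weights, strong off-axis clutter and
incoherent noise get small MSR values, which is what suppresses them in the
weighted image W x Y_MV.
"""

from __future__ import annotations

import logging

import numpy as np

from .beamform import BeamformerConfig

log = logging.getLogger(__name__)

#: relative floor used when normalizing reciprocal ASDs
_SIGMA_FLOOR = 1e-12
#: std/mean ratio below which the MSR is considered degenerate
_MSR_EPS = 1e-12


def coherence_factor(x) -> float:
    """Coherence factor |sum x|^2 / (N sum |x|^2), in [0, 1].

    1 for perfectly coherent (identical) entries, 0 for perfectly
    misaligned ones; an all-zero vector returns 0.
    """
    x = np.asarray(x)
    total = np.sum(np.abs(x) ** 2)
    if total == 0.0:
        return 0.0
    return float(np.abs(np.sum(x)) ** 2 / (x.size * total))


def generalized_cf(x, M0: int) -> float:
    """Generalized coherence factor: low-spatial-frequency energy fraction.

    The aperture vector is Fourier transformed across the aperture; the
    numerator sums the 2*M0+1 bins k in [-M0, M0] of the spectrum, the
    denominator is the total energy.
    """
    x = np.asarray(x)
    n = x.size
    if not (0 <= M0 <= n // 2):
        raise ValueError("M0 must be in [0, N/2]")
    s = np.fft.fft(x) / np.sqrt(n)
    power = np.abs(s) ** 2
    total = power.sum()
    if total == 0.0:
        return 0.0
    k = np.rint(np.fft.fftfreq(n) * n).astype(int)
    return float(power[np.abs(k) <= M0].sum() / total)


def aperture_asd(x) -> float:
    """Population standard deviation of the aperture entries about their mean.

    Complex entries contribute through the squared modulus of their
    deviations, which reduces to the printed real formula for real data.
    """
    x = np.asarray(x)
    if x.size < 2:
        raise ValueError("need at least 2 aperture entries")
    mean = x.mean()
    return float(np.sqrt(np.mean(np.abs(x - mean) ** 2)))


def normalize_asd(sigma, exponent: float = 1.0 / 3.0) -> np.ndarray:
    """Image-wide normalized reciprocal ASD map sigma' in (0, 1].

    t = sigma^(-exponent) per pixel (sigma clamped below at
    1e-12 * max sigma), then divided by the image-wide maximum of t, so the
    weakest pixel maps to 1.  A two-pass, whole-image operation.
    """
    sigma = np.asarray(sigma, dtype=np.float64)
    smax = sigma.max() if sigma.size else 0.0
    if smax <= 0.0:
        raise ValueError("all-zero ASD map: degenerate image")
    clamped = np.maximum(sigma, _SIGMA_FLOOR * smax)
    t = clamped ** (-exponent)
    return t / t.max()


def dynamic_subarray_length(sigma_prime, L_max: int):
    """L' = floor(sigma' * L_max), clamped below at 2."""
    lp = np.floor(np.asarray(sigma_prime) * L_max).astype(int)
    return np.maximum(lp, 2)


def smooth_covariance(x, L_prime: int) -> np.ndarray:
    """Spatial-only smoothed covariance of the single center vector.

    Averages the outer products of the N - L' + 1 sliding subarrays; no
    temporal smoothing enters this estimate.
    """
    x = np.asarray(x, dtype=complex)
    n = x.size
    if not (2 <= L_prime <= n):
        raise ValueError("L' must satisfy 2 <= L' <= N")
    subs = np.lib.stride_tricks.sliding_window_view(x, L_prime)
    return subs.T @ subs.conj() / subs.shape[0]


def exchange_matrix(n: int) -> np.ndarray:
    """Anti-diagonal identity J."""
    return np.eye(n)[::-1]


def rotary_average(R, mode: str = "as_printed") -> np.ndarray:
    """Rotary averaging of a square covariance matrix.

    ``as_printed`` evaluates (R + J R^T + J R J + R^T J) / 4 term by term
    with J the exchange matrix.  ``classic_fb`` is the conventional
    forward-backward average (R + J R^T J) / 2.
    """
    R = np.asarray(R)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("rotary averaging needs a square matrix")
    Rt = R.T
    if mode == "as_printed":
        return (R + Rt[::-1, :] + R[::-1, ::-1] + Rt[:, ::-1]) / 4.0
    if mode == "classic_fb":
        return (R + Rt[::-1, ::-1]) / 2.0
    raise ValueError(f"unknown rotary mode {mode!r}")


def diagonal_reduce(R_hat, delta: float) -> np.ndarray:
    """Subtract delta times the diagonal part: delta=1 zeroes the diagonal."""
    if not (0.0 <= delta <= 1.0):
        raise ValueError("diagonal reducing factor must be in [0, 1]")
    R_hat = np.asarray(R_hat)
    out = R_hat.copy()
    idx = np.arange(R_hat.shape[-1])
    out[..., idx, idx] = (1.0 - delta) * R_hat[..., idx, idx]
    return out


def matrix_msr(M, cap: float = 1e6) -> float:
    """Mean-to-standard-deviation ratio of all matrix entries.

    Complex entries enter via their real part (the reduced covariance has a
    real diagonal and near-conjugate-symmetric off-diagonals, so this reduces
    to the printed real formula).  A degenerate all-equal matrix returns the
    configured cap; the all-zero matrix returns 0.
    """
    A = np.asarray(M).real
    mean = A.mean()
    std = np.sqrt(np.mean((A - mean) ** 2))
    if std <= _MSR_EPS * abs(mean):
        if mean == 0.0:
            return 0.0
        log.debug("degenerate MSR (constant matrix); returning cap")
        return float(cap)
    return float(mean / std)


def adaptive_delta(w_cf: float, sigma_prime: float, delta_max: float) -> float:
    """Coherence-driven diagonal reducing factor delta_ac = W_CF^sigma' * delta_max.

    Ranges over [0, delta_max]: coherent mainlobe pixels get the full
    reduction, incoherent noise almost none.  sigma' is clamped at 1e-6 so
    0^0 never evaluates; W_CF = 0 maps to 0.
    """
    if not (0.0 <= delta_max <= 1.0):
        raise ValueError("delta_max must be in [0, 1]")
    if w_cf <= 0.0:
        return 0.0
    return float(w_cf ** max(sigma_prime, 1e-6) * delta_max)


def cmsf_weight(x, sigma_prime: float, cfg: BeamformerConfig) -> float:
    """CMSF pixel weight: the full chain with the constant delta."""
    lp = int(dynamic_subarray_length(sigma_prime, cfg.L_max))
    R = smooth_covariance(x, lp)
    R_hat = rotary_average(R, cfg.rotary_mode)
    return matrix_msr(diagonal_reduce(R_hat, cfg.delta), cfg.msr_cap)


def cmsaw_weight(x, sigma_prime: float, cfg: BeamformerConfig) -> float:
    """CMSAW pixel weight: same chain with the CF-adaptive delta_ac."""
    lp = int(dynamic_subarray_length(sigma_prime, cfg.L_max))
    R = smooth_covariance(x, lp)
    R_hat = rotary_average(R, cfg.rotary_mode)
    d_ac = adaptive_delta(coherence_factor(x), sigma_prime, cfg.delta_max)
    return matrix_msr(diagonal_reduce(R_hat, d_ac), cfg.msr_cap)


def apply_pixel_weight(weight_map, image):
    """Element-wise weighting of the complex beamformed image.

    Applied before envelope detection; the weight maps are used raw (the
    display normalization absorbs any global scale).
    """
    weight_map = np.asarray(weight_map)
    image = np.asarray(image)
    if weight_map.shape != image.shape:
        raise ValueError("weight map and image shapes differ")
    return weight_map * image
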