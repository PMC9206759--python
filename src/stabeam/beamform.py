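"""Per-pixel DAS, minimum-variance (Capon) and eigenspace-based MV.

The MV beamformer minimizes output power subject to unit gain toward the
focal point: with covariance R and steering vector a = 1 (the data are
already delay-compensated), w = R^-1 a / (a^H R^-1 a).  The covariance is
estimated by spatial smoothing over length-L subarrays and temporal smoothing
over 2K+1 axial neighbors, and stabilized by diagonal loading
eps = Delta * trace(R).  ESBMV projects the MV weights onto the dominant
eigen-subspace (eigenvalues >= gamma * lambda_max).

These functions operate on single pixels and are deliberately simple; the
vectorized whole-image drivers live in :mod:`stabeam.imaging` and are tested
against them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

log = logging.getLogger(__name__)


@dataclass
class BeamformerConfig:
    """Parameters for every beamformer in the comparison.

    Defaults mirror the canonical study settings: L = N/2, Delta = 0.1/L,
    2K+1 = 9 axial points, gamma = 0.5, M0 = 1, delta = delta_max = 1,
    L_max = N/2.  ``L``, ``delta_load`` and ``L_max`` may be left as None and
    are then resolved from the element count via :meth:`resolved`.
    """

    L: int | None = None
    K: int = 4
    delta_load: float | None = None
    gamma: float = 0.5
    window: str = "rectangular"
    f_number: float = 0.0
    M0: int = 1
    delta: float = 1.0
    delta_max: float = 1.0
    L_max: int | None = None
    msr_cap: float = 1e6
    asd_exponent: float = 1.0 / 3.0
    rotary_mode: str = "as_printed"
    #: rows between the 2K+1 temporal-smoothing samples; None resolves to
    #: quarter-wavelength spacing on the imaging grid (the axial correlation
    #: scale), 1 means adjacent rows.
    temporal_stride: int | None = 1

    def resolved(self, n_elements: int) -> "BeamformerConfig":
        """Concrete config for an N-element array (fills derived defaults)."""
        cfg = replace(self)
        if cfg.L is None:
            cfg.L = n_elements // 2
        if cfg.delta_load is None:
            cfg.delta_load = 0.1 / cfg.L
        if cfg.L_max is None:
            cfg.L_max = n_elements // 2
        cfg.validate(n_elements)
        return cfg

    def validate(self, n_elements: int) -> None:
        if not (2 <= self.L <= n_elements):
            raise ValueError("subarray length L must satisfy 2 <= L <= N")
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.delta_load <= 0:
            raise ValueError("diagonal loading Delta must be positive")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must be in (0, 1]")
        if not (0 <= self.delta <= 1 and 0 <= self.delta_max <= 1):
            raise ValueError("delta and delta_max must be in [0, 1]")
        if not (2 <= self.L_max <= n_elements):
            raise ValueError("L_max must satisfy 2 <= L_max <= N")
        if not (0 <= self.M0 <= n_elements // 2):
            raise ValueError("M0 must be in [0, N/2]")


@dataclass
class CovarianceMatrix:
    """Hermitian covariance estimate with its smoothing metadata."""

    R: np.ndarray
    L: int
    n_subarrays: int
    n_temporal: int

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R)
        if self.R.shape != (self.L, self.L):
            raise ValueError("R must be L x L")


def das_pixel(x, window="rectangular", f_number: float = 0.0, geometry=None, pixel=None):
    """Delay-and-sum over the transmit-synthesized aperture vector.

    Applies the transmit apodization w_i (same window / f-number rule as the
    receive synthesis).  With the default full rectangular aperture this is a
    plain sum.
    """
    from .focus import active_aperture, aperture_taper

    x = np.asarray(x)
    n = x.size
    if f_number > 0:
        if geometry is None or pixel is None:
            raise ValueError("f_number > 0 requires geometry and pixel")
        mask = active_aperture(geometry.element_x, pixel[0], pixel[1], f_number)
    else:
        mask = np.ones(n, dtype=bool)
    if isinstance(window, str):
        w = np.zeros(n)
        w[mask] = aperture_taper(int(mask.sum()), window)
    else:
        w = np.where(mask, np.asarray(window, dtype=np.float64), 0.0)
    return np.sum(w * x)


def mv_covariance(x_stack, L: int) -> CovarianceMatrix:
    """Spatially and temporally smoothed covariance estimate.

    ``x_stack`` is the sequence of aperture vectors at the pixel and its
    axial neighbors (2K+1 of them, possibly fewer at image edges); the
    estimate averages outer products of every length-L sliding subarray of
    every vector in the stack.
    """
    x_stack = [np.asarray(x) for x in x_stack]
    n = x_stack[0].size
    if L > n:
        raise ValueError("subarray length L exceeds aperture size N")
    n_sub = n - L + 1
    R = np.zeros((L, L), dtype=complex)
    for x in x_stack:
        for l in range(n_sub):
            sub = x[l : l + L]
            R += np.outer(sub, sub.conj())
    R /= len(x_stack) * n_sub
    return CovarianceMatrix(R=R, L=L, n_subarrays=n_sub, n_temporal=len(x_stack))


def diagonal_load(cov: CovarianceMatrix, delta_load: float) -> CovarianceMatrix:
    """Diagonal loading R_hat = R + Delta*trace(R)*I."""
    if delta_load <= 0:
        raise ValueError("Delta must be positive")
    tr = np.trace(cov.R).real
    if tr == 0.0:
        log.warning("zero-trace covariance (pure-zero pixel); loading skipped")
        return cov
    R = cov.R + delta_load * tr * np.eye(cov.L)
    return CovarianceMatrix(R=R, L=cov.L, n_subarrays=cov.n_subarrays,
                            n_temporal=cov.n_temporal)


def mv_weights(cov: CovarianceMatrix) -> np.ndarray:
    """Capon weights w = R^-1 a / (a^H R^-1 a) with a = ones.

    Solved via a Hermitian (Cholesky) linear solve; a singular matrix falls
    back to the uniform w = a/L (logged).
    """
    L = cov.L
    a = np.ones(L)
    try:
        w0 = cho_solve(cho_factor(cov.R), a.astype(complex))
    except (LinAlgError, np.linalg.LinAlgError):
        try:
            w0 = np.linalg.lstsq(cov.R, a.astype(complex), rcond=None)[0]
        except np.linalg.LinAlgError:
            w0 = None
        if w0 is None or not np.all(np.isfinite(w0)):
            log.warning("singular covariance even after loading; uniform fallback")
            return a / L
    denom = np.sum(w0)
    if denom == 0 or not np.isfinite(denom):
        log.warning("degenerate Capon denominator; uniform fallback")
        return a / L
    return w0 / denom


def _subarray_average(x: np.ndarray, L: int) -> np.ndarray:
    """Mean of the sliding length-L subarrays of the center vector."""
    n = x.size
    n_sub = n - L + 1
    subs = np.lib.stride_tricks.sliding_window_view(x, L)
    assert subs.shape == (n_sub, L)
    return subs.mean(axis=0)


def mv_pixel(x_stack, cfg: BeamformerConfig) -> complex:
    """MV beamformed output: averaged w^H x_l over the center vector's subarrays."""
    x_stack = [np.asarray(x, dtype=complex) for x in x_stack]
    center = x_stack[len(x_stack) // 2]
    cov = diagonal_load(mv_covariance(x_stack, cfg.L), cfg.delta_load)
    w = mv_weights(cov)
    return complex(np.vdot(w, _subarray_average(center, cfg.L)))


def esbmv_weights(cov: CovarianceMatrix, w_mv: np.ndarray, gamma: float) -> np.ndarray:
    """Project the MV weights onto the signal eigen-subspace.

    Eigenvectors with eigenvalue >= gamma * lambda_max span the signal
    subspace (the largest is always included).  When every eigenvalue passes,
    the projection is the identity and w_mv is returned unchanged so that the
    gamma -> 0 limit reproduces MV exactly.
    """
    if not (0 < gamma <= 1):
        raise ValueError("gamma must be in (0, 1]")
    evals, evecs = np.linalg.eigh(cov.R)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    mask = evals >= gamma * evals[0]
    mask[0] = True
    if mask.all():
        return w_mv
    Es = evecs[:, mask]
    return Es @ (Es.conj().T @ w_mv)


def esbmv_pixel(x_stack, cfg: BeamformerConfig) -> complex:
    """Eigenspace-based MV beamformed output for one pixel."""
    x_stack = [np.asarray(x, dtype=complex) for x in x_stack]
    center = x_stack[len(x_stack) // 2]
    cov = diagonal_load(mv_covariance(x_stack, cfg.L), cfg.delta_load)
    w = esbmv_weights(cov, mv_weights(cov), cfg.gamma)
    return complex(np.vdot(w, _subarray_average(center, cfg.L)))
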