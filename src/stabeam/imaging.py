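"""Whole-image beamforming drivers.

These vectorized routines compute, for every pixel of an imaging grid, what
the per-pixel functions in :mod:`stabeam.beamform` and
:mod:`stabeam.weights` compute for a single pixel; the test suite asserts
the two paths agree to 1e-10.  All routines are pure functions of their
inputs, so results do not depend on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .beamform import BeamformerConfig
from .focus import ChannelDataCube, ImagingGrid, analytic_signal

_WINDOW_KINDS = {"rectangular": 0, "hamming": 1}


@dataclass
class PixelCounters:
    """Per-stage robustness counters accumulated over an image."""

    oob_samples: int = 0
    singular_pixels: int = 0
    clamped_lprime: int = 0
    capped_msr: int = 0

    def merged(self, other: "PixelCounters") -> "PixelCounters":
        return PixelCounters(
            self.oob_samples + other.oob_samples,
            self.singular_pixels + other.singular_pixels,
            self.clamped_lprime + other.clamped_lprime,
            self.capped_msr + other.capped_msr,
        )

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def synthesize_aperture(
    cube: ChannelDataCube,
    grid: ImagingGrid,
    window: str = "rectangular",
    f_number: float = 0.0,
):
    """Receive-synthesized analytic aperture data for a whole grid.

    Returns ``(ap, counters)`` with ``ap[iz, ix, tx]`` complex: the fused
    delay-compensation + receive-DAS kernel followed by analytic-signal
    conversion along the axial axis (the axial grid must be uniform, which it
    is for grids built with :meth:`ImagingGrid.regular`).
    """
    if window not in _WINDOW_KINDS:
        raise ValueError(f"unsupported window {window!r} for the fused kernel")
    az = grid.axial_z
    if az.size >= 3:
        dzs = np.diff(az)
        if not np.allclose(dzs, dzs[0], rtol=1e-6):
            raise ValueError("analytic conversion requires a uniform axial grid")
    g = cube.geometry
    real_ap, oob = _kernels.synthesize_aperture_kernel(
        cube.rf,
        g.element_x,
        grid.lateral_x.astype(np.float64),
        az.astype(np.float64),
        g.c,
        g.fs,
        g.t0,
        float(f_number),
        _WINDOW_KINDS[window],
    )
    if az.size >= 2:
        ap = analytic_signal(real_ap, axis=0)
    else:
        ap = real_ap.astype(complex)
    return ap, PixelCounters(oob_samples=int(oob))


def sigma_map(ap: np.ndarray) -> np.ndarray:
    """Per-pixel aperture amplitude standard deviation (population)."""
    mean = ap.mean(axis=-1, keepdims=True)
    return np.sqrt(np.mean(np.abs(ap - mean) ** 2, axis=-1))


def cf_map(ap: np.ndarray) -> np.ndarray:
    """Per-pixel coherence factor in [0, 1]."""
    num = np.abs(ap.sum(axis=-1)) ** 2
    den = ap.shape[-1] * np.sum(np.abs(ap) ** 2, axis=-1)
    out = np.zeros(ap.shape[:-1])
    np.divide(num, den, out=out, where=den > 0)
    return out


def gcf_map(ap: np.ndarray, M0: int) -> np.ndarray:
    """Per-pixel generalized coherence factor in [0, 1]."""
    n = ap.shape[-1]
    power = np.abs(np.fft.fft(ap, axis=-1)) ** 2
    k = np.rint(np.fft.fftfreq(n) * n).astype(int)
    num = power[..., np.abs(k) <= M0].sum(axis=-1)
    den = power.sum(axis=-1)
    out = np.zeros(ap.shape[:-1])
    np.divide(num, den, out=out, where=den > 0)
    return out


def das_image(ap: np.ndarray, window: str = "rectangular") -> np.ndarray:
    """Complex DAS image: transmit apodization applied to the aperture data."""
    n = ap.shape[-1]
    if window == "rectangular":
        return ap.sum(axis=-1)
    if window == "hamming":
        return ap @ np.hamming(n)
    raise ValueError(f"unknown window {window!r}")


def _row_stack(subs: np.ndarray, r: int, K: int, stride: int = 1) -> np.ndarray:
    """Temporal stack of subarray views for axial row r (edge-shrunk).

    The 2K+1 temporal samples sit ``stride`` rows apart; at the image edges
    the window shrinks symmetrically to the available rows.
    """
    n_z = subs.shape[0]
    kk = min(K, r // stride, (n_z - 1 - r) // stride)
    A = subs[r - kk * stride : r + kk * stride + 1 : stride]
    return A.transpose(1, 0, 2, 3).reshape(A.shape[1], -1, A.shape[3])


def mv_esbmv_images(ap: np.ndarray, cfg: BeamformerConfig, want_esbmv: bool = True):
    """MV and (optionally) ESBMV complex images from aperture data.

    Row-by-row: build the temporally and spatially smoothed covariance for
    every pixel of the row as a batched Gram matrix, diagonally load it,
    solve the Capon system, and for ESBMV project the weights onto the
    signal eigen-subspace.  Returns ``(mv, esbmv, counters)``.
    """
    n_z, n_x, n = ap.shape
    L = cfg.L
    n_sub = n - L + 1
    subs = np.lib.stride_tricks.sliding_window_view(ap, L, axis=2)
    mv = np.empty((n_z, n_x), dtype=complex)
    esb = np.empty((n_z, n_x), dtype=complex) if want_esbmv else None
    counters = PixelCounters()
    eye = np.eye(L)
    stride = cfg.temporal_stride or 1
    for r in range(n_z):
        A = _row_stack(subs, r, cfg.K, stride)
        # R_ab = mean_l x_a conj(x_b): outer products x x^H averaged
        R = A.transpose(0, 2, 1) @ A.conj() / A.shape[1]
        R = 0.5 * (R + R.conj().transpose(0, 2, 1))
        tr = np.einsum("pll->p", R).real
        Rh = R + (cfg.delta_load * tr)[:, None, None] * eye
        try:
            w0 = np.linalg.solve(Rh, np.ones((n_x, L, 1), dtype=complex))[..., 0]
            bad = ~np.all(np.isfinite(w0), axis=1)
        except np.linalg.LinAlgError:
            w0 = np.empty((n_x, L), dtype=complex)
            bad = np.zeros(n_x, dtype=bool)
            for p in range(n_x):
                try:
                    w0[p] = np.linalg.solve(Rh[p], np.ones(L, dtype=complex))
                except np.linalg.LinAlgError:
                    bad[p] = True
        if np.any(bad):
            counters.singular_pixels += int(bad.sum())
            w0[bad] = 1.0  # uniform fallback (normalized below to a/L)
        denom = w0.sum(axis=1)
        degenerate = (denom == 0) | ~np.isfinite(denom)
        if np.any(degenerate):
            counters.singular_pixels += int((degenerate & ~bad).sum())
            w0[degenerate] = 1.0
            denom = w0.sum(axis=1)
        w = w0 / denom[:, None]
        xbar = subs[r].mean(axis=1)  # mean subarray of the center vector
        mv[r] = np.einsum("pl,pl->p", w.conj(), xbar)
        if want_esbmv:
            evals, evecs = np.linalg.eigh(Rh)
            lam_max = evals[:, -1]
            mask = evals >= cfg.gamma * lam_max[:, None]
            mask[:, -1] = True
            coef = np.einsum("plk,pl->pk", evecs.conj(), w)
            coef = np.where(mask, coef, 0.0)
            w_e = np.einsum("plk,pk->pl", evecs, coef)
            full = mask.all(axis=1)
            w_e[full] = w[full]  # identity projection, kept bit-exact
            esb[r] = np.einsum("pl,pl->p", w_e.conj(), xbar)
    return mv, esb, counters


def _rotary_average_batched(R: np.ndarray, mode: str) -> np.ndarray:
    Rt = R.transpose(0, 2, 1)
    if mode == "as_printed":
        return (R + Rt[:, ::-1, :] + R[:, ::-1, ::-1] + Rt[:, :, ::-1]) / 4.0
    if mode == "classic_fb":
        return (R + Rt[:, ::-1, ::-1]) / 2.0
    raise ValueError(f"unknown rotary mode {mode!r}")


def _msr_batched(M: np.ndarray, cap: float):
    A = M.real
    mean = A.mean(axis=(1, 2))
    std = np.sqrt(np.mean((A - mean[:, None, None]) ** 2, axis=(1, 2)))
    degen = std <= 1e-12 * np.abs(mean)
    out = np.empty(mean.shape)
    ok = ~degen
    out[ok] = mean[ok] / std[ok]
    out[degen] = np.where(mean[degen] == 0.0, 0.0, cap)
    n_capped = int(np.count_nonzero(degen & (mean != 0.0)))
    return out, n_capped


def cmsf_cmsaw_maps(
    ap: np.ndarray,
    sigma_prime: np.ndarray,
    cfg: BeamformerConfig,
    want_cmsf: bool = True,
    want_cmsaw: bool = True,
):
    """CMSF and CMSAW weight maps plus the intermediate per-pixel maps.

    Pixels are grouped by their dynamic subarray length L' so every group is
    a single batched smoothing + rotary averaging + diagonal reducing + MSR
    evaluation.  Returns ``(maps, counters)`` where ``maps`` holds
    ``w_cmsf``, ``w_cmsaw``, ``w_cf``, ``l_prime`` and ``delta_ac``.
    """
    n_z, n_x, n = ap.shape
    flat = ap.reshape(-1, n)
    sp = np.asarray(sigma_prime).reshape(-1)
    if sp.size != flat.shape[0]:
        raise ValueError("sigma_prime shape must match the image grid")
    raw_lp = np.floor(sp * cfg.L_max).astype(int)
    lp = np.maximum(raw_lp, 2)
    counters = PixelCounters(clamped_lprime=int(np.count_nonzero(raw_lp < 2)))
    wcf = cf_map(ap).reshape(-1)
    dac = np.where(wcf <= 0.0, 0.0, wcf ** np.maximum(sp, 1e-6) * cfg.delta_max)
    out_cmsf = np.zeros(flat.shape[0]) if want_cmsf else None
    out_cmsaw = np.zeros(flat.shape[0]) if want_cmsaw else None
    idx_diag_cache: dict[int, np.ndarray] = {}
    for L_prime in np.unique(lp):
        sel = np.flatnonzero(lp == L_prime)
        xs = flat[sel]
        subs = np.lib.stride_tricks.sliding_window_view(xs, L_prime, axis=1)
        R = subs.transpose(0, 2, 1) @ subs.conj() / subs.shape[1]
        Rh = _rotary_average_batched(R, cfg.rotary_mode)
        idx = idx_diag_cache.setdefault(int(L_prime), np.arange(L_prime))
        if want_cmsf:
            Rr = Rh.copy()
            Rr[:, idx, idx] = (1.0 - cfg.delta) * Rh[:, idx, idx]
            vals, capped = _msr_batched(Rr, cfg.msr_cap)
            out_cmsf[sel] = vals
            counters.capped_msr += capped
        if want_cmsaw:
            Rr = Rh.copy()
            Rr[:, idx, idx] = (1.0 - dac[sel])[:, None] * Rh[:, idx, idx]
            vals, capped = _msr_batched(Rr, cfg.msr_cap)
            out_cmsaw[sel] = vals
            counters.capped_msr += capped
    shape = (n_z, n_x)
    maps = {
        "w_cf": wcf.reshape(shape),
        "l_prime": lp.reshape(shape),
        "delta_ac": dac.reshape(shape),
    }
    if want_cmsf:
        maps["w_cmsf"] = out_cmsf.reshape(shape)
    if want_cmsaw:
        maps["w_cmsaw"] = out_cmsaw.reshape(shape)
    return maps, counters


METHODS = ("das", "mv", "esbmv", "gcf_mv", "cmsf_mv", "cmsaw_mv")


def beamform_methods(
    ap: np.ndarray,
    sigma_prime: np.ndarray | None,
    cfg: BeamformerConfig,
    methods=METHODS,
):
    """Compute the requested complex images from one region's aperture data.

    ``sigma_prime`` may be None when no CMSF/CMSAW method is requested.
    Returns ``(images, weight_maps, counters)``.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    images: dict[str, np.ndarray] = {}
    wmaps: dict[str, np.ndarray] = {}
    counters = PixelCounters()
    need_mv = bool({"mv", "esbmv", "gcf_mv", "cmsf_mv", "cmsaw_mv"} & set(methods))
    if "das" in methods:
        images["das"] = das_image(ap, cfg.window)
    if need_mv:
        mv, esb, c = mv_esbmv_images(ap, cfg, want_esbmv="esbmv" in methods)
        counters = counters.merged(c)
        if "mv" in methods:
            images["mv"] = mv
        if "esbmv" in methods:
            images["esbmv"] = esb
        if "gcf_mv" in methods:
            wmaps["w_gcf"] = gcf_map(ap, cfg.M0)
            images["gcf_mv"] = wmaps["w_gcf"] * mv
        if {"cmsf_mv", "cmsaw_mv"} & set(methods):
            if sigma_prime is None:
                raise ValueError("CMSF/CMSAW need the normalized ASD map")
            maps, c2 = cmsf_cmsaw_maps(
                ap,
                sigma_prime,
                cfg,
                want_cmsf="cmsf_mv" in methods,
                want_cmsaw="cmsaw_mv" in methods,
            )
            counters = counters.merged(c2)
            wmaps.update(maps)
            if "cmsf_mv" in methods:
                images["cmsf_mv"] = maps["w_cmsf"] * mv
            if "cmsaw_mv" in methods:
                images["cmsaw_mv"] = maps["w_cmsaw"] * mv
    return images, wmaps, counters
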