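"""Numba kernels for the two per-sample hot loops.

Everything here is a plain function of its arrays: no global state, no RNG,
so results are independent of call order and identical across reruns.
"""

import numba
import numpy as np


@numba.njit(cache=False, fastmath=True)
def deposit_echoes(rf, dists, amp, c, fs, t0, pulse, pulse_t0, pulse_dt, spreading):
    """Accumulate pulse-convolved echoes into rf[tx, rx, time].

    ``dists[e, s]`` is the element-to-scatterer distance; the pulse waveform
    is a lookup table sampled at ``pulse_dt`` starting at ``pulse_t0``
    relative to the arrival time, linearly interpolated.  With ``spreading``
    the echo amplitude carries the 1/(d_tx*d_rx) geometric factor.  The
    (tx, rx) and (rx, tx) traces are identical by reciprocity and filled
    together.
    """
    n_el, n_sc = dists.shape
    n_t = rf.shape[2]
    n_p = pulse.size
    span = pulse_t0 + (n_p - 1) * pulse_dt
    for i in range(n_el):
        for j in range(i, n_el):
            for s in range(n_sc):
                a = amp[s]
                if a == 0.0:
                    continue
                if spreading:
                    a = a / (dists[i, s] * dists[j, s])
                tau = (dists[i, s] + dists[j, s]) / c
                lo = tau + pulse_t0
                hi = tau + span
                n0 = int(np.ceil((lo - t0) * fs))
                n1 = int(np.floor((hi - t0) * fs))
                if n0 < 0:
                    n0 = 0
                if n1 > n_t - 1:
                    n1 = n_t - 1
                for n in range(n0, n1 + 1):
                    tt = t0 + n / fs - tau
                    u = (tt - pulse_t0) / pulse_dt
                    k = int(u)
                    if k < 0 or k >= n_p - 1:
                        continue
                    frac = u - k
                    v = a * (pulse[k] * (1.0 - frac) + pulse[k + 1] * frac)
                    rf[i, j, n] += v
                    if j != i:
                        rf[j, i, n] += v


@numba.njit(cache=False)
def synthesize_aperture_kernel(rf, el_x, lat, ax, c, fs, t0, f_number, window_kind):
    """Fused delay compensation + receive DAS for a whole grid.

    Returns ``(out, n_oob)`` with ``out[iz, ix, tx]`` the real
    receive-synthesized sample for each pixel and transmission, and the count
    of out-of-window (zero-filled) channel reads.  ``window_kind``: 0 =
    rectangular, 1 = hamming, applied over the active receive elements.
    """
    n_el = el_x.size
    n_t = rf.shape[2]
    n_x = lat.size
    n_z = ax.size
    out = np.zeros((n_z, n_x, n_el))
    d = np.empty(n_el)
    w = np.empty(n_el)
    oob = 0
    for ix in range(n_x):
        px = lat[ix]
        for iz in range(n_z):
            pz = ax[iz]
            for e in range(n_el):
                dx = el_x[e] - px
                d[e] = np.sqrt(dx * dx + pz * pz)
            # active receive aperture (contiguous for a linear array)
            if f_number > 0.0:
                half = pz / (2.0 * f_number)
                a0 = -1
                a1 = -1
                for e in range(n_el):
                    if abs(el_x[e] - px) <= half:
                        if a0 < 0:
                            a0 = e
                        a1 = e
                if a0 < 0:  # keep the nearest element so the sum is nonempty
                    best = 0
                    for e in range(1, n_el):
                        if abs(el_x[e] - px) < abs(el_x[best] - px):
                            best = e
                    a0 = best
                    a1 = best
            else:
                a0 = 0
                a1 = n_el - 1
            m = a1 - a0 + 1
            for e in range(n_el):
                w[e] = 0.0
            if window_kind == 1 and m > 1:
                for e in range(a0, a1 + 1):
                    w[e] = 0.54 - 0.46 * np.cos(2.0 * np.pi * (e - a0) / (m - 1))
            else:
                for e in range(a0, a1 + 1):
                    w[e] = 1.0
            for i in range(n_el):
                acc = 0.0
                for j in range(a0, a1 + 1):
                    tau = (d[i] + d[j]) / c
                    u = (tau - t0) * fs
                    k = int(np.floor(u))
                    if k < 0 or k >= n_t - 1:
                        oob += 1
                        continue
                    frac = u - k
                    acc += w[j] * (
                        rf[i, j, k] * (1.0 - frac) + rf[i, j, k + 1] * frac
                    )
                out[iz, ix, i] = acc
    return out, oob
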