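"""Array geometry, two-way focusing delays and receive-aperture synthesis.

Synthetic transmit aperture (STA) imaging fires one element at a time and
records on all elements, so a full N x N channel-data matrix exists for every
image point after delay compensation.  This module turns a raw
:class:`ChannelDataCube` into per-pixel aperture vectors: the receive aperture
is collapsed by delay-and-sum, one entry per transmission, which is the input
every adaptive beamformer downstream operates on.

Conventions: lateral ``x`` is centered on the array (x = 0 at the array
center), axial ``z`` is positive into the medium, elements sit at z = 0, and
all positions are in meters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert


class GeometryError(ValueError):
    """Raised for invalid array geometry or imaging-point placement."""


@dataclass(frozen=True)
class ArrayGeometry:
    """Uniform linear array plus acquisition timing.

    Parameters
    ----------
    n_elements : int
        Number of elements N (>= 2).
    pitch : float
        Element spacing in meters.
    f0 : float
        Pulse center frequency in Hz.
    fs : float
        Sampling frequency in Hz; must exceed 2*f0.
    c : float
        Speed of sound in m/s.
    t0 : float
        Time of the first recorded sample in seconds.
    """

    n_elements: int
    pitch: float
    f0: float
    fs: float
    c: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise GeometryError("need at least 2 elements")
        if self.pitch <= 0 or self.f0 <= 0 or self.c <= 0:
            raise GeometryError("pitch, f0 and c must be positive")
        if self.fs <= 2 * self.f0:
            raise GeometryError("fs must exceed 2*f0 (Nyquist for RF data)")

    @property
    def element_x(self) -> np.ndarray:
        """Lateral element positions in meters, centered on x = 0."""
        n = self.n_elements
        return (np.arange(n) - (n - 1) / 2.0) * self.pitch

    @property
    def aperture(self) -> float:
        """Physical aperture width D = N * pitch in meters."""
        return self.n_elements * self.pitch

    @property
    def wavelength(self) -> float:
        return self.c / self.f0

    def replace(self, **kw) -> "ArrayGeometry":
        return dataclasses.replace(self, **kw)


@dataclass
class ChannelDataCube:
    """Raw STA RF channel data: rf[transmit, receive, time sample]."""

    rf: np.ndarray
    geometry: ArrayGeometry

    def __post_init__(self) -> None:
        self.rf = np.asarray(self.rf, dtype=np.float64)
        n = self.geometry.n_elements
        if self.rf.ndim != 3 or self.rf.shape[0] != n or self.rf.shape[1] != n:
            raise ValueError(
                f"rf must have shape (N, N, T) with N={n}, got {self.rf.shape}"
            )
        if not np.all(np.isfinite(self.rf)):
            raise ValueError("rf contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.rf.shape[2]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("rf", data=self.rf.astype(np.float32))
            g = self.geometry
            for k in ("n_elements", "pitch", "f0", "fs", "c", "t0"):
                d.attrs[k] = getattr(g, k)

    @classmethod
    def from_hdf5(cls, path) -> "ChannelDataCube":
        import h5py

        with h5py.File(path, "r") as f:
            d = f["rf"]
            geom = ArrayGeometry(
                n_elements=int(d.attrs["n_elements"]),
                pitch=float(d.attrs["pitch"]),
                f0=float(d.attrs["f0"]),
                fs=float(d.attrs["fs"]),
                c=float(d.attrs["c"]),
                t0=float(d.attrs["t0"]),
            )
            return cls(rf=d[...].astype(np.float64), geometry=geom)


@dataclass(frozen=True)
class ImagingGrid:
    """Rectilinear imaging grid: lateral and axial pixel coordinates (meters)."""

    lateral_x: np.ndarray
    axial_z: np.ndarray

    def __post_init__(self) -> None:
        lx = np.asarray(self.lateral_x, dtype=np.float64)
        az = np.asarray(self.axial_z, dtype=np.float64)
        object.__setattr__(self, "lateral_x", lx)
        object.__setattr__(self, "axial_z", az)
        if lx.size == 0 or az.size == 0:
            raise ValueError("empty imaging grid")
        if lx.size > 1 and not np.all(np.diff(lx) > 0):
            raise ValueError("lateral_x must be strictly increasing")
        if az.size > 1 and not np.all(np.diff(az) > 0):
            raise ValueError("axial_z must be strictly increasing")
        if np.any(az <= 0):
            raise GeometryError("axial_z must be positive (medium side)")

    @property
    def shape(self) -> tuple:
        return (self.axial_z.size, self.lateral_x.size)

    @classmethod
    def regular(cls, x0, x1, dx, z0, z1, dz) -> "ImagingGrid":
        """Build a grid from bounds and step sizes (all meters)."""
        nx = int(round((x1 - x0) / dx)) + 1
        nz = int(round((z1 - z0) / dz)) + 1
        return cls(x0 + dx * np.arange(nx), z0 + dz * np.arange(nz))


@dataclass
class ApertureVector:
    """Receive-synthesized complex aperture data x(p) for one pixel.

    One entry per transmission; the receive aperture has already been
    collapsed by delay-and-sum.
    """

    x: np.ndarray
    pixel: tuple = (0, 0)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        if self.x.ndim != 1:
            raise ValueError("aperture vector must be one-dimensional")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("aperture vector contains non-finite entries")


def two_way_delay(tx_x, rx_x, pixel, c):
    """Round-trip propagation delay transmit element -> pixel -> receive element.

    Parameters are lateral element positions (meters), the pixel as an
    ``(x, z)`` pair with z > 0, and the speed of sound.  Accepts scalars or
    broadcastable arrays; returns seconds.
    """
    px, pz = pixel
    if c <= 0:
        raise GeometryError("speed of sound must be positive")
    if np.any(np.asarray(pz) <= 0):
        raise GeometryError("pixel depth z must be positive")
    d_tx = np.hypot(np.asarray(tx_x) - px, pz)
    d_rx = np.hypot(np.asarray(rx_x) - px, pz)
    return (d_tx + d_rx) / c


def _sample_linear(trace: np.ndarray, t: float, fs: float, t0: float):
    """Linearly interpolated sample of ``trace`` at absolute time ``t``.

    Returns (value, in_window flag); out-of-window delays read as zero.
    """
    u = (t - t0) * fs
    k = int(np.floor(u))
    if k < 0 or k >= trace.size - 1:
        return 0.0, False
    frac = u - k
    return trace[k] * (1.0 - frac) + trace[k + 1] * frac, True


def delay_compensate_pixel(cube: ChannelDataCube, pixel):
    """Full N x N delay-compensated data matrix X(p) for a single pixel.

    Returns ``(X, n_out_of_window)``; samples whose two-way delay falls
    outside the recorded window are zero-filled and counted.
    """
    g = cube.geometry
    ex = g.element_x
    n = g.n_elements
    X = np.zeros((n, n))
    oob = 0
    tau = two_way_delay(ex[:, None], ex[None, :], pixel, g.c)
    for i in range(n):
        for j in range(n):
            v, ok = _sample_linear(cube.rf[i, j], tau[i, j], g.fs, g.t0)
            X[i, j] = v
            oob += not ok
    return X, oob


def delay_compensate(cube: ChannelDataCube, grid: ImagingGrid):
    """Delay-compensated matrices X(p) for every pixel of ``grid``.

    Returns ``(X, n_out_of_window)`` where X has shape (Pz, Px, N, N) — only
    suitable for small grids; the imaging pipeline uses the fused kernel in
    :mod:`stabeam.imaging` instead.
    """
    nz, nx = grid.shape
    n = cube.geometry.n_elements
    out = np.zeros((nz, nx, n, n))
    oob = 0
    for iz, z in enumerate(grid.axial_z):
        for ix, x in enumerate(grid.lateral_x):
            out[iz, ix], bad = delay_compensate_pixel(cube, (x, z))
            oob += bad
    return out, oob


def active_aperture(element_x, pixel_x, pixel_z, f_number):
    """Boolean mask of receive elements active for a pixel.

    ``f_number == 0`` means the full aperture; otherwise elements with
    ``|element_x - pixel_x| <= z / (2 * f_number)`` are active.
    """
    element_x = np.asarray(element_x)
    if f_number == 0:
        return np.ones(element_x.size, dtype=bool)
    half = pixel_z / (2.0 * f_number)
    return np.abs(element_x - pixel_x) <= half


def aperture_taper(n_active: int, kind: str) -> np.ndarray:
    """Apodization taper over ``n_active`` contiguous active elements."""
    if kind == "rectangular":
        return np.ones(n_active)
    if kind == "hamming":
        return np.hamming(n_active)
    raise ValueError(f"unknown window {kind!r}")


def synthesize_receive(
    X_p: np.ndarray,
    geometry: ArrayGeometry,
    pixel,
    rx_window="rectangular",
    f_number: float = 0.0,
) -> np.ndarray:
    """Collapse the receive dimension of X(p) by weighted summation.

    ``rx_window`` is either a taper name or an explicit length-N weight
    vector; with ``f_number > 0`` the receive aperture shrinks with depth
    (named tapers are recomputed over the active elements, explicit weight
    vectors are masked).  Returns the length-N aperture vector x(p), one entry
    per transmission.
    """
    X_p = np.asarray(X_p)
    n = geometry.n_elements
    if X_p.shape != (n, n):
        raise ValueError(f"X_p must be (N, N) = ({n}, {n})")
    px, pz = pixel
    mask = active_aperture(geometry.element_x, px, pz, f_number)
    w = np.zeros(n)
    if isinstance(rx_window, str):
        w[mask] = aperture_taper(int(mask.sum()), rx_window)
    else:
        rx_window = np.asarray(rx_window, dtype=np.float64)
        if rx_window.shape != (n,):
            raise ValueError("explicit rx_window must have length N")
        if np.any(rx_window < 0):
            raise ValueError("rx_window weights must be nonnegative")
        w[mask] = rx_window[mask]
    if not np.any(w > 0):
        raise ValueError("all-zero receive window")
    return X_p @ w


def analytic_signal(rf: np.ndarray, axis: int = -1) -> np.ndarray:
    """Complex analytic signal via one-sided spectrum doubling.

    The real part equals the input; the imaginary part is its quadrature.
    """
    rf = np.asarray(rf, dtype=np.float64)
    if rf.shape[axis] < 2:
        raise ValueError("need at least 2 samples along the transform axis")
    if not np.all(np.isfinite(rf)):
        raise ValueError("non-finite input")
    return hilbert(rf, axis=axis)
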