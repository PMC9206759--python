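"""Envelope display and image-quality metrics: FWHM, CR, gCNR, sSNR.

All metrics operate on the pre-compression envelope (the modulus of the
complex beamformed image); every one of them is invariant to a global
positive scaling of the envelope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .focus import ImagingGrid


@dataclass
class BeamformedImage:
    """Complex beamformed pixel values on an imaging grid."""

    values: np.ndarray
    grid: ImagingGrid
    method: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError("image shape must match the grid")

    @property
    def envelope(self) -> np.ndarray:
        return np.abs(self.values)


def log_compress(envelope: np.ndarray, dynamic_range_db: float = 60.0) -> np.ndarray:
    """Display image: 20*log10(env / max env), clipped to [-DR, 0] dB."""
    envelope = np.asarray(envelope)
    peak = envelope.max()
    if peak <= 0:
        raise ValueError("all-zero envelope cannot be log-compressed")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(envelope / peak)
    return np.clip(db, -dynamic_range_db, 0.0)


class UnresolvedPointError(RuntimeError):
    """Raised when no -6 dB crossing exists inside the point ROI."""


def _db_crossing(xs, dbs, i0, i1, level):
    """Linear-in-dB interpolated lateral position where dbs crosses level."""
    x0, x1 = xs[i0], xs[i1]
    d0, d1 = dbs[i0], dbs[i1]
    if d1 == d0:
        return x1
    return x0 + (level - d0) / (d1 - d0) * (x1 - x0)


def lateral_fwhm(image: BeamformedImage, roi: dict) -> float:
    """Lateral -6 dB full width of a point target, in millimeters.

    ``roi`` holds ``center`` (x, z) and ``half_lat`` / ``half_ax`` search
    half-extents in meters.  The envelope peak is located inside the ROI,
    the lateral profile through the peak's axial row is extracted, and the
    two -6 dB crossings (relative to the peak, linear interpolation in dB
    between grid samples) delimit the width.
    """
    env = image.envelope
    lx, az = image.grid.lateral_x, image.grid.axial_z
    cx, cz = roi["center"]
    mx = np.abs(lx - cx) <= roi["half_lat"]
    mz = np.abs(az - cz) <= roi["half_ax"]
    if not (mx.any() and mz.any()):
        raise ValueError("point ROI does not intersect the grid")
    sub = env[np.ix_(mz, mx)]
    iz, ix = np.unravel_index(np.argmax(sub), sub.shape)
    row = np.flatnonzero(mz)[iz]
    col = np.flatnonzero(mx)[ix]
    profile = env[row, :]
    peak = profile[col]
    if peak <= 0:
        raise UnresolvedPointError("zero peak inside point ROI")
    with np.errstate(divide="ignore"):
        dbs = 20.0 * np.log10(profile / peak)
    level = -6.0
    search = np.flatnonzero(mx)
    left = None
    for i in range(col, search[0], -1):
        if dbs[i - 1] <= level <= dbs[i]:
            left = _db_crossing(lx, dbs, i - 1, i, level)
            break
    right = None
    for i in range(col, search[-1]):
        if dbs[i + 1] <= level <= dbs[i]:
            right = _db_crossing(lx, dbs, i, i + 1, level)
            break
    if left is None or right is None:
        raise UnresolvedPointError("no -6 dB crossing inside the point ROI")
    return (right - left) * 1e3


def contrast_ratio(env_cyst, env_bck) -> float:
    """CR = 20*log10(mu_cyst / mu_bck) in dB, on pre-compression envelopes.

    Negative for anechoic/hypoechoic targets; -inf (reported downstream as
    "< -100 dB") when the cyst mean is exactly zero.
    """
    env_cyst = np.asarray(env_cyst).ravel()
    env_bck = np.asarray(env_bck).ravel()
    if env_cyst.size == 0 or env_bck.size == 0:
        raise ValueError("empty ROI")
    mu_b = env_bck.mean()
    if mu_b <= 0:
        raise ValueError("background mean must be positive")
    mu_c = env_cyst.mean()
    if mu_c == 0:
        return -np.inf
    return float(20.0 * np.log10(mu_c / mu_b))


def gcnr(env_cyst, env_bck, n_bins: int = 256) -> float:
    """Generalized CNR: 1 minus the overlap of the two envelope PDFs.

    Histogram PDF estimates on a common equal-width binning spanning the
    pooled range; robust against dynamic-range transformations.
    """
    a = np.asarray(env_cyst, dtype=np.float64).ravel()
    b = np.asarray(env_bck, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty ROI")
    import warnings

    if min(a.size, b.size) < 100:
        warnings.warn("fewer than 100 pixels in an ROI; gCNR estimate is noisy")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    overlap = np.minimum(pa / a.size, pb / b.size).sum()
    return float(1.0 - overlap)


def ssnr(env_bck) -> float:
    """Speckle SNR: mean / population std of the background envelope.

    Approaches sqrt(pi / (4 - pi)) ~ 1.91 for fully developed (Rayleigh)
    speckle.
    """
    env = np.asarray(env_bck, dtype=np.float64).ravel()
    if env.size < 2:
        raise ValueError("need at least 2 background pixels")
    std = env.std()
    if std == 0:
        raise ValueError("zero-variance background ROI")
    return float(env.mean() / std)


def circle_mask(grid: ImagingGrid, center, radius) -> np.ndarray:
    """Boolean pixel mask of a circular ROI; ``radius`` None selects all."""
    if radius is None:
        return np.ones(grid.shape, dtype=bool)
    cx, cz = center
    xx = grid.lateral_x[None, :] - cx
    zz = grid.axial_z[:, None] - cz
    return xx**2 + zz**2 <= radius**2


def box_mask(grid: ImagingGrid, center, half_lat, half_ax) -> np.ndarray:
    """Boolean pixel mask of a rectangular ROI centered at ``center``."""
    cx, cz = center
    mx = np.abs(grid.lateral_x - cx) <= half_lat
    mz = np.abs(grid.axial_z - cz) <= half_ax
    return mz[:, None] & mx[None, :]


def roi_mask(grid: ImagingGrid, roi: dict) -> np.ndarray:
    """Mask from an ROI dict: circular if it has ``radius``, else box."""
    if "radius" in roi:
        return circle_mask(grid, roi.get("center"), roi.get("radius"))
    if "half_lat" in roi:
        return box_mask(grid, roi["center"], roi["half_lat"], roi["half_ax"])
    return np.ones(grid.shape, dtype=bool)


@dataclass
class MetricsReport:
    """Per-method metric values with the ROI definitions that produced them."""

    entries: list = field(default_factory=list)
    rois: dict = field(default_factory=dict)

    def add(self, method: str, **values) -> None:
        self.entries.append({"method": method, **values})

    def as_table(self) -> str:
        if not self.entries:
            return ""
        keys = [k for k in self.entries[0] if k != "method"]
        lines = ["method," + ",".join(keys)]
        for e in self.entries:
            cells = []
            for k in keys:
                v = e.get(k)
                if v is None:
                    cells.append("")
                elif v == -np.inf:
                    cells.append("< -100 dB")
                else:
                    cells.append(f"{v:.4g}")
            lines.append(e["method"] + "," + ",".join(cells))
        return "\n".join(lines) + "\n"

    def to_csv(self, path) -> None:
        with open(path, "w") as f:
            f.write(self.as_table())

    def to_json(self, path) -> None:
        def clean(v):
            if isinstance(v, float) and not np.isfinite(v):
                return "< -100 dB" if v < 0 else "inf"
            return v

        payload = {
            "rois": self.rois,
            "entries": [{k: clean(v) for k, v in e.items()} for e in self.entries],
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=2, default=str)
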