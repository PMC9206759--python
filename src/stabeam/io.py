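"""Optional readers for externally acquired STA channel data.

The public k-space / BRL archives distribute MATLAB v5 files with
archive-specific variable names, so the adapter takes a user-supplied
mapping from the fields we need to the variable names in the file.  Nothing
in the package requires these files; they are strictly optional inputs.
"""

from __future__ import annotations

import numpy as np

from .focus import ArrayGeometry, ChannelDataCube

#: default variable mapping; override any entry per archive
DEFAULT_MAT_MAPPING = {
    "rf": "rf",
    "n_elements": "no_elements",
    "pitch": "pitch",
    "f0": "f0",
    "fs": "fs",
    "c": "c",
    "t0": "t0",
}


def _scalar(d, name, default=None):
    if name in d:
        return float(np.asarray(d[name]).ravel()[0])
    if default is not None:
        return default
    raise KeyError(f"variable {name!r} not found in MAT file")


def load_mat_cube(path, mapping=None, geometry: ArrayGeometry | None = None):
    """Load an STA channel-data cube from a MATLAB v5 file.

    ``mapping`` maps the required fields (see ``DEFAULT_MAT_MAPPING``) to
    variable names in the file; unknown layouts can alternatively pass a
    complete ``geometry`` and only map ``rf``.  The rf variable must be
    (tx, rx, time) or (time, rx, tx) — the time axis is taken to be the
    longest one and moved last.
    """
    from scipy.io import loadmat

    m = dict(DEFAULT_MAT_MAPPING)
    if mapping:
        m.update(mapping)
    data = loadmat(path)
    rf = np.asarray(data[m["rf"]], dtype=np.float64)
    if rf.ndim != 3:
        raise ValueError("rf variable must be three-dimensional")
    t_axis = int(np.argmax(rf.shape))
    rf = np.moveaxis(rf, t_axis, 2)
    if geometry is None:
        geometry = ArrayGeometry(
            n_elements=int(_scalar(data, m["n_elements"], rf.shape[0])),
            pitch=_scalar(data, m["pitch"]),
            f0=_scalar(data, m["f0"]),
            fs=_scalar(data, m["fs"]),
            c=_scalar(data, m["c"]),
            t0=_scalar(data, m["t0"], 0.0),
        )
    return ChannelDataCube(rf=rf, geometry=geometry)


def bandpass_filter(cube: ChannelDataCube, low: float, high: float, order: int = 4):
    """Zero-phase Butterworth bandpass of every channel trace.

    Plain time-domain bandpass (no space-time dip filtering); used to clean
    experimental channel data before beamforming.
    """
    from scipy.signal import butter, sosfiltfilt

    fs = cube.geometry.fs
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    rf = sosfiltfilt(sos, cube.rf, axis=2)
    return ChannelDataCube(rf=np.ascontiguousarray(rf), geometry=cube.geometry)
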