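"""Synthetic STA channel data: scatterer phantoms, pulse model, noise.

The simulator emulates a Field-II-style point-scatterer experiment: a
tissue-mimicking slab populated with Gaussian-amplitude scatterers at a fixed
density per resolution cell, optional anechoic / hypo- / hyperechoic
spherical cysts, bright point targets, and additive Gaussian channel noise at
a prescribed SNR.  Echoes are Gaussian-enveloped cosines at the array center
frequency; element directivity, attenuation and nonlinear propagation are not
modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .focus import ArrayGeometry, ChannelDataCube, ImagingGrid


@dataclass(frozen=True)
class PulseModel:
    """Gaussian-enveloped cosine transmit/receive pulse.

    ``fractional_bandwidth`` is the two-sided -6 dB bandwidth divided by f0.
    For a Gaussian envelope exp(-t^2 / (2 sigma_t^2)) the -6 dB spectral
    half-width df satisfies 2 pi^2 sigma_t^2 df^2 = ln 2.
    """

    f0: float
    fractional_bandwidth: float = 0.6
    envelope: str = "gaussian"

    def __post_init__(self) -> None:
        if not (0.0 < self.fractional_bandwidth < 2.0):
            raise ValueError("fractional_bandwidth must be in (0, 2)")
        if self.envelope != "gaussian":
            raise ValueError("only the gaussian envelope is supported")

    @property
    def sigma_t(self) -> float:
        """Envelope standard deviation in seconds."""
        df = 0.5 * self.fractional_bandwidth * self.f0
        return np.sqrt(np.log(2.0) / 2.0) / (np.pi * df)

    @property
    def half_duration(self) -> float:
        """Half support of the truncated pulse (4 sigma_t)."""
        return 4.0 * self.sigma_t

    @property
    def axial_length(self) -> float:
        """Pulse length in time, used for the axial resolution-cell size."""
        return 2.0 * self.half_duration

    def waveform(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        return np.exp(-(t**2) / (2.0 * self.sigma_t**2)) * np.cos(
            2.0 * np.pi * self.f0 * t
        )

    def table(self, oversample: int = 16, fs: float = 40e6):
        """Lookup table (waveform, t_start, dt) for the deposit kernel."""
        dt = 1.0 / (oversample * fs)
        t0 = -self.half_duration
        n = int(np.ceil(2 * self.half_duration / dt)) + 1
        t = t0 + dt * np.arange(n)
        return self.waveform(t), t0, dt


@dataclass(frozen=True)
class PhantomSpec:
    """Scatterer phantom description.

    ``extent`` gives the (x, y, z) bounds in meters as three (lo, hi) pairs;
    y is the elevation slab.  ``cyst_regions`` are spheres
    (center xyz, radius, amplitude_scale) with scale 0 = anechoic,
    < 1 hypoechoic, > 1 hyperechoic.  ``point_targets`` are
    (position xyz, amplitude) pairs appended after the diffuse scatterers.
    """

    extent: tuple
    scatterer_density: float = 40.0
    point_targets: tuple = ()
    cyst_regions: tuple = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.scatterer_density <= 0:
            raise ValueError("scatterer density must be positive")
        for _, radius, scale in self.cyst_regions:
            if radius <= 0:
                raise ValueError("cyst radius must be positive")
            if scale < 0:
                raise ValueError("cyst amplitude scale must be >= 0")

    @property
    def volume(self) -> float:
        v = 1.0
        for lo, hi in self.extent:
            v *= hi - lo
        return v

    @property
    def z_mid(self) -> float:
        lo, hi = self.extent[2]
        return 0.5 * (lo + hi)


@dataclass
class ScattererField:
    """Point scatterers: positions (S, 3) in meters, real amplitudes (S,)."""

    positions: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if self.positions.shape != (self.amplitudes.size, 3):
            raise ValueError("positions must be (S, 3) matching amplitudes")

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("pos", data=self.positions)
            f.create_dataset("amp", data=self.amplitudes)

    @classmethod
    def from_hdf5(cls, path) -> "ScattererField":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(f["pos"][...], f["amp"][...])


def resolution_cell_volume(
    geom: ArrayGeometry, pulse: PulseModel, spec: PhantomSpec
) -> float:
    """Resolution-cell volume used to convert density to scatterer count.

    Lateral width lambda*z_mid/D (one-way FWHM beamwidth at the phantom
    mid-depth), elevation = slab thickness, axial c/(2B) with B the -6 dB
    pulse bandwidth.
    """
    lat = geom.wavelength * spec.z_mid / geom.aperture
    y_lo, y_hi = spec.extent[1]
    elev = y_hi - y_lo
    bandwidth = pulse.fractional_bandwidth * pulse.f0
    ax = geom.c / (2.0 * bandwidth)
    return lat * elev * ax


def make_scatterers(
    spec: PhantomSpec, geom: ArrayGeometry, pulse: PulseModel
) -> ScattererField:
    """Draw the diffuse scatterers and append the point targets.

    Scatterer count = density * phantom volume / resolution-cell volume;
    positions i.i.d. uniform over the extent, amplitudes i.i.d. N(0, 1)
    scaled by the enclosing cyst region (if any).  Deterministic given
    ``spec.rng_seed``.
    """
    if spec.volume <= 0:
        raise ValueError("phantom extent has zero volume")
    cell = resolution_cell_volume(geom, pulse, spec)
    count = int(round(spec.scatterer_density * spec.volume / cell))
    rng = np.random.default_rng(spec.rng_seed)
    lows = np.array([lo for lo, _ in spec.extent])
    highs = np.array([hi for _, hi in spec.extent])
    pos = rng.uniform(lows, highs, size=(count, 3))
    amp = rng.standard_normal(count)
    for center, radius, scale in spec.cyst_regions:
        d2 = np.sum((pos - np.asarray(center)) ** 2, axis=1)
        amp[d2 <= radius**2] *= scale
    for p, a in spec.point_targets:
        pos = np.vstack([pos, np.asarray(p, dtype=np.float64)])
        amp = np.append(amp, a)
    return ScattererField(pos, amp)


def required_window(
    field: ScattererField, geom: ArrayGeometry, pulse: PulseModel
) -> tuple:
    """(t_start, n_samples) covering every echo including pulse tails."""
    ex = geom.element_x
    dx = field.positions[:, 0][None, :] - ex[:, None]
    dy = field.positions[:, 1][None, :]
    dz = field.positions[:, 2][None, :]
    dists = np.sqrt(dx**2 + dy**2 + dz**2)
    dmin = dists.min(axis=0)
    dmax = dists.max(axis=0)
    t_lo = 2.0 * dmin.min() / geom.c - pulse.half_duration
    t_hi = 2.0 * dmax.max() / geom.c + pulse.half_duration
    t_start = max(t_lo, 0.0)
    n = int(np.ceil((t_hi - t_start) * geom.fs)) + 2
    return t_start, n


def simulate_sta(
    field: ScattererField,
    geom: ArrayGeometry,
    pulse: PulseModel,
    t0: float | None = None,
    n_samples: int | None = None,
    spreading: bool = True,
) -> ChannelDataCube:
    """Simulate the full STA channel-data cube for a scatterer field.

    Each rf trace is the superposition of Gaussian-enveloped cosine echoes at
    the per-scatterer two-way delays; ``spreading`` applies the
    1/(d_tx * d_rx) geometric amplitude factor.  Raises if the requested time
    window cannot contain the echoes.
    """
    if field.amplitudes.size == 0:
        raise ValueError("empty scatterer field")
    auto_t0, auto_n = required_window(field, geom, pulse)
    if t0 is None:
        t0 = auto_t0
    if n_samples is None:
        n_samples = int(np.ceil((auto_t0 + auto_n / geom.fs - t0) * geom.fs)) + 1
    t_end_needed = auto_t0 + auto_n / geom.fs
    if np.any(field.amplitudes != 0.0) and (
        t0 + n_samples / geom.fs < t_end_needed - 1.0 / geom.fs
    ):
        need = int(np.ceil((t_end_needed - t0) * geom.fs)) + 1
        raise ValueError(
            f"time window too short to contain echoes: need n_samples >= {need}"
        )
    ex = geom.element_x
    dx = field.positions[:, 0][None, :] - ex[:, None]
    dy = field.positions[:, 1][None, :]
    dz = field.positions[:, 2][None, :]
    dists = np.sqrt(dx**2 + dy**2 + dz**2)
    wav, p_t0, p_dt = pulse.table(fs=geom.fs)
    rf = np.zeros((geom.n_elements, geom.n_elements, n_samples))
    _kernels.deposit_echoes(
        rf,
        dists,
        field.amplitudes,
        geom.c,
        geom.fs,
        t0,
        wav,
        p_t0,
        p_dt,
        spreading,
    )
    return ChannelDataCube(rf=rf, geometry=geom.replace(t0=t0))


def add_channel_noise(
    cube: ChannelDataCube, snr_db, rng_seed: int
) -> ChannelDataCube:
    """Add i.i.d. Gaussian channel noise at the requested SNR in dB.

    Noise variance = mean power over the nonzero signal support divided by
    10^(snr/10).  ``snr_db`` of None or +inf returns the cube unchanged.
    Deterministic given ``rng_seed``.
    """
    if snr_db is None or snr_db == np.inf:
        return cube
    mask = cube.rf != 0.0
    if not np.any(mask):
        raise ValueError("all-zero cube: SNR undefined")
    p_sig = np.mean(cube.rf[mask] ** 2)
    sigma = np.sqrt(p_sig / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(rng_seed)
    noisy = cube.rf + sigma * rng.standard_normal(cube.rf.shape)
    return ChannelDataCube(rf=noisy, geometry=cube.geometry)


# --------------------------------------------------------------------------
# Reference study setups


@dataclass
class StudySetup:
    """Everything needed to run one simulation study end to end."""

    geometry: ArrayGeometry
    phantom: PhantomSpec
    pulse: PulseModel
    snr_db: float
    regions: dict = field(default_factory=dict)
    rois: dict = field(default_factory=dict)
    beamformer: object = None  # BeamformerConfig; None = library defaults

    def with_seed(self, seed: int) -> "StudySetup":
        out = replace(self)
        out.phantom = replace(self.phantom, rng_seed=int(seed))
        return out


_MM = 1e-3
_POINT_AMPLITUDE = 200.0  # ~30 dB above the speckle envelope mean at 40/cell


def _axial_step(geom: ArrayGeometry) -> float:
    return geom.c / (2.0 * geom.fs)


def reference_setups() -> dict:
    """The two canonical study configurations.

    ``simulation``: 64-element, 0.24 mm pitch, 3.33 MHz array sampled at
    40 MHz, c = 1540 m/s; 22 x 0.5 x 15 mm speckle slab at 40 scatterers per
    resolution cell with three point targets (x = 0, z = 19/24/29 mm) and a
    5 mm anechoic cyst at (-6, 24.5) mm; 10 dB channel SNR.

    ``toy``: 32 elements, 10 scatterers per cell, one point and a 4 mm cyst,
    sized so the whole pipeline runs in well under a minute for tests.
    """
    # full-scale simulation study
    geom = ArrayGeometry(n_elements=64, pitch=0.24e-3, f0=3.33e6, fs=40e6, c=1540.0)
    pulse = PulseModel(f0=geom.f0)
    spec = PhantomSpec(
        extent=((-11 * _MM, 11 * _MM), (-0.25 * _MM, 0.25 * _MM), (17.5 * _MM, 32.5 * _MM)),
        scatterer_density=40.0,
        point_targets=(
            ((0.0, 0.0, 19 * _MM), _POINT_AMPLITUDE),
            ((0.0, 0.0, 24 * _MM), _POINT_AMPLITUDE),
            ((0.0, 0.0, 29 * _MM), _POINT_AMPLITUDE),
        ),
        cyst_regions=(((-6 * _MM, 0.0, 24.5 * _MM), 2.5 * _MM, 0.0),),
    )
    dz = _axial_step(geom)
    regions = {
        "cyst": ImagingGrid.regular(-8.75 * _MM, -3.25 * _MM, 60e-6, 21.75 * _MM, 27.25 * _MM, dz),
        "background": ImagingGrid.regular(3.25 * _MM, 8.75 * _MM, 60e-6, 21.75 * _MM, 27.25 * _MM, dz),
        "point": ImagingGrid.regular(-2 * _MM, 2 * _MM, 10e-6, 23.25 * _MM, 24.75 * _MM, dz),
    }
    rois = {
        "cyst": {"region": "cyst", "center": (-6 * _MM, 24.5 * _MM), "radius": 1.8 * _MM},
        "background": {"region": "background", "center": (6 * _MM, 24.5 * _MM), "radius": 2.4 * _MM},
        "point": {"region": "point", "center": (0.0, 24 * _MM), "half_lat": 2 * _MM, "half_ax": 0.6 * _MM},
    }
    from .beamform import BeamformerConfig

    # Study beamformer settings: L = N/2, Delta = 0.1/L, 2K+1 = 9 with the
    # temporal samples spaced a quarter wavelength apart on the image grid,
    # gamma = 0.5, M0 = 1, delta = delta_max = 1.  L_max for the dynamic
    # subarray is N/4: the value at which the CMSAW weighting preserves
    # speckle statistics (see docs/methods.md).
    sim_bf = BeamformerConfig(L_max=geom.n_elements // 4, temporal_stride=None)
    simulation = StudySetup(
        geometry=geom, phantom=spec, pulse=pulse, snr_db=10.0,
        regions=regions, rois=rois, beamformer=sim_bf,
    )

    # reduced toy variant for fast end-to-end tests
    tgeom = ArrayGeometry(n_elements=32, pitch=0.24e-3, f0=3.33e6, fs=40e6, c=1540.0)
    tspec = PhantomSpec(
        extent=((-8 * _MM, 8 * _MM), (-0.25 * _MM, 0.25 * _MM), (14.5 * _MM, 25.5 * _MM)),
        scatterer_density=10.0,
        point_targets=(((0.0, 0.0, 22.5 * _MM), _POINT_AMPLITUDE),),
        cyst_regions=(((-4.5 * _MM, 0.0, 19.5 * _MM), 2.0 * _MM, 0.0),),
    )
    tdz = _axial_step(tgeom)
    tregions = {
        "cyst": ImagingGrid.regular(-6.7 * _MM, -2.3 * _MM, 60e-6, 17.3 * _MM, 21.7 * _MM, tdz),
        "background": ImagingGrid.regular(2.3 * _MM, 6.7 * _MM, 60e-6, 17.3 * _MM, 21.7 * _MM, tdz),
        "point": ImagingGrid.regular(-2.5 * _MM, 2.5 * _MM, 20e-6, 21.75 * _MM, 23.25 * _MM, tdz),
    }
    trois = {
        "cyst": {"region": "cyst", "center": (-4.5 * _MM, 19.5 * _MM), "radius": 1.2 * _MM},
        "background": {"region": "background", "center": (4.5 * _MM, 19.5 * _MM), "radius": 1.9 * _MM},
        "point": {"region": "point", "center": (0.0, 22.5 * _MM), "half_lat": 2.2 * _MM, "half_ax": 0.6 * _MM},
    }
    toy_bf = BeamformerConfig(L_max=tgeom.n_elements // 4, temporal_stride=None)
    toy = StudySetup(
        geometry=tgeom, phantom=tspec, pulse=PulseModel(f0=tgeom.f0),
        snr_db=10.0, regions=tregions, rois=trois, beamformer=toy_bf,
    )
    return {"simulation": simulation, "toy": toy}


def pure_speckle_setup(n_elements: int = 32, density: float = 40.0) -> StudySetup:
    """Homogeneous speckle slab (no cysts, no points) for statistics checks.

    The density default is high enough for fully developed speckle, and the
    evaluation grid stays inside the aperture footprint laterally so the
    Rayleigh statistics are not diluted by the sensitivity roll-off beyond
    the array edges.  Sized for a couple hundred independent resolution
    cells, giving a speckle-SNR estimate stable to roughly +-0.1 per
    realization.
    """
    geom = ArrayGeometry(
        n_elements=n_elements, pitch=0.24e-3, f0=3.33e6, fs=40e6, c=1540.0
    )
    spec = PhantomSpec(
        extent=((-8 * _MM, 8 * _MM), (-0.25 * _MM, 0.25 * _MM), (13 * _MM, 28 * _MM)),
        scatterer_density=density,
    )
    dz = 2.0 * _axial_step(geom)
    half = 0.45 * geom.aperture
    # grid carries a ~1 mm axial margin beyond the ROI so the analytic-signal
    # transients at the patch edges stay outside the statistics
    regions = {
        "background": ImagingGrid.regular(-half, half, 0.1 * _MM, 13.5 * _MM, 27.5 * _MM, dz)
    }
    rois = {
        "background": {
            "region": "background",
            "center": (0.0, 20.75 * _MM),
            "half_lat": half,
            "half_ax": 6.25 * _MM,
        }
    }
    from .beamform import BeamformerConfig

    return StudySetup(
        geometry=geom, phantom=spec, pulse=PulseModel(f0=geom.f0),
        snr_db=10.0, regions=regions, rois=rois,
        beamformer=BeamformerConfig(L_max=n_elements // 4, temporal_stride=None),
    )
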