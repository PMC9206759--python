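"""Configuration-driven orchestration: simulate -> beamform -> weight -> report.

The eight pipeline stages are: (1) two-way delay computation and
compensation, (2) receive-aperture synthesis, (3) image-wide ASD
normalization, (4) covariance estimation with dynamic subarray length plus
rotary averaging, (5) the coherence-driven adaptive reducing factor,
(6) diagonal reducing in both constant and adaptive modes, (7) the CMSF and
CMSAW weight values, (8) weighting of the MV output.  Stages 1-2 live in
:mod:`stabeam.focus` / :mod:`stabeam.imaging`, 3-8 in
:mod:`stabeam.weights` / :mod:`stabeam.imaging`; this module wires them
together, computes metrics, and writes the artifact directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__, imaging, metrics, weights
from .beamform import BeamformerConfig
from .focus import ArrayGeometry, ChannelDataCube
from .phantom import (
    PulseModel,
    StudySetup,
    add_channel_noise,
    make_scatterers,
    reference_setups,
    simulate_sta,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One end-to-end run: phantom (or cube path), methods, beamformer, seed."""

    setup: StudySetup | None = None
    preset: str = "toy"
    cube_path: str | None = None
    methods: tuple = imaging.METHODS
    beamformer: BeamformerConfig | None = None  # None = the setup's own config
    rng_seed: int | None = 0
    out_dir: str | None = None
    dump_weights: bool = False
    dynamic_range_db: float = 60.0
    spreading: bool = True

    def resolved_setup(self) -> StudySetup:
        setup = self.setup or reference_setups()[self.preset]
        if self.cube_path is None and self.rng_seed is None:
            raise ValueError("a synthetic phantom run needs an rng_seed")
        if not self.methods:
            raise ValueError("at least one method must be requested")
        return setup

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        bf = BeamformerConfig(**raw.pop("beamformer", {}))
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(beamformer=bf, **raw)


@dataclass
class RunResult:
    """In-memory artifact of one pipeline run."""

    images: dict
    weight_maps: dict
    report: metrics.MetricsReport
    counters: imaging.PixelCounters
    setup: StudySetup
    seed: int | None


def acquire(config: RunConfig) -> ChannelDataCube:
    """Stage 0: simulate the phantom (or load a recorded cube)."""
    if config.cube_path is not None:
        return ChannelDataCube.from_hdf5(config.cube_path)
    setup = config.resolved_setup()
    spec = setup.phantom
    if config.rng_seed is not None:
        spec = type(spec)(**{**spec.__dict__, "rng_seed": int(config.rng_seed)})
    field_ = make_scatterers(spec, setup.geometry, setup.pulse)
    cube = simulate_sta(field_, setup.geometry, setup.pulse, spreading=config.spreading)
    if setup.snr_db is not None and config.rng_seed is not None:
        cube = add_channel_noise(cube, setup.snr_db, int(config.rng_seed) + 1)
    return cube


def beamform_regions(
    cube: ChannelDataCube,
    regions: dict,
    cfg: BeamformerConfig,
    methods=imaging.METHODS,
):
    """Stages 1-8 over every named region grid.

    The ASD normalization (stage 3) is a single pass pooled across all
    regions, so every region's sigma' shares one image-wide maximum; the
    same map then drives both the dynamic subarray length and the adaptive
    reducing factor.
    """
    cfg = cfg.resolved(cube.geometry.n_elements)
    aps: dict[str, np.ndarray] = {}
    strides: dict[str, int] = {}
    counters = imaging.PixelCounters()
    for name, grid in regions.items():
        ap, c = imaging.synthesize_aperture(cube, grid, cfg.window, cfg.f_number)
        counters = counters.merged(c)
        aps[name] = ap
        if cfg.temporal_stride is None:
            # quarter-wavelength temporal-sample spacing on this grid
            dz = float(np.median(np.diff(grid.axial_z))) if grid.axial_z.size > 1 else 0.0
            lam = cube.geometry.wavelength
            strides[name] = max(1, int(round(lam / 4.0 / dz))) if dz > 0 else 1
        else:
            strides[name] = cfg.temporal_stride
    need_sigma = bool({"cmsf_mv", "cmsaw_mv"} & set(methods))
    sigma_primes: dict[str, np.ndarray | None] = {n: None for n in aps}
    if need_sigma:
        sig = {n: imaging.sigma_map(ap) for n, ap in aps.items()}
        pooled = np.concatenate([s.ravel() for s in sig.values()])
        normed = weights.normalize_asd(pooled, cfg.asd_exponent)
        ofs = 0
        for n, s in sig.items():
            sigma_primes[n] = normed[ofs : ofs + s.size].reshape(s.shape)
            ofs += s.size
    images: dict[str, dict] = {}
    wmaps: dict[str, dict] = {}
    from dataclasses import replace as _replace

    for name, ap in aps.items():
        cfg_r = _replace(cfg, temporal_stride=strides[name])
        imgs, wm, c = imaging.beamform_methods(ap, sigma_primes[name], cfg_r, methods)
        counters = counters.merged(c)
        images[name] = {
            m: metrics.BeamformedImage(v, regions[name], m) for m, v in imgs.items()
        }
        wmaps[name] = wm
    return images, wmaps, counters


def evaluate(
    images: dict, rois: dict, depth_compensation: bool = True
) -> metrics.MetricsReport:
    """Compute FWHM / CR / gCNR / sSNR for every method from the ROI spec.

    With ``depth_compensation`` the envelope is multiplied by (z/z_mid)^2
    before the ROI statistics — the time-gain compensation a scanner applies
    to undo two-way geometric spreading, without which sSNR and gCNR would
    measure the deterministic depth trend instead of speckle statistics.
    The lateral FWHM is taken along a single axial row and needs none.
    """
    report = metrics.MetricsReport(rois={k: {kk: vv for kk, vv in v.items()} for k, v in rois.items()})
    some_region = next(iter(images))
    for method in images[some_region]:
        row: dict = {}
        if "point" in rois and "point" in images:
            img = images["point"][method]
            try:
                row["fwhm_mm"] = metrics.lateral_fwhm(img, rois["point"])
            except metrics.UnresolvedPointError:
                row["fwhm_mm"] = None
        env = {}
        for key in ("cyst", "background"):
            roi = rois.get(key)
            if roi and roi["region"] in images:
                img = images[roi["region"]][method]
                mask = metrics.roi_mask(img.grid, roi)
                envelope = img.envelope
                if depth_compensation:
                    z = img.grid.axial_z
                    gain = (z / z[z.size // 2]) ** 2
                    envelope = envelope * gain[:, None]
                env[key] = envelope[mask]
        if "cyst" in env and "background" in env:
            row["cr_db"] = metrics.contrast_ratio(env["cyst"], env["background"])
            row["gcnr"] = metrics.gcnr(env["cyst"], env["background"])
        if "background" in env:
            row["ssnr"] = metrics.ssnr(env["background"])
        report.add(method, **row)
    return report


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline; write the artifact directory if configured."""
    setup = config.resolved_setup()
    cube = acquire(config)
    bf = config.beamformer or setup.beamformer or BeamformerConfig()
    try:
        images, wmaps, counters = beamform_regions(
            cube, setup.regions, bf, config.methods
        )
    except Exception as exc:  # tag the failing stage for the operator
        raise RuntimeError(f"beamforming stage failed: {exc}") from exc
    report = evaluate(images, setup.rois, depth_compensation=config.spreading)
    result = RunResult(images, wmaps, report, counters, setup, config.rng_seed)
    if config.out_dir is not None:
        write_artifacts(result, config)
    return result


def _config_hash(config: RunConfig) -> str:
    bf = config.beamformer.__dict__ if config.beamformer is not None else None
    blob = repr(
        (
            config.preset,
            config.methods,
            sorted(bf.items()) if bf else None,
            config.rng_seed,
            config.spreading,
        )
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_artifacts(result: RunResult, config: RunConfig) -> None:
    """Images (HDF5 + PNG), metrics (CSV + JSON), weight maps, manifest."""
    import h5py

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / "images.h5", "w") as f:
        for region, methods in result.images.items():
            grp = f.create_group(region)
            any_img = next(iter(methods.values()))
            grp.create_dataset("lateral_x", data=any_img.grid.lateral_x)
            grp.create_dataset("axial_z", data=any_img.grid.axial_z)
            for m, img in methods.items():
                grp.create_dataset(m, data=img.values)
            if config.dump_weights:
                for wname, wmap in result.weight_maps.get(region, {}).items():
                    grp.create_dataset(wname, data=wmap)
    for region, methods in result.images.items():
        for m, img in methods.items():
            _write_png(img, out / f"{region}_{m}.png", config.dynamic_range_db)
    result.report.to_csv(out / "metrics.csv")
    result.report.to_json(out / "metrics.json")
    manifest = {
        "config_hash": _config_hash(config),
        "seed": result.seed,
        "versions": _versions(),
        "counters": result.counters.as_dict(),
        "methods": list(config.methods),
        "dynamic_range_db": config.dynamic_range_db,
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)


def _versions() -> dict:
    import numpy
    import scipy

    return {"stabeam": __version__, "numpy": numpy.__version__, "scipy": scipy.__version__}


def _write_png(img: metrics.BeamformedImage, path, dr_db: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    disp = metrics.log_compress(img.envelope, dr_db)
    fig, ax = plt.subplots(figsize=(4, 4))
    extent = [
        img.grid.lateral_x[0] * 1e3,
        img.grid.lateral_x[-1] * 1e3,
        img.grid.axial_z[-1] * 1e3,
        img.grid.axial_z[0] * 1e3,
    ]
    im = ax.imshow(disp, cmap="gray", vmin=-dr_db, vmax=0, extent=extent, aspect="auto")
    ax.set_xlabel("lateral [mm]")
    ax.set_ylabel("depth [mm]")
    ax.set_title(f"{img.method} ({dr_db:.0f} dB range)")
    fig.colorbar(im, ax=ax, label="dB")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# --------------------------------------------------------------------------
# Test fixtures


def _oracle_msr(M: np.ndarray) -> float:
    """Direct double-loop mean-to-std ratio on real parts (fixture oracle)."""
    A = np.asarray(M).real
    n = A.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += A[i, j]
    mean = total / n**2
    acc = 0.0
    for i in range(n):
        for j in range(n):
            acc += (A[i, j] - mean) ** 2
    std = np.sqrt(acc / n**2)
    return mean / std if std > 0 else (0.0 if mean == 0 else 1e6)


def canonical_vectors(seed: int, n: int = 16) -> dict:
    """The four canonical aperture vectors: coherent, speckle-like, strong
    off-axis (alternating sign), and incoherent white noise."""
    rng = np.random.default_rng(seed)
    speckle = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    noise = 0.1 * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    return {
        "coherent": np.ones(n, dtype=complex),
        "speckle": speckle,
        "alternating": ((-1.0) ** np.arange(n)).astype(complex),
        "noise": noise,
    }


def make_fixtures(seed: int, out_dir) -> dict:
    """Small deterministic fixtures plus oracle-computed golden values.

    Writes the four canonical aperture vectors, a 3-scatterer mini channel
    cube, and a JSON of golden values (direct-loop MSR of each vector's
    rotary-averaged, diagonal-zeroed smoothed covariance, and the mini-cube
    DAS peak depth).  Reproducible bit-exact from the seed.
    """
    import h5py

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vecs = canonical_vectors(seed)
    golden: dict = {"seed": int(seed), "msr": {}}
    n = 16
    lp = n // 2
    J = np.eye(lp)[::-1]
    for name, x in vecs.items():
        n_sub = n - lp + 1
        R = np.zeros((lp, lp), dtype=complex)
        for l in range(n_sub):
            sub = x[l : l + lp]
            R += np.outer(sub, sub.conj())
        R /= n_sub
        Rh = (R + J @ R.T + J @ R @ J + R.T @ J) / 4.0
        Rr = Rh - np.diag(np.diag(Rh))
        golden["msr"][name] = _oracle_msr(Rr)
    geom = ArrayGeometry(n_elements=8, pitch=0.3e-3, f0=3e6, fs=30e6, c=1540.0)
    pulse = PulseModel(f0=geom.f0)
    positions = np.array(
        [[0.0, 0.0, 10e-3], [1e-3, 0.0, 12e-3], [-1.5e-3, 0.0, 14e-3]]
    )
    from .phantom import ScattererField

    cube = simulate_sta(ScattererField(positions, np.ones(3)), geom, pulse)
    cube.to_hdf5(out / "mini_cube.h5")
    golden["mini_cube"] = {
        "scatterer_z_mm": [10.0, 12.0, 14.0],
        "t0": cube.geometry.t0,
        "n_samples": cube.n_samples,
    }
    with h5py.File(out / "canonical_vectors.h5", "w") as f:
        for name, x in vecs.items():
            f.create_dataset(name, data=x)
    with open(out / "golden.json", "w") as f:
        json.dump(golden, f, indent=2)
    return golden
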