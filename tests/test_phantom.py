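"""Scatterer phantoms, the STA simulator, and channel noise."""

import numpy as np
import pytest
from scipy import stats

from stabeam.focus import ArrayGeometry, ChannelDataCube
from stabeam.phantom import (
    PhantomSpec,
    PulseModel,
    ScattererField,
    add_channel_noise,
    make_scatterers,
    pure_speckle_setup,
    reference_setups,
    resolution_cell_volume,
    simulate_sta,
)

MM = 1e-3


@pytest.fixture()
def geom():
    return ArrayGeometry(n_elements=8, pitch=0.3e-3, f0=3e6, fs=30e6, c=1540.0)


@pytest.fixture()
def pulse():
    return PulseModel(f0=3e6)


def tiny_spec(seed=0, **kw):
    base = dict(
        extent=((-3 * MM, 3 * MM), (-0.25 * MM, 0.25 * MM), (8 * MM, 14 * MM)),
        scatterer_density=5.0,
        rng_seed=seed,
    )
    base.update(kw)
    return PhantomSpec(**base)


class TestMakeScatterers:
    def test_count_matches_density_and_is_reproducible(self, geom, pulse):
        spec = tiny_spec()
        cell = resolution_cell_volume(geom, pulse, spec)
        expected = int(round(spec.scatterer_density * spec.volume / cell))
        f1 = make_scatterers(spec, geom, pulse)
        f2 = make_scatterers(spec, geom, pulse)
        assert f1.amplitudes.size == expected
        np.testing.assert_array_equal(f1.positions, f2.positions)
        np.testing.assert_array_equal(f1.amplitudes, f2.amplitudes)

    def test_positions_inside_extent(self, geom, pulse):
        f = make_scatterers(tiny_spec(), geom, pulse)
        for axis, (lo, hi) in enumerate(tiny_spec().extent):
            assert f.positions[:, axis].min() >= lo
            assert f.positions[:, axis].max() <= hi

    def test_anechoic_region_exactly_zero(self, geom, pulse):
        cyst = ((0.0, 0.0, 11 * MM), 1.5 * MM, 0.0)
        f = make_scatterers(tiny_spec(cyst_regions=(cyst,)), geom, pulse)
        d2 = np.sum((f.positions - np.array(cyst[0])) ** 2, axis=1)
        inside = d2 <= cyst[1] ** 2
        assert inside.sum() > 10
        np.testing.assert_array_equal(f.amplitudes[inside], 0.0)

    def test_amplitudes_gaussian(self, geom, pulse):
        spec = tiny_spec(scatterer_density=5.0)
        cell = resolution_cell_volume(geom, pulse, spec)
        density = 5000.0 * cell / spec.volume
        f = make_scatterers(tiny_spec(scatterer_density=density), geom, pulse)
        assert abs(f.amplitudes.size - 5000) <= 1
        assert stats.normaltest(f.amplitudes).pvalue > 0.01

    def test_point_targets_appended(self, geom, pulse):
        pt = ((1 * MM, 0.0, 10 * MM), 25.0)
        f = make_scatterers(tiny_spec(point_targets=(pt,)), geom, pulse)
        np.testing.assert_allclose(f.positions[-1], pt[0])
        assert f.amplitudes[-1] == 25.0

    def test_zero_volume_rejected(self, geom, pulse):
        spec = tiny_spec(extent=((0, 0), (-1e-3, 1e-3), (8 * MM, 14 * MM)))
        with pytest.raises(ValueError):
            make_scatterers(spec, geom, pulse)


class TestSimulateSta:
    def test_single_scatterer_echo_time(self, geom, pulse):
        field = ScattererField(np.array([[0.0, 0.0, 30 * MM]]), np.array([1.0]))
        cube = simulate_sta(field, geom, pulse, spreading=False)
        n = geom.n_elements
        # the two central elements straddle x=0
        i = n // 2
        trace = np.abs(cube.rf[i, i])
        t_peak = cube.geometry.t0 + np.argmax(trace) / geom.fs
        d = np.sqrt(geom.element_x[i] ** 2 + (30 * MM) ** 2)
        assert abs(t_peak - 2 * d / geom.c) < pulse.half_duration / 4

    def test_superposition(self, geom, pulse):
        p1 = np.array([[0.0, 0.0, 10 * MM]])
        p2 = np.array([[1 * MM, 0.0, 12 * MM]])
        both = ScattererField(np.vstack([p1, p2]), np.array([1.0, -0.5]))
        t0, n = 1.0e-5, 700
        c_both = simulate_sta(both, geom, pulse, t0=t0, n_samples=n)
        c_1 = simulate_sta(ScattererField(p1, [1.0]), geom, pulse, t0=t0, n_samples=n)
        c_2 = simulate_sta(ScattererField(p2, [-0.5]), geom, pulse, t0=t0, n_samples=n)
        np.testing.assert_allclose(
            c_both.rf, c_1.rf + c_2.rf, rtol=1e-10, atol=1e-13 * np.abs(c_1.rf).max()
        )

    def test_zero_amplitudes_give_zero_cube(self, geom, pulse):
        field = ScattererField(np.array([[0.0, 0.0, 10 * MM]]), np.array([0.0]))
        cube = simulate_sta(field, geom, pulse, t0=0.5e-5, n_samples=400)
        np.testing.assert_array_equal(cube.rf, 0.0)

    def test_window_too_short_reports_requirement(self, geom, pulse):
        field = ScattererField(np.array([[0.0, 0.0, 30 * MM]]), np.array([1.0]))
        with pytest.raises(ValueError, match=r"n_samples >= \d+"):
            simulate_sta(field, geom, pulse, t0=0.0, n_samples=10)

    def test_reciprocity(self, geom, pulse):
        field = ScattererField(
            np.array([[1 * MM, 0.0, 9 * MM], [-2 * MM, 0.0, 12 * MM]]),
            np.array([1.0, 2.0]),
        )
        cube = simulate_sta(field, geom, pulse)
        np.testing.assert_array_equal(cube.rf, cube.rf.transpose(1, 0, 2))


class TestChannelNoise:
    def make_cube(self, geom, rng, T=4096):
        n = geom.n_elements
        return ChannelDataCube(rng.standard_normal((n, n, T)), geom)

    def test_empirical_snr_within_tolerance(self, geom, rng):
        cube = self.make_cube(geom, rng, T=16384)  # 64 * 16384 > 1e6 samples
        noisy = add_channel_noise(cube, 10.0, 99)
        noise = noisy.rf - cube.rf
        snr = 10 * np.log10(np.mean(cube.rf**2) / np.mean(noise**2))
        assert snr == pytest.approx(10.0, abs=0.2)

    def test_deterministic_given_seed(self, geom, rng):
        cube = self.make_cube(geom, rng)
        a = add_channel_noise(cube, 10.0, 7)
        b = add_channel_noise(cube, 10.0, 7)
        np.testing.assert_array_equal(a.rf, b.rf)

    def test_none_sentinel_returns_cube_unchanged(self, geom, rng):
        cube = self.make_cube(geom, rng)
        assert add_channel_noise(cube, None, 0) is cube
        assert add_channel_noise(cube, np.inf, 0) is cube

    def test_all_zero_cube_rejected(self, geom):
        cube = ChannelDataCube(np.zeros((8, 8, 64)), geom)
        with pytest.raises(ValueError):
            add_channel_noise(cube, 10.0, 0)


class TestReferenceSetups:
    def test_simulation_geometry_matches_study(self):
        g = reference_setups()["simulation"].geometry
        assert g.n_elements == 64
        assert g.pitch == pytest.approx(0.24e-3)
        assert g.f0 == pytest.approx(3.33e6)
        assert g.fs == pytest.approx(40e6)
        assert g.c == pytest.approx(1540.0)
        assert g.aperture == pytest.approx(15.36e-3)

    def test_simulation_phantom_dimensions(self):
        spec = reference_setups()["simulation"].phantom
        (x0, x1), (y0, y1), (z0, z1) = spec.extent
        assert (x1 - x0, y1 - y0, z1 - z0) == pytest.approx((22e-3, 0.5e-3, 15e-3))
        assert spec.scatterer_density == 40.0
        center, radius, scale = spec.cyst_regions[0]
        assert 2 * radius == pytest.approx(5e-3)  # 5 mm diameter cyst
        assert scale == 0.0
        assert len(spec.point_targets) == 3
        assert any(p[0][2] == pytest.approx(24e-3) for p in spec.point_targets)

    def test_toy_variant_is_reduced(self):
        toy = reference_setups()["toy"]
        assert toy.geometry.n_elements == 32
        assert toy.phantom.scatterer_density == 10.0


class TestSpeckleInvariants:
    def test_mean_power_proportional_to_density(self):
        # doubling density doubles mean envelope power (incoherent sum);
        # the slab is sized for ~175 resolution cells so the 3-seed mean
        # ratio concentrates well inside +-10%
        from stabeam.imaging import das_image, synthesize_aperture
        from stabeam.focus import ImagingGrid

        geom = ArrayGeometry(n_elements=16, pitch=0.3e-3, f0=3e6, fs=30e6, c=1540.0)
        pulse = PulseModel(f0=3e6)
        ratios = []
        for seed in range(3):
            powers = []
            for density in (10.0, 20.0):
                spec = PhantomSpec(
                    extent=((-6 * MM, 6 * MM), (-0.25 * MM, 0.25 * MM), (6 * MM, 18 * MM)),
                    scatterer_density=density,
                    rng_seed=seed,
                )
                f = make_scatterers(spec, geom, pulse)
                cube = simulate_sta(f, geom, pulse, spreading=False)
                grid = ImagingGrid.regular(
                    -5.5 * MM, 5.5 * MM, 0.25 * MM, 7 * MM, 17 * MM, 77e-6
                )
                ap, _ = synthesize_aperture(cube, grid)
                powers.append(np.mean(np.abs(das_image(ap)) ** 2))
            ratios.append(powers[1] / powers[0])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.10)

    def test_speckle_setup_is_pure_speckle(self):
        s = pure_speckle_setup()
        assert not s.phantom.point_targets
        assert not s.phantom.cyst_regions
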