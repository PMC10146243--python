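import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canopyflux.radiation import (SkyModel, VoxelGrid, beam_interception,
                                  compute_irradiance, direction_vector,
                                  estimate_longwave_and_nir,
                                  extraterrestrial_ppfd_horizontal,
                                  g_function, solar_position,
                                  split_diffuse_direct, voxelize, _traverse)


def cooper_declination(doy):
    """Independent declination oracle (Cooper 1969)."""
    return 23.45 * math.sin(math.radians(360.0 * (284 + doy) / 365.0))


class TestSolarPosition:
    def test_equinox_noon_equator(self):
        elev, _ = solar_position(0.0, 0.0, 80, 12.0)
        assert elev == pytest.approx(90.0, abs=1.0)

    def test_midnight_sun_down(self):
        elev, _ = solar_position(40.0, 0.0, 172, 0.0)
        assert elev < 0

    def test_solstice_noon_elevation(self):
        # closed-form noon elevation: 90 - lat + declination
        elev, _ = solar_position(40.0, 0.0, 172, 12.0)
        assert elev == pytest.approx(90.0 - 40.0 + 23.44, abs=0.5)

    def test_against_independent_declination_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            lat = rng.uniform(-60, 60)
            doy = int(rng.integers(1, 366))
            hour = rng.uniform(6, 18)
            elev, _ = solar_position(lat, 0.0, doy, hour)
            dec = math.radians(cooper_declination(doy))
            latr = math.radians(lat)
            H = math.radians(15.0 * (hour - 12.0))
            sin_el = (math.sin(latr) * math.sin(dec)
                      + math.cos(latr) * math.cos(dec) * math.cos(H))
            oracle = math.degrees(math.asin(sin_el))
            # Cooper's declination itself carries up to ~1 deg error
            assert elev == pytest.approx(oracle, abs=1.0)


class TestDiffuseDirectSplit:
    def test_zero_input(self):
        assert split_diffuse_direct(0.0, 45.0, 200) == (0.0, 0.0)

    def test_overcast_regime_all_diffuse(self):
        # kt <= 0.22: fully diffuse (clearness-index piecewise model)
        i0h = extraterrestrial_ppfd_horizontal(40.0, 200)
        direct, diffuse = split_diffuse_direct(0.2 * i0h, 40.0, 200)
        assert direct == 0.0
        assert diffuse == pytest.approx(0.2 * i0h)

    def test_night_all_diffuse(self):
        direct, diffuse = split_diffuse_direct(50.0, -5.0, 200)
        assert direct == 0.0 and diffuse == 50.0

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(ppfd=st.floats(0.0, 2500.0), elev=st.floats(1.0, 89.0),
           doy=st.integers(1, 365))
    def test_partition_conserves_total(self, ppfd, elev, doy):
        direct, diffuse = split_diffuse_direct(ppfd, elev, doy)
        assert direct + diffuse == pytest.approx(ppfd, abs=1e-9)
        assert direct >= 0 and diffuse >= 0

    def test_diffuse_fraction_monotone_in_clearness(self):
        i0h = extraterrestrial_ppfd_horizontal(50.0, 200)
        kts = np.linspace(0.05, 0.95, 40)
        fds = []
        for kt in kts:
            d, f = split_diffuse_direct(kt * i0h, 50.0, 200)
            fds.append(f / (d + f))
        assert all(a >= b - 1e-12 for a, b in zip(fds, fds[1:]))


class TestLongwaveNir:
    def test_nir_ratio_matches_ppfd(self):
        lw, nd, nf = estimate_longwave_and_nir(25.0, 60.0, 1000.0, 700.0,
                                               50.0, 200)
        assert nd / (nd + nf) == pytest.approx(0.7)

    def test_longwave_increases_with_temperature(self):
        lws = [estimate_longwave_and_nir(t, 60.0, 0.0, 0.0, -5.0, 200)[0]
               for t in (10.0, 20.0, 30.0)]
        assert lws[0] < lws[1] < lws[2]

    def test_against_clear_sky_oracle(self):
        # Brutsaert clear-sky emissivity oracle, clear conditions
        T, rh = 20.0, 50.0
        i0h = extraterrestrial_ppfd_horizontal(60.0, 180)
        ppfd = 0.75 * i0h  # clear sky
        direct, _ = split_diffuse_direct(ppfd, 60.0, 180)
        lw, _, _ = estimate_longwave_and_nir(T, rh, ppfd, direct, 60.0, 180)
        ea_hpa = 0.6108 * math.exp(17.27 * T / (T + 237.3)) * rh / 100 * 10
        eps = 1.24 * (ea_hpa / (T + 273.15)) ** (1 / 7)
        oracle = eps * 5.670374419e-8 * (T + 273.15) ** 4
        assert lw == pytest.approx(oracle, rel=0.15)

    def test_rejects_bad_rh(self):
        with pytest.raises(ValueError):
            estimate_longwave_and_nir(20.0, 150.0, 100.0, 50.0, 30.0, 200)


class TestVoxelize:
    def test_single_leaf(self, small_scene):
        from canopyflux.reconstruction import CanopyScene
        leaf = small_scene.leaves[0]
        from dataclasses import replace
        scene = CanopyScene(leaves=[replace(leaf, area=50.0)])
        grid = voxelize(scene, edge=1.0)
        assert (grid.lad > 0).sum() == 1
        assert grid.lad.max() == pytest.approx(0.005)

    def test_area_conservation_random_scenes(self, allom, angles):
        from canopyflux.synthetic import gen_shoot_skeleton
        from canopyflux.reconstruction import assemble_canopy
        for seed in range(10):
            shoots = gen_shoot_skeleton({"counts": {"long": 5, "short": 5}},
                                        seed=seed)
            scene = assemble_canopy(shoots, allom, angles, seed=seed)
            for method in ("centroid", "split"):
                grid = voxelize(scene, edge=0.4, method=method)
                assert grid.total_leaf_area == pytest.approx(
                    scene.total_leaf_area_cm2() * 1e-4, rel=1e-3)

    def test_resolution_invariant_total(self, small_scene):
        g1 = voxelize(small_scene, edge=0.4)
        g2 = voxelize(small_scene, edge=0.2)
        assert g1.total_leaf_area == pytest.approx(g2.total_leaf_area,
                                                   rel=1e-9)

    def test_rejects_bad_edge(self, small_scene):
        with pytest.raises(ValueError):
            voxelize(small_scene, edge=0.0)


class TestGFunction:
    def test_spherical_distribution(self, spherical_normals):
        for el, az in [(90.0, 0.0), (45.0, 120.0), (15.0, 300.0)]:
            assert g_function(spherical_normals, (el, az)) == \
                pytest.approx(0.5, abs=0.01)

    def test_horizontal_leaves_limits(self):
        normals = np.array([[0.0, 0.0, 1.0]])
        assert g_function(normals, (90.0, 0.0)) == pytest.approx(1.0)
        assert g_function(normals, (1e-6, 0.0)) == pytest.approx(0.0,
                                                                 abs=1e-6)

    def test_rejects_below_horizon(self):
        with pytest.raises(ValueError):
            g_function(np.array([[0, 0, 1.0]]), (-5.0, 0.0))


class TestBeamInterception:
    def _grid(self, lad, dims=(3, 3, 4), edge=0.5):
        return VoxelGrid(origin=np.zeros(3), edge=np.full(3, edge),
                         lad=np.full(dims, lad),
                         normals=np.array([[0.0, 0.0, 1.0]]))

    def test_empty_grid_transparent(self):
        res = beam_interception(self._grid(0.0), (60.0, 90.0), 500.0)
        assert res.transmitted == pytest.approx(res.incident)
        assert res.intercepted.sum() == 0.0

    def test_homogeneous_vertical_closed_form(self):
        # LAI = 0.5 * 4 * 0.5 = 1; horizontal leaves, vertical beam: G = 1
        res = beam_interception(self._grid(0.5), (90.0, 0.0), 1000.0)
        assert res.transmitted / res.incident == pytest.approx(
            math.exp(-1.0), rel=1e-6)

    def test_oblique_column_optical_depth(self):
        """One full ray path through a homogeneous slab has optical depth
        G*LAD*H/sin(h) (per-ray closed form)."""
        grid = self._grid(0.8, dims=(40, 40, 4), edge=0.5)
        elev = 35.0
        d = -direction_vector(elev, 45.0)
        origin = np.array([10.0, 10.0, grid.upper_corner[2]])
        path = sum(seg for *_, seg in _traverse(grid, origin, d))
        H = 4 * 0.5
        assert path == pytest.approx(H / math.sin(math.radians(elev)),
                                     rel=1e-9)

    def test_energy_conservation_random_grids(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            lad = rng.uniform(0.0, 3.0, size=(3, 3, 3))
            grid = VoxelGrid(origin=np.zeros(3), edge=np.full(3, 0.4),
                             lad=lad, normals=np.array([[0.0, 0.0, 1.0]]))
            elev = rng.uniform(10.0, 90.0)
            res = beam_interception(grid, (elev, rng.uniform(0, 360)),
                                    800.0)
            closure = res.intercepted.sum() + res.transmitted
            assert closure == pytest.approx(res.incident, rel=1e-9)

    def test_transmittance_decreases_with_lad(self):
        taus = []
        for lad in (0.2, 0.6, 1.2, 2.0):
            res = beam_interception(self._grid(lad), (90.0, 0.0), 100.0)
            taus.append(res.transmitted / res.incident)
        assert all(a > b for a, b in zip(taus, taus[1:]))

    def test_sunlit_fraction_bounds(self):
        res = beam_interception(self._grid(1.5), (45.0, 200.0), 100.0)
        assert np.all(res.sunlit_fraction >= 0.0)
        assert np.all(res.sunlit_fraction <= 1.0 + 1e-12)


class TestIrradiance:
    def test_zero_ppfd_zero_field(self, small_scene):
        grid = voxelize(small_scene, edge=0.4)
        sky = SkyModel.turtle46()
        rec = {"ppfd": 0.0, "tair": 20.0, "rh": 60.0, "wind": 1.0,
               "doy": 200, "hour": 12.0}
        irr = compute_irradiance(grid, sky, rec)
        assert np.all(irr.absorbed_direct == 0.0)
        assert np.all(irr.absorbed_diffuse == 0.0)

    def test_sky_weights_sum_to_one(self):
        sky = SkyModel.turtle46()
        assert sky.weights.sum() == pytest.approx(1.0)
        assert len(sky.directions) == 46
        assert np.all(sky.directions[:, 0] > 0)

    def test_isotropic_sky_uniform_on_test_surface(self):
        """46-direction sky above a clear domain with a thin horizontal
        absorbing sheet at the bottom: the flux collected per sheet cell
        is laterally uniform within 3% (numeric integration check)."""
        lad = np.zeros((6, 6, 4))
        lad[:, :, 0] = 0.05  # thin test sheet
        grid = VoxelGrid(origin=np.zeros(3), edge=np.full(3, 0.5),
                         lad=lad, normals=np.array([[0.0, 0.0, 1.0]]))
        sky = SkyModel.turtle46()
        ground = np.zeros((6, 6))
        for (el, az), w in zip(sky.directions, sky.weights):
            res = beam_interception(grid, (el, az), 1.0)
            ground += w * res.intercepted[:, :, 0]
        assert ground.std() / ground.mean() < 0.03

    def test_optically_thin_first_order(self):
        lad = 0.01
        grid = VoxelGrid(origin=np.zeros(3), edge=np.full(3, 1.0),
                         lad=np.full((1, 1, 1), lad),
                         normals=np.array([[0.0, 0.0, 1.0]]))
        res = beam_interception(grid, (90.0, 0.0), 1000.0)
        expected = 1000.0 * 1.0 * lad * 1.0  # I * G * LAD * path * area
        assert res.intercepted.sum() == pytest.approx(expected, rel=0.01)
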