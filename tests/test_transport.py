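"""Unit tests for the Monte Carlo transport engine."""

import math

import numpy as np
import pytest

from nirsim.head_model import PhantomSpec, TissueLabelVolume, \
    add_frontal_sinus, make_layer_phantom
from nirsim.optics import AIR, CSF, GRAY, SCALP, OpticalCoefficientSet
from nirsim.transport import (PhotonState, absorption_overlap,
                              estimate_surface_normal, propagate_photon,
                              run_channel)


def _uniform_volume(label, edge=20):
    labels = np.full((edge, edge, edge), label, dtype=np.uint8)
    return TissueLabelVolume(labels, 1.0, np.full(3, 0.5))


def _coefficients(mu_a=0.0, mu_s=0.0, g=0.0, n=1.0):
    """Homogeneous coefficient set: same optics in every tissue class."""
    return OpticalCoefficientSet(np.full(6, mu_a), np.full(6, mu_s),
                                 np.full(6, g), np.full(6, n))


class TestSurfaceNormal:
    def test_planar_interface_axis_aligned(self, slab_volume):
        # deepest scalp voxel borders skull below: normal is exactly +z
        n = estimate_surface_normal(slab_volume, (30, 30, 3))
        np.testing.assert_allclose(n, [0, 0, 1], atol=1e-12)

    def test_unit_norm(self, slab_volume):
        n = estimate_surface_normal(slab_volume, (30, 30, 10))
        assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-12)

    def test_digitised_sphere_normals_near_radial(self):
        edge, radius = 45, 18
        labels = np.full((edge, edge, edge), CSF, dtype=np.uint8)
        c = (edge - 1) / 2.0
        ii, jj, kk = np.mgrid[0:edge, 0:edge, 0:edge]
        inside = (ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2 <= radius ** 2
        labels[inside] = GRAY
        vol = TissueLabelVolume(labels, 1.0, np.full(3, 0.5))
        # gray voxels with a CSF face neighbour
        offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                            [0, 0, 1], [0, 0, -1]])
        boundary = []
        for ijk in np.argwhere(inside):
            nb = ijk + offsets
            ok = np.all((nb >= 0) & (nb < edge), axis=1)
            if np.any(labels[nb[ok, 0], nb[ok, 1], nb[ok, 2]] == CSF):
                boundary.append(ijk)
        angles = []
        for ijk in boundary[::2]:  # systematic half-sample of the surface
            n = estimate_surface_normal(vol, ijk, other_label=CSF)
            radial = (ijk - c) / np.linalg.norm(ijk - c)
            angles.append(math.degrees(math.acos(
                np.clip(np.dot(n, radial), -1, 1))))
        angles = np.array(angles)
        assert np.mean(angles <= 15.0) >= 0.95

    def test_interior_voxel_rejected(self, slab_volume):
        with pytest.raises(ValueError):
            estimate_surface_normal(slab_volume, (30, 30, 30))


class TestPhotonState:
    def test_enforces_unit_direction_and_weight_range(self):
        PhotonState(r=[0, 0, 0], e=[0, 0, 1], W=1.0)
        with pytest.raises(ValueError):
            PhotonState(r=[0, 0, 0], e=[0, 0, 2], W=1.0)
        with pytest.raises(ValueError):
            PhotonState(r=[0, 0, 0], e=[0, 0, 1], W=1.5)


class TestPropagatePhoton:
    def test_free_flight_through_non_interacting_medium(self):
        vol = _uniform_volume(CSF)
        out = propagate_photon(vol, _coefficients(), (10.0, 10.0, 0.0),
                               rng=3)
        assert out.status == "escaped"
        assert out.exit_weight == 1.0
        assert out.deposits == []
        # straight vertical ray through the 20 mm cube
        np.testing.assert_allclose(out.exit_position[:2], [10.0, 10.0],
                                   atol=1e-6)
        assert out.exit_position[2] == pytest.approx(20.0, abs=1e-6)
        assert out.partial_pathlengths[CSF] == pytest.approx(20.0, abs=1e-6)

    def test_all_air_volume_has_no_launch_surface(self):
        vol = _uniform_volume(AIR)
        with pytest.raises(ValueError, match="air/scalp"):
            propagate_photon(vol, _coefficients(), (10.0, 10.0, 0.0))

    def test_straight_ray_beer_lambert_deposition(self):
        # pure absorber (mu_s = 0): every photon deposits its full weight
        # at the first interaction, whose depth is Exponential(mu_a)
        mu_a, edge, n_photons = 0.15, 30, 8000
        vol = _uniform_volume(SCALP, edge=edge)
        coef = _coefficients(mu_a=mu_a)
        depths = []
        for seed in range(n_photons):
            out = propagate_photon(vol, coef, (15.0, 15.0, 0.0), rng=seed,
                                   max_events=64)
            assert abs(out.weight_balance - 1.0) < 1e-9
            if out.deposits:
                (i, j, k), dw = out.deposits[0]
                assert (i, j) == (15, 15)  # on the launch ray
                assert dw == pytest.approx(1.0)
                depths.append(k)
        depths = np.array(depths)
        for d in (3.0, 8.0, 15.0, 25.0):
            simulated = np.mean(depths < d) * len(depths) / n_photons
            analytic = 1.0 - math.exp(-mu_a * d)
            assert simulated == pytest.approx(analytic, abs=0.02)

    def test_weight_accounting_closes_on_random_phantoms(self, coefficients):
        rng = np.random.default_rng(5)
        for _ in range(5):
            spec = PhantomSpec(cube_edge=24.0,
                               d_scalp=float(rng.uniform(1, 4)),
                               d_skull=float(rng.uniform(2, 6)),
                               d_csf=float(rng.uniform(0, 3)),
                               d_gray=float(rng.uniform(2, 6)))
            vol = make_layer_phantom(spec)
            if rng.random() < 0.5:
                vol = add_frontal_sinus(vol, (12.0, 12.0, spec.d_scalp
                                              + spec.d_skull / 2),
                                        (4.0, 4.0, 1.5))
            for seed in range(40):
                out = propagate_photon(vol, coefficients, (12.0, 12.0, 0.0),
                                       rng=seed, max_events=100_000)
                assert abs(out.weight_balance - 1.0) < 1e-9

    def test_photon_weight_never_negative(self, coefficients, small_slab):
        for seed in range(20):
            out = propagate_photon(small_slab, coefficients,
                                   (15.0, 15.0, 0.0), rng=seed,
                                   max_events=100_000)
            assert out.exit_weight >= 0.0
            assert all(dw > 0 for _, dw in out.deposits)


class TestRunChannel:
    def test_same_seed_bit_identical(self, small_slab, coefficients):
        kwargs = dict(emitter=np.array([10.0, 15.0, 0.0]),
                      detector=np.array([20.0, 15.0, 0.0]),
                      n_detected_target=40, seed=7, detector_radius=3.0)
        a = run_channel(small_slab, coefficients, **kwargs)
        b = run_channel(small_slab, coefficients, **kwargs)
        np.testing.assert_array_equal(a.absorption_map, b.absorption_map)
        assert a.n_launched == b.n_launched
        np.testing.assert_array_equal(a.gm_pathlengths, b.gm_pathlengths)

    def test_different_seeds_differ(self, small_slab, coefficients):
        kwargs = dict(emitter=np.array([10.0, 15.0, 0.0]),
                      detector=np.array([20.0, 15.0, 0.0]),
                      n_detected_target=40, detector_radius=3.0)
        a = run_channel(small_slab, coefficients, seed=1, **kwargs)
        b = run_channel(small_slab, coefficients, seed=2, **kwargs)
        assert absorption_overlap(a.absorption_map, b.absorption_map) < 1.0

    def test_reaches_requested_detections(self, small_channel_run):
        assert small_channel_run.n_detected == 100

    def test_air_absorbs_nothing(self, coefficients):
        vol = make_layer_phantom(PhantomSpec(
            cube_edge=30.0, d_scalp=2.0, d_skull=5.0, d_csf=1.0, d_gray=4.0,
            sinus_center=(15.0, 15.0, 4.5), sinus_semi_axes=(5.0, 5.0, 2.0)))
        res = run_channel(vol, coefficients, np.array([10.0, 15.0, 0.0]),
                          np.array([20.0, 15.0, 0.0]),
                          n_detected_target=50, seed=3, detector_radius=3.0)
        assert res.tissue_energy[AIR] == 0.0
        assert np.all(res.absorption_map[vol.labels == AIR] == 0.0)

    def test_energy_balance_closes(self, small_channel_run):
        assert small_channel_run.energy_balance == pytest.approx(
            1.0, abs=1e-6)

    def test_tissue_energy_consistent_with_map(self, small_channel_run):
        assert small_channel_run.tissue_energy.sum() == pytest.approx(
            small_channel_run.absorption_map.sum(), abs=1e-9)

    def test_save_load_round_trip(self, small_channel_run, tmp_path):
        from nirsim.transport import ChannelResult

        stem = tmp_path / "chan"
        small_channel_run.save(stem)
        back = ChannelResult.load(stem)
        np.testing.assert_allclose(back.absorption_map,
                                   small_channel_run.absorption_map,
                                   rtol=1e-6)
        assert back.n_detected == small_channel_run.n_detected
        assert back.seed == small_channel_run.seed


class TestBeerLambertClosure:
    def test_attenuation_matches_pathlength_reweighting_oracle(self):
        """Absorption bookkeeping closes against the Beer-Lambert path
        integral: the detected intensity at absorption mu_a equals the
        zero-absorption ensemble average of exp(-mu_a L), because
        absorption factorises along each path. Engine route (albedo
        deposits at mu_t-sampled collisions) vs analytic reweighting of
        the mu_a = 0 run must agree within Monte Carlo error."""
        labels = np.full((40, 40, 30), SCALP, dtype=np.uint8)
        vol = TissueLabelVolume(labels, 1.0, np.full(3, 0.5))

        def coef(mu_a):
            # homogeneous reduced-scalp scattering, index-matched to air
            return OpticalCoefficientSet(np.full(6, mu_a), np.full(6, 1.9),
                                         np.zeros(6), np.ones(6))

        em = np.array([15.0, 20.0, 0.0])
        det = np.array([25.0, 20.0, 0.0])
        mu_a = 0.004
        r0 = run_channel(vol, coef(0.0), em, det, detector_radius=3.0,
                         n_detected_target=2000, seed=5)
        ra = run_channel(vol, coef(mu_a), em, det, detector_radius=3.0,
                         n_detected_target=2000, seed=6)
        a_measured = math.log((r0.detected_weight / r0.n_launched)
                              / (ra.detected_weight / ra.n_launched))
        a_oracle = -math.log(np.mean(np.exp(-mu_a * r0.total_pathlengths)))
        assert a_measured == pytest.approx(a_oracle, rel=0.12)


class TestAbsorptionOverlap:
    def test_identical_maps(self):
        m = np.random.default_rng(0).random((4, 4, 4))
        assert absorption_overlap(m, m) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = np.array([1.0, 1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 2.0, 2.0])
        assert absorption_overlap(a, b) == 0.0

    def test_hand_computed_partial_overlap(self):
        a = np.array([1.0, 1.0, 0.0, 0.0])
        b = np.array([0.0, 1.0, 1.0, 0.0])
        assert absorption_overlap(a, b) == pytest.approx(0.5)

    def test_zero_map_rejected(self):
        with pytest.raises(ValueError):
            absorption_overlap(np.zeros(4), np.ones(4))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            absorption_overlap(np.ones(4), np.ones(5))


class TestAbsorptionShape:
    def test_deeper_reach_between_optodes_than_under_them(self, slab_run):
        """The detected-photon absorption cloud is ellipsoidal: it reaches
        deeper midway between the optodes than directly beneath them."""
        amap = slab_run.absorption_map
        z = np.arange(amap.shape[2]) + 0.5

        def mean_depth(x_station):
            sl = amap[x_station - 2:x_station + 3, :, :]
            w = sl.sum(axis=(0, 1))
            return float(np.average(z, weights=w))

        mid = mean_depth(30)
        under_emitter = mean_depth(15)
        under_detector = mean_depth(45)
        assert mid > under_emitter
        assert mid > under_detector
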