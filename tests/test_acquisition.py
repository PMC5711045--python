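"""Acquisition: schedules, projector physics against a dense ray-sum oracle, noise."""

import math

import numpy as np
import pytest

import cbctmotion as cm
from cbctmotion import ScanProtocol, angle_schedule, forward_project, add_noise

from _oracles import pixel_position, ray_sum_oracle


class TestAngleSchedule:
    def test_full_fan_endpoints(self):
        p = ScanProtocol.full_fan()
        angles, times = angle_schedule(p)
        assert len(angles) == 200
        assert math.degrees(angles[0]) == 0.0
        assert math.degrees(angles[-1]) == pytest.approx(200.0)
        assert times[0] == 0.0 and times[-1] == 30.0

    def test_half_fan_angular_step(self):
        p = ScanProtocol.half_fan()
        angles, _ = angle_schedule(p)
        steps = np.diff(np.rad2deg(angles))
        assert np.allclose(steps, 360.0 / (p.n_projections - 1))

    def test_scan_covers_many_motion_cycles(self):
        # both protocols span well over one 4 s breathing period
        for p in (ScanProtocol.full_fan(), ScanProtocol.half_fan()):
            _, times = angle_schedule(p)
            assert times[-1] / 4.0 >= 7.0


class TestForwardProject:
    def test_central_ray_through_uniform_cube(self):
        # mu * path = 0.02/mm * 50 mm = 1.0 for the perpendicular central ray
        values = np.zeros((64, 64, 64))
        values[19:44, 19:44, 19:44] = 0.02  # 50 mm cube on a 2 mm grid
        origin = tuple(-(64 - 1) / 2.0 * 2.0 for _ in range(3))
        vol = cm.VoxelVolume(values=values, spacing=2.0, origin=origin)
        prot = ScanProtocol(
            mode="full_fan", arc_deg=200, duration_s=30, n_projections=2,
            nu=63, nv=63, pitch=3.0,
        )
        projs = forward_project(vol, cm.static(), prot)
        center = prot.nu // 2
        assert projs.data[0, center, center] == pytest.approx(1.0, rel=1e-3)

    def test_zero_volume_gives_zero_projections(self):
        vol = cm.VoxelVolume(np.zeros((32, 32, 32)), 2.0, (-31.0, -31.0, -31.0))
        prot = ScanProtocol.full_fan(desk_scale=True)
        projs = forward_project(vol, cm.static(), prot)
        assert np.all(projs.data == 0.0)

    def test_oblique_rays_match_dense_oracle(self, default_cfg, static_volume):
        prot = ScanProtocol.full_fan()
        angles, _ = angle_schedule(prot)
        projs = forward_project(static_volume, cm.static(), prot)
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(12):
            p = int(rng.integers(0, prot.n_projections))
            iu = int(rng.integers(24, prot.nu - 24))
            iv = int(rng.integers(24, prot.nv - 24))
            beta = angles[p]
            src = np.array(
                [prot.sad * math.cos(beta), prot.sad * math.sin(beta), 0.0]
            )
            dst = pixel_position(prot, beta, iu, iv)
            expected = ray_sum_oracle(static_volume, src, dst)
            if expected < 0.1:
                continue
            assert projs.data[p, iv, iu] == pytest.approx(expected, rel=5e-3)
            checked += 1
        assert checked >= 5

    def test_full_circle_repeats_for_static_phantom(self, static_volume):
        prot = ScanProtocol.half_fan(desk_scale=True)
        projs = forward_project(static_volume, cm.static(), prot)
        # first and last projections view the same direction (0 and 360 deg)
        assert np.allclose(projs.data[0], projs.data[-1], atol=1e-9)

    def test_zero_amplitude_motion_equals_static(self, static_volume):
        prot = ScanProtocol.full_fan(desk_scale=True)
        a = forward_project(static_volume, cm.static(), prot)
        b = forward_project(static_volume, cm.sinusoidal(0.0, 0.25, 1.0), prot)
        assert np.array_equal(a.data, b.data)

    @pytest.mark.filterwarnings("ignore:phantom content")
    def test_linearity_in_the_phantom(self):
        rng = np.random.default_rng(3)
        origin = (-31.0, -31.0, -31.0)
        va = cm.VoxelVolume(rng.random((32, 32, 32)) * 0.01, 2.0, origin)
        vb = cm.VoxelVolume(rng.random((32, 32, 32)) * 0.01, 2.0, origin)
        vab = cm.VoxelVolume(va.values + vb.values, 2.0, origin)
        prot = ScanProtocol(
            mode="full_fan", arc_deg=200, duration_s=30, n_projections=4,
            nu=32, nv=32, pitch=3.0,
        )
        pa = forward_project(va, cm.static(), prot).data
        pb = forward_project(vb, cm.static(), prot).data
        pab = forward_project(vab, cm.static(), prot).data
        assert np.allclose(pab, pa + pb, rtol=1e-9, atol=1e-12)


class TestAddNoise:
    def _flat_set(self, value, shape=(4, 16, 16)):
        n = shape[0]
        prot = ScanProtocol(
            mode="full_fan", arc_deg=200, duration_s=30, n_projections=n,
            nu=shape[2], nv=shape[1], pitch=3.0,
        )
        angles, times = angle_schedule(prot)
        return cm.ProjectionSet(
            data=np.full(shape, value), angles_rad=angles, times_s=times, protocol=prot
        )

    def test_infinite_photon_limit(self):
        projs = self._flat_set(1.3)
        noisy = add_noise(projs, photons_per_ray=1e15, seed=0)
        assert np.allclose(noisy.data, projs.data, atol=1e-6)

    def test_seed_reproducibility(self):
        projs = self._flat_set(0.8)
        a = add_noise(projs, 1e4, seed=42).data
        b = add_noise(projs, 1e4, seed=42).data
        assert np.array_equal(a, b)
        c = add_noise(projs, 1e4, seed=43).data
        assert not np.array_equal(a, c)

    def test_flat_field_variance(self):
        # log-domain variance of a unit-transmission ray is ~1/photons
        projs = self._flat_set(0.0, shape=(10, 32, 32))
        noisy = add_noise(projs, photons_per_ray=1000.0, seed=1)
        assert np.var(noisy.data) == pytest.approx(1e-3, rel=0.05)


class TestProtocolValidation:
    def test_full_fan_with_offset_rejected(self):
        with pytest.raises(ValueError):
            ScanProtocol(
                mode="full_fan", arc_deg=200, duration_s=30, n_projections=10,
                lateral_offset_mm=100.0,
            )

    def test_desk_scale_halves_projections(self):
        assert ScanProtocol.full_fan(desk_scale=True).n_projections == 100
        assert ScanProtocol.half_fan(desk_scale=True).n_projections == 180

    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            ScanProtocol(mode="full_fan", arc_deg=0, duration_s=30, n_projections=10)
        with pytest.raises(ValueError):
            ScanProtocol(
                mode="full_fan", arc_deg=200, duration_s=30, n_projections=10,
                sad=1500, sdd=1000,
            )
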