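"""Phantom construction: voxelization fidelity, invariants, validation."""

import numpy as np
import pytest

import cbctmotion as cm
from cbctmotion.phantom import PhantomConfig, TargetSpec


class TestBuildPhantom:
    def test_no_targets_contains_only_material_values(self):
        cfg = PhantomConfig()
        vol = cm.build_phantom(cfg)
        assert set(np.unique(vol.values)) <= {cfg.mu_air, cfg.mu_foam, cfg.mu_water}

    def test_target_z_extent_in_voxels(self, default_cfg, static_volume):
        # 40 mm z extent on a 2 mm grid -> exactly 20 voxels of target value
        t = default_cfg.target("large")
        _, prof = cm.target_axial_profile(static_volume, t)
        assert (prof == t.mu).sum() == 20

    def test_total_excess_attenuation_matches_cuboid_volumes(self, default_cfg):
        # integral over (phantom - no-target phantom) = sum of cuboid volumes
        # times the target/foam contrast, within one boundary-voxel layer
        cfg = default_cfg
        with_t = cm.build_phantom(cfg).values
        without = cm.build_phantom(PhantomConfig()).values
        voxel = cfg.spacing ** 3
        got = (with_t - without).sum() * voxel
        expected = sum(
            np.prod(t.extents) * (t.mu - cfg.mu_foam) for t in cfg.targets
        )
        # one voxel layer per face of each cuboid
        slack = sum(
            2 * cfg.spacing * (e1 * e2 + e1 * e3 + e2 * e3) * (t.mu - cfg.mu_foam)
            for t in cfg.targets
            for e1, e2, e3 in [t.extents]
        )
        assert abs(got - expected) <= slack

    def test_deterministic(self, default_cfg):
        a = cm.build_phantom(default_cfg).values
        b = cm.build_phantom(default_cfg).values
        assert np.array_equal(a, b)

    def test_doubling_resolution_halves_extent_error(self):
        # worst-case voxelized z-extent error over alignments scales with spacing
        extent = 11.3
        errors = {}
        for spacing, n in ((2.0, 96), (1.0, 192)):
            worst = 0.0
            for shift in np.linspace(0.0, spacing, 9):
                cfg = PhantomConfig(
                    shape=(n, n, n), spacing=spacing,
                    targets=(TargetSpec("t", (50, 30, extent), (0, 0, shift)),),
                )
                vol = cm.build_phantom(cfg)
                _, prof = cm.target_axial_profile(vol, cfg.targets[0])
                measured = (prof == cfg.targets[0].mu).sum() * spacing
                worst = max(worst, abs(measured - extent))
            errors[spacing] = worst
        assert errors[2.0] <= 2.0
        assert errors[1.0] <= errors[2.0] / 2 + 0.1

    def test_supersampling_softens_boundaries(self):
        cfg = cm.default_config(supersample=2)
        vol = cm.build_phantom(cfg)
        t = cfg.target("small")
        # off-grid boundaries acquire intermediate values only; interior intact
        ix, iy, iz = vol.index_of(t.center)
        assert vol.values[ix, iy, iz] == pytest.approx(t.mu)


class TestValidation:
    def test_overlapping_targets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PhantomConfig(
                targets=(
                    TargetSpec("a", (20, 20, 20), (0, 0, 0)),
                    TargetSpec("b", (20, 20, 20), (5, 5, 5)),
                )
            )

    def test_target_outside_foam_rejected(self):
        with pytest.raises(ValueError, match="foam"):
            PhantomConfig(targets=(TargetSpec("a", (20, 20, 20), (0, -35, 0)),))

    def test_touching_targets_allowed(self):
        PhantomConfig(
            targets=(
                TargetSpec("a", (20, 20, 20), (-10, 0, 0)),
                TargetSpec("b", (20, 20, 20), (10, 0, 0)),
            )
        )


class TestAxialProfile:
    def test_top_hat_width(self, default_cfg, static_volume):
        t = default_cfg.target("large")
        z, prof = cm.target_axial_profile(static_volume, t)
        inside = prof == t.mu
        width = (inside.sum()) * static_volume.spacing
        assert width == pytest.approx(t.L0, abs=static_volume.spacing)

    def test_column_outside_targets_is_foam(self, default_cfg, static_volume):
        ghost = TargetSpec("ghost", (2, 2, 2), (-45.0, 30.0, 60.0))
        _, prof = cm.target_axial_profile(static_volume, ghost)
        assert set(np.unique(prof)) == {default_cfg.mu_foam}

    def test_profile_integral_above_baseline(self, default_cfg, static_volume):
        # excess integral = (mu_target - mu_foam) * L0, within one voxel
        t = default_cfg.target("medium")
        _, prof = cm.target_axial_profile(static_volume, t)
        excess = (prof - default_cfg.mu_foam).sum() * static_volume.spacing
        expected = (t.mu - default_cfg.mu_foam) * t.L0
        assert abs(excess - expected) <= (t.mu - default_cfg.mu_foam) * static_volume.spacing

    def test_center_outside_grid_rejected(self, static_volume):
        bad = TargetSpec("bad", (10, 10, 10), (500.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            cm.target_axial_profile(static_volume, bad)
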