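"""Registration, resampling, dose-zone ROIs and DVH metrics."""

import numpy as np
import pytest

from deltazone import (
    DoseZoneScheme,
    ImageVolume,
    ROIMask,
    RigidTransform,
    build_dose_zone_rois,
    dvh_metrics,
    resample_to_grid,
    rigid_register,
)
from conftest import make_mask, make_volume


def _blob_volume(shift_mm=(0.0, 0.0, 0.0), angle_z=0.0, shape=(32, 32, 24),
                 spacing=(2.0, 2.0, 2.5)):
    """Smooth anisotropic blob with optional rigid displacement applied
    analytically (the ground truth for registration recovery)."""
    origin = [-(n - 1) * s / 2 for n, s in zip(shape, spacing)]
    ax = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    ca, sa = np.cos(angle_z), np.sin(angle_z)
    Xr = ca * (X - shift_mm[0]) + sa * (Y - shift_mm[1])
    Yr = -sa * (X - shift_mm[0]) + ca * (Y - shift_mm[1])
    Zr = Z - shift_mm[2]
    data = (
        1000.0 * np.exp(-(Xr**2 / 500 + Yr**2 / 300 + Zr**2 / 400))
        + 400.0 * np.exp(-(((Xr - 15) ** 2 + (Yr + 10) ** 2 + Zr**2) / 150))
    )
    return ImageVolume(data, spacing, tuple(origin))


class TestRigidRegister:
    def test_identity_on_self(self):
        vol = _blob_volume()
        t = rigid_register(vol, vol)
        assert np.linalg.norm(t.translation_mm) < 0.1
        assert np.max(np.abs(t.rotation_rad)) < 1e-3

    def test_known_translation_recovered(self):
        fixed = _blob_volume()
        moving = _blob_volume(shift_mm=(3.0, -2.0, 1.0))
        t = rigid_register(moving, fixed)
        # mapping fixed points onto the moving image recovers the shift
        assert np.allclose(t.translation_mm, (3.0, -2.0, 1.0), atol=0.5)

    def test_known_rotation_recovered(self):
        fixed = _blob_volume()
        moving = _blob_volume(angle_z=np.deg2rad(5.0))
        t = rigid_register(moving, fixed)
        assert abs(t.rotation_rad[2] - np.deg2rad(5.0)) < np.deg2rad(0.5)
        assert abs(t.rotation_rad[0]) < np.deg2rad(0.5)

    def test_register_then_resample_is_identity_within_tolerance(self):
        fixed = _blob_volume()
        moving = _blob_volume(shift_mm=(4.0, 1.0, -2.0))
        t = rigid_register(moving, fixed)
        aligned = resample_to_grid(moving, fixed, t)
        inner = np.s_[4:-4, 4:-4, 4:-4]
        assert np.max(np.abs(aligned.data[inner] - fixed.data[inner])) < 15.0


class TestResample:
    def test_identity_same_grid_returns_values(self):
        vol = _blob_volume()
        out = resample_to_grid(vol, vol, RigidTransform())
        assert np.allclose(out.data, vol.data, atol=1e-9)

    def test_constant_volume_stays_constant(self):
        vol = ImageVolume(np.full((12, 12, 10), 7.0), (1.5, 1.5, 2.0), (-9, -9, -9))
        t = RigidTransform(rotation_rad=(0.0, 0.0, 0.2), translation_mm=(1.0, -0.5, 0.7))
        out = resample_to_grid(vol, vol, t)
        core = out.data[2:-2, 2:-2, 2:-2]
        assert np.allclose(core, 7.0, atol=1e-9)

    def test_linear_ramp_under_half_voxel_shift_matches_closed_form(self):
        shape, spacing = (16, 12, 10), (2.0, 2.0, 2.0)
        x = np.arange(shape[0]) * spacing[0]
        ramp = np.broadcast_to(x[:, None, None], shape).copy()
        vol = ImageVolume(ramp, spacing)
        t = RigidTransform(translation_mm=(1.0, 0.0, 0.0))  # half a voxel
        out = resample_to_grid(vol, vol, t)
        interior = out.data[:-1, :, :]
        expected = ramp[:-1] + 1.0
        assert np.max(np.abs(interior - expected)) < 1e-6

    def test_mask_resampling_stays_binary(self):
        mask = make_mask(np.zeros((10, 10, 8)))
        arr = np.zeros((10, 10, 8), dtype=bool)
        arr[3:6, 3:6, 3:5] = True
        mask = ROIMask(arr, (1.0, 1.0, 1.0), zone_label="50-55")
        out = resample_to_grid(mask, mask, RigidTransform(translation_mm=(0.4, 0, 0)))
        assert out.data.dtype == bool and out.zone_label == "50-55"

    def test_disjoint_fov_raises(self):
        vol = ImageVolume(np.ones((8, 8, 8)), (1.0, 1.0, 1.0))
        t = RigidTransform(translation_mm=(1000.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="overlap"):
            resample_to_grid(vol, vol, t)


class TestDoseZones:
    def test_uniform_dose_yields_single_zone_equal_to_lung(self):
        lung = np.zeros((10, 10, 10), dtype=bool)
        lung[2:8, 2:8, 2:8] = True
        dose = make_volume(np.full((10, 10, 10), 12.0), (5.0, 5.0, 5.0))
        zones, dropped = build_dose_zone_rois(dose, make_mask(lung, (5.0, 5.0, 5.0)))
        assert [z.zone_label for z in zones] == ["10-15"]
        assert np.array_equal(zones[0].data, lung)
        assert dropped == []

    def test_phantom_zones_match_brute_force(self, phantom_rp, phantom_zones):
        _, _, dose, lung, _ = phantom_rp
        zones, dropped = phantom_zones
        edges = DoseZoneScheme().edges_Gy
        labels = DoseZoneScheme().labels
        by_label = {z.zone_label: z.data for z in zones}
        for i, lab in enumerate(labels):
            lo, hi = edges[i], edges[i + 1]
            if i == len(labels) - 1:
                expect = lung.data & (dose.data >= lo) & (dose.data <= hi)
            else:
                expect = lung.data & (dose.data >= lo) & (dose.data < hi)
            if lab in by_label:
                assert np.array_equal(by_label[lab], expect)
            else:
                assert lab in dropped or expect.sum() == 0

    def test_zone_partition_covers_lung_disjointly(self, phantom_rp, phantom_zones):
        _, _, dose, lung, _ = phantom_rp
        zones, _ = phantom_zones
        stack = np.stack([z.data for z in zones])
        assert (stack.sum(axis=0) <= 1).all()
        covered = stack.any(axis=0)
        in_range = lung.data & (dose.data >= 0) & (dose.data <= 60)
        assert np.array_equal(covered, in_range)

    def test_tiny_zone_dropped_by_volume_rule(self):
        lung = np.ones((10, 10, 10), dtype=bool)  # 1 cm^3 at 1 mm voxels
        dose = np.full((10, 10, 10), 2.0)
        dose[0, 0, 0:3] = 52.0  # 3 voxels at 1 mm^3 each = 0.003 cm^3
        zones, dropped = build_dose_zone_rois(
            make_volume(dose), make_mask(lung)
        )
        assert dropped == ["50-55"]
        assert [z.zone_label for z in zones] == ["0-5"]

    def test_grid_mismatch_rejected(self):
        dose = make_volume(np.zeros((4, 4, 4)))
        lung = make_mask(np.ones((5, 5, 5)))
        with pytest.raises(ValueError):
            build_dose_zone_rois(dose, lung)


class TestDvh:
    def test_uniform_dose_metrics(self):
        lung = make_mask(np.ones((6, 6, 6)))
        ptv = make_mask(np.pad(np.ones((2, 2, 2)), ((0, 4),) * 3))
        dose = make_volume(np.full((6, 6, 6), 10.0))
        m = dvh_metrics(dose, lung, ptv)
        assert m.MLD_Gy == pytest.approx(10.0)
        assert (m.V5, m.V20, m.V30, m.V40) == (100.0, 0.0, 0.0, 0.0)
        assert m.PTV_LV_ratio == pytest.approx(8 / 216)

    def test_half_and_half(self):
        arr = np.zeros((4, 4, 4))
        arr[:2] = 25.0
        m = dvh_metrics(make_volume(arr), make_mask(np.ones((4, 4, 4))),
                        make_mask(np.ones((4, 4, 4))))
        assert m.MLD_Gy == pytest.approx(12.5)
        assert (m.V5, m.V20, m.V30) == (50.0, 50.0, 0.0)

    def test_phantom_matches_loop_oracle(self, phantom_rp):
        _, _, dose, lung, ptv = phantom_rp
        m = dvh_metrics(dose, lung, ptv)
        # independent brute-force voxel loop on a subsample-free full grid
        total, acc = 0, {5: 0, 20: 0, 30: 0, 40: 0}
        sum_d = 0.0
        for idx in zip(*np.nonzero(lung.data)):
            total += 1
            d = dose.data[idx]
            sum_d += d
            for xx in acc:
                acc[xx] += d >= xx
        assert m.MLD_Gy == pytest.approx(sum_d / total)
        for xx, attr in ((5, m.V5), (20, m.V20), (30, m.V30), (40, m.V40)):
            assert attr == pytest.approx(100.0 * acc[xx] / total)

    def test_vxx_monotone_property(self, rng):
        dose = make_volume(rng.uniform(0, 70, (8, 8, 8)))
        lung = make_mask(rng.random((8, 8, 8)) < 0.6)
        ptv = make_mask(np.ones((8, 8, 8)))
        m = dvh_metrics(dose, lung, ptv)
        assert m.V5 >= m.V20 >= m.V30 >= m.V40

    def test_empty_lung_raises(self):
        with pytest.raises(ValueError, match="empty"):
            dvh_metrics(make_volume(np.zeros((3, 3, 3))),
                        make_mask(np.zeros((3, 3, 3))),
                        make_mask(np.ones((3, 3, 3))))


class TestScheme:
    def test_default_scheme_is_nine_zones(self):
        s = DoseZoneScheme()
        assert len(s.labels) == 9
        assert s.edges_Gy[0] == 0 and s.edges_Gy[-1] == 60

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            DoseZoneScheme(edges_Gy=(0, 5, 5, 10), labels=("a", "b", "c"))
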