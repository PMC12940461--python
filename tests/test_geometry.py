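"""Geometry: anchors, trajectories, polar contours, and the two warps."""

import numpy as np
import pytest

from spinewarp.geometry import (
    CordTrajectory,
    DisplacementField,
    HeartAnchor,
    Point3,
    StructureMask,
    apply_body_correction,
    apply_spine_correction,
    build_spine_vectors,
    centroid_of_mask,
    compose_corrections,
    extract_cord_trajectory,
    sample_polar_contour,
)

from conftest import centered_volume, disk_mask, make_volume


class TestCentroid:
    def test_single_voxel(self):
        vol = make_volume(origin=(8.0, 17.0, 27.0), spacing=(1.0, 1.5, 3.0))
        m = np.zeros(vol.shape, bool)
        m[1, 2, 2] = True  # physical (8+2, 17+3, 27+3)
        c = centroid_of_mask(StructureMask("s", m), vol)
        assert (c.x, c.y, c.z) == (10.0, 20.0, 30.0)

    def test_two_voxel_symmetry(self):
        vol = make_volume()
        m = np.zeros(vol.shape, bool)
        m[0, 0, 0] = m[0, 0, 2] = True
        c = centroid_of_mask(StructureMask("s", m), vol)
        assert (c.x, c.y, c.z) == (1.0, 0.0, 0.0)

    def test_random_mask_matches_bruteforce(self, rng):
        vol = make_volume(shape=(6, 12, 12), spacing=(1.0, 1.0, 3.0))
        m = np.zeros(vol.shape, bool)
        flat = rng.choice(m.size, size=50, replace=False)
        m.ravel()[flat] = True
        c = centroid_of_mask(StructureMask("s", m), vol)
        acc = np.zeros(3)
        for k, r, col in np.argwhere(m):
            acc += [col * 1.0, r * 1.0, k * 3.0]
        acc /= m.sum()
        np.testing.assert_allclose([c.x, c.y, c.z], acc, atol=1e-12)

    def test_empty_mask_raises(self):
        vol = make_volume()
        with pytest.raises(ValueError, match="empty structure"):
            centroid_of_mask(StructureMask("s", np.zeros(vol.shape, bool)), vol)


class TestTrajectory:
    def test_straight_column(self):
        vol = make_volume()
        m = np.zeros(vol.shape, bool)
        m[:, 5, 7] = True
        t = extract_cord_trajectory(StructureMask("cord", m), vol)
        assert len(t) == vol.shape[0]
        np.testing.assert_allclose(t.centers, [[7.0, 5.0]] * vol.shape[0])

    def test_sinusoid_matches_per_slice_average(self, rng):
        vol = make_volume(shape=(10, 30, 30))
        m = np.zeros(vol.shape, bool)
        for k in range(10):
            c = 15 + int(round(5 * np.sin(k)))
            m[k, 10:13, c - 1 : c + 2] = True
        t = extract_cord_trajectory(StructureMask("cord", m), vol)
        for i, k in enumerate(range(10)):
            rr, cc = np.argwhere(m[k]).mean(axis=0)
            np.testing.assert_allclose(t.centers[i], [cc, rr])

    def test_gap_slice_omitted(self):
        vol = make_volume()
        m = np.zeros(vol.shape, bool)
        m[:, 5, 7] = True
        m[2] = False
        t = extract_cord_trajectory(StructureMask("cord", m), vol)
        assert len(t) == vol.shape[0] - 1
        assert 2.0 not in t.z  # slice z == k with unit spacing

    def test_all_empty_raises(self):
        vol = make_volume()
        with pytest.raises(ValueError, match="empty"):
            extract_cord_trajectory(
                StructureMask("cord", np.zeros(vol.shape, bool)), vol
            )


class TestSpineVectors:
    def test_definition(self):
        heart = HeartAnchor(Point3(0, 0, 0))
        traj = CordTrajectory(np.array([12.0]) , np.array([[5.0, -40.0]]))
        vs = build_spine_vectors(heart, traj)
        np.testing.assert_allclose(vs.V, [[5.0, -40.0, 12.0]])

    def test_identity_pair_gives_zero_dv(self):
        heart = HeartAnchor(Point3(1, 2, 3))
        z = np.arange(5, dtype=float)
        c = np.column_stack([np.linspace(0, 4, 5), np.full(5, -30.0)])
        vs = build_spine_vectors(heart, CordTrajectory(z, c), CordTrajectory(z, c))
        np.testing.assert_allclose(vs.dV, 0.0)

    def test_uniform_shift(self):
        heart = HeartAnchor(Point3(0, 0, 0))
        z = np.arange(6, dtype=float)
        c = np.column_stack([np.zeros(6), np.full(6, -30.0)])
        shifted = c + [0.0, 3.0]
        vs = build_spine_vectors(
            heart, CordTrajectory(z, c), CordTrajectory(z, shifted)
        )
        np.testing.assert_allclose(vs.dV, np.tile([0.0, 3.0, 0.0], (6, 1)))

    def test_resampling_onto_sct_grid(self):
        heart = HeartAnchor(Point3(0, 0, 0))
        zd = np.array([0.0, 2.0, 4.0, 6.0])
        cd = np.column_stack([np.linspace(0, 6, 4), np.zeros(4)])  # x == z
        zs = np.array([1.0, 3.0, 5.0])
        cs = np.column_stack([np.zeros(3), np.zeros(3)])
        vs = build_spine_vectors(
            heart, CordTrajectory(zd, cd), CordTrajectory(zs, cs)
        )
        np.testing.assert_allclose(vs.z, zs)
        np.testing.assert_allclose(vs.V[:, 0], zs)  # interpolated dCT x

    def test_no_overlap_raises(self):
        heart = HeartAnchor(Point3(0, 0, 0))
        t1 = CordTrajectory(np.array([0.0, 1.0]), np.zeros((2, 2)))
        t2 = CordTrajectory(np.array([10.0, 11.0]), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="overlap"):
            build_spine_vectors(heart, t1, t2)


class TestPolarContour:
    def test_disk_radius(self):
        vol = centered_volume(shape=(3, 120, 120), spacing=(1.0, 1.0, 3.0))
        body = disk_mask(vol, (0.0, 0.0), 50.0)
        c = sample_polar_contour(body.mask[0], (0.0, 0.0), vol, n_angles=37)
        np.testing.assert_allclose(c.radii, 50.0, atol=0.75)

    def test_offset_direction_consistency(self):
        vol = centered_volume(shape=(3, 120, 120), spacing=(1.0, 1.0, 3.0))
        body = disk_mask(vol, (0.0, 0.0), 50.0)
        c = sample_polar_contour(body.mask[0], (0.0, 0.0), vol, n_angles=37)
        ang = np.degrees(np.arctan2(c.offsets[:, 1], c.offsets[:, 0]))
        step = c.angles[1] - c.angles[0]
        assert np.all(np.abs(ang - c.angles) <= step / 2 + 1e-9)

    def test_ellipse_closed_form(self):
        vol = centered_volume(shape=(3, 260, 260), spacing=(1.0, 1.0, 3.0))
        a, b = 100.0, 60.0
        xs, ys = vol.x_coords(), vol.y_coords()
        X, Y = np.meshgrid(xs, ys)
        sl = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
        c = sample_polar_contour(sl, (0.0, 0.0), vol, n_angles=61)
        th = np.deg2rad(c.angles)
        r_true = a * b / np.sqrt(b**2 * np.cos(th) ** 2 + a**2 * np.sin(th) ** 2)
        assert np.max(np.abs(c.radii - r_true)) < 1.0  # within one voxel

    def test_displaced_center_matches_ray_march_oracle(self):
        vol = centered_volume(shape=(3, 130, 130), spacing=(1.0, 1.0, 3.0))
        body = disk_mask(vol, (0.0, 0.0), 50.0)
        center = (10.0, 0.0)
        c = sample_polar_contour(body.mask[0], center, vol, n_angles=25)
        # independent per-ray pixel march at a finer step
        for j, theta in enumerate(np.deg2rad(c.angles)):
            r, last = 0.0, None
            while r < 90.0:
                x = center[0] + r * np.cos(theta)
                y = center[1] + r * np.sin(theta)
                col = int(round((x - vol.origin.x)))
                row = int(round((y - vol.origin.y)))
                if 0 <= row < 130 and 0 <= col < 130 and body.mask[0][row, col]:
                    last = r
                r += 0.05
            assert abs(c.radii[j] - last) < 0.5

    def test_center_outside_raises(self):
        vol = centered_volume(shape=(3, 60, 60), spacing=(1.0, 1.0, 3.0))
        body = disk_mask(vol, (0.0, 0.0), 10.0)
        with pytest.raises(ValueError, match="center outside body"):
            sample_polar_contour(body.mask[0], (25.0, 0.0), vol)

    def test_open_contour_raises(self):
        vol = centered_volume(shape=(3, 20, 20), spacing=(1.0, 1.0, 3.0))
        sl = np.ones(vol.shape[1:], dtype=bool)  # body fills the grid
        with pytest.raises(ValueError, match="open contour"):
            sample_polar_contour(sl, (0.0, 0.0), vol, n_angles=19)

    def test_too_few_angles_raises(self):
        vol = centered_volume(shape=(3, 60, 60), spacing=(1.0, 1.0, 3.0))
        body = disk_mask(vol, (0.0, 0.0), 20.0)
        with pytest.raises(ValueError):
            sample_polar_contour(body.mask[0], (0.0, 0.0), vol, n_angles=10)


def _phantom_slice_volume():
    vol = centered_volume(shape=(8, 60, 60), spacing=(2.0, 2.0, 3.0))
    xs, ys = vol.x_coords(), vol.y_coords()
    X, Y = np.meshgrid(xs, ys)
    body2d = (X / 50.0) ** 2 + (Y / 45.0) ** 2 <= 1.0
    vol.voxels[:, body2d] = 40.0
    body = StructureMask("body", np.repeat(body2d[None], 8, axis=0))
    cord2d = X**2 + (Y - 10.0) ** 2 <= 6.0**2
    cord = StructureMask("cord", np.repeat(cord2d[None], 8, axis=0))
    return vol, body, cord


class TestSpineCorrection:
    def test_zero_field_is_identity(self):
        vol, body, cord = _phantom_slice_volume()
        f = DisplacementField(vol.slice_z, np.zeros((8, 3)))
        out, masks = apply_spine_correction(vol, [body, cord], f)
        np.testing.assert_array_equal(out.voxels, vol.voxels)
        np.testing.assert_array_equal(masks[1].mask, cord.mask)

    def test_constant_inplane_translation(self):
        vol, body, cord = _phantom_slice_volume()
        f = DisplacementField(vol.slice_z, np.tile([2.0, 0.0, 0.0], (8, 1)))
        out, _ = apply_spine_correction(vol, [body, cord], f)
        # 2 mm == exactly one voxel in x; edge column filled with air
        expected = np.full_like(vol.voxels, -1000.0)
        expected[:, :, 1:] = vol.voxels[:, :, :-1]
        np.testing.assert_allclose(out.voxels, expected, atol=1e-3)

    def test_smooth_field_moves_cord_onto_target(self):
        vol, body, cord = _phantom_slice_volume()
        z = vol.slice_z
        d = np.column_stack(
            [3.0 * np.sin(z / 30.0), 2.0 + 0.05 * z, np.zeros(8)]
        )
        f = DisplacementField(z, d)
        out, masks = apply_spine_correction(vol, [body, cord], f)
        traj_in = extract_cord_trajectory(cord, vol)
        traj_out = extract_cord_trajectory(masks[1], out)
        target = traj_in.centers + d[:, :2]
        rms = np.sqrt(np.mean(np.sum((traj_out.centers - target) ** 2, axis=1)))
        assert rms < 2.0  # one in-plane voxel

    def test_z_shift_resamples_slices(self):
        vol, body, cord = _phantom_slice_volume()
        vol.voxels[3] += 100.0  # marker slice
        f = DisplacementField(vol.slice_z, np.tile([0.0, 0.0, 3.0], (8, 1)))
        out, _ = apply_spine_correction(vol, [body, cord], f)
        # dz == 3 mm, so content moves up exactly one slice
        np.testing.assert_allclose(out.voxels[4], vol.voxels[3], atol=1e-3)

    def test_plausibility_bound(self):
        vol, body, cord = _phantom_slice_volume()
        f = DisplacementField(vol.slice_z, np.tile([60.0, 0.0, 0.0], (8, 1)))
        with pytest.raises(ValueError, match="plausibility"):
            apply_spine_correction(vol, [body, cord], f)


class TestBodyCorrection:
    @staticmethod
    def _setup():
        vol, body, cord = _phantom_slice_volume()
        traj = extract_cord_trajectory(cord, vol)
        contours = {
            float(z): sample_polar_contour(
                body.mask[k], tuple(traj.interp_at(z)[0]), vol, n_angles=37
            )
            for k, z in enumerate(vol.slice_z)
        }
        return vol, body, cord, traj, contours

    def test_identity_within_one_hu(self):
        vol, body, cord, traj, contours = self._setup()
        out, masks = apply_body_correction(
            vol, [body, cord], traj, contours, n_angles=37
        )
        assert np.max(np.abs(out.voxels - vol.voxels)) <= 1.0
        np.testing.assert_array_equal(masks[0].mask, body.mask)

    def test_uniform_posterior_stretch(self):
        vol, body, cord, traj, contours = self._setup()
        from spinewarp.geometry import PolarContour

        grown = {
            z: PolarContour(c.angles, c.offsets * (1 + 5.0 / c.radii)[:, None])
            for z, c in contours.items()
        }
        out, masks = apply_body_correction(
            vol, [body, cord], traj, grown, n_angles=37
        )
        k = 4
        cy = traj.interp_at(vol.slice_z[k])[0][1]
        rows_post = vol.y_coords() >= cy - 1.0  # half a voxel below midline
        before = body.mask[k]
        after = masks[0].mask[k]
        # anterior half-plane untouched
        np.testing.assert_array_equal(after[~rows_post], before[~rows_post])
        # posterior extent grows by ~5 mm
        y_before = vol.y_coords()[np.argwhere(before)[:, 0].max()]
        y_after = vol.y_coords()[np.argwhere(after)[:, 0].max()]
        assert 5.0 - 2.1 <= y_after - y_before <= 5.0 + 2.1

    def test_recomputed_contour_matches_target(self):
        vol, body, cord, traj, contours = self._setup()
        from spinewarp.geometry import PolarContour

        target = {
            z: PolarContour(c.angles, c.offsets * 0.9)
            for z, c in contours.items()
        }
        out, masks = apply_body_correction(
            vol, [body, cord], traj, target, n_angles=37
        )
        k = 4
        z = float(vol.slice_z[k])
        new = sample_polar_contour(
            masks[0].mask[k], tuple(traj.interp_at(z)[0]), vol, n_angles=37
        )
        assert np.max(np.abs(new.radii - target[z].radii)) < 2.1  # one voxel

    def test_nonpositive_target_raises(self):
        vol, body, cord, traj, contours = self._setup()
        from spinewarp.geometry import PolarContour

        z0 = float(vol.slice_z[0])
        bad = dict(contours)
        offs = bad[z0].offsets.copy()
        offs[5] = 0.0
        bad[z0] = PolarContour.__new__(PolarContour)
        bad[z0].angles = contours[z0].angles
        bad[z0].offsets = offs
        with pytest.raises(ValueError, match="non-positive"):
            apply_body_correction(vol, [body, cord], traj, bad, n_angles=37)


class TestCompose:
    def test_equals_sequential_application(self):
        vol, body, cord = _phantom_slice_volume()
        z = vol.slice_z
        f = DisplacementField(z, np.column_stack(
            [np.full(8, 2.0), np.full(8, -2.0), np.zeros(8)]
        ))
        v1, m1 = apply_spine_correction(vol, [body, cord], f)
        traj1 = extract_cord_trajectory(
            next(m for m in m1 if m.name == "cord"), v1
        )
        contours = {}
        from spinewarp.geometry import PolarContour

        for k, zk in enumerate(z):
            c = sample_polar_contour(
                next(m for m in m1 if m.name == "body").mask[k],
                tuple(traj1.interp_at(zk)[0]), v1, n_angles=37,
            )
            contours[float(zk)] = PolarContour(c.angles, c.offsets * 0.95)
        v2, m2 = apply_body_correction(v1, m1, traj1, contours, n_angles=37)
        v3, m3 = compose_corrections(
            vol, [body, cord], f, traj1, contours, n_angles=37
        )
        np.testing.assert_array_equal(v2.voxels, v3.voxels)
        np.testing.assert_array_equal(m2[0].mask, m3[0].mask)

    def test_order_sensitivity(self):
        # applying body first then spine differs from the sanctioned order
        vol, body, cord = _phantom_slice_volume()
        z = vol.slice_z
        f = DisplacementField(z, np.tile([0.0, 4.0, 0.0], (8, 1)))
        traj = extract_cord_trajectory(cord, vol)
        from spinewarp.geometry import PolarContour

        contours = {}
        for k, zk in enumerate(z):
            c = sample_polar_contour(
                body.mask[k], tuple(traj.interp_at(zk)[0]), vol, n_angles=37
            )
            contours[float(zk)] = PolarContour(c.angles, c.offsets * 0.9)
        sanctioned, _ = compose_corrections(
            vol, [body, cord], f, traj, contours, n_angles=37
        )
        vb, mb = apply_body_correction(
            vol, [body, cord], traj, contours, n_angles=37
        )
        swapped, _ = apply_spine_correction(vb, mb, f)
        assert np.max(np.abs(sanctioned.voxels - swapped.voxels)) > 100.0

    def test_mass_change_only_posterior(self):
        vol, body, cord = _phantom_slice_volume()
        traj = extract_cord_trajectory(cord, vol)
        from spinewarp.geometry import PolarContour

        contours = {}
        for k, zk in enumerate(vol.slice_z):
            c = sample_polar_contour(
                body.mask[k], tuple(traj.interp_at(zk)[0]), vol, n_angles=37
            )
            contours[float(zk)] = PolarContour(c.angles, c.offsets * 0.85)
        _, masks = apply_body_correction(
            vol, [body, cord], traj, contours, n_angles=37
        )
        ys = vol.y_coords()
        for k, zk in enumerate(vol.slice_z):
            cy = traj.interp_at(zk)[0][1]
            anterior = ys < cy - 1.0  # strictly above the midline seam
            np.testing.assert_array_equal(
                masks[0].mask[k][anterior], body.mask[k][anterior]
            )


class TestBoneAlignment:
    def test_translation_recovered_and_applied(self):
        from spinewarp.geometry import (
            align_by_bone_centroid,
            bone_centroid_translation,
        )

        vol, body, cord = _phantom_slice_volume()
        vol.voxels[:, 20:25, 28:32] = 500.0  # bone block
        moved = vol.copy()
        moved.voxels[:] = -1000.0
        moved.voxels[:, :, 2:] = vol.voxels[:, :, :-2]  # shifted +4 mm in x
        t = bone_centroid_translation(moved, vol)
        np.testing.assert_allclose(t, [-4.0, 0.0, 0.0], atol=1e-6)
        back, _ = align_by_bone_centroid(moved, [body], vol)
        np.testing.assert_allclose(
            back.voxels[:, :, :-2], vol.voxels[:, :, :-2], atol=1e-3
        )
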