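"""TPS warps, correspondence editing with undo, and the registration loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainplane.alignment import AlignmentMap, APAnchor
from brainplane.errors import RegistrationError
from brainplane.registration import (
    CorrespondencePointSet,
    ThinPlateSpline,
    apply_warp,
    edit_points,
    fit_warp,
    init_correspondence,
    load_warps,
    regi_loop,
    save_warps,
)


def random_pairs(rng, n=8, extent=100.0, jitter=5.0):
    src = rng.uniform(0, extent, (n, 2))
    dst = src + rng.normal(0, jitter, (n, 2))
    return src, dst


class TestThinPlateSpline:
    def test_identity(self):
        pts = np.array([[0, 0], [10, 0], [0, 10], [10, 10], [5, 3]], float)
        tps = ThinPlateSpline.fit(pts, pts)
        probes = np.array([[2.2, 7.7], [9.1, 0.3], [5.0, 5.0]])
        assert np.abs(tps(probes) - probes).max() <= 1e-9

    def test_pure_translation(self):
        pts = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float)
        tps = ThinPlateSpline.fit(pts, pts + [10.0, -5.0])
        probes = np.random.default_rng(0).uniform(-20, 30, (50, 2))
        assert np.abs(tps(probes) - (probes + [10.0, -5.0])).max() <= 1e-9

    def test_interpolates_controls_at_zero_regularization(self):
        rng = np.random.default_rng(1)
        src, dst = random_pairs(rng, n=8)
        tps = ThinPlateSpline.fit(src, dst, 0.0)
        assert np.abs(tps(src) - dst).max() <= 1e-6

    def test_matches_scipy_rbf_thin_plate(self):
        from scipy.interpolate import RBFInterpolator

        rng = np.random.default_rng(2)
        src, dst = random_pairs(rng, n=12)
        tps = ThinPlateSpline.fit(src, dst, 0.0)
        rbf = RBFInterpolator(src, dst, kernel="thin_plate_spline", degree=1)
        probes = rng.uniform(10, 90, (40, 2))
        assert np.abs(tps(probes) - rbf(probes)).max() <= 1e-6

    def test_bending_energy_non_increasing_with_regularization(self):
        rng = np.random.default_rng(3)
        src, dst = random_pairs(rng, n=10, jitter=8.0)
        energies = [
            ThinPlateSpline.fit(src, dst, lam).bending_energy()
            for lam in (0.0, 1.0, 10.0, 100.0)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_collinear_controls_rejected(self):
        src = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
        with pytest.raises(RegistrationError, match="collinear"):
            ThinPlateSpline.fit(src, src)

    def test_duplicate_controls_rejected(self):
        src = np.array([[0, 0], [10, 0], [0, 10], [10, 0]], float)
        with pytest.raises(RegistrationError, match="duplicate"):
            ThinPlateSpline.fit(src, src)

    def test_too_few_pairs_rejected(self):
        src = np.array([[0, 0], [1, 0], [0, 1]], float)
        with pytest.raises(RegistrationError, match="at least 4"):
            ThinPlateSpline.fit(src, src)


class TestWarp:
    def test_forward_inverse_round_trip_inside_hull(self):
        # well-spread controls: a jittered grid with a mild deformation
        rng = np.random.default_rng(4)
        gx, gy = np.meshgrid(np.linspace(0, 100, 5), np.linspace(0, 100, 5))
        src = np.column_stack([gx.ravel(), gy.ravel()])
        src += rng.uniform(-2, 2, src.shape)
        dst = src + np.column_stack(
            [3.0 * np.sin(src[:, 1] / 30.0), 3.0 * np.cos(src[:, 0] / 40.0)]
        )
        warp = fit_warp(CorrespondencePointSet(dst, src), 0.0)
        probes = rng.uniform(25, 75, (100, 2))  # well inside the hull
        back = apply_warp(warp, apply_warp(warp, probes, "forward"), "inverse")
        err = np.hypot(*(back - probes).T)
        assert err.max() <= 0.5

    def test_empty_point_list(self):
        pts = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float)
        warp = fit_warp(CorrespondencePointSet(pts, pts))
        assert apply_warp(warp, np.empty((0, 2))).shape == (0, 2)

    def test_save_load_round_trip_transforms_identically(self, tmp_path):
        rng = np.random.default_rng(5)
        src, dst = random_pairs(rng, n=9)
        warp = fit_warp(CorrespondencePointSet(dst, src), 0.0)
        save_warps({-0.42: warp}, tmp_path)
        assert (tmp_path / "plate_m0.420.warp").exists()
        assert (tmp_path / "plate_m0.420.csv").exists()
        back = load_warps(tmp_path)[-0.42]
        probes = rng.uniform(0, 100, (30, 2))
        np.testing.assert_array_equal(
            warp.transform(probes), back.transform(probes)
        )


class TestEditPoints:
    def make_ps(self, n=6):
        pts = np.arange(2 * n, dtype=float).reshape(n, 2)
        return CorrespondencePointSet(pts, pts + 100.0)

    def test_add_then_undo_restores(self):
        ps = self.make_ps()
        before = ps.atlas_xy.copy()
        edit_points(ps, "add", ((1.0, 2.0), (3.0, 4.0)))
        assert len(ps) == 7
        edit_points(ps, "undo")
        np.testing.assert_array_equal(ps.atlas_xy, before)

    def test_remove_preserves_order(self):
        ps = self.make_ps(10)
        third = ps.atlas_xy[4].copy()
        edit_points(ps, "remove", 3)
        assert len(ps) == 9
        np.testing.assert_array_equal(ps.atlas_xy[3], third)

    def test_add_move_undo_undo_restores(self):
        ps = self.make_ps()
        orig = (ps.atlas_xy.copy(), ps.image_xy.copy())
        edit_points(ps, "add", ((5.0, 5.0), (6.0, 6.0)))
        edit_points(ps, "move", (0, "image", (9.0, 9.0)))
        edit_points(ps, "undo")
        edit_points(ps, "undo")
        np.testing.assert_array_equal(ps.atlas_xy, orig[0])
        np.testing.assert_array_equal(ps.image_xy, orig[1])

    def test_undo_on_empty_history_rejected(self):
        with pytest.raises(IndexError, match="empty history"):
            edit_points(self.make_ps(), "undo")

    def test_bad_index_rejected(self):
        with pytest.raises(IndexError):
            edit_points(self.make_ps(), "remove", 17)

    @given(
        actions=st.lists(
            st.sampled_from(["add", "remove", "move"]), min_size=1, max_size=12
        ),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=50, deadline=None)
    def test_edits_then_equal_undos_restore(self, actions, seed):
        rng = np.random.default_rng(seed)
        ps = self.make_ps(8)
        orig = (ps.atlas_xy.copy(), ps.image_xy.copy())
        applied = 0
        for action in actions:
            if action == "add":
                edit_points(
                    ps, "add",
                    (tuple(rng.uniform(0, 10, 2)), tuple(rng.uniform(0, 10, 2))),
                )
            elif action == "remove":
                if len(ps) == 0:
                    continue
                edit_points(ps, "remove", int(rng.integers(len(ps))))
            else:
                if len(ps) == 0:
                    continue
                edit_points(
                    ps, "move",
                    (int(rng.integers(len(ps))),
                     rng.choice(["atlas", "image"]),
                     tuple(rng.uniform(0, 10, 2))),
                )
            applied += 1
        for _ in range(applied):
            edit_points(ps, "undo")
        np.testing.assert_array_equal(ps.atlas_xy, orig[0])
        np.testing.assert_array_equal(ps.image_xy, orig[1])


class TestInitCorrespondence:
    def test_point_count_contract(self, small_phantom):
        plate = small_phantom["atlas"].plates[2]
        image = small_phantom["manifest"].read_plane(30)
        ps = init_correspondence(image, plate, n_points=32)
        assert len(ps) == 32

    def test_self_rendering_pairs_nearly_coincide(self, small_phantom):
        plate = small_phantom["atlas"].plates[2]
        image = small_phantom["manifest"].read_plane(30)
        ps = init_correspondence(image, plate, n_points=32)
        delta = ps.atlas_xy - ps.image_xy
        aligned = delta - delta.mean(axis=0)  # after centroid alignment
        d = np.hypot(aligned[:, 0], aligned[:, 1])
        # same ellipse geometry in image and plate, so the residual is just
        # rasterisation: every pair coincides to about a pixel
        assert d.max() <= 1.0

    def test_clockwise_cyclic_order_on_both_curves(self, small_phantom):
        plate = small_phantom["atlas"].plates[2]
        image = small_phantom["manifest"].read_plane(30)
        ps = init_correspondence(image, plate, n_points=24)
        for pts in (ps.atlas_xy, ps.image_xy):
            c = pts.mean(axis=0)
            ang = np.unwrap(np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0]))
            assert np.all(np.diff(ang) > 0)  # monotone angle = consistent

    def test_blank_image_rejected(self, small_phantom):
        plate = small_phantom["atlas"].plates[0]
        with pytest.raises(RegistrationError):
            init_correspondence(np.zeros((64, 64)), plate)


class TestRegiLoop:
    def test_registers_all_plates_with_small_residual(self, small_phantom):
        atlas = small_phantom["atlas"]
        truth = small_phantom["truth"]
        n = small_phantom["spec"].n_planes
        amap = AlignmentMap(
            n, 2.5,
            [APAnchor(0, float(truth.true_ap[0])),
             APAnchor(n - 1, float(truth.true_ap[-1]))],
        )
        warps = regi_loop(
            small_phantom["manifest"], amap, atlas, atlas.plate_aps
        )
        assert sorted(warps) == sorted(atlas.plate_aps)
        for w in warps.values():
            resid = np.hypot(
                *(w.transform(w.control_image) - w.control_atlas).T
            )
            assert resid.mean() <= 1.0

    def test_resume_skips_saved_plates(self, small_phantom, tmp_path):
        atlas = small_phantom["atlas"]
        truth = small_phantom["truth"]
        n = small_phantom["spec"].n_planes
        amap = AlignmentMap(
            n, 2.5,
            [APAnchor(0, float(truth.true_ap[0])),
             APAnchor(n - 1, float(truth.true_ap[-1]))],
        )
        first_two = atlas.plate_aps[:2]
        regi_loop(
            small_phantom["manifest"], amap, atlas, first_two,
            save_dir=tmp_path,
        )
        calls = []

        def counting_corrector(ps, image, plate):
            calls.append(plate.ap_mm)
            return ps

        warps = regi_loop(
            small_phantom["manifest"], amap, atlas, atlas.plate_aps,
            counting_corrector, save_dir=tmp_path,
        )
        assert sorted(warps) == sorted(atlas.plate_aps)
        assert sorted(calls) == sorted(atlas.plate_aps[2:])  # saved skipped
        assert len(list(tmp_path.glob("plate_*.warp"))) == len(atlas.plate_aps)

    def test_aborting_corrector_skips_plate(self, small_phantom, tmp_path):
        atlas = small_phantom["atlas"]
        truth = small_phantom["truth"]
        n = small_phantom["spec"].n_planes
        amap = AlignmentMap(
            n, 2.5,
            [APAnchor(0, float(truth.true_ap[0])),
             APAnchor(n - 1, float(truth.true_ap[-1]))],
        )
        skip_ap = atlas.plate_aps[1]

        def picky(ps, image, plate):
            return None if plate.ap_mm == skip_ap else ps

        warps = regi_loop(
            small_phantom["manifest"], amap, atlas, atlas.plate_aps, picky
        )
        assert skip_ap not in warps
        assert len(warps) == len(atlas.plate_aps) - 1
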