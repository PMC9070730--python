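"""AP interpolation, the choice game, midpoint checks and morph diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainplane.alignment import (
    AlignmentMap,
    APAnchor,
    ChoiceGameConfig,
    choice_game,
    interpolate_ap,
    linear_prediction_error,
    midpoint_check,
    morph_profile,
    refine_alignment,
)
from brainplane.errors import MonotonicityError
from brainplane.phantom import morph_curve, oracle_chooser, random_morph


def endpoint_map(true_ap, z_step_um=2.5):
    n = len(true_ap)
    return AlignmentMap(
        n, z_step_um,
        anchors=[APAnchor(0, float(true_ap[0])),
                 APAnchor(n - 1, float(true_ap[-1]))],
    )


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------


class TestInterpolateAP:
    def test_exact_at_anchor(self):
        amap = AlignmentMap(101, 2.5, [APAnchor(0, 3.2), APAnchor(100, 0.0)])
        assert interpolate_ap(amap, 0) == 3.2

    def test_linear_midpoint(self):
        amap = AlignmentMap(101, 2.5, [APAnchor(0, 2.0), APAnchor(100, 0.0)])
        assert interpolate_ap(amap, 50) == pytest.approx(1.0)

    def test_bracketing_segment(self):
        amap = AlignmentMap(
            101, 2.5,
            [APAnchor(0, 2.0), APAnchor(40, 1.0), APAnchor(100, 0.0)],
        )
        # z=70 lies halfway through the (40, 100) segment: 1.0 -> 0.0
        assert interpolate_ap(amap, 70) == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        amap = AlignmentMap(101, 2.5, [APAnchor(0, 2.0), APAnchor(100, 0.0)])
        with pytest.raises(IndexError):
            interpolate_ap(amap, 101)

    def test_endpoints_required_before_interpolation(self):
        amap = AlignmentMap(101, 2.5, [APAnchor(0, 2.0), APAnchor(50, 1.0)])
        with pytest.raises(MonotonicityError, match="endpoints"):
            amap.interpolate(25)

    @given(
        n=st.integers(min_value=10, max_value=400),
        seed=st.integers(min_value=0, max_value=2**16),
        k=st.integers(min_value=0, max_value=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_strictly_decreasing_for_any_valid_map(self, n, seed, k):
        rng = np.random.default_rng(seed)
        interior_z = rng.choice(np.arange(1, n - 1), size=min(k, n - 2),
                                replace=False)
        zs = np.concatenate([[0], np.sort(interior_z), [n - 1]]).astype(int)
        aps = np.sort(rng.uniform(-4.0, 2.0, len(zs)))[::-1]
        if len(np.unique(aps)) < len(aps):
            return
        amap = AlignmentMap(
            n, 2.5, [APAnchor(int(z), float(a)) for z, a in zip(zs, aps)]
        )
        out = amap.all_plane_aps()
        assert np.all(np.diff(out) < 0)

    def test_monotonicity_violations_rejected(self):
        amap = AlignmentMap(101, 2.5, [APAnchor(0, 2.0), APAnchor(100, 0.0)])
        amap.add_anchor(APAnchor(50, 1.0, "choice_game"))
        with pytest.raises(MonotonicityError):
            amap.add_anchor(APAnchor(60, 1.5, "choice_game"))
        with pytest.raises(MonotonicityError):
            amap.add_anchor(APAnchor(40, 0.5, "choice_game"))


# ---------------------------------------------------------------------------
# choice game
# ---------------------------------------------------------------------------


class AlwaysMiddle:
    def __init__(self):
        self.presented = []

    def choose(self, left, middle, right, reference_ap, context):
        self.presented.append((left, middle, right))
        return "middle"

    def accept_midpoint(self, z_index, ap_mm, context):
        return True


class TestChoiceGame:
    def test_middle_chooser_fixed_point(self):
        true_ap = morph_curve(500, 1.0, -0.25)
        amap = endpoint_map(true_ap)
        chooser = AlwaysMiddle()
        initial = amap.plane_at_ap(0.4)
        anchor = choice_game(amap, 0.4, chooser, ChoiceGameConfig())
        assert anchor.z_index == initial
        assert len(chooser.presented) == 4  # one cycle per schedule level
        assert anchor.source == "choice_game"
        assert anchor.ap_mm == 0.4

    def test_default_schedule_spacings_in_order(self):
        true_ap = morph_curve(600, 1.0, -0.5)
        amap = endpoint_map(true_ap)
        chooser = AlwaysMiddle()
        choice_game(amap, 0.25, chooser, ChoiceGameConfig())
        spacings = [m - l for l, m, r in chooser.presented]
        assert spacings == [200, 100, 30, 10]

    def test_truthful_chooser_lands_within_finest_step(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            true_ap = random_morph(rng, 300, 0.40, -0.35)
            ref = rng.uniform(true_ap[-1] + 0.05, true_ap[0] - 0.05)
            amap = endpoint_map(true_ap)
            anchor = choice_game(
                amap, ref, oracle_chooser(true_ap), ChoiceGameConfig()
            )
            true_plane = int(np.argmin(np.abs(true_ap - ref)))
            assert abs(anchor.z_index - true_plane) <= 10

    def test_call_bound_at_whole_brain_scale(self):
        # with n_planes >> coarsest step and an interpolation-based initial
        # guess, a truthful game stays within n/s0 + len(schedule) calls
        rng = np.random.default_rng(7)
        cfg = ChoiceGameConfig()
        n = 2400
        bound = n / cfg.step_schedule[0] + len(cfg.step_schedule)
        for _ in range(10):
            true_ap = random_morph(rng, n, 2.2, -4.2, amp_range_mm=(0.1, 0.3))
            ref = rng.uniform(true_ap[-1] + 0.3, true_ap[0] - 0.3)
            amap = endpoint_map(true_ap)
            chooser = oracle_chooser(true_ap)
            choice_game(amap, ref, chooser, cfg)
            assert chooser.n_choose_calls <= bound

    def test_reference_outside_endpoint_range_rejected(self):
        amap = endpoint_map(morph_curve(100, 1.0, 0.0))
        with pytest.raises(ValueError, match="strictly inside"):
            choice_game(amap, 1.5, AlwaysMiddle(), ChoiceGameConfig())

    def test_violating_choice_reprompted_then_errors(self):
        # an anchor at plane 50 blocks posterior-of-50 planes from carrying
        # a more anterior AP; a chooser that insists raises after re-prompt
        true_ap = morph_curve(300, 1.0, -0.5)
        amap = endpoint_map(true_ap)
        amap.add_anchor(APAnchor(50, 0.75, "choice_game"))

        class InsistRight:
            def __init__(self):
                self.calls = 0

            def choose(self, left, middle, right, reference_ap, context):
                self.calls += 1
                return "right"

            def accept_midpoint(self, *a):
                return True

        chooser = InsistRight()
        with pytest.raises(MonotonicityError, match="insists"):
            # reference AP anterior to anchor at plane 50: the true plane is
            # < 50, moving right far enough must violate
            choice_game(
                amap, 0.8, chooser,
                ChoiceGameConfig(step_schedule=(100, 10)),
            )
        assert chooser.calls >= 2  # was re-prompted before giving up


# ---------------------------------------------------------------------------
# midpoint check
# ---------------------------------------------------------------------------


class TestMidpointCheck:
    def test_accept_all_leaves_map_unchanged(self):
        true_ap = morph_curve(300, 0.4, -0.35, bump_amp_mm=0.1)
        amap = endpoint_map(true_ap)
        choice_game(amap, 0.0, oracle_chooser(true_ap), ChoiceGameConfig())
        anchors_before = list(amap.anchors)
        midpoint_check(amap, None, AlwaysMiddle(), ChoiceGameConfig())
        assert amap.anchors == anchors_before

    def test_single_rejection_adds_one_anchor(self):
        true_ap = morph_curve(300, 0.4, -0.35, bump_amp_mm=0.1)
        amap = endpoint_map(true_ap)
        oracle = oracle_chooser(true_ap, ap_tol_mm=0.025)

        class RejectFirst:
            def __init__(self):
                self.asked = 0

            def choose(self, *a):
                return oracle.choose(*a)

            def accept_midpoint(self, z_index, ap_mm, context):
                self.asked += 1
                return self.asked > 1

        before = len(amap.anchors)
        midpoint_check(amap, None, RejectFirst(), ChoiceGameConfig())
        assert len(amap.anchors) == before + 1
        assert amap.anchors[1].source == "midpoint_check"

    def test_error_profile_does_not_worsen(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            true_ap = random_morph(rng, 400, 0.5, -0.5)
            amap = endpoint_map(true_ap)
            oracle = oracle_chooser(true_ap, ap_tol_mm=0.01)
            ref = rng.uniform(true_ap[-1] + 0.1, true_ap[0] - 0.1)
            choice_game(amap, ref, oracle, ChoiceGameConfig())
            err_before = np.max(np.abs(amap.all_plane_aps() - true_ap))
            midpoint_check(amap, None, oracle, ChoiceGameConfig())
            err_after = np.max(np.abs(amap.all_plane_aps() - true_ap))
            assert err_after <= err_before + 1e-12

    def test_refinement_converges(self):
        true_ap = morph_curve(400, 0.5, -0.5, bump_amp_mm=0.15)
        amap = endpoint_map(true_ap)
        oracle = oracle_chooser(true_ap, ap_tol_mm=0.02)
        refine_alignment(amap, None, oracle, ChoiceGameConfig())
        # every surviving midpoint is now inside tolerance
        for a, b in zip(amap.anchors, amap.anchors[1:]):
            if b.z_index - a.z_index < 2:
                continue
            zm = (a.z_index + b.z_index) // 2
            assert abs(amap.interpolate(zm) - true_ap[zm]) <= 0.02 + 1e-12


# ---------------------------------------------------------------------------
# morph profile and linear error
# ---------------------------------------------------------------------------


class TestMorphProfile:
    def test_uniform_anchors_all_ratio_one(self):
        amap = AlignmentMap(
            301, 2.5,
            [APAnchor(z, 1.0 - z / 300.0) for z in (0, 100, 200, 300)],
        )
        prof = morph_profile(amap)
        assert [i.morph_ratio for i in prof.intervals] == pytest.approx(
            [1.0, 1.0, 1.0]
        )

    def test_two_interval_ratios_by_hand(self):
        # equal |dAP| but 100 vs 300 planes -> ratios 0.5 and 1.5
        amap = AlignmentMap(
            401, 2.5,
            [APAnchor(0, 2.0), APAnchor(100, 1.0), APAnchor(400, 0.0)],
        )
        prof = morph_profile(amap)
        ratios = [i.morph_ratio for i in prof.intervals]
        assert ratios == pytest.approx([0.5, 1.5])

    def test_single_interval_self_normalizes(self):
        amap = AlignmentMap(101, 2.5, [APAnchor(0, 2.0), APAnchor(100, 0.3)])
        prof = morph_profile(amap)
        assert prof.intervals[0].morph_ratio == pytest.approx(1.0)

    @given(
        seed=st.integers(min_value=0, max_value=2**16),
        k=st.integers(min_value=0, max_value=10),
    )
    @settings(max_examples=80, deadline=None)
    def test_weighted_mean_is_one(self, seed, k):
        rng = np.random.default_rng(seed)
        n = 500
        interior = rng.choice(np.arange(1, n - 1), size=k, replace=False)
        zs = np.concatenate([[0], np.sort(interior), [n - 1]]).astype(int)
        aps = np.sort(rng.uniform(-4, 2, len(zs)))[::-1]
        if len(np.unique(aps)) < len(aps):
            return
        amap = AlignmentMap(
            n, 2.5, [APAnchor(int(z), float(a)) for z, a in zip(zs, aps)]
        )
        assert morph_profile(amap).weighted_mean() == pytest.approx(
            1.0, abs=1e-9
        )


class TestLinearPredictionError:
    def test_endpoint_only_map_has_zero_error(self):
        amap = AlignmentMap(201, 2.5, [APAnchor(0, 1.0), APAnchor(200, -1.0)])
        table = linear_prediction_error(amap)
        assert np.allclose(table["error_um"], 0.0)

    def test_quadratic_morph_matches_analytic_difference(self):
        # true AP = linear + quadratic term vanishing at both ends
        n = 201
        z = np.arange(n)
        t = z / (n - 1)
        true_ap = 1.0 - 2.0 * t - 0.2 * t * (1 - t)
        amap = AlignmentMap(
            n, 2.5,
            [APAnchor(0, float(true_ap[0])),
             APAnchor(50, float(true_ap[50])),
             APAnchor(100, float(true_ap[100])),
             APAnchor(150, float(true_ap[150])),
             APAnchor(200, float(true_ap[-1]))],
        )
        table = linear_prediction_error(amap)
        linear = 1.0 - 2.0 * t
        expected_at_anchor = (true_ap - linear) * 1000.0
        for zi in (0, 50, 100, 150, 200):
            got = float(table.loc[table["z_index"] == zi, "error_um"].iloc[0])
            assert got == pytest.approx(expected_at_anchor[zi], abs=1e-6)

    def test_sign_convention_posterior_anchor_negative(self):
        # the interior anchor sits more posterior (smaller AP) than its
        # linear prediction of 0.0 -> negative error there
        amap = AlignmentMap(
            201, 2.5,
            [APAnchor(0, 1.0), APAnchor(100, -0.2), APAnchor(200, -1.0)],
        )
        table = linear_prediction_error(amap)
        assert float(table.loc[100, "error_um"]) == pytest.approx(-200.0)
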