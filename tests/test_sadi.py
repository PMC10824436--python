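"""SADI geometry: landmarks, segment regression angle, cohort LLN, flagging."""

import math

import numpy as np
import pytest

from pftinterp import (
    CohortNorm,
    DegenerateCurveError,
    FlowVolumeCurve,
    InsufficientDataError,
    InterpretationResult,
    Obstruction,
    PFTRecord,
    Restriction,
    Dlco,
    SmallAirway,
    compute_sadi,
    derive_lln,
    flag_small_airway,
    interpret_record,
    locate_landmarks,
)
from pftinterp.sadi import _fit_slope

from conftest import make_triangle_curve


def vector_angle_oracle(slope_ab: float, slope_bc: float) -> float:
    """Independent check: interior angle at B between direction vectors of the
    two fitted lines, via the dot product."""
    u = np.array([-1.0, -slope_ab])  # direction B -> A
    w = np.array([1.0, slope_bc])  # direction B -> C
    cos = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
    return math.degrees(math.acos(np.clip(cos, -1, 1)))


class TestLandmarks:
    def test_triangle_closed_form(self, triangle_curve):
        lm = locate_landmarks(triangle_curve)
        assert lm.a == (pytest.approx(0.4), pytest.approx(8.0))
        assert lm.b[0] == pytest.approx(0.75 * 4.0)
        # B's flow lies on the straight descent from (0.4, 8) to (4, 0)
        assert lm.b[1] == pytest.approx(8.0 * (4.0 - 3.0) / (4.0 - 0.4))
        assert lm.c == (pytest.approx(4.0), 0.0)

    def test_zero_crossing_interpolated_between_samples(self):
        v = np.linspace(0, 1.9, 20)
        f = 4.0 - 2.7 * v  # crosses zero at v = 4/2.7, between grid samples
        f[0] = 0.5  # make index 1 the peak, keep v[0] = 0 start
        curve = FlowVolumeCurve("z", v, f)
        lm = locate_landmarks(curve)
        assert lm.c[0] == pytest.approx(4.0 / 2.7)
        assert lm.c[1] == 0.0

    def test_monotonically_rising_curve_is_degenerate(self):
        v = np.linspace(0, 4, 20)
        with pytest.raises(DegenerateCurveError, match="descending"):
            locate_landmarks(FlowVolumeCurve("m", v, v**2))

    def test_peak_after_75pct_vc_is_degenerate(self):
        v = np.linspace(0, 4, 40)
        f = np.where(v <= 3.6, v, 9 * (4 - v))  # peak at 90 % of VC
        with pytest.raises(DegenerateCurveError):
            locate_landmarks(FlowVolumeCurve("late", v, f))

    def test_first_peak_wins_on_ties(self):
        v = np.linspace(0, 4, 41)
        f = np.minimum(5.0, 50 * np.minimum(v, 4 - v))  # plateau at 5.0
        lm = locate_landmarks(FlowVolumeCurve("tie", v, f))
        assert lm.a[0] == pytest.approx(v[np.argmax(f == 5.0)])


class TestComputeSadi:
    def test_collinear_descent_gives_180(self, triangle_curve):
        assert compute_sadi(triangle_curve).angle_deg == pytest.approx(180.0, abs=1e-9)

    def test_piecewise_limb_matches_vector_geometry_oracle(self):
        # descent slope -2.0 until 75 % VC, then -0.2 down to the axis; the
        # kink sits at 0.75 * VC when both legs meet there:
        # 8 - 2 (0.75 vc - 0.4) = 0.2 (vc - 0.75 vc)  =>  vc = 8.8 / 1.55
        vc = 8.8 / 1.55
        vb = 0.75 * vc
        grid = np.unique(np.concatenate([np.linspace(0, vc, 111), [0.4, vb]]))
        f = np.where(
            grid <= 0.4,
            20.0 * grid,
            np.where(grid <= vb, 8.0 - 2.0 * (grid - 0.4), 0.2 * (vc - grid)),
        )
        res = compute_sadi(FlowVolumeCurve("pw", grid, f))
        assert res.slope_ab == pytest.approx(-2.0, abs=1e-9)
        assert res.slope_bc == pytest.approx(-0.2, abs=1e-9)
        expected = 180 - abs(math.degrees(math.atan(-2.0)) - math.degrees(math.atan(-0.2)))
        assert expected == pytest.approx(127.8749836510982)
        assert res.angle_deg == pytest.approx(expected, abs=1e-9)
        assert res.angle_deg == pytest.approx(vector_angle_oracle(-2.0, -0.2), abs=1e-9)

    def test_similarity_invariance_under_uniform_rescale(self, triangle_curve):
        base = make_triangle_curve(vc=4.0, pef=6.0, peak_frac=0.12)
        scaled = FlowVolumeCurve("s", base.volume * 3.0, base.flow * 3.0)
        assert compute_sadi(scaled).angle_deg == pytest.approx(
            compute_sadi(base).angle_deg, abs=1e-9
        )

    def test_fit_slope_invariant_under_volume_translation(self):
        v = np.array([1.0, 2.0, 3.0, 4.5])
        f = np.array([5.0, 3.5, 3.0, 1.0])
        assert _fit_slope(v + 7.3, f) == pytest.approx(_fit_slope(v, f), abs=1e-12)

    def test_aspect_changes_angle(self):
        curve = _kinked_curve()
        a1 = compute_sadi(curve, aspect=1.0).angle_deg
        a2 = compute_sadi(curve, aspect=2.0).angle_deg
        assert a1 != pytest.approx(a2, abs=1e-6)

    def test_insufficient_segment_points_named(self):
        # only 2 samples fall between A and B
        v = np.concatenate([[0.0, 0.1], np.linspace(3.2, 4.0, 9)])
        f = np.concatenate([[0.0, 8.0], np.linspace(1.0, 0.0, 9)])
        with pytest.raises(InsufficientDataError, match="A-B"):
            compute_sadi(FlowVolumeCurve("few", v, f), min_segment_points=4)


def _kinked_curve():
    vc = 8.8 / 1.55
    vb = 0.75 * vc
    grid = np.unique(np.concatenate([np.linspace(0, vc, 111), [0.4, vb]]))
    f = np.where(
        grid <= 0.4,
        20.0 * grid,
        np.where(grid <= vb, 8.0 - 2.0 * (grid - 0.4), 0.2 * (vc - grid)),
    )
    return FlowVolumeCurve("kink", grid, f)


class TestDeriveLln:
    def test_published_moments_reproduce_lln(self):
        norm = CohortNorm.from_moments(mean=156.5, sd=16.9, multiplier=1.64)
        assert round(norm.lln, 1) == 128.8

    def test_constant_sample_lln_equals_mean(self):
        norm = derive_lln([150.0] * 5)
        assert norm.sd == 0.0
        assert norm.lln == norm.mean == 150.0

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(150, 10, 200)
        n0, n1 = derive_lln(x), derive_lln(x + 7.0)
        assert n1.mean == pytest.approx(n0.mean + 7.0)
        assert n1.sd == pytest.approx(n0.sd)
        assert n1.lln == pytest.approx(n0.lln + 7.0)

    def test_monte_carlo_recovery_from_4711_draws(self):
        rng = np.random.default_rng(20180301)
        norm = derive_lln(rng.normal(156.5, 16.9, size=4711))
        assert norm.lln == pytest.approx(128.8, abs=1.0)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(InsufficientDataError):
            derive_lln([150.0])


class TestFlagSmallAirway:
    norm = CohortNorm.from_moments(156.5, 16.9)

    def _result(self, obstruction):
        return InterpretationResult(
            "r", obstruction, Restriction.NOT_RESTRICTED, Dlco.NORMAL
        )

    def _sadi(self, angle):
        res = compute_sadi(make_triangle_curve())
        object.__setattr__(res, "angle_deg", angle)
        return res

    @pytest.mark.parametrize(
        "obstruction, angle, expected",
        [
            (Obstruction.NOT_OBSTRUCTED, 120.0, SmallAirway.FLAGGED),
            (Obstruction.NOT_OBSTRUCTED, 128.8, SmallAirway.NOT_FLAGGED),  # strict "<"
            (Obstruction.NOT_OBSTRUCTED, 170.0, SmallAirway.NOT_FLAGGED),
            (Obstruction.OBSTRUCTED, 100.0, SmallAirway.NOT_ASSESSABLE),
            (Obstruction.NOT_ASSESSABLE, 100.0, SmallAirway.NOT_ASSESSABLE),
        ],
    )
    def test_flag_rule(self, obstruction, angle, expected):
        # explicit lln so the 128.8-equality boundary case is exact
        norm = CohortNorm(n=0, mean=156.5, sd=16.9, lln=128.8)
        assert flag_small_airway(self._result(obstruction), self._sadi(angle), norm) is expected

    def test_absent_curve_not_assessable(self):
        assert (
            flag_small_airway(self._result(Obstruction.NOT_OBSTRUCTED), None, self.norm)
            is SmallAirway.NOT_ASSESSABLE
        )

    def test_end_to_end_flag_on_record(self):
        rec = PFTRecord("r", fev1_fvc_ratio=0.80)
        res = interpret_record(rec)
        sres = compute_sadi(make_triangle_curve())  # 180 degrees
        assert flag_small_airway(res, sres, self.norm) is SmallAirway.NOT_FLAGGED
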