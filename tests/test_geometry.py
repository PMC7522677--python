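"""Ellipsoid section areas: closed forms vs summation vs quadrature."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microtese.geometry import (
    DomainError,
    NonIntegerRatioError,
    PlaneOrientation,
    TestisEllipsoid,
    ellipsoid_volume,
    half_cross_section_area,
    plane_section_area_quadrature,
    slice_face_sum_closed,
    slice_face_sum_direct,
)

T = PlaneOrientation.TRANSVERSE
S = PlaneOrientation.SAGITTAL
C = PlaneOrientation.CORONAL

ratio_triples = st.tuples(
    st.integers(1, 8), st.integers(1, 8), st.integers(1, 8)
).map(lambda t: tuple(sorted(t, reverse=True)))


class TestHalfCrossSection:
    @pytest.mark.parametrize(
        "abc_l, orient, index, expected",
        [
            ((2, 1, 1, 1), T, 0, math.pi / 2),  # central section of the long axis
            ((2, 1, 1, 1), T, 2, 0.0),  # pole section degenerates to a point
            ((3, 2, 1, 1), S, 1, 9 * math.pi / 8),
            ((3, 2, 1, 1), T, 1, math.pi * 2 * 1 * 8 / (2 * 9)),
        ],
    )
    def test_known_sections(self, abc_l, orient, index, expected):
        t = TestisEllipsoid(*abc_l)
        assert half_cross_section_area(t, orient, index) == pytest.approx(
            expected, abs=1e-12
        )

    def test_out_of_range_index_names_valid_range(self):
        t = TestisEllipsoid(3, 2, 1, l=1)
        with pytest.raises(DomainError, match=r"\[-3, 3\]"):
            half_cross_section_area(t, T, 4)
        with pytest.raises(DomainError, match=r"\[-2, 2\]"):
            half_cross_section_area(t, S, -3)

    @settings(max_examples=60, derandomize=True)
    @given(abc=ratio_triples, orient=st.sampled_from(list(PlaneOrientation)),
           index=st.integers(-8, 8))
    def test_even_in_index(self, abc, orient, index):
        t = TestisEllipsoid(*abc, l=1.5)
        r = t.ratio_along(orient)
        if abs(index) > r:
            return
        plus = half_cross_section_area(t, orient, index)
        minus = half_cross_section_area(t, orient, -index)
        assert plus == pytest.approx(minus, rel=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(abc=ratio_triples, orient=st.sampled_from(list(PlaneOrientation)))
    def test_strictly_decreasing_in_abs_index(self, abc, orient):
        t = TestisEllipsoid(*abc, l=1.0)
        r = int(t.ratio_along(orient))
        areas = [half_cross_section_area(t, orient, i) for i in range(r + 1)]
        assert all(a > b for a, b in zip(areas, areas[1:]))
        assert areas[-1] == 0.0

    @settings(max_examples=40, derandomize=True)
    @given(abc=ratio_triples, scale=st.sampled_from([0.5, 2.0, 2.5]))
    def test_areas_scale_as_l_squared(self, abc, scale):
        base = TestisEllipsoid(*abc, l=1.0)
        scaled = TestisEllipsoid(*abc, l=scale)
        for orient in PlaneOrientation:
            assert slice_face_sum_direct(scaled, orient) == pytest.approx(
                scale**2 * slice_face_sum_direct(base, orient), rel=1e-12
            )
        assert ellipsoid_volume(scaled) == pytest.approx(
            scale**3 * ellipsoid_volume(base), rel=1e-12
        )


class TestQuadratureOracle:
    """The implicit-equation quadrature is the independent check on every closed form."""

    def test_central_circle(self):
        t = TestisEllipsoid(2, 1, 1, l=1)
        assert plane_section_area_quadrature(t, T, 0, 1024) == pytest.approx(
            math.pi, rel=1e-6
        )

    def test_matches_closed_half_area(self):
        t = TestisEllipsoid(3, 2, 1, l=1)
        got = plane_section_area_quadrature(t, T, 1, 1024)
        assert got == pytest.approx(math.pi * 2 * 8 / 9, rel=1e-6)

    def test_pole_section_is_zero(self):
        for abc in [(3, 2, 1), (5, 4, 2)]:
            t = TestisEllipsoid(*abc, l=1)
            assert plane_section_area_quadrature(t, T, abc[0], 128) == pytest.approx(
                0.0, abs=1e-3
            )

    @pytest.mark.parametrize("orient", list(PlaneOrientation))
    @pytest.mark.parametrize("abc_l", [(3, 2, 1, 1.0), (5, 3, 2, 2.5), (4, 4, 1, 0.5)])
    def test_oracle_equivalence_grid(self, abc_l, orient):
        t = TestisEllipsoid(*abc_l[:3], l=abc_l[3])
        r = int(t.ratio_along(orient))
        for index in range(r):
            closed = 2 * half_cross_section_area(t, orient, index)
            quad = plane_section_area_quadrature(t, orient, index, 1024)
            assert quad == pytest.approx(closed, rel=1e-4)

    def test_resolution_floor_enforced(self):
        t = TestisEllipsoid(2, 1, 1, l=1)
        with pytest.raises(ValueError, match="resolution"):
            plane_section_area_quadrature(t, T, 0, 32)


class TestSliceFaceSums:
    @pytest.mark.parametrize(
        "abc_l, orient, expected",
        [
            ((1, 1, 1, 1), T, 2 * math.pi),  # single central cut of a unit sphere
            ((2, 1, 1, 1), T, 5 * math.pi),
            ((3, 2, 1, 1), T, 140 * math.pi / 9),
            ((3, 2, 1, 1), S, 15 * math.pi),
        ],
    )
    def test_known_sums_both_routes(self, abc_l, orient, expected):
        t = TestisEllipsoid(*abc_l)
        assert slice_face_sum_direct(t, orient) == pytest.approx(expected, rel=1e-12)
        assert slice_face_sum_closed(t, orient) == pytest.approx(expected, rel=1e-12)

    def test_closed_equals_direct_exhaustively(self):
        for a in range(1, 13):
            for b in range(1, a + 1):
                for c in range(1, b + 1):
                    for l in (0.5, 1.0, 2.5):
                        t = TestisEllipsoid(a, b, c, l=l)
                        for orient in PlaneOrientation:
                            closed = slice_face_sum_closed(t, orient)
                            direct = slice_face_sum_direct(t, orient)
                            assert abs(closed - direct) <= 1e-9 * direct

    def test_generalized_mode_non_integer_ratios(self):
        t = TestisEllipsoid(2.5, 1.6, 1.2, l=1.0, strict=False)
        # lattice cuts strictly inside: |x| <= 2, |y| <= 1, |z| <= 1
        expected = sum(
            4 * half_cross_section_area(t, T, i) for i in (-2, -1, 0, 1, 2)
        )
        assert slice_face_sum_direct(t, T) == pytest.approx(expected, rel=1e-12)
        with pytest.raises(NonIntegerRatioError, match="generalized"):
            slice_face_sum_closed(t, T)

    def test_strict_mode_rejects_non_integer_ratios(self):
        with pytest.raises(NonIntegerRatioError, match="strict"):
            TestisEllipsoid(2.5, 1.5, 1.0, l=1.0)


class TestContinuumLimit:
    def test_slice_sum_times_width_approaches_twice_volume(self):
        """With A, B, C fixed, sum(4S)*l -> 2V as l -> 0 (two faces per slice)."""
        A, B, C = 1.0, 0.8, 0.6
        errors = []
        for a in (10, 20, 40, 80):
            l = A / a
            t = TestisEllipsoid(a, round(B / l), round(C / l), l=l, strict=False)
            target = 2 * ellipsoid_volume(t)
            got = slice_face_sum_direct(t, PlaneOrientation.TRANSVERSE) * l
            errors.append(abs(got - target) / target)
        assert all(e2 < e1 for e1, e2 in zip(errors, errors[1:]))
        assert errors[-1] < 1e-3


class TestEllipsoidVolume:
    @pytest.mark.parametrize(
        "abc_l, expected",
        [
            ((1, 1, 1, 1), 4 * math.pi / 3),
            ((3, 2, 1, 1), 8 * math.pi),
            ((3, 2, 1, 0.5), math.pi),
        ],
    )
    def test_known_volumes(self, abc_l, expected):
        assert ellipsoid_volume(TestisEllipsoid(*abc_l)) == pytest.approx(expected)


class TestInvariantValidation:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError, match="a >= b >= c"):
            TestisEllipsoid(1, 2, 3, l=1)

    def test_positive_lengths_enforced(self):
        with pytest.raises(ValueError):
            TestisEllipsoid(3, 2, 1, l=0)
        with pytest.raises(ValueError):
            TestisEllipsoid(3, 2, 0, l=1)
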