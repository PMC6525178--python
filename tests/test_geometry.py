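"""Spherical-cap truncation geometry: closed forms, symmetry, monotonicity."""

import math

import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from fishsection.geometry import (
    SectionSpec,
    cap_volume,
    enumeration_window,
    fraction_full_diameter,
    fraction_full_volume_given_image,
    fraction_image_at_least,
    fraction_volume_at_least_given_image,
    image_diameter_fraction,
    mean_retained_volume,
    retained_volume,
    retention_probability,
    sphere_volume,
)

PI = math.pi

# frozen retention probabilities at d=3, c=0.8 (quadrature-verified)
P_T2 = 0.5149473684210526
P_T4 = 0.6822068965517241
P_T6 = 0.7636923076923077


class TestSphereAndCap:
    @pytest.mark.parametrize(
        "d, expected",
        [(3.0, 4.5 * PI), (2.0, 4.0 / 3.0 * PI), (0.0, 0.0)],
    )
    def test_sphere_volume(self, d, expected):
        assert sphere_volume(d) == pytest.approx(expected, rel=1e-12)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            sphere_volume(-1.0)

    @pytest.mark.parametrize(
        "x, d, expected",
        [
            (0.0, 3.0, 0.0),
            (3.0, 3.0, 4.5 * PI),  # cap height = d recovers the full sphere
            (1.5, 3.0, 2.25 * PI),  # half sphere by symmetry
        ],
    )
    def test_cap_volume(self, x, d, expected):
        assert cap_volume(x, d) == pytest.approx(expected, abs=1e-12)

    def test_cap_out_of_range(self):
        with pytest.raises(ValueError):
            cap_volume(3.5, 3.0)
        with pytest.raises(ValueError):
            cap_volume(-0.1, 3.0)

    @given(st.floats(0.01, 2.99), st.floats(0.011, 3.0))
    @settings(derandomize=True, max_examples=50)
    def test_cap_monotone_in_height(self, x1, x2):
        lo, hi = sorted((x1, x2))
        assert cap_volume(lo, 3.0) <= cap_volume(hi, 3.0) + 1e-12


class TestRetainedVolume:
    @pytest.mark.parametrize(
        "x, t, expected",
        [
            (1.0, 4.0, (1.5 - 1.0 / 3.0) * PI),  # rising cap branch
            (3.5, 4.0, 4.5 * PI),  # fully inside the slab
            (2.5, 2.0, (23.0 / 6.0) * PI),  # cap(2.5) - cap(0.5), thin-section middle branch
        ],
    )
    def test_hand_derived_values(self, x, t, expected):
        assert retained_volume(x, SectionSpec(t=t)) == pytest.approx(expected, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            retained_volume(7.5, SectionSpec(t=4.0))

    @pytest.mark.parametrize("t", [1.0, 2.0, 3.0, 4.0, 8.0])
    def test_reflection_symmetry(self, t):
        spec = SectionSpec(t=t)
        span = t + spec.d
        for i in range(101):
            x = span * i / 100
            assert retained_volume(x, spec) == pytest.approx(
                retained_volume(span - x, spec), abs=1e-9
            )

    @pytest.mark.parametrize("t", [2.0, 3.0, 4.0])
    def test_continuity_at_branch_points(self, t):
        spec = SectionSpec(t=t)
        eps = 1e-9
        for b in (t, spec.d):
            lo = max(b - eps, 0.0)
            hi = min(b + eps, t + spec.d)
            assert retained_volume(lo, spec) == pytest.approx(
                retained_volume(hi, spec), abs=1e-6
            )

    def test_thick_thin_regimes_agree_at_t_equals_d(self):
        # Eq for t >= d and Eq for t < d must coincide at the boundary
        just_thick = SectionSpec(t=3.0 + 1e-9)
        just_thin = SectionSpec(t=3.0 - 1e-9)
        for x in (0.5, 1.5, 2.9, 3.1, 4.0, 5.5):
            assert retained_volume(x, just_thick) == pytest.approx(
                retained_volume(x, just_thin), abs=1e-6
            )

    def test_full_volume_plateau_requires_thick_section(self):
        spec = SectionSpec(t=5.0)
        v0 = sphere_volume(3.0)
        assert retained_volume(3.0, spec) == pytest.approx(v0)
        assert retained_volume(5.0, spec) == pytest.approx(v0)
        thin = SectionSpec(t=2.0)
        assert retained_volume(2.5, thin) < sphere_volume(3.0)


class TestEnumerationWindow:
    @pytest.mark.parametrize(
        "c, x1, x2",
        [(0.8, 0.6, 6.4), (1.0, 1.5, 5.5), (1e-9, 0.0, 7.0)],
    )
    def test_window_bounds(self, c, x1, x2):
        w = enumeration_window(SectionSpec(t=4.0, c=c))
        assert w.x1 == pytest.approx(x1, abs=1e-6)
        assert w.x2 == pytest.approx(x2, abs=1e-6)

    def test_window_widens_as_threshold_relaxes(self):
        widths = [
            enumeration_window(SectionSpec(t=4.0, c=c)).width for c in (1.0, 0.9, 0.8, 0.7)
        ]
        assert widths == sorted(widths)

    @pytest.mark.parametrize("t", [2.0, 4.0, 8.0])
    @pytest.mark.parametrize("c", [0.7, 0.8, 0.9])
    def test_image_fraction_equals_threshold_at_window_edges(self, t, c):
        spec = SectionSpec(t=t, c=c)
        w = enumeration_window(spec)
        assert image_diameter_fraction(w.x1, spec) == pytest.approx(c, abs=1e-9)
        assert image_diameter_fraction(w.x2, spec) == pytest.approx(c, abs=1e-9)

    def test_invalid_spec_rejected(self):
        for kwargs in ({"t": 0.0}, {"t": 4.0, "d": -1.0}, {"t": 4.0, "c": 0.0}, {"t": 4.0, "c": 1.1}):
            with pytest.raises(ValueError):
                SectionSpec(**kwargs)


class TestMeanVolumeAndRetention:
    @pytest.mark.parametrize(
        "t, expected_over_pi",
        [(4.0, 3.0699310344827584), (2.0, 2.3172631578947365)],
    )
    def test_mean_retained_volume_frozen(self, t, expected_over_pi):
        assert mean_retained_volume(SectionSpec(t=t)) == pytest.approx(
            expected_over_pi * PI, rel=1e-12
        )

    def test_mean_volume_limit_is_full_sphere(self):
        assert mean_retained_volume(SectionSpec(t=1e4)) == pytest.approx(
            sphere_volume(3.0), rel=1e-3
        )

    @pytest.mark.parametrize("t", range(1, 11))
    @pytest.mark.parametrize("d", [2.0, 3.0, 4.0])
    @pytest.mark.parametrize("c", [0.7, 0.8, 0.9, 1.0])
    def test_closed_form_matches_adaptive_quadrature(self, t, d, c):
        spec = SectionSpec(t=float(t), d=d, c=c)
        w = enumeration_window(spec)
        pts = [b for b in (d, float(t)) if w.x1 < b < w.x2]
        num, _ = quad(
            lambda x: retained_volume(x, spec), w.x1, w.x2, points=pts or None, limit=200
        )
        assert mean_retained_volume(spec) == pytest.approx(num / w.width, rel=1e-10)

    @pytest.mark.parametrize(
        "t, expected", [(2.0, P_T2), (4.0, P_T4), (6.0, P_T6)]
    )
    def test_retention_probability_frozen(self, t, expected):
        assert retention_probability(SectionSpec(t=t)) == pytest.approx(expected, rel=1e-12)

    def test_retention_limit(self):
        assert retention_probability(SectionSpec(t=1e4)) == pytest.approx(1.0, abs=1e-3)

    def test_retention_strictly_increasing_in_thickness(self):
        ps = [retention_probability(SectionSpec(t=t)) for t in (1, 2, 3, 4, 5, 6, 8, 10)]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_retention_nondecreasing_in_threshold(self):
        for t in (2.0, 4.0, 8.0):
            ps = [retention_probability(SectionSpec(t=t, c=c)) for c in (0.7, 0.8, 0.9, 1.0)]
            assert all(a <= b + 1e-12 for a, b in zip(ps, ps[1:]))


class TestImageDiameterFraction:
    def test_window_edge_chord(self):
        assert image_diameter_fraction(0.6, SectionSpec(t=4.0)) == pytest.approx(0.8)

    def test_centre_in_slab_gives_full_image(self):
        assert image_diameter_fraction(3.0, SectionSpec(t=4.0)) == 1.0

    def test_tangent_nucleus_has_no_image(self):
        spec = SectionSpec(t=4.0)
        assert image_diameter_fraction(7.0, spec) == 0.0
        assert image_diameter_fraction(0.0, spec) == 0.0


class TestCompleteNucleusFractions:
    """Fractions of complete / nearly complete nuclei vs section thickness."""

    @pytest.mark.parametrize("t, expected", [(2.0, 0.40), (8.0, 8.0 / 11.0)])
    def test_full_diameter_fraction(self, t, expected):
        assert fraction_full_diameter(t, 3.0) == pytest.approx(expected, rel=1e-12)

    def test_full_diameter_limit(self):
        assert fraction_full_diameter(1e6, 3.0) == pytest.approx(1.0, abs=1e-5)

    @pytest.mark.parametrize("t, expected", [(2.0, 0.76), (8.0, 9.8 / 11.0)])
    def test_image_at_least_fraction(self, t, expected):
        assert fraction_image_at_least(t, 3.0, 0.8) == pytest.approx(expected, rel=1e-12)

    def test_image_at_least_relaxed_threshold_limit(self):
        assert fraction_image_at_least(2.0, 3.0, 1e-9) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize(
        "t, expected", [(8.0, 5.0 / 9.8), (2.0, 0.0), (3.0, 0.0)]
    )
    def test_full_volume_given_image(self, t, expected):
        assert fraction_full_volume_given_image(t, 3.0, 0.8) == pytest.approx(
            expected, abs=1e-12
        )

    def test_volume_at_least_reduces_to_full_volume_at_v1(self):
        assert fraction_volume_at_least_given_image(8.0, 3.0, 0.8, 1.0) == pytest.approx(
            fraction_full_volume_given_image(8.0, 3.0, 0.8), abs=1e-9
        )

    def test_volume_at_least_derived_value(self):
        # cap-height root h ~ 0.8614 for v = 0.8 -> (t - d + 2h) / (x2 - x1)
        assert fraction_volume_at_least_given_image(8.0, 3.0, 0.8, 0.8) == pytest.approx(
            0.686, abs=5e-4
        )

    def test_volume_at_least_any_retention_qualifies(self):
        assert fraction_volume_at_least_given_image(8.0, 3.0, 0.8, 1e-9) == pytest.approx(
            1.0, abs=1e-3
        )

    def test_thin_section_has_no_high_volume_nuclei_near_max(self):
        # for t < d the maximum retained fraction is below 1
        assert fraction_volume_at_least_given_image(2.0, 3.0, 0.8, 0.95) == 0.0

    def test_complement_of_full_diameter(self):
        t, d = 5.0, 3.0
        assert fraction_full_diameter(t, d) + d / (t + d) == pytest.approx(1.0)
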