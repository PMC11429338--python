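"""Unit and property tests for the LOBF / BAD / ID statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from agegap.metrics import (
    AgeWindow,
    GroupFit,
    build_group_pdf,
    compute_bad,
    compute_id,
    compute_id_windows,
    fit_lobf,
)
from agegap._errors import ConfigurationError, DegenerateFitError

WINDOW = AgeWindow(55.0, 75.0)


def id_quadrature_oracle(fit_a: GroupFit, fit_b: GroupFit, window: AgeWindow) -> float:
    """Independent two-stage adaptive quadrature of the ID double integral."""

    def inner(x: float) -> float:
        m1, m2 = float(fit_a.predict(x)), float(fit_b.predict(x))
        s1, s2 = fit_a.sigma, fit_b.sigma
        lo = min(m1 - 12 * s1, m2 - 12 * s2)
        hi = max(m1 + 12 * s1, m2 + 12 * s2)
        val, _ = quad(
            lambda y: abs(norm.pdf(y, m1, s1) - norm.pdf(y, m2, s2)),
            lo,
            hi,
            limit=400,
        )
        return val

    outer, _ = quad(inner, window.x_min, window.x_max, limit=200, epsabs=1e-10)
    return outer / (2.0 * window.span)


class TestFitLobf:
    def test_identity_line(self):
        x = np.array([50.0, 60.0, 70.0, 80.0])
        fit = fit_lobf((x, x))
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.sigma == pytest.approx(0.0, abs=1e-9)

    def test_constant_predictions(self):
        fit = fit_lobf((np.array([60.0, 70.0, 80.0]), np.array([70.0, 70.0, 70.0])))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(70.0)
        assert fit.sigma == pytest.approx(0.0, abs=1e-9)

    def test_hand_derived_normal_equations(self):
        # Sxy = 140, Sxx = 200 -> slope 0.7; intercept 66 - 0.7*65 = 20.5;
        # residuals (+1, -2, +1) -> population sigma = sqrt(2)
        fit = fit_lobf((np.array([55.0, 65.0, 75.0]), np.array([60.0, 64.0, 74.0])))
        assert fit.slope == pytest.approx(0.7)
        assert fit.intercept == pytest.approx(20.5)
        assert fit.sigma == pytest.approx(np.sqrt(2.0))

    def test_sample_sd_convention(self):
        fit = fit_lobf(
            (np.array([55.0, 65.0, 75.0]), np.array([60.0, 64.0, 74.0])), ddof=2
        )
        assert fit.sigma == pytest.approx(np.sqrt(6.0))  # sum sq 6 / (3-2)

    @pytest.mark.parametrize(
        "x, y",
        [
            ([60.0], [61.0]),
            ([60.0, 60.0, 60.0], [59.0, 61.0, 63.0]),
        ],
    )
    def test_degenerate_inputs_rejected(self, x, y):
        with pytest.raises(DegenerateFitError):
            fit_lobf((np.array(x), np.array(y)))

    def test_dataframe_group_filter(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "age": [55.0, 65.0, 75.0, 60.0, 70.0],
                "predicted_age": [55.0, 65.0, 75.0, 70.0, 80.0],
                "diagnosis": ["CU", "CU", "CU", "AD", "AD"],
            }
        )
        fit_ad = fit_lobf(frame, "AD")
        assert fit_ad.group == "AD"
        assert fit_ad.n == 2
        assert fit_ad.intercept == pytest.approx(10.0)


class TestBad:
    def test_identical_fits_zero(self):
        f = GroupFit(0.9, 5.0, 2.0, 10)
        assert compute_bad(f, f, WINDOW) == 0.0

    def test_constant_offset(self):
        f_cu = GroupFit(0.9, 5.0, 2.0, 10)
        f_ad = GroupFit(0.9, 10.0, 2.0, 10)
        assert compute_bad(f_cu, f_ad, WINDOW) == pytest.approx(5.0)

    def test_linear_difference_worked_example(self):
        # mean of (18 - 0.2 x) over [55, 75] = 18 - 0.2 * 65 = 5.0
        f_cu = GroupFit(0.8, 10.0, 1.0, 10)
        f_ad = GroupFit(0.6, 28.0, 1.0, 10)
        assert compute_bad(f_cu, f_ad, WINDOW) == pytest.approx(5.0, abs=1e-12)

    def test_matches_numeric_quadrature(self):
        f_cu = GroupFit(0.83, 9.4, 1.0, 10)
        f_ad = GroupFit(0.61, 27.2, 1.0, 10)
        xs = np.linspace(WINDOW.x_min, WINDOW.x_max, 100001)
        ref = np.trapezoid(f_ad.predict(xs) - f_cu.predict(xs), xs) / WINDOW.span
        assert compute_bad(f_cu, f_ad, WINDOW) == pytest.approx(ref, abs=1e-9)

    @given(
        slope=st.floats(-1.5, 1.5),
        intercept=st.floats(-30, 30),
        scale=st.floats(-3, 3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linearity_and_antisymmetry(self, slope, intercept, scale):
        f_cu = GroupFit(1.0, 0.0, 1.0, 10)
        f_ad = GroupFit(1.0 + slope * 0.01, intercept, 1.0, 10)
        bad = compute_bad(f_cu, f_ad, WINDOW)
        assert compute_bad(f_ad, f_cu, WINDOW) == pytest.approx(-bad, abs=1e-9)
        f_scaled = GroupFit(
            1.0 + scale * (f_ad.slope - 1.0),
            scale * f_ad.intercept,
            1.0,
            10,
        )
        assert compute_bad(f_cu, f_scaled, WINDOW) == pytest.approx(
            scale * bad, rel=1e-9, abs=1e-9
        )


class TestGroupPdf:
    def test_mean_and_sd(self):
        pdf = build_group_pdf(GroupFit(1.0, 0.0, 2.0, 10), 60.0)
        assert pdf.mean() == pytest.approx(60.0)
        assert pdf.std() == pytest.approx(2.0)

    def test_normalizes_to_one(self):
        pdf = build_group_pdf(GroupFit(0.7, 12.0, 3.5, 10), 68.0)
        total, _ = quad(pdf.pdf, -np.inf, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_peak_height_closed_form(self):
        sigma = 1.7
        pdf = build_group_pdf(GroupFit(1.0, 0.0, sigma, 10), 70.0)
        assert pdf.pdf(70.0) == pytest.approx(1.0 / (sigma * np.sqrt(2 * np.pi)))

    def test_zero_sigma_rejected(self):
        with pytest.raises(DegenerateFitError):
            build_group_pdf(GroupFit(1.0, 0.0, 0.0, 10), 60.0)


class TestId:
    def test_identical_fits_zero(self):
        f = GroupFit(1.0, 0.0, 3.0, 10)
        assert compute_id(f, f, WINDOW) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("ratio", [0.1, 0.5, 1.0, 2.0, 4.0, 8.0])
    def test_equal_sigma_closed_form(self, ratio):
        sigma = 3.1
        delta = ratio * sigma
        f_cu = GroupFit(1.0, 0.0, sigma, 10)
        f_ad = GroupFit(1.0, delta, sigma, 10)
        expected = 2.0 * norm.cdf(delta / (2.0 * sigma)) - 1.0
        assert compute_id(f_cu, f_ad, WINDOW) == pytest.approx(expected, abs=1e-6)

    def test_disjoint_limit(self):
        f_cu = GroupFit(1.0, 0.0, 1.0, 10)
        f_ad = GroupFit(1.0, 50.0, 1.0, 10)
        assert compute_id(f_cu, f_ad, WINDOW) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize(
        "fit_a, fit_b",
        [
            (GroupFit(1.0, 0.0, 2.0, 10), GroupFit(0.9, 12.0, 3.5, 10)),
            (GroupFit(0.8, 14.0, 4.9, 10), GroupFit(0.75, 22.0, 6.1, 10)),
            (GroupFit(1.0, 0.0, 1.0, 10), GroupFit(1.0, 2.0, 5.0, 10)),
        ],
    )
    def test_unequal_sigma_matches_quadrature_oracle(self, fit_a, fit_b):
        ours = compute_id(fit_a, fit_b, WINDOW)
        ref = id_quadrature_oracle(fit_a, fit_b, WINDOW)
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_node_count_converged(self):
        fit_a = GroupFit(1.0, 0.0, 2.0, 10)
        fit_b = GroupFit(0.85, 15.0, 3.0, 10)
        assert compute_id(fit_a, fit_b, WINDOW, nodes=64) == pytest.approx(
            compute_id(fit_a, fit_b, WINDOW, nodes=256), abs=1e-9
        )

    def test_monotone_in_gap_and_sigma(self):
        sigma = 3.0
        ids_by_gap = [
            compute_id(
                GroupFit(1.0, 0.0, sigma, 10), GroupFit(1.0, d, sigma, 10), WINDOW
            )
            for d in (1.0, 2.0, 4.0, 8.0)
        ]
        assert all(a < b for a, b in zip(ids_by_gap, ids_by_gap[1:]))
        ids_by_sigma = [
            compute_id(GroupFit(1.0, 0.0, s, 10), GroupFit(1.0, 5.0, s, 10), WINDOW)
            for s in (1.0, 2.0, 4.0, 8.0)
        ]
        assert all(a > b for a, b in zip(ids_by_sigma, ids_by_sigma[1:]))

    def test_degenerate_zero_sigma(self):
        same = GroupFit(1.0, 0.0, 0.0, 10)
        assert compute_id(same, same, WINDOW) == 0.0
        offset = GroupFit(1.0, 4.0, 0.0, 10)
        assert compute_id(same, offset, WINDOW) == 1.0
        diffuse = GroupFit(1.0, 0.0, 3.0, 10)
        assert compute_id(same, diffuse, WINDOW) == 1.0

    @given(
        slope_a=st.floats(0.5, 1.5),
        int_a=st.floats(-20, 20),
        sig_a=st.floats(0.5, 8.0),
        slope_b=st.floats(0.5, 1.5),
        int_b=st.floats(-20, 20),
        sig_b=st.floats(0.5, 8.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounds_and_symmetry(self, slope_a, int_a, sig_a, slope_b, int_b, sig_b):
        fa = GroupFit(slope_a, int_a, sig_a, 10)
        fb = GroupFit(slope_b, int_b, sig_b, 10)
        ours = compute_id(fa, fb, WINDOW)
        assert 0.0 <= ours <= 1.0
        assert compute_id(fb, fa, WINDOW) == pytest.approx(ours, abs=1e-12)


class TestIdWindows:
    def test_four_year_increments_partition(self):
        f_cu = GroupFit(1.0, 0.0, 3.0, 10)
        f_ad = GroupFit(1.0, 8.0, 3.0, 10)
        out = compute_id_windows(f_cu, f_ad, WINDOW, 4.0)
        edges = [(w.x_min, w.x_max) for w, _ in out]
        assert edges == [(55, 59), (59, 63), (63, 67), (67, 71), (71, 75)]

    def test_constant_gap_gives_equal_subwindow_ids(self):
        f_cu = GroupFit(1.0, 0.0, 3.0, 10)
        f_ad = GroupFit(1.0, 8.0, 3.0, 10)
        full = compute_id(f_cu, f_ad, WINDOW)
        for _, sub_id in compute_id_windows(f_cu, f_ad, WINDOW, 4.0):
            assert sub_id == pytest.approx(full, abs=1e-9)

    def test_shrinking_gap_gives_decreasing_ids(self):
        # gap 18 - 0.2 x decreases over the window; equal sigmas, so each
        # sub-window ID must strictly decrease (cross-checked by oracle)
        f_cu = GroupFit(0.8, 10.0, 2.5, 10)
        f_ad = GroupFit(0.6, 28.0, 2.5, 10)
        out = compute_id_windows(f_cu, f_ad, WINDOW, 4.0)
        ids = [v for _, v in out]
        assert all(a > b for a, b in zip(ids, ids[1:]))
        for w, v in out:
            assert v == pytest.approx(id_quadrature_oracle(f_cu, f_ad, w), abs=1e-6)

    def test_invalid_increment(self):
        f = GroupFit(1.0, 0.0, 3.0, 10)
        with pytest.raises(ConfigurationError):
            compute_id_windows(f, f, WINDOW, 0.0)


def test_window_validation():
    with pytest.raises(ConfigurationError):
        AgeWindow(75.0, 55.0)
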