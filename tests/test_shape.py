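"""Width, symmetry and curvature statistics of spectrum-shaped curves.

Geometric reference shapes with known curvature (circles, parabolas,
straight lines) check the finite-difference machinery; analytic cascade
spectra check the end-to-end shape metrics.
"""

import numpy as np
import pytest

import mfhrv as M
from mfhrv.spectrum import MultifractalSpectrum


def curve(alpha, f, q=None):
    return MultifractalSpectrum.from_curve(alpha, f, q=q)


def analytic_curve(weights, base, qgrid=None):
    spec = M.CascadeSpec(base=base, weights=weights, levels=2)
    an = M.analytic_spectrum(spec, qgrid)
    return curve(an.alpha_exact, an.f_exact, q=an.q), an


class TestWidthAndSymmetry:
    def test_binomial_spectrum_is_symmetric(self, binom_spectrum):
        m = M.width_and_symmetry(binom_spectrum)
        assert m.r == pytest.approx(1.0, abs=0.02)
        assert m.skew_label == "symmetric"
        assert m.delta_alpha == pytest.approx(m.delta_right + m.delta_left,
                                              abs=1e-12)

    def test_trinomial_r_matches_analytic(self, trinom_spectrum, trinom_spec,
                                          qgrid):
        an = M.analytic_spectrum(trinom_spec, qgrid)
        m = M.width_and_symmetry(trinom_spectrum)
        assert m.r == pytest.approx(an.r_exact, rel=0.05)

    def test_endpoint_convention(self):
        # alpha decreasing in q; alpha_max at q_min, alpha_min at q_max
        q = np.linspace(-2, 2, 41)
        alpha = 1.5 - 0.2 * q
        f = 1 - 0.3 * (alpha - 1.5) ** 2
        m = M.width_and_symmetry(curve(alpha, f, q=q))
        assert m.alpha_max == pytest.approx(1.9)
        assert m.alpha_min == pytest.approx(1.1)

    def test_degenerate_left_width_reports_inf(self):
        q = np.linspace(-1, 1, 21)
        alpha = np.concatenate([1.0 + 0.1 * np.arange(10, 0, -1),
                                np.full(11, 1.0)])
        f = 1 - (alpha - 1.0) ** 2
        with pytest.warns(RuntimeWarning, match="degenerate"):
            m = M.width_and_symmetry(curve(alpha, f, q=q))
        assert m.r == float("inf")


class TestClassifySkew:
    @pytest.mark.parametrize("r,label", [
        (6.65, "sharply_right"),   # most right-skewed healthy 24 h subject
        (2.5, "sharply_right"),
        (1.5, "right"),
        (1.0, "symmetric"),
        (0.9, "left"),
        (0.4, "sharply_left"),     # most left-skewed CHF 24 h subject
        (0.5, "left"),             # boundary: sharp threshold is exclusive
    ])
    def test_thresholds(self, r, label):
        assert M.classify_skew(r) == label

    def test_custom_thresholds(self):
        t = M.SkewThresholds(t_sharp_low=0.2, t_low=0.8, t_high=1.2,
                             t_sharp_high=5.0)
        assert M.classify_skew(0.4, t) == "left"

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            M.classify_skew(0.0)


class TestDerivatives:
    def test_linear_curve(self):
        alpha = np.linspace(0.5, 1.5, 51)
        first, second = M.derivatives(curve(alpha, alpha.copy()))
        np.testing.assert_allclose(first, 1.0, atol=1e-9)
        np.testing.assert_allclose(second, 0.0, atol=1e-6)

    @pytest.mark.parametrize("mode", ["uniform", "nonuniform"])
    def test_uniform_parabola_second_derivative(self, mode):
        alpha = np.linspace(0.0, 2.0, 101)
        f = 1 - (alpha - 1.0) ** 2
        _, second = M.derivatives(curve(alpha, f), mode=mode)
        np.testing.assert_allclose(second, -2.0, atol=1e-8)

    def test_nonuniform_mode_exact_on_irregular_parabola(self, rng):
        alpha = np.sort(rng.uniform(0.0, 2.0, 60))
        f = 1 - 0.7 * (alpha - 1.0) ** 2
        _, second = M.derivatives(curve(alpha, f), mode="nonuniform")
        np.testing.assert_allclose(second, -1.4, atol=1e-7)

    def test_point_counts_201_200_199(self, binom_spectrum):
        for mode in ("uniform", "nonuniform"):
            first, second = M.derivatives(binom_spectrum, mode=mode)
            assert first.size == 200 and second.size == 199

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            M.derivatives(curve([1.0, 1.1], [0.9, 1.0]))


class TestCurvatureProfile:
    @pytest.mark.parametrize("mode", ["uniform", "nonuniform"])
    def test_circle_curvature_is_one_over_radius(self, mode):
        # dense upper arc sampled uniformly in x
        rho = 2.0
        x = np.linspace(-0.7 * rho, 0.7 * rho, 400)
        y = np.sqrt(rho**2 - x**2)
        prof = M.curvature_profile(curve(x, y), mode=mode)
        np.testing.assert_allclose(prof.k, 1 / rho, rtol=0.01)

    def test_circle_nonuniform_sampling_needs_exact_formulas(self):
        # uniform-in-angle sampling gives an irregular x grid; only the
        # unequal-spacing formulas stay consistent there
        rho = 2.0
        theta = np.linspace(0.25 * np.pi, 0.75 * np.pi, 400)[::-1]
        prof = M.curvature_profile(
            curve(rho * np.cos(theta), rho * np.sin(theta)),
            mode="nonuniform")
        np.testing.assert_allclose(prof.k, 1 / rho, rtol=0.01)

    def test_parabola_vertex_curvature_is_2c(self):
        c = 0.8
        alpha = np.linspace(0.0, 2.0, 201)
        f = 1 - c * (alpha - 1.0) ** 2
        prof = M.curvature_profile(curve(alpha, f))
        assert prof.k[100] == pytest.approx(2 * c, rel=0.01)

    def test_k_nonnegative_and_center_at_q0(self, binom_spectrum):
        prof = M.curvature_profile(binom_spectrum)
        assert np.all(prof.k >= 0)
        assert len(prof) == 199
        assert prof.center_index == 99
        assert prof.q_index[99] == pytest.approx(0.0, abs=1e-12)

    def test_tails_flatten_to_zero(self, binom_spectrum):
        prof = M.curvature_profile(binom_spectrum)
        vertex = prof.k[prof.center_index]
        tails = np.concatenate([prof.k[:10], prof.k[-10:]])
        assert tails.max() < 0.05 * vertex

    def test_reversal_invariance(self, binom_spectrum):
        prof = M.curvature_profile(binom_spectrum, mode="nonuniform")
        rev = curve(binom_spectrum.alpha[::-1], binom_spectrum.f[::-1],
                    q=binom_spectrum.q[::-1])
        prof_rev = M.curvature_profile(rev, mode="nonuniform")
        np.testing.assert_allclose(prof.k, prof_rev.k[::-1], rtol=1e-9)

    def test_symmetric_spectrum_gives_symmetric_profile(self, qgrid):
        ms, _ = analytic_curve((0.6, 0.4), base=2, qgrid=qgrid)
        prof = M.curvature_profile(ms, mode="nonuniform")
        np.testing.assert_allclose(prof.k, prof.k[::-1], atol=1e-6)


class TestMaxCurvature:
    def test_simple_argmax(self):
        prof = M.CurvatureProfile(k=[0.1, 5.0, 0.2],
                                  q_index=[-0.1, 0.0, 0.1], center_index=1)
        assert M.max_curvature(prof) == (5.0, 0.0)

    def test_window_restriction(self):
        prof = M.CurvatureProfile(k=[9.0, 1.0, 2.0, 1.0, 8.0],
                                  q_index=[-5.0, -1.0, 0.0, 1.0, 5.0],
                                  center_index=2)
        kmax, kq = M.max_curvature(prof, window_halfwidth_q=1.0)
        assert (kmax, kq) == (2.0, 0.0)

    def test_tie_goes_to_smallest_abs_q(self):
        prof = M.CurvatureProfile(k=[3.0, 1.0, 3.0],
                                  q_index=[-0.2, 0.0, 0.1], center_index=1)
        assert M.max_curvature(prof) == (3.0, 0.1)

    def test_narrow_spectrum_has_larger_vertex_curvature(self, qgrid):
        broad, _ = analytic_curve((0.4, 0.35, 0.25), base=3, qgrid=qgrid)
        narrow, _ = analytic_curve((0.30, 0.34, 0.36), base=3, qgrid=qgrid)
        k_b, _ = M.max_curvature(M.curvature_profile(broad))
        k_n, _ = M.max_curvature(M.curvature_profile(narrow))
        assert k_n > k_b

    def test_monofractal_profile_flags_infinite_curvature(self):
        meas = M.BoxMeasure(p=np.full(64, 1 / 64), base=2, m=6)
        spec = M.compute_spectrum(meas)
        prof = M.curvature_profile(spec)
        assert prof.degenerate
        assert M.max_curvature(prof)[0] == float("inf")

    def test_alpha_axis_narrowing_scales_vertex_curvature(self, qgrid):
        """Compressing the alpha axis by s about the vertex multiplies the
        vertex curvature by 1/s**2 (zero slope there)."""
        ms, an = analytic_curve((0.6, 0.4), base=2, qgrid=qgrid)
        k1, _ = M.max_curvature(M.curvature_profile(ms, mode="nonuniform"))
        s = 0.5
        a0 = an.alpha0_exact
        squeezed = curve(a0 + s * (an.alpha_exact - a0), an.f_exact, q=an.q)
        k2, _ = M.max_curvature(M.curvature_profile(squeezed,
                                                    mode="nonuniform"))
        assert k2 / k1 == pytest.approx(1 / s**2, rel=0.05)


class TestExports:
    def test_metrics_csv_header_and_row(self, binom_spectrum, tmp_path):
        import csv
        m = M.compute_shape_metrics(binom_spectrum)
        out = tmp_path / "metrics.csv"
        M.metrics_to_csv([("b06", "unknown", "none", "h24", m)], out)
        with open(out) as fh:
            rows = list(csv.reader(fh))
        assert rows[0][:4] == ["subject_id", "condition", "nyha", "segment"]
        assert len(rows) == 2
        assert float(rows[1][10]) == pytest.approx(m.r, rel=1e-4)

    def test_profile_csv_indexing(self, binom_spectrum, tmp_path):
        import pandas as pd
        prof = M.curvature_profile(binom_spectrum)
        out = tmp_path / "prof.csv"
        M.profile_to_csv(prof, out)
        df = pd.read_csv(out)
        assert list(df.columns) == ["index", "q", "K"]
        assert len(df) == 199
        # index 100 (1-based) is the q = 0 center point
        assert df.loc[df["index"] == 100, "q"].iloc[0] == pytest.approx(0.0)
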