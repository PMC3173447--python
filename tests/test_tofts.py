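"""Tofts model: forward evaluation, closed form, and parameter recovery."""

import numpy as np
import pytest
from scipy.integrate import quad

import dcekinet as dk
from dcekinet.tofts import _ConvolutionOperator

PARAM_GRID = [(kt, ve) for kt in (0.05, 0.2, 1.0) for ve in (0.1, 0.3, 0.6)]


def _weinmann_cp(u, dose=0.1):
    return dose * (3.99 * np.exp(-0.144 * u) + 4.78 * np.exp(-0.0111 * u))


class TestClosedForm:
    @pytest.mark.parametrize("ktrans,ve", PARAM_GRID)
    def test_agreement_with_adaptive_quadrature(self, ktrans, ve):
        """Independent oracle: direct adaptive quadrature of the convolution."""
        p = dk.ToftsParams(ktrans, ve)
        for t in (1.36, 5.10, 8.44):
            brute, _ = quad(
                lambda u: _weinmann_cp(u) * np.exp(-p.kep * (t - u)),
                0.0, t, epsabs=1e-14, epsrel=1e-13,
            )
            cf = dk.tofts_forward_biexp(p, eval_times=np.array([t])).values[0]
            assert cf == pytest.approx(ktrans * brute, rel=1e-10)

    def test_zero_ktrans_gives_zero_curve(self, frame_times):
        curve = dk.tofts_forward_biexp(dk.ToftsParams(0.0, 0.3), eval_times=frame_times)
        np.testing.assert_array_equal(curve.values, 0.0)

    def test_kep_equal_rate_constant_limit(self):
        """Removable singularity at kep == m_i handled continuously."""
        t = np.linspace(0.5, 8.0, 10)
        exact_match = dk.ToftsParams(0.144 * 0.3, 0.3)  # kep == m1 exactly
        nearby = dk.ToftsParams(0.144 * 0.3 * (1 + 1e-6), 0.3)
        a = dk.tofts_forward_biexp(exact_match, eval_times=t).values
        b = dk.tofts_forward_biexp(nearby, eval_times=t).values
        np.testing.assert_allclose(a, b, rtol=1e-4)

    def test_boundedness(self):
        """The kernel integral is bounded: C_t stays finite and positive at
        long times for a decaying input."""
        t = np.array([50.0, 200.0, 1000.0])
        vals = dk.tofts_forward_biexp(dk.ToftsParams(0.3, 0.4), eval_times=t).values
        assert np.all(vals > 0)
        assert np.all(np.diff(vals) < 0)  # eventually washes out


class TestNumericalForward:
    @pytest.mark.parametrize("ktrans,ve", PARAM_GRID)
    def test_matches_closed_form_on_frame_times(self, ktrans, ve, frame_times):
        p = dk.ToftsParams(ktrans, ve)
        aif = dk.weinmann_aif(dose=0.1, times=frame_times)
        num = dk.tofts_forward(p, aif, frame_times).values
        ref = dk.tofts_forward_biexp(p, eval_times=frame_times).values
        np.testing.assert_allclose(num[1:], ref[1:], rtol=1e-4)

    def test_linearity_in_cp(self, frame_times):
        p = dk.ToftsParams(0.2, 0.3)
        aif = dk.weinmann_aif(dose=0.1, times=frame_times)
        aif2 = dk.weinmann_aif(dose=0.3, times=frame_times)
        a = dk.tofts_forward(p, aif, frame_times).values
        b = dk.tofts_forward(p, aif2, frame_times).values
        np.testing.assert_allclose(b, 3 * a, rtol=1e-12)

    def test_convergence_order_in_grid_step(self, frame_times):
        """Error vs the closed form shrinks at least first order in dt."""
        p = dk.ToftsParams(0.4, 0.2)
        aif = dk.weinmann_aif(dose=0.1, times=frame_times)
        ref = dk.tofts_forward_biexp(p, eval_times=frame_times).values[1:]
        errs = []
        for dt in (0.08, 0.04, 0.02, 0.01):
            num = dk.tofts_forward(p, aif, frame_times, dt=dt).values[1:]
            errs.append(np.max(np.abs(num - ref)))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders >= 1.0)

    def test_interpolated_measured_aif_path(self, frame_times):
        """A sampled (non-analytic) AIF runs through the interpolation route
        and stays close to the analytic result."""
        dense_t = np.linspace(0, 8.44, 845)
        aif_meas = dk.Aif(times=dense_t, cp=_weinmann_cp(dense_t), kind="measured")
        p = dk.ToftsParams(0.2, 0.3)
        num = dk.tofts_forward(p, aif_meas, frame_times).values
        ref = dk.tofts_forward_biexp(p, eval_times=frame_times).values
        np.testing.assert_allclose(num[1:], ref[1:], rtol=1e-3)

    def test_eval_beyond_measured_support_rejected(self, frame_times):
        aif = dk.Aif(times=frame_times, cp=np.r_[0.0, np.linspace(1, 0.5, 7)], kind="measured")
        with pytest.raises(ValueError):
            dk.tofts_forward(dk.ToftsParams(0.2, 0.3), aif, np.array([9.5]))

    def test_large_kep_is_finite(self, frame_times):
        """The recursion form stays finite at extreme efflux rates where the
        naive cumulative formulation overflows."""
        aif = dk.weinmann_aif(dose=0.1, times=frame_times)
        vals = dk.tofts_forward(dk.ToftsParams(10.0, 1e-3), aif, frame_times).values
        assert np.all(np.isfinite(vals))


class TestFit:
    def test_noise_free_recovery(self, frame_times):
        aif = dk.weinmann_aif(dose=0.1, times=frame_times)
        ct = dk.tofts_forward_biexp(dk.ToftsParams(0.25, 0.4), eval_times=frame_times)
        res = dk.fit_tofts(ct, aif)
        assert res.params.ktrans == pytest.approx(0.25, abs=1e-3)
        assert res.params.ve == pytest.approx(0.4, abs=1e-3)
        assert res.converged and not res.degenerate

    def test_zero_curve_degenerate(self, frame_times):
        aif = dk.weinmann_aif(dose=0.1, times=frame_times)
        ct = dk.ConcentrationCurve(times=frame_times, values=np.zeros(8))
        res = dk.fit_tofts(ct, aif)
        assert res.params.ktrans == 0.0
        assert res.degenerate

    def test_all_negative_curve_degenerate(self, frame_times):
        aif = dk.weinmann_aif(dose=0.1, times=frame_times)
        ct = dk.ConcentrationCurve(times=frame_times, values=-np.ones(8))
        assert dk.fit_tofts(ct, aif).degenerate

    def test_optimum_beats_truth_residual(self, frame_times):
        """Optimizer sanity: the fitted residual is never worse than the
        residual at the generating parameters."""
        rng = np.random.default_rng(7)
        aif = dk.weinmann_aif(dose=0.1, times=frame_times)
        truth = dk.ToftsParams(0.2, 0.3)
        clean = dk.tofts_forward_biexp(truth, eval_times=frame_times).values
        noisy = clean + rng.normal(0, 0.02 * clean.max(), clean.shape)
        ct = dk.ConcentrationCurve(times=frame_times, values=noisy)
        res = dk.fit_tofts(ct, aif)
        op = _ConvolutionOperator(aif, frame_times, 0.01)
        rss_truth = float(np.sum((op.curve(truth.ktrans, truth.ve) - noisy) ** 2))
        assert res.rss <= rss_truth + 1e-9

    def test_monte_carlo_recovery_under_noise(self, frame_times):
        """Median recovered parameters within 10% of truth at 2% Gaussian
        noise over 100 replicates on the 8-frame protocol."""
        rng = np.random.default_rng(42)
        aif = dk.weinmann_aif(dose=0.1, times=frame_times)
        truth = dk.ToftsParams(0.2, 0.3)
        clean = dk.tofts_forward_biexp(truth, eval_times=frame_times).values
        sigma = 0.02 * clean.max()
        kts, ves = [], []
        for _ in range(100):
            noisy = clean + rng.normal(0, sigma, clean.shape)
            res = dk.fit_tofts(dk.ConcentrationCurve(frame_times, noisy), aif)
            kts.append(res.params.ktrans)
            ves.append(res.params.ve)
        assert np.median(kts) == pytest.approx(0.2, rel=0.10)
        assert np.median(ves) == pytest.approx(0.3, rel=0.10)

    def test_aif_amplitude_scaling_semantics(self, frame_times):
        """Rescaling only the AIF amplitude (relative vs absolute units)
        leaves the efflux rate kep invariant while Ktrans (and hence Ve)
        scale inversely with the amplitude — so percent changes between two
        exams sharing one scale are unit-free."""
        aif = dk.weinmann_aif(dose=0.1, times=frame_times)
        truth = dk.ToftsParams(0.25, 0.4)
        ct = dk.tofts_forward_biexp(truth, eval_times=frame_times)
        k = 4.0
        aif_rel = dk.Aif(times=aif.times, cp=aif.cp * k, kind="measured")
        res = dk.fit_tofts(ct, aif_rel)
        assert res.params.kep == pytest.approx(truth.kep, rel=5e-3)
        assert res.params.ktrans == pytest.approx(truth.ktrans / k, rel=5e-3)
        assert res.params.ve == pytest.approx(truth.ve / k, rel=5e-3)
        assert res.scale_note == "relative-units"

    def test_too_few_samples_rejected(self):
        aif = dk.weinmann_aif(dose=0.1, times=np.array([0.0, 1.0, 2.0]))
        ct = dk.ConcentrationCurve(np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.5, 0.6]))
        with pytest.raises(ValueError):
            dk.fit_tofts(ct, aif)


class TestMap:
    def test_two_region_lesion_recovery(self):
        cfg = dk.PhantomConfig(
            lesions=[
                dk.LesionSpec(center=(9, 9, 3), radius=2.0, ktrans=0.1, ve=0.3),
                dk.LesionSpec(center=(17, 17, 3), radius=2.0, ktrans=0.4, ve=0.3),
            ],
            sigma=0.01,
            noise="gaussian",
            seed=11,
        )
        ph = dk.generate_phantom(cfg)
        pm = dk.fit_tofts_map(ph.series, ph.rois["tumor"], ph.aif)
        for center, kt_true in (((9, 9, 3), 0.1), ((17, 17, 3), 0.4)):
            sub = ph.truth.ktrans == kt_true
            med = np.median(pm.ktrans[sub & pm.mask])
            assert med == pytest.approx(kt_true, rel=0.05)
            assert np.median(pm.ve[sub & pm.mask]) == pytest.approx(0.3, rel=0.05)

    def test_noise_free_map_median_exact(self, clean_phantom):
        pm = dk.fit_tofts_map(clean_phantom.series, clean_phantom.rois["tumor"], clean_phantom.aif)
        kt, ve = dk.summarize_roi(pm)
        assert kt == pytest.approx(0.2, abs=1e-3)
        assert ve == pytest.approx(0.3, abs=1e-3)
        assert pm.n_fitted == int(clean_phantom.truth.mask.sum())

    def test_non_enhancing_roi_masked_with_warning(self, frame_times):
        series = dk.DceSeries(np.full((5, 5, 2, 8), 80.0), frame_times)
        roi = dk.Roi([[1, 1, 0], [2, 2, 1]])
        aif = dk.weinmann_aif(dose=0.1, times=frame_times)
        with pytest.warns(UserWarning, match="enhancement"):
            pm = dk.fit_tofts_map(series, roi, aif)
        assert pm.n_fitted == 0
        assert np.all(np.isnan(pm.ktrans))
        with pytest.raises(ValueError):
            dk.summarize_roi(pm)
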