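"""Spectral deconvolution, uptake ratios, linearity, widths."""

import numpy as np
import pytest

from qpid.core_model import EnergySpectrum, ValidationError
from qpid.quantify import (
    DeconvolutionProblem,
    bioequivalence,
    decay_correct,
    deconvolve_activities,
    fit_linearity,
    hist_width,
    normalize_basis,
    percent_injected_activity,
    qpid_microdose_ratio,
)

EDGES = np.arange(0.0, 8016.0, 16.0)
CENTERS = 0.5 * (EDGES[:-1] + EDGES[1:])


def alpha_basis():
    # mylar+saturation-distorted alpha line region around 4 MeV
    phi = np.exp(-((CENTERS - 4000.0) ** 2) / (2 * 300.0**2))
    return EnergySpectrum(EDGES, phi / phi.sum(), normalized=True)


def beta_basis():
    phi = np.where(CENTERS <= 1000.0, np.exp(-CENTERS / 300.0), 0.0)
    return EnergySpectrum(EDGES, phi / phi.sum(), normalized=True)


def lstsq_oracle(data, bases):
    """Independent closed-form normal-equations solution."""
    phi = np.column_stack([b.counts for b in bases])
    return np.linalg.solve(phi.T @ phi, phi.T @ data)


class TestNormalizeBasis:
    def test_simple_and_idempotent(self):
        spec = EnergySpectrum([0.0, 1.0, 2.0], [2.0, 2.0])
        out = normalize_basis(spec)
        assert np.allclose(out.counts, [0.5, 0.5]) and out.normalized
        again = normalize_basis(out)
        assert np.allclose(again.counts, out.counts)

    def test_sums_to_one(self, rng):
        counts = rng.uniform(0, 10, len(EDGES) - 1)
        assert normalize_basis(EnergySpectrum(EDGES, counts)).counts.sum() == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            normalize_basis(EnergySpectrum([0.0, 1.0], [0.0]))


class TestDeconvolution:
    def test_noiseless_two_basis_recovery(self):
        b1, b2 = alpha_basis(), beta_basis()
        data = EnergySpectrum(EDGES, 2.0 * b1.counts + 3.0 * b2.counts)
        res = deconvolve_activities(
            DeconvolutionProblem(data=data, bases={"a": b1, "b": b2})
        )
        assert res.activities["a"] == pytest.approx(2.0, abs=1e-8)
        assert res.activities["b"] == pytest.approx(3.0, abs=1e-8)

    def test_single_basis(self):
        b1 = alpha_basis()
        data = EnergySpectrum(EDGES, 5.0 * b1.counts)
        res = deconvolve_activities(DeconvolutionProblem(data=data, bases={"a": b1}))
        assert res.activities["a"] == pytest.approx(5.0, abs=1e-8)

    def test_poisson_recovery_and_oracle_equality(self, rng):
        """Mean recovery within 2% over 100 replicates; every unconstrained
        fit equals the normal-equations oracle; 1-sigma coverage ~68%."""
        b1, b2 = alpha_basis(), beta_basis()
        truth = np.array([400.0, 100.0])
        lam = truth[0] * b1.counts + truth[1] * b2.counts
        fits, cover, within_3sig = [], np.zeros(2), []
        for _ in range(100):
            s = rng.poisson(lam).astype(float)
            problem = DeconvolutionProblem(
                data=EnergySpectrum(EDGES, s), bases={"a": b1, "b": b2}
            )
            res = deconvolve_activities(problem, nonnegative=False)
            a = np.array([res.activities["a"], res.activities["b"]])
            sig = np.array([res.uncertainties["a"], res.uncertainties["b"]])
            oracle = lstsq_oracle(s, [b1, b2])
            assert np.allclose(a, oracle, rtol=1e-6)
            if np.all(oracle >= 0):
                constrained = deconvolve_activities(problem)
                assert np.allclose(
                    [constrained.activities["a"], constrained.activities["b"]],
                    oracle, rtol=1e-6,
                )
            within_3sig.extend(np.abs(a - truth) <= 3 * sig)
            cover += np.abs(a - truth) <= sig
            fits.append(a)
        mean_fit = np.mean(fits, axis=0)
        assert np.all(np.abs(mean_fit - truth) / truth < 0.02)
        # ~0.3% of Gaussian draws legitimately exceed 3 sigma
        assert np.mean(within_3sig) >= 0.99
        assert np.all((cover >= 60) & (cover <= 75))

    def test_collinear_bases_rejected(self):
        b1 = alpha_basis()
        data = EnergySpectrum(EDGES, b1.counts.copy())
        with pytest.raises(ValidationError, match="condition"):
            deconvolve_activities(
                DeconvolutionProblem(data=data, bases={"a": b1, "b": alpha_basis()})
            )

    def test_mismatched_binning_rejected(self):
        b1 = alpha_basis()
        other = EnergySpectrum([0.0, 1.0, 2.0], [0.5, 0.5], normalized=True)
        with pytest.raises(ValidationError, match="binning"):
            DeconvolutionProblem(data=other, bases={"a": b1})


class TestUptakeRatios:
    def test_percent_injected_activity(self):
        assert percent_injected_activity(5.0, 5.0) == 100.0
        assert percent_injected_activity(0.0, 5.0) == 0.0
        # residual correction shrinks the denominator -> %IA rises
        assert percent_injected_activity(2.0, 4.0) > percent_injected_activity(2.0, 5.0)

    def test_bioequivalence(self):
        assert bioequivalence(1.0, 1.0) == 1.0
        assert bioequivalence(0.5, 1.0) == 0.5
        with pytest.raises(ValidationError):
            bioequivalence(1.0, 0.0)

    def test_ratio_identity_pct_ia_vs_activity(self, rng):
        """The injected-activity factor cancels exactly."""
        for _ in range(20):
            qpid_act, micro_act = rng.uniform(0.1, 100.0, 2)
            injected = rng.uniform(1.0, 1000.0)
            from_pct = qpid_microdose_ratio(
                percent_injected_activity(qpid_act, injected),
                percent_injected_activity(micro_act, injected),
            )
            from_act = qpid_microdose_ratio(qpid_act, micro_act)
            assert from_pct == pytest.approx(from_act, abs=1e-12)

    def test_bioequivalence_from_raw_activities_when_injected_fixed(self):
        ra_inj, f_inj = 111e3, 7.4e6
        ra_act, f_act = 50.0, 2000.0
        b = bioequivalence(
            percent_injected_activity(ra_act, ra_inj),
            percent_injected_activity(f_act, f_inj),
        )
        assert b == pytest.approx((ra_act / ra_inj) / (f_act / f_inj))

    def test_thickness_regression_recovers_planted_attenuation(self, rng):
        """A planted linear thickness dependence of the alpha/beta activity
        ratio is recovered by ordinary regression on synthetic samples."""
        slope_true, intercept_true = -0.0049, 0.701
        thickness = np.array([10.0, 20.0, 30.0, 50.0])
        ratios = intercept_true + slope_true * thickness + rng.normal(0, 1e-4, 4)
        fit = fit_linearity(np.column_stack([thickness, ratios]))
        assert fit.slope == pytest.approx(slope_true, rel=0.05)
        assert fit.intercept == pytest.approx(intercept_true, rel=0.01)


class TestDecayCorrect:
    def test_closed_form_and_composition(self):
        assert decay_correct(10.0, 100.0, 100.0) == pytest.approx(20.0)
        assert decay_correct(10.0, 0.0, 100.0) == 10.0
        two_step = decay_correct(decay_correct(7.0, 30.0, 50.0), 20.0, 50.0)
        assert two_step == pytest.approx(decay_correct(7.0, 50.0, 50.0))

    def test_f18_half_life_from_table(self):
        from qpid.synthetic_source import half_life_s

        assert half_life_s("F-18") == pytest.approx(109.77 * 60.0, rel=1e-3)
        assert decay_correct(1.0, half_life_s("F-18"), half_life_s("F-18")) == 2.0


class TestLinearityFit:
    def test_exact_line_recovery(self):
        activity = np.array([10.0, 50.0, 100.0, 400.0])
        pairs = np.column_stack([activity, 2.49 * activity])
        fit = fit_linearity(pairs)
        assert fit.slope == pytest.approx(2.49)
        assert np.allclose(fit.residuals_pct, 0.0, atol=1e-9)
        assert not fit.nonlinear

    def test_saturating_response_flags_nonlinearity(self):
        activity = np.array([10.0, 100.0, 500.0, 1000.0, 2000.0])
        rate = np.minimum(0.5 * activity, 300.0)  # readout cap
        fit = fit_linearity(np.column_stack([activity, rate]))
        assert fit.nonlinear
        assert fit.residuals_pct[-1] < -10.0

    def test_ols_residuals_sum_to_zero(self, rng):
        activity = np.linspace(10, 1000, 8)
        rate = 0.5 * activity + rng.normal(0, 5, 8)
        fit = fit_linearity(np.column_stack([activity, rate]))
        absolute_resid = rate - (fit.slope * activity + fit.intercept)
        assert abs(absolute_resid.sum()) < 1e-8

    def test_single_level_rejected(self):
        with pytest.raises(ValidationError):
            fit_linearity([(10.0, 5.0), (10.0, 6.0)])


class TestHistWidth:
    def test_gaussian_closed_forms(self, rng):
        sigma = 10.0
        samples = rng.normal(0.0, sigma, 400_000)
        counts, edges = np.histogram(samples, bins=400, range=(-60, 60))
        fwhm, fwtm = hist_width(EnergySpectrum(edges, counts.astype(float)))
        assert fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma, rel=0.02)
        assert fwtm == pytest.approx(2 * np.sqrt(2 * np.log(10)) * sigma, rel=0.02)

    def test_single_occupied_bin(self):
        counts = np.zeros(11)
        counts[5] = 100.0
        fwhm, _ = hist_width(EnergySpectrum(np.arange(12.0), counts))
        assert fwhm <= 2.0  # at the binning resolution floor

    def test_flat_top_width_at_least_plateau(self):
        edges = np.arange(0.0, 41.0)
        counts = np.zeros(40)
        counts[10:25] = 100.0  # 15-bin plateau, steep edges
        fwhm, fwtm = hist_width(EnergySpectrum(edges, counts))
        assert fwhm >= 15.0
        assert fwtm >= fwhm

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            hist_width(EnergySpectrum([0.0, 1.0, 2.0], [0.0, 0.0]))
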