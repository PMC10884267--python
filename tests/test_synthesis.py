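"""Random-effects pooling and meta-regression on the prevalence product."""

import math

import numpy as np
import pytest

from comorbid.contingency import StudyRecord
from comorbid.synthesis import (
    PairAssociation,
    fit_meta_regression,
    pool_random_effects,
    predict_or,
    select_synthesis,
)


def _effect_record(i, log_or, se, prev_a=None, prev_b=None):
    return StudyRecord(f"s{i}", "A", "B", log_or=log_or, se_log_or=se,
                       prev_a=prev_a, prev_b=prev_b)


class TestPooling:
    def test_identical_studies_have_zero_heterogeneity(self):
        recs = [_effect_record(i, 0.7, 0.2) for i in range(5)]
        assoc = pool_random_effects(recs)
        assert assoc.mode == "pooled"
        assert assoc.pooled_log_or == pytest.approx(0.7)
        assert assoc.tau2 == 0.0
        assert assoc.k_studies == 5

    def test_symmetric_pair_pools_to_midpoint(self):
        recs = [_effect_record(0, 0.0, 0.3), _effect_record(1, math.log(4), 0.3)]
        assert pool_random_effects(recs).pooled_log_or == pytest.approx(math.log(2))

    def test_monte_carlo_recovery_of_true_effect(self):
        rng = np.random.default_rng(42)
        true, tau, se = 0.8, 0.2, 0.15
        y = rng.normal(true, math.sqrt(se**2 + tau**2), size=200)
        recs = [_effect_record(i, yi, se) for i, yi in enumerate(y)]
        assoc = pool_random_effects(recs)
        assert abs(assoc.pooled_log_or - true) < 0.05
        assert assoc.tau2 > 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no study records"):
            pool_random_effects([])

    def test_agrees_with_statsmodels_combine_effects(self):
        """Dual route: DL pooling must match the statsmodels implementation.

        Uses genuinely heterogeneous data so the moment estimate of tau^2 is
        positive: statsmodels does not floor a negative tau^2 at zero, so the
        two routes only coincide away from that boundary.
        """
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(7)
        se = rng.uniform(0.1, 0.4, size=12)
        y = rng.normal(0.5, np.sqrt(se**2 + 0.4**2))
        assoc = pool_random_effects(
            [_effect_record(i, yi, si) for i, (yi, si) in enumerate(zip(y, se))]
        )
        res = combine_effects(y, se**2, method_re="dl")
        frame = res.summary_frame()
        assert assoc.pooled_log_or == pytest.approx(
            frame.loc["random effect", "eff"], rel=1e-8
        )
        assert assoc.tau2 == pytest.approx(res.tau2, rel=1e-8)


class TestMetaRegression:
    def test_exact_linear_data_recovered_to_machine_precision(self):
        x = np.linspace(0.01, 0.09, 6)
        recs = [
            _effect_record(i, -20.0 * xi + 2.0, 0.1, prev_a=xi / 0.1, prev_b=0.1)
            for i, xi in enumerate(x)
        ]
        assoc = fit_meta_regression(recs)
        assert assoc.mode == "metareg"
        assert assoc.slope_m == pytest.approx(-20.0, abs=1e-8)
        assert assoc.intercept_c == pytest.approx(2.0, abs=1e-8)
        assert assoc.tau2 == pytest.approx(0.0, abs=1e-8)

    def test_covariance_is_symmetric_psd(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0.01, 0.2, size=10)
        recs = [
            _effect_record(i, -5 * xi + 1 + rng.normal(0, 0.2), 0.2,
                           prev_a=xi / 0.3, prev_b=0.3)
            for i, xi in enumerate(x)
        ]
        cov = fit_meta_regression(recs).cov_mc
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() >= -1e-12

    def test_moderator_rescaling_rescales_slope(self):
        """Scaling the prevalence product by s gives slope m/s, same intercept."""
        rng = np.random.default_rng(3)
        x = rng.uniform(0.02, 0.3, size=8)
        y = -4 * x + 1.2 + rng.normal(0, 0.1, size=8)
        recs1 = [_effect_record(i, yi, 0.15, prev_a=xi, prev_b=0.5)
                 for i, (xi, yi) in enumerate(zip(x, y))]
        s = 0.5
        recs2 = [_effect_record(i, yi, 0.15, prev_a=xi * s, prev_b=0.5)
                 for i, (xi, yi) in enumerate(zip(x, y))]
        a1 = fit_meta_regression(recs1)
        a2 = fit_meta_regression(recs2)
        assert a2.slope_m == pytest.approx(a1.slope_m / s, rel=1e-6)
        assert a2.intercept_c == pytest.approx(a1.intercept_c, rel=1e-6)

    def test_coefficient_ci_coverage(self):
        """95% normal CIs for (m, c) cover the truth in >= 90% of replicates."""
        rng = np.random.default_rng(2024)
        m_true, c_true, tau, k = -15.0, 1.5, 0.15, 50
        cover_m = cover_c = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.uniform(0.005, 0.1, size=k)
            se = rng.uniform(0.1, 0.3, size=k)
            y = c_true + m_true * x + rng.normal(0, tau, size=k) + rng.normal(0, se)
            recs = [
                _effect_record(i, yi, si, prev_a=xi / 0.2, prev_b=0.2)
                for i, (xi, yi, si) in enumerate(zip(x, y, se))
            ]
            a = fit_meta_regression(recs)
            half_m = 1.96 * math.sqrt(a.cov_mc[0, 0])
            half_c = 1.96 * math.sqrt(a.cov_mc[1, 1])
            cover_m += abs(a.slope_m - m_true) <= half_m
            cover_c += abs(a.intercept_c - c_true) <= half_c
        assert cover_m / n_rep >= 0.90
        assert cover_c / n_rep >= 0.90

    def test_agrees_with_r_metafor_reml(self, tmp_path):
        """Dual route: REML meta-regression must match metafor::rma."""
        import shutil
        import subprocess

        rng = np.random.default_rng(13)
        x = rng.uniform(0.01, 0.15, size=20)
        se = rng.uniform(0.1, 0.3, size=20)
        y = 1.4 - 12.0 * x + rng.normal(0, 0.15, size=20) + rng.normal(0, se)
        recs = [
            _effect_record(i, yi, si, prev_a=xi / 0.3, prev_b=0.3)
            for i, (xi, yi, si) in enumerate(zip(x, y, se))
        ]
        assoc = fit_meta_regression(recs)

        data = tmp_path / "d.csv"
        np.savetxt(data, np.column_stack([y, se, x]), delimiter=",",
                   header="y,se,x", comments="")
        script = (
            f"d <- read.csv('{data}'); suppressMessages(library(metafor)); "
            "m <- rma(yi=d$y, sei=d$se, mods=~d$x, method='REML'); "
            "cat(coef(m)[2], coef(m)[1], m$se[2], m$se[1], m$tau2)"
        )
        out = subprocess.run(
            [shutil.which("Rscript") or "Rscript", "-e", script],
            capture_output=True, text=True, check=True,
        )
        m_r, c_r, se_m_r, se_c_r, tau2_r = map(float, out.stdout.split())
        assert assoc.slope_m == pytest.approx(m_r, rel=1e-4)
        assert assoc.intercept_c == pytest.approx(c_r, rel=1e-4)
        assert math.sqrt(assoc.cov_mc[0, 0]) == pytest.approx(se_m_r, rel=1e-3)
        assert math.sqrt(assoc.cov_mc[1, 1]) == pytest.approx(se_c_r, rel=1e-3)
        assert assoc.tau2 == pytest.approx(tau2_r, abs=1e-4)

    def test_too_few_records_redirects_to_pooling(self):
        recs = [_effect_record(i, 0.5, 0.2, prev_a=0.1, prev_b=0.1) for i in range(2)]
        with pytest.raises(ValueError, match="pool_random_effects"):
            fit_meta_regression(recs)

    def test_degenerate_moderator_rejected(self):
        recs = [_effect_record(i, 0.5, 0.2, prev_a=0.1, prev_b=0.2) for i in range(4)]
        with pytest.raises(ValueError, match="degenerate moderator"):
            fit_meta_regression(recs)


class TestSelectSynthesis:
    def test_three_or_more_records_use_meta_regression(self):
        rng = np.random.default_rng(5)
        recs = [
            _effect_record(i, 0.5, 0.2, prev_a=p, prev_b=0.2)
            for i, p in enumerate(rng.uniform(0.05, 0.4, size=4))
        ]
        assert select_synthesis(recs).mode == "metareg"

    def test_two_records_are_pooled(self):
        recs = [_effect_record(i, 0.5, 0.2) for i in range(2)]
        assert select_synthesis(recs).mode == "pooled"

    def test_fixed_or_used_only_without_records(self):
        assoc = select_synthesis([], fixed_or=(2.3, 0.2), cond_a="TB", cond_b="Depression")
        assert assoc.mode == "fixed"
        assert assoc.pooled_log_or == pytest.approx(math.log(2.3))
        assert assoc.pooled_se == pytest.approx(0.2)
        assert assoc.tau2 == 0.0

    def test_no_evidence_is_an_error(self):
        with pytest.raises(ValueError, match="no evidence"):
            select_synthesis([])


class TestPredictOr:
    def test_flat_surface_returns_intercept_or(self):
        assoc = PairAssociation("A", "B", "metareg", 3, slope_m=0.0,
                                intercept_c=math.log(3), cov_mc=np.zeros((2, 2)))
        assert predict_or(assoc, 0.2, 0.4) == pytest.approx(3.0)

    def test_metareg_surface_evaluation(self):
        assoc = PairAssociation("A", "B", "metareg", 3, slope_m=-10.0,
                                intercept_c=1.0, cov_mc=np.zeros((2, 2)))
        assert predict_or(assoc, 0.1, 0.1) == pytest.approx(math.exp(0.9))

    def test_pooled_mode_ignores_prevalences(self):
        assoc = PairAssociation("A", "B", "pooled", 2, pooled_log_or=0.0, pooled_se=0.1)
        assert predict_or(assoc, 0.05, 0.3) == pytest.approx(1.0)
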