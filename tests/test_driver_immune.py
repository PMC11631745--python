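import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from comutnet import (
    assign_driver_groups,
    default_taxonomy,
    firth_fit,
    pdl1_group_test,
    penalized_lrt,
    tmb_group_test,
)
from comutnet.driver_immune import DRIVER_NEGATIVE, _penalized_loglik
from comutnet.io_model import AltClass, Component, Tier

from conftest import make_alt, make_sample


class TestFirthFit:
    def test_intercept_only_closed_form(self):
        # Firth estimate for a binomial intercept is logit((y+1/2)/(n+1))
        for n, y in [(1, 0), (1, 1), (5, 2), (10, 0), (12, 12), (30, 17)]:
            X = np.ones((n, 1))
            yy = np.array([1.0] * y + [0.0] * (n - y))
            fit = firth_fit(X, yy)
            assert fit.converged
            p_hat = expit(fit.coef[0])
            assert p_hat == pytest.approx((y + 0.5) / (n + 1), abs=1e-8)

    def test_finite_under_complete_separation(self):
        x = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones_like(x), x])
        fit = firth_fit(X, y)
        assert fit.converged
        assert np.all(np.isfinite(fit.coef))

    def test_matches_numeric_penalized_mle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=25)
        y = (rng.uniform(size=25) < expit(0.5 + 1.2 * x)).astype(float)
        X = np.column_stack([np.ones_like(x), x])
        fit = firth_fit(X, y)
        res = minimize(
            lambda b: -_penalized_loglik(X, y, b),
            np.zeros(2),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        assert fit.coef == pytest.approx(res.x, abs=1e-6)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank"):
            firth_fit(X, np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0]))

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            firth_fit(np.ones((3, 1)), np.array([0.0, 0.5, 1.0]))


class TestPenalizedLrt:
    def test_statistic_nonnegative_and_chi2(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        g = (rng.uniform(size=30) < 0.5).astype(float)
        y = (rng.uniform(size=30) < expit(0.3 * x)).astype(float)
        X_full = np.column_stack([np.ones(30), x, g])
        X_null = np.column_stack([np.ones(30), x])
        stat, df, p = penalized_lrt(X_full, X_null, y)
        assert stat >= 0.0
        assert df == 1
        assert 0.0 <= p <= 1.0

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=20)
        y = (rng.uniform(size=20) < 0.5).astype(float)
        X_full = np.column_stack([np.ones(20), x])
        X_null = np.column_stack([x + 1.0])  # not a column of the full design
        with pytest.raises(ValueError, match="nested"):
            penalized_lrt(X_full, X_null, y)

    def test_separated_contrast_gives_valid_p(self):
        # group perfectly predicts the outcome; Firth keeps this testable
        g = np.array([0.0] * 10 + [1.0] * 10)
        y = g.copy()
        X_full = np.column_stack([np.ones(20), g])
        X_null = np.ones((20, 1))
        stat, df, p = penalized_lrt(X_full, X_null, y)
        assert math.isfinite(stat) and stat > 0
        assert p < 0.01


class TestGroupAssignment:
    def _cohort(self):
        samples = [make_sample(f"P{i}") for i in range(6)]
        alterations = [
            make_alt("P0", "KRAS", "G12C", tier=Tier.GUIDELINE_INDICATED),
            make_alt("P1", "KRAS", "G12D"),
            make_alt("P2", "KRAS", "Q99X"),  # matches no named rule
            make_alt("P3", "MET", "exon 14 skipping", alt_class=AltClass.EXON_SKIP,
                     component=Component.RNA),
            make_alt("P4", "ALK", "EML4-ALK fusion", alt_class=AltClass.FUSION,
                     component=Component.RNA),
        ]
        return samples, alterations

    def test_first_match_and_fallback(self):
        samples, alterations = self._cohort()
        asg = assign_driver_groups(alterations, samples, default_taxonomy())
        kras = asg.groups("KRAS")
        assert kras["P0"] == "KRAS G12C"
        assert kras["P1"] == "KRAS G12D"
        assert kras["P2"] == "other KRAS alteration"

    def test_driver_negative_set_is_global(self):
        samples, alterations = self._cohort()
        asg = assign_driver_groups(alterations, samples, default_taxonomy())
        # P5 has nothing; P3 (MET) and P4 (ALK) are positive elsewhere
        assert asg.driver_negative == {"P5"}

    def test_rna_event_groups(self):
        samples, alterations = self._cohort()
        asg = assign_driver_groups(alterations, samples, default_taxonomy())
        assert "exon" in asg.groups("MET")["P3"].lower() or "skip" in asg.groups(
            "MET"
        )["P3"].lower()
        assert "fusion" in asg.groups("ALK")["P4"].lower()


class TestGroupTests:
    def _tmb_cohort(self):
        rng = np.random.default_rng(21)
        samples, alterations = [], []
        for i in range(60):
            sid = f"K{i}"
            samples.append(make_sample(sid, tmb=float(rng.lognormal(2.3, 0.4))))
            alterations.append(
                make_alt(sid, "KRAS", "G12C", tier=Tier.GUIDELINE_INDICATED)
            )
        for i in range(60):
            sid = f"N{i}"
            samples.append(make_sample(sid, tmb=float(rng.lognormal(1.3, 0.4))))
        return samples, alterations

    def test_tmb_contrast_sign_and_bonferroni(self):
        samples, alterations = self._tmb_cohort()
        asg = assign_driver_groups(alterations, samples, default_taxonomy())
        results = tmb_group_test(samples, asg, "KRAS")
        assert len(results) == 1
        r = results[0]
        pair = {r.group_a, r.group_b}
        assert pair == {"KRAS G12C", DRIVER_NEGATIVE}
        # G12C carriers were planted with higher TMB
        est = r.estimate if r.group_a == "KRAS G12C" else -r.estimate
        assert est > 0
        assert r.p_bonferroni == pytest.approx(min(1.0, r.p_raw * 1))

    def test_tmb_no_histology_variation_drops_covariate(self):
        # all-adenocarcinoma cohort: the squamous indicator is constant
        # and must be dropped rather than crash the fit
        samples, alterations = self._tmb_cohort()
        asg = assign_driver_groups(alterations, samples, default_taxonomy())
        results = tmb_group_test(samples, asg, "KRAS", include_histology=True)
        assert results and math.isfinite(results[0].p_raw)

    def test_tmb_single_group_returns_empty(self):
        samples = [make_sample("A", tmb=5.0), make_sample("B", tmb=6.0)]
        alterations = [
            make_alt("A", "KRAS", "G12C", tier=Tier.GUIDELINE_INDICATED),
            make_alt("B", "KRAS", "G12C", tier=Tier.GUIDELINE_INDICATED),
        ]
        asg = assign_driver_groups(alterations, samples, default_taxonomy())
        assert tmb_group_test(samples, asg, "KRAS") == []

    def test_pdl1_contrasts_estimate_direction(self):
        rng = np.random.default_rng(22)
        samples, alterations = [], []
        for i in range(80):
            sid = f"B{i}"
            tps = 75.0 if rng.uniform() < 0.7 else 5.0
            samples.append(make_sample(sid, pdl1_tps=tps))
            alterations.append(
                make_alt(sid, "BRAF", "V600E", tier=Tier.GUIDELINE_INDICATED)
            )
        for i in range(80):
            sid = f"N{i}"
            tps = 75.0 if rng.uniform() < 0.15 else 5.0
            samples.append(make_sample(sid, pdl1_tps=tps))
        asg = assign_driver_groups(alterations, samples, default_taxonomy())
        results = pdl1_group_test(samples, asg, "BRAF")
        high = next(r for r in results if r.marker == "pdl1_high_vs_rest")
        est = high.estimate if high.group_a == "BRAF V600E" else -high.estimate
        assert est > 0  # V600E group planted PD-L1-high-enriched
        assert high.p_bonferroni < 0.05
        # Bonferroni multiplier is contrasts x two dichotomies, counted
        # before any degenerate dichotomy is skipped
        assert high.p_bonferroni == pytest.approx(min(1.0, high.p_raw * 2))

    def test_pdl1_skips_degenerate_dichotomy(self):
        # nobody is PD-L1 high: the high-vs-rest dichotomy has no events
        samples = [make_sample(f"A{i}", pdl1_tps=5.0) for i in range(10)] + [
            make_sample(f"N{i}", pdl1_tps=0.0) for i in range(10)
        ]
        alterations = [
            make_alt(f"A{i}", "BRAF", "V600E", tier=Tier.GUIDELINE_INDICATED)
            for i in range(10)
        ]
        asg = assign_driver_groups(alterations, samples, default_taxonomy())
        results = pdl1_group_test(samples, asg, "BRAF")
        assert all(r.marker == "pdl1_pos_vs_neg" for r in results)
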