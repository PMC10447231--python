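from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats
from scipy.special import gammaln, logsumexp

from clonetrace.core_io import CountMatrix, SampleMeta, VariantSite
from clonetrace.variant_filtering import (
    ErrorModel,
    FilterConfig,
    apply_quality_filters,
    betabinom_logpmf,
    betabinom_sf,
    bh_qvalues,
    call_presence,
    classify_germline,
    designate_diploid_samples,
    fit_error_model,
    germline_test,
    presence_matrix,
)


def _site(asmd=None, clpm=None, pos=1):
    ann = {}
    if asmd is not None:
        ann["ASMD"] = asmd
    if clpm is not None:
        ann["CLPM"] = clpm
    return VariantSite("1", pos, "A", "C", annotations=ann)


class TestQualityFilters:
    def test_boundary_retained(self):
        kept, rej = apply_quality_filters([_site(140, 0)], FilterConfig())
        assert len(kept) == 1 and not rej

    def test_asmd_below_rejected(self):
        kept, rej = apply_quality_filters([_site(139, 0)], FilterConfig())
        assert not kept and rej[0][1] == "ASMD"

    def test_clpm_above_rejected(self):
        kept, rej = apply_quality_filters([_site(150, 0.5)], FilterConfig())
        assert not kept and rej[0][1] == "CLPM"

    def test_missing_annotation_policies(self):
        kept, _ = apply_quality_filters([_site()], FilterConfig())
        assert len(kept) == 1  # default: retain with warning
        kept, rej = apply_quality_filters(
            [_site()], FilterConfig(missing_annotation_policy="reject")
        )
        assert not kept and rej[0][1] == "missing_annotation"

    def test_against_independent_predicate(self):
        rng = np.random.default_rng(2)
        sites = [
            _site(float(rng.integers(120, 160)), float(rng.choice([0, 0, 1])),
                  pos=i + 1)
            for i in range(100)
        ]
        cfg = FilterConfig()
        kept, rej = apply_quality_filters(sites, cfg)
        expected_kept = [
            s for s in sites
            if s.annotations["ASMD"] >= 140 and s.annotations["CLPM"] <= 0
        ]
        assert kept == expected_kept
        assert len(kept) + len(rej) == 100


class TestGermlineTest:
    def test_zero_variant_reads_closed_form(self):
        assert germline_test(0, 30) == pytest.approx(2.0 ** -30, rel=1e-9)

    def test_full_support(self):
        assert germline_test(30, 30) == pytest.approx(1.0)

    def test_exact_enumeration_oracle(self):
        # P(X <= 12), X ~ Binom(60, 1/2), by exact rational arithmetic
        exact = Fraction(sum(comb(60, k) for k in range(13)), 2 ** 60)
        assert germline_test(12, 60) == pytest.approx(float(exact), rel=1e-12)

    @pytest.mark.parametrize("v,d", [(0, 1), (3, 10), (50, 100), (998, 2000)])
    def test_matches_summation_oracle(self, v, d):
        exact = Fraction(sum(comb(d, k) for k in range(v + 1)), 2 ** d)
        assert germline_test(v, d) == pytest.approx(float(exact), rel=1e-12)

    def test_zero_depth_warns_p1(self):
        assert germline_test(0, 0) == 1.0

    @settings(max_examples=50, deadline=None)
    @given(hst.integers(1, 500).flatmap(
        lambda d: hst.tuples(hst.just(d), hst.integers(0, d))
    ))
    def test_is_probability_and_monotone_in_v(self, dv):
        d, v = dv
        p = germline_test(v, d)
        assert 0.0 <= p <= 1.0
        if v < d:
            assert germline_test(v + 1, d) >= p

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            germline_test(5, 3)


class TestBH:
    def test_single_p(self):
        np.testing.assert_allclose(bh_qvalues(np.array([1e-6])), [1e-6])

    def test_hand_computation(self):
        q = bh_qvalues(np.array([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])

    def test_monotone_in_rank_and_order_invariant(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        q = bh_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        perm = rng.permutation(200)
        np.testing.assert_allclose(bh_qvalues(p[perm]), q[perm])

    def test_empty(self):
        assert bh_qvalues(np.array([])).size == 0

    @settings(max_examples=50, deadline=None)
    @given(hst.lists(hst.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_qvalues_dominate_pvalues(self, ps):
        p = np.array(ps)
        q = bh_qvalues(p)
        assert np.all(q <= 1.0 + 1e-15)
        assert np.all(q >= p - 1e-15)


class TestClassifyGermline:
    def _simulated(self, seed=0, n_het=300, n_somatic=300, depth=100,
                   n_samples=4):
        rng = np.random.default_rng(seed)
        sites = [VariantSite("1", i + 1, "A", "C")
                 for i in range(n_het + n_somatic)]
        samples = [SampleMeta(f"s{j}") for j in range(n_samples)]
        d = rng.poisson(depth, (n_het + n_somatic, n_samples))
        v = np.zeros_like(d)
        v[:n_het] = rng.binomial(d[:n_het], 0.5)
        v[n_het:] = rng.binomial(d[n_het:], 0.15)  # subclonal somatic
        cm = CountMatrix(sites, samples, v, d)
        labels = ["germline"] * n_het + ["somatic"] * n_somatic
        return cm, labels

    def test_single_site_somatic(self):
        cm = CountMatrix([VariantSite("1", 1, "A", "C")], [SampleMeta("s")],
                         np.array([[0]]), np.array([[40]]))
        rep = classify_germline(cm, ["s"])
        assert rep["label"][0] == "somatic"
        assert rep["q_value"][0] == pytest.approx(2.0 ** -40, rel=1e-9)

    def test_accuracy_on_seeded_truth(self):
        cm, truth = self._simulated(seed=42)
        rep = classify_germline(cm, [s.sample_id for s in cm.samples])
        acc = float(np.mean(rep["label"].to_numpy() == np.array(truth)))
        assert acc >= 0.99

    def test_empty_diploid_set_rejected(self):
        cm, _ = self._simulated()
        with pytest.raises(ValueError):
            classify_germline(cm, [])

    def test_designate_diploid_samples(self):
        cm, _ = self._simulated()
        cm.samples[0].ploidy = 3.2
        cm.samples[1].role = "normal"
        assert designate_diploid_samples(cm) == ["s2", "s3"]


class TestBetaBinomial:
    @pytest.mark.parametrize("d", [10, 100, 1000, 10_000])
    def test_rho_zero_tail_equals_binomial(self, d):
        v = np.arange(0, d + 1, max(1, d // 50))
        bb = betabinom_sf(v, d, 1e-3, 0.0)
        binom = stats.binom.sf(v - 1, d, 1e-3)
        np.testing.assert_allclose(bb, binom, atol=1e-10)

    def test_rho_small_converges_to_binomial(self):
        v, d, eps = 5, 200, 1e-2
        binom = float(stats.binom.sf(v - 1, d, eps))
        for rho in [1e-6, 1e-8]:
            assert betabinom_sf(v, d, eps, rho) == pytest.approx(
                binom, rel=1e-3
            )


class TestErrorModel:
    def _counts(self, v, d, n_sites=1):
        sites = [VariantSite("1", i + 1, "A", "C") for i in range(n_sites)]
        samples = [SampleMeta(f"n{j}", role="panel") for j in range(v.shape[1])]
        return CountMatrix(sites, samples, v, d)

    def test_all_zero_negatives_floor(self):
        d = np.full((1, 20), 100)
        cm = self._counts(np.zeros((1, 20), dtype=int), d)
        model = fit_error_model(cm, cm.sample_ids)
        floor = 0.5 / (d.sum() + 1.0)
        assert model.epsilon[0] == pytest.approx(floor)
        assert model.rho[0] == 0.0

    def test_parameter_recovery_betabinom(self):
        # per-site MLEs are noisy (heavy-tailed beta draws), so recovery is
        # asserted on the median over sites at a fixed seed
        rng = np.random.default_rng(3)
        eps, rho, n_neg, depth, n_sites = 1e-3, 0.05, 50, 200, 20
        a = eps * (1 - rho) / rho
        b = (1 - eps) * (1 - rho) / rho
        d = np.full((n_sites, n_neg), depth)
        p = rng.beta(a, b, size=(n_sites, n_neg))
        v = rng.binomial(d, p)
        cm = self._counts(v, d, n_sites=n_sites)
        model = fit_error_model(cm, cm.sample_ids)
        assert eps / 2 <= np.median(model.epsilon) <= eps * 2
        assert 0.01 <= np.median(model.rho) <= 0.15

    def test_rho_zero_reduction(self):
        rng = np.random.default_rng(4)
        d = np.full((1, 50), 200)
        v = rng.binomial(d, 1e-3)
        cm = self._counts(v, d)
        model = fit_error_model(cm, cm.sample_ids)
        eps_mle = max(v.sum() / d.sum(), 0.5 / (d.sum() + 1.0))
        ll_binom = float(np.sum(stats.binom.logpmf(v, d, eps_mle)))
        assert model.loglik[0] == pytest.approx(ll_binom, abs=1e-3)

    def test_few_negatives_flagged(self):
        cm = self._counts(np.array([[1]]), np.array([[100]]))
        model = fit_error_model(cm, cm.sample_ids)
        assert model.low_confidence[0]
        assert model.rho[0] == 0.0

    def test_error_model_invariants(self):
        with pytest.raises(ValueError):
            ErrorModel(epsilon=np.array([0.6]), rho=np.array([0.0]))
        with pytest.raises(ValueError):
            ErrorModel(epsilon=np.array([0.1]), rho=np.array([1.0]))


class TestCallPresence:
    def _setup(self, v, d, eps=1e-3, rho=0.0):
        n = v.shape[0]
        sites = [VariantSite("1", i + 1, "A", "C") for i in range(n)]
        samples = [SampleMeta(f"s{j}") for j in range(v.shape[1])]
        cm = CountMatrix(sites, samples, v, d)
        model = ErrorModel(epsilon=np.full(n, eps), rho=np.full(n, rho))
        return cm, model

    def test_zero_reads_absent(self):
        cm, model = self._setup(np.array([[0]]), np.array([[100]]))
        calls = call_presence(cm, model)
        assert calls[0].p_value == 1.0 and not calls[0].present

    def test_strong_signal_present_with_exact_tail(self):
        cm, model = self._setup(np.array([[30]]), np.array([[100]]))
        calls = call_presence(cm, model)
        exact = float(stats.binom.sf(29, 100, 1e-3))
        assert calls[0].p_value == pytest.approx(exact, rel=1e-10)
        assert calls[0].present

    def test_presence_requires_nonzero_reads(self):
        v = np.array([[0], [40]])
        d = np.array([[100], [100]])
        cm, model = self._setup(v, d)
        mat = presence_matrix(call_presence(cm, model), v.shape)
        assert not mat[0, 0] and mat[1, 0]

    def test_null_fdr_controlled(self):
        rng = np.random.default_rng(9)
        n, eps = 2000, 1e-3
        d = np.full((n, 1), 100)
        v = rng.binomial(d, eps)
        cm, model = self._setup(v, d, eps=eps)
        calls = call_presence(cm, model, FilterConfig(presence_alpha=1e-3))
        fdr = sum(c.present for c in calls) / n
        assert fdr <= 5e-3


class TestLogTailOracle:
    """Exact-tail agreement with an independent log-space summation."""

    # points sit in the upper tail (p well below 1), where "relative error
    # in log p" is well-conditioned
    @pytest.mark.parametrize("v,d,eps", [
        (10, 10_000, 1.6e-4),
        (10, 100, 1e-3),
        (320, 1_000_000, 1.6e-4),
        (500, 1_000_000, 1e-4),
    ])
    def test_binomial_logsf_vs_summation(self, v, d, eps):
        ks = np.arange(v, min(d, v + 4000) + 1)
        log_terms = (
            gammaln(d + 1) - gammaln(ks + 1) - gammaln(d - ks + 1)
            + ks * np.log(eps) + (d - ks) * np.log1p(-eps)
        )
        oracle = logsumexp(log_terms)
        got = float(stats.binom.logsf(v - 1, d, eps))
        assert got == pytest.approx(oracle, rel=1e-8)
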