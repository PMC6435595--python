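"""Joint genotype classification: priors, likelihoods, posteriors."""

import numpy as np
import pytest
from scipy.special import logsumexp

from purecall.classify import (classify_sites, conditional_loglik,
                               joint_posterior, site_priors)
from purecall.config import PriorConfig
from purecall.containers import CloneModel, SiteAnnotation, SiteCounts


def _two_sample_site(rb, rt):
    return SiteCounts(chrom=["chr1"], pos=[100], ref_allele=["A"],
                      a_allele=["A"], b_allele=["T"],
                      r_total=[list(rt)], r_b=[list(rb)])


def _cm(f=(0.25, 0.60), w=1e4):
    f = np.atleast_2d(f)
    j = f.shape[1]
    return CloneModel(f=f, c_center=np.full(j, 2.0), w_disp=np.full(j, w))


class TestSitePriors:
    def test_unseen_allele_gets_default_frequency(self, cfg):
        ann = SiteAnnotation(f_pop_a=[1.0], f_pop_b=[0.0], omega=[0])
        pi_s, pi_ab, pi_aa, pi_o = site_priors(ann, cfg, [False])
        f_b = cfg.f_pop_default_snv
        # Hardy-Weinberg shares with the substituted frequency
        assert pi_ab[0] / pi_aa[0] == pytest.approx(
            2 * f_b * (1 - f_b) / (1 - f_b) ** 2)
        assert pi_s[0] > 0

    def test_common_variant_cannot_be_somatic(self, cfg):
        ann = SiteAnnotation(f_pop_a=[0.99], f_pop_b=[0.01], omega=[5])
        pi_s, *_ = site_priors(ann, cfg, [False])
        assert pi_s[0] == 0.0

    def test_hotspot_scaling(self, cfg):
        ann = SiteAnnotation(f_pop_a=[1.0, 1.0], f_pop_b=[0.0, 0.0],
                             omega=[0, 10])
        pi_s, *_ = site_priors(ann, cfg, [False, False])
        assert pi_s[1] / pi_s[0] == pytest.approx(11.0, rel=1e-3)

    def test_indel_rates(self, cfg):
        ann = SiteAnnotation(f_pop_a=[1.0, 1.0], f_pop_b=[0.0, 0.0],
                             omega=[0, 0])
        pi_s, *_ = site_priors(ann, cfg, [False, True])
        assert pi_s[1] < pi_s[0]

    def test_priors_normalized(self, cfg):
        ann = SiteAnnotation(f_pop_a=[1.0, 0.7], f_pop_b=[0.0, 0.3],
                             omega=[0, 2])
        parts = site_priors(ann, cfg, [False, False])
        np.testing.assert_allclose(np.sum(parts, axis=0), 1.0)


class TestConditionalAndPosterior:
    def test_no_alt_reads_is_homozygous(self, cfg):
        sites = _two_sample_site((0, 0), (200, 250))
        ann = SiteAnnotation.default(1)
        call = joint_posterior(sites, ann, [], _cm(), cfg)
        assert call.label == "Homozygous"
        assert call.posterior_hom > 0.99

    def test_half_fraction_both_samples_is_het(self, cfg):
        # private germline variant: absent from databases but AF ~ 0.5
        # in both samples -- the motivating case for joint modeling
        sites = _two_sample_site((101, 98), (200, 200))
        ann = SiteAnnotation.default(1)
        call = joint_posterior(sites, ann, [], _cm(), cfg)
        assert call.label == "GermlineHet"

    def test_purity_scaled_fractions_are_somatic(self, cfg):
        # AF (0.05, 0.30) at purities (0.25, 0.60): phi_S = f/2 scaling
        sites = _two_sample_site((10, 60), (200, 200))
        ann = SiteAnnotation.default(1)
        call = joint_posterior(sites, ann, [], _cm(), cfg)
        assert call.label == "Somatic"

    def test_hand_built_bayes_oracle(self, cfg):
        """Posterior equals a directly assembled four-genotype Bayes
        computation from the conditional likelihoods and priors."""
        sites = _two_sample_site((10, 60), (200, 200))
        ann = SiteAnnotation.default(1)
        cm = _cm()
        logp = []
        for g in ("S", "G_AB", "G_AA", "O"):
            ll = sum(conditional_loglik(sites, j, g, cm, [], cfg)[0]
                     for j in range(2))
            logp.append(ll)
        pi = np.array([p[0] for p in site_priors(ann, cfg, [False])])
        post = np.exp(logp + np.log(pi)
                      - logsumexp(logp + np.log(pi)))
        call = joint_posterior(sites, ann, [], cm, cfg)
        assert call.posterior_somatic == pytest.approx(post[0], abs=1e-12)
        assert call.posterior_het == pytest.approx(post[1], abs=1e-12)

    def test_posteriors_sum_to_one(self, cfg, rng):
        n = 50
        rt = rng.integers(20, 300, (n, 2))
        rb = rng.integers(0, rt + 1)
        sites = SiteCounts(chrom=np.full(n, "chr1", dtype=object),
                           pos=np.arange(n) + 1,
                           ref_allele=np.full(n, "A", dtype=object),
                           a_allele=np.full(n, "A", dtype=object),
                           b_allele=np.full(n, "T", dtype=object),
                           r_total=rt, r_b=rb)
        df = classify_sites(sites, SiteAnnotation.default(n), [], _cm(), cfg)
        total = df[["p_somatic", "p_het", "p_hom", "p_other"]].sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_sample_permutation_invariance(self, cfg):
        a = _two_sample_site((10, 60), (200, 200))
        b = _two_sample_site((60, 10), (200, 200))
        ann = SiteAnnotation.default(1)
        cm_ab = _cm((0.25, 0.60))
        cm_ba = _cm((0.60, 0.25))
        pa = joint_posterior(a, ann, [], cm_ab, cfg).posterior_somatic
        pb = joint_posterior(b, ann, [], cm_ba, cfg).posterior_somatic
        assert pa == pytest.approx(pb, rel=1e-12)

    def test_hotspot_count_never_decreases_somatic_posterior(self, cfg):
        sites = _two_sample_site((10, 60), (200, 200))
        last = -1.0
        for omega in (0, 1, 5, 20, 100):
            ann = SiteAnnotation(f_pop_a=[1.0], f_pop_b=[0.0],
                                 omega=[omega])
            p = joint_posterior(sites, ann, [], _cm(), cfg).posterior_somatic
            assert p >= last
            last = p

    def test_single_sample_reduces_to_simple_bayes(self, cfg):
        sites = SiteCounts(chrom=["chr1"], pos=[10], ref_allele=["A"],
                           a_allele=["A"], b_allele=["T"],
                           r_total=[[200]], r_b=[[30]])
        ann = SiteAnnotation.default(1)
        cm = _cm(np.array([[0.30]]))
        call = joint_posterior(sites, ann, [], cm, cfg)
        logp = [conditional_loglik(sites, 0, g, cm, [], cfg)[0]
                for g in ("S", "G_AB", "G_AA", "O")]
        pi = np.array([p[0] for p in site_priors(ann, cfg, [False])])
        post = np.exp(logp + np.log(pi) - logsumexp(logp + np.log(pi)))
        assert call.posterior_somatic == pytest.approx(post[0])

    def test_w_limit_matches_binomial_decisions(self, cfg, rng):
        """In the W -> infinity limit the four-genotype decision equals a
        pure-binomial Bayes rule (independent oracle, 100 random sites)."""
        from scipy import stats as st
        n = 100
        rt = rng.integers(30, 250, (n, 2))
        rb = rng.integers(0, rt + 1)
        sites = SiteCounts(chrom=np.full(n, "chr1", dtype=object),
                           pos=np.arange(n) + 1,
                           ref_allele=np.full(n, "A", dtype=object),
                           a_allele=np.full(n, "A", dtype=object),
                           b_allele=np.full(n, "T", dtype=object),
                           r_total=rt, r_b=rb)
        ann = SiteAnnotation.default(n)
        cm = _cm((0.25, 0.60), w=1e8)
        df = classify_sites(sites, ann, [], cm, cfg)
        # oracle: binomial likelihoods at the same expected fractions
        phis = {"S": np.array([0.125, 0.30]),
                "G_AB": np.array([0.5, 0.5]),
                "G_AA": np.array([cfg.e_hom] * 2),
                "O": np.array([1 - cfg.e_hom] * 2)}
        pi = np.stack(site_priors(ann, cfg, sites.is_indel), axis=1)
        logp = np.stack([st.binom.logpmf(rb, rt, phis[g][None, :]).sum(1)
                         for g in ("S", "G_AB", "G_AA", "O")], axis=1)
        want = np.argmax(logp + np.log(pi), axis=1)
        got = np.argmax(df[["p_somatic", "p_het", "p_hom",
                            "p_other"]].to_numpy(), axis=1)
        assert (want == got).mean() == 1.0

    def test_reject_gates(self, cfg):
        sites = _two_sample_site((10, 60), (200, 200))
        ann = SiteAnnotation.default(1)
        df = classify_sites(sites, ann, [], _cm(), cfg,
                            trust_score=np.array([0.5]))
        assert df["label"].iloc[0] == "Reject"
        df = classify_sites(sites, ann, [], _cm(), cfg,
                            candidate_mask=np.array([False]))
        assert df["label"].iloc[0] == "Reject"


class TestOnSimulatedData:
    def test_error_rates_at_standard_operating_point(self, recovery_sim,
                                                     recovery_fit):
        """Diploid two-sample simulation, purities (0.25, 0.60), 200X:
        somatic sensitivity is high and the germline-het false positive
        rate stays below 1% at the 0.8 posterior threshold."""
        truth = recovery_sim.truth
        som = (truth["true_class"] == "somatic").to_numpy()
        het = (truth["true_class"] == "germline_het").to_numpy()
        called = (recovery_fit.calls["label"] == "Somatic").to_numpy()
        assert called[som].mean() >= 0.80
        assert called[het].mean() <= 0.01
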