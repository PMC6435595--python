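"""Clone-model initialization, objective, optimizer and EM driver."""

import numpy as np
import pytest

from purecall.clonal import (FitData, assign_variant_clone, em_driver,
                             init_params, objective, optimize)
from purecall.config import PriorConfig
from purecall.containers import CloneModel, SiteCounts
from purecall.copy_number import ScoreInputs
from purecall.classify import site_states, somatic_assignment
from purecall.likelihood import (allele_count_loglik, delta_f_prior,
                                 exon_depth_loglik, expected_het_af)
from purecall.segmentation import segment_genome
from purecall.simulate import SimConfig, simulate_counts
from purecall import clonal as clonal_mod


def _fit_data(sim):
    return FitData(sites=sim.sites, exons=sim.exons,
                   annotation=sim.annotation)


def _prepared(sim, cfg, true_labels=True):
    """Segments + score inputs with truth-derived labels."""
    data = _fit_data(sim)
    het = (sim.truth["true_class"] == "germline_het").to_numpy()
    som = (sim.truth["true_class"] == "somatic").to_numpy()
    segs = segment_genome(sim.exons, sim.sites, het, cfg, seed=0)
    pos0 = sim.sites.pos - 1
    for s in segs:
        s.het_indices = np.where(het & s.contains(sim.sites.chrom, pos0))[0]
    si = ScoreInputs(sim.sites, sim.exons, data.db_mask(cfg), het, som,
                     int(data.db_mask(cfg).sum()), cfg.rho_snv)
    return data, segs, si, np.where(som)[0]


class TestInit:
    def test_structure_two_samples(self, cfg):
        sim = simulate_counts(SimConfig(purities=(0.2, 0.6),
                                        coverage=(100, 100), n_somatic=20,
                                        n_germline_het=200, seed=8))
        cm = init_params(_fit_data(sim), cfg)
        assert cm.n_clones == 5                      # 2J + 1
        np.testing.assert_allclose(cm.f[0], [0.1, 0.7])

    def test_structure_single_sample(self, cfg):
        sim = simulate_counts(SimConfig(purities=(0.5,), coverage=(100,),
                                        n_somatic=10, n_germline_het=100,
                                        seed=8))
        cm = init_params(_fit_data(sim), cfg)
        assert cm.n_clones == 3

    def test_dispersion_large_for_binomial_hets(self, cfg):
        # pure binomial draws: method-of-moments must infer low
        # overdispersion, i.e. W far above the read depth
        sim = simulate_counts(SimConfig(purities=(0.5, 0.5),
                                        coverage=(100, 100), n_somatic=0,
                                        n_germline_het=2000, seed=9))
        cm = init_params(_fit_data(sim), cfg)
        assert np.all(cm.w_disp >= 10 * 100)

    def test_centering_maps_diploid_to_control(self, cfg):
        sim = simulate_counts(SimConfig(purities=(0.4, 0.4),
                                        coverage=(100, 100), n_somatic=0,
                                        n_germline_het=500, seed=10,
                                        control_depth=200))
        cm = init_params(_fit_data(sim), cfg)
        # R_T = 2 R_C / C at diploid: C ~ 2 * 200 / 100; the heuristic
        # uses medians of lognormal depths, so allow their small bias
        np.testing.assert_allclose(cm.c_center, [4.0, 4.0], rtol=0.1)


class TestObjective:
    def test_empty_clone_changes_score_by_penalty(self, cfg):
        sim = simulate_counts(SimConfig(purities=(0.3, 0.6),
                                        coverage=(100, 100), n_somatic=0,
                                        n_germline_het=300, seed=11))
        _, segs, si, _ = _prepared(sim, cfg)
        cm = CloneModel(f=[[0.3, 0.6]], c_center=[4, 4], w_disp=[1e4, 1e4])
        cm2 = CloneModel(f=np.vstack([cm.f, [0.2, 0.2]]),
                         c_center=cm.c_center, w_disp=cm.w_disp)
        base = objective(cm, segs, si, cfg)
        grown = objective(cm2, segs, si, cfg)
        assert grown - base == pytest.approx(-2 * cfg.lambda_penalty)

    def test_score_equals_hand_summed_components(self, cfg):
        """Tiny single-segment fixture: the objective equals the sum of
        its printed ingredients computed one by one."""
        sim = simulate_counts(SimConfig(purities=(0.3, 0.6),
                                        coverage=(100, 100), n_somatic=5,
                                        n_germline_het=20, seed=12))
        _, segs, si, som_idx = _prepared(sim, cfg)
        assert len(segs) == 1
        seg = segs[0]
        f = np.array([0.3, 0.6])
        cm = CloneModel(f=f[None, :], c_center=[4, 4], w_disp=[1e4, 1e4])
        got = objective(cm, segs, si, cfg,
                        somatic_sites=sim.sites.subset(som_idx))

        # hand computation, neutral (2,1) segment: no delta-f factor
        pi_n = np.log(cfg.copy_number_prior(2))
        pi_m = np.log(cfg.minor_prior(1))
        want = 0.0
        for j in range(2):
            lx = exon_depth_loglik(si.exons.r_tumor_mean[seg.exon_indices, j],
                                   si.exons.r_control_mean[seg.exon_indices],
                                   2, f[j], 4.0)
            want += pi_n + lx.mean()
            phi = expected_het_af(f[j], 2, 1)
            ly = allele_count_loglik(si.sites.r_b[seg.het_indices, j],
                                     si.sites.r_total[seg.het_indices, j],
                                     phi, 1e4)
            want += pi_m + ly.mean()
        som = sim.sites.subset(som_idx)
        _, _, ll = somatic_assignment(som, cm, site_states(som, segs), cfg)
        want += np.mean(np.log(delta_f_prior(f, cfg)) + ll.sum(axis=1))
        want -= 2 * 1 * cfg.lambda_penalty
        assert got == pytest.approx(want)

    def test_nesting_without_penalty(self, cfg):
        """With lambda = 0 a superset model never scores worse at the
        same shared parameters."""
        from dataclasses import replace
        cfg0 = replace(cfg, lambda_penalty=0.0)
        sim = simulate_counts(SimConfig(purities=(0.3, 0.6),
                                        coverage=(100, 100), n_somatic=10,
                                        n_germline_het=200, seed=13))
        _, segs, si, som_idx = _prepared(sim, cfg0)
        som = sim.sites.subset(som_idx)
        cm = CloneModel(f=[[0.3, 0.6]], c_center=[4, 4], w_disp=[1e4, 1e4])
        cm2 = CloneModel(f=np.vstack([cm.f, [0.8, 0.1]]),
                         c_center=cm.c_center, w_disp=cm.w_disp)
        assert objective(cm2, segs, si, cfg0, som) \
            >= objective(cm, segs, si, cfg0, som) - 1e-9


class TestOptimize:
    def test_stops_after_xi_stale_iterations(self, cfg, monkeypatch, rng):
        sim = simulate_counts(SimConfig(purities=(0.3, 0.6),
                                        coverage=(100, 100), n_somatic=0,
                                        n_germline_het=100, seed=14))
        _, segs, si, _ = _prepared(sim, cfg)
        cm = init_params(_fit_data(sim), cfg)
        monkeypatch.setattr(clonal_mod, "objective",
                            lambda *a, **k: 0.0)     # constant surface
        trace = []
        optimize(cm, segs, si, cfg, seed=0, trace=trace)
        assert len(trace) == cfg.xi
        assert not any(t["improved"] for t in trace)

    def test_penalty_suppresses_spurious_clones(self, cfg):
        """Data generated by a single clone: the fitted model keeps at
        most two clonal groups in nearly all seeded runs."""
        sim = simulate_counts(SimConfig(purities=(0.25, 0.6),
                                        coverage=(150, 150), n_somatic=60,
                                        n_germline_het=600, seed=15))
        _, segs, si, som_idx = _prepared(sim, cfg)
        som = sim.sites.subset(som_idx)
        small_k = 0
        n_runs = 8
        for r in range(n_runs):
            cm0 = init_params(_fit_data(sim), cfg)
            cm, _, _ = optimize(cm0, segs, si, cfg, seed=100 + r,
                                somatic_sites=som)
            small_k += cm.n_clones <= 2
        assert small_k >= int(0.9 * n_runs)


class TestVariantCloneAssignment:
    def test_single_clone_diploid(self, cfg):
        sim = simulate_counts(SimConfig(purities=(0.3, 0.6),
                                        coverage=(200, 200), n_somatic=10,
                                        n_germline_het=50, seed=16))
        _, segs, si, som_idx = _prepared(sim, cfg)
        cm = CloneModel(f=[[0.3, 0.6]], c_center=[4, 4], w_disp=[1e4, 1e4])
        k, a = assign_variant_clone(sim.sites, cm, segs, cfg,
                                    site_index=int(som_idx[0]))
        assert k == 1

    def test_major_allele_recovered_in_gain(self, cfg):
        """Somatic variants on the major allele of a (3,1) gain at 60%
        purity, 400X: the allele call is 2 almost always."""
        sim = simulate_counts(SimConfig(purities=(0.6, 0.6),
                                        coverage=(400, 400), n_total=3,
                                        m_minor=1, somatic_allele=2,
                                        n_somatic=100, n_germline_het=500,
                                        seed=17))
        _, segs, si, som_idx = _prepared(sim, cfg)
        for s in segs:       # evaluate at the true copy state
            if s.chrom == "chr2":
                s.n_total, s.m_minor = 3, 1
        cm = CloneModel(f=[[0.6, 0.6]], c_center=[4, 4], w_disp=[1e4, 1e4])
        som = sim.sites.subset(som_idx)
        _, a_z, _ = somatic_assignment(som, cm, site_states(som, segs), cfg)
        assert (a_z == 2).mean() >= 0.95

    def test_zero_alt_reads_still_assigned(self, cfg):
        sites = SiteCounts(chrom=["chr1"], pos=[100], ref_allele=["A"],
                           a_allele=["A"], b_allele=["T"],
                           r_total=[[100, 120]], r_b=[[0, 0]])
        cm = CloneModel(f=[[0.3, 0.6]], c_center=[4, 4], w_disp=[1e4, 1e4])
        k, a = assign_variant_clone(sites, cm, [], cfg)
        assert k >= 1 and a in (1, 2)


class TestEMDriver:
    def test_recovers_sample_fractions(self, recovery_sim, recovery_fit):
        """Two-sample diploid data at purities (0.25, 0.60): the main
        clone's fractions land within +/-0.05 per sample."""
        cm = recovery_fit.clone_model
        truth = np.array([0.25, 0.60])
        best = min(np.abs(cm.f - truth).max(axis=1))
        assert best <= 0.05

    def test_recovery_dispersion_and_centering(self, recovery_sim,
                                               recovery_fit):
        cm = recovery_fit.clone_model
        # true C = 2 * control / coverage = 2 * 200 / 200
        np.testing.assert_allclose(cm.c_center, [2.0, 2.0], rtol=0.2)
        assert np.all(cm.w_disp >= 500)     # binomial data: large W

    def test_converges_quickly(self, recovery_fit):
        assert recovery_fit.converged
        assert recovery_fit.n_iter <= 10

    def test_zero_candidates_copy_number_only(self, cfg):
        sim = simulate_counts(SimConfig(purities=(0.3, 0.6),
                                        coverage=(100, 100), n_somatic=0,
                                        n_germline_het=200, seed=18))
        sim.sites.r_b[:] = 0                 # nothing reaches candidacy
        res = em_driver(_fit_data(sim), cfg, seed=0)
        assert res.converged
        assert (res.calls["label"] == "Somatic").sum() == 0
        assert len(res.segments) >= 1

    def test_final_k_bounded(self, recovery_fit, cfg):
        j = 2
        assert recovery_fit.clone_model.n_clones \
            <= 2 * j + 1 + cfg.max_extra_clones
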