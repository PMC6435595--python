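"""Allele-specific copy-number state assignment per segment.

Each segment g gets the total copy number N, minor allele copy number M
and clonal group index k that maximize the segment score SLL_g: the
exon-depth Poisson likelihoods with the copy-number prior, the het
allele-count beta-binomial likelihoods with the minor-copy and
sample-fraction-difference priors, and two database-count penalty terms
that keep the genotype mix at known germline positions plausible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (CloneModel, DegenerateStateError, ExonDepth,
                         SegmentState, SiteCounts)
from .config import PriorConfig
from .likelihood import (allele_count_loglik, delta_f_prior,
                         exon_depth_loglik, expected_het_af,
                         het_count_loglik, het_detect_prob,
                         somatic_at_db_loglik)

__all__ = ["ScoreInputs", "segment_score", "assign_states"]


@dataclass
class ScoreInputs:
    """Per-run data shared by all segment-score evaluations.

    ``db_mask`` flags sites whose population minor-allele frequency
    exceeds the somatic ceiling (database germline positions);
    ``het_labels`` / ``somatic_labels`` are the current classification of
    each site; ``eta_d`` is the genome-wide database position count.
    """

    sites: SiteCounts
    exons: ExonDepth
    db_mask: np.ndarray
    het_labels: np.ndarray
    somatic_labels: np.ndarray
    eta_d: int
    rho: float

    def db_counts(self, seg: SegmentState):
        """(eta_dg, Y_dg, Z_dg) for the segment."""
        pos0 = self.sites.pos - 1
        inside = seg.contains(self.sites.chrom, pos0) & self.db_mask
        return (int(inside.sum()),
                int((inside & self.het_labels).sum()),
                int((inside & self.somatic_labels).sum()))


def segment_score(seg: SegmentState, n_total: int, m_minor: int,
                  clone_index: int, clone_model: CloneModel,
                  data: ScoreInputs, cfg: PriorConfig,
                  delta_prior_cache=None) -> float:
    """Segment log-likelihood score SLL_g for a candidate state."""
    f = clone_model.f[clone_index - 1]            # length J
    c = clone_model.c_center
    w = clone_model.w_disp
    j_n = clone_model.n_samples
    log_pi_n = np.log(max(cfg.copy_number_prior(n_total), 1e-300))
    log_pi_m = np.log(max(cfg.minor_prior(m_minor), 1e-300))
    if (n_total, m_minor) == (2, 1):
        # copy-neutral: no alteration, hence no carrying clone and no
        # sample-fraction-difference prior factor
        log_pi_df = 0.0
    elif delta_prior_cache is not None:
        log_pi_df = delta_prior_cache[clone_index - 1]
    else:
        log_pi_df = np.log(max(delta_f_prior(f, cfg), 1e-300))

    try:
        phi_g = expected_het_af(f, n_total, m_minor)   # length J
    except DegenerateStateError:
        return -np.inf
    phi_g = np.atleast_1d(phi_g)

    ex = seg.exon_indices
    r_t = data.exons.r_tumor_mean[ex]                  # (X, J)
    r_c = data.exons.r_control_mean[ex][:, None]
    lxj = exon_depth_loglik(r_t, r_c, n_total, f[None, :], c[None, :])
    score = float(np.sum(log_pi_n + lxj.mean(axis=0)))

    het = seg.het_indices
    if len(het):
        rb = data.sites.r_b[het]                       # (Y, J)
        rt = data.sites.r_total[het]
        lyj = allele_count_loglik(rb, rt, phi_g[None, :], w[None, :])
        score += float(np.sum(log_pi_df + log_pi_m + lyj.mean(axis=0)))

    eta_dg, y_dg, z_dg = data.db_counts(seg)
    if eta_dg > 0 and data.eta_d > 0:
        depth_j = r_t.mean(axis=0)
        weight = eta_dg / data.eta_d
        for j in range(j_n):
            p_het = het_detect_prob(depth_j[j], phi_g[j], cfg.r_b_min)
            score += weight * (het_count_loglik(y_dg, eta_dg, p_het)
                               + somatic_at_db_loglik(z_dg, eta_dg,
                                                      data.rho))
    return score


def assign_states(segments, clone_model: CloneModel, data: ScoreInputs,
                  cfg: PriorConfig):
    """Exhaustive argmax of SLL_g over the state grid for every segment.

    Grid: N in 0..n_max, M in 0..N//2, k in 1..K.  Ties resolve to the
    lowest N, then the highest M, then the lowest clone index; the
    result is independent of segment ordering.  Segments are updated in
    place and the total best score returned.
    """
    if not segments:
        raise ValueError("no segments to assign")
    log_df = np.log(np.maximum(
        [delta_f_prior(clone_model.f[k], cfg)
         for k in range(clone_model.n_clones)], 1e-300))
    total = 0.0
    for seg in segments:
        best = (-np.inf, None)
        for n in range(cfg.n_max + 1):
            for m in range(n // 2, -1, -1):       # highest M first
                for k in range(1, clone_model.n_clones + 1):
                    s = segment_score(seg, n, m, k, clone_model, data,
                                      cfg, delta_prior_cache=log_df)
                    if s > best[0]:
                        best = (s, (n, m, k))
        if best[1] is None:
            raise RuntimeError("no valid state for segment "
                               f"{seg.chrom}:{seg.start}-{seg.end}")
        seg.n_total, seg.m_minor, seg.clone_index = best[1]
        seg.n_bases_db, _, _ = data.db_counts(seg)
        total += best[0]
    return total
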