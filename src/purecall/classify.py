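"""Joint somatic / germline-het / homozygous classification.

Read counts in the J samples are assumed independent given the genotype,
so the joint likelihood of each genotype is the product of per-sample
beta-binomial likelihoods evaluated at that genotype's expected allele
fraction: phi_S for somatic (at the maximum-likelihood clone and
allele), phi_G for germline heterozygous, a sequencing-error fraction
e_hom for homozygous A, and 1 - e_hom for the remaining (BB) genotype.
Posteriors combine these with population-frequency Hardy-Weinberg priors
and a hotspot-scaled somatic rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .containers import CloneModel, SiteAnnotation, SiteCounts
from .config import PriorConfig
from .likelihood import _somatic_af, allele_count_loglik, expected_het_af

__all__ = ["VariantCall", "site_priors", "conditional_loglik",
           "joint_posterior", "classify_sites", "site_states",
           "somatic_assignment"]

LABELS = ("Somatic", "GermlineHet", "Homozygous", "Unknown", "Reject")


@dataclass
class VariantCall:
    """Joint classification of one candidate position."""

    chrom: str
    pos: int
    posterior_somatic: float
    posterior_het: float
    posterior_hom: float
    posterior_other: float
    clone_index: int
    allele: int
    af_expected: np.ndarray
    trust_score: float
    label: str


def site_priors(annotation: SiteAnnotation, cfg: PriorConfig, is_indel):
    """Normalized genotype priors (pi_S, pi_AB, pi_AA, pi_O) per site.

    Alleles unseen in the population panels get the configured default
    frequency; sites whose minor population frequency exceeds
    ``f_max_somatic`` cannot be somatic (pi_S = 0).  The somatic prior is
    the baseline rate rho scaled by (1 + omega) hotspot observations.
    """
    is_indel = np.asarray(is_indel, dtype=bool)
    f_default = np.where(is_indel, cfg.f_pop_default_indel,
                         cfg.f_pop_default_snv)
    rho = np.where(is_indel, cfg.rho_indel, cfg.rho_snv)
    f_b = np.where(annotation.f_pop_b > 0, annotation.f_pop_b, f_default)
    f_a = np.where(annotation.f_pop_a > 0, annotation.f_pop_a, 1.0 - f_b)
    pi_aa = (1.0 - f_b) ** 2
    pi_ab = 2.0 * f_b * (1.0 - f_b)
    pi_s = rho * (1.0 + annotation.omega)
    pi_s = np.where(np.minimum(f_a, f_b) > cfg.f_max_somatic, 0.0, pi_s)
    pi_o = np.full_like(pi_aa, cfg.pi_other)
    total = pi_s + pi_ab + pi_aa + pi_o
    return pi_s / total, pi_ab / total, pi_aa / total, pi_o / total


def site_states(sites: SiteCounts, segments):
    """Per-site (N, M, k_g) from segment membership; diploid copy-neutral
    defaults for sites outside every segment."""
    n = np.full(sites.n_sites, 2, dtype=int)
    m = np.ones(sites.n_sites, dtype=int)
    k = np.ones(sites.n_sites, dtype=int)
    pos0 = sites.pos - 1
    for seg in segments:
        inside = seg.contains(sites.chrom, pos0)
        n[inside], m[inside], k[inside] = seg.n_total, seg.m_minor, \
            seg.clone_index
    return n, m, k


def somatic_assignment(sites: SiteCounts, clone_model: CloneModel,
                       states, cfg: PriorConfig):
    """Maximum-likelihood clone and allele for each site as a somatic
    variant.

    Returns (k_z, a_z, ll_somatic) where ll_somatic has shape
    (n_sites, J), evaluated at the chosen clone/allele.  The allele is
    only free when the variant shares the segment's altered clone; ties
    resolve to the lowest clone index, then the minor allele.
    """
    n_arr, m_arr, kg_arr = (np.asarray(a) for a in states)
    k_count = clone_model.n_clones
    f = clone_model.f                                   # (K, J)
    f_kg = f[kg_arr - 1]                                # (n, J)
    # phi[i, j, k, a]
    f_kz = f.T[None, :, :, None]                        # (1, J, K, 1)
    same = (np.arange(1, k_count + 1)[None, :] == kg_arr[:, None])
    same4 = same[:, None, :, None]
    allele4 = np.array([1, 2])[None, None, None, :]
    phi = _somatic_af(f_kz, f_kg[:, :, None, None],
                      n_arr[:, None, None, None],
                      m_arr[:, None, None, None], same4, allele4)
    ll = allele_count_loglik(sites.r_b[:, :, None, None],
                             sites.r_total[:, :, None, None], phi,
                             clone_model.w_disp[None, :, None, None])
    # drop the redundant major-allele option when the clone differs
    ll_opts = ll.sum(axis=1)                            # (n, K, 2)
    ll_opts = np.where(same4[:, 0] | (allele4[:, 0] == 1), ll_opts, -np.inf)
    flat = ll_opts.reshape(len(n_arr), -1)
    pick = np.argmax(flat, axis=1)                      # first max = tiebreak
    k_z = pick // 2 + 1
    a_z = pick % 2 + 1
    idx = np.arange(len(n_arr))
    ll_somatic = ll[idx, :, k_z - 1, a_z - 1]
    return k_z, a_z, ll_somatic


def conditional_loglik(sites: SiteCounts, sample_j: int, genotype: str,
                       clone_model: CloneModel, segments,
                       cfg: PriorConfig) -> np.ndarray:
    """log P(D_j | genotype) per site, genotype in {S, G_AB, G_AA, O}."""
    states = site_states(sites, segments)
    rb, rt = sites.r_b[:, sample_j], sites.r_total[:, sample_j]
    w = clone_model.w_disp[sample_j]
    if genotype == "S":
        _, _, ll = somatic_assignment(sites, clone_model, states, cfg)
        return ll[:, sample_j]
    if genotype == "G_AB":
        n_arr, m_arr, kg = states
        phi = expected_het_af(clone_model.f[kg - 1, sample_j], n_arr, m_arr)
        return allele_count_loglik(rb, rt, phi, w)
    if genotype == "G_AA":
        return allele_count_loglik(rb, rt, cfg.e_hom, w)
    if genotype == "O":
        return allele_count_loglik(rb, rt, 1.0 - cfg.e_hom, w)
    raise ValueError(f"unknown genotype {genotype!r}")


def classify_sites(sites: SiteCounts, annotation: SiteAnnotation,
                   segments, clone_model: CloneModel, cfg: PriorConfig,
                   trust_score=None, candidate_mask=None) -> pd.DataFrame:
    """Joint posterior classification of all sites; returns the call table.

    Sites failing the candidate or trust gates are labeled ``Reject``;
    sites whose four posteriors all stay below their thresholds are
    ``Unknown``.
    """
    n_sites = sites.n_sites
    states = site_states(sites, segments)
    n_arr, m_arr, kg_arr = states
    k_z, a_z, ll_s = somatic_assignment(sites, clone_model, states, cfg)
    phi_g = expected_het_af(clone_model.f[kg_arr - 1], n_arr[:, None],
                            m_arr[:, None])
    w = clone_model.w_disp[None, :]
    ll_ab = allele_count_loglik(sites.r_b, sites.r_total, phi_g, w)
    ll_aa = allele_count_loglik(sites.r_b, sites.r_total, cfg.e_hom, w)
    ll_o = allele_count_loglik(sites.r_b, sites.r_total, 1.0 - cfg.e_hom, w)

    pi = np.stack(site_priors(annotation, cfg, sites.is_indel), axis=1)
    with np.errstate(divide="ignore"):
        log_joint = np.stack([ll_s.sum(1), ll_ab.sum(1), ll_aa.sum(1),
                              ll_o.sum(1)], axis=1) + np.log(pi)
    norm = logsumexp(log_joint, axis=1)
    bad = ~np.isfinite(norm)
    post = np.exp(log_joint - np.where(bad, 0.0, norm)[:, None])
    post[bad] = 0.0

    label = np.full(n_sites, "Unknown", dtype=object)
    label[post[:, 0] >= cfg.t_somatic] = "Somatic"
    label[post[:, 1] >= cfg.t_germline] = "GermlineHet"
    label[post[:, 2] >= cfg.t_germline] = "Homozygous"
    if candidate_mask is not None:
        label[~np.asarray(candidate_mask, bool)] = "Reject"
    if trust_score is not None:
        label[np.asarray(trust_score) <= cfg.t_pass] = "Reject"

    idx = np.arange(n_sites)
    f_kz = clone_model.f[k_z - 1]                       # (n, J)
    same = k_z == kg_arr
    af_exp = _somatic_af(f_kz, clone_model.f[kg_arr - 1],
                         n_arr[:, None], m_arr[:, None],
                         same[:, None], a_z[:, None])
    out = pd.DataFrame({
        "chrom": sites.chrom, "pos": sites.pos, "ref": sites.ref_allele,
        "A": sites.a_allele, "B": sites.b_allele,
        "p_somatic": post[:, 0], "p_het": post[:, 1],
        "p_hom": post[:, 2], "p_other": post[:, 3],
        "clone": k_z, "allele": a_z, "label": label,
        "n_total": n_arr, "m_minor": m_arr,
    })
    for j in range(sites.n_samples):
        out[f"af_exp_s{j}"] = af_exp[:, j]
        out[f"dp_s{j}"] = sites.r_total[:, j]
        out[f"ad_b_s{j}"] = sites.r_b[:, j]
    out["trust"] = 1.0 if trust_score is None else np.asarray(trust_score)
    return out


def joint_posterior(sites: SiteCounts, annotation: SiteAnnotation,
                    segments, clone_model: CloneModel, cfg: PriorConfig,
                    site_index: int = 0, trust_score: float = 1.0
                    ) -> VariantCall:
    """Classification of a single site as a :class:`VariantCall`."""
    df = classify_sites(sites, annotation, segments, clone_model, cfg)
    row = df.iloc[site_index]
    return VariantCall(
        chrom=row["chrom"], pos=int(row["pos"]),
        posterior_somatic=float(row["p_somatic"]),
        posterior_het=float(row["p_het"]),
        posterior_hom=float(row["p_hom"]),
        posterior_other=float(row["p_other"]),
        clone_index=int(row["clone"]), allele=int(row["allele"]),
        af_expected=np.array([row[f"af_exp_s{j}"]
                              for j in range(sites.n_samples)]),
        trust_score=trust_score, label=row["label"])
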