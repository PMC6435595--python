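"""Clonal variant group fitting: initialization, objective, optimizer
and the outer expectation-maximization driver.

The parameters are the K x J sample-fraction matrix f, the per-sample
depth centering C and the per-sample beta-binomial concentration W.  The
objective is the sum of segment scores plus the averaged somatic variant
log-likelihoods with their sample-fraction-difference prior, minus a
J * K * lambda penalty on model size.  The search alternates bounded
derivative-free local optimization (on logit/log-transformed parameters)
with re-centering, clone addition (seeded random trial columns) and
clone removal, stopping after xi consecutive macro-iterations without a
new maximum.  The outer EM alternates copy-state assignment, joint
classification and parameter optimization until the call set stabilizes.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .classify import classify_sites, site_states, somatic_assignment
from .config import PriorConfig
from .containers import CloneModel, ExonDepth, SiteAnnotation, SiteCounts
from .copy_number import ScoreInputs, assign_states, segment_score
from .likelihood import delta_f_prior
from .segmentation import segment_genome, select_common_hets

__all__ = ["FitData", "init_params", "objective", "optimize",
           "assign_variant_clone", "em_driver", "EMResult"]

log = logging.getLogger(__name__)

_F_EPS = 1e-4       # logit clipping for sample fractions
_IMPROVE_TOL = 1e-6


@dataclass
class FitData:
    """Input bundle for a joint calling run."""

    sites: SiteCounts
    exons: ExonDepth
    annotation: SiteAnnotation
    trust: np.ndarray = None        # per-site quality trust score

    def __post_init__(self):
        if self.trust is None:
            self.trust = np.ones(self.sites.n_sites)

    @property
    def n_samples(self) -> int:
        return self.sites.n_samples

    def db_mask(self, cfg: PriorConfig) -> np.ndarray:
        """Database germline positions: population minor-allele frequency
        above the somatic ceiling."""
        return np.minimum(self.annotation.f_pop_a,
                          self.annotation.f_pop_b) > cfg.f_max_somatic


def _prior_fractions(cfg: PriorConfig, n_samples: int) -> np.ndarray:
    f_pi = np.asarray(cfg.f_prior, dtype=float)
    if len(f_pi) == n_samples:
        return f_pi
    if n_samples == 1:
        return np.array([f_pi.mean()])
    # interpolate the configured low..high range across the samples
    return np.interp(np.linspace(0, 1, n_samples),
                     np.linspace(0, 1, len(f_pi)), np.sort(f_pi))


def init_params(data: FitData, cfg: PriorConfig, het_mask=None) -> CloneModel:
    """Heuristic starting point for {f, W, C}.

    K = 2J + 1 clonal variant groups: one main group at the prior
    fractions in every sample, J groups clonal in one sample each and low
    elsewhere, and J groups subclonal in one sample each and very low
    elsewhere.  C maps the median tumor/control depth ratio to the
    diploid expectation; W comes from a method-of-moments fit of the
    allele-fraction overdispersion at heterozygous sites.
    """
    j_n = data.n_samples
    f_pi = _prior_fractions(cfg, j_n)
    rows = [f_pi]
    for j in range(j_n):
        row = np.full(j_n, cfg.f_init_private)
        row[j] = f_pi[j]
        rows.append(row)
    for j in range(j_n):
        row = np.full(j_n, cfg.f_init_sub_private)
        row[j] = cfg.f_init_sub_scale * f_pi[j]
        rows.append(row)
    f = np.clip(np.array(rows), _F_EPS, 1 - _F_EPS)

    r_c = data.exons.r_control_mean
    c = np.empty(j_n)
    for j in range(j_n):
        r_t = data.exons.r_tumor_mean[:, j]
        ok = (r_t > 0) & (r_c > 0)
        c[j] = 2.0 * np.median(r_c[ok] / r_t[ok]) if ok.any() else 2.0

    if het_mask is None:
        with np.errstate(invalid="ignore"):
            af_pool = data.sites.r_b.sum(1) / np.maximum(
                data.sites.r_total.sum(1), 1)
        het_mask = (af_pool > 0.3) & (af_pool < 0.7)
    w = np.empty(j_n)
    for j in range(j_n):
        n = data.sites.r_total[het_mask, j]
        k = data.sites.r_b[het_mask, j]
        ok = n >= 10
        if ok.sum() < 10:
            w[j] = 100.0
            continue
        p = k[ok] / n[ok]
        phi = p.mean()
        var_obs = p.var()
        var_binom = np.mean(phi * (1 - phi) / n[ok])
        excess = var_obs - var_binom
        denom = phi * (1 - phi) * np.mean(1.0 - 1.0 / n[ok])
        rho_ic = max(excess / denom, 1e-7) if denom > 0 else 1e-7
        w[j] = np.clip(1.0 / rho_ic - 1.0, 10.0, 1e6)
    return CloneModel(f=f, c_center=c, w_disp=w)


def objective(clone_model: CloneModel, segments, score_inputs: ScoreInputs,
              cfg: PriorConfig, somatic_sites: SiteCounts = None) -> float:
    """Model score: sum of segment scores at their assigned states, plus
    the averaged somatic term, minus the J*K*lambda size penalty."""
    log_df = np.log(np.maximum(
        [delta_f_prior(clone_model.f[k], cfg)
         for k in range(clone_model.n_clones)], 1e-300))
    total = 0.0
    for seg in segments:
        total += segment_score(seg, seg.n_total, seg.m_minor,
                               seg.clone_index, clone_model, score_inputs,
                               cfg, delta_prior_cache=log_df)
    if somatic_sites is not None and somatic_sites.n_sites:
        k_z, _, ll = somatic_assignment(somatic_sites, clone_model,
                                        site_states(somatic_sites, segments),
                                        cfg)
        total += float(np.mean(log_df[k_z - 1] + ll.sum(axis=1)))
    total -= clone_model.n_samples * clone_model.n_clones * cfg.lambda_penalty
    if not np.isfinite(total):
        raise FloatingPointError("non-finite model objective")
    return total


def _pack(cm: CloneModel) -> np.ndarray:
    return np.concatenate([logit(np.clip(cm.f, _F_EPS, 1 - _F_EPS)).ravel(),
                           np.log(cm.w_disp), np.log(cm.c_center)])


def _unpack(x: np.ndarray, k: int, j: int) -> CloneModel:
    f = expit(x[:k * j]).reshape(k, j)
    w = np.exp(np.clip(x[k * j:k * j + j], np.log(2.0), np.log(1e7)))
    c = np.exp(np.clip(x[k * j + j:], np.log(0.05), np.log(50.0)))
    return CloneModel(f=f, c_center=c, w_disp=w)


def _segments_without_clone(segments, drop_k: int):
    """Shallow segment copies with clone indices remapped after removing
    clone ``drop_k`` (1-based); orphaned segments fall back to clone 1."""
    out = []
    for seg in segments:
        s = copy.copy(seg)
        if s.clone_index == drop_k:
            s.clone_index = 1
        elif s.clone_index > drop_k:
            s.clone_index -= 1
        out.append(s)
    return out


def optimize(clone_model: CloneModel, segments, score_inputs: ScoreInputs,
             cfg: PriorConfig, seed: int = 0,
             somatic_sites: SiteCounts = None, trace: list = None):
    """Maximize the objective over {f, W, C} and the number of clones.

    Returns (clone_model, segments, score).  Segments are returned
    because removing a clonal group remaps segment clone indices.  If
    ``trace`` is a list, one record per macro-iteration is appended.
    """
    rng = np.random.default_rng(seed)
    j_n = clone_model.n_samples
    k_cap = 2 * j_n + 1 + cfg.max_extra_clones

    def obj(cm, segs):
        return objective(cm, segs, score_inputs, cfg, somatic_sites)

    def local_opt(cm, segs):
        k = cm.n_clones
        x0 = _pack(cm)
        res = minimize(lambda x: -obj(_unpack(x, k, j_n), segs), x0,
                       method="Nelder-Mead",
                       options={"maxfev": cfg.opt_maxfev_per_param * len(x0),
                                "fatol": 1e-3, "xatol": 1e-3})
        cm_new = _unpack(res.x, k, j_n)
        return cm_new, obj(cm_new, segs)

    best_cm, best_segs = clone_model.copy(), list(segments)
    best = obj(best_cm, best_segs)
    stale = 0
    while stale < cfg.xi:
        improved = False

        # --- re-centering: alternative C starting points -----------------
        factors = (0.5, 2.0 / 3.0, 1.0, 4.0 / 3.0, 1.5, 2.0)
        starts = []
        for fac in factors:
            cm = best_cm.copy()
            cm.c_center = cm.c_center * fac
            starts.append((obj(cm, best_segs), fac, cm))
        _, _, cm0 = max(starts, key=lambda t: t[0])
        cm_new, s_new = local_opt(cm0, best_segs)
        if s_new > best + _IMPROVE_TOL:
            best_cm, best = cm_new, s_new
            improved = True

        # --- add clonal variant groups -----------------------------------
        while best_cm.n_clones < k_cap:
            trials = rng.random((cfg.n_add_trials, j_n))
            scored = []
            for row in trials:
                cm = CloneModel(np.vstack([best_cm.f,
                                           np.clip(row, _F_EPS, 1 - _F_EPS)]),
                                best_cm.c_center.copy(),
                                best_cm.w_disp.copy())
                scored.append((obj(cm, best_segs), cm))
            cm_new, s_new = local_opt(max(scored, key=lambda t: t[0])[1],
                                      best_segs)
            if s_new > best + _IMPROVE_TOL:
                best_cm, best = cm_new, s_new
                improved = True
            else:
                break

        # --- remove clonal variant groups --------------------------------
        while best_cm.n_clones > 1:
            scored = []
            for drop in range(1, best_cm.n_clones + 1):
                f = np.delete(best_cm.f, drop - 1, axis=0)
                cm = CloneModel(f, best_cm.c_center.copy(),
                                best_cm.w_disp.copy())
                segs = _segments_without_clone(best_segs, drop)
                scored.append((obj(cm, segs), cm, segs))
            s_try, cm_try, segs_try = max(scored, key=lambda t: t[0])
            cm_new, s_new = local_opt(cm_try, segs_try)
            if s_new > best + _IMPROVE_TOL:
                best_cm, best_segs, best = cm_new, segs_try, s_new
                improved = True
            else:
                break

        stale = 0 if improved else stale + 1
        if trace is not None:
            trace.append({"improved": improved, "K": best_cm.n_clones,
                          "score": best})
    return best_cm, best_segs, best


def assign_variant_clone(sites: SiteCounts, clone_model: CloneModel,
                         segments, cfg: PriorConfig, site_index: int = 0):
    """Maximum-likelihood (clone, allele) for one candidate somatic
    variant; ties break to the lower clone index, then the minor allele."""
    sub = sites.subset([site_index])
    k_z, a_z, _ = somatic_assignment(sub, clone_model,
                                     site_states(sub, segments), cfg)
    return int(k_z[0]), int(a_z[0])


@dataclass
class EMResult:
    """Converged (or best-seen) state of the outer EM."""

    clone_model: CloneModel
    segments: list
    calls: pd.DataFrame
    iterations: pd.DataFrame
    converged: bool
    n_iter: int
    objective: float


def _iteration_row(it, cm: CloneModel, score) -> dict:
    row = {"iteration": it, "K": cm.n_clones, "objective": score}
    for j in range(cm.n_samples):
        row[f"C_s{j}"] = cm.c_center[j]
        row[f"W_s{j}"] = cm.w_disp[j]
    for k in range(cm.n_clones):
        for j in range(cm.n_samples):
            row[f"f_k{k + 1}_s{j}"] = cm.f[k, j]
    return row


def em_driver(data: FitData, cfg: PriorConfig, seed: int = 0) -> EMResult:
    """Full joint-calling loop.

    Segments once, then iterates copy-state assignment, joint variant
    classification and parameter optimization until the somatic/germline
    call labels repeat, or ``max_em_iter`` is reached (then the
    best-scoring iterate is returned with a warning).
    """
    sites, exons = data.sites, data.exons
    candidate = (sites.r_b >= cfg.r_b_min).any(axis=1)
    with np.errstate(invalid="ignore"):
        af_pool = sites.r_b.sum(1) / np.maximum(sites.r_total.sum(1), 1)
    het_labels = candidate & (af_pool > 0.3) & (af_pool < 0.7)
    somatic_labels = np.zeros(sites.n_sites, dtype=bool)
    db_mask = data.db_mask(cfg)
    eta_d = int(db_mask.sum())

    f_pop_min = np.minimum(data.annotation.f_pop_a, data.annotation.f_pop_b)
    common = select_common_hets(sites, f_pop_min, cfg)
    clone_model = init_params(data, cfg, het_mask=het_labels)
    segments = segment_genome(exons, sites, common | het_labels, cfg, seed)

    pos0 = sites.pos - 1
    rows, prev_labels = [], None
    best = None
    converged = False
    calls = None
    score = -np.inf
    for it in range(1, cfg.max_em_iter + 1):
        for seg in segments:
            inside = seg.contains(sites.chrom, pos0)
            seg.het_indices = np.where(inside & het_labels)[0]
        score_inputs = ScoreInputs(sites, exons, db_mask, het_labels,
                                   somatic_labels, eta_d, cfg.rho_snv)
        assign_states(segments, clone_model, score_inputs, cfg)

        calls = classify_sites(sites, data.annotation, segments,
                               clone_model, cfg, trust_score=data.trust,
                               candidate_mask=candidate)
        labels = calls["label"].to_numpy()
        new_het = labels == "GermlineHet"
        new_som = labels == "Somatic"
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            converged = True
            rows.append(_iteration_row(it, clone_model, score))
            if best is None or score >= best[0]:
                best = (score, clone_model, segments, calls)
            break
        prev_labels = labels
        het_labels, somatic_labels = new_het, new_som

        score_inputs = ScoreInputs(sites, exons, db_mask, het_labels,
                                   somatic_labels, eta_d, cfg.rho_snv)
        som_idx = np.where(somatic_labels)[0]
        som_sites = sites.subset(som_idx) if len(som_idx) else None
        clone_model, segments, score = optimize(
            clone_model, segments, score_inputs, cfg,
            seed=seed + it, somatic_sites=som_sites)
        rows.append(_iteration_row(it, clone_model, score))
        if best is None or score > best[0]:
            best = (score, clone_model.copy(),
                    [copy.copy(s) for s in segments], calls)
        log.info("EM iteration %d: K=%d objective=%.2f somatic=%d het=%d",
                 it, clone_model.n_clones, score, int(new_som.sum()),
                 int(new_het.sum()))
    else:
        warnings.warn("EM did not converge within max_em_iter; returning "
                      "best-scoring iterate", RuntimeWarning)

    if converged:
        final = EMResult(clone_model, segments, calls,
                         pd.DataFrame(rows), True, it, score)
    else:
        score, clone_model, segments, calls = best
        final = EMResult(clone_model, segments, calls,
                         pd.DataFrame(rows), False, len(rows), score)
    return final
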