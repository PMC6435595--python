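"""Likelihood and prior primitives of the joint tumor-only model.

Expected allele fractions
-------------------------
With sample fraction ``f`` of tumor cells carrying a copy-number state
(N total, M minor copies), a germline heterozygous variant sits on the
minor allele of the altered cells and one of two alleles of the normal
cells, so its expected allele fraction is

    phi_G = (f * M + (1 - f)) / (f * N + 2 * (1 - f)).

A somatic variant's expected fraction phi_S depends on whether it shares
the clone of the copy alteration (and then which parental allele carries
it) or belongs to an independent, copy-neutral clone.

Counts
------
Exon mean depths are Poisson around the copy-scaled control depth;
allele counts are beta-binomial with concentration W; segment-level
het/somatic counts at database positions use binomial tails.  Everything
is computed and returned in log space.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, gammaln
from scipy.stats import beta as beta_dist
from scipy.stats import binom

from .containers import CloneModel, DegenerateStateError, SegmentState
from .config import ConfigError, PriorConfig

__all__ = [
    "expected_het_af", "expected_somatic_af", "exon_depth_loglik",
    "allele_count_loglik", "het_detect_prob", "het_count_loglik",
    "somatic_at_db_loglik", "delta_f_prior", "mean_pairwise_diff",
]


def _round_half_up(x):
    """Round half away from zero (for nonnegative x: half up), matching
    the model's printed round(.) convention rather than banker's rounding."""
    x = np.asarray(x, dtype=float)
    return np.floor(x + 0.5)


def expected_het_af(f, n_total, m_minor):
    """Expected allele fraction of a germline heterozygous variant.

    Parameters are broadcastable; ``f`` is the sample fraction of cells
    with the (N, M) state.  Raises :class:`DegenerateStateError` when the
    denominator vanishes (homozygous deletion at purity one).
    """
    f = np.asarray(f, dtype=float)
    n = np.asarray(n_total, dtype=float)
    m = np.asarray(m_minor, dtype=float)
    denom = f * n + 2.0 * (1.0 - f)
    if np.any(denom <= 0):
        raise DegenerateStateError(
            "undefined het allele fraction: homozygous deletion at purity 1")
    out = (f * m + (1.0 - f)) / denom
    return out if out.ndim else float(out)


def expected_somatic_af(clone_model: CloneModel, sample_j: int,
                        seg: SegmentState, k_z: int, allele_z: int):
    """Expected allele fraction of a somatic variant in sample ``j``.

    ``k_z`` is the 1-based clone carrying the variant and ``allele_z`` is
    1 (minor allele) or 2 (major allele); the allele only matters when
    the variant shares the clone of the segment's copy alteration.
    """
    if allele_z not in (1, 2):
        raise ValueError("allele_z must be 1 (minor) or 2 (major)")
    f_kg = clone_model.f[seg.clone_index - 1, sample_j]
    f_kz = clone_model.f[k_z - 1, sample_j]
    return _somatic_af(f_kz, f_kg, seg.n_total, seg.m_minor,
                       k_z == seg.clone_index, allele_z)


def _somatic_af(f_kz, f_kg, n_total, m_minor, same_clone, allele_z):
    """Vectorized somatic AF kernel (broadcasting arrays allowed)."""
    f_kz = np.asarray(f_kz, dtype=float)
    f_kg = np.asarray(f_kg, dtype=float)
    n = np.asarray(n_total, dtype=float)
    m = np.asarray(m_minor, dtype=float)
    denom = f_kg * n + 2.0 * (1.0 - f_kg)
    if np.any(denom <= 0):
        raise DegenerateStateError(
            "undefined somatic allele fraction: homozygous deletion at purity 1")
    same = np.asarray(same_clone, dtype=bool)
    a2 = np.asarray(allele_z, dtype=int) == 2
    copies = np.where(a2, n - m, m)
    num = np.where(same, f_kg * copies, f_kz)
    out = np.clip(num / denom, 0.0, 1.0)
    return out if out.ndim else float(out)


def exon_depth_loglik(r_tumor, r_control, n_total, f, c_center):
    """Log Poisson likelihood of an exon's mean tumor depth.

    The rate is the control depth rescaled for copy number, purity and
    centering: round((1/C) * (N f R_C + 2 (1 - f) R_C)); the observation
    is round(R_T).  Both are rounded half away from zero.  A zero rate
    with positive observed depth gives -inf.
    """
    obs = _round_half_up(r_tumor)
    rate = _round_half_up(
        (np.asarray(n_total, float) * np.asarray(f, float)
         + 2.0 * (1.0 - np.asarray(f, float)))
        * np.asarray(r_control, float) / np.asarray(c_center, float))
    obs, rate = np.broadcast_arrays(obs, rate)
    out = np.full(obs.shape, -np.inf)
    pos = rate > 0
    out[pos] = (obs[pos] * np.log(rate[pos]) - rate[pos]
                - gammaln(obs[pos] + 1.0))
    out[(rate == 0) & (obs == 0)] = 0.0
    return out if out.ndim else float(out)


def allele_count_loglik(r_b, r_total, phi, w_disp):
    """Log beta-binomial pmf of the B-allele count.

    alpha = W * phi, beta = W * (1 - phi); implemented with log-gamma for
    stability.  phi exactly 0 or 1 is the degenerate point mass at 0 or
    r_total reads.
    """
    k = np.asarray(r_b, dtype=float)
    n = np.asarray(r_total, dtype=float)
    phi = np.asarray(phi, dtype=float)
    w = np.asarray(w_disp, dtype=float)
    if np.any((phi < 0) | (phi > 1)):
        raise ValueError("phi must be in [0, 1]")
    k, n, phi, w = np.broadcast_arrays(k, n, phi, w)
    out = np.full(k.shape, -np.inf)
    interior = (phi > 0) & (phi < 1)
    if np.any(interior):
        a = w[interior] * phi[interior]
        b = w[interior] * (1.0 - phi[interior])
        ki, ni = k[interior], n[interior]
        out[interior] = (gammaln(ni + 1) - gammaln(ki + 1)
                         - gammaln(ni - ki + 1)
                         + betaln(ki + a, ni - ki + b) - betaln(a, b))
    out[(phi == 0) & (k == 0)] = 0.0
    out[(phi == 1) & (k == n)] = 0.0
    return out if out.ndim else float(out)


def het_detect_prob(r_total_mean, phi_het, r_b_min: int):
    """Probability that a germline het would reach candidate status.

    Upper-tail binomial: P(X >= r_b_min) with n = round(mean depth) and
    p = phi_G.
    """
    if np.any(np.asarray(r_b_min) < 1):
        raise ValueError("r_b_min must be >= 1")
    n = _round_half_up(r_total_mean).astype(np.int64)
    p = binom.sf(np.asarray(r_b_min) - 1, n, np.asarray(phi_het, float))
    return p if np.ndim(p) else float(p)


def het_count_loglik(y_obs, eta_db, p_het):
    """Log probability of detecting at most ``y_obs`` hets among
    ``eta_db`` database positions (lower-tail binomial CDF)."""
    y = np.asarray(y_obs)
    eta = np.asarray(eta_db)
    if np.any((y < 0) | (y > eta)):
        raise ValueError("y_obs must be in [0, eta_db]")
    out = binom.logcdf(y, eta, np.asarray(p_het, float))
    return out if np.ndim(out) else float(out)


def somatic_at_db_loglik(z_obs, eta_db, rho):
    """Log probability of ``z_obs`` or more somatic calls among
    ``eta_db`` database positions at baseline somatic rate ``rho``
    (upper-tail binomial); zero calls gives log 1 = 0."""
    z = np.asarray(z_obs)
    eta = np.asarray(eta_db)
    if np.any((z < 0) | (z > eta)):
        raise ValueError("z_obs must be in [0, eta_db]")
    out = binom.logsf(z - 1, eta, rho)
    return out if np.ndim(out) else float(out)


def mean_pairwise_diff(values, epsilon: float) -> float:
    """Mean absolute pairwise difference across samples plus epsilon."""
    v = np.asarray(values, dtype=float)
    j = len(v)
    if j < 2:
        raise ValueError("need at least two samples")
    diffs = np.abs(v[:, None] - v[None, :])
    return float(diffs[np.triu_indices(j, k=1)].mean() + epsilon)


def delta_f_prior(f_column, prior_cfg: PriorConfig) -> float:
    """Prior probability that a clone's sample fractions differ across
    samples at least as much as expected.

    Beta CDF of the observed mean pairwise difference, with the Beta
    shaped so its mode equals the mean pairwise difference of the
    configured prior fractions f^pi.  For a single sample the difference
    is undefined and the prior is 1.
    """
    f_column = np.asarray(f_column, dtype=float)
    if len(f_column) < 2:
        return 1.0
    a = prior_cfg.alpha_pi
    d_prior = mean_pairwise_diff(prior_cfg.f_prior, prior_cfg.epsilon_df)
    if d_prior <= 0:
        raise ConfigError("prior sample fractions are identical with "
                          "epsilon_df = 0; delta-f prior undefined")
    b = (a - 1.0) / d_prior - a + 2.0
    d_k = min(mean_pairwise_diff(f_column, prior_cfg.epsilon_df), 1.0)
    return float(beta_dist.cdf(d_k, a, b))
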