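"""Position-quality classification and cross-sample trust scoring.

A quadratic discriminant model, fit per sample on high-confidence PASS
and artifact-like REJECT training sites, scores every candidate position
with a posterior probability of belonging to the PASS group.  SNVs and
indels are fit separately.  Per-sample posteriors combine into a trust
score — a geometric mean weighted by the variant-supporting read count —
and only positions with trust above ``t_pass`` proceed to genotype
classification.  Homozygous calls are later re-scored with A-allele-only
metrics (difference metrics zeroed), since B-allele metrics are
meaningless without B reads.

The 16 default metrics span the artifact axes such a filter must see:
mapping quality of both alleles and their difference, base quality,
read-position and strand-bias structure of the variant allele, soft
clipping, edit distance, homopolymer context, and control-panel behavior
at the position.  The training thresholds (clean top quartile on every
metric for PASS; bottom decile on two or more metrics for REJECT) are
package defaults and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricSpec", "DEFAULT_METRICS", "QualityVector",
           "assign_training_groups", "fit_and_score", "trust_score",
           "refit_homozygous", "quality_pipeline"]


@dataclass(frozen=True)
class MetricSpec:
    """One quality metric: direction of goodness and how it transforms
    when re-scoring homozygous positions (``refit``: 'self' keeps it,
    'zero' zeroes it, any other string names the A-allele counterpart)."""

    name: str
    higher_is_better: bool
    refit: str = "self"


DEFAULT_METRICS = (
    MetricSpec("mean_mapq_a", True),
    MetricSpec("mean_mapq_b", True, refit="mean_mapq_a"),
    MetricSpec("mapq_diff", False, refit="zero"),
    MetricSpec("mean_baseq_b", True, refit="zero"),
    MetricSpec("read_pos_b", True, refit="zero"),
    MetricSpec("read_pos_diff", False, refit="zero"),
    MetricSpec("strand_bias_b", False, refit="zero"),
    MetricSpec("strand_bias_diff", False, refit="zero"),
    MetricSpec("frac_low_mapq", False),
    MetricSpec("frac_softclip_b", False, refit="zero"),
    MetricSpec("mean_indel_dist", True),
    MetricSpec("homopolymer_len", False),
    MetricSpec("control_baf", False),
    MetricSpec("control_pos_qual", True),
    MetricSpec("depth_ratio_control", True),
    MetricSpec("frac_b_high_edit", False, refit="zero"),
)


@dataclass
class QualityVector:
    """Metric matrix (n_sites x n_metrics) for one sample with training
    labels in {'PASS', 'REJECT', ''} (empty = unlabeled)."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)


def _goodness(values: np.ndarray, specs) -> np.ndarray:
    sign = np.array([1.0 if s.higher_is_better else -1.0 for s in specs])
    return values * sign[None, :]


def assign_training_groups(values: np.ndarray, specs=DEFAULT_METRICS,
                           pass_quantile: float = 0.25,
                           reject_quantile: float = 0.10,
                           reject_min_metrics: int = 2) -> QualityVector:
    """Label training sites.

    PASS: clean top quartile of the composite goodness (mean
    standardized metric, oriented so higher is better) with no single
    metric in the reject decile.  REJECT: bottom decile on at least
    ``reject_min_metrics`` metrics.  Aborts if either class is smaller
    than twice the metric count (relax the thresholds in that case)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    g = _goodness(values, specs)
    informative = g.std(axis=0) > 0          # constant metrics carry nothing
    z = (g - g.mean(axis=0)) / np.where(informative, g.std(axis=0), 1)
    composite = z.mean(axis=1)
    lo = np.quantile(g, reject_quantile, axis=0)
    n_low = np.sum((g <= lo) & informative[None, :], axis=1)
    is_pass = (composite >= np.quantile(composite, 1.0 - pass_quantile)) \
        & (n_low == 0)
    is_reject = (n_low >= reject_min_metrics) & ~is_pass
    labels = np.full(len(values), "", dtype=object)
    labels[is_pass] = "PASS"
    labels[is_reject] = "REJECT"
    need = 2 * values.shape[1]
    if is_pass.sum() < need or is_reject.sum() < need:
        raise ValueError(
            f"training groups too small (PASS={is_pass.sum()}, "
            f"REJECT={is_reject.sum()}, need {need}); relax the "
            "pass/reject threshold quantiles")
    return QualityVector(values, labels)


class _QuadraticDiscriminant:
    """Two-class quadratic discriminant with a trace-scaled covariance
    ridge, so zeroed or collinear metrics stay well defined."""

    def __init__(self, reg: float = 1e-6):
        self.reg = reg

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_QuadraticDiscriminant":
        self.params_ = []
        p = x.shape[1]
        for cls in (0, 1):
            sub = x[y == cls]
            mu = sub.mean(axis=0)
            cov = np.atleast_2d(np.cov(sub.T))
            ridge = self.reg * max(np.trace(cov), 1.0) / p
            cov = cov + ridge * np.eye(p)
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise np.linalg.LinAlgError("degenerate class covariance")
            self.params_.append((mu, np.linalg.inv(cov), logdet))
        return self

    def _log_density(self, x: np.ndarray, cls: int) -> np.ndarray:
        mu, inv, logdet = self.params_[cls]
        d = x - mu
        maha = np.einsum("ij,jk,ik->i", d, inv, d)
        return -0.5 * (maha + logdet + x.shape[1] * np.log(2 * np.pi))

    def posterior_pass(self, x: np.ndarray) -> np.ndarray:
        # equal class priors
        delta = self._log_density(x, 0) - self._log_density(x, 1)
        return 1.0 / (1.0 + np.exp(np.clip(delta, -700, 700)))


def fit_and_score(qv: QualityVector, reg: float = 1e-6):
    """Posterior P(PASS) per site from a quadratic discriminant fit on
    the labeled sites (equal class priors; covariance ridge ``reg``,
    scaled by the covariance trace)."""
    labeled = qv.labels != ""
    x = qv.values[labeled]
    y = (qv.labels[labeled] == "PASS").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both PASS and REJECT classes are required")
    qda = _QuadraticDiscriminant(reg=reg).fit(x, y)
    return qda.posterior_pass(qv.values), qda


def trust_score(posteriors, weights) -> np.ndarray:
    """Geometric mean of per-sample PASS posteriors weighted by the
    variant-supporting read counts.

    Invariant to sample order and to rescaling the weights; rows with no
    supporting reads anywhere fall back to the unweighted geometric
    mean; any zero posterior with positive weight forces a zero score.
    """
    p = np.atleast_2d(np.asarray(posteriors, dtype=float))
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    if np.any(w < 0) or np.any((p < 0) | (p > 1)):
        raise ValueError("posteriors must be in [0,1], weights >= 0")
    w = np.where(w.sum(axis=1, keepdims=True) > 0, w, 1.0)
    with np.errstate(divide="ignore"):
        logp = np.where(p > 0, np.log(np.maximum(p, 1e-300)), -np.inf)
    out = np.exp((w * logp).sum(axis=1) / w.sum(axis=1))
    out[np.any((p == 0) & (w > 0), axis=1)] = 0.0
    return out


def refit_transform(values: np.ndarray, specs=DEFAULT_METRICS) -> np.ndarray:
    """A-allele-only metric variant used for homozygous re-scoring."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    names = [s.name for s in specs]
    out = values.copy()
    for i, s in enumerate(specs):
        if s.refit == "zero":
            out[:, i] = 0.0
        elif s.refit != "self":
            out[:, i] = values[:, names.index(s.refit)]
    return out


def refit_homozygous(values: np.ndarray, posteriors: np.ndarray,
                     hom_mask, specs=DEFAULT_METRICS, **train_kw):
    """Re-score homozygous-labeled sites with A-only metrics.

    A separate discriminant model is trained on the transformed metric
    matrix and the homozygous sites' posteriors are replaced; all other
    sites keep their original scores.
    """
    hom_mask = np.asarray(hom_mask, dtype=bool)
    out = np.asarray(posteriors, dtype=float).copy()
    if not hom_mask.any():
        return out
    x = refit_transform(values, specs)
    qv = assign_training_groups(x, specs, **train_kw)
    scores, _ = fit_and_score(qv)
    out[hom_mask] = scores[hom_mask]
    return out


def quality_pipeline(sites, specs=DEFAULT_METRICS, return_posteriors=False,
                     **train_kw):
    """Trust scores for a :class:`SiteCounts` with quality metrics in
    ``extra``.

    SNVs and indels are trained and scored separately within each
    sample; sites without the full metric set get a neutral score of 1.
    """
    names = [s.name for s in specs]
    if any(n not in sites.extra for n in names):
        trust = np.ones(sites.n_sites)
        post = np.ones((sites.n_sites, sites.n_samples))
        return (trust, post) if return_posteriors else trust
    post = np.ones((sites.n_sites, sites.n_samples))
    for j in range(sites.n_samples):
        x = np.stack([sites.extra[n][:, j] for n in names], axis=1)
        for mask in (~sites.is_indel, sites.is_indel):
            if mask.sum() < 4 * len(names):
                continue
            qv = assign_training_groups(x[mask], specs, **train_kw)
            scores, _ = fit_and_score(qv)
            post[mask, j] = scores
    trust = trust_score(post, sites.r_b)
    return (trust, post) if return_posteriors else trust
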