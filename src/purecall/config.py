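"""Model configuration: priors, thresholds and every tunable knob.

The defaults encode the caller's standard operating point: a two-sample
design (one low-purity tumor-adjacent sample, one higher-purity tumor
sample), Hardy–Weinberg germline priors driven by population allele
frequencies, and a small constant somatic rate scaled by hotspot counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

CONFIG_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


@dataclass
class PriorConfig:
    """Priors, thresholds and algorithmic defaults for the joint caller.

    Attributes
    ----------
    f_prior : tuple of float
        Expected sample fractions f^pi, one per sample.  The default
        (0.1, 0.7) assumes a low tumor-content and a high tumor-content
        sample from the same patient.
    alpha_pi : float
        Shape parameter of the Beta prior on the mean pairwise difference
        of clone sample fractions; must exceed 1 so the Beta has a mode.
    cn_priors : tuple of float
        pi(N = 0) .. pi(N = 4) and pi(N >= 5); the tail mass is divided
        equally over N = 5 .. n_max.
    minor_priors : tuple of float
        pi(M = 0), pi(M = 1), pi(M >= 2); the tail mass is divided equally
        over M = 2 .. n_max // 2.
    alpha_seg : float
        Significance cutoff for the segment-boundary pruning t-tests.
    rho_snv, rho_indel : float
        Baseline somatic rate constants used in the somatic prior and in
        the database somatic-call penalty term.
    f_pop_default_snv, f_pop_default_indel : float
        Population allele frequency assigned to alleles never observed in
        the population panels.
    f_max_somatic : float
        Maximum population allele frequency for a site to be considered a
        possible somatic variant.
    q_min_map, q_min_base : float
        Minimum mapping / base quality for a read or base to be counted
        (applied at pileup time, upstream of this package).
    t_pass, t_somatic, t_germline : float
        Posterior thresholds for quality PASS, somatic and germline calls.
    xi : int
        Number of consecutive parameter-fitting macro-iterations without a
        new maximum before the search stops.
    lambda_penalty : float
        Per-degree-of-freedom penalty for adding clonal variant groups
        (the objective subtracts J * K * lambda).
    r_b_min : int
        Minimum variant-supporting reads, in at least one sample, for a
        position to be a candidate variant.
    epsilon_df : float
        Epsilon added to mean pairwise sample-fraction differences so the
        Delta-f prior is defined for identical fractions.
    sim_lognormal_sigma : float
        Log-scale sigma of the simulator's total-depth lognormal.
    """

    f_prior: tuple = (0.1, 0.7)
    alpha_pi: float = 1.5
    cn_priors: tuple = (0.01, 0.25, 0.3, 0.2, 0.15, 0.09)
    minor_priors: tuple = (0.25, 0.5, 0.25)
    alpha_seg: float = 1e-5
    rho_snv: float = 1e-5
    rho_indel: float = 1e-6
    f_pop_default_snv: float = 1e-5
    f_pop_default_indel: float = 1e-6
    f_max_somatic: float = 2e-5
    q_min_map: float = 10.0
    q_min_base: float = 5.0
    t_pass: float = 0.8
    t_somatic: float = 0.8
    t_germline: float = 0.8
    xi: int = 3
    lambda_penalty: float = 5.0
    r_b_min: int = 3
    epsilon_df: float = 1e-3
    sim_lognormal_sigma: float = 0.5

    # --- search-space and numerical knobs -------------------------------
    n_max: int = 8                     # copy-number search bound
    e_hom: float = 1e-3                # effective AF of hom-ref (error reads)
    pi_other: float = 1e-4             # prior of the "other" (BB) genotype
    common_het_min_pop: float = 0.05   # min population freq for BAF hets
    max_extra_clones: int = 3          # K never exceeds 2J + 1 + this
    max_em_iter: int = 20
    n_add_trials: int = 10             # random columns tried when adding a clone
    f_init_private: float = 0.05       # off-sample fraction, clonal init rows
    f_init_sub_scale: float = 0.5      # in-sample scale, subclonal init rows
    f_init_sub_private: float = 0.01   # off-sample fraction, subclonal rows
    cbs_alpha: float = 0.01            # split significance inside CBS
    cbs_n_perm: int = 199              # permutations per CBS split test
    cbs_min_size: int = 3              # min points per CBS segment
    opt_maxfev_per_param: int = 30     # Nelder-Mead budget scale

    def __post_init__(self):
        if not 0 < len(self.f_prior):
            raise ConfigError("f_prior must have at least one entry")
        if any(not 0 <= f <= 1 for f in self.f_prior):
            raise ConfigError("f_prior entries must be in [0, 1]")
        if self.alpha_pi <= 1:
            raise ConfigError("alpha_pi must exceed 1")
        for name in ("cn_priors", "minor_priors"):
            vals = getattr(self, name)
            if any(v < 0 for v in vals) or abs(sum(vals) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be nonnegative and sum to 1")
        if self.r_b_min < 1:
            raise ConfigError("r_b_min must be >= 1")
        if self.n_max < 2:
            raise ConfigError("n_max must be >= 2")

    def copy_number_prior(self, n_total: int) -> float:
        """pi(N) over the searched grid 0..n_max (sums to 1)."""
        if not 0 <= n_total <= self.n_max:
            return 0.0
        if n_total < 5:
            return self.cn_priors[n_total]
        return self.cn_priors[5] / (self.n_max - 4)

    def minor_prior(self, m_minor: int) -> float:
        """pi(M) over the searched grid 0..n_max//2 (sums to 1)."""
        m_hi = self.n_max // 2
        if not 0 <= m_minor <= m_hi:
            return 0.0
        if m_minor < 2:
            return self.minor_priors[m_minor]
        return self.minor_priors[2] / (m_hi - 1)

    def to_yaml(self, path) -> None:
        doc = {"schema_version": CONFIG_SCHEMA_VERSION}
        doc.update({k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(self).items()})
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PriorConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        version = doc.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ConfigError(f"unsupported config schema version {version}")
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        tuple_keys = {"f_prior", "cn_priors", "minor_priors"}
        doc = {k: (tuple(v) if k in tuple_keys else v) for k, v in doc.items()}
        return cls(**doc)
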