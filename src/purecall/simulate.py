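"""Read-count simulator with known truth.

Per site and sample, total depth is drawn from a lognormal whose mean is
the configured coverage scaled by the purity-attenuated copy-number
factor, and the variant-supporting read count is binomial at the
expected allele fraction for the site's true class (clonal somatic or
germline heterozygous) given the tumor purity and copy state.  Somatic
variants are clonal: present in every tumor cell, i.e. a single clone
whose sample fraction equals the purity.

Non-diploid states are embedded on their own chromosome next to a
diploid background chromosome, mirroring the focal nature of real copy
alterations and keeping the depth-centering parameter identifiable.
Germline sites are annotated as absent from the population database by
default — the private-germline case that makes somatic/germline
discrimination nontrivial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PriorConfig
from .containers import ExonDepth, SiteAnnotation, SiteCounts
from .likelihood import _somatic_af, expected_het_af

__all__ = ["SimConfig", "SimulatedDataset", "simulate_counts",
           "simulate_pooled", "power_grid", "COVERAGE_LADDER"]

COVERAGE_LADDER = (50, 100, 200, 400, 800, 1600, 3200, 6400)

_EXON_WIDTH = 200
_EXON_SPACING = 1000


@dataclass
class SimConfig:
    """Study conditions for one simulated patient dataset.

    ``purities`` and ``coverage`` are per sample; ``n_total`` /
    ``m_minor`` / ``somatic_allele`` define the focal copy state shared
    by all somatic variants (allele 2 = the major allele).
    """

    purities: tuple = (0.1, 0.7)
    coverage: tuple = (200.0, 200.0)
    n_total: int = 2
    m_minor: int = 1
    somatic_allele: int = 1
    n_somatic: int = 1000
    n_germline_het: int = 10000
    lognormal_sigma: float = 0.5
    seed: int = 0
    control_depth: float = 200.0
    exon_sigma: float = 0.15
    n_exons_focal: int = 60
    n_exons_background: int = 60
    background_het_frac: float = 0.5
    n_artifacts: int = 0

    def __post_init__(self):
        if len(self.purities) != len(self.coverage):
            raise ValueError("purities and coverage must align")
        if any(not 0 <= p <= 1 for p in self.purities):
            raise ValueError("purities must be in [0, 1]")
        if any(c <= 0 for c in self.coverage):
            raise ValueError("coverage must be positive")
        if self.m_minor > self.n_total - self.m_minor:
            raise ValueError("m_minor exceeds n_total - m_minor")

    @property
    def is_diploid(self) -> bool:
        return (self.n_total, self.m_minor) == (2, 1)


@dataclass
class SimulatedDataset:
    """Simulator output bundle: counts, truth, exon depths, annotation."""

    sites: SiteCounts
    truth: pd.DataFrame
    exons: ExonDepth
    annotation: SiteAnnotation
    config: SimConfig = None


def _lognormal(rng, mean, sigma, size=None):
    mu = np.log(np.maximum(mean, 1e-9)) - sigma ** 2 / 2.0
    return rng.lognormal(mu, sigma, size)


_PASS_METRIC_MEANS = {
    "mean_mapq_a": (58.0, 2.0), "mean_mapq_b": (57.0, 2.5),
    "mapq_diff": (1.0, 1.0), "mean_baseq_b": (32.0, 2.0),
    "read_pos_b": (40.0, 6.0), "read_pos_diff": (2.0, 2.0),
    "strand_bias_b": (1.0, 0.5), "strand_bias_diff": (0.5, 0.4),
    "frac_low_mapq": (0.02, 0.015), "frac_softclip_b": (0.02, 0.015),
    "mean_indel_dist": (30.0, 5.0), "homopolymer_len": (1.5, 0.8),
    "control_baf": (0.005, 0.004), "control_pos_qual": (0.95, 0.03),
    "depth_ratio_control": (1.0, 0.08), "frac_b_high_edit": (0.02, 0.015),
}
_REJECT_METRIC_SHIFT = {      # artifact cluster offsets in units of sd
    "mean_mapq_a": -6, "mean_mapq_b": -10, "mapq_diff": +8,
    "mean_baseq_b": -6, "read_pos_b": -4, "read_pos_diff": +6,
    "strand_bias_b": +8, "strand_bias_diff": +6, "frac_low_mapq": +8,
    "frac_softclip_b": +8, "mean_indel_dist": -4, "homopolymer_len": +5,
    "control_baf": +8, "control_pos_qual": -6, "depth_ratio_control": -3,
    "frac_b_high_edit": +8,
}


def _draw_metrics(rng, n, n_samples, artifact=False):
    out = {}
    for name, (mu, sd) in _PASS_METRIC_MEANS.items():
        shift = _REJECT_METRIC_SHIFT[name] * sd if artifact else 0.0
        out[name] = rng.normal(mu + shift, sd, size=(n, n_samples))
    return out


def simulate_counts(cfg: SimConfig) -> SimulatedDataset:
    """Generate one multi-sample dataset with truth.

    Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    j_n = len(cfg.purities)
    purity = np.asarray(cfg.purities, dtype=float)
    coverage = np.asarray(cfg.coverage, dtype=float)

    # genome layout: background diploid chr1 (absent for diploid focal
    # states), focal state chr2
    regions = []
    if not cfg.is_diploid:
        regions.append(("chr1", cfg.n_exons_background, 2, 1))
    regions.append(("chr2" if not cfg.is_diploid else "chr1",
                    cfg.n_exons_focal, cfg.n_total, cfg.m_minor))

    ex_chrom, ex_start, ex_end, ex_state = [], [], [], []
    for chrom, n_ex, n, m in regions:
        for i in range(n_ex):
            ex_chrom.append(chrom)
            ex_start.append(i * _EXON_SPACING)
            ex_end.append(i * _EXON_SPACING + _EXON_WIDTH)
            ex_state.append((n, m))
    ex_chrom = np.array(ex_chrom, dtype=object)
    ex_start = np.array(ex_start)
    ex_end = np.array(ex_end)
    ex_n = np.array([s[0] for s in ex_state], dtype=float)

    r_control = _lognormal(rng, cfg.control_depth, 0.25, len(ex_start))
    depth_factor = (ex_n[:, None] * purity[None, :]
                    + 2.0 * (1.0 - purity[None, :])) / 2.0
    r_tumor = _lognormal(rng, coverage[None, :] * depth_factor,
                         cfg.exon_sigma)
    exons = ExonDepth(chrom=ex_chrom, start=ex_start, end=ex_end,
                      r_tumor_mean=r_tumor, r_control_mean=r_control)

    # --- site placement ---------------------------------------------------
    n_het_bg = 0 if cfg.is_diploid else \
        int(round(cfg.n_germline_het * cfg.background_het_frac))
    n_het_focal = cfg.n_germline_het - n_het_bg

    def place(n_sites, chrom_mask):
        ex_idx = rng.choice(np.where(chrom_mask)[0], size=n_sites)
        offs = rng.integers(0, _EXON_WIDTH, size=n_sites)
        return ex_idx, ex_start[ex_idx] + offs + 1       # 1-based

    focal_chrom = regions[-1][0]
    blocks = []   # (chrom, pos, class, n, m, phi (n,J), region)
    if n_het_bg:
        ei, pos = place(n_het_bg, ex_chrom == "chr1")
        phi = np.broadcast_to(expected_het_af(purity, 2, 1),
                              (n_het_bg, j_n))
        blocks.append(("chr1", pos, "germline_het", 2, 1, phi, "background"))
    if n_het_focal:
        ei, pos = place(n_het_focal, ex_chrom == focal_chrom)
        phi = np.broadcast_to(
            expected_het_af(purity, cfg.n_total, cfg.m_minor),
            (n_het_focal, j_n))
        blocks.append((focal_chrom, pos, "germline_het", cfg.n_total,
                       cfg.m_minor, phi, "focal"))
    if cfg.n_somatic:
        ei, pos = place(cfg.n_somatic, ex_chrom == focal_chrom)
        phi = np.broadcast_to(
            _somatic_af(purity, purity, cfg.n_total, cfg.m_minor, True,
                        cfg.somatic_allele), (cfg.n_somatic, j_n))
        blocks.append((focal_chrom, pos, "somatic", cfg.n_total,
                       cfg.m_minor, phi, "focal"))
    if cfg.n_artifacts:
        ei, pos = place(cfg.n_artifacts, ex_chrom == focal_chrom)
        phi = rng.uniform(0.03, 0.4, size=(cfg.n_artifacts, 1)) \
            * np.ones((1, j_n))
        blocks.append((focal_chrom, pos, "artifact", cfg.n_total,
                       cfg.m_minor, phi, "focal"))

    chrom = np.concatenate([np.full(len(b[1]), b[0], dtype=object)
                            for b in blocks])
    pos = np.concatenate([b[1] for b in blocks])
    klass = np.concatenate([np.full(len(b[1]), b[2], dtype=object)
                            for b in blocks])
    phi = np.vstack([np.asarray(b[5], dtype=float) for b in blocks])
    region = np.concatenate([np.full(len(b[1]), b[6], dtype=object)
                             for b in blocks])

    # coordinate-sort, as a pileup would emit
    order = np.lexsort((pos, chrom.astype(str)))
    chrom, pos, klass, phi, region, state_n = (
        chrom[order], pos[order], klass[order], phi[order], region[order],
        np.concatenate([np.full(len(b[1]), b[3]) for b in blocks])[order])

    n_sites = len(pos)
    factor = (state_n[:, None] * purity[None, :]
              + 2.0 * (1.0 - purity[None, :])) / 2.0
    depth = np.maximum(
        np.round(_lognormal(rng, coverage[None, :] * factor,
                            cfg.lognormal_sigma)), 1).astype(int)
    alt = rng.binomial(depth, np.clip(phi, 0.0, 1.0))

    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = bases[rng.integers(0, 4, n_sites)]
    b_allele = np.array([bases[(list(bases).index(r) + 1) % 4]
                         for r in ref], dtype=object)
    extra = _draw_metrics(rng, n_sites, j_n) if cfg.n_artifacts else {}
    if cfg.n_artifacts:
        art = klass == "artifact"
        bad = _draw_metrics(rng, int(art.sum()), j_n, artifact=True)
        for name in extra:
            extra[name][art] = bad[name]

    sites = SiteCounts(chrom=chrom, pos=pos, ref_allele=ref,
                       a_allele=ref, b_allele=b_allele,
                       r_total=depth, r_b=alt, extra=extra)
    truth = pd.DataFrame({"chrom": chrom, "pos": pos, "true_class": klass,
                          "true_allele": np.where(
                              klass == "somatic", cfg.somatic_allele, 0),
                          "region": region})
    for j in range(j_n):
        truth[f"af_true_s{j}"] = phi[:, j]
    annotation = SiteAnnotation.default(n_sites)
    return SimulatedDataset(sites=sites, truth=truth, exons=exons,
                            annotation=annotation, config=cfg)


def simulate_pooled(ds: SimulatedDataset,
                    other: SimulatedDataset = None) -> SimulatedDataset:
    """In-silico pooled dataset: read depths summed across samples.

    With one argument, the samples of ``ds`` are merged into a single
    pseudo-sample; with two, the two datasets (same site set required)
    are merged site-wise.  The pooled effective purity is the
    coverage-weighted mean of the inputs.
    """
    if other is not None:
        if not np.array_equal(ds.sites.pos, other.sites.pos) or \
           not np.array_equal(ds.sites.chrom, other.sites.chrom):
            raise ValueError("pooling requires identical site sets")
        r_total = np.hstack([ds.sites.r_total, other.sites.r_total])
        r_b = np.hstack([ds.sites.r_b, other.sites.r_b])
        r_tumor = np.hstack([ds.exons.r_tumor_mean,
                             other.exons.r_tumor_mean])
    else:
        r_total, r_b = ds.sites.r_total, ds.sites.r_b
        r_tumor = ds.exons.r_tumor_mean
    sites = SiteCounts(
        chrom=ds.sites.chrom, pos=ds.sites.pos,
        ref_allele=ds.sites.ref_allele, a_allele=ds.sites.a_allele,
        b_allele=ds.sites.b_allele,
        r_total=r_total.sum(axis=1, keepdims=True),
        r_b=r_b.sum(axis=1, keepdims=True),
        is_indel=ds.sites.is_indel,
        extra={k: v.mean(axis=1, keepdims=True)
               for k, v in ds.sites.extra.items()})
    exons = ExonDepth(chrom=ds.exons.chrom, start=ds.exons.start,
                      end=ds.exons.end,
                      r_tumor_mean=r_tumor.sum(axis=1, keepdims=True),
                      r_control_mean=ds.exons.r_control_mean)
    return SimulatedDataset(sites=sites, truth=ds.truth, exons=exons,
                            annotation=ds.annotation, config=ds.config)


def _call_sensitivity(ds: SimulatedDataset, cfg: PriorConfig, seed: int,
                      f_prior=None) -> float:
    """Run the full joint pipeline on a simulated dataset and return the
    somatic sensitivity in the focal region."""
    from .clonal import FitData, em_driver      # deferred: avoids cycle

    call_cfg = cfg
    if f_prior is not None:
        from dataclasses import replace
        call_cfg = replace(cfg, f_prior=tuple(f_prior))
    data = FitData(sites=ds.sites, exons=ds.exons,
                   annotation=ds.annotation)
    result = em_driver(data, call_cfg, seed=seed)
    som_true = (ds.truth["true_class"] == "somatic").to_numpy()
    if som_true.sum() == 0:
        return float("nan")
    called = (result.calls["label"] == "Somatic").to_numpy()
    return float(called[som_true].mean())


def power_grid(purity_pairs, coverages=COVERAGE_LADDER,
               states=((2, 1, 1), (3, 1, 2)), cfg: PriorConfig = None,
               detect_threshold: float = 0.8, n_somatic: int = 200,
               n_germline_het: int = 2000, seed: int = 0,
               pooled: bool = False) -> pd.DataFrame:
    """Minimal per-sample coverage reaching the target somatic
    sensitivity for each purity pair and copy state.

    Walks the coverage ladder upward and records the first coverage with
    sensitivity >= ``detect_threshold``, or NaN if none does (the ladder
    is capped at its last rung, 6400X by default).
    """
    cfg = cfg or PriorConfig()
    rows = []
    for pa, pb in purity_pairs:
        for n, m, allele in states:
            found, sens_at = np.nan, {}
            for ci, cov in enumerate(sorted(coverages)):
                sim = SimConfig(purities=(pa, pb), coverage=(cov, cov),
                                n_total=n, m_minor=m, somatic_allele=allele,
                                n_somatic=n_somatic,
                                n_germline_het=n_germline_het,
                                seed=seed + 1000 * ci)
                ds = simulate_counts(sim)
                if pooled:
                    ds = simulate_pooled(ds)
                sens = _call_sensitivity(ds, cfg, seed=seed)
                sens_at[cov] = sens
                if sens >= detect_threshold:
                    found = cov
                    break
            rows.append({"purity_a": pa, "purity_b": pb, "n_total": n,
                         "m_minor": m, "allele": allele,
                         "min_coverage": found,
                         "max_sensitivity": max(sens_at.values())})
    return pd.DataFrame(rows)
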