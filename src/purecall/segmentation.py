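"""Multi-sample segmentation of depth ratios and B-allele fractions.

Each sample's exon log2 depth ratio and common-het folded B-allele
fraction series are segmented independently by binary segmentation with
permutation p-values (a CBS-style changepoint search).  Boundaries from
all samples and both data types are pooled, then pruned: adjacent
segments are compared by Welch t-tests per series, p-values combined
across the 2J series by geometric mean, and the weakest boundary removed
until every survivor is significant at ``alpha_seg``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import ExonDepth, SegmentState, SiteCounts
from .config import PriorConfig

__all__ = ["BoundarySet", "cbs_segment", "merge_and_prune",
           "segment_genome", "fold_baf", "select_common_hets"]

_P_FLOOR = 1e-300


@dataclass
class BoundarySet:
    """Per-chromosome sorted, unique breakpoint positions with provenance
    tags recording which (sample, data type) proposed each one."""

    positions: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add(self, chrom: str, pos: int, tag=None):
        self.provenance.setdefault(chrom, {}).setdefault(int(pos), set())
        if tag is not None:
            self.provenance[chrom][int(pos)].add(tag)
        self.positions[chrom] = np.array(
            sorted(self.provenance[chrom]), dtype=np.int64)

    def update(self, other: "BoundarySet"):
        for chrom, tags in other.provenance.items():
            for pos, ts in tags.items():
                for t in ts or {None}:
                    self.add(chrom, pos, t)

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.positions.get(chrom, np.array([], dtype=np.int64))


def _best_split(values: np.ndarray, min_size: int):
    """Best two-sample t split of an ordered series; returns (index, |t|)
    where index is the size of the left part, or (None, 0) if no valid
    split exists."""
    n = len(values)
    if n < 2 * min_size:
        return None, 0.0
    cs = np.cumsum(values)
    cs2 = np.cumsum(values ** 2)
    k = np.arange(min_size, n - min_size + 1, dtype=float)
    sum_l = cs[min_size - 1:n - min_size]
    sum2_l = cs2[min_size - 1:n - min_size]
    mean_l = sum_l / k
    mean_r = (cs[-1] - sum_l) / (n - k)
    var_l = np.maximum(sum2_l / k - mean_l ** 2, 0.0) * k / np.maximum(k - 1, 1)
    var_r = np.maximum((cs2[-1] - sum2_l) / (n - k) - mean_r ** 2, 0.0) \
        * (n - k) / np.maximum(n - k - 1, 1)
    se = np.sqrt(var_l / k + var_r / (n - k))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(mean_l - mean_r) / se
    t[~np.isfinite(t)] = 0.0
    i = int(np.argmax(t))
    return int(k[i]), float(t[i])


def cbs_segment(positions, values, rng=None, alpha: float = 0.01,
                n_perm: int = 199, min_size: int = 3) -> np.ndarray:
    """Changepoint positions of an ordered genomic series.

    Recursive binary segmentation: the maximal Welch-t split of each
    segment is kept if its permutation p-value (values shuffled within
    the segment) is below ``alpha``.  Returns the genomic positions of
    the first point of each right-hand segment; deterministic for a
    fixed ``rng`` seed.
    """
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    if len(positions) != len(values):
        raise ValueError("positions and values must align")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    breaks: list[int] = []

    def recurse(lo: int, hi: int):
        seg = values[lo:hi]
        split, t_obs = _best_split(seg, min_size)
        if split is None or t_obs == 0.0:
            return
        exceed = 0
        for _ in range(n_perm):
            _, t_perm = _best_split(rng.permutation(seg), min_size)
            exceed += t_perm >= t_obs
        p = (1.0 + exceed) / (1.0 + n_perm)
        if p <= alpha:
            breaks.append(lo + split)
            recurse(lo, lo + split)
            recurse(lo + split, hi)

    recurse(0, len(values))
    return positions[np.array(sorted(breaks), dtype=int)] if breaks \
        else np.array([], dtype=positions.dtype)


def _welch_p(left: np.ndarray, right: np.ndarray) -> float:
    """Welch t-test p-value; 1.0 when either side has < 2 observations
    or the statistic is undefined (zero variance on both sides)."""
    if len(left) < 2 or len(right) < 2:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(left, right, equal_var=False).pvalue
    return float(p) if np.isfinite(p) else 1.0


def merge_and_prune(boundaries: np.ndarray, series, alpha_seg: float):
    """Prune pooled boundaries on one chromosome until all survivors are
    significant.

    ``series`` is a list of (positions, values) pairs — one per sample
    and data type.  Each boundary's p-value is the geometric mean of the
    Welch t-test p-values comparing the flanking segments in every
    series; the boundary with the highest combined p is removed (ties:
    leftmost) and its flanks re-tested, until all combined p-values are
    below ``alpha_seg``.  Returns the surviving boundary positions.
    """
    bnds = sorted(set(int(b) for b in np.asarray(boundaries).ravel()))
    series = [(np.asarray(p), np.asarray(v, float)) for p, v in series]

    def seg_values(pos, vals, lo, hi):
        return vals[(pos >= lo) & (pos < hi)] if hi is not None \
            else vals[pos >= lo]

    def boundary_p(i: int) -> float:
        lo = bnds[i - 1] if i > 0 else -np.inf
        mid = bnds[i]
        hi = bnds[i + 1] if i + 1 < len(bnds) else np.inf
        logs = []
        for pos, vals in series:
            left = vals[(pos >= lo) & (pos < mid)]
            right = vals[(pos >= mid) & (pos < hi)]
            logs.append(np.log(max(_welch_p(left, right), _P_FLOOR)))
        return float(np.exp(np.mean(logs)))

    pvals = [boundary_p(i) for i in range(len(bnds))]
    while pvals:
        i = int(np.argmax(pvals))      # argmax takes the leftmost tie
        if pvals[i] < alpha_seg:
            break
        del bnds[i], pvals[i]
        for jj in (i - 1, i):
            if 0 <= jj < len(bnds):
                pvals[jj] = boundary_p(jj)
    return np.array(bnds, dtype=np.int64)


def fold_baf(af):
    """Mirror allele fractions at 0.5 so phase does not create
    breakpoints."""
    af = np.asarray(af, dtype=float)
    return 0.5 + np.abs(af - 0.5)


def select_common_hets(sites: SiteCounts, f_pop_min, cfg: PriorConfig
                       ) -> np.ndarray:
    """Mask of sites usable as common heterozygous B-allele markers:
    population minor-allele frequency above the configured floor and an
    observed allele fraction within (0.1, 0.9) in at least one sample."""
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(sites.r_total > 0, sites.r_b / np.maximum(sites.r_total, 1), 0.0)
    in_band = np.any((af > 0.1) & (af < 0.9), axis=1)
    return (np.asarray(f_pop_min) > cfg.common_het_min_pop) & in_band


def segment_genome(exons: ExonDepth, sites: SiteCounts, het_mask,
                   cfg: PriorConfig, seed: int = 0):
    """Segment the capture space jointly across samples and data types.

    Returns a list of :class:`SegmentState` skeletons (diploid defaults)
    tiling each chromosome from the first to the last exon, with
    ``exon_indices`` and ``het_indices`` filled in.
    """
    rng = np.random.default_rng(seed)
    het_mask = np.asarray(het_mask, dtype=bool)
    mids = (exons.start + exons.end) // 2
    with np.errstate(divide="ignore"):
        log_ratio = np.log2((exons.r_tumor_mean + 0.5)
                            / (exons.r_control_mean[:, None] + 0.5))
    site_pos0 = sites.pos - 1
    with np.errstate(invalid="ignore"):
        af = sites.r_b / np.maximum(sites.r_total, 1)

    boundaries = BoundarySet()
    chroms = list(dict.fromkeys(exons.chrom))     # stable order
    for chrom in chroms:
        ex = np.where(exons.chrom == chrom)[0]
        het = np.where((sites.chrom == chrom) & het_mask)[0]
        for j in range(exons.n_samples):
            for pos in cbs_segment(mids[ex], log_ratio[ex, j], rng,
                                   cfg.cbs_alpha, cfg.cbs_n_perm,
                                   cfg.cbs_min_size):
                boundaries.add(chrom, pos, (j, "log2"))
            if len(het):
                order = het[np.argsort(site_pos0[het], kind="stable")]
                for pos in cbs_segment(site_pos0[order],
                                       fold_baf(af[order, j]), rng,
                                       cfg.cbs_alpha, cfg.cbs_n_perm,
                                       cfg.cbs_min_size):
                    boundaries.add(chrom, pos, (j, "baf"))

    segments = []
    for chrom in chroms:
        ex = np.where(exons.chrom == chrom)[0]
        het = np.where((sites.chrom == chrom) & het_mask)[0]
        series = []
        for j in range(exons.n_samples):
            series.append((mids[ex], log_ratio[ex, j]))
            series.append((site_pos0[het], fold_baf(af[het, j])))
        kept = merge_and_prune(boundaries.chrom_positions(chrom), series,
                               cfg.alpha_seg)
        edges = np.concatenate(([exons.start[ex].min()], kept,
                                [exons.end[ex].max()]))
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi <= lo:
                continue
            exi = ex[(mids[ex] >= lo) & (mids[ex] < hi)]
            heti = het[(site_pos0[het] >= lo) & (site_pos0[het] < hi)]
            if len(exi) == 0:
                continue
            segments.append(SegmentState(chrom=str(chrom), start=int(lo),
                                         end=int(hi), exon_indices=exi,
                                         het_indices=heti))
    return segments
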