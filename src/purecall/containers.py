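"""Core in-memory containers for the joint caller.

All containers are column-oriented: per-site or per-exon quantities are
numpy arrays, and per-sample quantities are 2-D arrays with shape
(n_records, n_samples).  Genomic intervals are 0-based half-open
internally; positions of point variants are 1-based (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DegenerateStateError(ValueError):
    """A copy/purity combination with no defined allele fraction
    (homozygous deletion in a sample of purity one)."""


def _as2d(a, n_rows: int) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim == 1:
        a = a[:, None]
    if a.shape[0] != n_rows:
        raise ValueError(f"expected {n_rows} rows, got {a.shape[0]}")
    return a


@dataclass
class SiteCounts:
    """Read counts and quality metrics at candidate variant positions.

    ``r_total``/``r_b`` are total and B-allele (variant-supporting) read
    depths, shape (n_sites, n_samples).  ``q_map_a``/``q_map_b`` are mean
    mapping qualities of A- and B-supporting reads and ``q_base_b`` the
    mean base quality of B bases; ``extra`` holds any further per-sample
    quality metrics keyed by name.
    """

    chrom: np.ndarray
    pos: np.ndarray                       # 1-based
    ref_allele: np.ndarray
    a_allele: np.ndarray
    b_allele: np.ndarray
    r_total: np.ndarray                   # (n, J)
    r_b: np.ndarray                       # (n, J)
    q_map_a: np.ndarray = None
    q_map_b: np.ndarray = None
    q_base_b: np.ndarray = None
    is_indel: np.ndarray = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n = len(self.pos)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.a_allele = np.asarray(self.a_allele, dtype=object)
        self.b_allele = np.asarray(self.b_allele, dtype=object)
        self.r_total = _as2d(self.r_total, n).astype(np.int64)
        self.r_b = _as2d(self.r_b, n).astype(np.int64)
        j = self.r_total.shape[1]
        for name in ("q_map_a", "q_map_b", "q_base_b"):
            v = getattr(self, name)
            if v is None:
                v = np.full((n, j), 60.0 if "map" in name else 30.0)
            setattr(self, name, _as2d(v, n).astype(float))
        if self.is_indel is None:
            self.is_indel = np.zeros(n, dtype=bool)
        self.is_indel = np.asarray(self.is_indel, dtype=bool)
        self.validate()

    def validate(self):
        if np.any(self.pos < 1):
            raise ValueError("positions must be >= 1")
        if np.any(self.r_b < 0) or np.any(self.r_b > self.r_total):
            bad = np.where((self.r_b < 0) | (self.r_b > self.r_total))[0]
            raise ValueError(f"r_b outside [0, r_total] at site rows {bad[:5]}")
        if np.any(self.a_allele == self.b_allele):
            raise ValueError("A and B alleles must differ at every site")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return self.r_total.shape[1]

    def subset(self, indices) -> "SiteCounts":
        """Row subset (copy) of the container."""
        idx = np.asarray(indices)
        return SiteCounts(
            chrom=self.chrom[idx], pos=self.pos[idx],
            ref_allele=self.ref_allele[idx], a_allele=self.a_allele[idx],
            b_allele=self.b_allele[idx], r_total=self.r_total[idx],
            r_b=self.r_b[idx], q_map_a=self.q_map_a[idx],
            q_map_b=self.q_map_b[idx], q_base_b=self.q_base_b[idx],
            is_indel=self.is_indel[idx],
            extra={k: v[idx] for k, v in self.extra.items()})

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the documented TSV column layout."""
        d = {"chrom": self.chrom, "pos": self.pos, "ref": self.ref_allele,
             "A": self.a_allele, "B": self.b_allele,
             "is_indel": self.is_indel.astype(int)}
        for s in range(self.n_samples):
            p = f"s{s}_"
            d[p + "dp"] = self.r_total[:, s]
            d[p + "ad_b"] = self.r_b[:, s]
            d[p + "qmap_a"] = self.q_map_a[:, s]
            d[p + "qmap_b"] = self.q_map_b[:, s]
            d[p + "qbase_b"] = self.q_base_b[:, s]
            for name, arr in sorted(self.extra.items()):
                d[p + name] = arr[:, s]
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SiteCounts":
        j = 0
        while f"s{j}_dp" in df.columns:
            j += 1
        if j == 0:
            raise ValueError("no per-sample blocks (s0_dp ...) found")
        core = {"dp", "ad_b", "qmap_a", "qmap_b", "qbase_b"}
        extra_names = sorted({c[len("s0_"):] for c in df.columns
                              if c.startswith("s0_")
                              and c[len("s0_"):] not in core})
        stack = lambda name: np.stack(
            [df[f"s{s}_{name}"].to_numpy() for s in range(j)], axis=1)
        return cls(
            chrom=df["chrom"].to_numpy(), pos=df["pos"].to_numpy(),
            ref_allele=df["ref"].to_numpy(), a_allele=df["A"].to_numpy(),
            b_allele=df["B"].to_numpy(),
            r_total=stack("dp"), r_b=stack("ad_b"),
            q_map_a=stack("qmap_a"), q_map_b=stack("qmap_b"),
            q_base_b=stack("qbase_b"),
            is_indel=df["is_indel"].to_numpy().astype(bool),
            extra={name: stack(name) for name in extra_names},
        )


@dataclass
class ExonDepth:
    """Mean read depths per capture exon.

    Intervals are 0-based half-open, sorted, non-overlapping within each
    chromosome.  ``r_tumor_mean`` has shape (n_exons, n_samples);
    ``r_control_mean`` is the unmatched-control panel mean depth.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    r_tumor_mean: np.ndarray
    r_control_mean: np.ndarray

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        n = len(self.start)
        self.r_tumor_mean = _as2d(self.r_tumor_mean, n).astype(float)
        self.r_control_mean = np.asarray(self.r_control_mean, dtype=float)
        self.validate()

    def validate(self):
        if np.any(self.end <= self.start):
            raise ValueError("exon intervals must have end > start")
        if np.any(self.r_tumor_mean < 0) or np.any(self.r_control_mean < 0):
            raise ValueError("depths must be nonnegative")
        for c in pd.unique(self.chrom):
            m = self.chrom == c
            s, e = self.start[m], self.end[m]
            if np.any(np.diff(s) < 0):
                raise ValueError(f"exons not sorted on {c}")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping exons on {c}")

    @property
    def n_exons(self) -> int:
        return len(self.start)

    @property
    def n_samples(self) -> int:
        return self.r_tumor_mean.shape[1]

    def to_frame(self) -> pd.DataFrame:
        d = {"chrom": self.chrom, "start": self.start, "end": self.end}
        for s in range(self.n_samples):
            d[f"s{s}_depth"] = self.r_tumor_mean[:, s]
        d["control_depth"] = self.r_control_mean
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExonDepth":
        j = 0
        while f"s{j}_depth" in df.columns:
            j += 1
        return cls(chrom=df["chrom"].to_numpy(), start=df["start"].to_numpy(),
                   end=df["end"].to_numpy(),
                   r_tumor_mean=np.stack(
                       [df[f"s{s}_depth"].to_numpy() for s in range(j)], axis=1),
                   r_control_mean=df["control_depth"].to_numpy())


@dataclass
class SiteAnnotation:
    """Population allele frequencies and hotspot counts, one row per site
    (aligned with a :class:`SiteCounts`)."""

    f_pop_a: np.ndarray
    f_pop_b: np.ndarray
    omega: np.ndarray

    def __post_init__(self):
        self.f_pop_a = np.asarray(self.f_pop_a, dtype=float)
        self.f_pop_b = np.asarray(self.f_pop_b, dtype=float)
        self.omega = np.asarray(self.omega, dtype=np.int64)
        if np.any((self.f_pop_a < 0) | (self.f_pop_a > 1)) or \
           np.any((self.f_pop_b < 0) | (self.f_pop_b > 1)):
            raise ValueError("population frequencies must be in [0, 1]")
        if np.any(self.omega < 0):
            raise ValueError("hotspot counts must be >= 0")

    @classmethod
    def default(cls, n_sites: int) -> "SiteAnnotation":
        """Annotation for sites absent from all databases."""
        z = np.zeros(n_sites)
        return cls(f_pop_a=np.ones(n_sites), f_pop_b=z, omega=z)


@dataclass
class SegmentState:
    """A genomic segment and its allele-specific copy-number assignment.

    ``n_total`` is the total copy number N, ``m_minor`` the minor allele
    copy number M (2M <= N), and ``clone_index`` the 1-based clonal
    variant group carrying the alteration.
    """

    chrom: str
    start: int
    end: int
    exon_indices: np.ndarray
    het_indices: np.ndarray = field(default_factory=lambda: np.array([], int))
    n_total: int = 2
    m_minor: int = 1
    clone_index: int = 1
    n_bases_db: int = 0                 # eta_dg, database positions inside

    def __post_init__(self):
        self.exon_indices = np.asarray(self.exon_indices, dtype=np.int64)
        self.het_indices = np.asarray(self.het_indices, dtype=np.int64)
        if self.m_minor > self.n_total - self.m_minor:
            raise ValueError("minor copy number exceeds N - M")
        if self.clone_index < 1:
            raise ValueError("clone_index is 1-based")

    def contains(self, chrom, pos0) -> np.ndarray:
        """Membership mask for 0-based positions."""
        return (chrom == self.chrom) & (pos0 >= self.start) & (pos0 < self.end)


@dataclass
class CloneModel:
    """Clonal variant group sample fractions and per-sample nuisance
    parameters.

    ``f`` is the K x J matrix of sample fractions (fraction of cells in
    sample j carrying clone k's alterations), ``c_center`` the per-sample
    depth centering C > 0 and ``w_disp`` the per-sample beta-binomial
    concentration W > 0 (larger W = closer to binomial).
    """

    f: np.ndarray
    c_center: np.ndarray
    w_disp: np.ndarray

    def __post_init__(self):
        self.f = np.atleast_2d(np.asarray(self.f, dtype=float))
        self.c_center = np.asarray(self.c_center, dtype=float)
        self.w_disp = np.asarray(self.w_disp, dtype=float)
        if np.any((self.f < 0) | (self.f > 1)):
            raise ValueError("sample fractions must be in [0, 1]")
        if np.any(self.c_center <= 0) or np.any(self.w_disp <= 0):
            raise ValueError("C and W must be strictly positive")
        if self.f.shape[1] != len(self.c_center) or \
           self.f.shape[1] != len(self.w_disp):
            raise ValueError("f columns must match len(C) and len(W)")

    @property
    def n_clones(self) -> int:
        return self.f.shape[0]

    @property
    def n_samples(self) -> int:
        return self.f.shape[1]

    def copy(self) -> "CloneModel":
        return CloneModel(self.f.copy(), self.c_center.copy(),
                          self.w_disp.copy())
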