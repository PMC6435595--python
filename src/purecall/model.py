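"""High-level modelling interface.

:class:`JointSomaticModel` is built from the per-site counts, per-exon
depths and site annotation for one patient; :meth:`JointSomaticModel.fit`
runs the full joint-calling EM and returns a
:class:`JointSomaticResults` carrying the fitted clone fractions, the
copy-number segmentation, the call table, an iteration log and a
``summary()`` report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as pcio
from .clonal import EMResult, FitData, em_driver
from .config import PriorConfig
from .containers import CloneModel, ExonDepth, SiteAnnotation, SiteCounts
from .quality import (DEFAULT_METRICS, quality_pipeline, refit_homozygous,
                      trust_score)

__all__ = ["JointSomaticModel", "JointSomaticResults"]


class JointSomaticModel:
    """Joint tumor-only somatic variant calling model for one patient.

    Parameters
    ----------
    sites : SiteCounts
        Candidate variant positions with per-sample read counts.
    exons : ExonDepth
        Per-exon mean tumor depths and unmatched-control depths.
    annotation : SiteAnnotation, optional
        Population allele frequencies and hotspot counts per site;
        defaults to "never seen in any database".
    config : PriorConfig, optional
        Priors and thresholds; defaults encode the standard two-sample
        operating point.

    Examples
    --------
    >>> model = JointSomaticModel(sites, exons, annotation)
    >>> res = model.fit(seed=7)
    >>> print(res.summary())
    """

    def __init__(self, sites: SiteCounts, exons: ExonDepth,
                 annotation: SiteAnnotation = None,
                 config: PriorConfig = None):
        if sites.n_samples != exons.n_samples:
            raise ValueError("sites and exons disagree on sample count")
        self.sites = sites
        self.exons = exons
        self.annotation = annotation or SiteAnnotation.default(sites.n_sites)
        if len(self.annotation.omega) != sites.n_sites:
            raise ValueError("annotation rows must match sites")
        self.config = config or PriorConfig()

    @classmethod
    def from_tables(cls, counts_path, depths_path, annotation_path=None,
                    config: PriorConfig = None) -> "JointSomaticModel":
        """Build the model from the TSV interchange files."""
        sites = pcio.read_counts_table(counts_path)
        exons = pcio.read_exon_depths(depths_path)
        ann = pcio.read_annotation(annotation_path, sites.n_sites) \
            if annotation_path else None
        return cls(sites, exons, ann, config)

    @classmethod
    def from_simulation(cls, dataset, config: PriorConfig = None
                        ) -> "JointSomaticModel":
        """Build the model from a :class:`~purecall.simulate.SimulatedDataset`."""
        return cls(dataset.sites, dataset.exons, dataset.annotation, config)

    @property
    def n_samples(self) -> int:
        return self.sites.n_samples

    def fit(self, seed: int = 0) -> "JointSomaticResults":
        """Run quality filtering and the joint-calling EM."""
        trust, post = quality_pipeline(self.sites,
                                       return_posteriors=True)
        data = FitData(sites=self.sites, exons=self.exons,
                       annotation=self.annotation, trust=trust)
        res = em_driver(data, self.config, seed=seed)
        calls = res.calls
        # re-score homozygous positions with A-only metrics
        hom = (calls["label"] == "Homozygous").to_numpy()
        names = [s.name for s in DEFAULT_METRICS]
        if hom.any() and all(n in self.sites.extra for n in names):
            for j in range(self.n_samples):
                x = np.stack([self.sites.extra[n][:, j] for n in names],
                             axis=1)
                try:
                    post[:, j] = refit_homozygous(x, post[:, j], hom)
                except ValueError:
                    pass      # training groups too small: keep original
            trust = trust_score(post, self.sites.r_b)
            calls = calls.copy()
            calls["trust"] = trust
            fail = hom & (trust <= self.config.t_pass)
            calls.loc[fail, "label"] = "Reject"
        return JointSomaticResults(self, res, calls, trust)


class JointSomaticResults:
    """Fitted state of a :class:`JointSomaticModel`."""

    def __init__(self, model: JointSomaticModel, em: EMResult,
                 calls: pd.DataFrame, trust: np.ndarray):
        self.model = model
        self.clone_model: CloneModel = em.clone_model
        self.segments = em.segments
        self.calls = calls
        self.iterations = em.iterations
        self.converged = em.converged
        self.n_iter = em.n_iter
        self.objective = em.objective
        self.trust = trust

    # -- tidy accessors ---------------------------------------------------
    @property
    def sample_fractions(self) -> pd.DataFrame:
        """Clone-by-sample fraction matrix f."""
        cm = self.clone_model
        return pd.DataFrame(
            cm.f, index=[f"clone{k + 1}" for k in range(cm.n_clones)],
            columns=[f"sample{j}" for j in range(cm.n_samples)])

    @property
    def somatic_calls(self) -> pd.DataFrame:
        return self.calls[self.calls["label"] == "Somatic"]

    def call_counts(self) -> pd.Series:
        return self.calls["label"].value_counts()

    def summary(self) -> str:
        """Human-readable fit report."""
        cm = self.clone_model
        lines = ["Joint tumor-only somatic calling results",
                 "=" * 44,
                 f"samples: {cm.n_samples}   clonal variant groups: "
                 f"{cm.n_clones}",
                 f"EM iterations: {self.n_iter} "
                 f"({'converged' if self.converged else 'not converged'})"
                 f"   objective: {self.objective:.2f}", "",
                 "Sample fractions f (clone x sample):"]
        lines.append(self.sample_fractions.round(3).to_string())
        lines.append("")
        lines.append("centering C: "
                     + np.array2string(cm.c_center, precision=3))
        lines.append("dispersion W: "
                     + np.array2string(cm.w_disp, precision=1))
        lines.append("")
        lines.append("Segments:")
        for seg in self.segments:
            lines.append(f"  {seg.chrom}:{seg.start}-{seg.end}  "
                         f"N={seg.n_total} M={seg.m_minor} "
                         f"clone={seg.clone_index}")
        lines.append("")
        lines.append("Calls: " + ", ".join(
            f"{k}={v}" for k, v in self.call_counts().items()))
        return "\n".join(lines)

    # -- output -----------------------------------------------------------
    def to_vcf(self, path, sample_names=None) -> None:
        pcio.write_vcf(self.calls, path, sample_names)

    def save_segments(self, path_prefix):
        return pcio.write_segments(self.segments, self.clone_model,
                                   self.model.exons, path_prefix,
                                   sites=self.model.sites)

    def save_iteration_log(self, path) -> None:
        self.iterations.to_csv(path, sep="\t", index=False)

    def plot_allele_fractions(self, ax=None):
        """Observed allele fractions by position, colored by call label."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        colors = {"Somatic": "crimson", "GermlineHet": "gray",
                  "Homozygous": "tan", "Unknown": "skyblue",
                  "Reject": "lightgray"}
        df = self.calls
        af = df["ad_b_s0"] / df["dp_s0"].clip(lower=1)
        for label, color in colors.items():
            sel = df["label"] == label
            if sel.any():
                ax.scatter(df.loc[sel, "pos"], af[sel], s=6, c=color,
                           label=label, alpha=0.6)
        ax.set_xlabel("position")
        ax.set_ylabel("allele fraction (sample 0)")
        ax.legend(fontsize=7, markerscale=2)
        return ax
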