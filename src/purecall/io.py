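"""File formats: counts/depth/annotation tables, segment BED/TSV, VCF.

Tab-separated tables are the interchange format (the pileup step that
produces them from BAMs is outside this package).  Genomic intervals are
0-based half-open in BED and the depth table; variant positions are
1-based in the counts table and the VCF, and every output states its
convention in a header line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .containers import ExonDepth, SiteAnnotation, SiteCounts

__all__ = ["read_counts_table", "write_counts_table", "read_exon_depths",
           "write_exon_depths", "read_annotation", "write_annotation",
           "write_vcf", "write_segments", "read_truth"]

_COUNTS_CORE = ["chrom", "pos", "ref", "A", "B", "is_indel"]


class TableFormatError(ValueError):
    """Malformed input table."""


def read_counts_table(path) -> SiteCounts:
    """Read the per-site counts TSV.

    Layout: columns chrom, pos (1-based), ref, A, B, is_indel, then one
    block per sample: s{j}_dp, s{j}_ad_b, s{j}_qmap_a, s{j}_qmap_b,
    s{j}_qbase_b plus any extra metric columns s{j}_<name>.  Rows with
    AD_B > DP or non-monotone positions within a chromosome are rejected
    with their line numbers.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _COUNTS_CORE if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    j = 0
    while f"s{j}_dp" in df.columns:
        j += 1
    if j == 0:
        raise TableFormatError(f"{path}: no per-sample blocks (s0_dp ...)")
    for s in range(j):
        bad = df[f"s{s}_ad_b"] > df[f"s{s}_dp"]
        if bad.any():
            lines = (np.where(bad)[0] + 2).tolist()[:5]
            raise TableFormatError(
                f"{path}: AD_B > DP for sample {s} at line(s) {lines}")
    for chrom, grp in df.groupby("chrom", sort=False):
        if np.any(np.diff(grp["pos"].to_numpy()) < 0):
            raise TableFormatError(
                f"{path}: positions not sorted within {chrom}")
    return SiteCounts.from_frame(df)


def write_counts_table(sites: SiteCounts, path) -> None:
    with open(path, "w") as fh:
        fh.write("# per-site read counts; pos is 1-based\n")
        sites.to_frame().to_csv(fh, sep="\t", index=False)


def read_exon_depths(path) -> ExonDepth:
    """Read the per-exon mean-depth table (BED-convention intervals:
    0-based half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for c in ("chrom", "start", "end", "control_depth", "s0_depth"):
        if c not in df.columns:
            raise TableFormatError(f"{path}: missing column {c}")
    return ExonDepth.from_frame(df)


def write_exon_depths(exons: ExonDepth, path) -> None:
    with open(path, "w") as fh:
        fh.write("# per-exon mean depths; intervals 0-based half-open\n")
        exons.to_frame().to_csv(fh, sep="\t", index=False)


def read_annotation(path, n_sites=None) -> SiteAnnotation:
    """Read the site annotation table (f_pop_a, f_pop_b, omega)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    ann = SiteAnnotation(f_pop_a=df["f_pop_a"].to_numpy(),
                         f_pop_b=df["f_pop_b"].to_numpy(),
                         omega=df["omega"].to_numpy())
    if n_sites is not None and len(ann.omega) != n_sites:
        raise TableFormatError(
            f"{path}: {len(ann.omega)} rows, expected {n_sites}")
    return ann


def write_annotation(ann: SiteAnnotation, path) -> None:
    pd.DataFrame({"f_pop_a": ann.f_pop_a, "f_pop_b": ann.f_pop_b,
                  "omega": ann.omega}).to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_vcf(calls: pd.DataFrame, path, sample_names=None) -> None:
    """Write the call table as VCF 4.2 via pysam.

    INFO: PS/PG (posterior somatic / germline het), CN, MACN, CLONE,
    AF_EXP (expected AF per sample), TRUST; FORMAT: AD, DP.  FILTER is
    PASS for somatic/germline calls, REJECT for quality failures and
    Unknown otherwise.
    """
    n_samples = sum(1 for c in calls.columns if c.startswith("dp_s"))
    if sample_names is None:
        sample_names = [f"SAMPLE{j}" for j in range(n_samples)]
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom in dict.fromkeys(calls["chrom"]):
        header.contigs.add(str(chrom))
    header.filters.add("REJECT", None, None, "Failed quality trust score")
    header.filters.add("Unknown", None, None,
                       "No genotype posterior above threshold")
    header.info.add("PS", 1, "Float", "Posterior probability somatic")
    header.info.add("PG", 1, "Float",
                    "Posterior probability germline heterozygous")
    header.info.add("CN", 1, "Integer", "Segment total copy number")
    header.info.add("MACN", 1, "Integer", "Segment minor allele copy number")
    header.info.add("CLONE", 1, "Integer", "Clonal variant group index")
    header.info.add("AF_EXP", ".", "Float",
                    "Expected allele fraction per sample")
    header.info.add("TRUST", 1, "Float", "Cross-sample quality trust score")
    header.info.add("CALL", 1, "String", "Joint classification label")
    header.formats.add("AD", "R", "Integer",
                       "Allelic depths (A allele, B allele)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    for name in sample_names:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for _, row in calls.iterrows():
            ref = str(row["ref"])
            alt = str(row["B"]) if str(row["B"]) != ref else str(row["A"])
            rec = out.new_record(contig=str(row["chrom"]),
                                 start=int(row["pos"]) - 1,
                                 alleles=(ref, alt))
            label = row["label"]
            rec.filter.add("PASS" if label in
                           ("Somatic", "GermlineHet", "Homozygous")
                           else ("REJECT" if label == "Reject"
                                 else "Unknown"))
            rec.info["PS"] = float(row["p_somatic"])
            rec.info["PG"] = float(row["p_het"])
            rec.info["CN"] = int(row["n_total"])
            rec.info["MACN"] = int(row["m_minor"])
            rec.info["CLONE"] = int(row["clone"])
            rec.info["AF_EXP"] = tuple(
                float(row[f"af_exp_s{j}"]) for j in range(n_samples))
            rec.info["TRUST"] = float(row["trust"])
            rec.info["CALL"] = str(label)
            for j, name in enumerate(sample_names):
                dp = int(row[f"dp_s{j}"])
                ad_b = int(row[f"ad_b_s{j}"])
                rec.samples[name]["AD"] = (dp - ad_b, ad_b)
                rec.samples[name]["DP"] = dp
            out.write(rec)


def write_segments(segments, clone_model, exons: ExonDepth, path_prefix,
                   sites=None):
    """Write segment calls as BED and as a TSV with state, per-sample
    clone fraction, mean log2 depth ratio and (when ``sites`` is given)
    mean folded B-allele fraction columns."""
    prefix = Path(path_prefix)
    rows = []
    with np.errstate(divide="ignore"):
        log_ratio = np.log2((exons.r_tumor_mean + 0.5)
                            / (exons.r_control_mean[:, None] + 0.5))
    for seg in segments:
        row = {"chrom": seg.chrom, "start": seg.start, "end": seg.end,
               "n_total": seg.n_total, "m_minor": seg.m_minor,
               "clone": seg.clone_index}
        for j in range(clone_model.n_samples):
            row[f"f_s{j}"] = clone_model.f[seg.clone_index - 1, j]
            row[f"log2_ratio_s{j}"] = float(
                log_ratio[seg.exon_indices, j].mean())
            if sites is not None:
                het = seg.het_indices
                if len(het):
                    af = sites.r_b[het, j] / np.maximum(
                        sites.r_total[het, j], 1)
                    row[f"baf_folded_s{j}"] = float(
                        (0.5 + np.abs(af - 0.5)).mean())
                else:
                    row[f"baf_folded_s{j}"] = float("nan")
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(prefix.with_suffix(".tsv"), "w") as fh:
        fh.write("# segment copy-number calls; intervals 0-based half-open\n")
        df.to_csv(fh, sep="\t", index=False)
    with open(prefix.with_suffix(".bed"), "w") as fh:
        fh.write('#chrom\tstart\tend\tname\n')
        for _, r in df.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t"
                     f"CN{r['n_total']}_M{r['m_minor']}_K{r['clone']}\n")
    return df
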