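"""Truth-based scoring of call sets.

Sensitivity here is against the somatic truth labels; germline
heterozygous truth sites called somatic are the false positives.  A
truth label of ``ambiguous`` removes a site from all counts, so
consensus-style truth protocols (where single-caller variants are
neither true nor false) are representable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["confusion", "f1", "allele_fraction"]


def allele_fraction(ref_depth, alt_depth):
    """Variant allele fraction alt / (ref + alt)."""
    ref = np.asarray(ref_depth, dtype=float)
    alt = np.asarray(alt_depth, dtype=float)
    total = ref + alt
    out = np.divide(alt, total, out=np.full_like(alt, np.nan),
                    where=total > 0)
    return out if out.ndim else float(out)


def confusion(calls: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Somatic-call confusion counts and rates against a truth table.

    ``calls`` needs (chrom, pos, label); ``truth`` needs
    (chrom, pos, true_class).  Undefined rates (0/0) are NaN.
    """
    merged = truth.merge(calls[["chrom", "pos", "label"]],
                         on=["chrom", "pos"], how="left")
    merged["label"] = merged["label"].fillna("Reject")
    merged = merged[merged["true_class"] != "ambiguous"]
    is_pos = (merged["true_class"] == "somatic").to_numpy()
    called = (merged["label"] == "Somatic").to_numpy()
    tp = int((is_pos & called).sum())
    fn = int((is_pos & ~called).sum())
    fp = int((~is_pos & called).sum())
    tn = int((~is_pos & ~called).sum())

    def rate(num, den):
        return num / den if den > 0 else float("nan")

    return {"TP": tp, "FP": fp, "FN": fn, "TN": tn,
            "TPR": rate(tp, tp + fn), "FNR": rate(fn, tp + fn),
            "FPR": rate(fp, fp + tn), "PPV": rate(tp, tp + fp)}


def f1(tpr: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and precision."""
    if not (0 <= tpr <= 1 and 0 <= ppv <= 1):
        raise ValueError("tpr and ppv must be in [0, 1]")
    if tpr + ppv == 0:
        raise ValueError("f1 undefined when both arguments are 0")
    return 2.0 * tpr * ppv / (tpr + ppv)
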