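"""Exon read-depth CNV calling against a control panel.

The caller works on per-exon read-count matrices (exons x samples):
sample depths are balanced to a common mean, a reference level per exon is
taken as the (optionally trimmed) mean over normalized control samples,
and tumor exon copy number is CN = 2 x tumor / reference (diploid = 2).
A gene is called a gain when ALL of its evaluable exons have CN > 2.8,
a loss when all have CN < 1.2, and is not called at all with fewer than
three evaluable exons — conservative all-exon rules chosen to suppress
false positives at the expense of subclonal or focal events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CnvThresholds:
    gain_cn: float = 2.8        # gain iff every evaluable exon CN > gain_cn
    loss_cn: float = 1.2        # loss iff every evaluable exon CN < loss_cn
    min_exons: int = 3          # "more than two exons"
    min_control_level: float = 1.0   # usable-exon floor on the reference

    def __post_init__(self):
        if not (self.loss_cn < 2 < self.gain_cn):
            raise ValueError("need loss_cn < 2 < gain_cn")
        if self.min_exons < 1:
            raise ValueError("min_exons must be >= 1")


def normalize_by_depth(counts: pd.DataFrame) -> pd.DataFrame:
    """Balance samples by average sequencing depth.

    Each sample (column) is scaled so its mean per-exon count equals the
    global mean of per-sample means; relative exon structure is untouched.
    """
    means = counts.mean(axis=0)
    if (means <= 0).any():
        bad = means[means <= 0].index[0]
        raise ValueError(f"sample {bad!r} has no reads")
    return counts * (means.mean() / means)


def build_control_panel(
    normalized_controls: pd.DataFrame,
    min_control_level: float = 1.0,
    method: str = "mean",
    trim: float = 0.1,
) -> pd.DataFrame:
    """Per-exon reference level from >= 2 normalized control samples.

    Returns a frame indexed by exon with columns ``reference`` and
    ``usable``; exons whose reference falls below ``min_control_level``
    are flagged unusable rather than dropped.
    """
    if normalized_controls.shape[1] < 2:
        raise ValueError("need at least 2 control samples")
    if method == "mean":
        ref = normalized_controls.mean(axis=1)
    elif method == "trimmed":
        from scipy.stats import trim_mean
        ref = pd.Series(
            trim_mean(normalized_controls.to_numpy(), trim, axis=1),
            index=normalized_controls.index,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame({"reference": ref, "usable": ref >= min_control_level})


def exon_copy_numbers(tumor_normalized, panel: pd.DataFrame):
    """CN(exon) = 2 x tumor / reference on usable exons; unusable -> NaN.

    Accepts a Series (one tumor) or DataFrame (exons x tumors) aligned to
    the panel's exon index.
    """
    ref = panel["reference"]
    usable = panel["usable"]
    if isinstance(tumor_normalized, pd.DataFrame):
        cn = tumor_normalized.div(ref, axis=0) * 2.0
        return cn.where(usable, np.nan)
    cn = 2.0 * tumor_normalized / ref
    return cn.where(usable, np.nan)


def call_gene_cnv(
    exon_cn: pd.Series,
    exon_model: pd.DataFrame,
    thresholds: CnvThresholds = CnvThresholds(),
) -> pd.DataFrame:
    """Gene-level gain/loss/neutral/no_call decisions for one sample.

    ``exon_cn`` is indexed by exon_id (NaN = not evaluable); ``exon_model``
    maps exon_id -> gene. Genes with fewer than ``min_exons`` evaluable
    exons are ``no_call``.
    """
    gene_of = exon_model.set_index("exon_id")["gene"]
    rows = []
    for gene, exons in gene_of.groupby(gene_of):
        cns = exon_cn.reindex(exons.index).dropna()
        n_eval = len(cns)
        if n_eval < thresholds.min_exons:
            call = "no_call"
        elif (cns > thresholds.gain_cn).all():
            call = "gain"
        elif (cns < thresholds.loss_cn).all():
            call = "loss"
        else:
            call = "neutral"
        rows.append({"gene": gene, "call": call, "n_evaluable_exons": n_eval,
                     "mean_cn": cns.mean() if n_eval else np.nan})
    return pd.DataFrame(rows).set_index("gene")


def cohort_cnv_summary(calls_per_sample: dict[str, pd.DataFrame]) -> dict:
    """Gene x sample call matrix plus per-gene gain/loss frequencies.

    ``calls_per_sample`` maps sample id -> output of :func:`call_gene_cnv`.
    Frequencies are affected samples / cohort size.
    """
    if not calls_per_sample:
        raise ValueError("need at least one sample")
    matrix = pd.DataFrame({s: df["call"] for s, df in calls_per_sample.items()})
    n = matrix.shape[1]
    freq = pd.DataFrame({
        "gain_freq": (matrix == "gain").sum(axis=1) / n,
        "loss_freq": (matrix == "loss").sum(axis=1) / n,
    })
    gained = sorted(freq.index[freq["gain_freq"] > 0])
    lost = sorted(freq.index[freq["loss_freq"] > 0])
    return {"matrix": matrix, "frequencies": freq,
            "gained_genes": gained, "lost_genes": lost}


def cohort_overlap(genes_a, genes_b) -> dict:
    """Set comparison of two cohorts' affected-gene lists."""
    a, b = set(genes_a), set(genes_b)
    return {"shared": sorted(a & b), "only_a": sorted(a - b), "only_b": sorted(b - a)}
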