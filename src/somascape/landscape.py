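"""Cohort-level mutation landscape: gene x sample matrices, frequencies,
cross-cohort exclusivity, catalog joins, and over-representation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSampleMatrix:
    """Binary gene x sample mutation indicator for one cohort."""

    matrix: pd.DataFrame      # genes x samples, entries 0/1
    cohort: str = ""

    @property
    def cohort_size(self) -> int:
        return self.matrix.shape[1]

    @property
    def frequencies(self) -> pd.Series:
        """Fraction of cohort samples carrying >= 1 qualifying mutation."""
        return self.matrix.sum(axis=1) / self.cohort_size

    @property
    def counts(self) -> pd.Series:
        return self.matrix.sum(axis=1)


@dataclass(frozen=True)
class EnrichmentParams:
    """Over-representation settings. Defaults follow the convention of a
    raw-p cutoff of 0.01 for mutated-gene lists (0.05 is typical for CNV
    gene lists) with a minimum overlap of 2."""

    min_overlap: int = 2
    p_cutoff: float = 0.01

    def __post_init__(self):
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not (0 < self.p_cutoff < 1):
            raise ValueError("p_cutoff must be in (0,1)")


def gene_sample_matrix(variants: pd.DataFrame, cohort_samples, cohort: str = "") -> GeneSampleMatrix:
    """Binarized gene x sample matrix over an explicit cohort sample list.

    Samples with no mutations still contribute columns (and to the
    denominator); a variant from a sample outside the cohort is an error.
    """
    cohort_samples = list(cohort_samples)
    unknown = set(variants["sample"]) - set(cohort_samples)
    if unknown:
        raise ValueError(f"variant sample(s) not in cohort list: {sorted(unknown)[:5]}")
    genes = sorted(variants["gene"].unique())
    mat = pd.DataFrame(0, index=genes, columns=cohort_samples, dtype=int)
    for gene, sample in zip(variants["gene"], variants["sample"]):
        mat.loc[gene, sample] = 1
    return GeneSampleMatrix(mat, cohort)


def cohort_exclusive_genes(
    matrix_a: GeneSampleMatrix,
    matrix_b: GeneSampleMatrix,
    min_freq_a: float = 0.2,
    max_count_b: int = 0,
) -> pd.DataFrame:
    """Genes frequent in cohort A but (near-)absent from cohort B.

    Matrices are aligned on the union of gene universes (absent = 0).
    """
    genes = matrix_a.matrix.index.union(matrix_b.matrix.index)
    freq_a = matrix_a.frequencies.reindex(genes, fill_value=0.0)
    count_a = matrix_a.counts.reindex(genes, fill_value=0)
    count_b = matrix_b.counts.reindex(genes, fill_value=0)
    keep = (freq_a >= min_freq_a) & (count_b <= max_count_b)
    out = pd.DataFrame({
        "freq_a": freq_a[keep],
        "count_a": count_a[keep],
        "count_b": count_b[keep],
    }).sort_values("freq_a", ascending=False)
    out.index.name = "gene"
    return out


def subset_by_catalog(obj, catalog) -> pd.DataFrame | GeneSampleMatrix:
    """Restrict a variant table or gene-sample matrix to catalog genes."""
    catalog = set(catalog)
    if not catalog:
        raise ValueError("catalog is empty")
    if isinstance(obj, GeneSampleMatrix):
        keep = [g for g in obj.matrix.index if g in catalog]
        return GeneSampleMatrix(obj.matrix.loc[keep], obj.cohort)
    return obj[obj["gene"].isin(catalog)].reset_index(drop=True)


def recurrent_genes(variants: pd.DataFrame, min_count: int = 2, unit: str = "records") -> pd.Series:
    """Genes mutated at least ``min_count`` times in the cohort.

    ``unit="records"`` counts mutation records (the default reading of
    "mutated more than once"); ``unit="samples"`` counts distinct samples.
    Returns the qualifying genes with their counts.
    """
    if unit == "records":
        counts = variants.groupby("gene").size()
    elif unit == "samples":
        counts = variants.groupby("gene")["sample"].nunique()
    else:
        raise ValueError(f"unknown unit {unit!r}")
    return counts[counts >= min_count].sort_values(ascending=False)


def ora_enrichment(
    gene_list,
    gene_sets: dict[str, set[str]],
    universe,
    params: EnrichmentParams = EnrichmentParams(),
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    p = P(X >= k) with N = |universe|, K = |set ∩ universe|,
    n = |gene_list|, k = |overlap|. Sets overlapping fewer than
    ``min_overlap`` genes are excluded. Raw p drives the pass rule;
    Benjamini-Hochberg q-values are reported alongside.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_list = set(gene_list)
    outside = gene_list - universe
    if outside:
        raise ValueError(f"gene_list not contained in universe: {sorted(outside)[:5]}")
    N, n = len(universe), len(gene_list)
    rows = []
    for name, members in gene_sets.items():
        members = members & universe
        k = len(gene_list & members)
        if k < params.min_overlap:
            continue
        K = len(members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "set_size": K, "overlap": k, "p": p})
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["pass"] = df["p"] < params.p_cutoff
        df = df.sort_values("p").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["pass"] = pd.Series(dtype=bool)
    return df


def stratified_gene_comparison(
    matrix: GeneSampleMatrix,
    clinical: pd.DataFrame,
    stratum_field: str,
    groups: dict[str, set],
    min_count: int = 1,
) -> dict[str, pd.Series]:
    """Genes mutated exclusively in one clinical stratum.

    ``groups`` maps group label -> set of accepted stratum-field values
    (e.g. {"N0": {"0"}, "N1/N2": {"1", "2"}}). For each group, returns
    genes mutated in >= ``min_count`` of its samples and in none of the
    complement, with their in-group counts.
    """
    clin = clinical.set_index("sample_id")
    value_of = clin[stratum_field].astype(str)
    sample_group = {}
    for s in matrix.matrix.columns:
        if s not in value_of.index:
            raise ValueError(f"sample {s!r} missing from clinical table")
        val = value_of[s]
        hits = [g for g, vals in groups.items() if val in {str(v) for v in vals}]
        if len(hits) != 1:
            raise ValueError(f"stratum value {val!r} of sample {s!r} matches {len(hits)} groups")
        sample_group[s] = hits[0]
    out = {}
    for g in groups:
        in_cols = [s for s, grp in sample_group.items() if grp == g]
        out_cols = [s for s in matrix.matrix.columns if s not in in_cols]
        n_in = matrix.matrix[in_cols].sum(axis=1)
        n_out = matrix.matrix[out_cols].sum(axis=1) if out_cols else 0
        exclusive = n_in[(n_in >= min_count) & (n_out == 0)]
        out[g] = exclusive.sort_values(ascending=False)
    return out
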