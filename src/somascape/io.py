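"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions: variant positions are 1-based (as in VCF/MAF);
exon intervals are 0-based half-open (BED). Conversion happens only at
comparison time, never on ingest.

The MAF-like dialect is a minimal tab-separated table with a documented
header (see :data:`MAF_REQUIRED_COLUMNS`); columns beyond the known ones
are preserved opaquely so round-trips are lossless.
"""

from __future__ import annotations

import sys
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
VARIANT_CLASSES = ("SNV", "INS", "DEL")
SOMATIC_FLAGS = ("ISOWN", "SOMVARIUS", "BOTH", "NONE")

MAF_REQUIRED_COLUMNS = (
    "sample",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "impact",
    "alt_depth",
    "total_depth",
    "pop_af",
)
MAF_OPTIONAL_COLUMNS = (
    "variant_class",
    "consequence",
    "protein_change",
    "context3",
    "somatic_flag",
)


class SchemaError(ValueError):
    """A required column is missing or a table-level invariant is broken."""


class RowError(ValueError):
    """One or more rows failed validation; carries (line, message) pairs."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in problems[:10])
        extra = "" if len(problems) <= 10 else f" (+{len(problems) - 10} more)"
        super().__init__(f"{len(problems)} invalid row(s): {detail}{extra}")


def classify_alleles(ref: str, alt: str) -> str:
    """SNV iff both alleles have length 1; longer alt is INS, longer ref DEL."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "INS"
    if len(ref) > len(alt):
        return "DEL"
    raise ValueError(f"cannot classify alleles {ref!r}>{alt!r}")


def _validate_variant_rows(df: pd.DataFrame, lines: np.ndarray,
                           missing_af_is_rare: bool) -> pd.DataFrame:
    problems: list[tuple[int, str]] = []
    df = df.copy()

    if "pop_af" in df.columns:
        if missing_af_is_rare:
            df["pop_af"] = df["pop_af"].fillna(0.0)
        else:
            for i in np.flatnonzero(df["pop_af"].isna().to_numpy()):
                problems.append((int(lines[i]), "pop_af missing (set missing_af_is_rare to treat as 0)"))

    vclass = []
    for i, row in enumerate(df.itertuples(index=False)):
        ln = int(lines[i])
        try:
            cls = classify_alleles(str(row.ref), str(row.alt))
        except ValueError as exc:
            problems.append((ln, str(exc)))
            vclass.append(None)
            continue
        vclass.append(cls)
        if row.pos < 1:
            problems.append((ln, f"pos {row.pos} < 1"))
        if row.alt_depth > row.total_depth:
            problems.append((ln, f"alt_depth {row.alt_depth} > total_depth {row.total_depth}"))
        if row.alt_depth < 0 or row.total_depth < 0:
            problems.append((ln, "negative depth"))
        if not pd.isna(row.pop_af) and not (0.0 <= row.pop_af <= 1.0):
            problems.append((ln, f"pop_af {row.pop_af} outside [0,1]"))
        if row.impact not in IMPACTS:
            problems.append((ln, f"unknown impact {row.impact!r}"))

    if "variant_class" in df.columns:
        for i, (given, derived) in enumerate(zip(df["variant_class"], vclass)):
            if derived is not None and not pd.isna(given) and given != derived:
                problems.append((int(lines[i]), f"variant_class {given!r} inconsistent with alleles ({derived})"))
    else:
        df["variant_class"] = vclass

    if "somatic_flag" in df.columns:
        bad = ~df["somatic_flag"].isin(SOMATIC_FLAGS) & df["somatic_flag"].notna()
        for i in np.flatnonzero(bad.to_numpy()):
            problems.append((int(lines[i]), f"unknown somatic_flag {df['somatic_flag'].iloc[i]!r}"))

    if problems:
        raise RowError(sorted(problems))
    return df


def read_variant_table(path, dialect: str = "maf_tsv", *,
                       missing_af_is_rare: bool = False,
                       vcf_info_keys: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read an annotated variant table.

    Parameters
    ----------
    path : str or Path
        Input file.
    dialect : {"maf_tsv", "vcf_min"}
        ``maf_tsv`` is the documented tab-separated dialect; ``vcf_min``
        reads a standard VCF via cyvcf2, taking depths from the per-sample
        AD field and annotations from the INFO keys in ``vcf_info_keys``.
    missing_af_is_rare : bool
        If set, a missing population allele frequency is treated as 0
        (i.e. rare). Default is to reject such rows: the rarity filter
        depends critically on this field.
    vcf_info_keys : mapping
        For ``vcf_min``: maps {"gene", "impact", "pop_af"} to INFO keys.
        Defaults to {"gene": "GENE", "impact": "IMPACT", "pop_af": "MAX_AF"}.
    """
    if dialect == "maf_tsv":
        return _read_maf_tsv(path, missing_af_is_rare)
    if dialect == "vcf_min":
        return _read_vcf_min(path, vcf_info_keys, missing_af_is_rare)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_maf_tsv(path, missing_af_is_rare: bool) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    for col in MAF_REQUIRED_COLUMNS:
        if col != "pop_af" and col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    if "pop_af" not in df.columns:
        if missing_af_is_rare:
            df["pop_af"] = 0.0
        else:
            raise SchemaError(f"required column 'pop_af' missing from {path}")
    # data line numbers in the physical file: header is line 1
    lines = np.asarray(df.index) + 2
    df = df.astype({"pos": int, "alt_depth": int, "total_depth": int, "pop_af": float})
    return _validate_variant_rows(df, lines, missing_af_is_rare).reset_index(drop=True)


_DEFAULT_VCF_KEYS = {"gene": "GENE", "impact": "IMPACT", "pop_af": "MAX_AF"}


def _read_vcf_min(path, info_keys, missing_af_is_rare: bool) -> pd.DataFrame:
    from cyvcf2 import VCF

    keys = dict(_DEFAULT_VCF_KEYS, **(info_keys or {}))
    vcf = VCF(str(path))
    samples = vcf.samples
    rows = []
    for var in vcf:
        if not var.ALT:
            continue
        alt = var.ALT[0]
        gene = var.INFO.get(keys["gene"])
        impact = var.INFO.get(keys["impact"])
        pop_af = var.INFO.get(keys["pop_af"])
        ad = var.format("AD")
        for si, sample in enumerate(samples):
            if ad is None:
                continue
            ref_d, alt_d = int(ad[si][0]), int(ad[si][1])
            if alt_d <= 0:
                continue
            rows.append({
                "sample": sample, "gene": gene, "chrom": var.CHROM,
                "pos": var.POS, "ref": var.REF, "alt": alt,
                "impact": impact, "alt_depth": alt_d,
                "total_depth": ref_d + alt_d,
                "pop_af": float(pop_af) if pop_af is not None else np.nan,
            })
    df = pd.DataFrame(rows, columns=list(MAF_REQUIRED_COLUMNS))
    if df.empty:
        df["variant_class"] = pd.Series(dtype=object)
        return df
    lines = np.arange(len(df)) + 1  # record ordinal; VCF line numbers are opaque here
    return _validate_variant_rows(df, lines, missing_af_is_rare).reset_index(drop=True)


# ---------------------------------------------------------------------------
# 96-channel signature matrices

_BASES = "ACGT"
SUB_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Channel labels in canonical (COSMIC v2) order: substitution-major,
#: contexts alphabetical within each substitution class.
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUB_TYPES
    for five in _BASES
    for three in _BASES
)


def read_signature_matrix(path) -> pd.DataFrame:
    """Read a 96-channel x signatures probability matrix (TSV).

    The first column must hold channel labels like ``A[C>A]A`` in any
    order; rows are canonicalized to :data:`CHANNELS_96` order. Columns
    are renormalized to sum to 1 when within 1e-3 of 1, otherwise the
    file is rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[0] != 96:
        raise SchemaError(f"expected 96 channel rows, found {df.shape[0]}")
    if set(df.index) != set(CHANNELS_96):
        missing = sorted(set(CHANNELS_96) - set(df.index))[:3]
        raise SchemaError(f"channel labels not the canonical 96 (e.g. missing {missing})")
    if (df.values < 0).any():
        raise SchemaError("negative entry in signature matrix")
    sums = df.sum(axis=0)
    off = sums[(sums - 1.0).abs() > 1e-3]
    if len(off):
        raise SchemaError(
            f"signature column(s) {list(off.index)} sum to {list(off.round(4))}, not 1 within 1e-3")
    df = df.loc[list(CHANNELS_96)]
    return df / df.sum(axis=0)


def write_signature_matrix(sigs: pd.DataFrame, path) -> None:
    sigs.to_csv(path, sep="\t", index_label="channel")


# ---------------------------------------------------------------------------
# clinical, exon model, gene sets

CLINICAL_REQUIRED = ("sample_id", "status", "months")


def read_clinical(path) -> pd.DataFrame:
    """Read the per-patient clinical table (TSV; schema of the cohort table)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    for col in CLINICAL_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"required clinical column {col!r} missing")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"duplicate sample_id {dup!r}")
    df["months"] = df["months"].astype(float)
    if (df["months"] < 0).any():
        raise SchemaError("negative months_to_last_followup")
    bad = ~df["status"].isin(["Alive", "Dead"])
    if bad.any():
        raise SchemaError(f"status must be Alive/Dead, got {df.loc[bad, 'status'].unique()}")
    return df


def load_example_clinical() -> pd.DataFrame:
    """Bundled 15-patient gallbladder-NEC cohort clinical table."""
    with resources.as_file(resources.files("somascape") / "data" / "gbnec_clinical.tsv") as p:
        return read_clinical(p)


def read_exon_model(path) -> pd.DataFrame:
    """Read a BED file of exons (0-based half-open) into an exon model.

    The BED name field is the exon id; a gene symbol is derived from a
    ``GENE_e<k>`` style name, else the name itself is used as the gene.
    Identical duplicate intervals of one gene are merged.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "exon_id"],
                     dtype={"chrom": str, "exon_id": str})
    if df["exon_id"].isna().any():
        raise SchemaError("BED name field (exon_id) required")
    if (df["start"] < 0).any():
        raise SchemaError("negative BED coordinate")
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise SchemaError(f"start >= end for exon {bad.exon_id}")
    df["gene"] = [
        eid.rsplit("_e", 1)[0] if "_e" in eid else eid for eid in df["exon_id"]
    ]
    df = df.drop_duplicates(["gene", "chrom", "start", "end"]).reset_index(drop=True)
    if df["exon_id"].duplicated().any():
        dup = df.loc[df["exon_id"].duplicated(), "exon_id"].iloc[0]
        raise SchemaError(f"duplicate exon_id {dup!r}")
    return df[["exon_id", "gene", "chrom", "start", "end"]]


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> member genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"GMT line {ln}: fewer than 3 fields")
            name, _desc, *members = parts
            members = {m for m in members if m}
            if not members:
                raise SchemaError(f"GMT line {ln}: empty gene set {name!r}")
            sets[name] = members
    return sets


# ---------------------------------------------------------------------------
# generic TSV output with provenance header

def write_table(df: pd.DataFrame, path, params: Mapping[str, object] | None = None,
                index: bool = False) -> None:
    """Write a TSV with a ``#`` header block recording version and parameters."""
    with open(path, "w") as fh:
        fh.write(f"# somascape {__version__}\n")
        for key, val in (params or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=index)


def log_counts(stage: str, n: int, stream=sys.stderr) -> None:
    print(f"[somascape] {stage}: {n} records", file=stream)


def run_report(stages: Iterable[tuple[str, int]], path=None) -> pd.DataFrame:
    """Per-stage record counts as a TSV-writable report."""
    df = pd.DataFrame(list(stages), columns=["stage", "n_records"])
    if path is not None:
        write_table(df, path)
    return df
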