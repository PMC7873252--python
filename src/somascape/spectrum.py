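"""Substitution spectra and 96-channel trinucleotide catalogs.

Both encodings use the pyrimidine-reference (COSMIC) convention: a
substitution observed with a purine reference base is reverse-complemented,
flanks included, before classification. Channel order is substitution-major
(C>A, C>G, C>T, T>A, T>C, T>G) with the 16 flank contexts alphabetical
within each class — bit-compatible with COSMIC v2 signature files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CHANNELS_96, SUB_TYPES

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_TRANSITIONS = {"C>T", "T>C"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def substitution_class(ref: str, alt: str) -> str:
    """Map an SNV to one of the six pyrimidine-reference classes."""
    ref, alt = str(ref).upper(), str(alt).upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"not an SNV: {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt identical: {ref}")
    if ref in "AG":  # purine reference: fold onto the complementary strand
        ref, alt = revcomp(ref), revcomp(alt)
    return f"{ref}>{alt}"


@dataclass
class SpectrumSummary:
    """Six-class spectrum: per-sample and pooled counts, Ti/Tv totals."""

    per_sample_counts: pd.DataFrame   # samples x 6 classes
    pooled_counts: pd.Series          # 6 classes

    @property
    def per_sample_fractions(self) -> pd.DataFrame:
        totals = self.per_sample_counts.sum(axis=1)
        frac = self.per_sample_counts.div(totals, axis=0)
        return frac.where(totals > 0)  # zero-SNV samples -> NaN, not 0/0 noise

    @property
    def pooled_fractions(self) -> pd.Series:
        total = self.pooled_counts.sum()
        return self.pooled_counts / total if total > 0 else self.pooled_counts * np.nan

    @property
    def ti_count(self) -> int:
        return int(self.pooled_counts[list(_TRANSITIONS)].sum())

    @property
    def tv_count(self) -> int:
        return int(self.pooled_counts.sum()) - self.ti_count


def _snv_mask(variants: pd.DataFrame) -> pd.Series:
    if "variant_class" in variants.columns:
        return variants["variant_class"] == "SNV"
    return (variants["ref"].str.len() == 1) & (variants["alt"].str.len() == 1)


def spectrum6(variants: pd.DataFrame) -> SpectrumSummary:
    """Per-sample and pooled six-class spectrum; non-SNV rows are ignored."""
    snvs = variants[_snv_mask(variants)]
    samples = sorted(variants["sample"].unique()) if "sample" in variants.columns else ["pooled"]
    counts = pd.DataFrame(0, index=samples, columns=list(SUB_TYPES))
    if len(snvs):
        cls = [substitution_class(r, a) for r, a in zip(snvs["ref"], snvs["alt"])]
        sam = snvs["sample"] if "sample" in snvs.columns else ["pooled"] * len(snvs)
        tab = pd.crosstab(pd.Series(list(sam), name="sample"), pd.Series(cls, name="class"))
        counts = counts.add(tab.reindex(index=samples, columns=list(SUB_TYPES), fill_value=0),
                            fill_value=0).astype(int)
    return SpectrumSummary(counts, counts.sum(axis=0))


@dataclass
class Catalog96:
    """Counts of somatic SNVs over the 96 trinucleotide channels."""

    counts: pd.Series          # indexed by CHANNELS_96, canonical order
    n_excluded: int = 0        # SNVs with unresolvable context

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def collapse6(self) -> pd.Series:
        """Collapse over flanks back to the six-class spectrum."""
        cls = [ch[2:5] for ch in self.counts.index]
        return self.counts.groupby(cls).sum().reindex(list(SUB_TYPES), fill_value=0)


def channel_of(ref: str, alt: str, context3: str) -> str:
    """96-channel label of an SNV given its 3-mer reference context."""
    context3 = str(context3).upper()
    if len(context3) != 3 or any(b not in "ACGT" for b in context3):
        raise ValueError(f"unresolvable context {context3!r}")
    if context3[1] != ref.upper():
        raise ValueError(f"context middle base {context3[1]} != ref {ref}")
    if ref.upper() in "AG":
        context3, alt = revcomp(context3), revcomp(alt.upper())
    return f"{context3[0]}[{context3[1]}>{alt.upper()}]{context3[2]}"


def build_catalog96(
    variants: pd.DataFrame,
    context_source: str = "column",
    reference=None,
) -> Catalog96:
    """Build the 96-channel catalog for the SNVs of a variant table.

    ``context_source="column"`` takes the 3-mer from a ``context3`` column;
    ``"fasta"`` looks it up in ``reference`` (a pyfaidx.Fasta or a path).
    SNVs whose context cannot be resolved (N bases, missing value, absent
    chromosome) are excluded and tallied in ``n_excluded``. A context whose
    middle base contradicts the reference allele is a row error.
    """
    snvs = variants[_snv_mask(variants)]
    counts = pd.Series(0, index=list(CHANNELS_96), dtype=int)
    excluded = 0

    if context_source == "fasta":
        if reference is None:
            raise ValueError("fasta mode requires a reference")
        import pyfaidx
        if not isinstance(reference, pyfaidx.Fasta):
            reference = pyfaidx.Fasta(str(reference))

    for row in snvs.itertuples(index=False):
        if context_source == "column":
            ctx = getattr(row, "context3", None)
            if ctx is None or pd.isna(ctx):
                excluded += 1
                continue
        else:
            if row.chrom not in reference:
                excluded += 1
                continue
            ctx = str(reference[row.chrom][row.pos - 2: row.pos + 1]).upper()
        ctx = str(ctx).upper()
        if len(ctx) != 3 or any(b not in "ACGT" for b in ctx):
            excluded += 1
            continue
        counts[channel_of(str(row.ref), str(row.alt), ctx)] += 1

    return Catalog96(counts, n_excluded=excluded)
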