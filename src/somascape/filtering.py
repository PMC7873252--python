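"""The rare-and-nonsilent variant filter cascade.

Tumor-only exomes carry germline polymorphisms and silent changes in vast
excess over candidate drivers. The cascade retains a mutation only if

1. its predicted annotation impact is HIGH or MODERATE (nonsilent),
2. the alternative-allele read depth is strictly greater than 5, and
3. its maximum population allele frequency is strictly below 0.0005
   (rare in the general population).

Stages are reported in that fixed order; the retained set is the
conjunction and therefore order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the filter cascade. Depth and AF cuts are strict."""

    allowed_impacts: frozenset[str] = frozenset({"HIGH", "MODERATE"})
    min_alt_depth: int = 5       # retained iff alt_depth > min_alt_depth
    max_pop_af: float = 0.0005   # retained iff pop_af < max_pop_af

    def __post_init__(self):
        if not self.allowed_impacts:
            raise ValueError("allowed_impacts must be non-empty")
        if self.min_alt_depth < 0 or self.max_pop_af < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class FilterReport:
    """Per-stage record counts; counts are non-increasing by construction."""

    n_input: int
    n_after_impact: int
    n_after_depth: int
    n_after_af: int
    n_after_blacklist: int
    per_sample: dict[str, int] = field(default_factory=dict)

    @property
    def n_final(self) -> int:
        return self.n_after_blacklist

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "impact", "alt_depth", "pop_af", "blacklist"],
                "n_records": [self.n_input, self.n_after_impact,
                              self.n_after_depth, self.n_after_af,
                              self.n_after_blacklist],
            }
        )


def _require(df: pd.DataFrame, cols: list[str]) -> None:
    for col in cols:
        if col not in df.columns:
            raise ValueError(f"required column {col!r} absent")
        na = df[col].isna()
        if na.any():
            row = int(na.idxmax())
            raise ValueError(f"column {col!r} missing on row {row}")


def apply_filter_cascade(
    variants: pd.DataFrame,
    criteria: FilterCriteria = FilterCriteria(),
    blacklist: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply impact -> alt-depth -> population-AF filters (then blacklist).

    ``blacklist`` is an optional table of known false-positive sites with
    columns chrom, pos, ref, alt; matching rows are removed last.
    Returns the retained table and a :class:`FilterReport` whose stage
    counts reflect the stated order.
    """
    _require(variants, ["impact", "alt_depth", "pop_af"])
    n_input = len(variants)

    m_impact = variants["impact"].isin(criteria.allowed_impacts)
    m_depth = variants["alt_depth"] > criteria.min_alt_depth
    m_af = variants["pop_af"] < criteria.max_pop_af

    n_after_impact = int(m_impact.sum())
    n_after_depth = int((m_impact & m_depth).sum())
    keep = m_impact & m_depth & m_af
    n_after_af = int(keep.sum())

    if blacklist is not None and len(blacklist):
        sites = set(zip(blacklist["chrom"], blacklist["pos"],
                        blacklist["ref"], blacklist["alt"]))
        m_black = [
            (c, p, r, a) not in sites
            for c, p, r, a in zip(variants["chrom"], variants["pos"],
                                  variants["ref"], variants["alt"])
        ]
        keep = keep & pd.Series(m_black, index=variants.index)
    n_final = int(keep.sum())

    out = variants[keep].reset_index(drop=True)
    per_sample = out.groupby("sample").size().to_dict() if "sample" in out.columns else {}
    report = FilterReport(n_input, n_after_impact, n_after_depth,
                          n_after_af, n_final, per_sample)
    return out, report


def intersect_somatic_flags(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep variants called somatic by both tumor-only classifiers.

    Expects a ``somatic_flag`` column with values ISOWN / SOMVARIUS /
    BOTH / NONE; only BOTH survives.
    """
    if "somatic_flag" not in variants.columns:
        raise ValueError("required column 'somatic_flag' absent")
    return variants[variants["somatic_flag"] == "BOTH"].reset_index(drop=True)


def _norm_hgvs_p(text: str) -> str:
    text = str(text).strip()
    return text if text.startswith("p.") else "p." + text


def flag_hotspots(variants: pd.DataFrame, hotspot_catalog: pd.DataFrame) -> pd.DataFrame:
    """Flag variants matching a (gene, protein_change) hotspot catalog.

    Matching is exact on the normalized HGVS.p text (a ``p.`` prefix is
    added when absent); rows without a protein change are never flagged.
    In-frame deletion notation (e.g. ``p.Tyr220_Pro223del``) matches like
    any other string.
    """
    out = variants.copy()
    if len(hotspot_catalog):
        pairs = set(zip(hotspot_catalog["gene"],
                        hotspot_catalog["protein_change"].map(_norm_hgvs_p)))
    else:
        pairs = set()
    if "protein_change" in out.columns:
        flags = [
            (not pd.isna(pc)) and (g, _norm_hgvs_p(pc)) in pairs
            for g, pc in zip(out["gene"], out["protein_change"])
        ]
    else:
        flags = [False] * len(out)
    out["hotspot"] = flags
    return out
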