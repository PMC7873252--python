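"""Run configuration: one TOML file, every pipeline threshold a key.

Unset keys fall back to the pipeline defaults (the thresholds the
analysis was designed around); unknown keys are rejected so typos never
silently revert a threshold to its default.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

from .cnv import CnvThresholds
from .filtering import FilterCriteria
from .kataegis import KataegisParams
from .landscape import EnrichmentParams

_SECTIONS = {"filter", "cnv", "kataegis", "enrichment", "signatures"}


@dataclass
class SignatureOptions:
    strategy: str = "greedy_forward"
    max_signatures: int = 6


@dataclass
class PipelineConfig:
    filter: FilterCriteria = field(default_factory=FilterCriteria)
    missing_af_is_rare: bool = False
    cnv: CnvThresholds = field(default_factory=CnvThresholds)
    kataegis: KataegisParams = field(default_factory=KataegisParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    signatures: SignatureOptions = field(default_factory=SignatureOptions)


def load_config(path) -> PipelineConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - _SECTIONS - {"missing_af_is_rare"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    cfg = PipelineConfig()
    filt = raw.get("filter", {})
    if filt:
        cfg.filter = FilterCriteria(
            allowed_impacts=frozenset(filt.get("allowed_impacts", ["HIGH", "MODERATE"])),
            min_alt_depth=filt.get("min_alt_depth", 5),
            max_pop_af=filt.get("max_pop_af", 0.0005),
        )
    cfg.missing_af_is_rare = bool(raw.get("missing_af_is_rare", False))
    if "cnv" in raw:
        cfg.cnv = CnvThresholds(**raw["cnv"])
    if "kataegis" in raw:
        cfg.kataegis = KataegisParams(**raw["kataegis"])
    if "enrichment" in raw:
        cfg.enrichment = EnrichmentParams(**raw["enrichment"])
    if "signatures" in raw:
        cfg.signatures = SignatureOptions(**raw["signatures"])
    return cfg
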