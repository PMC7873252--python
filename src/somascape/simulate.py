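"""Seeded generators emulating every input the pipeline consumes.

Each generator returns its ground truth alongside the data so every
pipeline stage has a closed-loop recovery test. A single root seed is
expanded into independent per-generator streams (SeedSequence spawn
keys), so adding a generator never perturbs existing fixtures.

Defaults emulate the study conditions the pipeline was designed around: a
15-sample tumor-only exome cohort at ~117x mean depth with mean variant
allele fraction 0.31, headline per-gene mutation frequencies (TP53 0.73,
ZFHX3 0.40, HMCN1 0.33, ..., NAB2 0.20), an SNV:INDEL ratio of ~10:1, and
exon count matrices at 200x with 20 diploid controls.

The bundled 30-signature reference (:func:`synthetic_signature_matrix`)
is a synthetic stand-in for a COSMIC-style matrix — deterministic, with
the same shape and normalization contract — not the COSMIC signatures
themselves, which users supply as a TSV when available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import CHANNELS_96
from .spectrum import revcomp

_BASES = np.array(list("ACGT"))

# stream indices under the root seed
_STREAM_COHORT = 0
_STREAM_SIGNATURE = 1
_STREAM_CNV = 2
_STREAM_SURVIVAL = 3
_STREAM_SIGMATRIX = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def synthetic_signature_matrix(n_signatures: int = 30, seed: int = 1234,
                               alpha: float = 0.15) -> pd.DataFrame:
    """Deterministic synthetic reference of 96-channel signatures.

    Columns are sparse Dirichlet(alpha) draws — distinct, peaky profiles
    resembling real mutational processes in shape and satisfying the
    column-sums-to-1 contract. This is a synthetic stand-in used for
    testing and simulation; pass a real reference matrix (e.g. COSMIC v2)
    to the fitting functions for production analyses.
    """
    rng = _rng(seed, _STREAM_SIGMATRIX)
    mat = rng.dirichlet([alpha] * 96, size=n_signatures).T
    cols = [f"Signature {i + 1}" for i in range(n_signatures)]
    return pd.DataFrame(mat, index=list(CHANNELS_96), columns=cols)


# ---------------------------------------------------------------------------
# cohort variant tables

#: Headline per-gene mutation frequencies of the emulated 15-sample cohort.
DEFAULT_GENE_FREQS = {
    "TP53": 0.73, "ZFHX3": 0.40, "HMCN1": 0.33,
    "CTNNB1": 0.27, "FAT4": 0.27, "KMT2C": 0.27, "LRP1B": 0.27,
    "PTPRT": 0.27, "RB1": 0.27,
    "ALK": 0.20, "CNTRL": 0.20, "COL1A1": 0.20, "EP300": 0.20,
    "FANCA": 0.20, "FAT1": 0.20, "NAB2": 0.20, "PTPRC": 0.20, "TRIM33": 0.20,
}

DEFAULT_IMPACT_MIX = {"HIGH": 0.20, "MODERATE": 0.55, "LOW": 0.18, "MODIFIER": 0.07}


@dataclass
class CohortSpec:
    n_samples: int = 15
    gene_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GENE_FREQS))
    n_background_genes: int = 200
    background_freq: float = 0.05
    impact_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_IMPACT_MIX))
    mean_depth: float = 117.0
    mean_vaf: float = 0.31
    common_af_fraction: float = 0.15   # rows given pop_af >= 0.0005
    indel_fraction: float = 0.09       # ~10:1 SNV:INDEL
    seed: int = 0


def simulate_cohort_variants(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene Bernoulli mutation tables with filter ground truth.

    Returns (variants, truth); ``truth`` mirrors the variant rows and adds
    ``expected_pass`` — whether the row survives the default filter
    cascade (impact HIGH/MODERATE, alt_depth > 5, pop_af < 0.0005).
    """
    rng = _rng(spec.seed, _STREAM_COHORT)
    freqs = dict(spec.gene_freqs)
    for i in range(spec.n_background_genes):
        freqs[f"BG{i + 1:04d}"] = spec.background_freq
    impacts = list(spec.impact_mix)
    probs = np.array([spec.impact_mix[i] for i in impacts], float)
    probs = probs / probs.sum()
    a = spec.mean_vaf * 10.0   # Beta(10m, 10(1-m)) keeps VAF spread realistic
    b = (1 - spec.mean_vaf) * 10.0

    rows = []
    for s in range(spec.n_samples):
        sample = f"SYN_{s + 1}"
        for gene, freq in freqs.items():
            if rng.random() >= freq:
                continue
            total = int(rng.poisson(spec.mean_depth)) + 1
            alt = int(rng.binomial(total, rng.beta(a, b)))
            impact = impacts[rng.choice(len(impacts), p=probs)]
            if rng.random() < spec.common_af_fraction:
                pop_af = float(rng.uniform(0.0005, 0.05))
            else:
                pop_af = float(rng.uniform(0.0, 0.0004999))
            if rng.random() < spec.indel_fraction:
                ref = str(rng.choice(_BASES))
                ins = rng.random() < 0.5
                other = str(rng.choice(_BASES))
                ref, alt_allele = (ref, ref + other) if ins else (ref + other, ref)
            else:
                ref = str(rng.choice(_BASES))
                alt_allele = str(rng.choice([x for x in "ACGT" if x != ref]))
            rows.append({
                "sample": sample, "gene": gene,
                "chrom": f"chr{int(rng.integers(1, 23))}",
                "pos": int(rng.integers(1, 100_000_000)),
                "ref": ref, "alt": alt_allele, "impact": impact,
                "alt_depth": alt, "total_depth": total, "pop_af": pop_af,
            })
    variants = pd.DataFrame(rows, columns=["sample", "gene", "chrom", "pos", "ref",
                                           "alt", "impact", "alt_depth",
                                           "total_depth", "pop_af"])
    truth = variants.copy()
    truth["expected_pass"] = (
        variants["impact"].isin(["HIGH", "MODERATE"])
        & (variants["alt_depth"] > 5)
        & (variants["pop_af"] < 0.0005)
    )
    return variants, truth


# ---------------------------------------------------------------------------
# signature-driven SNVs with optional kataegis plants

@dataclass
class SignatureSimSpec:
    exposures: dict[str, float] = field(default_factory=dict)  # label -> weight, sums to 1
    n_mutations: int = 2000
    kataegis_plants: list[tuple[str, int, int, int]] = field(default_factory=list)
    # each plant: (chrom, start, count, spacing_bp)
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 100_000_000 for i in range(1, 23)}
    )
    sample_id: str = "SYN_1"
    seed: int = 0


def _channel_to_snv(channel: str, rng: np.random.Generator):
    """ref, alt, context for a channel; half the time on the purine strand."""
    five, ref, alt, three = channel[0], channel[2], channel[4], channel[6]
    ctx = five + ref + three
    if rng.random() < 0.5:  # emit the reverse-complement (purine-reference) strand
        ctx, alt = revcomp(ctx), revcomp(alt)
        ref = ctx[1]
    return ref, alt, ctx


def simulate_signature_snvs(
    spec: SignatureSimSpec, signatures: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """SNVs whose 96-channel distribution follows a signature mixture.

    Background positions are uniform over the chromosome lengths; planted
    kataegis clusters are placed at their exact start/spacing. Contexts
    are emitted on the rows (column mode), so no reference genome is
    needed downstream. Truth carries the exposure vector and plants.
    """
    missing = [s for s in spec.exposures if s not in signatures.columns]
    if missing:
        raise ValueError(f"exposure label(s) not in matrix: {missing}")
    w = np.array(list(spec.exposures.values()), float)
    if len(w) and abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("exposures must sum to 1")
    rng = _rng(spec.seed, _STREAM_SIGNATURE)

    if len(w):
        p = signatures[list(spec.exposures)].to_numpy(float) @ w
        p = p / p.sum()
    else:
        p = np.full(96, 1.0 / 96)

    chroms = list(spec.chrom_lengths)
    rows = []

    def add_snv(chrom, pos):
        ch = int(rng.choice(96, p=p))
        ref, alt, ctx = _channel_to_snv(CHANNELS_96[ch], rng)
        rows.append({
            "sample": spec.sample_id, "gene": ".", "chrom": chrom, "pos": int(pos),
            "ref": ref, "alt": alt, "impact": "MODERATE",
            "alt_depth": 30, "total_depth": 100, "pop_af": 0.0,
            "context3": ctx,
        })

    for _ in range(spec.n_mutations):
        ci = int(rng.integers(len(chroms)))
        chrom = chroms[ci]
        add_snv(chrom, rng.integers(1, spec.chrom_lengths[chrom]))
    for chrom, start, count, spacing in spec.kataegis_plants:
        for i in range(count):
            add_snv(chrom, start + i * spacing)

    variants = pd.DataFrame(rows)
    truth = {"exposures": dict(spec.exposures), "plants": list(spec.kataegis_plants)}
    return variants, truth


# ---------------------------------------------------------------------------
# exon count matrices with planted CNV events

@dataclass
class CnvSimSpec:
    n_genes: int = 50
    exons_per_gene: int = 5
    mean_depth: float = 200.0
    dispersion: float = 0.01    # NB: var = m + dispersion * m^2
    n_controls: int = 20
    n_tumors: int = 1
    events: list[tuple[str, int]] = field(default_factory=list)  # (gene, integer CN), all tumors
    seed: int = 0


def _nb_draw(rng, mean, dispersion, size):
    if dispersion <= 1e-12:
        return rng.poisson(mean, size=size)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion, size=size)
    return rng.poisson(lam)


def simulate_exon_counts(spec: CnvSimSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial exon counts for controls and tumors.

    Per-exon capture weights are lognormal; tumor means are scaled by
    CN/2 on planted genes. Returns (counts, exon_model, truth) where
    truth lists every planted (sample, gene, cn).
    """
    for gene, cn in spec.events:
        if cn < 0 or int(cn) != cn:
            raise ValueError(f"planted CN must be a non-negative integer, got {cn}")
    rng = _rng(spec.seed, _STREAM_CNV)
    genes = [f"GENE{i + 1}" for i in range(spec.n_genes)]
    exon_rows = []
    pos = 0
    for g in genes:
        for e in range(spec.exons_per_gene):
            exon_rows.append({"exon_id": f"{g}_e{e + 1}", "gene": g, "chrom": "chr1",
                              "start": pos, "end": pos + 150})
            pos += 5000
    exon_model = pd.DataFrame(exon_rows)
    n_exons = len(exon_model)
    weights = rng.lognormal(mean=0.0, sigma=0.25, size=n_exons)
    base_mean = spec.mean_depth * weights

    counts = {}
    for c in range(spec.n_controls):
        counts[f"control_{c + 1}"] = _nb_draw(rng, base_mean, spec.dispersion, n_exons)
    cn_of = {gene: cn for gene, cn in spec.events}
    scale = np.array([cn_of.get(g, 2) / 2.0 for g in exon_model["gene"]])
    truth_rows = []
    for t in range(spec.n_tumors):
        name = f"tumor_{t + 1}"
        counts[name] = _nb_draw(rng, base_mean * scale, spec.dispersion, n_exons)
        truth_rows.extend({"sample": name, "gene": g, "cn": cn} for g, cn in spec.events)
    counts_df = pd.DataFrame(counts, index=exon_model["exon_id"].to_numpy())
    counts_df.index.name = "exon_id"
    truth = pd.DataFrame(truth_rows, columns=["sample", "gene", "cn"])
    return counts_df, exon_model, truth


# ---------------------------------------------------------------------------
# right-censored survival

def _uniform_censor_bound(rate: float, target: float) -> float:
    """Upper bound u of U(0,u) censoring giving P(C < T) = target for Exp(rate)."""
    # P(censored) = (1 - exp(-rate*u)) / (rate*u), decreasing from 1 to 0
    f = lambda x: (1.0 - np.exp(-x)) / x - target
    x = brentq(f, 1e-9, 1e6)
    return x / rate


def simulate_survival(
    n_per_group: int = 200,
    hazard_ratio: float = 1.0,
    censoring_fraction: float = 0.2,
    seed: int = 0,
    median_control: float = 12.0,
) -> pd.DataFrame:
    """Exponential survival with a group hazard ratio and uniform censoring.

    Group "wt" has median ``median_control`` months; group "mut" hazard is
    scaled by ``hazard_ratio``. Censoring times are uniform with the bound
    calibrated per group to the target censoring fraction.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not (0 <= censoring_fraction < 1):
        raise ValueError("censoring_fraction must be in [0,1)")
    rng = _rng(seed, _STREAM_SURVIVAL)
    lam0 = np.log(2.0) / median_control
    rows = []
    for group, lam in (("wt", lam0), ("mut", lam0 * hazard_ratio)):
        t = rng.exponential(1.0 / lam, size=n_per_group)
        if censoring_fraction > 0:
            u = _uniform_censor_bound(lam, censoring_fraction)
            c = rng.uniform(0.0, u, size=n_per_group)
        else:
            c = np.full(n_per_group, np.inf)
        time = np.minimum(t, c)
        event = t <= c
        for i in range(n_per_group):
            rows.append({"sample_id": f"{group}_{i + 1}", "group": group,
                         "time": float(time[i]), "event": bool(event[i])})
    return pd.DataFrame(rows)
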