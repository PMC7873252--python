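"""Refitting 96-channel catalogs against a reference signature matrix.

A catalog of n somatic SNVs is modeled as n draws from a convex mixture of
reference signature columns. Exposures for a candidate signature subset are
obtained by non-negative least squares on the probability-normalized
catalog; the subset itself is chosen by the Bayesian information criterion

    BIC = k ln(n) - 2 lnL,

with k the number of signatures in the subset and lnL the multinomial
log-likelihood of the catalog under the renormalized reconstruction (the
constant multinomial coefficient is dropped — it cancels between models).
Subset search is greedy-forward by default; exhaustive search over small
pools is available and serves as the oracle in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import CHANNELS_96
from .spectrum import Catalog96, build_catalog96

_PROB_FLOOR = 1e-12


@dataclass
class SignatureFit:
    """A fitted decomposition: subset, exposures, BIC, cosine, reconstruction."""

    labels: tuple[str, ...]
    exposures: pd.Series            # fractional weights over `labels`, sum 1
    loglik: float
    bic: float
    cosine: float
    reconstruction: pd.Series       # 96-vector scaled to the catalog total
    n_mutations: int
    low_n: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def exposure_counts(self) -> pd.Series:
        return self.exposures * self.n_mutations


def _as_counts(catalog) -> pd.Series:
    if isinstance(catalog, Catalog96):
        return catalog.counts
    counts = pd.Series(catalog)
    if list(counts.index) != list(CHANNELS_96):
        counts = counts.reindex(list(CHANNELS_96), fill_value=0)
    return counts


def fit_exposures(catalog, signatures: pd.DataFrame, subset) -> SignatureFit:
    """NNLS exposures of ``subset`` signatures for one catalog.

    The cosine similarity is computed between the raw count vector and the
    reconstruction scaled to the catalog total (scale-invariant either way).
    """
    counts = _as_counts(catalog).astype(float)
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    unknown = [s for s in subset if s not in signatures.columns]
    if unknown:
        raise ValueError(f"unknown signature label(s) {unknown}")
    n = counts.sum()
    if n <= 0:
        raise ValueError("catalog has no mutations")

    A = signatures[list(subset)].to_numpy(float)
    p = (counts / n).to_numpy()
    w, _ = nnls(A, p)

    recon_p = A @ w
    total_w = recon_p.sum()
    if total_w <= 0:
        recon_p = np.full(96, 1.0 / 96)
    else:
        recon_p = recon_p / total_w
    floored = np.maximum(recon_p, _PROB_FLOOR)
    loglik = float(counts.to_numpy() @ np.log(floored))
    k = len(subset)
    bic = k * np.log(n) - 2.0 * loglik

    recon_counts = pd.Series(recon_p * n, index=list(CHANNELS_96))
    c = counts.to_numpy()
    r = recon_counts.to_numpy()
    cosine = float(c @ r / (np.linalg.norm(c) * np.linalg.norm(r)))

    frac = w / w.sum() if w.sum() > 0 else np.full(k, 1.0 / k)
    return SignatureFit(
        labels=subset,
        exposures=pd.Series(frac, index=list(subset)),
        loglik=loglik,
        bic=float(bic),
        cosine=min(max(cosine, 0.0), 1.0),
        reconstruction=recon_counts,
        n_mutations=int(round(n)),
    )


def _tie_key(fit: SignatureFit):
    # rank by BIC, then prefer smaller subsets, then lexicographic labels
    return (round(fit.bic, 9), len(fit.labels), tuple(sorted(fit.labels)))


def select_model(
    catalog,
    signatures: pd.DataFrame,
    strategy: str = "greedy_forward",
    max_signatures: int = 6,
) -> SignatureFit:
    """Choose the signature subset minimizing BIC.

    greedy_forward: start from the best single signature, repeatedly add
    the signature whose inclusion most decreases BIC, stop when no addition
    decreases BIC or ``max_signatures`` is reached. exhaustive: evaluate
    every subset of size <= ``max_signatures`` (pool must be <= 12).
    """
    pool = list(signatures.columns)
    if not pool:
        raise ValueError("empty signature pool")
    if max_signatures < 1:
        raise ValueError("max_signatures must be >= 1")

    if strategy == "exhaustive":
        if len(pool) > 12:
            raise ValueError("exhaustive search limited to pools of <= 12 signatures")
        best = None
        for k in range(1, min(max_signatures, len(pool)) + 1):
            for subset in itertools.combinations(pool, k):
                fit = fit_exposures(catalog, signatures, subset)
                if best is None or _tie_key(fit) < _tie_key(best):
                    best = fit
        return best

    if strategy != "greedy_forward":
        raise ValueError(f"unknown strategy {strategy!r}")

    singles = [fit_exposures(catalog, signatures, (s,)) for s in pool]
    current = min(singles, key=_tie_key)
    while len(current.labels) < max_signatures:
        remaining = [s for s in pool if s not in current.labels]
        if not remaining:
            break
        candidates = [
            fit_exposures(catalog, signatures, current.labels + (s,))
            for s in remaining
        ]
        best_add = min(candidates, key=_tie_key)
        if best_add.bic < current.bic:
            current = best_add
        else:
            break
    return current


def per_sample_decomposition(
    variants: pd.DataFrame,
    signatures: pd.DataFrame,
    strategy: str = "greedy_forward",
    max_signatures: int = 6,
    min_snvs_warn: int = 50,
) -> dict[str, SignatureFit | None]:
    """Fit each sample's catalog plus a pooled fit over all samples.

    Samples with zero context-resolvable SNVs map to ``None`` (unfit, not
    an error); fits on fewer than ``min_snvs_warn`` SNVs carry ``low_n``.
    The pooled fit is stored under the key ``"pooled"``.
    """
    fits: dict[str, SignatureFit | None] = {}
    for sample, group in variants.groupby("sample"):
        cat = build_catalog96(group)
        if cat.total == 0:
            fits[str(sample)] = None
            continue
        fit = select_model(cat, signatures, strategy, max_signatures)
        fit.low_n = cat.total < min_snvs_warn
        fits[str(sample)] = fit
    pooled_cat = build_catalog96(variants)
    if pooled_cat.total > 0:
        pooled = select_model(pooled_cat, signatures, strategy, max_signatures)
        pooled.low_n = pooled_cat.total < min_snvs_warn
        fits["pooled"] = pooled
    else:
        fits["pooled"] = None
    return fits


def fits_to_frame(fits: dict[str, SignatureFit | None]) -> pd.DataFrame:
    """Tabulate a per-sample decomposition for TSV output."""
    rows = []
    for sample, fit in fits.items():
        if fit is None:
            rows.append({"sample": sample, "n_snvs": 0, "signatures": "",
                         "exposures": "", "bic": np.nan, "cosine": np.nan,
                         "low_n": True})
            continue
        rows.append({
            "sample": sample,
            "n_snvs": fit.n_mutations,
            "signatures": ",".join(fit.labels),
            "exposures": ",".join(f"{x:.4f}" for x in fit.exposures),
            "bic": fit.bic,
            "cosine": fit.cosine,
            "low_n": fit.low_n,
        })
    return pd.DataFrame(rows)
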