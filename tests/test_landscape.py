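import math

import numpy as np
import pandas as pd
import pytest

from somascape.landscape import (EnrichmentParams, cohort_exclusive_genes,
                                 gene_sample_matrix, ora_enrichment,
                                 recurrent_genes, stratified_gene_comparison,
                                 subset_by_catalog)


def _variants(pairs):
    return pd.DataFrame([{"sample": s, "gene": g} for s, g in pairs])


COHORT15 = [f"P{i}" for i in range(1, 16)]


def test_frequency_counts_samples_not_records():
    pairs = [(f"P{i}", "TP53") for i in range(1, 12)] + [("P1", "TP53")]  # duplicate
    gsm = gene_sample_matrix(_variants(pairs), COHORT15)
    assert gsm.matrix.loc["TP53"].sum() == 11
    assert gsm.frequencies["TP53"] == pytest.approx(11 / 15)
    assert round(100 * gsm.frequencies["TP53"]) == 73


def test_empty_table_and_unknown_sample():
    gsm = gene_sample_matrix(_variants([]).reindex(columns=["sample", "gene"]), COHORT15)
    assert gsm.matrix.shape == (0, 15)
    with pytest.raises(ValueError, match="not in cohort"):
        gene_sample_matrix(_variants([("X99", "TP53")]), COHORT15)


def test_cohort_exclusivity_rule_and_disjointness():
    a = gene_sample_matrix(_variants(
        [(f"P{i}", "RB1") for i in (1, 2, 3, 4)] + [("P5", "SHARED")]), COHORT15)
    b_samples = [f"G{i}" for i in range(1, 23)]
    b = gene_sample_matrix(_variants([("G1", "SHARED"), ("G2", "NCOR2")]), b_samples)
    excl_a = cohort_exclusive_genes(a, b, min_freq_a=0.2, max_count_b=0)
    assert list(excl_a.index) == ["RB1"]
    assert excl_a.loc["RB1", "freq_a"] == pytest.approx(4 / 15)
    # one carrier in B is enough to disqualify at max_count_b=0
    b2 = gene_sample_matrix(_variants([("G1", "RB1")]), b_samples)
    assert len(cohort_exclusive_genes(a, b2, 0.2, 0)) == 0
    # swapped comparison finds B-exclusive genes, disjoint from the A list
    excl_b = cohort_exclusive_genes(b, a, min_freq_a=1 / 22, max_count_b=0)
    assert set(excl_a.index).isdisjoint(excl_b.index)
    assert "NCOR2" in excl_b.index


def test_catalog_subsetting_and_recurrence_counting():
    v = _variants([("P1", "TP53"), ("P1", "TP53"), ("P2", "ALK"), ("P3", "BG1")])
    sub = subset_by_catalog(v, {"TP53", "ALK"})
    assert set(sub["gene"]) == {"TP53", "ALK"}
    assert len(subset_by_catalog(v, {"NOPE"})) == 0
    with pytest.raises(ValueError):
        subset_by_catalog(v, set())
    # "mutated more than once": records vs samples
    by_records = recurrent_genes(v, min_count=2, unit="records")
    assert list(by_records.index) == ["TP53"]
    by_samples = recurrent_genes(v, min_count=2, unit="samples")
    assert len(by_samples) == 0


def _exact_tail(N, K, n, k):
    denom = math.comb(N, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i)
               for i in range(k, min(K, n) + 1)) / denom


def test_ora_matches_exact_tail_sum_oracle():
    universe = [f"g{i}" for i in range(20)]
    gene_list = universe[:5]
    gene_sets = {"SetA": set(universe[3:8])}  # K=5, overlap k=3 with first 5? g3,g4 -> k=2
    gene_sets["SetA"] = {"g0", "g1", "g2", "g10", "g11"}  # K=5, k=3
    res = ora_enrichment(gene_list, gene_sets, universe, EnrichmentParams(min_overlap=2, p_cutoff=0.05))
    assert res.loc[0, "p"] == pytest.approx(_exact_tail(20, 5, 5, 3), rel=1e-12)
    assert res.loc[0, "p"] == pytest.approx(0.0726, abs=5e-4)


def test_ora_min_overlap_and_degenerate_case():
    universe = [f"g{i}" for i in range(10)]
    sets = {"Zero": {"x1", "x2"}, "All": set(universe)}
    res = ora_enrichment(universe, sets, universe)
    assert "Zero" not in set(res["set"])  # k=0 excluded by min_overlap
    assert res.set_index("set").loc["All", "p"] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="universe"):
        ora_enrichment(["g1"], sets, [])
    with pytest.raises(ValueError, match="contained"):
        ora_enrichment(["nope"], sets, universe)


def test_ora_reports_bh_q_alongside_raw_p():
    rng = np.random.default_rng(0)
    universe = [f"g{i}" for i in range(30)]
    sets = {f"S{j}": set(rng.choice(universe, size=8, replace=False)) for j in range(6)}
    res = ora_enrichment(universe[:10], sets, universe, EnrichmentParams(min_overlap=1))
    assert (res["q"] >= res["p"] - 1e-15).all()


def test_stratum_exclusive_genes():
    clin = pd.DataFrame({
        "sample_id": COHORT15,
        "n_stage": ["0"] * 6 + ["1"] * 5 + ["2"] * 4,
        "status": "Dead", "months": 1.0,
    })
    v = _variants([("P1", "TGFB3"), ("P2", "TGFB3"),          # N0 only
                   ("P7", "FAT4"), ("P8", "FAT4"),            # N1/N2 only
                   ("P1", "TP53"), ("P7", "TP53")])           # both strata
    gsm = gene_sample_matrix(v, COHORT15)
    groups = {"N0": {"0"}, "N1/N2": {"1", "2"}}
    res = stratified_gene_comparison(gsm, clin, "n_stage", groups, min_count=1)
    assert list(res["N0"].index) == ["TGFB3"]
    assert list(res["N1/N2"].index) == ["FAT4"]
    union = set(res["N0"].index) | set(res["N1/N2"].index)
    assert union <= set(gsm.matrix.index)
    with pytest.raises(ValueError, match="matches 0 groups|missing"):
        stratified_gene_comparison(gsm, clin, "n_stage", {"N0": {"0"}})
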