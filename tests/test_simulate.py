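import numpy as np
import pandas as pd
import pytest

from somascape.cnv import build_control_panel, call_gene_cnv, exon_copy_numbers, normalize_by_depth
from somascape.kataegis import detect_kataegis, intermutation_distances
from somascape.spectrum import build_catalog96
from somascape.simulate import (CnvSimSpec, CohortSpec, SignatureSimSpec,
                                simulate_cohort_variants, simulate_exon_counts,
                                simulate_signature_snvs, simulate_survival,
                                synthetic_signature_matrix)


def test_generators_are_seed_deterministic(sigs):
    for maker in [
        lambda s: simulate_cohort_variants(CohortSpec(seed=s))[0],
        lambda s: simulate_signature_snvs(
            SignatureSimSpec(exposures={"Signature 1": 1.0}, n_mutations=100, seed=s), sigs)[0],
        lambda s: simulate_exon_counts(CnvSimSpec(seed=s))[0],
        lambda s: simulate_survival(seed=s),
    ]:
        pd.testing.assert_frame_equal(maker(7), maker(7))
        assert not maker(7).equals(maker(8))


def test_streams_are_independent_of_each_other():
    # the cohort stream is unaffected by whether other generators ran
    a, _ = simulate_cohort_variants(CohortSpec(seed=3))
    simulate_survival(seed=3)
    b, _ = simulate_cohort_variants(CohortSpec(seed=3))
    pd.testing.assert_frame_equal(a, b)


def test_cohort_gene_frequency_calibration():
    hits = []
    for seed in range(200):
        spec = CohortSpec(seed=seed, n_background_genes=0,
                          gene_freqs={"TP53": 0.73})
        variants, _ = simulate_cohort_variants(spec)
        hits.append(variants["sample"].nunique() / spec.n_samples)
    assert np.mean(hits) == pytest.approx(0.73, abs=0.05)


def test_cohort_zero_frequency_and_truth_consistency():
    spec = CohortSpec(seed=1, gene_freqs={}, n_background_genes=0)
    variants, truth = simulate_cohort_variants(spec)
    assert variants.empty
    variants, truth = simulate_cohort_variants(CohortSpec(seed=2))
    recomputed = (truth["impact"].isin(["HIGH", "MODERATE"])
                  & (truth["alt_depth"] > 5) & (truth["pop_af"] < 0.0005))
    assert (truth["expected_pass"] == recomputed).all()
    # both filter-exercising contaminants are present
    assert (variants["pop_af"] >= 0.0005).any()
    assert variants["impact"].isin(["LOW", "MODIFIER"]).any()


def test_pure_signature_sampling_matches_its_column(sigs):
    spec = SignatureSimSpec(exposures={"Signature 1": 1.0}, n_mutations=5000, seed=6)
    variants, truth = simulate_signature_snvs(spec, sigs)
    cat = build_catalog96(variants)
    a = cat.counts.to_numpy(float)
    b = sigs["Signature 1"].to_numpy()
    cosine = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
    assert cosine >= 0.99
    assert truth["exposures"] == {"Signature 1": 1.0}


def test_zero_mutations_gives_empty_table(sigs):
    spec = SignatureSimSpec(exposures={"Signature 1": 1.0}, n_mutations=0, seed=0)
    variants, _ = simulate_signature_snvs(spec, sigs)
    assert len(variants) == 0


def test_planted_kataegis_detected_end_to_end(sigs):
    spec = SignatureSimSpec(exposures={"Signature 1": 1.0}, n_mutations=500,
                            kataegis_plants=[("chr19", 10**6, 8, 200)], seed=9)
    variants, _ = simulate_signature_snvs(spec, sigs)
    regions = detect_kataegis(intermutation_distances(variants))
    chr19 = regions[regions["chrom"] == "chr19"]
    assert (chr19["n_mutations"] >= 8).any()


def test_exposure_validation(sigs):
    with pytest.raises(ValueError, match="sum to 1"):
        simulate_signature_snvs(SignatureSimSpec(exposures={"Signature 1": 0.5}), sigs)
    with pytest.raises(ValueError, match="not in matrix"):
        simulate_signature_snvs(
            SignatureSimSpec(exposures={"Nope": 1.0}), sigs)


def test_planted_cnv_recovered_through_the_caller():
    spec = CnvSimSpec(events=[("GENE7", 4)], mean_depth=200, dispersion=0.01, seed=14)
    counts, model, truth = simulate_exon_counts(spec)
    norm = normalize_by_depth(counts)
    ctrl = [c for c in counts.columns if c.startswith("control")]
    panel = build_control_panel(norm[ctrl])
    calls = call_gene_cnv(exon_copy_numbers(norm["tumor_1"], panel), model)
    assert calls.loc["GENE7", "call"] == "gain"
    assert truth.iloc[0].tolist() == ["tumor_1", "GENE7", 4]


def test_cnv_spec_rejects_fractional_cn():
    with pytest.raises(ValueError, match="integer"):
        simulate_exon_counts(CnvSimSpec(events=[("GENE1", 2.5)]))


def test_survival_censoring_calibration():
    df = simulate_survival(400, 1.0, 0.0, seed=2)
    assert df["event"].all()
    fracs = [1 - simulate_survival(400, 1.0, 0.3, seed=s)["event"].mean()
             for s in range(20)]
    assert np.mean(fracs) == pytest.approx(0.3, abs=0.03)


def test_survival_median_ratio_tracks_hazard_ratio():
    ratios = []
    for seed in range(100):
        df = simulate_survival(200, 4.0, 0.0, seed=seed)
        med = df.groupby("group")["time"].median()
        ratios.append(med["wt"] / med["mut"])
    assert np.mean(ratios) == pytest.approx(4.0, rel=0.2)


def test_signature_matrix_stand_in_contract():
    m = synthetic_signature_matrix()
    assert m.shape == (96, 30)
    np.testing.assert_allclose(m.sum(axis=0), 1.0, atol=1e-12)
    assert (m.to_numpy() >= 0).all()
    pd.testing.assert_frame_equal(m, synthetic_signature_matrix())
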