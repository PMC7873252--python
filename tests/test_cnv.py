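import numpy as np
import pandas as pd
import pytest

from somascape.cnv import (CnvThresholds, build_control_panel, call_gene_cnv,
                           cohort_cnv_summary, cohort_overlap,
                           exon_copy_numbers, normalize_by_depth)
from somascape.simulate import CnvSimSpec, simulate_exon_counts


def test_normalization_removes_depth_scale():
    rng = np.random.default_rng(0)
    a = rng.integers(50, 400, size=20).astype(float)
    counts = pd.DataFrame({"A": a, "B": 2 * a})
    norm = normalize_by_depth(counts)
    np.testing.assert_allclose(norm["A"], norm["B"])
    means = norm.mean(axis=0)
    np.testing.assert_allclose(means, means.iloc[0], rtol=1e-9)


def test_normalization_single_sample_and_zero_sample():
    counts = pd.DataFrame({"A": [10.0, 20.0, 30.0]})
    norm = normalize_by_depth(counts)
    np.testing.assert_allclose(norm["A"] / counts["A"], 1.0)
    with pytest.raises(ValueError, match="no reads"):
        normalize_by_depth(pd.DataFrame({"A": [1.0], "B": [0.0]}))


def test_control_panel_reference_and_usability():
    ident = pd.DataFrame({"c1": [100.0, 0.0, 50.0], "c2": [100.0, 0.0, 50.0]})
    panel = build_control_panel(ident)
    np.testing.assert_allclose(panel["reference"], ident["c1"])
    assert not panel.loc[1, "usable"]  # zero in all controls
    assert panel.loc[0, "usable"]
    with pytest.raises(ValueError, match="2 control"):
        build_control_panel(ident[["c1"]])


def test_control_panel_close_to_generative_mean():
    spec = CnvSimSpec(n_controls=20, n_tumors=0, mean_depth=200, dispersion=0.01, seed=9)
    counts, model, _ = simulate_exon_counts(spec)
    norm = normalize_by_depth(counts)
    panel = build_control_panel(norm)
    # panel of 20 controls at 200x: reference within 5% of the panel-wide
    # per-exon mean structure for >= 95% of exons
    tolerant = (np.abs(panel["reference"] - norm.mean(axis=1)) / norm.mean(axis=1) < 0.05)
    assert tolerant.mean() >= 0.95


def test_copy_number_identity_and_doubling():
    panel = pd.DataFrame({"reference": [100.0, 100.0], "usable": [True, False]})
    cn = exon_copy_numbers(pd.Series([100.0, 100.0]), panel)
    assert cn.iloc[0] == pytest.approx(2.0)
    assert np.isnan(cn.iloc[1])  # unusable exon excluded
    cn2 = exon_copy_numbers(pd.Series([200.0, 0.0]), panel)
    assert cn2.iloc[0] == pytest.approx(4.0)


@pytest.mark.parametrize(
    "cns,expected",
    [
        ([3.0, 2.9, 3.1], "gain"),       # all exons above the gain cut
        ([3.0, 2.7, 3.1], "neutral"),    # one exon <= 2.8 blocks the gain
        ([1.0, 1.1, 0.9], "loss"),
        ([5.0, 5.0], "no_call"),         # fewer than three evaluable exons
        ([2.0, 2.1, 1.9], "neutral"),
    ],
)
def test_gene_call_rules(cns, expected):
    model = pd.DataFrame({"exon_id": [f"G_e{i}" for i in range(len(cns))],
                          "gene": "G", "chrom": "chr1",
                          "start": range(len(cns)), "end": range(1, len(cns) + 1)})
    cn = pd.Series(cns, index=model["exon_id"].to_numpy())
    calls = call_gene_cnv(cn, model)
    assert calls.loc["G", "call"] == expected


def test_unusable_exons_do_not_convert_no_call():
    model = pd.DataFrame({"exon_id": ["G_e1", "G_e2", "G_e3"], "gene": "G",
                          "chrom": "chr1", "start": [0, 1, 2], "end": [1, 2, 3]})
    cn = pd.Series([5.0, 5.0, np.nan], index=model["exon_id"].to_numpy())
    assert call_gene_cnv(cn, model).loc["G", "call"] == "no_call"


def test_scale_invariance_of_calls():
    spec = CnvSimSpec(events=[("GENE3", 4), ("GENE9", 1)], seed=21)
    counts, model, _ = simulate_exon_counts(spec)
    def pipeline(c):
        norm = normalize_by_depth(c)
        ctrl = [s for s in c.columns if s.startswith("control")]
        panel = build_control_panel(norm[ctrl])
        return call_gene_cnv(exon_copy_numbers(norm["tumor_1"], panel), model)
    base = pipeline(counts)
    scaled = counts.copy()
    scaled["tumor_1"] = scaled["tumor_1"] * 7  # a constant depth factor
    pd.testing.assert_series_equal(pipeline(scaled)["call"], base["call"])


def test_perfect_recovery_at_zero_dispersion():
    events = [("GENE2", 0), ("GENE5", 1), ("GENE8", 4), ("GENE11", 6)]
    spec = CnvSimSpec(events=events, dispersion=0.0, mean_depth=500, seed=2)
    counts, model, truth = simulate_exon_counts(spec)
    norm = normalize_by_depth(counts)
    ctrl = [s for s in counts.columns if s.startswith("control")]
    panel = build_control_panel(norm[ctrl])
    calls = call_gene_cnv(exon_copy_numbers(norm["tumor_1"], panel), model)
    want = {"GENE2": "loss", "GENE5": "loss", "GENE8": "gain", "GENE11": "gain"}
    for gene, expected in want.items():
        assert calls.loc[gene, "call"] == expected
    others = calls.drop(index=list(want))
    assert (others["call"] == "neutral").all()


def test_cohort_summary_frequencies_and_overlap():
    model = pd.DataFrame({"exon_id": ["G_e1"], "gene": "G", "chrom": "chr1",
                          "start": [0], "end": [1]})
    gain = pd.DataFrame({"call": ["gain"], "n_evaluable_exons": 3}, index=["G"])
    neutral = pd.DataFrame({"call": ["neutral"], "n_evaluable_exons": 3}, index=["G"])
    calls = {f"s{i}": (gain if i < 3 else neutral) for i in range(15)}
    summary = cohort_cnv_summary(calls)
    assert summary["frequencies"].loc["G", "gain_freq"] == pytest.approx(3 / 15)
    assert summary["gained_genes"] == ["G"]
    ov = cohort_overlap(["A", "B"], ["B", "C"])
    assert ov == {"shared": ["B"], "only_a": ["A"], "only_b": ["C"]}
    assert cohort_overlap(["A"], ["B"])["shared"] == []
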