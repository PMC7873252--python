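import pandas as pd
import pytest

from somascape import load_example_clinical
from somascape.simulate import synthetic_signature_matrix


@pytest.fixture(scope="session")
def sigs():
    """Deterministic synthetic 30-signature x 96-channel reference."""
    return synthetic_signature_matrix()


@pytest.fixture(scope="session")
def clinical():
    return load_example_clinical()


@pytest.fixture()
def tiny_variants():
    """Four hand-written variant rows covering SNV/INS and both impacts."""
    return pd.DataFrame({
        "sample": ["S1", "S1", "S2", "S2"],
        "gene": ["TP53", "RB1", "TP53", "NAB2"],
        "chrom": ["chr17", "chr13", "chr17", "chr12"],
        "pos": [7578406, 48941648, 7577121, 57486250],
        "ref": ["C", "C", "G", "A"],
        "alt": ["T", "T", "A", "AT"],
        "impact": ["MODERATE", "HIGH", "MODERATE", "MODERATE"],
        "alt_depth": [30, 12, 25, 9],
        "total_depth": [90, 60, 80, 40],
        "pop_af": [0.0, 0.0001, 0.0, 0.0002],
        "variant_class": ["SNV", "SNV", "SNV", "INS"],
        "context3": ["ACG", "TCA", "TGT", None],
        "protein_change": ["p.Arg248Trp", "p.Gln689*", None, "p.Leu466Phe"],
    })
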