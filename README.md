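# somascape

Tumor-only whole-exome mutational-landscape analysis for small cancer
cohorts, built for studies — such as gallbladder neuroendocrine carcinoma
(GB-NEC) cohorts — where no matched normal tissue is available and somatic
analysis must run on annotated tumor-only calls.

Given annotated per-variant tables (MAF-like TSV or minimal VCF), per-exon
read-count matrices, a clinical table, and reference resources (a 96-channel
signature matrix, gene sets in GMT, gene/variant catalogs), the package
provides:

- **Variant filter cascade** — retain mutations that are nonsilent
  (annotation impact HIGH or MODERATE), well supported (alternative-allele
  depth > 5), and rare in the general population (max population allele
  frequency < 0.0005), with per-stage reporting, an optional false-positive
  blacklist, and an intersection rule for dual tumor-only somatic
  classifiers (keep calls flagged by both).
- **Mutation spectra** — six-class substitution spectra (pyrimidine
  reference), Ti/Tv summaries, and 96-channel trinucleotide catalogs in
  COSMIC channel order, with contexts from a column or a FASTA.
- **Signature refitting** — exposures of a catalog over a reference
  signature matrix by non-negative least squares, with the signature subset
  chosen by BIC = k·ln(n) − 2·lnL (multinomial log-likelihood), greedy
  forward search by default and exhaustive search on small pools; reports
  exposures, BIC and observed-vs-reconstructed cosine similarity.
- **Exon read-depth CNV calling** — depth balancing, a control panel
  (panel of normals) from ≥ 2 non-tumor samples, per-exon copy number
  CN = 2 · tumor/reference, and gene-level calls: gain iff **all** exons
  have CN > 2.8, loss iff all have CN < 1.2, on genes with ≥ 3 evaluable
  exons.
- **Kataegis detection** — intermutation distances (rainfall) and
  hypermutation regions (≥ 6 consecutive SNVs with mean IMD ≤ 1 kb),
  annotated with overlapping genes.
- **Cohort landscape** — gene × sample matrices, mutation frequencies,
  cross-cohort exclusive genes, catalog joins, recurrence counting, and
  hypergeometric over-representation analysis (raw p plus BH q).
- **Survival stratification** — Kaplan–Meier curves and medians
  (lifelines), log-rank tests with the O/E-ratio hazard ratio
  HR = (O_A/E_A)/(O_B/E_B), grouped by mutation or CNV status.
- **Synthetic data** — seeded generators for every input (cohort variant
  tables, signature-mixture SNVs with planted kataegis clusters,
  negative-binomial exon counts with planted copy-number events,
  right-censored survival), each emitting machine-readable ground truth.

## Worked example

Fit a synthetic 2,000-SNV catalog drawn from a known three-signature
mixture, detect a planted kataegis cluster, and stratify the bundled
15-patient GB-NEC clinical table by a two-carrier CNV group:

```python
import pandas as pd
import somascape as sc
from somascape import simulate as sim

sigs = sim.synthetic_signature_matrix()          # synthetic 30 x 96 reference
spec = sim.SignatureSimSpec(
    exposures={"Signature 1": 0.5, "Signature 3": 0.3, "Signature 6": 0.2},
    n_mutations=2000, kataegis_plants=[("chr19", 1_000_000, 8, 200)], seed=7)
snvs, truth = sim.simulate_signature_snvs(spec, sigs)

fit = sc.select_model(sc.build_catalog96(snvs), sigs, "greedy_forward", 6)
regions = sc.detect_kataegis(sc.intermutation_distances(snvs))

clin = sc.load_example_clinical()
mat = pd.DataFrame(0, index=["AAMDC_CNV"], columns=clin["sample_id"])
mat.loc["AAMDC_CNV", ["GBNEC_2", "GBNEC_7"]] = 1
cmp = sc.compare_by_feature(clin, mat, "AAMDC_CNV")
```

Output:

```
selected : Signature 1, Signature 3, Signature 6
exposures: Signature 1=0.494, Signature 3=0.322, Signature 6=0.184
BIC      : 15391.416   cosine: 0.992
chrom   start     end  n_mutations  mean_imd
chr19 1000000 1001400            8     200.0
carriers n=2  wild-type n=13
plain median OS (carriers): 3.48 months
KM median OS (wild-type) : 20.07 months
log-rank chi2=4.971  p=0.0258  HR=4.62
```

The BIC search recovers exactly the three generating signatures with
exposures close to the simulated 0.5/0.3/0.2 mixture (cosine 0.992 between
the observed and reconstructed catalogs), the planted 8-SNV cluster at
200 bp spacing is returned as a single chr19 region, and the survival
comparison reports both median conventions (plain median of the two
carriers' follow-up, KM median of the 13 wild-type patients) with the
log-rank p value and hazard ratio.

A `somascape` command-line tool mirrors the library
(`filter`, `spectrum`, `signatures`, `cnv-call`, `kataegis`, `summarize`,
`enrich`, `survival`, `simulate`); see `somascape --help`.

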