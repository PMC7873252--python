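# Methods

This note documents the models and procedures implemented in somascape,
the defaults they ship with, and what the synthetic-data tests do and do
not demonstrate about real data.

## Variant filter cascade

Tumor-only exome call sets mix somatic mutations with germline
polymorphisms, silent changes and FFPE artifacts. The cascade retains a
row iff all three predicates hold: annotation impact ∈ {HIGH, MODERATE};
alternative-allele depth > 5 (strict); maximum population allele frequency
< 0.0005 (strict). The retained set is a conjunction and therefore
independent of stage order; the per-stage report fixes the order
impact → depth → AF for reproducibility. INDELs pass through the same
cascade as SNVs. A missing population AF is an error by default
(`missing_af_is_rare` opts into treating it as 0), because the rarity
filter is the cascade's strongest discriminator and a silent default
would be invisible data loss. An optional blacklist of known
false-positive sites (chrom, pos, ref, alt) is applied last and is empty
by default. Somatic status from two tumor-only classifiers is honored as
an intersection rule: only calls flagged by both survive
`intersect_somatic_flags`.

## Spectra and catalogs

Both the six-class spectrum and the 96-channel catalog use the
pyrimidine-reference convention: purine-reference substitutions are
reverse-complemented (flanks included) before classification, making the
encodings strand-invariant. Channel order is substitution-major with
alphabetical flank contexts — the COSMIC v2 file order — so catalogs and
signature matrices align positionally. SNVs whose 3-mer context cannot
be resolved (missing column value, N bases, chromosome absent from the
FASTA) are excluded and counted rather than guessed; a context whose
middle base contradicts the reference allele is a hard row error, since
it indicates corrupted annotation rather than missing information.
Per-sample spectra for samples with zero SNVs are reported as missing
(NaN fractions), not as zeros.

## Signature refitting and BIC model selection

A catalog of n SNVs is treated as n multinomial draws from a convex
mixture of reference signature columns. For a candidate subset of k
signatures, exposures solve the non-negative least-squares problem on the
probability-normalized catalog; exposure fractions are the normalized
weights. The model score is BIC = k·ln(n) − 2·lnL with lnL the
multinomial log-likelihood of the counts under the renormalized
reconstruction, probabilities floored at 1e-12; the constant multinomial
coefficient is dropped because it cancels between models on the same
catalog. This NNLS-for-exposures / multinomial-likelihood-for-scoring
pairing is the standard refitting practice and keeps both halves of the
procedure transparent. Cosine similarity is reported between the raw
count vector and the reconstruction scaled to the catalog total
(scale-invariant, so the choice of scale only fixes the contract).

Search is greedy-forward by default: start from the best single-signature
BIC, add the signature that most decreases BIC, stop when no addition
helps or at `max_signatures` (default 6, a typical size for a refitted
tumor catalog). Exhaustive search over all subsets is available for pools
of ≤ 12 signatures and serves as the oracle for the greedy path in tests.
Ties break toward smaller subsets, then lexicographic label order, making
selection deterministic. Adding a signature that receives zero exposure
leaves lnL unchanged and raises BIC by exactly ln(n) — a tested
invariant.

Because no reference signature matrix is bundled, tests and simulations
use a deterministic synthetic 30 × 96 stand-in
(`simulate.synthetic_signature_matrix`): sparse Dirichlet(0.15) columns,
which are peaky, mutually distinct profiles. Real matrices (e.g. COSMIC
v2) are read from TSV with `read_signature_matrix`, which canonicalizes
channel order and renormalizes columns within a 1e-3 tolerance. Recovery
results on the synthetic reference demonstrate correctness of the
optimizer and search, not identifiability of any particular real
signature pair (some real COSMIC signatures are nearly collinear; flat
signatures are harder to pin down than peaky ones).

## Exon read-depth CNV calling

Counts are balanced per sample so every sample's mean per-exon count
equals the global mean of per-sample means (multiplicative scaling —
depth is a pure scale factor on a count matrix). The control panel is the
per-exon mean (optionally trimmed mean) across ≥ 2 normalized non-tumor
samples; exons whose reference falls below `min_control_level` (default
1.0 normalized count, i.e. essentially uncovered) are flagged unusable
and excluded from evaluation rather than silently dropped, so they can
never convert a no-call into a call. Tumor copy number per exon is
CN = 2 · tumor/reference (diploid = 2). Gene calls follow strict all-exon
rules — gain iff every evaluable exon has CN > 2.8, loss iff every one
has CN < 1.2 — and genes with fewer than 3 evaluable exons are `no_call`.
No GC or mappability correction is applied; the panel of normals is the
only bias control, which is appropriate when tumors and controls share a
capture design.

Known limitation: the all-exon rule is deliberately specificity-first.
The loss threshold 1.2 leaves only a 20% relative margin over a true
single-copy loss, which is comparable to the per-exon count coefficient
of variation at a few hundred reads per exon with negative-binomial
dispersion around 0.01. Single-copy losses on ~5-exon genes are therefore
recalled imperfectly at realistic noise (one noisy exon vetoes the gene),
while precision and diploid-null specificity stay at 1.0; recall reaches
1.0 as dispersion → 0 or depth grows. The tests assert exactly this
behavior rather than an idealized recall.

## Kataegis

Intermutation distance (IMD) is the distance to the previous SNV on the
same chromosome after sorting; the first SNV per chromosome has undefined
IMD. A window of `min_count` consecutive SNVs qualifies when the mean of
its internal IMDs is ≤ `max_mean_imd`; overlapping qualifying windows are
merged into maximal regions. Defaults (≥ 6 SNVs, mean IMD ≤ 1 kb) follow
the community convention for kataegis; both are configurable. The merged
region's mean IMD is recomputed over its members, and for pathological
spacings it can slightly exceed the per-window cap — the qualifying
condition applies to windows, the region is their maximal union. Runs are
evaluated on consecutive SNVs, not fixed genomic windows, matching
rainfall-plot semantics; detection is translation-invariant by
construction.

## Cohort landscape and over-representation

Gene × sample matrices binarize to "≥ 1 qualifying mutation", so
frequencies are robust to duplicate records; the cohort sample list is an
explicit input so unmutated samples count in denominators. Cross-cohort
exclusivity takes the union of gene universes (absent = 0) and returns
genes at ≥ `min_freq_a` in one cohort and ≤ `max_count_b` carriers in the
other. "Mutated more than once" defaults to counting mutation records
(`unit="records"`), with a per-sample variant available, because the two
readings genuinely differ on recurrently mutated genes.
Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) with the universe defaulting to the genes observed in the
cohort; sets overlapping fewer than `min_overlap` = 2 genes are excluded.
The pass rule uses the raw p cutoff (0.01 for mutated-gene lists by
convention, 0.05 typical for CNV gene lists); Benjamini–Hochberg q-values
are reported alongside because raw-p cutoffs are anticonservative across
many sets.

## Survival

KM curves and KM medians come from lifelines (deaths processed before
censorings at ties, per the product-limit convention). The log-rank
statistic is computed in-package in the O/E form with the hypergeometric
variance at each distinct event time, p two-sided from the 1-df
chi-square; the hazard ratio is the Mantel–Haenszel-style O/E ratio
(O_A/E_A)/(O_B/E_B), which lifelines does not expose — lifelines is kept
as the independent oracle for the statistic in tests. Both median-OS
conventions (KM median: first time S(t) ≤ 0.5; plain median of observed
follow-up times, which ignores censoring) are reported for group
comparisons, because published group medians often mix the two. The O/E
hazard ratio is a consistent but biased estimator that attenuates toward
1 under heavy censoring or large effects; the tests bound its error at
15% for moderate effects without censoring.

## Synthetic data

Generators expand one root seed into independent SeedSequence streams per
generator, so fixtures are bit-reproducible and adding a generator never
perturbs another's output. Defaults encode the cohort conditions the
pipeline targets: 15 samples, ~117× mean depth, mean VAF 0.31 (Beta
depth-allocated), headline per-gene frequencies (TP53 0.73 … NAB2 0.20)
plus 200 background genes at 0.05, ~10:1 SNV:INDEL, and a 15% admixture
of common-AF / silent rows to exercise the filter; CNV simulations use
50 genes × 5 exons at 200× with dispersion 0.01 and 20 controls;
survival uses exponential event times (control median 12 months) with
uniform censoring calibrated per group to the target censoring fraction.
Contexts are emitted directly on variant rows so tests need no reference
genome. What the simulations do not model: genome-realistic coordinates
and gene footprints, mappability/GC structure, FFPE damage profiles
beyond the AF/impact admixture, subclonality, or correlated noise between
tumor and control captures. Passing recovery tests therefore validate the
algorithms under their stated noise models, not end-to-end performance on
real FFPE exomes.

Problem sizes in the test and acceptance runs (10,000 filter rows,
2,000-SNV catalogs, 100-seed recovery loops, 1,000 log-rank null
replicates) were chosen to make sampling error small relative to the
asserted tolerances while keeping a full run around a minute.

## Numerical choices

NNLS via scipy's Lawson–Hanson; reconstruction probabilities floored at
1e-12 before the log; signature-matrix column sums accepted within 1e-3
and renormalized; BIC ties resolved at 1e-9 rounding; zero-SNV samples
are "unfit" (None), not errors, and fits on < 50 SNVs carry a `low_n`
flag; log-rank variance terms with a single subject at risk contribute 0;
a comparison with zero events overall is returned flagged undefined
rather than raising.
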