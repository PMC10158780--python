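# Methods

This note documents the quantitative model behind `cfchip`, the choices
made where the procedure left room, and what the synthetic study used in
the tests does and does not establish.

## Enrichment model

A targeted capture panel sequences a fixed set of genes deeply. For a
(cf)ChIP sample, the per-gene deduplicated read count `N_i` is converted to
an enrichment

    E_i = N_i * 1e9 / (T * k_i),        T = sum over included genes of N_i

where `k_i` is the gene's *coverage factor*: the number of bases of gene
`i` effectively captured by the panel, estimated once from a reference
capture experiment as the count of bases with depth strictly above 100 and
treated as a constant thereafter. Dividing by `T` removes sequencing depth
(the profile is invariant to scaling all counts); dividing by `k_i` makes
genes with different captured footprints comparable, analogous to an RPKM
with the captured width in place of transcript length. The denominator is
read as `(Σ N_i) · k_i` — per-gene footprint outside the library-size sum —
because only under that reading is enrichment comparable across genes and
is the background-subtracted variant below dimensionally consistent. The
identity `Σ E_i · k_i = 1e9` over included genes holds per sample by
construction and is checked (at 1e-6 relative tolerance) by the pipeline
and the test suite as a guard on the implementation.

Plasma cfDNA is dominated by hematopoietic turnover, so a patient's cfChIP
profile is background-corrected against the mean count profile `H̄_i` of
healthy donors:

    E_i = (N_i − H̄_i) * 1e9 / ((ΣN − ΣH̄) * k_i).

Values may be negative (depletion below the healthy background) and are
kept in linear space. Group comparisons use

    log2FC_i = log2(mean_a E_i + ε) − log2(mean_b E_i + ε)

with group means taken as arithmetic means of per-sample enrichment,
negative means clamped to zero before the log, and a pseudo-enrichment ε
(half the smallest positive group mean across both groups; fallback 1e-3)
so that non-positive means are loggable. The clamping/ε policy is symmetric
in the two groups, so swapping groups negates the result exactly.

Genes captured solely within the first 25% of the gene body measured from
the TSS in the direction of transcription are excluded from all enrichment
sums: H3K36me3 accumulates toward the 3' end of transcribed genes, so a
TSS-proximal-only capture is blind to activity and would produce false
negatives. The window is `floor(0.25 · gene_length)` bases and a gene is
excluded only when *every* captured base falls inside it. The gene span,
not the spliced transcript length, defines the body; coordinates are
0-based half-open throughout. Genes with `k = 0` are retained in the panel
for bookkeeping but never enter analysis.

## Differential expression

TPM matrices are analysed on the log2(TPM+1) scale. Genes with group-mean
log2(TPM+1) ≤ 0.2 in *both* groups are removed before testing (a gene
active in one group is always tested). Per gene, a two-sided Welch t-test
compares replicate values between groups; Welch rather than pooled because
dispersions differ between cell lines and conditions and nothing is lost at
equal variances. Benjamini–Hochberg adjustment runs across the post-filter
gene set only. Calls: `up_in_a` at log2FC > 1 and q < 0.05, `up_in_b`
symmetrically. Degenerate genes with zero variance in both groups get
p = 1 when means agree (no evidence) and p = 0 with a logged warning when
they differ. The fold-change is the difference of group means of
log2(TPM+1) — a mean of logs, not the log of mean TPM.

## Concordance statistics

*Spearman correlation* uses average ranks for ties; the two-sided p-value
is an exact permutation tail for n ≤ 9 and the classical t-approximation
beyond, which at cohort-scale n agrees with the refined published
algorithms to plotting precision.

*ROC analysis* scores each included gene's enrichment against its
activity label. The AUC is computed through the Mann–Whitney rank identity
with ties counted one half, its standard error by the Hanley–McNeil (1982)
formula, and the departure from chance tested with z = (AUC − 0.5)/SE
(two-tailed normal). The curve is the step function over the distinct
observed scores, and sensitivity-at-specificity reports the maximum
sensitivity among thresholds whose specificity meets the cut-off (default
0.75), without interpolation.

*Direction agreement*: a gene called differentially expressed toward group
a agrees with the enrichment profile when its relative enrichment log2FC is
strictly positive (strictly negative for group b); a zero fold-change
counts as disagreement, which is conservative and logged. Per-direction
sensitivity is agreeing/total, and the 2×2 table (DE direction × enrichment
direction) is tested with a two-sided Fisher's exact test implemented by
the probability-mass convention — summing hypergeometric probabilities of
all tables, at fixed margins, no more probable than the observed one.

## Allele fractions

The mutational allele fraction of a variant is alt depth / total depth.
Variants observed in both the input-plasma and cfChIP compartments of the
same patient form pairs; unpaired observations are dropped with a logged
count, and each variant is its own pair (mutations, not genes, are the
unit — multiple variants in one gene are not collapsed). The per-pair
difference (cfChIP − input) is reported in percentage points with a
t-based 95% CI and a two-sided paired t-test; identical differences
degenerate the CI to a point and fall back to the zero-variance rule above.
A positive mean shift indicates preferential precipitation of the mutant
haplotype with the active-transcription mark, i.e. the mutant allele is
transcribed more than wild type.

## Synthetic study generator

The generator emulates the statistical shape of a targeted cfChIP study so
every stage can be exercised and calibrated without sequencing data. All
randomness flows from one seeded NumPy generator: identical seed and
configuration reproduce the dataset bit for bit.

Defaults mirror the study shape: a 197-gene panel with 36 TSS-excluded
genes (161 analysable), coverage factors 600–6000 bp, RNA-seq triplicates
for two tumour groups, 4 healthy donors, 8 + 4 patients, and 9 somatic
variants of which 7 carry a positive allele-expression bias.

* **Expression.** 76% of genes are active (150 of 197) with TPM drawn
  log-normal(μ=1.5, σ=1.3 natural log); inactive genes draw near-zero TPM
  (exponential, scale 0.03, capped below the activity threshold). Twenty
  genes are differentially expressed by a symmetric ±1 shift of the two
  group means on the log2(TPM+1) scale (a 4-fold total effect). Replicates
  add Gaussian noise with sd 0.1 on that scale — the typical tightness of
  cell-line RNA-seq triplicates, and the regime in which a study of this
  size can detect 2-fold changes from n = 3, as the analysis it emulates
  does.
* **Counts.** The expected read rate of gene i is
  `(slope · TPM_i + nonspecific) · k_i`, normalised to a library size drawn
  log-uniform (5e5–2e6 reads for ChIP and patient plasma; 1e5–4e5 for
  healthy donors, whose cfDNA yields are systematically lower — this also
  keeps the background-subtracted library size positive). Counts are
  negative binomial with shape 4 (Poisson available as a limit switch for
  analytic checks). The nonspecific term (default 1.5 TPM-equivalents)
  models antibody background and places single-sample active/inactive
  discrimination in the realistic AUC ≈ 0.87–0.91 range rather than at
  near-perfect separation; with it set to 0, zero-expression genes have
  exactly zero expected counts.
* **Plasma.** A patient sample mixes a sparse PBMC-like background
  expression vector (most genes near zero, ~8% highly expressed) with the
  tumour profile at tumour fraction 0.3; healthy donors are background
  only.
* **Variants.** Input-compartment alt depths are binomial at the
  configured allele fraction; the cfChIP compartment shifts the fraction on
  the logit scale by the variant's expression bias (default ±0.5), with
  total depth tied to the gene's simulated read count.

The generator provides an *analytic expectation* for the activity ROC AUC
of a single ChIP sample, conditional on the realised truth: for every
(active, inactive) gene pair the exceedance probability
`P(N_i/k_i > N_j/k_j) + P(=)/2` is evaluated from the two genes'
negative-binomial laws by summing over the inactive gene's truncated
support. The recovery tests require the observed AUC (mean over 20 seeds)
to sit within ±0.05 of this expectation — a check that the estimator and
the generator agree about the same quantity, not a claim about any real
cohort.

**What passing tests do not show.** The generator draws independent counts
per gene: it has no fragment-level structure, no inter-gene correlation
from chromatin domains, no GC/mappability bias, no batch effects, and its
background profile is a caricature of hematopoietic expression. Agreement
sensitivities and AUCs recovered from it therefore validate the estimators
and the pipeline plumbing, not the biological effect sizes of any
particular cohort.

## Numerical and interface choices

* Tolerances: conservation identities at 1e-6 relative; oracle equivalence
  (AUC pair counting, Fisher enumeration, exact Spearman permutations) at
  1e-12; t-test p-values against an independent implementation at 1e-9.
* Test-suite problem sizes: recovery uses 20 seeds of the default
  197-gene study; null calibrations use 1000 genes × 100 replicates per
  group (gene t-test) and 1000 simulations of 9 pairs at depth 2000
  (paired MAF test).
* Fisher's exact, AUC, Spearman and the Welch/paired t-tests are written
  against closed-form primitives (hypergeometric pmf, rank statistics,
  t distribution); library implementations of the same statistics
  (scipy's Fisher test, scikit-learn's AUC, statsmodels' Welch test) serve
  only as independent cross-checks in the tests.
* Degenerate inputs are errors, not silent results: empty samples, a zero
  background-subtracted library size, constant vectors in correlation,
  single-class ROC labels, all-zero contingency tables, duplicate variant
  records.
* The pipeline is a pure function of (inputs, config); outputs are TSV and
  JSON with stable ordering, and reruns are byte-identical. Exit codes for
  the CLI runner: 0 success, 2 validation failure, 3 stage error.

## Known limitations

* The TSS-exclusion rule uses the genomic gene span; if a transcript's
  spliced length differs greatly from its span, the 25% window is
  approximate.
* The Hanley–McNeil SE degenerates to 0 at AUC = 1, where the z-test is
  reported as infinite; with panel-scale gene counts this occurs only in
  contrived inputs.
* Background subtraction operates on raw counts, so it inherits the
  assumption that patient libraries are larger than the healthy mean —
  true of the cfDNA biology it models, but a pipeline run on inputs
  violating it will stop with a degenerate-library error.
* The paired MAF test treats pairs as exchangeable; multiple variants from
  one patient are not modelled as correlated.
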