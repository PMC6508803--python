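# Methods

## The experimental structure being modeled

The package targets a reciprocal allele-swap design: two inbred parents
(labelled backgrounds A and B) and two near-isogenic lines, each NIL
carrying the other parent's allele at a single introgressed locus. Every
genotype is profiled by bulk RNA-seq under control and stress, with
replicated samples (default 4 per cell, 32 samples total). Two factors are
therefore confounded deliberately by construction: *genetic background*
(A vs B) and *allele at the locus* (resistant vs sensitive), and the NILs
break the confound — parentA and nilB carry the resistant allele, nilA and
parentB the sensitive one.

## Count model and the DE engine

Counts are modeled as negative binomial with the quadratic mean–variance
law Var = μ + αμ². For gene g in sample j,

    K_gj ~ NB(mean = s_j · q_gj),   log q_gj = β₀ + β₁ x_j,

with x_j = 1 under stress. The reported effect is log₂FC = β₁/ln 2.

**Size factors** use the median-of-ratios convention: reference genes are
those with strictly positive counts in every sample; s_j is the median over
reference genes of K_gj divided by that gene's geometric mean. This is
scale-free: multiplying all counts by a constant leaves s unchanged (so
normalized means scale with the constant; only between-sample ratios are
invariant, which is what downstream contrasts use).

**Pre-filter.** Genes are removed when their total raw count over all
samples falls below T = (overall mean of normalized counts)/(number of
samples). The comparison is inclusive (a total exactly equal to T is kept):
the filter removes genes *below* the threshold. With 32 samples this
eliminates only near-silent genes, which is the intent — the filter guards
the multiple-testing burden, not the effect estimates.

**Dispersions.** Within every (genotype, treatment) cell with ≥ 2
replicates, a method-of-moments estimate (v − m)/m² is formed from
normalized counts and pooled across cells with (n_c − 1) weights, clipped
at zero. A hyperbolic trend α(μ) = a₀ + a₁/μ is least-squares fitted to the
positive gene-wise values, and the final dispersion is the geometric
interpolation exp(w·log α̂ + (1−w)·log α_trend) with w = 0.5 (configurable),
floored at 1e-8. The equal-weight choice reflects that with 4 replicates
the gene-wise estimate is noisy and with many replicates the trend matters
little; at 50 replicates the shrunken estimate lands within 25% of a true
α = 0.2 for ≳ 95% of genes, while pure method-of-moments manages only
~75% — the shrinkage is doing real work.

**Contrasts.** Stress-vs-control is fitted per genotype (the analyses
downstream compare per-genotype responses, so each genotype's DE list must
be self-contained). The NB GLM is fitted by IRLS with the final dispersion
treated as known; the Wald statistic β̂₁/SE is referred to the standard
normal, two-sided. Genes with all-zero counts among the contrast samples,
and the rare non-converging fits, are flagged with NaN statistics and
excluded from the BH denominator — never silently dropped. Under a
10,000-gene null simulation with known dispersions the observed type-I
error at p < 0.05 is ≈ 0.047–0.049 and the p-value distribution passes a
Kolmogorov–Smirnov uniformity check, so the normal approximation is
adequate even at 4+4 replicates for the expression levels the pre-filter
admits.

## DE calling and the allele-responsiveness ratio

A gene is called up-regulated when log₂FC ≥ 1, padj ≤ 0.05, and at least
one sample shows ≥ 8 normalized counts (K/s); down-regulation is symmetric.
The expression floor is interpreted on the normalized-count scale — the
most interpretable of the candidate scales — and is configurable.

The central comparative quantity is the ratio of a gene's stress response
under the two alleles, on the **linear** fold-change scale: a gene is in
the "≥ f×" class when log₂FC_ref − log₂FC_alt ≥ log₂ f. The comparison is
inclusive and applies an absolute slack of 1e-9: published tables report
log₂FC to two decimals, and pairs whose printed difference is exactly 1.00
(e.g. 1.21 vs 0.21) must pass the twofold threshold even though their
binary-float difference is 0.99999…; without the slack the boundary
behavior would depend on which decimals happen to round down. Threshold
nesting (≥ 2× implies ≥ 1.5×) is preserved by construction.

Magnitude comparisons between gene sets use Welch's two-sample t on log₂FC
values (no equal-variance assumption; gene sets differ in size by an order
of magnitude in this design); a Mann–Whitney option exists for heavy-tailed
sets. PCA uses the log₂(K/s + 1) transform, ranks genes by row variance,
takes the top 500, centers per gene without scaling, and reports sample
scores and variance proportions from the SVD. The shifted-log transform
stands in for regularized-log shrinkage transforms: it is monotone,
depth-aware, and sufficient for the separation structure PCA is asked to
display; it does under-stabilize variance for very low counts, which is why
gene ranking happens after transformation.

## Synthetic data: what it emulates, and what it does not

The generator plants five gene classes (default 80% null, 5% each other):

- *allele_dependent*: stress log₂FC = 2.5 under the resistant allele,
  attenuated to 0.3× (0.75) under the sensitive allele — magnitudes modeled
  on published allele-swap tables, where resistant-allele responses cluster
  around 2–3 log₂ units against 0.5–1.2 for the sensitive allele;
- *allele_independent*: log₂FC = 2.0 in every genotype;
- *background_specific*: log₂FC = 2.0 in background B only, either allele —
  mimicking genes that respond only in one genetic background;
- *introgression_effect*: a constant +1 log₂ baseline shift in the NILs,
  no treatment response — mimicking genes resident on the introgressed
  segment;
- *null*: nothing.

Baseline means are log-normal (meanlog 4, sdlog 1.5 — median ≈ 55 counts
with a realistic dynamic range spanning the pre-filter threshold), depth
factors log-uniform on [0.5, 2], and dispersions follow α(μ) = 0.01 + 1/μ,
matching the engine's own mean–variance law. Promoter libraries are i.i.d.
bases at a chosen GC content, with planted motif instances drawn uniformly
from the IUPAC expansion at non-overlapping positions (uniform via
stars-and-bars gap allocation), optionally over a rejection-sampled
motif-free background.

What passing synthetic tests shows: the estimators recover the parameters
of the model they assume, at the study's sample sizes, and the downstream
classification separates planted allele-dependent from allele-independent
genes essentially perfectly (Fisher p ≪ 0.01). What it does not show:
robustness to features real data have and the generator omits — batch
effects, correlated genes, outlier samples, GC- and length-dependent
coverage bias, isoform-level complexity, and promoter sequence composition
that is anything but i.i.d. Conclusions about real experiments rest on the
engine's assumptions holding approximately, not on these tests.

## Motif scanning

Patterns are IUPAC strings; scanning counts *overlapping* occurrences at
every offset (occurrence averages in the motivating analysis are raw
overlapping counts), ambiguity codes in the scanned sequence never match,
and the default is to scan only the extracted upstream strand, with
both-strand scanning behind a flag (for palindrome-closed patterns the
reverse-complement scan is skipped as a no-op). Promoters are anchored at
the start codon: the 2-kb interval upstream of the leftmost CDS start
(+ strand) or the reverse complement of the interval right of the rightmost
CDS end (− strand), clipped at contig boundaries; gene models without CDS
are skipped with a warning rather than silently anchored elsewhere.
Internally coordinates are 0-based half-open; reported intervals are
1-based inclusive. The chance expectation assumes i.i.d. bases:
E = (L − m + 1)·Π_i Σ_{b∈code_i} p_b, doubled for both-strand scans (an
expectation, so overlap dependence is irrelevant by linearity). For GGNVS
on uniform 2-kb sequence this gives 1996·3/128 ≈ 46.8 hits — the
quantitative sense in which a 5-bp degenerate element is uninformative as a
presence/absence signal.

## Sequence analyses

Translation uses the standard code, stops at the first stop codon, and in
strict mode rejects internal stops and lengths not divisible by 3. The
frameshift reconstruction takes the deletion coordinate as an explicit
1-based CDS position (the motivating description is ambiguous about
nucleotide vs codon indexing, so nothing is hard-coded), deletes one base,
appends the supplied 3′UTR sequence, and translates to the first in-frame
stop, raising if none exists. Protein differences come from a global
affine-gap alignment (BLOSUM62, gap open 10, extend 0.5, configurable):
substitutions are aligned mismatch columns; each maximal run of gap columns
is one indel event, matching how multi-residue indel blocks are counted in
curated alignments. Published counts derive from hand-curated alignments,
so exact agreement can require matching their (unstated) parameters; the
defaults are the field's conventional ones.

## Problem sizes and numerical choices

The calibration studies use 10,000 genes for the null type-I error, 1,000
genes for effect recovery, 1,000 sequences for the Monte-Carlo motif check
(3-SE agreement band), and 2,000 genes for the end-to-end planted-class
enrichment — sizes at which the Monte-Carlo error of each target quantity
is comfortably below its acceptance band. All randomness flows from a
single root seed through `numpy.random.SeedSequence` spawning; derived
seeds stay below 2³¹. Dispersions are floored at 1e-8; IRLS runs at most
100 iterations with tolerance 1e-8; ties in variance ranking and delta
sorting are broken stably (mergesort) so outputs are bit-reproducible.

## Known limitations

- The DE engine is a simplified NB Wald pipeline, not a reimplementation of
  any specific published tool: no independent filtering beyond the stated
  pre-filter, no outlier replacement, no fold-change shrinkage estimator.
- The per-genotype contrast model cannot borrow strength across genotypes;
  an interaction model would be more powerful but answers a different
  question than the per-genotype DE lists the design calls for.
- The dispersion trend is hyperbolic with only two parameters; count data
  with non-monotone mean–dispersion relationships would be mis-trended
  (shrinkage weight 0.5 limits the damage).
- `magnitude_test` treats genes as independent observations, as the
  motivating analyses implicitly do; correlated genes make the p-values
  optimistic.
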