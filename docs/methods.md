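# Methods

## The problem being modelled

A hybrid population descends from two breeds, each carrying variation the
other — and the single linear reference genome — does not. Genotyping the
cohort two ways gives complementary, imperfect call sets: a
single-reference (SR) set discovered from read alignments, which misses
reference-unrepresentable ("private") variants outright and miscalls
heterozygotes near structural variation, and a parental-panel (Pan) set,
genotyped against the variants carried by one assembled genome per parent
breed, which covers private variation but only at panel sites. The
package's core operation merges the two under an explicit concordance
rule and runs the downstream population-genomic analyses on the merged
set.

## Call-set integration

Records are biallelic only; multi-allelic, symbolic-ALT and
spanning-deletion (`*`) records are dropped at parse time and counted.
Half-missing calls (`./1`) are treated as missing — conservative and
deterministic. Variants are normalized (shared-base trimming; full
left-alignment when a reference sequence is supplied) so that "the same
site" is well defined; the key is (chrom, pos, ref, alt). Internal
coordinates are 0-based half-open; VCF/GFF3 conversion happens at the I/O
boundary only.

At overlapping keys, genotype concordance is the fraction of agreeing
calls among samples where both sources are non-missing; sites with
concordance strictly above 0.90 are retained once, the rest are discarded
(the only reading consistent with retention-by-consistency). Retained
overlaps keep the **panel** genotypes by default: panel calls carry no
reference-bias component, and keeping SR genotypes demonstrably
re-imports the het→hom-ref distortion into the merged set, where it can
masquerade as selection signal downstream. The choice is exposed as
`MergeParams.genotype_priority`.

QC runs after merging (counts are compared before/after QC on each set):
missingness > 10%, then MAF < 5% (computed on non-missing calls), then an
exact conditional Hardy–Weinberg test at P < 10⁻⁶, applied to SNPs and
INDELs only. Removal is attributed to the first failing filter, so report
counts reconcile exactly; the filters are idempotent. All thresholds are
strict inequalities: boundary sites stay. The HWE test enumerates every
heterozygote count compatible with the observed allele counts in log
space and sums the probabilities of outcomes no more likely than the
observed one; a chi-square approximation is unreliable at P ≈ 10⁻⁶ with
n ≈ 100. Variant classes by allele-length difference: 0 → SNP (or
multi-nucleotide substitution → INDEL class), 1–49 bp → INDEL, ≥ 50 bp →
SV (the conventional boundary; an exactly-50 bp event is an SV).

## Population structure

PCA mean-imputes missing dosages per variant, centers by 2p̂, scales by
√(2p̂(1−p̂)) (unscaled available behind a flag), drops zero-variance
columns, and eigendecomposes the sample covariance; signs are fixed so
each PC's largest-magnitude coordinate is positive. Admixture uses the
standard binomial mixture P(alt copy | i, j) = Σₖ q_ik f_kj fitted by EM
(responsibility updates for alt and ref copies separately; frequencies
clamped to [10⁻⁶, 1−10⁻⁶]; missing entries excluded from both numerators
and the per-sample denominator). Five seeded restarts from Dirichlet(1)
rows, best likelihood kept; the log-likelihood is asserted non-decreasing.
Component labels are aligned by the fixed rule "component 1 maximizes mean
ancestry among breed-A founders". K is a user parameter; cross-validation
for choosing K is out of scope.

## Selection scans

Windows slide from 0 in 25 kb steps with 50 kb size; enumeration stops
once a window reaches the chromosome end (a trailing partial is emitted
when the end is not otherwise covered). Per-site Weir–Cockerham (1984)
two-population variance components (a, b, c) are aggregated per window as
Σa / Σ(a+b+c) — the ratio-of-sums ("weighted") convention; negative
per-site estimates are not clamped. Windows with no usable sites or a
non-positive denominator are unscored.

The sweep statistic is a structural reimplementation of the
cross-population composite-likelihood ratio idea, not a numerical clone
of the original package. Per site, the neutral model integrates the
binomial likelihood of the object population's allele counts over a
truncated normal for its frequency, centered at the reference
population's frequency p with variance ω·p(1−p); tail mass outside (0,1)
is censored into point masses at 0 and 1; the integral uses a fixed
512-node midpoint rule. Under selection, a site at distance d from the
putative swept position escapes with probability c = 1 − exp(−r·d/s̃)
(r in Morgans/bp) and otherwise follows a two-component hitchhiked
distribution: a mass-p component centered at 1 − c(1−p) and a mass-(1−p)
component centered at c·p, each with variance c·ω·p(1−p) floored at 10⁻⁶.
CLR = 2·max over the s̃ grid of the summed log-likelihood ratio, floored
at zero (the grid contains s̃ = 0, where the models coincide). ω is
estimated genome-wide by the method of moments,
mean((p_obj − p_ref)²/(p_ref(1−p_ref))), over sites polymorphic in the
reference population. Each window is scored as the maximum over five
putative swept positions spaced across it, mirroring the original
method's scan-grid-then-summarize design; a single-center primitive is
also exposed. The default s̃ grid, {0} ∪ logspace(10⁻⁵, 10⁻¹, 15), is
matched to r = 1 cM/Mb; because c depends on r·d/s̃ only, analyses at
other recombination scales rescale the grid by the same factor.

Top-5% windows (empirical 95th percentile, linear interpolation, ties
included) are candidate regions; genes and QTL intervals are annotated by
≥ 1 bp overlap under half-open conventions. Because the denominator of
"percentage of overlapping genes" between two gene sets is ambiguous,
all three conventions (|A∩B|/|A|, |A∩B|/|B|, Jaccard) are reported.

## EigenGWAS

PC1 of the two contrasted populations serves as the phenotype; each
marker is tested by OLS with intercept (pairwise-complete over missing
dosages; markers with minor-allele count < 2 skipped), χ² = (β/SE)²,
λ_GC = median(χ²)/0.4549364, adjusted χ² = χ²/λ_GC with p from the 1-df
upper tail. Significance is strict: adjusted p < 0.05/n with n the
markers actually tested in the scan. Flanks of ±100 kb (clipped at
chromosome ends) annotate significant loci. Note that when PC1 is
computed from the same marker matrix, λ_GC concentrates near the
random-matrix edge (1+√(n_samples/n_markers))² even without structure —
about 1.3 at 100×5000 — and far above 1 under real differentiation; λ_GC
is a deflator here, not a model-fit diagnostic.

## Candidate genes

Evidence sets (Fst genes, CLR genes, EigenGWAS genes) are combined with a
differential-expression list by exact set algebra; "joint candidates" are
DE genes backed by at least `min_evidence` selection sets (default 1,
because the real study's exact combination rule across its scan rows is
not specified). Coding consequences classify SNPs against a gene model:
upstream/downstream within a configurable 5 kb of the transcript span
(strand-aware), intronic inside the span outside exons, exonic non-coding
inside exons outside CDS, and codon-level calls (synonymous / missense /
stop gained / stop lost) for CDS SNPs by substituting into the
strand-and-frame-correct codon; INDELs/SVs in CDS are reported without
frame analysis. Regional "haplotype" matrices are genotype dosages — the
pipeline never phases — which is sufficient to display the
reduced-heterozygosity footprint of a sweep.

## The synthetic cohort

The generator emulates the breeding design the pipeline targets: two
founder breeds diverged under a Balding–Nichols model (breed frequencies
Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) around ancestral p₀ ~ U(0.05, 0.95)), an
F1 from breed-A dams × breed-B sires, then random within-cohort mating to
F5 with Poisson-crossover recombination; under selection, parents (and
the sampled final-generation animals, reflecting deliberate selective
breeding) are drawn with weight 1 + s·dosage/2 at the sweep locus.
Sampled outputs are 31 breed-A animals, 40 breed-B animals (drawn from
the breed frequency pools, as the real cohorts are founders or their
relatives) and 37 final-generation hybrids.

Defaults, chosen once as the study conditions: two 4 Mb chromosomes with
12,000 SNPs, 1,800 INDELs and 90 SVs (insertion-type alleles; anchored
VCF style); divergence F = 0.2 (two distinct breeds); founder stocks of
200 dams and 21 sires; breeding cohort 250 per generation; recombination
2×10⁻⁶ crossovers/bp/meiosis. The genome is a compressed stand-in — about
two orders of magnitude smaller than a real genome with the per-bp
recombination rate inflated correspondingly (≈ 200 cM/Mb) so that linkage
decays within a chromosome and sliding-window statistics behave as they
would at real scale.

Reference bias is modelled by its two mechanisms: (i) a fraction of loci
are "private" (absent from SR) — 5% baseline, 50% inside bias regions
(±8 kb around each SV), 80% for SVs themselves, with 60% of INDELs placed
inside bias regions (reference misrepresentation clusters near structural
variation and hits INDELs hardest — this produces the INDEL-gain >
SNP-gain asymmetry); (ii) SR heterozygotes are miscalled hom-ref with
probability 0.15 inside bias regions (0.02 elsewhere), plus 3%
missingness. The Pan set is restricted to loci carried by one sampled
diploid per breed (one assembly per parent) with a 1% symmetric genotype
error. The default sweep (s = 20 at chr1:2,000,001) starts on few breed-A
haplotypes (pinned founder frequency p_A = 0.02) and is absent from breed B,
mirroring a breed-private favored haplotype driven toward fixation by
strong artificial selection; this makes the sweep hard and near-complete,
the regime both window statistics are designed to detect. Sixty
three-exon gene models are placed without overlap, one pinned across each
sweep locus; DE flags are drawn at 95% for sweep genes and 15% background.

All stochastic draws flow from one seed through named substreams, so any
stage can be pinned independently.

### What the generator does not emulate

Read-level error processes (depth, mapping quality, genotype
likelihoods), realistic LD beyond pedigree recombination, gene-density
and recombination heterogeneity along real chromosomes, deletion-type
ALT alleles, and the true error rates of the real pig call sets (none of
the rate defaults are claims about those data). Passing tests therefore
demonstrate that the pipeline's logic and statistics behave correctly
under a faithful *model* of reference bias and hybrid breeding — not that
any particular real cohort would show the same magnitudes.

## Numerical and policy choices

* Strict inequalities at every stated threshold (10% missingness, 5% MAF,
  P < 10⁻⁶, 90% concordance, 0.05/n): boundary cases retained/excluded
  exactly as worded.
* Concordance denominators exclude pairs with any missing call; an
  overlap with zero comparable pairs is discarded and counted separately.
* Density uniformity (CV = population SD / mean of per-window counts) is
  compared per variant type; SNPs carry the headline comparison because
  the variant classes tile the genome differently by construction.
* The window-enumeration rule stops at the first window reaching the
  chromosome end ("100 kb / 50 kb / 25 kb → exactly three windows").
* Problem sizes in the test-suite and analysis scripts (desk-scale
  genome, 108-sample cohort, 20-replicate direction-of-effect batches)
  were chosen so the full study runs in minutes on a laptop core while
  keeping every window statistic well-populated (~75 SNPs per 50 kb
  window).

## Known limitations

The CLR reimplementation preserves the structure of the published method
(drift null, distance-decaying escape, composite likelihood, grid
maximization) but is not numerically interchangeable with the original
package; its hard-sweep assumptions make it conservative for soft or
incomplete sweeps, which is visible in the simulator as weaker CLR than
Fst ranking when sweeps stall below ~90% frequency. EigenGWAS uses plain
OLS with λ_GC deflation rather than a mixed model, so closely related
samples inflate then deflate together; the Bonferroni count is per scan.
Haplotype displays are dosage-level, not phased.
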