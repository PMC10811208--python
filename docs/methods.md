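# Methods

This note documents the models and estimators implemented in `admixscan`,
the choices made where a design was genuinely open, and what the synthetic
data used to validate the pipeline does and does not emulate.

## Data model and conventions

Genotypes are alt-allele dosages in {0, 1, 2}, −1 for missing; phase is
discarded because no stage here is phase-aware (the local-ancestry model is
deliberately genotype-based). Positions are 1-based internally; BED is
0-based half-open at the file boundary, converted in a single function pair.
Per-site "RMS mapping quality" is consumed from the VCF `MQ` INFO field when
present and never computed. The two genotyping platforms
(reduced-representation vs whole-genome) differ only in missingness and are
carried as a per-sample tag, not separate classes.

## Diversity statistics

For a biallelic locus with alt frequency p over the called genotypes of one
population: Ho is the heterozygote fraction; He = 2p(1−p); Nei's gene
diversity 1 − p² − (1−p)² (identical to He for two alleles — asserted as an
invariant); PIC defaults to the gene-diversity form 1 − Σfᵢ² because the
commonly printed "1 − Σfᵢʳ" is read with r = 2, the only exponent that makes
the expression a diversity; the Botstein form (subtracting 2p²(1−p)²) is
available behind `pic_variant="botstein"` everywhere PIC appears. Population
summaries are unweighted means over loci with at least one called genotype.
He is uncorrected for sample size by default.

Per-site nucleotide diversity uses the unbiased pairwise estimator
2·c_alt·c_ref/(c(c−1)) with c the called allele count. Windows start at
position 1 and slide by the step (defaults 100 kb/10 kb for single-population
π, 50 kb/10 kb inside the sweep scan); window π divides the summed site π by
the nominal window size, except terminal truncated windows which divide by
their actual span — the choice matters only at chromosome ends and is stated
here because conventions differ between tools.

## Locus filtering and merging

`filter_loci` applies, in a fixed order: depth masking (genotypes below the
threshold become missing, so completeness is evaluated post-masking),
missingness, per-site quality, MAF (defaults 4 / 0.3 / 20 / 0.01). The order
changes per-step counts but not the surviving set of a conjunctive filter;
the per-step report records both. Merging two datasets intersects loci on
(chrom, pos) and requires identical ref/alt — a swapped or strand-flipped
pair is an error, never a silent flip — then concatenates samples;
re-filtering the merged matrix is the caller's next step.

## Weir–Cockerham FST and the sweep scan

Per-site variance components a (between populations), b (between individuals
within populations) and c (within individuals) follow the two-population
genotype-based Weir–Cockerham estimator, using observed heterozygosity and
the unequal-sample-size correction; sites need ≥ 2 called genotypes in both
populations. Window (and genome) FST is the weighted ratio of sums
Σa/Σ(a+b+c); negative estimates are retained. On Balding–Nichols data with
divergence F per population the genome estimate concentrates near F (checked
at F = 0.10 within [0.08, 0.12] and at 0 under a random split of one
population).

Z(FST) standardizes window FST by the genome-wide mean and sample standard
deviation (ddof = 1). The diversity contrast is log₂(π_A/π_B) with the
comparator population A in the numerator — the orientation is an explicit
argument of every scan because large positive values indicate diversity loss
in B, the putatively selected population. Windows lacking a valid FST site
or with zero π on either side are excluded from ranking and counted.
Candidate windows are those at or above the empirical (1 − f) quantiles
(linear interpolation, ties included) of *both* statistics, f = 0.05 by
default; quantiles are taken over the retained windows only. Candidates map
to the SNPs they contain and to gene intervals overlapping them by ≥ 1 bp,
deduplicated.

Enrichment of a candidate gene set against a background uses the upper-tail
hypergeometric probability P(X ≥ x); the one-sided Fisher test on the same
2×2 table is algebraically identical and is asserted to agree to 1e−12.
Benjamini–Hochberg step-up adjusts across all tested terms; significance is
reported at q < 0.05. Terms with no background genes are skipped with a
warning. No gene-length bias correction is applied (the data model carries
no transcript lengths; documented omission).

## Phylogenetics, kinship, PCA

Distances are p-distances on genotypes, Σ|gᵢ−gⱼ|/(2m_ij) with pairwise
deletion — the member of the usual distance-model pairing that is defined
for genotype dosages rather than sequences. Neighbor joining is the
Saitou–Nei agglomeration with the rate-corrected Q criterion; ties are
broken by the lexicographically smallest pair of minimum-descendant-leaf
labels so results are order-independent, and negative branch lengths are
clamped to zero. NJ recovers any additive matrix exactly (tested against a
path-length oracle on random trees and cross-checked against an independent
library implementation). Bootstrap support resamples loci with replacement
and reports, per internal bipartition of the full-data tree, the fraction of
replicate trees containing it. Outgroup rooting places the root on the edge
to the named leaf.

The genomic relationship matrix is the allele-frequency-standardized form
G_ij = Σ(gᵢ−2p)(gⱼ−2p)/(2p(1−p)) divided by the pair's count of co-called
loci (missing entries contribute zero); monomorphic loci must be filtered
first. PCA double-centers the relationship matrix before
eigendecomposition, so coordinates are exactly zero-mean; components are
ordered by descending eigenvalue, variance proportions are taken over the
positive spectrum, and signs follow the first-nonzero-loading-positive
convention.

## Admixture model

Genotypes are modelled as g_il ~ Binomial(2, Σ_k q_ik f_kl) with Q rows on
the simplex and F ∈ [0,1]; missing entries drop out of the likelihood. The
EM updates (responsibility-weighted allele counts) provably never decrease
the likelihood, which is asserted at every iteration; fitting uses 3 random
restarts by default and the best likelihood is kept. K = 1 has the closed
form q = 1, f = observed frequencies. EM convergence in Q is slow in its
tail; the default cap of 500 iterations (tolerance 1e−4 on the likelihood
gain) recovers Q to ~0.01 mean absolute error in the validation settings,
and reported fits include the full likelihood trace so convergence can be
inspected.

K is chosen by masking cross-validation: called genotype entries are
partitioned into random folds (redrawn, boundedly, if a fold would strip a
locus of all data); each fold is masked, the model refit, and held-out
entries scored by squared dosage error ((g − 2d)/2)². The loss is a
documented choice — the deleted-entry prediction error customary for this
model family. On a two-ancestry simulation CV selects K = 2; on a
homogeneous cohort it selects K = 1.

## Local-ancestry HMM

Each query genome is two independent haplotypes; each haplotype is a
two-state ancestry chain along the chromosome with stationary law
(α, 1−α) (α = 0.5 by default) and switch probability 1 − exp(−d·G) per
inter-locus genetic distance d (uniform 1 cM/Mb map by default) with G
generations since admixture (default 10, exposed as a parameter since the
true value is rarely known). The diploid chain is the Kronecker square over
ordered pairs, collapsed to the three unordered states {(1,1),(1,2),(2,2)}
for reporting. Emissions take panel allele frequencies f₁, f₂ (clamped to
[ε, 1−ε], ε = 1/(2n_panel+1), with clamp counts logged): the genotype is the
sum of two Bernoulli haplotype draws; missing genotypes are uninformative.
Forward–backward (scaled, vectorized across individuals) yields per-locus
posteriors; the expected ancestry-1 dosage is 2P(1,1) + P(1,2), the global
proportion its mean over loci divided by two (posterior means by default; a
Viterbi decoder is available and agrees with the posterior mode on > 95% of
loci in validation). This is a deliberately simple genotype-based model —
no phasing, no conditional-random-field smoothing — because the quantities
consumed downstream are global summaries, and the simple model is fully
testable: at panel divergence F = 0.2, G = 10 and 5,000 loci it calls
per-locus diploid ancestry with ≥ 97% accuracy and recovers cohort mean
proportions to a few tenths of a percentage point, degrading monotonically
as F shrinks.

## Core-SNP panel selection

Five conjunctive steps in a fixed order with per-step counts: depth ≥ 4
(masking genotypes; a strict mode drops loci on mean depth instead, since
the usual prose description is ambiguous between the two readings),
completeness ≥ 70%, MAF ≥ 0.01, PIC ≥ 0.4, and non-intergenic location
(genic or within the 5-kb flanks, classified against the gene annotation
with genic > upstream > downstream priority, strand-aware). Under the
default PIC form the 0.4 threshold algebraically implies MAF ≥ 0.2764 for
every surviving biallelic locus — with the Botstein form the same threshold
is attainable only near MAF 0.43, which is why the variant flag matters and
both are exposed.

## Synthetic data: what it emulates, and what it does not

The generator draws ancestral allele frequencies for two populations from
the Balding–Nichols Beta model around a shared base frequency (uniform on
[0.05, 0.95] by default) — chosen over coalescent simulation because the
analytic moments (E[f] = p, Var[f] = F·p(1−p)) and the FST expectation give
free oracles at desk scale. Panels are Hardy–Weinberg draws. Admixed
individuals get an ancestry-1 proportion q from a Beta with configurable
mean and concentration 20 (sd ≈ 0.10); haplotype ancestry along each
chromosome is a reversible two-state Markov chain with stationary (q, 1−q)
and the same 1 − exp(−d·G) switch kernel as the HMM — equivalent at this
scale to a Poisson tract process and trivially stationary. Alleles are
drawn independently given local ancestry. Sweeps are implanted by redrawing
a target population's genotypes in a region from frequencies pushed to
0.98/0.02. Platform effects are i.i.d. genotype missingness plus
Poisson-conditioned-≥ 1 depths.

Default conditions mirror the motivating study design: panels of 19 and 9,
an admixed cohort of 129 with mean ancestry-2 proportion 0.6278 on the
high-missingness platform, a near-pure cohort of 20 (mean ancestry-1
0.9514) on the low-missingness platform, depth mean 12.36, G = 10,
1 cM/Mb. The platform missingness default is 0.30, aligned with the
`miss ≤ 0.3` retention bound rather than with raw reduced-representation
integrity (often far lower), so that filtered desk-scale datasets retain
enough loci to exercise every stage. The divergence default F = 0.2 is a
realistic between-breed value for taurine cattle; it is also the setting at
which the validation suite quantifies ancestry recovery.

Not emulated — and therefore not demonstrated by passing tests: background
linkage disequilibrium beyond ancestry tracts (alleles are independent given
ancestry, so real-data LD will make effective marker counts smaller than
nominal); sequencing error in called genotypes; genotype-calling bias
correlated with depth; selection other than the implanted
frequency-displacement sweeps; and sample-relatedness structure within
populations. The realized cohort mean ancestry carries sampling variance
from the finite number of tracts per genome (~10 per haplotype at the
defaults), so it can sit a few percentage points from the Beta target in
any one replicate; recovery claims are always made against the realized
truth, which the generator records exactly (the per-individual global
proportion equals mean dosage/2 by construction).

## Numerical and validation choices

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` sub-streams; identical configurations are
bit-identical. Validation problem sizes (e.g. 20,000 loci and 100+100
samples for FST calibration; 20 implanted-sweep replicates on a 2-Mb
chromosome with ~4,000 loci and 50+50 panels; 5,000 loci, 50+50 panels and
60 admixed individuals for ancestry recovery; 100 bootstrap replicates)
were chosen so the full suite runs in well under an hour on a single core
while keeping Monte-Carlo noise far from the asserted bounds. Degenerate
inputs fail loudly: constant scans in the Z-transform, monomorphic loci in
the GRM, sample pairs with no shared loci, populations missing from the
map, conflicting alleles at merge.
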