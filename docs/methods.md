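# Methods

This note describes the models and procedures the package implements, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions that affect results.

## Study design the package targets

Two genotyping platforms applied to the same individuals: a dense panel
(WGS-like, order 10⁷ markers in the real setting) and a reduced panel
(chip-like, order 10⁴ markers) whose markers were ascertained for common
polymorphism. The analysis question is never "what is the truth" but "does
the reduced panel recover the same population-genetic inferences as the
dense one" — structure, diversity ranking, and selection signals — on a set
of breeding lines: two nearly undifferentiated sister lines from one breed
(A, B) and two clearly diverged lines from another (C, D).

## Quality control

Filters are applied identically to both platforms, in a fixed order:
non-autosomal sites out (autosome list configurable; chicken 1–39 with both
bare and `chr`-prefixed names by default, since naming dialects vary), then
sites with missing rate strictly above `max_site_missing_rate` (default
0.01), then samples strictly above `max_sample_missing_rate` (default
0.05). Sites exactly at a threshold are retained. Site-before-sample
ordering matters (removing a high-missing site lowers sample missing rates)
and is fixed.

LD pruning slides a window of 50 kept SNPs by steps of 5 along each
chromosome, removing the later member of any pair with squared Pearson
dosage correlation above 0.2, repeating passes until stable. r² uses
pairwise-complete observations; zero-variance pairs count as uncorrelated.
This is a genotype-correlation r², not a composite-haplotype measure — a
deliberate simplification, adequate because pruning is used here only to
thin markers. The earlier (left-most) member of a correlated pair is always
kept, which makes the retained set deterministic and means the first site
of a chromosome is never removed.

Pruned genotypes feed the structure stages (PCA, trees, admixture), where
LD would otherwise distort axes and likelihoods; windowed statistics
(π, F_ST, LSBL) use unpruned genotypes, since thinning inside windows
changes their site content. Both choices are recorded in the run manifest
and are per-stage configurable.

## Population structure

**PCA.** Dosages are mean-imputed per site, centred by 2p̂ and scaled by
√(p̂(1−p̂)) (Patterson scaling, p̂ = mean dosage / 2); fixed sites are
dropped. Scores are left singular vectors scaled by singular values;
eigenvalues are singular values squared over (n−1). Each component's sign
is fixed by making its largest-magnitude loading positive, so repeated runs
are bit-identical. Platform comparisons additionally re-align signs to
maximise r, because the sign convention is still arbitrary across different
marker sets.

**Trees.** Pairwise allele-sharing distance d(i,j) = mean over
pairwise-complete sites of |gᵢ − gⱼ|/2, then Saitou–Nei neighbor joining
with ties in the Q-criterion broken by smallest (row, column) index.
Negative NJ branch lengths are clamped to zero after length computation and
counted. Bootstrap support resamples sites with replacement; an internal
edge's support is the percentage of replicate trees containing the same
leaf bipartition.

**Admixture model.** Genotype g_ij ~ Binomial(2, f_ij), f_ij = Σ_k q_ik
p_kj, with Q rows on the simplex and P in [ε, 1−ε], ε = 10⁻⁶. The
log-likelihood (binomial coefficient omitted, as it is parameter-free) is
maximised by alternating multiplicative EM updates of Q then P; both are
exact EM steps, so the log-likelihood is non-decreasing — asserted in
tests. Defaults: tol 10⁻⁴ log-likelihood units, max_iter 2000, seeded
uniform initialisation around pooled frequencies. EM converges slowly near
the boundary, so fitted Q values for unadmixed individuals approach but do
not exactly reach 1; at desk-scale data the ML optimum itself also leaves a
few individuals visibly off the boundary (their signal is partially
absorbed by the frequency estimates), which bounds how sharp any correct
optimiser's Q can be.

**Choosing K.** Cross-validation masks non-missing genotype entries in
`n_folds` random folds (redrawn, boundedly, if a fold would empty a sample
or site), refits at each K, predicts masked dosages as 2f, and scores RMSE;
the reported optimum is the argmin of the fold-mean error. CV fits use
max_iter 500 / tol 10⁻³ — looser than a final fit because thirty-odd fits
are run and the argmin over K is far less sensitive than the parameter
values; both knobs are exposed. RMSE on masked entries is a simpler
criterion than the deviance-based one used by the standard ADMIXTURE tool;
only the location of the minimum is treated as comparable between the two.

## Diversity and selection statistics

Per line: Ho = fraction of called genotypes that are heterozygous; He =
2p(1−p) without small-sample correction (an optional 2n/(2n−1) factor is
off by default — means over tens of thousands of sites make the correction
negligible and the uncorrected form is the common default); MAF = min(p,
1−p). Line-level values are unweighted means over all sites with at least
one called genotype.

Per-site nucleotide diversity uses the unbiased pairwise form
2c(n−c)/(n(n−1)) with n the called allele count. Windows are 1-based
inclusive, anchored at position 1, advanced by the step (100 kb / 30 kb
default); window π divides the site sum by the window span in bp, so
π scales with marker density — on a chip panel it is orders of magnitude
below the dense-panel value by construction, and only rankings and ratios
are compared across platforms. Terminal partial windows are kept and
normalised by actual span. The genome-wide π in the diversity report is the
length-weighted mean over non-overlapping 100 kb windows.

F_ST uses the Weir–Cockerham (1984) two-population variance components a
(among populations), b (among individuals within), c (within individuals),
computed per site from per-line sample sizes, allele frequencies and
observed heterozygote fractions; a window reports Σa / Σ(a+b+c) (ratio of
sums). Sites with a line entirely missing or average sample size ≤ 1 are
excluded; negative values are reported unclamped, and empirical quantiles
operate on raw values.

LSBL for focal line X against references Y, Z is (F_ST(X,Y) + F_ST(X,Z) −
F_ST(Y,Z))/2 on non-overlapping 100 kb windows; missing F_ST propagates.
When the focal population is a pair of sister lines (A+B), their samples
are merged into one population before the three pairwise F_ST scans.

Candidate regions: the threshold is the ⌈fraction·N⌉-th largest of the N
non-missing window values (default fraction 0.05), and every window at or
above it is flagged — inclusive ties, so the flagged count can exceed
⌈fraction·N⌉. The joint divergence scan between a line pair flags windows
in the top 5% of F_ST whose log₂(π_X/π_Y) falls in either 2.5% tail, and
labels each with the line of reduced diversity (low tail → X, high tail →
Y). The tail fractions are config-exposed since "elevated" and "extreme"
admit a range of cutoffs. Windows with zero π in either line are excluded
from the ratio quantiles and never flagged: the log is undefined there and
such windows are sparse-panel artifacts.

## Concordance metrics

Per-PC Pearson r after sign alignment only (no Procrustes rotation, since
raw per-component scores are what get compared; a rotation option exists
but is off by default). Diversity agreement: Spearman ρ over lines for He
and π plus an exact-ordering flag — with only four lines the flag is the
primary criterion and ρ is reported for completeness. Candidate regions are
merged (adjacent or overlapping flagged windows fused) before computing
bp-level Jaccard, so overlapping step<window grids don't inflate counts.
Ancestry agreement is the RMSE between Q matrices minimised over all K!
column permutations (K ≤ 8), because components are identifiable only up to
relabelling.

## The simulator

Balding–Nichols drift: ancestral frequencies Uniform(0.05, 0.95); a
population with drift F draws its frequency Beta(p(1−F)/F, (1−p)(1−F)/F),
so the expected pairwise Weir–Cockerham F_ST between two populations
drifted with the same F is ≈ F (verified by simulation in tests).
Hierarchies are built by chaining draws (ancestral → breed → line); lines
in a `shared_ancestry` group reuse one line-frequency vector, emulating
sister lines separated in name only. Genotypes are Binomial(2, q);
optional admixed samples draw each allele from an ancestry chosen by the
sample's proportion vector. Selection spikes deterministically shift a
focal line's frequencies toward fixation (q → q + m(1−q)) inside a stated
interval, so truth regions for scan-recovery tests are known exactly.
Missingness is uniform at a configured rate. One seed drives four named
`numpy` child streams (frequencies, genotypes, positions, missingness).

The default four-line scenario: A (n=20) and B (n=34) share one frequency
vector (line drift 0.05 below breed level); C (n=34, F=0.10) and D (n=40,
F=0.03) drift independently within the second breed; breed-level drift
0.15 on both sides. This makes the breed split the leading axis of
variation, C–D divergence the second, and gives D the highest and C the
lowest heterozygosity — the qualitative orderings the evaluation needs.
Dense panel 50,000 markers over ten 20 Mb chromosomes (one marker per 4 kb,
~25 per 100 kb window), chip panel 5,000 markers ascertained at pooled
MAF ≥ 0.05, missing rate 0.005.

What the simulator does **not** model: linkage disequilibrium and
recombination (markers are independent given line frequencies — LD-pruning
tests therefore use constructed duplicated/perturbed columns), sex
chromosomes, genotyping error beyond uniform missingness, sequencing depth,
and any real chip's spacing rules (thinning is uniform among
MAF-eligible sites). Passing tests on this generator demonstrate the
statistics and their cross-platform behaviour under drift and
ascertainment; they do not demonstrate robustness to LD structure or
platform-specific error modes of real data.

## Problem sizes and determinism

Default analysis sizes were chosen so a full two-platform run and the
model-selection sweep each complete in minutes on one core: 50k/5k markers
for the scenario, 5,000 markers × 90 samples for the three-population CV
sweep with K ∈ {1..6} and 5 folds, 100 bootstrap replicates in the
pipeline (1,000 remains a flag away). All stochastic stages take explicit
seeds and are bit-reproducible; the run manifest checksums every artifact
so reruns can be verified. Floating-point reductions use fixed numpy
orderings throughout.

## Known limitations

* The EM optimiser is slower near convergence than quasi-Newton block
  relaxation; for datasets beyond ~10⁵ sites × 10³ samples a final fit can
  take minutes.
* Windowed statistics assume a shared window grid across platforms
  (anchored at position 1); chromosome lengths default to the maximum
  observed position unless supplied.
* Hudson- or Nei-style F_ST variants are not provided (Weir–Cockerham
  only, with Hudson used as an independent oracle in tests).
* The VCF writer emits the minimal GT-only v4.2 subset the pipeline needs;
  it is not a general-purpose VCF serialiser.
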