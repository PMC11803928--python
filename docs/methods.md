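# Methods

`fawpop` re-implements, as a tested pipeline over synthetic cohorts, the
population-genomic analysis of the two fall armyworm (*Spodoptera
frugiperda*) Z-chromosome strains: site filtering, diagnostic-marker
strain calling, windowed differentiation and diversity statistics, a
permutation test for genomic islands of divergence, and two
selective-sweep scans.  This note documents the models, the numerical
choices, and what the synthetic generator does and does not establish.

## The synthetic cohort generator

The generator is a Balding–Nichols differentiation model.  Each site has
an ancestral frequency p; each population draws its own frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F), whose Fst relative to the ancestral pool is
exactly F, so the Weir–Cockerham estimator is a consistent estimator of
the generating parameter.  Defaults follow the study design:

| parameter | default | meaning |
|---|---|---|
| `fst_z` | 0.671 | between-strain F on chromosome 31 (the Z) |
| `fst_autosome` | 0.086 | between-strain F on chromosomes 1–30 |
| `fst_subpop` | 0.047 | C-strain flyway sub-structure |
| `hybrid_fraction` | 0.03 | F1-like hybrids (≈ the observed 12/412) |
| `missing_rate` | 0.05 | i.i.d. genotype dropout |
| `depth_mean` | 100 | Poisson FORMAT/DP mean (deep WGS) |
| `gq_mean` | 60 | clamped-normal FORMAT/GQ mean (sd 15, clamp 0–99) |

All simulated moths are male (ZZ) — pheromone traps catch males — so the
Z is an ordinary diploid chromosome everywhere and no hemizygosity
handling exists.  Hybrids are F1-like: one haplotype drawn from each
strain's frequency at every site, hence heterozygous with probability 1
at fixed-difference diagnostic markers.  Four such markers (a Tpi
stand-in plus three diagnostic SNPs) are forced to fixed differences on
the Z.  Backcross gradations, recombination maps, demography, and
read-level error are deliberately out of scope: a green test on this
generator establishes estimator correctness and qualitative direction,
never a reproduction of the study's genome-scale numbers.

Two ancestral-frequency modes exist and the choice matters:

* `uniform` (default): p ~ Uniform(0.05, 0.95).  Convenient for
  differentiation statistics, but it over-weights intermediate
  frequencies, so Tajima's D is positive by construction (≈ +1.5 at the
  defaults).  Any D-based null check on this mode would be meaningless.
* `neutral`: p drawn with density ∝ 1/p on (0.002, 0.998).  Integrating
  Binom(j; n, p)/p over p gives exactly 1/j — the constant-size neutral
  site-frequency spectrum — so windowed Tajima's D has median near 0.
  The 0.002 truncation keeps a realized-site fraction high while holding
  the genome-wide D of the density itself below 0.1 (at 0.01 the
  truncation alone pushes D to ≈ +0.36).  All neutrality-null suites and
  the SFS-shape comparisons use this mode.

The sweep injector is all-or-nothing per site: at distance d from the
center, with probability exp(−d/strength) the target group's genotypes
are set to the group-major homozygote.  `strength` is the e-folding
distance in bp; the recorded truth interval is center ± strength.  This
reproduces the diversity trough of a completed hard sweep but not the
intermediate frequency distortion of partially escaped haplotypes.

## Filtering

Per-genotype masking at DP < 6 or GQ < 10 (the thresholds act per
genotype, as in VCFtools `--minDP`/`--minGQ`; GQ is inherently
per-genotype, and a site-level DP reading would make the rule
incoherent), then removal of sites with **more than** 50% missing
genotypes — ties at exactly 50% are retained.  The missing fraction is
evaluated after DP/GQ masking; the ordering is a declared choice, not an
inference.  Chromosome restriction keeps "1".."31" (chromosome 31 is the
Z).  The structure dataset additionally keeps only sites with exactly one
ALT allele and global minor-allele frequency ≥ 0.01, computed over all
samples before any hybrid removal.  Model-based imputation is replaced by
`naive_impute`: either a pairwise-deletion declaration (every statistic
here handles missingness internally) or modal-genotype fill; this is a
documented deviation, and no statistic in the package requires imputed
data.

## Statistics

**Weir–Cockerham Fst.**  The 1984 two-population variance components a
(among populations), b (among individuals within populations), c (within
individuals) are computed per site from sample sizes, allele frequencies
and observed heterozygosities.  Windowed and global estimates are always
ratio-of-sums, Σa / Σ(a+b+c) — never a mean of per-site ratios — which
makes window estimates associative with the global one.  Sites where
a+b+c = 0 are skipped and counted.  Hybrids are excluded upstream from
all between-strain Fst and Dxy.

**π and Dxy.**  Per site with m called alleles of which c₁ are ALT:
diffs = c₀c₁ and comps = m(m−1)/2 within a group; across groups,
diffs = c₁ᴬc₀ᴮ + c₀ᴬc₁ᴮ and comps = mᴬmᴮ.  A window's value is
Σdiffs/Σcomps, so invariant genotyped sites contribute to the denominator
only — the convention of invariant-site-aware Dxy tools.  On SNP-only
input the values are per-SNP rather than per-bp; per-bp diversity needs a
matrix that includes invariant sites.  Dxy drops sites with more than 20%
missing genotypes before computation.

**Tajima's D.**  Standard constants (a₁…e₂), with the window's effective
allele count set to the median called-allele count over its segregating
sites: missing data make n site-specific and the classical formula needs
a single n.  Windows with S = 0, n < 4, or non-positive variance are
missing.

**LD.**  r² is the squared Pearson correlation of unphased genotype
dosages (composite LD) with pairwise deletion; zero-variance pairs are
skipped.  Decay profiles use the eleven fixed distance bins (100 bp to
75 kb), each ± 50 bp; mean and median are both reported because the
upstream convention is ambiguous between them.

**Windows** are non-overlapping tiles anchored at coordinate 0, half-open
[start, end); a 1-based site at P falls in tile ⌊(P−1)/width⌋.  "Sliding"
windows with step = width are exactly these tiles.

## Islands of divergence

Windowed Z-chromosome Dxy is smoothed with a Gaussian Nadaraya–Watson
kernel at the window midpoints (missing windows get zero weight).  The
default bandwidth of 50 kb is a package choice — the upstream smoother is
unspecified — and is configurable; island extents are
bandwidth-dependent, so they are reported with the bandwidth.  The null
permutes the order of the window values over the same positions (whole
chromosome, not blocks), smooths each permutation, and takes the single
most extreme smoothed value anywhere in any permutation as the threshold.
Islands are maximal runs of midpoints whose observed smooth strictly
exceeds it.  By construction the family-wise chance of any island on
exchangeable data is ≈ 1/(n_perm + 1); this is verified empirically.

## CLR sweep scan

The background SFS is estimated genome-wide per population by
hypergeometric projection of every site to a common allele count n
(default: the modal called-allele count; sites below n are skipped) and
is folded (ancestral states are unknown), which makes the spectrum
symmetric.  Deliberate extension: the spectrum keeps the
group-monomorphic classes (counts 0 and n).  In SNP-only data a completed
hard sweep manifests locally as sites that are fixed within the swept
population while still segregating in the full cohort; without the
monomorphic classes that signal is invisible and, with the all-or-nothing
injector above, there would be nothing to detect.  The conventional
polymorphic folded spectrum remains available as
`BackgroundSFS.spectrum`.

At candidate position x, each lineage at distance d escapes the sweep
with probability p_e = 1 − exp(−αd).  Conditional on k of n lineages
escaping, the k escapees plus the single sweeping ancestor are modeled as
a background sample of size k+1 (star-tree approximation); the ancestor's
allele is copied into the n−k swept lineages.  At k = n this is exactly
the background spectrum, so the model nests the null and the per-site
log-ratio is identically 0 in the all-escape limit — CLR is floored at 0.
α is maximized over a fixed 16-point logarithmic ladder (10⁻⁷…10⁻²
per bp), deterministic and testable.  Per-site likelihoods are binned
over αd (48 geometric bins on [10⁻⁴, 25]; beyond 25 the ratio is 0 to
machine precision), which turns a scan into a few matrix products plus
prefix-sum range queries — a full 10 Mb chromosome at 5 kb spacing runs
in well under a second.

Grid size is ⌊length/spacing⌋ points, evenly spaced (segment centers).
Outliers are grid points at or above the pooled genome-wide
99.99th-percentile CLR per population (pooling is switchable to
per-chromosome; the upstream convention is ambiguous).  All-equal grids
are degenerate and yield no outliers.  Refinement reruns the scan at 1 kb
on the outlier chromosome and reports the maximal run of consecutive fine
windows containing the outlier with CLR at or above that chromosome's
99th fine-grid percentile.

## ω scan

Within each 5 kb autosomal evaluation window, the SNPs are split at every
inter-SNP boundary into a left and right block, each truncated to an
extent between `minwin` = 500 and `maxwin` = 2500 bp from the boundary
(units are bp — a declared reading; the upstream units are unstated), on
a 5-point extent ladder.  ω is mean within-block r² over mean
between-block r², maximized over splits and extents; windows with fewer
than 4 SNPs are missing, and a zero between-block sum is capped at the
declared ceiling 10⁶ and flagged.  The scan refuses the Z: pooled-cohort
LD is globally elevated there, so an LD scan would be dominated by false
positives.  Outliers are reported by rank; no formal threshold is
defined.

## PCA

Sites are normalized as (g − 2p̂)/√(p̂(1−p̂)) with the shrunk frequency
p̂ = (1 + Σg)/(2 + 2n_called); missing entries are zeroed after
centering, monomorphic sites dropped.  Components come from the exact
eigendecomposition of the sample covariance, deterministic up to sign
(tests are sign-agnostic).  Percent variance is the eigenvalue over the
covariance trace.  Tracy–Widom component significance and iterative
outlier removal are out of scope.  Pairwise a-priori group Fst reuses the
weighted Weir–Cockerham estimator; pairs with a group of fewer than two
samples are reported missing.

## Known limitations

* The generator has no linkage within populations beyond what strain
  mixing induces; LD decay curves on single-strain synthetic data are
  flat at the 1/n noise floor rather than decaying from a high intercept.
* Per-SNP (not per-bp) diversity on SNP-only input, as noted above.
* The island test's sensitivity depends on the unspecified smoothing
  bandwidth; calls are only comparable at a fixed bandwidth.
* The CLR model detects the loss-of-polymorphism footprint; with no
  partially swept intermediate-frequency classes in the injector, its
  power against soft or ongoing sweeps is untested.
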