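# Methods

`colonpop` implements the population-genetic inference stack used to dissect
the history of a recently introduced, highly selfing plant metapopulation:
multiple introductions from diverged native-range sources, admixture between
an early dominant lineage and later arrivals, purging of deleterious
mutations by admixture, ongoing selection at immunity loci, and an
environmental-similarity signal in shared ancestry. Every stage is
exercisable on a bundled scenario simulator with recorded truth, so the whole
stack is testable without sequencing data.

## Data model

The central object is a site × haplotype matrix of polarized biallelic
alleles (0 ancestral, 1 derived, −1 missing) with physical (bp, 1-based) and
genetic (cM) coordinates. Phasing and polarization are upstream concerns:
VCFs are assumed phased; ancestral states come from an external per-site
table (`polarize` flips or drops sites). Group labels at four hierarchy
levels (*group*, *subcluster*, *cluster*, *region*), as produced by external
haplotype-sharing clustering, are consumed from a TSV, never inferred.

Because the organism is predominantly selfing, a diploid is usually fully
homozygous; `read_vcf(..., haploidize_policy="collapse_homozygous")` collapses
such individuals to one haplotype and sets residual heterozygous calls to
missing. Missing data are handled by complete-case analysis within each
group at each site — no imputation anywhere.

## The scenario simulator

The generator trades coalescent realism for controllable truth:

1. **Source layer.** Ancestral allele frequencies p̄ ~ Uniform(0.05, 0.95);
   each source *g* drifts to p_g ~ Beta(p̄(1−F_g)/F_g, (1−p̄)(1−F_g)/F_g)
   (Balding–Nichols), so the expected Hudson FST between two sources ≈ F.
   A "relict-like" outgroup pool uses a larger F (default 0.5).
2. **Haplotype layer.** Each source pool starts as Bernoulli(p_g) draws
   (default 50 haplotypes) and is passed through R = 30 rounds of
   frequency-preserving pairwise recombination (complementary crossovers;
   Poisson along the genetic map — implemented exactly through per-gap
   crossover-parity switches) plus symmetric mutation flips at
   μ = 10⁻³/site/round. This produces within-source linkage at the scale of
   a few cM without changing the marginal frequencies appreciably.
3. **Colonists.** A colonist haplotype is a Markov mosaic over the sources:
   tract source ~ the group's ancestry proportions, tract length ~
   Exponential(mean 100/switch_rate cM), tract content copied from one
   uniformly chosen pool haplotype. Truth tracts (1-based inclusive bp) are
   recorded. With probability `selfing` (default 0.97) an individual's two
   haplotypes are identical copies. Each lineage also receives private
   post-colonization flips (5 × 10⁻⁴/site), so unrelated individuals are
   never exact duplicates — without this, haplotype-homozygosity statistics
   see artificial plateaus.
4. **Annotation and load design.** Sites are assigned synonymous /
   nonsynonymous-tolerated / nonsynonymous-deleterious categories
   (0.40/0.35/0.25); each source additionally receives a disjoint set of
   *private fixed* deleterious alleles (default 50) — frequency 1 in that
   source, 0 elsewhere. Deleterious alleles are neutral markers with
   constructed frequencies; no fitness machinery is simulated, because the
   load statistics only consume frequency patterns.
5. **Sweeps.** `inject_sweep` overwrites the ±window flank (default 500 kb —
   deliberately long, since selfing suppresses effective recombination and
   recent sweeps in such genomes ride large haplotypes) of randomly chosen
   haplotypes with the flank of one founder (hard) or of k founders (soft)
   until the focal derived frequency reaches the target. The focal site is
   the nearest site to the requested position whose current frequency does
   not already exceed the target.
6. **Environment.** Deme environments are standard-normal per variable;
   the response is y = α_g + Σβ_gk·x + σ·t_ν with group coefficients
   scattered N(pooled, τ) around pooled truth. Defaults put the pooled truth
   at the scale of the study's reported posterior (intercept 0.139, slopes
   −0.064/−0.180/−0.001/−0.232, σ 0.395); τ = 0.3 and ν = 8 are this
   package's chosen realistic heavy-tailed regime.

Everything emitted (VCF, group/category/map/tract/environment TSVs, truth
JSON) is a deterministic function of (config, seed), byte-for-byte.

What the generator does **not** emulate: coalescent genealogies and
realistic site-frequency spectra, background selection, genotyping error and
missingness patterns, RAD-seq ascertainment, real recombination-rate
variation, population growth. Passing tests therefore demonstrate estimator
correctness and qualitative behaviour under a controlled model of drift,
admixture and linkage — not performance on any particular empirical dataset.

## f-statistics

Patterson-style frequency statistics: f2 with the unbiased small-sample
correction; f3(C; A, B) = mean (c−a)(c−b) with optional c(1−c)/(n_C−1)
correction (outgroup form when C is the outgroup, admixture form when C is
the test group — significantly negative ⇒ admixed); f4 = mean (a−b)(c−d);
D = Σ(ABBA−BABA)/Σ(ABBA+BABA) with ABBA = (1−p1)p2p3(1−p4). Sites lacking
the minimum call count in any involved group are excluded per statistic.

Standard errors come from a weighted delete-one block jackknife (Busing
weights proportional to per-block usable-site counts) over contiguous
physical blocks, default 5 Mb, never spanning chromosomes. With equal
weights this reduces exactly to the textbook delete-1 formula. Blocks must
exceed the correlation scale of the data for the variance to be honest; the
simulator's pool linkage (~cM scale) satisfies this, but colonist ancestry
tracts at the default switch rate are chromosome-scale, so calibration
scenarios for jackknife-based tests use a higher switch rate (tracts ≪
block length). This caveat applies equally to real data with megabase LD.

The multi-wave (rank-0) test builds v_j = f4(L1, L2; R_base, R_j) over the
right-group list, estimates Cov(v) by delete-one block jackknife, and tests
v = 0 with Hotelling's T². Because the covariance rests on a finite number g
of blocks, the p-value uses the exact small-sample distribution
χ²·(g−m)/(m(g−1)) ~ F(m, g−m) rather than the asymptotic χ²_m tail (the two
agree as g → ∞; at g ≈ 30 the asymptotic tail nearly doubles the type-I
error). Only the rank-0 hypothesis is implemented — the question the
analysis needs — not the full likelihood rank ladder of ADMIXTOOLS.

## Rare-allele sharing

Sites are ascertained in the reference panel only: derived allele count
within [2, 20] and panel missingness < 10%. For each ascertained allele a
target carries (≥1 derived haplotype; no target-side frequency threshold),
every donor subcluster containing ≥1 panel carrier receives weight
1/(number of carrier subclusters); unweighted counts are reported alongside,
and shares are normalized both by the target's ascertained-allele total and
optionally by donor panel size, since pipelines differ on this point.

## Selection scans

EHH for a carrier class is the fraction of carrier pairs identical (and
fully called) from the focal SNP out to a flanking site; a missing call
permanently removes a haplotype from the pair set. iHS integrates EHH over
cM on the ancestral vs derived background, iHS = ln(iHH_A/iHH_D) (the
analysis downstream uses |iHS|); nSL is identical machinery with distance
counted in segregating sites; XP-EHH compares all-haplotype iHH between two
populations over a shared span (out to where the pooled EHH crosses the
cutoff).

Numerical policy: EHH cutoff 0.05; inter-SNP gaps > 200 kb truncate the
integral and flag the SNP (excluded from standardization, like chromosome-
edge truncation); integration is additionally capped at 1 Mb either side
(100 SNPs for nSL), the usual practice of field implementations — essential
in selfers, where homozygosity can plateau above the cutoff indefinitely.
SNPs with derived frequency outside [0.05, 0.95] or with < 2 carriers in
either class are excluded with flags. Scores are standardized within
derived-frequency bins (default 50; bins with < 2 scores merge into a
neighbor) and converted to genome-wide two-sided empirical p-values,
p_i = #{j : |z_j| ≥ |z_i|}/(N+1). Scans of selfing material should be run on
one haplotype per homozygous individual (the collapse policy's output);
duplicated selfed haplotypes otherwise distort the haplotype spectrum.

Garud's H statistics are computed over exact haplotype strings in SNP
windows (defaults 500 SNPs / step 10 as in the study; haplotypes containing
missing calls are dropped per window): H1 = Σp², H12 = H1 + 2p₁p₂,
H2/H1 = (H1−p₁²)/H1. Hard sweeps give high H12 and low H2/H1; soft sweeps
the reverse. Tajima's D uses the textbook constants in 50 kb / 5 kb windows
on complete-case sites. Hudson FST is the ratio-of-sums estimator per
window (slightly negative values are reported as-is), with significance by
permuting individual labels between the two sets (default 1000
permutations; p = (1+#{perm ≥ obs})/(n_perm+1)).

## Mutational load

For each group × category, ϕ = n_fixed/n_total where "fixed" means derived
frequency exactly 1 among non-missing calls with ≥ 4 calls (the floor guards
single-sample artifacts) and "total" counts sites with any derived allele.
Admixture between diverged founders raises effective population size and
lowers ϕ in every category, so Φ_cat = ϕ_cat/ϕ_syn (and, always emitted
alongside, ϕ_cat/ϕ_genome-wide) isolates category-specific purging: a
specifically depressed Φ_deleterious in admixed groups is the purging
signal. Ancestry proportions are length-weighted (bp) tract sums per
individual, with region-restricted queries for local-ancestry contrasts.
Welch's unequal-variance t (via scipy) serves the category comparisons.

## Hierarchical environmental regression

y_gi ~ StudentT(ν, α_g + Σ_k β_gk x_gik, σ) with α_g ~ N(ā, τ₀),
β_gk ~ N(β̄_k, τ_k); covariates are per-variable absolute differences
(1-D Euclidean distances) between group and reference deme climates,
z-standardized over the design. Priors — stated as this package's
assumptions: ā, β̄_k ~ N(0,1); τ, σ ~ HalfNormal(1); ν ~ Gamma(2, rate 0.1)
truncated at ν ≥ 2. HDI mass is 0.94 (reported as hdi_3%/hdi_97%).

The sampler is written in-package rather than delegated to a PPL: adaptive
random-walk Metropolis vectorized across groups for α_g and β_gk (target
acceptance 0.30–0.45, scales adapted during warmup), conjugate Gibbs draws
for ā and β̄_k, log-scale slice sampling for τ, σ and ν (robust in the
funnel regime where a hierarchical scale collapses), joint translation
moves that shift a pooled mean together with all its group coefficients
(these carry the pooled level through the funnel neck), and two extra
σ/ν slice alternations per sweep because the pair is strongly correlated
under a t likelihood. Defaults: 4 chains, 800 warmup + 800 kept draws.
Split-chain R-hat is computed per parameter; > 1.01 emits a warning,
> 1.1 raises a convergence failure with diagnostics. A single-group design
collapses to a pooled robust regression (N(0,1) priors directly on the
coefficients). Identical seeds and chain counts give identical draws.

## Problem sizes in tests and the acceptance script

Statistical checks run on scaled-down scenarios chosen once: ~2,500–7,500
sites over 4–8 chromosomes of 10–20 Mb, pools of 40–100 haplotypes, colonist
groups of 15–25 individuals; null-calibration suites use 200–500 replicates
and the regression-recovery suite 50 fits of the full 29-group × 158-
reference design at 4 × (500 warmup + 500 draws). These sizes keep every
replicate's estimator in its well-behaved regime (≥ 30 jackknife blocks,
≥ 4,000 scored SNPs per scan) while keeping the whole suite desk-scale.

## Known limitations

- The jackknife assumes blocks longer than the correlation scale; extremely
  long homozygous tracts (near-clonal material) violate this and inflate Z.
- The rank-0 test covariance is a jackknife estimate; with fewer blocks
  than f4 dimensions it falls back to an uncorrected chi-square tail.
- EHH-based scans are integration-capped; in near-clonal populations the
  capped integrals compress extreme scores rather than letting them diverge.
- RAS attribution assumes the panel contains relatives of the true sources;
  alleles private to the target contribute no signal.
- The regression's Metropolis-within-Gibbs mixes more slowly than gradient
  samplers for strongly correlated group coefficients; R-hat is reported so
  under-mixing is visible, and iteration counts are configurable.
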