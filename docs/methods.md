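# Methods

This note documents the models, estimators and numerical choices behind
popkit, what the synthetic-data generator does and does not emulate, and
the places where the design was genuinely open.

## Data model

All accessions are treated as fully inbred lines: each carries a single
allele per site, so genotypes are haploid-equivalent and the bi-allelic
matrix is binary (0 = reference allele, 1 = site alternative allele).
Residual heterozygosity is assumed absent — consistent with the
homozygous-SNP filter upstream, which discards any call whose
alternative-read fraction is ≤ 90%. Everything downstream (p-distance,
PCA normalisation, admixture likelihood, haplotype diversity, LD)
uses this haploid representation; diploid or heterozygous data are out
of scope.

## Consensus SNP calling

Per accession and caller, a call is kept iff position read depth
≥ `min_depth` (default 5) and alt fraction > `min_alt_frac` (default
0.90). "Above 90%" is implemented as a strict inequality; the boundary
case (e.g. 9/10) is dropped. When a coverage track is supplied, the
depth bound is checked against it rather than against the
caller-reported DP (coverage is the authority on how deep the position
really is; disagreements are counted and logged); the alt fraction
always uses the caller's own read counts, which are the only estimate
of allelic balance available. The consensus is the allele-aware
intersection of the three callers' filtered calls: chromosome, position,
reference and alternative allele must all match. Record metadata of
surviving calls (alt_reads, depth) is taken from the first call set —
an arbitrary but fixed choice.

## Concordance categories

The five categories (identical_A/B/C, different_call, rnaseq_only) are
evaluated in a fixed precedence order so that the result is always a
partition. identical_B counts SNPs matching one or two (not three)
filtered per-caller exome sets; "raw" for identical_C is the union of
the three exome callers' unfiltered outputs; different_call requires a
positional hit with a different alternative allele anywhere in the raw
union — the broadest reading of "inconsistent". rnaseq_only does not
require the exome to have had coverage at the position; an optional
minimum-exome-depth gate would reclassify uncovered positions but is not
applied by default.

## Bi-allelic matrix

Candidate sites are the union of per-accession consensus positions. The
three criteria — called in ≥ 1 accession, depth ≥ 5 in all accessions,
third alleles in < 10% of accessions — are applied with the reference
accession included in the denominator of the third-allele fraction
(panel of 20 + reference = 21 in the motivating design). Two readings of
the construction were open:

- **Covered-but-uncalled → reference.** This is the only reading under
  which a matrix with *no missing data* is achievable: the depth
  criterion guarantees every accession is covered ≥ 5× at every kept
  site, so absence of a call is evidence for the reference allele, not
  missingness.
- **Minority third-allele carriers → recoded to reference** (default)
  rather than dropped, preserving the no-missing-data guarantee while
  honouring the < 10% tolerance; `recode_third_allele=False` excludes
  such sites instead.

The site's alternative allele is the plurality alt among calling
accessions, ties broken alphabetically (A < C < G < T) for determinism.

## Tree and PCA

p-distance is the proportion of differing sites; pairwise identity is
its complement, and the two are computed from the same difference-count
kernel so they agree to machine precision. Neighbour joining follows
Saitou–Nei exactly: join the pair minimising
Q(i,j) = (n−2)D(i,j) − r_i − r_j; branch lengths
l_i = D(i,j)/2 + (r_i−r_j)/(2(n−2)). Ties on Q are broken by the
lexicographically smallest joined label pair, making output independent
of platform iteration order. Negative branch lengths are clamped to
zero with the deficit moved to the sister branch, preserving the pair's
total length. On additive inputs NJ is exact; the test suite verifies
topology and branch lengths against a path-distance oracle for 4–7 taxa
and against scikit-bio's independent implementation.

PCA centres each polymorphic column and, by default, scales it by
√(p̂(1−p̂)) with p̂ = (1 + Σg)/(2 + n) — the shrunken allele-frequency
estimator in haploid form (n alleles observed, one per accession; the
diploid convention would use 2n). Raw (unnormalised) PCA is available
via a flag since the upstream tool's default is ambiguous. Scores are
eigenvectors of the accession covariance scaled by √eigenvalue, so
variance along PC k equals eigenvalue k.

## Admixture model

The sampler implements the classic admixture model specialised to
haploid genotypes: z[a,s] ~ Categorical(q[a]); x[a,s] ~ Bernoulli(p[z,s]).
Priors: p ~ Beta(λ, λ) with λ = 1 (uncorrelated frequencies — the
standard default), q ~ Dirichlet(α,…,α) with α shared across accessions,
uniform on (0, 10] and updated by a random-walk Metropolis step
(proposal sd 0.05). Gibbs sweeps update z, p, q, α in turn; all draws
come from one seeded generator, so runs are reproducible to the bit.
Reported Q and P are posterior means over post-burn-in sweeps; L(K) is
the mean data log-likelihood Σ log Σ_k q[a,k] P(x[a,s] | p[k,s]) over the
same sweeps. `reps` counts post-burn-in sweeps.

Evanno's ΔK uses replicate-wise second differences:
ΔK = mean_r |L_r(K−1) − 2L_r(K) + L_r(K+1)| / sd(L(K)), with the
across-replicate sd (ddof = 1). A zero sd with non-zero signal is
reported as infinity; zero sd with zero signal as 0 with a warning.
The documented full profile is 30,000 burn-in / 60,000 kept sweeps with
three runs per K over K = 1..15; tests and the default pipeline use a
desk-scale profile (burn-in 500, 2,000 kept sweeps, ≤ 500 sites), which
is sufficient for the well-separated synthetic panels — posterior-mean
Q errors are below 0.03 there — but underestimates uncertainty on real,
weakly structured data.

## Windowed statistics

Windows are non-overlapping tiles of width w (default 5 Mb, the last
window truncated). "Sliding" windows with a step smaller than the width
were considered; tiling (step = width) was chosen as the default because
no step was specified for the motivating analyses and tiled tracks are
the common genome-browser convention; the width is configurable.

Haplotype diversity per window is Nei's Hd = n/(n−1)(1 − Σp_i²) over the
group's window haplotypes. Windows with no sites are undefined (NaN),
never zero-filled; windows whose sites are monomorphic in the group give
Hd = 0. Note that Hd saturates at 1 when windows hold many sites
relative to the sample (every haplotype distinct); comparisons between
groups are informative when windows carry roughly as many sites as there
are accessions, which guides the window sizes used in the tests.

F_ST is Hudson's 1 − Hw/Hb: Hw is the mean pairwise difference count
within groups (averaged over the two groups), Hb the mean between-group
pairwise difference count, both summed over the window's sites.
Estimates are clamped to [0, 1]; Hb = 0 windows are undefined and
excluded from the genome-wide mean. Hudson's estimator was chosen over
Weir–Cockerham/Nei variants because it is simple, well-defined for
haploid data, and unbiased under the generator's model (for two groups
at Balding–Nichols divergence F its expectation is F, which the tests
verify). Absolute F_ST values from other estimators differ; only
orderings should be compared across estimators.

## Linkage disequilibrium

Haplotypes are observed directly (inbred lines), so no phasing or EM is
needed. For a site pair, D = p_AB − p_A p_B,
r² = D²/(p_A(1−p_A)p_B(1−p_B)), D′ = |D|/D_max with D_max the usual
sign-dependent bound. Defaults follow Haploview where the motivating
analysis was silent: 500 kb maximum pair distance, MAF ≥ 0.05.

Decay curves bin pairs by distance (default 1 kb bins); the half-decay
distance is the midpoint of the first bin whose mean r² falls to half
the first non-empty bin's mean (undefined if never reached). Note the
estimator r̂² has an upward bias of roughly 1/n, which flattens the far
tail for small panels.

Blocks use the Gabriel confidence-interval rule: a two-sided 90% CI on
D′ is obtained by normalising the multinomial likelihood of the four
observed two-locus haplotype counts over a D′ grid (step 0.001, allele
frequencies at their MLEs, D signed as observed). A pair is strong LD if
CI ∈ [≥ 0.70, ≥ 0.98], strong recombination if the upper bound < 0.90;
other pairs are uninformative. A site range qualifies as a block when
≥ 95% of its informative pairs are strong LD; maximal non-overlapping
blocks are selected greedily, longest bp span first, ties to the
leftmost. A minimum-span filter (e.g. ≥ 10 kb) is an output option, not
part of detection.

## Synthetic-data generator

The generator emulates the downstream products of an RNA-seq variant
study on a structured crop panel — two diverged sub-populations plus
admixed accessions — not the reads themselves.

- **Group frequencies.** Ancestral frequency p ~ Uniform(0.05, 0.95)
  (bounded away from fixation so sites are plausibly polymorphic); each
  group's frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) — the
  Balding–Nichols distribution, mean p, variance F·p(1−p). This gives
  direct control of the target F_ST at O(sites) cost, unlike a full
  coalescent; F = 0 is the point-mass case, F = 1 is rejected.
- **Haplotypes.** Donor mosaics: along a chromosome the current donor
  group persists across a gap of d bp with probability exp(−c·d) and is
  otherwise re-drawn from the accession's ancestry proportions; alleles
  are Bernoulli draws from the donor's site frequency. For admixed
  accessions this induces LD that decays on the tract scale 1/c
  (r² ∝ exp(−2cΔ), so the measured half-decay sits below 1/c); pure
  accessions have independent sites. Default c = 2×10⁻⁴ (5 kb tracts),
  matching the kb-scale decay reported for selfing crops.
- **Caller emulation.** Per-base depth ~ Poisson(λ) (λ = mean of the
  three profiles), shared across callers, since real callers read the
  same alignments. True alt sites get alt reads ~ Binomial(depth, 1−ε),
  ε = 0.01 by default (configurable; ε = 0 gives strictly noise-free
  fixtures); each caller misses a site independently with its fn_rate.
  False positives are placed uniformly at covered non-SNP positions at
  fp_rate per Mb and drawn from the same homozygous-looking read model —
  making them pass the per-caller filter but not the three-way
  intersection, which is the failure mode the consensus is designed to
  remove. A guard rejects profiles whose expected false calls exceed
  half the true calls. Default profiles give one conservative caller
  (fn 0.10, fp 2/Mb), one permissive (fn 0.02, fp 20/Mb) and one
  intermediate (fn 0.06, fp 8/Mb), echoing the rank pattern of
  freebayes / glfMultiples / samtools call counts.

What the generator does **not** emulate: read-level artefacts (mapping
bias, paralog collapse, allele-specific expression), expression-dependent
coverage structure of real RNA-seq (coverage here is genome-wide
Poisson), indels and multi-nucleotide variants, residual heterozygosity,
and linkage within pure groups (only admixture LD is modelled). Passing
tests therefore demonstrate correctness of the estimators and filters
under a known model, not robustness to those real-data artefacts.

## Problem sizes and determinism

Tests and the acceptance script run on deliberately small panels
(hundreds of sites, tens of accessions, desk-scale MCMC) chosen so each
statistical check has adequate power while the whole suite stays fast;
the generator and samplers scale to larger designs unchanged. All
randomness flows from explicit seeds through `numpy.random.default_rng`;
the pipeline writes plain text with fixed float formatting, so identical
configs and seeds reproduce every artifact byte-for-byte, MCMC included.

## Known limitations

- Haploid-only: no diploid genotype support anywhere in the chain.
- The admixture sampler has no linkage model and no location prior;
  label switching is handled only by post-hoc permutation matching.
- The Gabriel block scan is quadratic in sites per chromosome; it is
  intended for SNP densities where candidate spans hold at most a few
  hundred sites.
- The concordance module compares call sets, not genotypes: it does not
  weight categories by depth or quality.
- NJ is O(n³) with a Python inner loop — fine for panels of tens to a
  few hundred accessions, not for thousands.
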