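# Methods

`whalepop` re-implements, as a tested library, the population-genomic
analysis of a two-deme baleen-whale system: a large, recently whaled
Eastern North Pacific (ENP) population and a small, long-isolated Gulf of
California (GOC) population.  All analyses run on synthetic data with the
statistical structure the real study assumes; nothing requires sequence
downloads.

## Genotype data model

The core container is a diploid genotype matrix over biallelic variant
sites (derived-allele dosage 0/1/2, −1 missing) plus per-site functional
annotations (NEU/SYN/TOL/DEL/LOF with SIFT scores for coding sites) and an
aggregate account of monomorphic callable sites.  Monomorphic sites are
never materialised row-by-row: heterozygosity denominators and the SFS
0-bin only need their counts and per-population called-haploid tallies.

Synthetic genotypes come from msprime under the demographic-model
catalogue.  Sequencing noise is emulated at the genotype level: depth is
negative-binomial around a configurable mean, allele balance and genotype
quality come from a binomial read-support model with a small base-error
rate.  The filter cascade then mirrors the study design: genotypes failing
depth (min 8 reads, max 2.5× mean), GQ (min 20) or allele-balance rules
(hom-ref ≥ 0.9; het 0.2–0.8; hom-alt ≤ 0.1) become missing; sites with
>20 % missing or >75 % heterozygous genotypes are dropped.  The cascade is
idempotent.  Repeat/CpG masking is not emulated; the synthetic genome is
fully accessible.

## Site frequency spectra

Folded spectra are built from per-site (derived count d, called haploids
n) tallies, projected to a common haploid size m by hypergeometric
resampling — each site with n ≥ m contributes mass P(j | n, d, m) to class
j — and folded to minor-allele classes *after* projection (folding first
is not equivalent: the minor allele of the full sample need not be minor
in a subsample).  Projection sizes can be chosen to maximise retained
polymorphic mass.  Monomorphic sites enter the 0-bin (or (0,0) cell of the
joint spectrum) only when called in at least the projection size in every
population.  Projected masses stay real-valued; rounding half-up happens
only on text export (dadi-style flat format).

## Demographic inference

**Expected spectra.**  For piecewise-constant single-population histories
the expectation is analytic: the lineage-count process of the coalescent
is a pure-death chain with rate C(k,2)/2N(t); within each constant-size
epoch, one block matrix exponential yields both the end-point distribution
of the number of ancestral lineages and the expected occupation time
E[T_k] of each state.  The ancestral epoch contributes 2N·P(≥k lineages
on entry)/C(k,2).  Expected class masses follow from E[ξ_i] = μL Σ_k k
E[T_k] C(n−i−1, k−2)/C(n−1, k−1).  This formulation is numerically stable
at n = 44 where alternating-sum closed forms lose precision.  Expected
spectra for structured two-population models are Monte-Carlo: branch-mode
allele-frequency spectra averaged over independent msprime trees, with a
per-cell standard error.  The two engines agree within Monte-Carlo error
on single-deme models (tested).

**Fitting.**  The composite likelihood is multinomial over folded SFS
classes with the monomorphic bin masked (SNP-only); θ = 4·N_ANC·μ·L is
recovered afterwards by matching the total segregating-site mass, which
anchors scaled parameters (sizes relative to N_ANC, times in 2·N_ANC
generations) to diploids and generations (25.9 yr/generation for year
conversions).  Optimization is Nelder-Mead in log-parameter space with
log-uniform multi-starts; the spread between the best and 10th-best
restart is recorded for the convergence criterion.  The catalogue covers
1–4-epoch single-population models and the split-with-migration family
(no/symmetric/asymmetric migration, ancestral size change, whaling-era
change, isolation window, GOC change); two-population models are
expressed in physical units and converted to msprime demographies.

**Recent-contraction fits.**  A generations-old crash leaves only a
singleton-class deficit, so current size and crash time lie on a
likelihood ridge.  `fit_recent_contraction` pins the final epoch duration
in generations (the fixed-T model variants) self-consistently through the
θ anchor, using the parameter-free constant-size model for the initial
anchor so a degenerate multi-epoch restart cannot derail it.

**Uncertainty.**  Likelihood-ratio tests for nested models use
−2(ll_simple − ll_complex), floored at zero, against chi-square.
Parametric bootstrap CIs are point ± 2 SD of bootstrap re-estimates, with
three engines: multinomial SNP resampling (the classical SNP-based
scheme — which understates width under linkage), a coalescent engine that
simulates whole spectra with recombination under the fitted model (used
for the recovery validation), and a degenerate no-noise engine for
optimizer-only spread.  Bootstrap refits seed one restart at the
empirical MLE.  Grid search over (current size, crash time) reports the
region within two log-units of the grid maximum.

## Heterozygosity, F_ST, ROH, kinship

Heterozygosity is heterozygous genotypes over called genotypes (including
monomorphic), reported per kb, genome-wide and in non-overlapping 1-Mb
windows (windows >80 % missing masked).  F_ST is the Weir–Cockerham
variance-components estimator with ratio-of-sums multi-locus combining
and a 999-label-permutation p-value; the substructure inflation factor is
1/(1−F_ST).  LD pruning is greedy within 500-kb windows (step 100 kb) at
r² ≤ 0.2 and MAF ≥ 0.10 (window geometry is this package's choice).
Kinship is the PLINK-style method-of-moments IBD estimate from pooled
allele frequencies, kinship = k2/2 + k1/4.

ROH calling is a two-state (autozygous / Hardy–Weinberg) Viterbi HMM over
genotypes with a fixed genotype-error emission (default 10⁻³, emulating a
likelihood-free caller), distance-scaled transitions (default one switch
opportunity per Mb, autozygosity prior 0.05 — defaults set by
planted-tract recovery, which locates 2-Mb tracts to <50 kb), and a
100-kb reporting floor.  Segments are classed short [0.1, 1) Mb,
intermediate [1, 5) Mb, long ≥5 Mb; F_ROH divides qualifying length by
the callable genome.  ROH classes are dated by t = 100/(2·E[L]·r) with
r = 1 cM/Mb.

## Deleterious variation

Coding sites are classed synonymous, tolerated (SIFT ≥ 0.05), deleterious
(SIFT < 0.05) or loss-of-function; the most severe effect wins.
Per-individual derived-allele counts (additive proxy, h = 0.5) and
derived-homozygote counts (recessive proxy, h = 0) are normalized by mean
called genotypes over the individual's called genotypes.  The relative-
accumulation statistics are implemented exactly as defined:

    L_X,notY  = Σ_i (d_X/n_X)(1 − d_Y/n_Y)
    L²_X,notY = Σ_i [1 − 2 d_X(n_X−d_X)/(n_X(n_X−1))]·[2 d_Y(n_Y−d_Y)/(n_Y(n_Y−1))]
    R_XY = L_X,notY / L_Y,notX     R²_XY = L²_X,notY / L²_Y,notX

Sites ancestral-monomorphic in both populations are excluded; homozygote
sums additionally require n ≥ 2 in both populations (excluded-site count
reported).  Standard errors come from a weighted delete-one-block
jackknife on the log-ratio scale (50 contiguous equal-count blocks by
default) with a two-tailed Z test against R = 1.  R_XY(X,Y)·R_XY(Y,X) = 1
holds exactly.

## Forward simulation of genetic load

A discrete-generation Wright–Fisher engine: fitness-weighted parent
sampling with multiplicative fitness (het 1+hs, hom 1+s; s < 0),
per-gamete Poisson crossovers and mutations, migration as a binomial
fraction of offspring drawn from the source deme's fitness-weighted pool.
Nonsynonymous mutations arise only in exons at 2.31 : 1 to synonymous;
selection coefficients are gamma (shape 0.186, mean |s| 0.01314 — the
human-inferred distribution, an externally sourced default) with
dominance h = 0 for s < −0.01, h = 0.1 for −0.01 ≤ s < −0.001, h = 0.4
for −0.001 < s ≤ −10⁻⁵, smaller effects treated as neutral.  Genome
layout tiles multi-exon genes (150-bp exons, 8 per gene, 1.5-kb introns)
at a configurable exonic density.  Tracked statistics per deme: genetic
load (1 − mean multiplicative fitness relative to a mutation-free
genotype, globally fixed deleterious sites included), mean per-site
heterozygosity, F_ROH from homozygous tracts between observed
heterozygous positions (per-site θ is preserved by the rescaling, so
observed-het tracts measure the same quantity as the empirical F_ROH;
full identity-by-descent pedigree bookkeeping is not maintained), and
mean per-individual counts of strongly/moderately/weakly deleterious
alleles.

**Rescaling.**  `rescale_config` applies the standard λ transformation
(N/λ, t/λ, μλ, rλ, sλ, mλ), preserving θ = 4Nμ, ρ = 4Nr, N·s, N·m.
Standard rescaling does *not* preserve absolute load: Haldane's load is
governed by the per-diploid deleterious mutation rate U = 2μL_exon, which
grows λ-fold.  The `shrink_genome` option therefore also divides the
segment length by λ, keeping U — and hence load — invariant while leaving
per-site θ and all selection-drift ratios unchanged.  Rescaled |s| is
capped just below 1 (effectively lethal homozygotes).

**The two-deme load experiment** uses the fitted demography (ancestral
16,000 → 25,000 diploids 4,322 generations ago; split 616 generations
ago into 17,386 and 114 diploids; migrant fractions 3.42×10⁻³ into the
small deme and 9.24×10⁻⁵ into the large one), with and without
migration.  Desk-scale choices, made once:

* λ = 14.25, so the small deme is exactly 8 diploids (no integer-rounding
  distortion of N·m) and only ~5 % of the DFE mass hits the lethal cap;
* burn-in 10× the ancestral (scaled) size, per the study design;
* exonic density 7 % of the simulated segment.  The construction cited
  for the original genome layout is not reproduced in the source; 1.3 %
  (human-genome-like) exonic sequence caps equilibrium load near 1 %,
  which cannot produce the reported ~3 % large-deme load.  The density
  was therefore set by inverting Haldane's load analytically
  (load ≈ 1 − e^(−cU) with c ≈ 1 for this DFE/dominance mix) to match
  the reported large-deme equilibrium load, before any two-deme runs;
* neutral mutations are not materialised in the forward engine — they
  never touch fitness — and neutral diversity statistics come from a
  coalescent companion (`fin_whale_neutral_diversity`) run at *full*
  scale, which gives the model's neutral expectation without any
  rescaling artifact;
* replicates share ancestral burn-ins: each saved burn-in state is
  forked into several post-split runs per scenario variant, with
  matching fork seeds across variants (the standard burn-in-reuse
  recipe).  The post-split era is ~43 scaled generations, so forks are
  cheap and most of the replicate budget goes to independent ancestral
  states.

**What desk scale does and does not show.**  Means across forks reproduce
the direction and rough magnitude of the full-scale experiment (small
deme load above large deme; isolation above migration; strongly
deleterious alleles purged in the small deme).  Per-fork contrasts do
not: at λ = 14.25 the small-deme load is dominated by a fixation lottery
over a handful of moderate-effect mutations (per-fork spread comparable
to the mean), whereas at full scale thousands of small-effect mutations
make the load distribution tight.  Pairwise orderings that hold in every
replicate at full scale hold only on average here.  Separately, the
heterozygosity contrast between demes under the fitted parameters is
~40 % by exact coalescent computation (and ~35 % in forward runs with
background selection), larger than the originally reported 26.7 %; the
package reports its own computed value.

## Numerical choices and degenerate inputs

Zero-duration epochs are skipped; collapsed parameter bounds evaluate the
pinned point; expected-mass floors (10⁻³⁰⁰) guard log-likelihoods;
projection requires m ≥ 2; F_ST is undefined on monomorphic-only input
(error); kinship requires a minimum genotype overlap; ROH segments below
the floor are silently dropped; multi-allelic VCF records are skipped
with a warning and counted.  All stochastic operations take explicit
seeds and are bit-reproducible given them.

## Known limitations

* The Monte-Carlo joint-SFS engine makes two-population fitting slow at
  the default tree counts; single-population fitting is analytic and fast.
* The forward engine keeps dense haplotype matrices; very large scaled
  sizes (λ < ~7 for this demography) become memory/time bound.
* The noise model is a caricature of real sequencing (no mapping bias,
  no site-level quality correlation); it exists to exercise the filter
  semantics, not to simulate instruments.
* Neutral-site omission in the load scenario removes background-selection
  feedback on diversity inside the forward runs; the coalescent companion
  is strictly neutral.
* The ghost-deme model variants are expressible in the catalogue but not
  exercised by the acceptance pipeline.
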