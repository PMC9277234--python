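# Methods

This note documents the models, defaults and design choices behind
`symbiopleio`. It covers what each stage computes, what the synthetic-data
generator does and does not emulate, and the numerical decisions a
maintainer would need to know.

## Synthetic study generator

The generator emulates the data layout of a natural-isolate rhizobium panel
study at desk scale. Defaults (all in `SimConfig`) are S = 100 strains,
L = 5000 biallelic SNPs, 4 subpopulations at Fst = 0.1, 2% missing calls,
two host lines analysed separately throughout.

**Genotypes.** Per site an ancestral allele frequency is drawn
Uniform(0.05, 0.95); subpopulation frequencies are Beta-distributed around
it with variance parameter Fst (Balding–Nichols), and haploid strains carry
Bernoulli alleles at their subpopulation's frequency. Sites are split over
three replicons in proportion 0.54/0.21/0.25, mirroring the relative sizes
of the *S. meliloti* chromosome, pSymA and pSymB, and tiled into contiguous
non-overlapping genes with geometric lengths (mean 10 sites/gene). No
coalescent ancestry or linkage beyond what the shared subpopulation
frequencies induce; LD-driven phenomena (e.g. significant hitchhiking
neighbours of causal sites) are therefore under-represented relative to
real data, and tests on synthetic panels say nothing about LD handling.

**Planted effects.** Each causal "pair" is a single pleiotropic variant
with signed effects on two traits: same sign for concordant pairs, opposite
for discordant. Pair templates alternate between symbiotic combinations
(one rhizobium proxy × one plant proxy) and rhizobium-fitness combinations
(two rhizobium proxies); each pair acts on both hosts with probability
`host_shared_fraction` (default 0.5). Defaults plant 3 concordant + 3
discordant pairs with standardized effect 3.0. Two deliberate choices:

- *Sparse architecture.* Effects enter traits additively, so a trait
  carrying k causal variants has its standardized per-variant effect
  diluted by roughly 1/sqrt(k); a heavily polygenic large-effect
  architecture makes every individual variant undetectable by construction.
  The defaults keep roughly ≤2 causal variants per trait × host cell.
- *Moderate causal frequency.* Causal sites are drawn from MAF 0.1–0.3.
  Per-allele effect sizes scale inversely with dosage SD, so common causal
  variants saturate below the family-wise threshold while very rare ones
  carry no power; the 0.1–0.3 window is the detectable large-effect regime
  the analysis targets.

**Phenotypes.** Per host and trait, a strain's genetic value is the causal
sum plus a polygenic term drawn through the square root of the realized
kinship matrix (computed by the same routine the GWAS uses), scaled so
σ²_g/(σ²_g + σ²_e) equals `h2_polygenic` (default 0.3) with residual SD
`noise_sd` = 0.5. Single-strain traits are observed `reps_per_strain` = 4
times with a random rack assignment (3 racks, rack effects N(0, 1)) and
residual noise — matching a greenhouse design with rack as the nuisance
factor. The relative-fitness trait has no replicate rows; its genetic value
defines competitive fitness `w = exp(selection_gradient · z)` with z the
standardized breeding value.

**Pools.** Initial strain frequencies are equal by default (an option
perturbs them with a symmetric Dirichlet); one multiplicative selection
round gives final frequencies f_end ∝ f_init · w. Per pool and site, depth
is Poisson(`mean_depth` = 200) and the alternate count Binomial(depth,
(G f)_site). Six pools per host and timepoint. Real pooled sequencing adds
library and mapping biases not modelled here.

All draws route through per-stage children of a single seed; identical
configs reproduce byte-identical outputs.

## Strain means and correlations

EMMs come from the additive fixed-effect model `value = strain + rack`,
fitted by least squares with a pseudo-inverse, evaluated at the unweighted
average over rack levels — the standard marginal-means convention for a
two-factor design without interaction. Confounded designs (a strain seen in
a single rack of a singular layout) warn and fall back to the
pseudo-inverse solution rather than failing. A mixed model with random rack
was considered and rejected: the fixed-effect correction is sufficient at
these replicate counts and is exactly verifiable. Pairwise trait
correlations are Pearson r with the two-sided slope test; relative fitness
enters as the per-strain median of log2 fold-change across pools. No
multiple-testing correction is applied across the correlation grid — the
stars are per-pair raw significance, a deliberate caveat. Chlorophyll A is
analysed untransformed by default (`log_chlorophyll` flips this).

## Pool-frequency reconstruction and relative fitness

With known strain genotypes G (sites × strains, 0/1) and a pool's
alternate-allele fractions y, the frequency vector solves

    min_{f ≥ 0, Σf = 1}  Σ_sites w_site (y_site − (G f)_site)²

with depth-proportional weights normalized to sum to one (making the
objective and the 1e-8 gradient-mapping stopping tolerance scale-free).
The likelihood-based haplotype reconstruction used with real pool-seq data
targets the same estimand; the constrained least-squares form is convex and
deterministic, and the residual is reported so poor fits are visible.
The solver is monotone accelerated projected gradient (FISTA with a
monotonicity safeguard), step 1/L from the exact Hessian spectral norm,
capped at 10 000 iterations. Sites with zero depth, panel MAF < 0.05 or any
missing strain genotype are excluded.

Relative fitness per strain is `(f_final + pseudo)/(f_init_mean + pseudo)`
per pool, summarized as the cross-pool median within a host (pools are
never merged across hosts). The default pseudo-frequency is half a read at
the median-depth site, 1/(2·median total depth), keeping log2 fold-changes
finite; per-pool-then-median was chosen over pooling frequencies across
plants first, since it is robust to a single aberrant pool.

## Mixed-model association

The per-variant model is `y = 1α + xβ + u + ε` with `u ~ N(0, σ²_g K)`,
`K = X_c X_cᵀ/L` over filtered, mean-imputed, column-centered genotypes.
λ = σ²_g/σ²_e is estimated once per trait by REML on the intercept-only
model — eigen-rotation makes the covariance diagonal, the profile REML
criterion is scanned on a 51-point log grid over [1e-5, 1e5] and refined by
bounded Brent — rather than per SNP; at these panel sizes the per-SNP
refinement changes nothing detectable and the single fit keeps permutation
re-runs cheap. A grid-boundary λ is flagged on all results of that run.
Per site, generalized least squares in the rotated basis gives β, se(β) and
a Wald t test with n − 2 degrees of freedom. Trait vectors are standardized
to unit variance so β is comparable across proxies when signing pleiotropy;
raw-scale betas are emitted alongside. Missing genotypes are mean-imputed
for testing only. GWAS runs on per-strain summaries (EMMs; log2 fold-change
median for relative fitness), one value per genotype.

## Permutation significance

Family-wise thresholds come from permuting the trait vector across strains
(B = 1000 by default, α = 0.05), re-running the full scan with λ
re-estimated, and recording the maximum |β| and minimum Wald p. The
threshold is the ⌈(1−α)B⌉-th order statistic of the null maxima; a variant
is significant when its observed |β| reaches it. The max-|β| statistic
mirrors the effect-size framing of the downstream sign analysis; the min-p
variant is recorded too, and on panels with homogeneous allele frequencies
the two select identical variant sets. Permuting y breaks the
genotype–phenotype link while preserving LD and the kinship spectrum —
standard and conservative. Note that with heterogeneous MAF the |β|
threshold is driven by low-MAF sites (largest standard errors), which makes
it conservative for common variants.

## Pleiotropy classification

A variant is pleiotropic if significant for ≥2 traits on the same host.
Categories: rhizobium-fitness pleiotropy (≥2 of nodule number, nodule
weight, relative fitness) and symbiotic pleiotropy (≥1 rhizobium proxy and
≥1 of shoot biomass, chlorophyll A); a variant can hold both. Sign labels
are per trait pair (a three-trait variant contributes three labels),
computed on standardized-trait betas, with concordant ⇔ β_x·β_y > 0.
Summary percentages use the union of variants significant for either trait
of the pair as denominator. Variants map to the gene whose interval
contains them (1-based inclusive); intergenic variants keep a null gene id
and are excluded from selection scans.

## Neutrality statistics and category tests

Per gene, complete-case strains (no missing call across the gene's sites;
minimum 4) contribute to S, singleton count η_s, π (mean pairwise
differences; reported both total and per bp of gene length), Watterson's
θ_W = S/a_n, Tajima's D with the 1989 variance constants, and the
outgroup-free Fu & Li D* and F* built on singletons (an outgroup would be
needed for the unstarred variants; none exists for a single-species panel).
n = 2 genes give D = 0 exactly (π ≡ θ_W); monomorphic genes report the D
statistics as missing, never zero. The vectorized implementations are
pinned by a brute-force dual implementation (explicit pairwise Hamming
distances, term-by-term constants) in the test suite, and Tajima's D
additionally agrees to machine precision with tskit's site-mode statistic
on coalescent simulations.

The focal-category test formalizes a category-vs-null comparison: the null
pool is all genes containing GWAS-significant variants; the focal mean of a
statistic is compared with means of 1000 size-matched subsets drawn without
replacement from the pool, two-tailed empirical
p = (1 + #{|null − grand| ≥ |focal − grand|})/(reps + 1), flagged at
p < 0.1. Statistics are pooled across replicons for the test.

## Pipeline and determinism

Stages communicate only through declared file artifacts (VCF, GFF3, CSV,
TSV, JSON) in a run directory and are skipped when outputs are newer than
inputs, so deleting one intermediate re-executes exactly the downstream
stages. The manifest lists the config echo and sha256 checksums of every
artifact and is byte-identical across same-seed runs; wall-clock stage
timings are written to a separate `timings.json` so they cannot break
reproducibility comparisons. Default problem sizes (S = 100, L = 5000,
B = 1000, 1000 resampling reps) keep a full run under a minute on one CPU;
a field-scale panel (≈200 strains, tens of thousands of SNPs) is
reachable by config. The FWER and sign-recovery experiments in
`scripts/acceptance.py` use reduced per-dataset sizes (50–100 strains,
200–1000 sites, B = 300–500) chosen so that repeated whole-pipeline
replication remains cheap; the statistics they estimate are
size-calibrated, not size-dependent.

## Known limitations

- No LD beyond population structure: hitchhiking, multi-locus genotype
  packaging and LD-induced clustering of significant variants are not
  exercised by the synthetic panels.
- The |β|-based family-wise threshold is conservative for common variants
  when allele frequencies are heterogeneous (see above).
- The neutrality statistics assume the infinite-sites, biallelic setting of
  the simulated panels; recurrent mutation is not handled.
- The generator's selection model is a single multiplicative round; real
  select-and-resequence experiments involve nodulation sampling bottlenecks
  that add extra-binomial noise.
- Host lines are modelled as independent studies; shared environmental
  covariance between hosts is not simulated.
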