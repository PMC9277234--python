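# symbiopleio

Cooperation or conflict? In the legume–rhizobium mutualism, loci in the
symbiont genome can influence fitness-related traits of both partners
(*symbiotic pleiotropy*). When a variant's allelic effects on a rhizobium
fitness proxy and a plant fitness proxy share the same sign, host and
symbiont fitness are aligned at that locus; opposite signs indicate genomic
conflict. `symbiopleio` implements, as a tested and fully synthetic-data-
capable pipeline, the analysis chain used to ask that question for a panel
of *Sinorhizobium meliloti* strains on two *Medicago truncatula* host lines:

1. **Strain means** — rack-corrected estimated marginal means (EMMs) of
   single-strain fitness proxies (shoot biomass, leaf chlorophyll A, nodule
   number, nodule weight) per strain × host, and their pairwise Pearson
   correlations.
2. **Multi-strain relative fitness** — per-pool strain frequencies
   reconstructed from pooled nodule sequencing by depth-weighted least
   squares on the simplex, converted to fold-change relative fitness
   (select-and-resequence design).
3. **Mixed-model GWAS** — per-variant allelic effect sizes β from
   `y = 1α + xβ + u + ε`, `u ~ N(0, σ²_g K)`, `ε ~ N(0, σ²_e I)`, with the
   centered-genotype kinship `K = X_c X_cᵀ / L` absorbing population
   structure; λ = σ²_g/σ²_e fitted by REML via eigen-rotation, Wald tests
   per site; 5 proxies × 2 hosts = 10 runs.
4. **Permutation significance** — family-wise max-|β| thresholds from trait
   permutations.
5. **Pleiotropy classification** — variants significant for ≥2 traits on
   one host, labelled concordant (+,+ / −,−) or discordant (+,− / −,+) per
   trait pair; categories: rhizobium-fitness vs symbiotic pleiotropy;
   host-overlap tallies.
6. **Selection signatures** — per-gene π, Watterson's θ, Tajima's D and
   Fu & Li's D*/F* (outgroup-free), with pleiotropy gene categories tested
   against the pool of all significant genes by size-matched resampling.

Because the original strain panel is an external dataset, the package ships
a first-class synthetic-data module: Balding–Nichols population structure,
genes tiling three replicons (chromosome, pSymA, pSymB), planted
concordant/discordant causal variants with a ground-truth ledger,
greenhouse rack effects, and binomial pooled read sampling — so every stage
is testable end to end against known truth.

## Worked example

The numbered drivers under `analysis/` run the default synthetic study
(100 strains, 5000 sites, 4 subpopulations, 3 concordant + 3 discordant
planted pairs) through the whole chain; intermediates go to
`scratch/analysis_run/`, summary tables to `results/`:

```sh
cd analysis
python 01_simulate.py
python 02_pool_fitness.py
...
python 07_selection_scan.py
```

`01_simulate.py` reports the planted architecture, e.g.:

```
planted causal variants:
 pair_id          site_id host      label          category
       0       pSymB:7840  DZA concordant rhizobium_fitness
       3       pSymB:6200  DZA discordant         symbiotic
       ...
```

`03_strain_means.py` prints the phenotypic-level correlations, for example
a nodule number / nodule weight trade-off and alignment between nodule
weight and shoot biomass on host DZA:

```
host       trait_x          trait_y         r        p   n stars
 DZA shoot_biomass    nodule_number -0.360553 0.000229 100   ***
 DZA shoot_biomass    nodule_weight  0.345323 0.000434 100   ***
```

and `06_pleiotropy.py` the genomic-level verdict — which variants passed
the family-wise threshold for two traits and whether their effects align:

```
pleiotropic variants detected: 2
         site_id    gene_id host                   categories       trait_x          trait_y  sign_x  sign_y      label
chromosome:23480 gene_00218  DZA rhizobium_fitness_pleiotropy nodule_number relative_fitness       1       1 concordant
 chromosome:2420 gene_00029  DZA rhizobium_fitness_pleiotropy nodule_weight relative_fitness       1      -1 discordant
host overlap: 0 DZA-only, 0 A17-only, 2 shared
```

Both detected variants are planted causal sites and carry their true sign
class: the concordant one marks fitness alignment between nodulation and
competitive fitness, the discordant one a nodule-size/competition
trade-off. `07_selection_scan.py` then compares each category's gene-level
diversity statistics with the null pool of all significant genes.

The same pipeline is available as a CLI:

```sh
symbiopleio run-all --config run.yaml --outdir out/
```

with per-stage subcommands (`simulate`, `poolfit`, `means`, `gwas`,
`permute`, `pleiotropy`, `selection`) and idempotent re-runs driven by file
timestamps.

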