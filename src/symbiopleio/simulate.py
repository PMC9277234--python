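"""Synthetic study generator with a ground-truth ledger.

Emulates the full data layout of a legume-rhizobium panel study: a structured
haploid strain panel (Balding-Nichols differentiation across subpopulations,
three replicons, genes tiling the sites), replicate-level single-strain
phenotypes with greenhouse rack effects and planted pleiotropic variants, and
a multi-strain select-and-resequence experiment in which pooled nodule
samples are sequenced after one round of fitness-driven frequency change.

Every stochastic draw routes through ``numpy.random.default_rng`` seeded from
``SimConfig.seed`` plus a fixed per-stage tag, so an identical config
reproduces identical outputs regardless of which stages are re-run.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .config import (
    HOSTS,
    PLANT_TRAITS,
    RELATIVE_FITNESS_TRAIT,
    REPLICON_WEIGHTS,
    REPLICONS,
    RHIZOBIUM_TRAITS,
    SINGLE_STRAIN_TRAITS,
    ConfigError,
    SimConfig,
)
from .datatypes import MISSING, GenotypePanel, PoolObservation, TruthLedger

# rng stream tags, one per stage
_TAG_GENO, _TAG_GENES, _TAG_PHENO, _TAG_POOLS = 11, 13, 17, 19

_SITE_SPACING = 10  # bp between adjacent simulated SNPs on a replicon

# trait-pair templates cycled through when planting causal variants
_SYMBIOTIC_PAIRS = (
    ("nodule_weight", "shoot_biomass"),
    ("nodule_number", "shoot_biomass"),
    ("nodule_weight", "chlorophyll_a"),
    (RELATIVE_FITNESS_TRAIT, "shoot_biomass"),
    (RELATIVE_FITNESS_TRAIT, "chlorophyll_a"),
)
_RHIZOBIUM_PAIRS = (
    ("nodule_number", "nodule_weight"),
    ("nodule_number", RELATIVE_FITNESS_TRAIT),
    ("nodule_weight", RELATIVE_FITNESS_TRAIT),
)


def _rng(cfg: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), tag])


def _replicon_layout(n_sites: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign sites to replicons (by genome-share weights) and 1-based bp positions."""
    counts = np.floor(np.asarray(REPLICON_WEIGHTS) * n_sites).astype(int)
    counts[0] += n_sites - counts.sum()
    replicon = np.repeat(REPLICONS, counts)
    pos = np.concatenate([_SITE_SPACING * (np.arange(c) + 1) for c in counts])
    return replicon, pos


def simulate_genotypes(cfg: SimConfig) -> GenotypePanel:
    """Draw a structured haploid genotype panel.

    Per site, an ancestral allele frequency is drawn Uniform(0.05, 0.95);
    each subpopulation's frequency is then Beta-distributed around it with
    variance parameter ``fst`` (Balding-Nichols), and strains carry Bernoulli
    haploid alleles at their subpopulation's frequency. A ``missing_rate``
    fraction of calls is masked to exercise downstream filters.
    """
    cfg.validate()
    rng = _rng(cfg, _TAG_GENO)
    s, l, k = cfg.n_strains, cfg.n_sites, cfg.n_subpops

    subpop = np.sort(rng.integers(0, k, size=s))
    p_anc = rng.uniform(0.05, 0.95, size=l)
    shape = (1.0 - cfg.fst) / cfg.fst
    # Beta(p*shape, (1-p)*shape) has mean p and variance fst*p*(1-p)
    p_sub = rng.beta(p_anc * shape, (1.0 - p_anc) * shape, size=(k, l))
    geno = (rng.random((s, l)) < p_sub[subpop, :]).astype(np.int8)
    if cfg.missing_rate > 0:
        geno[rng.random((s, l)) < cfg.missing_rate] = MISSING

    replicon, pos = _replicon_layout(l)
    strain_ids = [f"strain_{i:04d}" for i in range(s)]
    return GenotypePanel(geno, strain_ids, replicon, pos, subpop=subpop, subpop_freq=p_sub)


def simulate_gene_map(panel: GenotypePanel, cfg: SimConfig) -> pd.DataFrame:
    """Tile each replicon's sites into contiguous non-overlapping genes.

    Gene lengths (in sites) are geometric with mean ``gene_size_mean``;
    intervals are 1-based inclusive bp ranges that partition the SNP grid, so
    every variant falls inside exactly one gene.
    """
    rng = _rng(cfg, _TAG_GENES)
    rows = []
    gid = 0
    for rep in REPLICONS:
        idx = np.where(panel.replicon == rep)[0]
        if idx.size == 0:
            continue
        pos = panel.pos[idx]
        start = 0
        while start < idx.size:
            length = int(rng.geometric(1.0 / cfg.gene_size_mean))
            stop = min(start + length, idx.size)
            rows.append(
                {
                    "gene_id": f"gene_{gid:05d}",
                    "replicon": rep,
                    "start": int(pos[start] - _SITE_SPACING // 2),
                    "end": int(pos[stop - 1] + _SITE_SPACING // 2 - 1),
                    "n_sites": stop - start,
                }
            )
            gid += 1
            start = stop
    return pd.DataFrame(rows)


def _plant_causal_pairs(panel: GenotypePanel, cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Choose causal sites and assign each a (trait, trait) effect pair.

    One causal variant per pair: it carries a signed beta on each of two
    traits, same-sign for concordant pairs, opposite-sign for discordant.
    Even-indexed pairs are symbiotic (rhizobium x plant proxy), odd-indexed
    are rhizobium-fitness (two rhizobium proxies), following
    ``symbiotic_fraction``; each pair acts on both hosts with probability
    ``host_shared_fraction``, else on a single host.
    """
    n_pairs = cfg.n_concordant_pairs + cfg.n_discordant_pairs
    if n_pairs == 0:
        return pd.DataFrame(
            columns=["pair_id", "site_index", "site_id", "trait", "host", "beta", "label", "category"]
        )
    maf = panel.maf()
    # plant large effects at moderate frequency (the detectable regime;
    # rare alleles carry no power, common ones dilute per-allele effects)
    informative = np.where((maf >= 0.1) & (maf <= 0.3))[0]
    if informative.size < n_pairs:
        informative = np.where(maf >= 0.1)[0]
    if informative.size < n_pairs:
        informative = np.where(maf > 0)[0]
    sites = rng.choice(informative, size=n_pairs, replace=False)
    site_ids = panel.site_ids()

    labels = ["concordant"] * cfg.n_concordant_pairs + ["discordant"] * cfg.n_discordant_pairs
    sym_cycle = itertools.cycle(_SYMBIOTIC_PAIRS)
    rhiz_cycle = itertools.cycle(_RHIZOBIUM_PAIRS)
    # spread the symbiotic share evenly over the pair list so both sign labels
    # contain both categories
    idx = np.arange(n_pairs)
    symbiotic_flags = np.floor((idx + 1) * cfg.symbiotic_fraction) - np.floor(idx * cfg.symbiotic_fraction) >= 1

    rows = []
    for pair_id, (site, label) in enumerate(zip(sites, labels)):
        symbiotic = bool(symbiotic_flags[pair_id])
        t1, t2 = next(sym_cycle) if symbiotic else next(rhiz_cycle)
        category = "symbiotic" if symbiotic else "rhizobium_fitness"
        sign1 = rng.choice([-1.0, 1.0])
        sign2 = sign1 if label == "concordant" else -sign1
        shared = rng.random() < cfg.host_shared_fraction
        hosts = HOSTS if shared else (HOSTS[pair_id % 2],)
        for host in hosts:
            for trait, sign in ((t1, sign1), (t2, sign2)):
                rows.append(
                    {
                        "pair_id": pair_id,
                        "site_index": int(site),
                        "site_id": site_ids[site],
                        "trait": trait,
                        "host": host,
                        "beta": float(sign * cfg.effect_size),
                        "label": label,
                        "category": category,
                    }
                )
    return pd.DataFrame(rows)


def simulate_phenotypes(panel: GenotypePanel, cfg: SimConfig) -> tuple[pd.DataFrame, TruthLedger]:
    """Generate replicate-level phenotypes and the ground-truth ledger.

    Per host and trait, a strain's genetic value is the planted causal
    contribution (betas on standardized genotypes) plus a polygenic term with
    covariance proportional to the realized kinship matrix, scaled so that
    sigma_g^2 / (sigma_g^2 + noise_sd^2) = ``h2_polygenic``. Single-strain
    traits are then observed ``reps_per_strain`` times per strain with an
    additive rack effect and residual noise. The relative-fitness trait has
    no replicate rows; its genetic value sets the competitive fitness
    ``w = exp(selection_gradient * standardized value)`` used by
    :func:`simulate_pools`.
    """
    from .gwas import compute_kinship  # local import: kinship convention shared with GWAS

    cfg.validate()
    rng = _rng(cfg, _TAG_PHENO)
    s = panel.n_strains

    causal = _plant_causal_pairs(panel, cfg, rng)

    x = panel.imputed()
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x_std = (x - mu) / sd

    kin = compute_kinship(panel)
    evals = np.clip(kin.eigenvalues, 0.0, None)
    scale = np.sqrt(np.mean(np.diag(kin.matrix))) or 1.0
    sigma_g = 0.0
    if cfg.h2_polygenic > 0:
        sigma_g = cfg.noise_sd * np.sqrt(cfg.h2_polygenic / (1.0 - cfg.h2_polygenic))

    genetic: dict[tuple[str, str], np.ndarray] = {}
    traits = SINGLE_STRAIN_TRAITS + (RELATIVE_FITNESS_TRAIT,)
    for host in HOSTS:
        for trait in traits:
            g = np.zeros(s)
            sub = causal[(causal.host == host) & (causal.trait == trait)] if len(causal) else causal
            for _, row in sub.iterrows():
                g += row.beta * x_std[:, int(row.site_index)]
            if sigma_g > 0:
                z = rng.standard_normal(s)
                u = kin.eigenvectors @ (np.sqrt(evals) * z)
                g += sigma_g * u / scale
            genetic[(host, trait)] = g

    rack_labels = [f"rack_{chr(ord('A') + i)}" for i in range(cfg.n_racks)]
    rows = []
    for host in HOSTS:
        rack_effects = rng.normal(0.0, cfg.rack_sd, size=cfg.n_racks)
        for trait in SINGLE_STRAIN_TRAITS:
            g = genetic[(host, trait)]
            racks = rng.integers(0, cfg.n_racks, size=(s, cfg.reps_per_strain))
            noise = rng.normal(0.0, cfg.noise_sd, size=(s, cfg.reps_per_strain))
            for i, strain in enumerate(panel.strain_ids):
                for r in range(cfg.reps_per_strain):
                    rows.append(
                        {
                            "strain": strain,
                            "host": host,
                            "rack": rack_labels[racks[i, r]],
                            "trait": trait,
                            "value": float(g[i] + rack_effects[racks[i, r]] + noise[i, r]),
                        }
                    )
    phenotypes = pd.DataFrame(rows)

    fit_rows = []
    for host in HOSTS:
        bv = genetic[(host, RELATIVE_FITNESS_TRAIT)]
        sd_bv = bv.std()
        z = (bv - bv.mean()) / sd_bv if sd_bv > 0 else np.zeros_like(bv)
        w = np.exp(cfg.selection_gradient * z)
        for strain, wi in zip(panel.strain_ids, w):
            fit_rows.append({"strain": strain, "host": host, "w": float(wi), "log_w": float(np.log(wi))})

    truth = TruthLedger(
        causal=causal,
        fitness=pd.DataFrame(fit_rows),
        initial_frequencies={},
        final_frequencies={},
        strain_ids=list(panel.strain_ids),
    )
    return phenotypes, truth


def selection_update(f_init: np.ndarray, w: np.ndarray) -> np.ndarray:
    """One round of selection: ``f_end`` proportional to ``f_init * w``."""
    f_init = np.asarray(f_init, dtype=float)
    if np.any(f_init < 0) or abs(f_init.sum() - 1.0) > 1e-9:
        raise ConfigError("initial frequencies must be non-negative and sum to 1")
    f = f_init * np.asarray(w, dtype=float)
    return f / f.sum()


def simulate_pools(
    panel: GenotypePanel, truth: TruthLedger, cfg: SimConfig
) -> tuple[list[PoolObservation], dict[str, np.ndarray]]:
    """Simulate pooled nodule sequencing before and after selection.

    Initial strain frequencies are equal (or Dirichlet-perturbed when
    ``dirichlet_init`` is set); final frequencies follow one multiplicative
    selection round with the true fitness ``w``. Per pool and site, read
    depth is Poisson(``mean_depth``) and the alternate-allele count is
    Binomial(depth, (G f)_site) using mean-imputed genotypes. Fills
    ``truth.initial_frequencies``/``final_frequencies`` and returns the pool
    observations plus the per-host initial frequency vectors.
    """
    rng = _rng(cfg, _TAG_POOLS)
    s = panel.n_strains
    g = panel.imputed()

    pools: list[PoolObservation] = []
    init_freqs: dict[str, np.ndarray] = {}
    for host in HOSTS:
        if cfg.dirichlet_init is None:
            f_init = np.full(s, 1.0 / s)
        else:
            f_init = rng.dirichlet(np.full(s, float(cfg.dirichlet_init)))
        w = (
            truth.fitness[truth.fitness.host == host]
            .set_index("strain")
            .loc[panel.strain_ids, "w"]
            .to_numpy()
        )
        f_end = selection_update(f_init, w)
        init_freqs[host] = f_init
        truth.initial_frequencies[host] = f_init
        truth.final_frequencies[host] = f_end

        for timepoint, f in (("initial", f_init), ("final", f_end)):
            p = np.clip(g.T @ f, 0.0, 1.0)
            for j in range(cfg.n_pools):
                depth = rng.poisson(cfg.mean_depth, size=panel.n_sites)
                alt = rng.binomial(depth, p)
                pools.append(
                    PoolObservation(
                        pool_id=f"{host}_pool_{j:02d}",
                        host=host,
                        timepoint=timepoint,
                        depth=depth,
                        alt_count=alt,
                        replicon=panel.replicon,
                        pos=panel.pos,
                    )
                )
    return pools, init_freqs


def trait_category(trait: str) -> str:
    """Classify a fitness proxy as rhizobium- or plant-side."""
    if trait in RHIZOBIUM_TRAITS:
        return "rhizobium"
    if trait in PLANT_TRAITS:
        return "plant"
    raise ConfigError(f"unknown trait {trait!r}")
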