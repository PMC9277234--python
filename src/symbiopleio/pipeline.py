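"""End-to-end orchestration over declared file artifacts.

Stages communicate only through files in the run directory, in dependency
order: simulate -> poolfit -> means -> gwas -> permute -> pleiotropy ->
selection -> manifest. A stage is skipped when all its outputs exist and are
newer than all its inputs, so deleting one intermediate re-executes only the
stages downstream of it. The manifest lists every artifact with a sha256
checksum plus the config echo and is byte-identical across same-seed runs;
wall-clock stage timings go to a separate ``timings.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import io as sio
from .config import (
    RELATIVE_FITNESS_TRAIT,
    SINGLE_STRAIN_TRAITS,
    RunConfig,
    save_run_config,
)
from .gwas import LMMWorkspace, compute_kinship, filter_variants, lmm_association
from .pleiotropy import (
    classify_pleiotropy,
    concordance_summary,
    gene_rollup,
    host_overlap,
    map_variants_to_genes,
)
from .pool_fitness import (
    default_pseudo_frequency,
    reconstruct_frequencies,
    relative_fitness,
)
from .selection import category_comparison, gene_stats_table
from .significance import permutation_threshold
from .simulate import (
    simulate_gene_map,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_pools,
)
from .strain_means import correlation_grid, estimated_marginal_means

log = logging.getLogger("symbiopleio")


def _derived_seed(base: int, *tags: int) -> int:
    """Deterministic child seed below 2^31."""
    ss = np.random.SeedSequence([int(base), *map(int, tags)])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class Stage:
    name: str
    inputs: list[Path]
    outputs: list[Path]
    run: Callable[[], None]

    def up_to_date(self) -> bool:
        if not all(p.exists() for p in self.outputs):
            return False
        if not self.inputs:
            return True
        newest_in = max(p.stat().st_mtime for p in self.inputs if p.exists())
        oldest_out = min(p.stat().st_mtime for p in self.outputs)
        return oldest_out >= newest_in


@dataclass
class PipelineRunner:
    cfg: RunConfig
    outdir: Path
    force: bool = False
    timings: dict[str, float] = field(default_factory=dict)
    executed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.cfg.validate()

    # --- artifact paths -------------------------------------------------
    def p(self, name: str) -> Path:
        return self.outdir / name

    def _runs(self) -> list[tuple[str, str]]:
        traits = list(SINGLE_STRAIN_TRAITS) + [RELATIVE_FITNESS_TRAIT]
        return [(trait, host) for host in self.cfg.hosts for trait in traits]

    # --- stages ---------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.cfg.sim
        panel = simulate_genotypes(cfg)
        genes = simulate_gene_map(panel, cfg)
        phen, truth = simulate_phenotypes(panel, cfg)
        pools, _ = simulate_pools(panel, truth, cfg)
        sio.write_vcf(panel, self.p("panel.vcf"))
        sio.write_gff3(genes, self.p("genes.gff3"))
        sio.write_phenotypes(phen, self.p("phenotypes.csv"))
        sio.write_pools(pools, self.p("pools.tsv"))
        sio.write_truth(truth, self.p("truth.json"))
        save_run_config(self.cfg, self.p("config.yaml"))

    def stage_poolfit(self) -> None:
        panel = sio.read_vcf(self.p("panel.vcf"))
        pools = sio.read_pools(self.p("pools.tsv"))
        freq_rows, diag_rows, fit_frames = [], [], []
        for host in self.cfg.hosts:
            host_pools = [p for p in pools if p.host == host]
            finals = []
            initials = []
            for obs in sorted(host_pools, key=lambda o: (o.timepoint, o.pool_id)):
                est = reconstruct_frequencies(obs, panel, maf_min=self.cfg.maf_min)
                (finals if obs.timepoint == "final" else initials).append(est)
                diag_rows.append(
                    {
                        "pool_id": est.pool_id,
                        "host": host,
                        "timepoint": est.timepoint,
                        "residual": est.residual,
                        "n_sites": est.n_sites,
                        "converged": est.converged,
                        "n_iter": est.n_iter,
                    }
                )
                for s, strain in enumerate(panel.strain_ids):
                    freq_rows.append(
                        {
                            "pool_id": est.pool_id,
                            "host": host,
                            "timepoint": est.timepoint,
                            "strain": strain,
                            "frequency": float(est.frequencies[s]),
                        }
                    )
            initial_mean = np.mean([e.frequencies for e in initials], axis=0)
            initial_mean = initial_mean / initial_mean.sum()
            pseudo = self.cfg.pseudo_frequency
            if pseudo is None:
                pseudo = default_pseudo_frequency([p for p in host_pools if p.timepoint == "final"])
            _, summary = relative_fitness(finals, initial_mean, panel.strain_ids, pseudo=pseudo)
            fit_frames.append(summary)
        sio.write_table(
            pd.DataFrame(freq_rows),
            self.p("pool_frequencies.tsv"),
            "reconstructed strain frequencies per pool (simplex per pool)",
        )
        sio.write_table(
            pd.DataFrame(diag_rows), self.p("pool_diagnostics.tsv"), "weighted MSE residual and convergence per pool"
        )
        sio.write_table(
            pd.concat(fit_frames, ignore_index=True),
            self.p("relative_fitness.tsv"),
            "fold-change of final vs mean initial frequency; per-strain median across pools",
        )

    def stage_means(self) -> None:
        phen = sio.read_phenotypes(self.p("phenotypes.csv"))
        if self.cfg.log_chlorophyll:
            mask = phen["trait"] == "chlorophyll_a"
            phen.loc[mask, "value"] = np.log(phen.loc[mask, "value"].clip(lower=1e-9))
        fitness = sio.read_table(self.p("relative_fitness.tsv"))
        emm_frames, corr_frames = [], []
        for host in self.cfg.hosts:
            summaries = {}
            for trait in SINGLE_STRAIN_TRAITS:
                emm = estimated_marginal_means(phen, trait, host)
                emm_frames.append(emm)
                summaries[trait] = emm
            fit = fitness[fitness.host == host]
            summaries[RELATIVE_FITNESS_TRAIT] = pd.DataFrame(
                {
                    "strain": fit["strain"],
                    "host": host,
                    "trait": RELATIVE_FITNESS_TRAIT,
                    "emm": fit["log2_fold_change"],
                }
            )
            corr = correlation_grid(summaries, host)
            corr_frames.append(corr)
        sio.write_table(
            pd.concat(emm_frames, ignore_index=True),
            self.p("strain_emms.tsv"),
            "rack-corrected estimated marginal means per strain x host x trait",
        )
        sio.write_table(
            pd.concat(corr_frames, ignore_index=True),
            self.p("correlations.tsv"),
            "pairwise Pearson correlations of per-strain summaries (relative fitness as cross-pool median of log2 fold-change)",
        )

    def _trait_vectors(self, panel_strains: list[str]) -> dict[tuple[str, str], np.ndarray]:
        emms = sio.read_table(self.p("strain_emms.tsv"))
        fitness = sio.read_table(self.p("relative_fitness.tsv"))
        vectors = {}
        for host in self.cfg.hosts:
            for trait in SINGLE_STRAIN_TRAITS:
                sub = emms[(emms.host == host) & (emms.trait == trait)].set_index("strain")
                vectors[(trait, host)] = sub.loc[panel_strains, "emm"].to_numpy(dtype=float)
            fit = fitness[fitness.host == host].set_index("strain")
            vectors[(RELATIVE_FITNESS_TRAIT, host)] = fit.loc[
                panel_strains, "log2_fold_change"
            ].to_numpy(dtype=float)
        return vectors

    def stage_gwas(self) -> None:
        panel = sio.read_vcf(self.p("panel.vcf"))
        fpanel, counts = filter_variants(panel, self.cfg.maf_min, self.cfg.miss_max)
        kin = compute_kinship(fpanel)
        ws = LMMWorkspace.build(fpanel, kin)
        vectors = self._trait_vectors(panel.strain_ids)
        frames = []
        for (trait, host), y in vectors.items():
            res = lmm_association(y, fpanel, kin, trait=trait, host=host, workspace=ws)
            frames.append(res)
        assoc = pd.concat(frames, ignore_index=True)
        sio.write_table(
            assoc,
            self.p("associations.tsv"),
            f"LMM association results; {counts['n_kept']}/{counts['n_in']} sites kept by MAF/missingness filter; beta on standardized traits",
        )

    def stage_permute(self) -> None:
        panel = sio.read_vcf(self.p("panel.vcf"))
        fpanel, _ = filter_variants(panel, self.cfg.maf_min, self.cfg.miss_max)
        kin = compute_kinship(fpanel)
        ws = LMMWorkspace.build(fpanel, kin)
        vectors = self._trait_vectors(panel.strain_ids)
        assoc = sio.read_table(self.p("associations.tsv"))
        thresholds = {}
        sig_frames = []
        for i, ((trait, host), y) in enumerate(vectors.items()):
            seed = _derived_seed(self.cfg.sim.seed, 101, i)
            null = permutation_threshold(
                y,
                fpanel,
                kin,
                n_permutations=self.cfg.permutations,
                alpha=self.cfg.alpha,
                seed=seed,
                trait=trait,
                host=host,
                workspace=ws,
            )
            run = assoc[(assoc.trait == trait) & (assoc.host == host)].copy()
            run["significant"] = null.significant(run).to_numpy()
            sig_frames.append(run)
            thresholds[f"{trait}|{host}"] = {
                "trait": trait,
                "host": host,
                "B": null.n_permutations,
                "alpha": null.alpha,
                "seed": seed,
                "threshold_beta": null.threshold_beta,
                "threshold_p": null.threshold_p,
            }
        self.p("thresholds.json").write_text(json.dumps(thresholds, sort_keys=True, indent=1) + "\n")
        sio.write_table(
            pd.concat(sig_frames, ignore_index=True),
            self.p("associations_significant.tsv"),
            "association results annotated with permutation FWER significance (|beta| >= threshold)",
        )

    def stage_pleiotropy(self) -> None:
        assoc = sio.read_table(self.p("associations_significant.tsv"))
        genes = sio.read_gff3(self.p("genes.gff3"))
        all_records = {}
        summary_rows = []
        rollup_frames = []
        for host in self.cfg.hosts:
            sub = assoc[assoc.host == host]
            sig_sets = {
                t: set(sub[(sub.trait == t) & sub.significant]["site_id"])
                for t in sub.trait.unique()
            }
            betas = {
                t: dict(zip(sub[sub.trait == t]["site_id"], sub[sub.trait == t]["beta"]))
                for t in sub.trait.unique()
            }
            records = classify_pleiotropy(sig_sets, betas, host)
            all_records[host] = records
            traits = sorted(sig_sets)
            for i, tx in enumerate(traits):
                for ty in traits[i + 1 :]:
                    summary_rows.append(concordance_summary(records, (tx, ty), host, sig_sets))
            rollup_frames.append(gene_rollup(records, genes))

        rec_rows = []
        for host, records in all_records.items():
            mapping = map_variants_to_genes([r.site_id for r in records], genes)
            gene_of = dict(zip(mapping.site_id, mapping.gene_id))
            for r in records:
                for (tx, ty), label in sorted(r.pair_labels.items()):
                    sx, sy = r.pair_signs[(tx, ty)]
                    rec_rows.append(
                        {
                            "site_id": r.site_id,
                            "gene_id": gene_of.get(r.site_id),
                            "host": host,
                            "categories": ";".join(r.categories),
                            "trait_x": tx,
                            "trait_y": ty,
                            "sign_x": sx,
                            "sign_y": sy,
                            "label": label,
                        }
                    )
        sio.write_table(
            pd.DataFrame(
                rec_rows,
                columns=[
                    "site_id",
                    "gene_id",
                    "host",
                    "categories",
                    "trait_x",
                    "trait_y",
                    "sign_x",
                    "sign_y",
                    "label",
                ],
            ),
            self.p("pleiotropy_records.tsv"),
            "per-variant per-trait-pair sign labels (concordant = same sign)",
        )
        sio.write_table(
            pd.DataFrame(summary_rows),
            self.p("concordance_summary.tsv"),
            "counts and shares of concordant/discordant pleiotropic variants per trait pair",
        )
        hosts = list(self.cfg.hosts)
        overlap = (
            host_overlap(all_records.get("DZA", []), all_records.get("A17", []))
            if len(hosts) == 2
            else {"note": "host overlap needs both host lines"}
        )
        self.p("host_overlap.json").write_text(json.dumps(overlap, sort_keys=True, indent=1) + "\n")
        rollup = (
            pd.concat(rollup_frames, ignore_index=True)
            if rollup_frames
            else pd.DataFrame(columns=["gene_id", "host", "n_variants", "categories", "labels"])
        )
        sio.write_table(rollup, self.p("gene_rollup.tsv"), "gene-level rollup of pleiotropic variants")

    def stage_selection(self) -> None:
        panel = sio.read_vcf(self.p("panel.vcf"))
        genes = sio.read_gff3(self.p("genes.gff3"))
        assoc = sio.read_table(self.p("associations_significant.tsv"))
        rollup = sio.read_table(self.p("gene_rollup.tsv"))
        records = sio.read_table(self.p("pleiotropy_records.tsv"))
        stats = gene_stats_table(panel, genes)
        sio.write_table(
            stats,
            self.p("gene_stats.tsv"),
            "per-gene diversity and neutrality statistics (complete-case strains per gene)",
        )

        sig_sites = assoc[assoc.significant]["site_id"].unique().tolist()
        null_genes = set(
            map_variants_to_genes(sig_sites, genes)["gene_id"].dropna()
        ) & set(stats.gene_id)
        comparisons = []
        if len(records):
            for cat_name, cat_key in (
                ("symbiotic_pleiotropy", "symbiotic_pleiotropy"),
                ("rhizobium_fitness_pleiotropy", "rhizobium_fitness_pleiotropy"),
            ):
                for label in ("concordant", "discordant"):
                    mask = records["categories"].str.contains(cat_key) & (records["label"] == label)
                    focal = set(records[mask]["gene_id"].dropna()) & null_genes
                    if not focal:
                        continue
                    for j, statistic in enumerate(
                        ("pi_per_site", "tajima_d", "fu_li_d_star", "fu_li_f_star")
                    ):
                        seed = _derived_seed(self.cfg.sim.seed, 211, j, len(comparisons))
                        cmp_res = category_comparison(
                            stats,
                            focal,
                            null_genes,
                            statistic,
                            reps=self.cfg.selection_reps,
                            seed=seed,
                            focal_category=f"{label}_{cat_name}",
                        )
                        comparisons.append(cmp_res.to_dict())
        self.p("category_comparisons.json").write_text(
            json.dumps(comparisons, sort_keys=True, indent=1) + "\n"
        )

    def stage_manifest(self) -> None:
        artifacts = sorted(
            p for p in self.outdir.iterdir() if p.is_file() and p.name not in ("manifest.json", "timings.json")
        )
        manifest = {
            "config": self.cfg.to_dict(),
            "artifacts": {p.name: _sha256(p) for p in artifacts},
        }
        self.p("manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")

    # --- driver ---------------------------------------------------------
    def stages(self) -> list[Stage]:
        p = self.p
        sim_out = [p("panel.vcf"), p("genes.gff3"), p("phenotypes.csv"), p("pools.tsv"), p("truth.json"), p("config.yaml")]
        return [
            Stage("simulate", [], sim_out, self.stage_simulate),
            Stage(
                "poolfit",
                [p("panel.vcf"), p("pools.tsv")],
                [p("pool_frequencies.tsv"), p("pool_diagnostics.tsv"), p("relative_fitness.tsv")],
                self.stage_poolfit,
            ),
            Stage(
                "means",
                [p("phenotypes.csv"), p("relative_fitness.tsv")],
                [p("strain_emms.tsv"), p("correlations.tsv")],
                self.stage_means,
            ),
            Stage(
                "gwas",
                [p("panel.vcf"), p("strain_emms.tsv"), p("relative_fitness.tsv")],
                [p("associations.tsv")],
                self.stage_gwas,
            ),
            Stage(
                "permute",
                [p("panel.vcf"), p("associations.tsv")],
                [p("thresholds.json"), p("associations_significant.tsv")],
                self.stage_permute,
            ),
            Stage(
                "pleiotropy",
                [p("associations_significant.tsv"), p("genes.gff3")],
                [
                    p("pleiotropy_records.tsv"),
                    p("concordance_summary.tsv"),
                    p("host_overlap.json"),
                    p("gene_rollup.tsv"),
                ],
                self.stage_pleiotropy,
            ),
            Stage(
                "selection",
                [p("panel.vcf"), p("genes.gff3"), p("associations_significant.tsv"), p("gene_rollup.tsv"), p("pleiotropy_records.tsv")],
                [p("gene_stats.tsv"), p("category_comparisons.json")],
                self.stage_selection,
            ),
        ]

    def run(self, only: list[str] | None = None) -> dict:
        for stage in self.stages():
            if only is not None and stage.name not in only:
                continue
            if not self.force and stage.up_to_date():
                log.info("[%s] up to date, skipped", stage.name)
                continue
            log.info("[%s] running", stage.name)
            t0 = time.perf_counter()
            try:
                stage.run()
            except Exception:
                log.error("[%s] stage failed", stage.name)
                raise
            self.timings[stage.name] = time.perf_counter() - t0
            self.executed.append(stage.name)
        self.stage_manifest()
        self.p("timings.json").write_text(json.dumps(self.timings, sort_keys=True, indent=1) + "\n")
        return json.loads(self.p("manifest.json").read_text())


def run_pipeline(cfg: RunConfig, outdir: str | Path, *, force: bool = False) -> dict:
    """Execute the full chain in ``outdir``; returns the manifest dict."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(name)s %(message)s")
    return PipelineRunner(cfg, Path(outdir), force=force).run()
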