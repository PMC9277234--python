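"""Sign-based classification of pleiotropic variants.

A variant is pleiotropic when it is significantly associated with more than
one fitness proxy on the same host line. Variants significant for two or
more rhizobium proxies show *rhizobium-fitness pleiotropy*; variants
significant for at least one rhizobium AND one plant proxy show *symbiotic
pleiotropy* (a variant can hold both). Each significant trait pair is
labelled concordant when the two effect sizes share sign (+,+ or -,-) —
fitness alignment — and discordant when they differ (+,- or -,+) — fitness
conflict. Sign labels use standardized-trait betas so proxy scale cannot
flip an interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .config import PLANT_TRAITS, RHIZOBIUM_TRAITS
from .datatypes import DataError


@dataclass
class PleiotropyRecord:
    site_id: str
    host: str
    traits: tuple[str, ...]  # traits where significant, sorted
    pair_labels: dict[tuple[str, str], str] = field(default_factory=dict)
    pair_signs: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    categories: tuple[str, ...] = ()


def _pair_label(beta_x: float, beta_y: float) -> str:
    if beta_x == 0.0 or beta_y == 0.0:
        raise DataError("cannot sign-classify a zero effect size")
    return "concordant" if beta_x * beta_y > 0 else "discordant"


def classify_pleiotropy(
    sig_sets: dict[str, set[str]],
    betas: dict[str, dict[str, float]],
    host: str,
) -> list[PleiotropyRecord]:
    """Build pleiotropy records from per-trait significant sets and betas.

    ``sig_sets`` maps trait -> set of significant site ids; ``betas`` maps
    trait -> {site_id: standardized beta}. Variants significant for fewer
    than two traits are excluded. Each trait PAIR gets its own sign label,
    so a variant significant for three traits contributes three labels.
    """
    known = RHIZOBIUM_TRAITS | PLANT_TRAITS
    for t in sig_sets:
        if t not in known:
            raise DataError(f"trait {t!r} is not tagged as rhizobium or plant proxy")
    site_traits: dict[str, list[str]] = {}
    for trait, sites in sig_sets.items():
        for s in sites:
            site_traits.setdefault(s, []).append(trait)

    records = []
    for site, traits in sorted(site_traits.items()):
        if len(traits) < 2:
            continue
        traits = sorted(traits)
        n_rhiz = sum(t in RHIZOBIUM_TRAITS for t in traits)
        n_plant = sum(t in PLANT_TRAITS for t in traits)
        cats = []
        if n_rhiz >= 2:
            cats.append("rhizobium_fitness_pleiotropy")
        if n_rhiz >= 1 and n_plant >= 1:
            cats.append("symbiotic_pleiotropy")
        if not cats:  # e.g. two plant proxies only: not a defined category
            continue
        rec = PleiotropyRecord(site_id=site, host=host, traits=tuple(traits), categories=tuple(cats))
        for tx, ty in combinations(traits, 2):
            bx, by = betas[tx][site], betas[ty][site]
            rec.pair_labels[(tx, ty)] = _pair_label(bx, by)
            rec.pair_signs[(tx, ty)] = (int(np.sign(bx)), int(np.sign(by)))
        records.append(rec)
    return records


def concordance_summary(
    records: list[PleiotropyRecord],
    trait_pair: tuple[str, str],
    host: str,
    sig_sets: dict[str, set[str]] | None = None,
) -> dict:
    """Counts and shares of concordant vs discordant variants for one pair.

    Percentages are computed against the union of variants significant for
    either trait of the pair when ``sig_sets`` is given (the denominator
    used in the genomic-level figure corners), else against the pleiotropic
    count.
    """
    tx, ty = sorted(trait_pair)
    labels = [
        r.pair_labels[(tx, ty)]
        for r in records
        if r.host == host and (tx, ty) in r.pair_labels
    ]
    n_con = sum(1 for l in labels if l == "concordant")
    n_dis = len(labels) - n_con
    if sig_sets is not None:
        denom = len(sig_sets.get(tx, set()) | sig_sets.get(ty, set()))
    else:
        denom = len(labels)
    pct = (lambda k: 100.0 * k / denom if denom else 0.0)
    return {
        "host": host,
        "trait_x": tx,
        "trait_y": ty,
        "n_concordant": n_con,
        "n_discordant": n_dis,
        "n_pleiotropic": len(labels),
        "n_significant_union": denom,
        "pct_concordant": pct(n_con),
        "pct_discordant": pct(n_dis),
    }


def host_overlap(
    records_dza: list[PleiotropyRecord], records_a17: list[PleiotropyRecord]
) -> dict:
    """Tally of variants pleiotropic on one host only vs shared between hosts."""
    sites_dza = {r.site_id for r in records_dza}
    sites_a17 = {r.site_id for r in records_a17}
    out = {
        "dza_only": len(sites_dza - sites_a17),
        "a17_only": len(sites_a17 - sites_dza),
        "shared": len(sites_dza & sites_a17),
        "total": len(sites_dza | sites_a17),
    }
    for cat in ("rhizobium_fitness_pleiotropy", "symbiotic_pleiotropy"):
        cd = {r.site_id for r in records_dza if cat in r.categories}
        ca = {r.site_id for r in records_a17 if cat in r.categories}
        out[cat] = {
            "dza_only": len(cd - ca),
            "a17_only": len(ca - cd),
            "shared": len(cd & ca),
        }
    return out


def map_variants_to_genes(site_ids: list[str], genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each ``replicon:pos`` variant to the gene interval containing it.

    Gene intervals are 1-based inclusive and non-overlapping; intergenic
    variants get a null gene id (and are excluded from selection scans).
    """
    rows = []
    by_rep = {rep: df.sort_values("start") for rep, df in genes.groupby("replicon")}
    for sid in site_ids:
        rep, pos_s = sid.rsplit(":", 1)
        pos = int(pos_s)
        gene_id = None
        tab = by_rep.get(rep)
        if tab is not None:
            starts = tab["start"].to_numpy()
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and pos <= int(tab["end"].iloc[i]):
                gene_id = tab["gene_id"].iloc[i]
        rows.append({"site_id": sid, "gene_id": gene_id})
    return pd.DataFrame(rows, columns=["site_id", "gene_id"])


def gene_rollup(records: list[PleiotropyRecord], genes: pd.DataFrame) -> pd.DataFrame:
    """Gene-level summary: for each gene, hosts, categories and sign labels
    of the pleiotropic variants it contains."""
    if not records:
        return pd.DataFrame(columns=["gene_id", "host", "n_variants", "categories", "labels"])
    mapping = map_variants_to_genes([r.site_id for r in records], genes)
    gene_of = dict(zip(mapping["site_id"], mapping["gene_id"]))
    rows = []
    for r in records:
        g = gene_of.get(r.site_id)
        if g is None:
            continue
        labels = sorted(set(r.pair_labels.values()))
        rows.append(
            {
                "gene_id": g,
                "host": r.host,
                "site_id": r.site_id,
                "categories": ";".join(r.categories),
                "labels": ";".join(labels),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["gene_id", "host", "n_variants", "categories", "labels"])
    return (
        df.groupby(["gene_id", "host"], as_index=False)
        .agg(
            n_variants=("site_id", "nunique"),
            categories=("categories", lambda v: ";".join(sorted(set(";".join(v).split(";"))))),
            labels=("labels", lambda v: ";".join(sorted(set(";".join(v).split(";"))))),
        )
    )
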