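"""Readers and writers for the pipeline's file formats.

Genotypes travel as haploid VCF (one sample column per strain, GT of ``0``,
``1`` or ``.``), gene annotations as GFF3 (1-based inclusive), replicate
phenotypes as long-format CSV, pooled counts as TSV and the truth ledger as
JSON. VCF reading goes through cyvcf2.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .config import REPLICONS
from .datatypes import MISSING, GenotypePanel, PoolObservation, TruthLedger


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for rep in REPLICONS:
        mask = panel.replicon == rep
        if mask.any():
            lines.append(f"##contig=<ID={rep},length={int(panel.pos[mask].max()) + 100}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.strain_ids))
    code = {0: "0", 1: "1", MISSING: "."}
    for j in range(panel.n_sites):
        gts = "\t".join(code[int(g)] for g in panel.genotypes[:, j])
        lines.append(
            f"{panel.replicon[j]}\t{panel.pos[j]}\t{panel.replicon[j]}:{panel.pos[j]}\tA\tT\t.\tPASS\t.\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> GenotypePanel:
    vcf = VCF(str(path), gts012=False)
    strain_ids = list(vcf.samples)
    genos, reps, pos = [], [], []
    for var in vcf:
        # haploid GT: one allele per sample; cyvcf2 pads to [allele, phased]
        alleles = np.array([g[0] for g in var.genotypes], dtype=np.int8)
        genos.append(np.where(alleles < 0, MISSING, alleles))
        reps.append(var.CHROM)
        pos.append(var.POS)
    vcf.close()
    return GenotypePanel(
        genotypes=np.array(genos, dtype=np.int8).T,
        strain_ids=strain_ids,
        replicon=np.array(reps),
        pos=np.array(pos, dtype=np.int64),
    )


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for _, g in genes.iterrows():
        attrs = f"ID={g.gene_id}"
        lines.append(
            f"{g.replicon}\tsymbiopleio\tgene\t{int(g.start)}\t{int(g.end)}\t.\t+\t.\t{attrs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        rows.append(
            {
                "gene_id": attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"),
                "replicon": f[0],
                "start": int(f[3]),
                "end": int(f[4]),
            }
        )
    return pd.DataFrame(rows)


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, index=False, float_format="%.10g")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_pools(pools: list[PoolObservation], path: str | Path) -> None:
    frames = []
    for p in pools:
        frames.append(
            pd.DataFrame(
                {
                    "pool_id": p.pool_id,
                    "host": p.host,
                    "timepoint": p.timepoint,
                    "replicon": p.replicon,
                    "pos": p.pos,
                    "depth": p.depth,
                    "alt_count": p.alt_count,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_pools(path: str | Path) -> list[PoolObservation]:
    df = pd.read_csv(path, sep="\t")
    pools = []
    for (pool_id, timepoint), sub in df.groupby(["pool_id", "timepoint"], sort=True):
        sub = sub.sort_values(["replicon", "pos"], kind="stable")
        # restore the original replicon order used by the panel
        sub["__rep_order"] = pd.Categorical(sub["replicon"], categories=REPLICONS).codes
        sub = sub.sort_values(["__rep_order", "pos"], kind="stable")
        pools.append(
            PoolObservation(
                pool_id=str(pool_id),
                host=str(sub["host"].iloc[0]),
                timepoint=str(timepoint),
                depth=sub["depth"].to_numpy(),
                alt_count=sub["alt_count"].to_numpy(),
                replicon=sub["replicon"].to_numpy(),
                pos=sub["pos"].to_numpy(),
            )
        )
    return pools


def write_truth(truth: TruthLedger, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), sort_keys=True, indent=1) + "\n")


def read_truth(path: str | Path) -> TruthLedger:
    return TruthLedger.from_json_dict(json.loads(Path(path).read_text()))


def write_table(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """TSV with an optional leading ``#`` comment naming units/conventions."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
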