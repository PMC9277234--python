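"""Per-gene diversity and neutrality statistics, and category-vs-null tests.

For each gene the module computes segregating sites S, nucleotide diversity
pi (mean pairwise differences), Watterson's theta, Tajima's D, and the
outgroup-free (starred) Fu & Li D* and F* built on singletons. Strains with
any missing call inside a gene are dropped for that gene (complete-case
rule); genes with fewer than four complete sequences are skipped, and
monomorphic genes report the D statistics as missing, never zero.

The category test formalizes a focal-vs-null comparison: the null is the
pool of all genes containing GWAS-significant variants, and the focal
category's mean statistic is compared with means of size-matched random
subsets of the null pool (two-tailed empirical p, flagged at p < 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DataError, GenotypePanel


@dataclass
class GeneStats:
    gene_id: str
    replicon: str
    n_sequences: int
    n_sites: int  # candidate sites within the gene interval
    gene_length: int  # bp length of the gene interval
    s_segregating: int
    n_singletons: int
    pi_total: float
    pi_per_site: float
    theta_w_total: float
    theta_w_per_site: float
    tajima_d: float  # NaN when undefined
    fu_li_d_star: float
    fu_li_f_star: float


def _harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i**power))


def tajima_constants(n: int) -> dict[str, float]:
    """Variance constants of Tajima (1989) for sample size ``n``."""
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "a2": a2, "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def fu_li_star_constants(n: int) -> dict[str, float]:
    """u/v weights of Fu & Li's (1993) outgroup-free D* and F*.

    Uses the corrected expressions in general use (as printed by DnaSP and
    libsequence); valid for n >= 3.
    """
    nf = float(n)
    a = _harmonic(n)
    b = _harmonic(n, 2)
    a_n1 = a + 1.0 / nf  # a_{n+1}
    c = 2.0 * (nf * a - 2.0 * (nf - 1.0)) / ((nf - 1.0) * (nf - 2.0))
    d = (
        c
        + (nf - 2.0) / (nf - 1.0) ** 2
        + (2.0 / (nf - 1.0)) * (1.5 - (2.0 * a_n1 - 3.0) / (nf - 2.0) - 1.0 / nf)
    )
    v_d = (
        (nf / (nf - 1.0)) ** 2 * b
        + a**2 * d
        - 2.0 * nf * a * (a + 1.0) / (nf - 1.0) ** 2
    ) / (a**2 + b)
    u_d = (nf / (nf - 1.0)) * (a - nf / (nf - 1.0)) - v_d
    v_f = (
        (2.0 * nf**3 + 110.0 * nf**2 - 255.0 * nf + 153.0) / (9.0 * nf**2 * (nf - 1.0))
        + 2.0 * (nf - 1.0) * a / nf**2
        - 8.0 * b / nf
    ) / (a**2 + b)
    u_f = (
        (4.0 * nf**2 + 19.0 * nf + 3.0 - 12.0 * (nf + 1.0) * a_n1)
        / (3.0 * nf * (nf - 1.0))
    ) / a - v_f
    return {"a1": a, "u_d": u_d, "v_d": v_d, "u_f": u_f, "v_f": v_f}


def site_counts(geno: np.ndarray) -> tuple[int, int, float]:
    """(S, singleton count, total pi) for a complete 0/1 matrix (n x sites)."""
    n = geno.shape[0]
    c_alt = geno.sum(axis=0)
    seg = (c_alt > 0) & (c_alt < n)
    s = int(seg.sum())
    singletons = int(np.sum(seg & ((c_alt == 1) | (c_alt == n - 1))))
    c = c_alt[seg].astype(float)
    pi = float(np.sum(2.0 * c * (n - c) / (n * (n - 1.0))))
    return s, singletons, pi


def gene_neutrality_stats(
    panel: GenotypePanel, gene: pd.Series | dict, *, min_sequences: int = 4
) -> GeneStats | None:
    """Neutrality statistics for one gene interval, or None when skipped.

    ``gene`` needs fields gene_id, replicon, start, end (1-based inclusive).
    """
    rep, start, end = gene["replicon"], int(gene["start"]), int(gene["end"])
    in_gene = (panel.replicon == rep) & (panel.pos >= start) & (panel.pos <= end)
    idx = np.where(in_gene)[0]
    length = end - start + 1
    if idx.size == 0:
        return None
    sub = panel.genotypes[:, idx]
    complete = ~(sub == -1).any(axis=1)
    n = int(complete.sum())
    if n < min_sequences:
        return None
    geno = sub[complete].astype(np.int8)
    s, eta_s, pi = site_counts(geno)

    a1 = _harmonic(n)
    theta_w = s / a1
    taj = np.nan
    d_star = np.nan
    f_star = np.nan
    if s > 0:
        if n == 2:
            taj = 0.0  # pi == theta_w identically at n = 2
        else:
            tc = tajima_constants(n)
            var = tc["e1"] * s + tc["e2"] * s * (s - 1.0)
            taj = (pi - s / tc["a1"]) / np.sqrt(var) if var > 0 else np.nan
        if n >= 3:
            fc = fu_li_star_constants(n)
            vd = fc["u_d"] * s + fc["v_d"] * s**2
            vf = fc["u_f"] * s + fc["v_f"] * s**2
            nf = float(n)
            if vd > 0:
                d_star = ((nf / (nf - 1.0)) * s - fc["a1"] * eta_s) / np.sqrt(vd)
            if vf > 0:
                f_star = (pi - ((nf - 1.0) / nf) * eta_s) / np.sqrt(vf)
    return GeneStats(
        gene_id=str(gene["gene_id"]),
        replicon=str(rep),
        n_sequences=n,
        n_sites=int(idx.size),
        gene_length=length,
        s_segregating=s,
        n_singletons=eta_s,
        pi_total=pi,
        pi_per_site=pi / length,
        theta_w_total=theta_w,
        theta_w_per_site=theta_w / length,
        tajima_d=float(taj),
        fu_li_d_star=float(d_star),
        fu_li_f_star=float(f_star),
    )


def gene_stats_table(
    panel: GenotypePanel, genes: pd.DataFrame, *, min_sequences: int = 4
) -> pd.DataFrame:
    """Neutrality statistics for every gene; skipped genes are omitted."""
    rows = []
    for _, gene in genes.iterrows():
        st = gene_neutrality_stats(panel, gene, min_sequences=min_sequences)
        if st is not None:
            rows.append(vars(st))
    return pd.DataFrame(rows)


@dataclass
class CategoryComparison:
    statistic: str
    focal_category: str
    n_focal: int
    n_null: int
    focal_mean: float
    null_grand_mean: float
    null_means: np.ndarray
    p_value: float
    significant: bool  # at the p < 0.1 convention

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "focal_category": self.focal_category,
            "n_focal": self.n_focal,
            "n_null": self.n_null,
            "focal_mean": self.focal_mean,
            "null_grand_mean": self.null_grand_mean,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def category_comparison(
    stats: pd.DataFrame,
    focal_ids: set[str],
    null_ids: set[str],
    statistic: str,
    *,
    reps: int = 1000,
    seed: int = 0,
    focal_category: str = "",
) -> CategoryComparison:
    """Two-tailed resampling test of a focal gene category against the null pool.

    Draws ``reps`` random subsets of size |focal| without replacement from
    the null pool and compares |focal mean - grand mean| against the
    resampled deviations: p = (1 + #{>=}) / (reps + 1).
    """
    if not focal_ids:
        raise DataError("focal category is empty")
    if not focal_ids <= null_ids:
        raise DataError("focal gene set must be a subset of the null pool")
    tab = stats.set_index("gene_id")[statistic]
    null_list = sorted(null_ids & set(tab.index))
    vals = tab.loc[null_list].to_numpy(dtype=float)
    focal_mask = np.isin(null_list, sorted(focal_ids))
    focal_vals = vals[focal_mask]
    focal_vals = focal_vals[np.isfinite(focal_vals)]
    if focal_vals.size == 0:
        raise DataError(f"statistic {statistic!r} is missing for every focal gene")
    focal_mean = float(focal_vals.mean())
    grand_mean = float(np.nanmean(vals[np.isfinite(vals)]))

    rng = np.random.default_rng(seed)
    k = int(focal_mask.sum())
    null_means = np.empty(reps)
    for b in range(reps):
        pick = rng.choice(vals.size, size=k, replace=False)
        v = vals[pick]
        v = v[np.isfinite(v)]
        null_means[b] = v.mean() if v.size else np.nan
    dev_obs = abs(focal_mean - grand_mean)
    dev_null = np.abs(null_means - grand_mean)
    p = (1.0 + float(np.sum(dev_null >= dev_obs))) / (reps + 1.0)
    return CategoryComparison(
        statistic=statistic,
        focal_category=focal_category,
        n_focal=k,
        n_null=vals.size,
        focal_mean=focal_mean,
        null_grand_mean=grand_mean,
        null_means=null_means,
        p_value=p,
        significant=p < 0.1,
    )
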