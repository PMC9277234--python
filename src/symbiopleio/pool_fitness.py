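"""Strain-frequency reconstruction from pooled sequencing and relative fitness.

A pooled nodule sample is a mixture of known haploid strains, so the expected
alternate-allele fraction at each site is the genotype matrix applied to the
(unknown) strain frequency vector. Frequencies are recovered by
depth-weighted least squares constrained to the probability simplex — the
same estimand as likelihood-based haplotype reconstruction under binomial
read sampling, but convex and deterministic. Relative fitness is then the
fold-change of a strain's reconstructed final frequency against its mean
initial frequency, summarized per strain as the median across pools of the
same host.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DataError, GenotypePanel, PoolObservation


@dataclass
class StrainFrequencyEstimate:
    pool_id: str
    host: str
    timepoint: str
    frequencies: np.ndarray  # simplex over panel strains
    residual: float  # weighted mean squared error at the optimum
    n_sites: int
    converged: bool
    n_iter: int
    objective_history: list[float] | None = None


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (Duchi et al. 2008)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / (np.arange(v.size) + 1) > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def _usable_sites(obs: PoolObservation, panel: GenotypePanel, maf_min: float) -> np.ndarray:
    if not (
        obs.replicon.shape == panel.replicon.shape
        and np.array_equal(obs.replicon, panel.replicon)
        and np.array_equal(obs.pos, panel.pos)
    ):
        raise DataError("pool sites do not align with the genotype panel")
    keep = (obs.depth > 0) & (panel.maf() >= maf_min)
    keep &= ~panel.missing_mask().any(axis=0)  # drop sites with any missing genotype
    return keep


def reconstruct_frequencies(
    obs: PoolObservation,
    panel: GenotypePanel,
    *,
    maf_min: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    track_objective: bool = False,
) -> StrainFrequencyEstimate:
    """Estimate one pool's strain frequency vector.

    Solves ``min_{f in simplex} sum_sites w_site (alt/depth - (G f)_site)^2``
    with depth-proportional weights (normalized to sum to 1 so tolerances are
    scale-free), by monotone accelerated projected gradient. Sites with zero
    depth, panel MAF below ``maf_min`` or any missing strain genotype are
    dropped; convergence is declared when the gradient-mapping norm falls
    below ``tol``.
    """
    keep = _usable_sites(obs, panel, maf_min)
    n_sites = int(keep.sum())
    if n_sites == 0:
        raise DataError("no informative sites with positive depth")
    s = panel.n_strains
    if s == 1:
        return StrainFrequencyEstimate(obs.pool_id, obs.host, obs.timepoint, np.array([1.0]), 0.0, n_sites, True, 0)

    g = panel.genotypes[:, keep].T.astype(float)  # (sites, strains)
    depth = obs.depth[keep].astype(float)
    y = obs.alt_count[keep] / depth
    w = depth / depth.sum()

    a = g * w[:, None]  # weighted rows
    hess = 2.0 * g.T @ a  # 2 G^T W G
    grad_const = -2.0 * a.T @ y
    lipschitz = float(np.linalg.eigvalsh(hess).max())
    step = 1.0 / lipschitz

    def objective(f: np.ndarray) -> float:
        r = y - g @ f
        return float(w @ r**2)

    def gradient(f: np.ndarray) -> np.ndarray:
        return hess @ f + grad_const

    f = np.full(s, 1.0 / s)
    z = f.copy()
    t_mom = 1.0
    obj = objective(f)
    history = [obj] if track_objective else None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cand = project_simplex(z - step * gradient(z))
        obj_cand = objective(cand)
        if obj_cand <= obj:  # monotone safeguard keeps the objective non-increasing
            f_new, obj_new = cand, obj_cand
        else:
            f_new, obj_new = f, obj
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        z = f_new + (t_mom / t_new) * (cand - f_new) + ((t_mom - 1.0) / t_new) * (f_new - f)
        f, obj, t_mom = f_new, obj_new, t_new
        if history is not None:
            history.append(obj)

        gm = (f - project_simplex(f - step * gradient(f))) / step
        if np.linalg.norm(gm) * step < tol:  # scale-free: ||f - P(f - t grad)|| < tol
            converged = True
            break
    return StrainFrequencyEstimate(
        pool_id=obs.pool_id,
        host=obs.host,
        timepoint=obs.timepoint,
        frequencies=f,
        residual=obj,
        n_sites=n_sites,
        converged=converged,
        n_iter=it,
        objective_history=history,
    )


def default_pseudo_frequency(pools: list[PoolObservation]) -> float:
    """Half a read's worth of frequency at the median-depth site across pools."""
    total = np.sum([p.depth for p in pools], axis=0)
    med = float(np.median(total))
    return 1.0 / (2.0 * med) if med > 0 else 1e-6


def relative_fitness(
    finals: list[StrainFrequencyEstimate],
    initial_mean: np.ndarray,
    strain_ids: list[str],
    *,
    pseudo: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold-change fitness of each strain against its mean initial frequency.

    Per pool, ``fold_change_s = (f_final_s + pseudo) / (initial_mean_s + pseudo)``;
    the per-strain summary is the median across pools (pools of one host
    only). A zero final frequency with ``pseudo=0`` yields fold_change 0 and
    a missing log2 value, flagged in the ``undefined_log2`` column. Returns
    (per_pool table, per_strain summary).
    """
    initial_mean = np.asarray(initial_mean, dtype=float)
    if np.any(initial_mean < 0) or abs(initial_mean.sum() - 1.0) > 1e-6:
        raise DataError("initial_mean must lie on the simplex")
    if pseudo < 0:
        raise DataError("pseudo must be >= 0")
    hosts = {e.host for e in finals}
    if len(hosts) > 1:
        raise DataError("pools from different host lines may not be merged")
    rows = []
    for est in finals:
        fc = (est.frequencies + pseudo) / (initial_mean + pseudo)
        lfc = np.where(fc > 0, np.log2(np.where(fc > 0, fc, 1.0)), np.nan)
        for s, strain in enumerate(strain_ids):
            rows.append(
                {
                    "strain": strain,
                    "host": est.host,
                    "pool_id": est.pool_id,
                    "fold_change": float(fc[s]),
                    "log2_fold_change": float(lfc[s]),
                    "undefined_log2": bool(fc[s] <= 0),
                }
            )
    per_pool = pd.DataFrame(rows)
    summary = per_pool.groupby(["strain", "host"], as_index=False).agg(
        fold_change=("fold_change", "median"),
        log2_fold_change=("log2_fold_change", "median"),
        n_pools=("pool_id", "nunique"),
        n_undefined=("undefined_log2", "sum"),
    )
    return per_pool, summary
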