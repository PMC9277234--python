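"""Rack-corrected strain means and pairwise phenotypic correlations.

Replicate-level measurements from the single-strain greenhouse experiments
carry a nuisance rack (bench position) effect. Each strain's estimated
marginal mean (EMM) comes from the additive fixed-effect model
``value = strain + rack`` evaluated at the unweighted average over rack
levels, matching the usual emmeans convention for a two-factor design
without interaction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DataError


class ModelRankWarning(UserWarning):
    """Strain and rack factors are confounded; EMMs come from a pseudo-inverse fit."""


def estimated_marginal_means(
    reps: pd.DataFrame, trait: str, host: str
) -> pd.DataFrame:
    """Per-strain EMMs (and standard errors) for one trait on one host line.

    ``reps`` is a long table with columns strain, host, rack, trait, value.
    Fits ``value ~ strain + rack`` by least squares with a pseudo-inverse
    (so rank-deficient, confounded designs still return estimates, with a
    :class:`ModelRankWarning`); the EMM of strain ``s`` averages the fitted
    cell means over all rack levels with equal weight.
    """
    sub = reps[(reps["trait"] == trait) & (reps["host"] == host)].copy()
    if sub.empty:
        raise DataError(f"no replicates for trait {trait!r} on host {host!r}")
    strains = sorted(sub["strain"].unique())
    racks = sorted(sub["rack"].unique())
    if len(strains) < 2:
        raise DataError("need at least two strains to fit the strain factor")

    s_idx = pd.Categorical(sub["strain"], categories=strains).codes
    r_idx = pd.Categorical(sub["rack"], categories=racks).codes
    n, ns, nr = len(sub), len(strains), len(racks)

    # cell-mean coding for strain, treatment coding for rack (first level ref)
    design = np.zeros((n, ns + nr - 1))
    design[np.arange(n), s_idx] = 1.0
    for j in range(1, nr):
        design[r_idx == j, ns + j - 1] = 1.0

    y = sub["value"].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            "strain and rack are confounded; EMMs from pseudo-inverse fit",
            ModelRankWarning,
            stacklevel=2,
        )
    pinv = np.linalg.pinv(design)
    coef = pinv @ y
    resid = y - design @ coef
    dof = max(n - rank, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * (pinv @ pinv.T)

    # EMM contrast: strain coefficient + unweighted mean of rack offsets
    rack_weight = np.full(nr - 1, 1.0 / nr)
    emms = np.empty(ns)
    ses = np.empty(ns)
    for i in range(ns):
        c = np.zeros(ns + nr - 1)
        c[i] = 1.0
        c[ns:] = rack_weight
        emms[i] = c @ coef
        ses[i] = np.sqrt(max(c @ cov @ c, 0.0))
    return pd.DataFrame(
        {"strain": strains, "host": host, "trait": trait, "emm": emms, "se": ses}
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def pairwise_correlation(
    emms_x: pd.DataFrame, emms_y: pd.DataFrame, host: str
) -> dict:
    """Pearson correlation between two per-strain summary tables on one host.

    Inner-joins on strain id; the two-sided p-value is the regression slope
    test (identical to the Pearson test). Requires >= 3 shared strains and
    nonzero variance in both variables.
    """
    merged = emms_x.merge(emms_y, on="strain", suffixes=("_x", "_y"))
    if len(merged) < 3:
        raise DataError("need at least three strains present in both tables")
    x = merged["emm_x"].to_numpy(dtype=float)
    y = merged["emm_y"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise DataError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return {
        "host": host,
        "trait_x": emms_x["trait"].iloc[0] if "trait" in emms_x else "x",
        "trait_y": emms_y["trait"].iloc[0] if "trait" in emms_y else "y",
        "r": float(r),
        "p": float(p),
        "n": int(len(merged)),
        "stars": _stars(float(p)),
    }


def correlation_grid(
    summaries: dict[str, pd.DataFrame], host: str
) -> pd.DataFrame:
    """All pairwise correlations among per-strain trait summaries for a host.

    ``summaries`` maps trait name to a table with columns strain, emm.
    No multiple-testing correction is applied across the grid (raw stars).
    """
    traits = list(summaries)
    rows = []
    for i, tx in enumerate(traits):
        for ty in traits[i + 1 :]:
            rep = pairwise_correlation(summaries[tx], summaries[ty], host)
            rep["trait_x"], rep["trait_y"] = tx, ty
            rows.append(rep)
    return pd.DataFrame(rows)
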