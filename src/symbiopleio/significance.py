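"""Permutation-based family-wise significance thresholds for GWAS runs.

The trait vector is permuted across strains (breaking the genotype-phenotype
link while preserving the kinship spectrum and LD), the whole mixed-model
scan is re-run, and the maximum |beta| (and minimum Wald p) is recorded per
permutation. The family-wise threshold at level alpha is the empirical
(1 - alpha) quantile of the null maxima; a variant is significant when its
observed |beta| meets the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError
from .datatypes import GenotypePanel
from .gwas import KinshipMatrix, LMMWorkspace, scan_statistics


@dataclass
class PermutationNull:
    trait: str
    host: str
    n_permutations: int
    alpha: float
    seed: int
    null_max_beta: np.ndarray  # per-permutation max |beta|
    null_min_p: np.ndarray  # per-permutation min Wald p
    threshold_beta: float
    threshold_p: float

    def significant(self, assoc: pd.DataFrame) -> pd.Series:
        """Boolean mask: observed |beta| at or above the FWER threshold."""
        return assoc["beta"].abs() >= self.threshold_beta


def _order_statistic(values: np.ndarray, alpha: float, upper: bool) -> float:
    """The ceil((1-alpha) B)-th order statistic (ascending for upper tails)."""
    b = values.size
    k = int(np.ceil((1.0 - alpha) * b))
    k = min(max(k, 1), b)
    ranked = np.sort(values)
    return float(ranked[k - 1] if upper else ranked[b - k])


def permutation_threshold(
    y: np.ndarray,
    panel: GenotypePanel,
    kinship: KinshipMatrix,
    *,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    trait: str = "",
    host: str = "",
    workspace: LMMWorkspace | None = None,
) -> PermutationNull:
    """Max-statistic permutation null for one (trait, host) run.

    Each permutation re-estimates the variance ratio and re-runs the full
    association scan on the shuffled trait. Requires ``n_permutations >= 100``
    and ``alpha`` in (0, 1].
    """
    if n_permutations < 100:
        raise ConfigError("need at least 100 permutations")
    if not (0.0 < alpha <= 1.0):
        raise ConfigError("alpha must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    ws = workspace or LMMWorkspace.build(panel, kinship)
    y = np.asarray(y, dtype=float)

    max_beta = np.empty(n_permutations)
    min_p = np.empty(n_permutations)
    for b in range(n_permutations):
        y_perm = y[rng.permutation(y.size)]
        beta, _, p, _ = scan_statistics(y_perm, ws)
        max_beta[b] = np.nanmax(np.abs(beta))
        min_p[b] = np.nanmin(p)

    return PermutationNull(
        trait=trait,
        host=host,
        n_permutations=n_permutations,
        alpha=alpha,
        seed=seed,
        null_max_beta=max_beta,
        null_min_p=min_p,
        threshold_beta=_order_statistic(max_beta, alpha, upper=True),
        threshold_p=_order_statistic(min_p, alpha, upper=False),
    )
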