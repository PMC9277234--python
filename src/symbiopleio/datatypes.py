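"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

MISSING = -1  # haploid genotype missing code


class DataError(ValueError):
    """Raised on malformed or non-conformable inputs."""


@dataclass
class GenotypePanel:
    """Haploid biallelic genotype matrix for ``S`` strains at ``L`` sites.

    ``genotypes`` is an ``(S, L)`` int8 array with entries 0 (ref), 1 (alt)
    or -1 (missing). Site metadata (replicon, 1-based position) aligns with
    columns; strain ids with rows.
    """

    genotypes: np.ndarray
    strain_ids: list[str]
    replicon: np.ndarray  # (L,) str
    pos: np.ndarray  # (L,) int, 1-based within replicon
    subpop: np.ndarray | None = None  # (S,) int labels, when simulated
    subpop_freq: np.ndarray | None = None  # (n_subpops, L) latent allele freqs, when simulated

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise DataError("genotypes must be a 2-D strains x sites matrix")
        s, l = self.genotypes.shape
        if len(self.strain_ids) != s:
            raise DataError("strain_ids length does not match genotype rows")
        self.replicon = np.asarray(self.replicon)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.replicon.shape != (l,) or self.pos.shape != (l,):
            raise DataError("site metadata does not match genotype columns")

    @property
    def n_strains(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def site_ids(self) -> np.ndarray:
        """Stable textual site identifiers, ``replicon:pos``."""
        return np.array([f"{r}:{p}" for r, p in zip(self.replicon, self.pos)])

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of strains with a missing call."""
        return self.missing_mask().mean(axis=0)

    def alt_frequency(self) -> np.ndarray:
        """Per-site alternate-allele frequency among non-missing calls."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        freq = g.mean(axis=0)
        return np.asarray(freq.filled(np.nan), dtype=float)

    def maf(self) -> np.ndarray:
        p = self.alt_frequency()
        return np.minimum(p, 1.0 - p)

    def imputed(self) -> np.ndarray:
        """Float copy with missing calls replaced by the site mean."""
        g = self.genotypes.astype(float)
        miss = self.missing_mask()
        g[miss] = np.nan
        means = np.nanmean(np.where(miss, np.nan, g), axis=0)
        means = np.nan_to_num(means, nan=0.0)
        idx = np.where(miss)
        g[idx] = means[idx[1]]
        return g

    def subset_sites(self, keep: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            genotypes=self.genotypes[:, keep],
            strain_ids=list(self.strain_ids),
            replicon=self.replicon[keep],
            pos=self.pos[keep],
            subpop=self.subpop,
            subpop_freq=self.subpop_freq[:, keep] if self.subpop_freq is not None else None,
        )


@dataclass
class TruthLedger:
    """Ground truth of a simulated study, for recovery tests only.

    ``causal`` is one row per planted causal site with its trait, host,
    signed beta, pair id, pair label (concordant/discordant) and pair
    category (symbiotic vs rhizobium-fitness pleiotropy).
    """

    causal: pd.DataFrame
    fitness: pd.DataFrame  # strain, host, w (positive multiplier), log_w
    initial_frequencies: dict[str, np.ndarray]  # host -> simplex over strains
    final_frequencies: dict[str, np.ndarray]  # host -> simplex over strains
    strain_ids: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "strain_ids": list(self.strain_ids),
            "causal": self.causal.to_dict(orient="records"),
            "fitness": self.fitness.to_dict(orient="records"),
            "initial_frequencies": {h: list(map(float, f)) for h, f in self.initial_frequencies.items()},
            "final_frequencies": {h: list(map(float, f)) for h, f in self.final_frequencies.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict[str, Any]) -> "TruthLedger":
        return cls(
            causal=pd.DataFrame(d["causal"]),
            fitness=pd.DataFrame(d["fitness"]),
            initial_frequencies={h: np.asarray(f, dtype=float) for h, f in d["initial_frequencies"].items()},
            final_frequencies={h: np.asarray(f, dtype=float) for h, f in d["final_frequencies"].items()},
            strain_ids=list(d.get("strain_ids", [])),
        )


@dataclass
class PoolObservation:
    """Pooled-sequencing read counts for one nodule pool at the panel sites."""

    pool_id: str
    host: str
    timepoint: str  # "initial" | "final"
    depth: np.ndarray  # (L,) int
    alt_count: np.ndarray  # (L,) int
    replicon: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        if self.depth.shape != self.alt_count.shape:
            raise DataError("depth and alt_count must align")
        if np.any(self.alt_count > self.depth) or np.any(self.depth < 0):
            raise DataError("require 0 <= alt_count <= depth at every site")
        if self.timepoint not in ("initial", "final"):
            raise DataError(f"unknown timepoint {self.timepoint!r}")
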