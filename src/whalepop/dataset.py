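"""Genotype dataset container shared by every analysis stage.

The container holds the *filtered-genotype* abstraction of a resequencing
study: diploid genotypes at biallelic variant sites (counting derived
alleles, ``-1`` = missing), per-site functional annotations, and an
aggregate account of the monomorphic callable sites that the site-frequency
spectrum and heterozygosity denominators need.  Monomorphic sites are not
materialised row-by-row; only their count and (optionally) per-population
called-haploid tallies are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

MISSING = -1

#: annotation codes: non-coding neutral, synonymous, tolerated NS,
#: deleterious NS (SIFT < 0.05), loss-of-function
ANNOTATIONS = ("NEU", "SYN", "TOL", "DEL", "LOF")
ANN_CODE = {name: i for i, name in enumerate(ANNOTATIONS)}
NEU, SYN, TOL, DEL, LOF = range(5)
CODING = (SYN, TOL, DEL, LOF)


@dataclass
class Dataset:
    """Diploid genotype matrix plus per-site metadata.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_sites)`` int8 array of derived-allele dosages
        in {0, 1, 2} with ``-1`` for missing.
    positions
        0-based bp coordinates, strictly increasing within a contig.
    pop_labels
        Population id per individual.
    annotation
        Per-site annotation code (see :data:`ANNOTATIONS`).
    sift_score
        SIFT score in [0, 1] for coding sites, NaN elsewhere.
    ancestral_known
        Whether the ancestral allele at the site is considered known.
    seq_len
        Total callable sequence length in bp (single synthetic contig).
    n_monomorphic
        Number of callable monomorphic sites not materialised in
        ``genotypes``.
    mono_called
        Optional ``(n_monomorphic, n_pops)`` int16 array with the number of
        called *diploid* genotypes per population at each monomorphic site.
        ``None`` means every monomorphic genotype is called.
    mono_called_ind
        Optional per-individual count of called monomorphic genotypes;
        ``None`` means all ``n_monomorphic`` are called for everyone.
    """

    genotypes: np.ndarray
    positions: np.ndarray
    pop_labels: np.ndarray
    annotation: np.ndarray = None
    sift_score: np.ndarray = None
    ancestral_known: np.ndarray = None
    seq_len: int = 0
    n_monomorphic: int = 0
    mono_called: np.ndarray | None = None
    mono_called_ind: np.ndarray | None = None
    contig: str = "1"

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.pop_labels = np.asarray(self.pop_labels)
        n_ind, n_sites = self.genotypes.shape
        if self.positions.shape != (n_sites,):
            raise ValueError("positions length must match genotype columns")
        if n_sites and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.pop_labels.shape != (n_ind,):
            raise ValueError("pop_labels length must match individuals")
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2,-1}")
        if self.annotation is None:
            self.annotation = np.full(n_sites, NEU, dtype=np.int8)
        else:
            self.annotation = np.asarray(self.annotation, dtype=np.int8)
        if self.sift_score is None:
            self.sift_score = np.full(n_sites, np.nan)
        else:
            self.sift_score = np.asarray(self.sift_score, dtype=float)
        coding = np.isin(self.annotation, CODING)
        if np.isnan(self.sift_score[coding]).any():
            raise ValueError("every coding site needs a sift_score")
        if self.ancestral_known is None:
            self.ancestral_known = np.ones(n_sites, dtype=bool)
        else:
            self.ancestral_known = np.asarray(self.ancestral_known, dtype=bool)
        if self.seq_len == 0:
            self.seq_len = int(self.positions[-1]) + 1 if n_sites else 0

    # -- basic accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict = {}
        for p in self.pop_labels:
            seen.setdefault(p, None)
        return list(seen)

    def individuals_of(self, pop: str) -> np.ndarray:
        idx = np.flatnonzero(self.pop_labels == pop)
        if idx.size == 0:
            raise KeyError(f"unknown population label: {pop!r}")
        return idx

    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes, shape ``(n_ind, n_sites)``."""
        return self.genotypes != MISSING

    def take_sites(self, mask: np.ndarray) -> "Dataset":
        """Subset to the selected variant sites (monomorphic block kept)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            positions=self.positions[idx],
            annotation=self.annotation[idx],
            sift_score=self.sift_score[idx],
            ancestral_known=self.ancestral_known[idx],
        )

    def take_individuals(self, idx: Sequence[int]) -> "Dataset":
        idx = np.asarray(idx)
        return replace(
            self,
            genotypes=self.genotypes[idx],
            pop_labels=self.pop_labels[idx],
            mono_called_ind=(
                None if self.mono_called_ind is None else self.mono_called_ind[idx]
            ),
        )


@dataclass
class FilterConfig:
    """Genotype- and site-level filter thresholds.

    Genotypes failing the depth / quality / allele-balance rules become
    missing; sites then exceeding the missingness or heterozygosity
    fractions are dropped entirely.
    """

    min_depth: int = 8
    max_depth_factor: float = 2.5
    min_gq: int = 20
    ab_homref_min: float = 0.9
    ab_het_min: float = 0.2
    ab_het_max: float = 0.8
    ab_homalt_max: float = 0.1
    max_site_missing: float = 0.20
    max_site_het: float = 0.75

    def __post_init__(self) -> None:
        for name in ("ab_homref_min", "ab_het_min", "ab_het_max",
                     "ab_homalt_max", "max_site_missing", "max_site_het"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {v}")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
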