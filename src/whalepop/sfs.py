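"""Folded one- and two-dimensional site frequency spectra.

Spectra are built from per-site (derived-count, called-haploid-count)
tallies and projected down to a common haploid sample size by hypergeometric
resampling, the standard device for accommodating missing genotypes.
Folding (minor-allele classes) happens *after* projection of the unfolded
tallies; folding first is not equivalent in general because the minor
allele of the full sample need not be the minor allele of a subsample.
Monomorphic sites enter the 0-bin only when called in at least the
projection size (per population, for joint spectra).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .dataset import Dataset, MISSING, NEU


@dataclass
class SiteTallies:
    """Unprojected per-site allele-count tallies for one population."""

    d: np.ndarray  # derived-allele count per site
    n: np.ndarray  # called haploid count per site
    n_dropped_all_missing: int = 0


@dataclass
class FoldedSFS:
    """Folded spectrum: real-valued mass per minor-allele class 0..n//2."""

    n_haploids: int
    counts: np.ndarray
    L_total: float = 0.0
    n_excluded_low_call: int = 0  # sites with fewer called haploids than m

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n_haploids // 2 + 1,):
            raise ValueError("folded SFS length must be n//2 + 1")
        if (self.counts < -1e-12).any():
            raise ValueError("SFS masses must be non-negative")

    @property
    def monomorphic_count(self) -> float:
        return float(self.counts[0])

    @property
    def polymorphic_mass(self) -> float:
        return float(self.counts[1:].sum())

    def to_dadi_text(self) -> str:
        """dadi-style flat export: size line, mass line, mask line."""
        n = self.n_haploids
        full = np.zeros(n + 1)
        full[: self.counts.size] = np.round(self.counts + 1e-12)  # half-up
        mask = np.ones(n + 1, dtype=int)
        mask[: self.counts.size] = 0
        mask[0] = 1  # monomorphic bin masked by convention
        return "{} folded\n{}\n{}\n".format(
            n + 1,
            " ".join(f"{v:.0f}" for v in full),
            " ".join(str(v) for v in mask),
        )


def read_dadi_text(text: str) -> FoldedSFS:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    header = lines[0].split()
    n = int(header[0]) - 1
    vals = np.array([float(v) for v in lines[1].split()])
    return FoldedSFS(n_haploids=n, counts=vals[: n // 2 + 1])


@dataclass
class JointSFS:
    """Two-population spectrum on derived-count classes (n1+1) x (n2+1).

    Kept unfolded internally; :meth:`folded` combines each cell with its
    complementary cell (dadi's joint folding convention).
    """

    n1: int
    n2: int
    counts: np.ndarray
    L_total: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError("joint SFS shape must be (n1+1, n2+1)")

    def folded(self) -> np.ndarray:
        """Minor-allele folded matrix: cell (i,j) pooled with (n1-i, n2-j)."""
        c = self.counts
        i = np.arange(self.n1 + 1)[:, None]
        j = np.arange(self.n2 + 1)[None, :]
        tot = i + j
        half = (self.n1 + self.n2) / 2.0
        out = np.where(tot < half, c + c[::-1, ::-1], c)
        out = np.where(tot == half, (c + c[::-1, ::-1]) / 2.0, out)
        out = np.where(tot > half, 0.0, out)
        return out


# ---------------------------------------------------------------------------
# tally construction

def build_sfs(ds: Dataset, pop: str, sites: np.ndarray | None = None) -> SiteTallies:
    """Tally per-site derived and called-haploid counts for one population.

    Parameters
    ----------
    sites
        Optional boolean mask over variant sites (e.g. an annotation
        filter); default keeps all sites.
    """
    idx = ds.individuals_of(pop)
    g = ds.genotypes[idx]
    if sites is not None:
        g = g[:, np.asarray(sites)]
    called = g != MISSING
    n = 2 * called.sum(axis=0)
    d = np.where(called, g, 0).sum(axis=0)
    keep = n > 0
    return SiteTallies(
        d=d[keep].astype(np.int64),
        n=n[keep].astype(np.int64),
        n_dropped_all_missing=int((~keep).sum()),
    )


def neutral_mask(ds: Dataset) -> np.ndarray:
    return ds.annotation == NEU


# ---------------------------------------------------------------------------
# projection

def _project_counts(d: np.ndarray, n: np.ndarray, m: int) -> tuple[np.ndarray, int]:
    """Unfolded projected masses over classes 0..m plus low-call exclusions.

    Each site with n >= m contributes hypergeometric mass
    P(j successes | population n, d derived, draws m) to class j.
    """
    out = np.zeros(m + 1)
    ok = n >= m
    excluded = int((~ok).sum())
    d, n = d[ok], n[ok]
    pairs, counts = np.unique(np.stack([n, d]), axis=1, return_counts=True)
    j = np.arange(m + 1)
    for (ni, di), c in zip(pairs.T, counts):
        out += c * hypergeom.pmf(j, ni, di, m)
    return out, excluded


def project_sfs(tallies: SiteTallies, m: int, fold: bool = True) -> FoldedSFS | np.ndarray:
    """Project tallies to ``m`` haploids; fold to minor-allele classes.

    With ``fold=False`` the raw unfolded mass vector (length m+1) is
    returned instead of a :class:`FoldedSFS`.
    """
    if m < 2:
        raise ValueError("projection size must be >= 2")
    unfolded, excluded = _project_counts(tallies.d, tallies.n, m)
    if not fold:
        return unfolded
    k = m // 2
    folded = np.zeros(k + 1)
    for j in range(m + 1):
        folded[min(j, m - j)] += unfolded[j]
    if m % 2 == 0:
        pass  # middle class j=m/2 maps to itself exactly once
    return FoldedSFS(n_haploids=m, counts=folded, n_excluded_low_call=excluded)


def choose_projection(tallies: SiteTallies, candidate_sizes) -> int:
    """Projection size maximizing retained polymorphic mass.

    Ties are broken toward the larger size (more frequency classes).
    """
    candidates = sorted(set(int(c) for c in candidate_sizes))
    if not candidates:
        raise ValueError("candidate_sizes must be non-empty")
    best_m, best_mass = None, -np.inf
    for m in candidates:  # ascending, so >= keeps the largest on ties
        sfs = project_sfs(tallies, m)
        mass = sfs.polymorphic_mass
        if mass >= best_mass - 1e-9:
            if mass > best_mass + 1e-9 or best_m is None or m > best_m:
                best_m, best_mass = m, max(mass, best_mass)
    return best_m


def project_joint_sfs(
    tx: SiteTallies, ty: SiteTallies, m1: int, m2: int
) -> JointSFS:
    """Joint projection assuming tallies are site-aligned (shared sites)."""
    if tx.d.size != ty.d.size:
        raise ValueError("joint projection requires site-aligned tallies")
    counts = np.zeros((m1 + 1, m2 + 1))
    ok = (tx.n >= m1) & (ty.n >= m2)
    j1 = np.arange(m1 + 1)
    j2 = np.arange(m2 + 1)
    key = np.stack([tx.n[ok], tx.d[ok], ty.n[ok], ty.d[ok]])
    pairs, reps = np.unique(key, axis=1, return_counts=True)
    for (n1, d1, n2, d2), c in zip(pairs.T, reps):
        p1 = hypergeom.pmf(j1, n1, d1, m1)
        p2 = hypergeom.pmf(j2, n2, d2, m2)
        counts += c * np.outer(p1, p2)
    return JointSFS(n1=m1, n2=m2, counts=counts)


# ---------------------------------------------------------------------------
# monomorphic bookkeeping

def count_qualifying_monomorphic(ds: Dataset, min_called_hap: dict[str, int]) -> int:
    """Monomorphic sites called in at least the given haploids per population."""
    pops = ds.populations
    if ds.mono_called is None:
        # fully called everywhere: qualifies iff thresholds are satisfiable
        for pop, m in min_called_hap.items():
            if 2 * len(ds.individuals_of(pop)) < m:
                return 0
        return int(ds.n_monomorphic)
    ok = np.ones(ds.mono_called.shape[0], dtype=bool)
    for pop, m in min_called_hap.items():
        ok &= 2 * ds.mono_called[:, pops.index(pop)] >= m
    return int(ok.sum())


def add_monomorphic(
    sfs: FoldedSFS | JointSFS, ds: Dataset, min_called_hap: dict[str, int]
) -> FoldedSFS | JointSFS:
    """Add qualifying monomorphic sites to the 0-bin (or (0,0)-cell)."""
    n_mono = count_qualifying_monomorphic(ds, min_called_hap)
    if isinstance(sfs, FoldedSFS):
        counts = sfs.counts.copy()
        counts[0] += n_mono
        return FoldedSFS(
            n_haploids=sfs.n_haploids,
            counts=counts,
            L_total=sfs.L_total + n_mono,
            n_excluded_low_call=sfs.n_excluded_low_call,
        )
    counts = sfs.counts.copy()
    counts[0, 0] += n_mono
    return JointSFS(n1=sfs.n1, n2=sfs.n2, counts=counts, L_total=sfs.L_total + n_mono)
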