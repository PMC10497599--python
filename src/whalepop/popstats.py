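"""Population summaries: heterozygosity, Weir-Cockerham F_ST with
permutation significance, substructure inflation, LD pruning and
method-of-moments kinship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import Dataset, MISSING


# ---------------------------------------------------------------------------
# heterozygosity

def genome_wide_heterozygosity(ds: Dataset, individual: int) -> float:
    """Heterozygous genotypes per kb of called genotypes (monomorphic
    sites included in the denominator)."""
    g = ds.genotypes[individual]
    called_var = int((g != MISSING).sum())
    if ds.mono_called_ind is not None:
        called_mono = int(ds.mono_called_ind[individual])
    else:
        called_mono = ds.n_monomorphic
    called = called_var + called_mono
    if called == 0:
        raise ValueError("individual has zero called genotypes")
    het = int((g == 1).sum())
    return 1000.0 * het / called


def windowed_heterozygosity(
    ds: Dataset,
    individual: int,
    window: int = 1_000_000,
    max_missing: float = 0.80,
) -> np.ndarray:
    """Per-window het/kb over non-overlapping windows; windows with more
    than ``max_missing`` missing data are NaN-masked.

    Monomorphic sites are assumed uniformly distributed over the sequence
    for the per-window called-site denominator.
    """
    g = ds.genotypes[individual]
    n_win = int(np.ceil(ds.seq_len / window))
    win_of = ds.positions // window
    het = np.bincount(win_of[g == 1], minlength=n_win).astype(float)
    called_var = np.bincount(win_of[g != MISSING], minlength=n_win).astype(float)
    # spread monomorphic mass uniformly across windows
    if ds.mono_called_ind is not None:
        mono_total = float(ds.mono_called_ind[individual])
    else:
        mono_total = float(ds.n_monomorphic)
    win_len = np.full(n_win, float(window))
    win_len[-1] = ds.seq_len - (n_win - 1) * window
    called = called_var + mono_total * win_len / ds.seq_len
    missing_frac = 1.0 - called / win_len
    out = np.where(called > 0, 1000.0 * het / np.maximum(called, 1e-12), 0.0)
    out[missing_frac > max_missing] = np.nan
    return out


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST

@dataclass
class FstResult:
    fst: float
    p_value: float | None
    inflation_factor: float
    n_permutations: int = 0


def _wc_components(g: np.ndarray, labels: np.ndarray):
    """Per-locus Weir-Cockerham (1984) variance components a, b, c.

    Two-level hierarchy (populations, individuals within populations) for
    a biallelic locus; missing genotypes excluded per locus.
    """
    pops = np.unique(labels)
    r = len(pops)
    n_loci = g.shape[1]
    a = np.zeros(n_loci)
    b = np.zeros(n_loci)
    c = np.zeros(n_loci)
    n_i = np.zeros((r, n_loci))      # called individuals per pop
    p_i = np.zeros((r, n_loci))      # allele frequency per pop
    h_i = np.zeros((r, n_loci))      # observed het frequency per pop
    for k, pop in enumerate(pops):
        gp = g[labels == pop]
        called = gp != MISSING
        n_i[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_i[k] = np.where(called, gp, 0).sum(axis=0) / np.maximum(2 * n_i[k], 1)
            h_i[k] = (gp == 1).sum(axis=0) / np.maximum(n_i[k], 1)
    n_tot = n_i.sum(axis=0)
    n_bar = n_tot / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_tot - (n_i**2).sum(axis=0) / np.maximum(n_tot, 1e-12)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / np.maximum(n_tot, 1e-12)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * np.maximum(n_bar, 1e-12))
        h_bar = (n_i * h_i).sum(axis=0) / np.maximum(n_tot, 1e-12)
        a = (n_bar / np.maximum(nc, 1e-12)) * (
            s2
            - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
            / np.maximum(n_bar - 1, 1e-12)
        )
        b = (n_bar / np.maximum(n_bar - 1, 1e-12)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    ok = (n_i > 0).all(axis=0) & (n_bar > 1)
    return a[ok], b[ok], c[ok]


def wc_fst(
    ds_or_genotypes,
    labels: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> FstResult:
    """Multi-locus ratio-of-sums Weir-Cockerham F_ST with permutation p.

    p = (1 + #{permuted F_ST >= observed}) / (1 + n_perm).
    """
    if isinstance(ds_or_genotypes, Dataset):
        g = ds_or_genotypes.genotypes
        labels = ds_or_genotypes.pop_labels if labels is None else labels
    else:
        g = np.asarray(ds_or_genotypes)
    labels = np.asarray(labels)
    pops, counts = np.unique(labels, return_counts=True)
    if len(pops) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 individuals each")

    def estimate(lab):
        a, b, c = _wc_components(g, lab)
        denom = (a + b + c).sum()
        if denom == 0:
            raise ValueError("F_ST undefined: no polymorphic loci")
        return a.sum() / denom

    fst = estimate(labels)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            try:
                if estimate(perm) >= fst:
                    exceed += 1
            except ValueError:
                pass
        p = (1 + exceed) / (1 + n_perm)
    return FstResult(
        fst=float(fst),
        p_value=p,
        inflation_factor=1.0 / (1.0 - fst) if fst < 1 else np.inf,
        n_permutations=n_perm,
    )


def substructure_inflation(fst: float) -> float:
    """Percent inflation of Ne estimates due to substructure: 1/(1-F_ST)-1."""
    if fst >= 1:
        raise ValueError("F_ST must be < 1")
    return (1.0 / (1.0 - fst) - 1.0) * 100.0


# ---------------------------------------------------------------------------
# LD pruning

def ld_prune(
    ds: Dataset,
    r2_max: float = 0.2,
    maf_min: float = 0.10,
    window: int = 500_000,
    step: int = 100_000,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained site indices.

    r^2 uses genotype correlation on pairwise-complete observations.  No
    retained pair within a window exceeds ``r2_max``; all retained sites
    have minor-allele frequency >= ``maf_min``.
    """
    g = ds.genotypes.astype(float)
    g[g == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    alive = maf >= maf_min
    pos = ds.positions
    start = 0
    while start < ds.seq_len:
        in_win = np.flatnonzero(alive & (pos >= start) & (pos < start + window))
        for ii, i in enumerate(in_win):
            if not alive[i]:
                continue
            for j in in_win[ii + 1:]:
                if not alive[j]:
                    continue
                r2 = _pair_r2(g[:, i], g[:, j])
                if r2 > r2_max:
                    alive[j] = False
        start += step
    return np.flatnonzero(alive)


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return 0.0
    xv, yv = x[ok], y[ok]
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    return float(np.corrcoef(xv, yv)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# kinship (PLINK-style method of moments)

def kinship_mom(
    ds: Dataset,
    pair: tuple[int, int],
    min_overlap: int = 20,
    allele_freqs: np.ndarray | None = None,
) -> float:
    """Method-of-moments IBD kinship for one pair of individuals.

    Estimates the IBD-sharing probabilities (k0, k1, k2) from identity-by-
    state counts given pooled allele frequencies and returns kinship
    0.5 k2 + 0.25 k1.  Self-pairs return 0.5 by definition.
    """
    i, j = pair
    gi = ds.genotypes[i].astype(float)
    gj = ds.genotypes[j].astype(float)
    gi[ds.genotypes[i] == MISSING] = np.nan
    gj[ds.genotypes[j] == MISSING] = np.nan
    ok = ~(np.isnan(gi) | np.isnan(gj))
    if ok.sum() < min_overlap:
        raise ValueError("insufficient genotype overlap for kinship")
    if i == j:
        return 0.5
    g1, g2 = gi[ok], gj[ok]
    if allele_freqs is None:
        gall = ds.genotypes.astype(float)
        gall[ds.genotypes == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            p = np.nanmean(gall, axis=0)[ok] / 2.0
    else:
        p = np.asarray(allele_freqs)[ok]
    q = 1.0 - p
    informative = (p > 0) & (p < 1)
    g1, g2, p, q = g1[informative], g2[informative], p[informative], q[informative]
    n = g1.size
    ibs0 = float((np.abs(g1 - g2) == 2).sum())
    ibs1 = float((np.abs(g1 - g2) == 1).sum())
    ibs2 = n - ibs0 - ibs1
    # expected IBS state probabilities given IBD state (Purcell et al. 2007)
    e0_ibd0 = float((2 * p**2 * q**2).sum())
    e1_ibd0 = float((4 * p**3 * q + 4 * p * q**3).sum())
    e1_ibd1 = float((2 * p**2 * q + 2 * p * q**2).sum())
    e2_ibd0 = float((p**4 + q**4 + 4 * p**2 * q**2).sum())
    e2_ibd1 = float((p**3 + q**3 + p**2 * q + p * q**2).sum())
    k0 = ibs0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
    k1 = (ibs1 - k0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    k2 = (ibs2 - k0 * e2_ibd0 - k1 * e2_ibd1) / n
    k0, k1, k2 = _clamp_simplex(k0, k1, k2)
    return 0.5 * k2 + 0.25 * k1


def _clamp_simplex(k0, k1, k2):
    ks = np.clip([k0, k1, k2], 0.0, 1.0)
    s = ks.sum()
    if s > 0:
        ks = ks / s
    return tuple(ks)
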