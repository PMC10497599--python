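"""Expected site frequency spectra under demographic models.

Two engines:

* an analytic expectation for piecewise-constant single-population models,
  obtained by integrating the lineage-count process of the coalescent
  epoch-by-epoch (matrix exponentials of the pure-death chain) and
  combining the expected inter-coalescent times with the classical
  combinatorial weights C(n-i-1, k-2)/C(n-1, k-1) for the probability that
  a branch ancestral to k lineages subtends i of the n leaves;
* a Monte-Carlo expectation for structured two-population models, averaging
  branch lengths subtending each joint frequency class over independent
  coalescent trees (the expectation step of SFS-based coalescent
  inference), with a per-cell standard error.

Expected spectra scale linearly in mu and L.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm
from scipy.special import gammaln

import msprime

from ..sfs import FoldedSFS, JointSFS
from .models import EpochModel, ScalingContext, TwoPopModel


def _branch_subtend_weights(n: int) -> np.ndarray:
    """W[k, i]: P(a random branch present while k lineages remain subtends
    exactly i of the n leaves); rows k=2..n, columns i=1..n-1."""
    k = np.arange(2, n + 1)[:, None]
    i = np.arange(1, n)[None, :]

    def logc(a, b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        bad = (b < 0) | (b > a)
        with np.errstate(invalid="ignore"):
            out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
        return np.where(bad, -np.inf, out)

    logw = logc(n - i - 1, k - 2) - logc(n - 1, k - 1)
    return np.exp(logw)


def expected_branch_times(model: EpochModel, n: int) -> np.ndarray:
    """E[T_k]: expected generations spent with k=2..n ancestral lineages.

    The lineage-count process is a pure-death chain with rate C(k,2)/(2N)
    while the population size is N; within each constant-size epoch both
    the end-point distribution and the occupation-time integral follow from
    one block matrix exponential.  The ancestral epoch contributes
    2N/C(k,2) times the probability of ever having k lineages there.
    """
    if n < 2:
        raise ValueError("need n >= 2 haploids")
    ks = np.arange(2, n + 1)
    rates = ks * (ks - 1) / 2.0  # C(k,2)
    dim = n - 1
    # Q for unit 2N: sub-diagonal feeds k -> k-1 (index k-2 -> k-3)
    Q0 = np.zeros((dim, dim))
    Q0[np.arange(dim), np.arange(dim)] = -rates
    Q0[np.arange(dim - 1), np.arange(1, dim)] = rates[1:]

    p = np.zeros(dim)
    p[-1] = 1.0  # start with n lineages
    ET = np.zeros(dim)

    # iterate finite epochs present -> past (ancestral epoch handled last)
    for size, dur in zip(model.sizes[:0:-1], model.durations[::-1]):
        if dur == 0.0:
            continue
        Q = Q0 / (2.0 * size)
        block = np.zeros((2 * dim, 2 * dim))
        block[:dim, :dim] = Q
        block[:dim, dim:] = np.eye(dim)
        eb = expm(block * dur)
        ET += eb[:dim, dim:] @ p
        p = eb[:dim, :dim] @ p
    # ancestral epoch (extends to -inf in forward time)
    n_anc = model.sizes[0]
    p_ge = np.cumsum(p[::-1])[::-1]  # P(at least k lineages on entry)
    ET += 2.0 * n_anc / rates * p_ge
    return ET


def expected_sfs_epoch(
    model: EpochModel,
    n: int,
    ctx: ScalingContext,
    fold: bool = True,
    monomorphic: str = "complement",
) -> FoldedSFS | np.ndarray:
    """Analytic expected SFS mass per frequency class for n haploids.

    E[xi_i] = mu L sum_k k E[T_k] W[k,i].  With ``fold=False`` the unfolded
    vector over derived classes 0..n is returned (class 0 and n carry the
    monomorphic complement mass and 0).  ``monomorphic='complement'`` puts
    L - sum(polymorphic) in the 0 class; ``'zero'`` leaves it empty.
    """
    ET = expected_branch_times(model, n)
    W = _branch_subtend_weights(n)
    ks = np.arange(2, n + 1)
    xi = ctx.mu * ctx.L * (ks * ET) @ W  # classes i=1..n-1
    full = np.zeros(n + 1)
    full[1:n] = xi
    if monomorphic == "complement":
        full[0] = max(ctx.L - xi.sum(), 0.0)
    if not fold:
        return full
    return FoldedSFS(n_haploids=n, counts=_fold_vector(full), L_total=ctx.L)


def expected_sfs_epoch_mc(
    model: EpochModel,
    n: int,
    ctx: ScalingContext,
    n_trees: int = 10_000,
    seed: int = 1,
    fold: bool = True,
):
    """Monte-Carlo counterpart of :func:`expected_sfs_epoch` (independent
    coalescent trees, branch-mode spectra); returns (masses, se)."""
    dem = model.to_msprime()
    reps = msprime.sim_ancestry(
        samples={"pop": n / 2},
        demography=dem,
        sequence_length=1,
        num_replicates=n_trees,
        random_seed=seed,
        ploidy=2,
    )
    acc = np.zeros(n + 1)
    acc2 = np.zeros(n + 1)
    for ts in reps:
        afs = ts.allele_frequency_spectrum(
            mode="branch", polarised=True, span_normalise=True
        )
        acc += afs
        acc2 += afs**2
    mean = acc / n_trees
    var = acc2 / n_trees - mean**2
    se = np.sqrt(np.maximum(var, 0) / n_trees) * ctx.mu * ctx.L
    exp = mean * ctx.mu * ctx.L
    if fold:
        exp = _fold_vector(exp)
        se = np.sqrt(_fold_vector(se**2))
    return exp, se


def _fold_vector(full: np.ndarray) -> np.ndarray:
    n = full.size - 1
    folded = np.zeros(n // 2 + 1)
    for j in range(n + 1):
        folded[min(j, n - j)] += full[j]
    return folded


def simulated_sfs_epoch(
    model: EpochModel,
    n: int,
    ctx: ScalingContext,
    rec: float = 1e-8,
    n_chunks: int = 40,
    seed: int = 1,
) -> FoldedSFS:
    """Coalescent-simulated folded SFS under a physical-unit epoch model.

    The sequence is split into independent chunks (recombination within
    chunks), so the spectrum carries realistic linkage noise — the
    generative process behind linkage-aware parametric bootstraps.
    """
    dem = model.to_msprime("pop")
    afs = np.zeros(n + 1)
    reps = msprime.sim_ancestry(
        samples={"pop": n / 2},
        demography=dem,
        sequence_length=ctx.L / n_chunks,
        recombination_rate=rec,
        num_replicates=n_chunks,
        random_seed=seed,
    )
    for i, ts in enumerate(reps):
        ts = msprime.sim_mutations(ts, rate=ctx.mu,
                                   random_seed=seed + 1009 * (i + 1))
        afs += ts.allele_frequency_spectrum(mode="site", polarised=True,
                                            span_normalise=False)
    return FoldedSFS(n, _fold_vector(afs), L_total=ctx.L)


def expected_sfs_structured_mc(
    model: TwoPopModel,
    n1: int,
    n2: int,
    ctx: ScalingContext,
    n_trees: int = 100_000,
    seed: int = 1,
) -> tuple[JointSFS, np.ndarray]:
    """Monte-Carlo expected joint SFS under the structured coalescent.

    Averages branch lengths subtending each (d1, d2) class over
    ``n_trees`` independent trees; returns the expected joint spectrum
    (mu L scaled) and the per-cell Monte-Carlo standard error.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    p1, p2 = model.pop_names
    samples = {}
    if n1 > 0:
        samples[p1] = n1 / 2
    if n2 > 0:
        samples[p2] = n2 / 2
    dem = model.to_msprime()
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=1,
        num_replicates=n_trees,
        random_seed=seed,
        ploidy=2,
    )
    shape = (n1 + 1, n2 + 1)
    acc = np.zeros(shape)
    acc2 = np.zeros(shape)

    def sample_sets_for(ts):
        out = []
        for name, count in ((p1, n1), (p2, n2)):
            if count > 0:
                pid = [p.id for p in ts.populations() if p.metadata.get("name") == name][0]
                out.append(ts.samples(population=pid))
        return out

    def fix_shape(afs):
        a = np.asarray(afs)
        if a.shape == shape:
            return a
        out = np.zeros(shape)
        if n1 > 0 and n2 == 0:
            out[:, 0] = a
        elif n1 == 0 and n2 > 0:
            out[0, :] = a
        else:
            raise ValueError("unexpected AFS shape")
        return out

    for ts in reps:
        a = fix_shape(ts.allele_frequency_spectrum(
            sample_sets=sample_sets_for(ts), mode="branch",
            polarised=True, span_normalise=True))
        acc += a
        acc2 += a**2
    mean = acc / n_trees
    var = np.maximum(acc2 / n_trees - mean**2, 0.0)
    scale = ctx.mu * ctx.L
    joint = JointSFS(n1=n1, n2=n2, counts=mean * scale, L_total=ctx.L)
    se = np.sqrt(var / n_trees) * scale
    return joint, se
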