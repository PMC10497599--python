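"""Synthetic genotype datasets with the statistical structure the
downstream analyses assume.

Coalescent genotypes come from msprime under the demographic model
catalogue; functional annotations (SYN/TOL/DEL/LOF with SIFT scores) are
assigned to exonic sites at a configurable nonsynonymous:synonymous ratio;
sequencing noise is emulated at the genotype level (negative-binomial
depth, binomial read support) so the study's depth / quality / allele
balance / missingness filter cascade is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import msprime

from .dataset import Dataset, FilterConfig, MISSING, NEU, SYN, TOL, DEL, LOF
from .demography.models import EpochModel, TwoPopModel


def simulate_genotypes(
    model: EpochModel | TwoPopModel,
    n_per_pop: dict[str, int] | int,
    seq_len: float,
    mu: float = 2.77e-8,
    rec: float = 1e-8,
    seed: int = 1,
    mispolarization_rate: float = 0.0,
) -> Dataset:
    """Coalescent-simulated diploid genotypes plus monomorphic bookkeeping.

    ``n_per_pop`` maps population name to diploid count (an int for
    single-population models).  Only biallelic SNPs are materialised; the
    monomorphic complement is recorded as a count.  Derived-allele coding
    is exact unless ``mispolarization_rate`` > 0, in which case the stated
    fraction of sites is flipped (and flagged ancestral-unknown).
    """
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    if mu < 0 or rec < 0:
        raise ValueError("rates must be non-negative")
    if isinstance(model, EpochModel):
        dem = model.to_msprime("pop")
        samples = {"pop": n_per_pop if isinstance(n_per_pop, int) else n_per_pop["pop"]}
    else:
        dem = model.to_msprime()
        samples = dict(n_per_pop)
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=seq_len,
        recombination_rate=rec,
        random_seed=seed,
        ploidy=2,
    )
    ts = msprime.sim_mutations(
        ts, rate=mu, random_seed=seed + 1, model=msprime.BinaryMutationModel()
    )
    n_ind = sum(int(v) for v in samples.values())
    keep_pos, genos = [], []
    for var in ts.variants():
        g = var.genotypes
        if len(var.alleles) > 2:
            continue  # multi-allelic sites are never emitted
        dip = g.reshape(n_ind, 2).sum(axis=1).astype(np.int8)
        if dip.min() == dip.max():
            continue  # fixed in the sample: counts toward monomorphic
        keep_pos.append(int(var.site.position))
        genos.append(dip)
    # de-duplicate integer positions (possible at high density)
    pos = np.array(keep_pos, dtype=np.int64)
    uniq = np.concatenate([[True], np.diff(pos) > 0]) if pos.size else np.zeros(0, bool)
    pos = pos[uniq]
    genotypes = (
        np.array(genos, dtype=np.int8).T[:, uniq]
        if genos
        else np.zeros((n_ind, 0), dtype=np.int8)
    )
    labels = np.concatenate(
        [np.repeat(name, int(cnt)) for name, cnt in samples.items()]
    )
    rng = np.random.default_rng(seed + 2)
    ancestral_known = np.ones(pos.size, dtype=bool)
    if mispolarization_rate > 0:
        flip = rng.random(pos.size) < mispolarization_rate
        genotypes[:, flip] = 2 - genotypes[:, flip]
        ancestral_known[flip] = False
    return Dataset(
        genotypes=genotypes,
        positions=pos,
        pop_labels=labels,
        ancestral_known=ancestral_known,
        seq_len=int(seq_len),
        n_monomorphic=int(seq_len) - pos.size,
    )


def assign_annotations(
    ds: Dataset,
    exon_fraction: float = 0.013,
    ns_to_s_ratio: float = 2.31,
    del_fraction: float = 0.5,
    lof_fraction: float = 0.02,
    seed: int = 1,
) -> Dataset:
    """Assign SYN/TOL/DEL/LOF classes and SIFT scores to exonic sites.

    Exonic sites are chosen as a random fraction of variant sites;
    nonsynonymous sites occur at ``ns_to_s_ratio`` : 1 relative to
    synonymous ones.  A ``del_fraction`` of nonsynonymous sites get SIFT
    scores below the 0.05 deleteriousness threshold (the rest are
    tolerated, score >= 0.05); a small ``lof_fraction`` of nonsynonymous
    sites are upgraded to loss-of-function.  Non-exonic sites stay NEUTRAL.
    """
    if exon_fraction < 0 or ns_to_s_ratio < 0 or del_fraction < 0:
        raise ValueError("fractions and ratios must be non-negative")
    rng = np.random.default_rng(seed)
    n = ds.n_sites
    ann = np.full(n, NEU, dtype=np.int8)
    sift = np.full(n, np.nan)
    exonic = rng.random(n) < exon_fraction
    p_ns = ns_to_s_ratio / (1.0 + ns_to_s_ratio)
    ns = exonic & (rng.random(n) < p_ns)
    ann[exonic] = SYN
    deleterious = ns & (rng.random(n) < del_fraction)
    ann[ns] = TOL
    ann[deleterious] = DEL
    lof = ns & (rng.random(n) < lof_fraction)
    ann[lof] = LOF
    # SIFT scores: deleterious < 0.05, tolerated/other coding >= 0.05
    n_sites = int(ns.sum())
    sift[ns] = np.where(
        deleterious[ns], rng.uniform(0.0, 0.05, n_sites),
        rng.uniform(0.05, 1.0, n_sites),
    )
    sift[exonic & ~ns] = rng.uniform(0.05, 1.0, int((exonic & ~ns).sum()))
    out = ds.take_sites(np.ones(n, dtype=bool))
    out.annotation = ann
    out.sift_score = sift
    return out


@dataclass
class NoiseModel:
    """Per-genotype sequencing-noise generator.

    Depth is negative-binomial around ``mean_depth`` (dispersion ``k``);
    genotype quality comes from a binomial read-support model: the number
    of reads supporting each allele given the true genotype, with a small
    base-error rate.  ``None``-like infinite-depth behaviour is obtained
    with ``error_rate=0`` and large ``mean_depth``.
    """

    mean_depth: float = 30.0
    dispersion: float = 10.0
    error_rate: float = 1e-3
    max_gq: int = 99

    def sample(self, shape, rng: np.random.Generator):
        p = self.dispersion / (self.dispersion + self.mean_depth)
        depth = rng.negative_binomial(self.dispersion, p, size=shape)
        return depth


def apply_filter_cascade(
    ds: Dataset,
    noise: NoiseModel | None,
    cfg: FilterConfig | None = None,
    seed: int = 1,
) -> tuple[Dataset, dict[str, int]]:
    """Emulate the genotype-level filter cascade and site-level pruning.

    Genotypes failing depth / GQ / allele-balance rules become missing;
    sites with more than ``max_site_missing`` missing genotypes or more
    than ``max_site_het`` heterozygous genotypes are dropped.  Returns the
    filtered dataset and per-rule removal tallies.  With ``noise=None``
    the cascade only applies the site-level rules (no genotype is touched),
    so the operation is idempotent.
    """
    if ds.n_sites == 0 and ds.n_monomorphic == 0:
        raise ValueError("empty dataset")
    cfg = cfg or FilterConfig()
    rng = np.random.default_rng(seed)
    g = ds.genotypes.copy()
    n_ind, n_sites = g.shape
    tallies = {
        "genotypes_fail_depth": 0,
        "genotypes_fail_gq": 0,
        "genotypes_fail_allele_balance": 0,
        "sites_fail_missingness": 0,
        "sites_fail_het_excess": 0,
    }
    mono_called = ds.mono_called
    mono_called_ind = ds.mono_called_ind

    if noise is not None and n_sites:
        depth = noise.sample((n_ind, n_sites), rng)
        max_depth = cfg.max_depth_factor * noise.mean_depth
        bad_depth = (depth < cfg.min_depth) | (depth > max_depth)
        # read support: alt reads ~ Binomial(depth, p) with p by genotype
        p_alt = np.select([g == 0, g == 1, g == 2],
                          [noise.error_rate, 0.5, 1.0 - noise.error_rate], 0.0)
        alt = rng.binomial(depth, p_alt)
        ref = depth - alt
        with np.errstate(invalid="ignore", divide="ignore"):
            ab = np.where(depth > 0, ref / np.maximum(depth, 1), 0.0)
        bad_ab = np.zeros_like(bad_depth)
        bad_ab |= (g == 0) & (ab < cfg.ab_homref_min)
        bad_ab |= (g == 1) & ((ab < cfg.ab_het_min) | (ab > cfg.ab_het_max))
        bad_ab |= (g == 2) & (ab > cfg.ab_homalt_max)
        # GQ from the likelihood gap of the binomial read-support model
        gq = _genotype_quality(ref, alt, noise.error_rate, noise.max_gq)
        bad_gq = gq < cfg.min_gq
        tallies["genotypes_fail_depth"] = int(bad_depth.sum())
        tallies["genotypes_fail_gq"] = int((bad_gq & ~bad_depth).sum())
        tallies["genotypes_fail_allele_balance"] = int(
            (bad_ab & ~bad_depth & ~bad_gq).sum()
        )
        g[bad_depth | bad_gq | bad_ab] = MISSING
        # monomorphic sites experience the homozygous-reference failure rate
        mono_called, mono_called_ind = _thin_monomorphic(
            ds, noise, cfg, rng
        )

    called = g != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        miss_frac = 1.0 - n_called / n_ind
        het_frac = np.where(n_called > 0, (g == 1).sum(axis=0) / np.maximum(n_called, 1), 1.0)
    drop_miss = miss_frac > cfg.max_site_missing
    drop_het = het_frac > cfg.max_site_het
    tallies["sites_fail_missingness"] = int(drop_miss.sum())
    tallies["sites_fail_het_excess"] = int((drop_het & ~drop_miss).sum())
    keep = ~(drop_miss | drop_het)
    out = ds.take_sites(keep)
    out.genotypes = g[:, keep]
    out.mono_called = mono_called
    out.mono_called_ind = mono_called_ind
    return out, tallies


def _genotype_quality(ref, alt, err, max_gq):
    """Phred-scaled gap between best and second-best genotype likelihood."""
    from scipy.stats import binom

    depth = ref + alt
    with np.errstate(divide="ignore"):
        ll0 = binom.logpmf(alt, depth, err)
        ll1 = binom.logpmf(alt, depth, 0.5)
        ll2 = binom.logpmf(alt, depth, 1.0 - err)
    lls = np.stack([ll0, ll1, ll2])
    srt = np.sort(lls, axis=0)
    gap = (srt[-1] - srt[-2]) * 10.0 / np.log(10.0)
    return np.minimum(gap, max_gq)


def _thin_monomorphic(ds, noise, cfg, rng):
    """Aggregate called-genotype bookkeeping for monomorphic sites.

    Each monomorphic genotype is called iff a homozygous-reference
    genotype passes depth/GQ/allele-balance; the pass probability is
    estimated once by Monte Carlo and per-site per-population called
    counts are drawn binomially.
    """
    probe = 20_000
    depth = noise.sample(probe, rng)
    max_depth = cfg.max_depth_factor * noise.mean_depth
    alt = rng.binomial(depth, noise.error_rate)
    ref = depth - alt
    ab = np.where(depth > 0, ref / np.maximum(depth, 1), 0.0)
    gq = _genotype_quality(ref, alt, noise.error_rate, noise.max_gq)
    ok = (
        (depth >= cfg.min_depth)
        & (depth <= max_depth)
        & (gq >= cfg.min_gq)
        & (ab >= cfg.ab_homref_min)
    )
    p_pass = ok.mean()
    pops = ds.populations
    n_mono = ds.n_monomorphic
    counts = np.empty((n_mono, len(pops)), dtype=np.int16)
    for j, pop in enumerate(pops):
        n_p = len(ds.individuals_of(pop))
        counts[:, j] = rng.binomial(n_p, p_pass, size=n_mono)
    called_ind = rng.binomial(n_mono, p_pass, size=ds.n_individuals)
    return counts, called_ind
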