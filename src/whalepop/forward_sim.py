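"""Forward Wright-Fisher simulation of deleterious variation.

Discrete generations, fitness-weighted parent sampling (multiplicative
fitness across sites: heterozygote 1-hs, homozygote 1-s), per-offspring
recombination and mutation on a genome of intergenic / intronic / exonic
elements.  Nonsynonymous mutations arise only in exons at a 2.31:1 ratio
to synonymous ones, with selection coefficients from a gamma distribution
of fitness effects estimated from human data (shape 0.186, mean |s|
0.01314) and dominance decreasing with effect size: s < -0.01 fully
recessive (h=0), -0.01 <= s < -0.001 partially recessive (h=0.1),
-0.001 < s <= -1e-5 nearly additive (h=0.4); smaller effects are treated
as neutral.

Population-size rescaling by a factor lambda (N/λ, t/λ, μλ, rλ, sλ, mλ)
preserves θ=4Nμ, ρ=4Nr, N·s and N·m and makes desk-scale runs feasible;
an optional genome-shrink variant (L/λ with μλ) additionally preserves
the per-diploid deleterious mutation rate U — and therefore absolute
genetic load, which under plain rescaling grows ~λ-fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .demography.models import EpochModel, TwoPopModel


# ---------------------------------------------------------------------------
# genome layout

@dataclass
class GenomeLayout:
    """Exon interval map over a simulated segment."""

    seq_len: float
    exon_starts: np.ndarray
    exon_ends: np.ndarray

    @property
    def exonic_bp(self) -> float:
        return float((self.exon_ends - self.exon_starts).sum())

    def is_exonic(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos)
        if self.exon_starts.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(self.exon_starts, pos, side="right") - 1
        idx = np.clip(idx, 0, len(self.exon_starts) - 1)
        return (pos >= self.exon_starts[idx]) & (pos < self.exon_ends[idx])


def build_genome_layout(
    seq_len: float,
    exon_fraction: float = 0.013,
    exon_len: float = 150.0,
    exons_per_gene: int = 8,
    intron_len: float = 1500.0,
    seed: int = 1,
) -> GenomeLayout:
    """Random gene structures tiling the segment.

    Genes of ``exons_per_gene`` exons separated by introns are placed with
    random intergenic gaps sized so the realized exonic fraction matches
    the target; deterministic for a given seed.
    """
    if exon_fraction <= 0:
        return GenomeLayout(seq_len, np.zeros(0), np.zeros(0))
    if exon_fraction > 1.0:
        raise ValueError("exon_fraction must be <= 1")
    # shrink introns (then gene size) until the layout fits the segment
    while True:
        gene_exonic = exons_per_gene * exon_len
        gene_span = gene_exonic + (exons_per_gene - 1) * intron_len
        n_genes = max(int(round(seq_len * exon_fraction / gene_exonic)), 1)
        if n_genes * gene_span <= seq_len:
            break
        if intron_len >= 2.0:
            intron_len /= 2.0
        elif exons_per_gene > 1:
            exons_per_gene -= 1
        elif exon_len > 1.0:
            exon_len = max(exon_len / 2.0, 1.0)
        else:
            raise ValueError("layout infeasible: raise seq_len or lower exon load")
    rng = np.random.default_rng(seed)
    slack = seq_len - n_genes * gene_span
    gaps = rng.dirichlet(np.ones(n_genes + 1)) * slack
    starts, ends = [], []
    cursor = 0.0
    for gidx in range(n_genes):
        cursor += gaps[gidx]
        for e in range(exons_per_gene):
            s = cursor + e * (exon_len + intron_len)
            starts.append(s)
            ends.append(s + exon_len)
        cursor += gene_span
    return GenomeLayout(seq_len, np.array(starts), np.array(ends))


# ---------------------------------------------------------------------------
# configuration

@dataclass
class DFE:
    """Gamma distribution of (negative) selection coefficients.

    Defaults are the human-inferred nonsynonymous DFE (gamma shape 0.186,
    mean |s| 0.01314) — externally sourced defaults, exposed as
    configuration.
    """

    shape: float = 0.186
    mean_s: float = 0.01314


#: dominance bins on the *unscaled* selection coefficient
DOMINANCE_MAP = ((-np.inf, -0.01, 0.0), (-0.01, -0.001, 0.1), (-0.001, -1e-5, 0.4))
NEUTRAL_S_FLOOR = 1e-5


def dominance_of(s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    h = np.full(s.shape, 0.5)
    for lo, hi, hv in DOMINANCE_MAP:
        h = np.where((s >= lo) & (s < hi), hv, h)
    return np.where(s == 0.0, 0.5, h)


def draw_mutation(is_exonic: bool, dfe: DFE, rng: np.random.Generator,
                  ns_to_s: float = 2.31) -> tuple[float, float]:
    """(s, h) for one new mutation at an exonic or non-exonic site."""
    if not is_exonic or rng.random() >= ns_to_s / (1.0 + ns_to_s):
        return 0.0, 0.5
    s = -rng.gamma(dfe.shape, dfe.mean_s / dfe.shape)
    if s > -NEUTRAL_S_FLOOR:
        return 0.0, 0.5
    return float(s), float(dominance_of(s))


@dataclass
class SimConfig:
    """Forward-simulation scenario.

    Sizes in diploids, times in generations, rates per bp per generation.
    ``demography`` is an :class:`EpochModel` or :class:`TwoPopModel`;
    burn-in lasts ``burnin_mult`` times the ancestral diploid size.
    """

    demography: EpochModel | TwoPopModel = None
    seq_len: float = 1e7
    mu: float = 2.77e-8
    rec: float = 1e-8
    ns_to_s: float = 2.31
    exon_fraction: float = 0.013
    dfe: DFE = field(default_factory=DFE)
    burnin_mult: float = 10.0
    sample_n: int = 40
    replicates: int = 25
    rescale_lambda: float = 1.0
    seed: int = 1
    roh_min_bp: float = 1e6
    s_scale: float = 1.0   # set by rescale_config
    #: with False, neutral mutations are not materialised: selection
    #: dynamics and load are unchanged (neutral sites never touch fitness)
    #: while the haplotype matrices stay small; diversity statistics must
    #: then come from a coalescent companion run.
    track_neutral: bool = True

    def validate(self) -> None:
        if self.rescale_lambda < 1:
            raise ValueError("rescale lambda must be >= 1")
        if self.demography is None:
            raise ValueError("a demography is required")
        if isinstance(self.demography, TwoPopModel):
            for m in (self.demography.m_1_to_2, self.demography.m_2_to_1):
                if m >= 1.0:
                    raise ValueError("migrant fraction out of range")


def rescale_config(cfg: SimConfig, lam: float, shrink_genome: bool = False) -> SimConfig:
    """Apply population-genetic rescaling by ``lam``.

    N -> N/λ, times -> t/λ, μ -> μλ, r -> rλ, s -> sλ, m -> mλ; θ=4Nμ,
    ρ=4Nr, N·s and N·m are invariant.  With ``shrink_genome`` the segment
    length (and the ROH length floor) is also divided by λ, keeping the
    per-diploid genomic mutation rate U = 2 μ L — and hence absolute load —
    unchanged; per-site θ stays invariant either way.

    Selection coefficients whose rescaled magnitude exceeds 1 are
    truncated to lethal at draw time; :func:`lethal_truncation_mass`
    reports the affected DFE mass.
    """
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    dem = cfg.demography
    f = 1.0 / lam
    if isinstance(dem, EpochModel):
        dem2 = EpochModel(
            [max(s * f, 2.0) for s in dem.sizes],
            [t * f for t in dem.durations],
            name=dem.name,
        )
    else:
        m12 = dem.m_1_to_2 * lam
        m21 = dem.m_2_to_1 * lam
        if m12 >= 1.0 or m21 >= 1.0:
            raise ValueError("rescaled migrant fraction mλ >= 1")
        dem2 = replace(
            dem,
            n_anc=max(dem.n_anc * f, 2.0),
            n_anc2=None if dem.n_anc2 is None else max(dem.n_anc2 * f, 2.0),
            n1=max(dem.n1 * f, 2.0),
            n2=max(dem.n2 * f, 2.0),
            t_a=dem.t_a * f,
            t_split=dem.t_split * f,
            m_1_to_2=m12,
            m_2_to_1=m21,
        )
    return replace(
        cfg,
        demography=dem2,
        mu=cfg.mu * lam,
        rec=cfg.rec * lam,
        seq_len=cfg.seq_len * (f if shrink_genome else 1.0),
        roh_min_bp=cfg.roh_min_bp * (f if shrink_genome else 1.0),
        rescale_lambda=lam,
        s_scale=cfg.s_scale * lam,
    )


def lethal_truncation_mass(cfg: SimConfig) -> float:
    """DFE probability mass with |s| * s_scale > 1 (truncated to lethal)."""
    from scipy.stats import gamma

    return float(
        gamma(cfg.dfe.shape, scale=cfg.dfe.mean_s / cfg.dfe.shape).sf(1.0 / cfg.s_scale)
    )


# ---------------------------------------------------------------------------
# statistics

S_BINS = {"strong": (-np.inf, -0.01), "moderate": (-0.01, -0.001),
          "weak": (-0.001, -NEUTRAL_S_FLOOR)}


@dataclass
class SimStats:
    """Per-population summary at one checkpoint."""

    load: float
    heterozygosity: float          # mean per-site heterozygous fraction
    f_roh: float
    alleles_per_ind: dict[str, float]
    mean_freq: dict[str, float]
    n_segregating: int


# ---------------------------------------------------------------------------
# engine internals

class _Registry:
    """Shared per-site metadata for all demes (columns of every H)."""

    def __init__(self):
        self.pos = np.zeros(0)
        self.s = np.zeros(0)       # simulation-scale selection coefficient
        self.s_raw = np.zeros(0)   # unscaled, for s-bin classification
        self.h = np.zeros(0)

    @property
    def n_sites(self) -> int:
        return self.pos.size

    def append(self, pos, s, s_raw, h):
        self.pos = np.concatenate([self.pos, pos])
        self.s = np.concatenate([self.s, s])
        self.s_raw = np.concatenate([self.s_raw, s_raw])
        self.h = np.concatenate([self.h, h])

    def select(self, idx):
        self.pos = self.pos[idx]
        self.s = self.s[idx]
        self.s_raw = self.s_raw[idx]
        self.h = self.h[idx]


class _Deme:
    """Haplotype matrix (2N x S int8) plus fixed-load bookkeeping."""

    def __init__(self, H: np.ndarray):
        self.H = H
        self.fixed_logw = 0.0
        self.fixed_bins = {k: 0 for k in S_BINS}

    def resize(self, n_dip: int, rng: np.random.Generator):
        old = self.H.shape[0] // 2
        if n_dip == old:
            return
        if n_dip < old:
            keep = rng.choice(old, size=n_dip, replace=False)
        else:
            keep = np.concatenate(
                [np.arange(old), rng.choice(old, size=n_dip - old, replace=True)]
            )
        rows = np.stack([2 * keep, 2 * keep + 1], axis=1).ravel()
        self.H = self.H[rows].copy()


def _fitness(H: np.ndarray, reg: _Registry) -> np.ndarray:
    """Relative fitness per diploid: w = prod (1+h s)^het (1+s)^hom, s<0."""
    sel = np.flatnonzero(reg.s != 0.0)
    n_ind = H.shape[0] // 2
    if sel.size == 0:
        return np.ones(n_ind)
    G = H[0::2][:, sel] + H[1::2][:, sel]
    logw = ((G == 1) @ np.log1p(reg.h[sel] * reg.s[sel])
            + (G == 2) @ np.log1p(reg.s[sel]))
    return np.exp(logw - logw.max())


def _gametes(H, parents, pos, seq_len, rec_per_hap, rng, extra_cols=0):
    """One gamete per entry of ``parents`` (diploid indices).

    ``extra_cols`` zero columns are appended for same-generation mutations
    (allocated here to avoid a second full-matrix copy).
    """
    n = parents.size
    S = pos.size
    gam = np.zeros((n, S + extra_cols), dtype=np.int8)
    nco = rng.poisson(rec_per_hap, size=n)
    which = rng.integers(0, 2, size=n)
    plain = nco == 0
    gam[plain, :S] = H[2 * parents[plain] + which[plain]]
    single = nco == 1
    if single.any():  # one crossover: batched two-segment splice
        idx = np.flatnonzero(single)
        bp = rng.uniform(0, seq_len, size=idx.size)
        right = pos[None, :] >= bp[:, None]
        a = H[2 * parents[idx] + which[idx]]
        b = H[2 * parents[idx] + 1 - which[idx]]
        gam[idx, :S] = np.where(right, b, a)
    for i in np.flatnonzero(nco > 1):
        bp = np.sort(rng.uniform(0, seq_len, size=nco[i]))
        seg = np.searchsorted(bp, pos) % 2
        a = H[2 * parents[i] + which[i]]
        b = H[2 * parents[i] + 1 - which[i]]
        gam[i, :S] = np.where(seg == 0, a, b)
    return gam


def _build_schedule(cfg: SimConfig):
    """Forward-time schedule: list of (sizes_by_pop, n_generations),
    plus the migration map {(receiver, source): fraction} and root deme."""
    dem = cfg.demography
    def gens(dur):
        # epochs with any positive duration survive rounding (a rescaled
        # crash shorter than one generation still happens)
        return max(1, int(round(dur))) if dur > 0 else 0

    if isinstance(dem, EpochModel):
        sizes = [max(int(round(s)), 2) for s in dem.sizes]
        schedule = [({"pop": sizes[0]}, int(round(cfg.burnin_mult * sizes[0])))]
        for size, dur in zip(sizes[1:], dem.durations):
            schedule.append(({"pop": size}, gens(dur)))
        return schedule, {}, "pop"
    p1, p2 = dem.pop_names
    n_anc = max(int(round(dem.n_anc)), 2)
    schedule = [({p1: n_anc}, int(round(cfg.burnin_mult * n_anc)))]
    if dem.n_anc2 is not None and dem.t_a > 0:
        schedule.append(({p1: max(int(round(dem.n_anc2)), 2)},
                         gens(dem.t_a)))
    schedule.append((
        {p1: max(int(round(dem.n1)), 2), p2: max(int(round(dem.n2)), 2)},
        gens(dem.t_split),
    ))
    migration = {(p2, p1): dem.m_1_to_2, (p1, p2): dem.m_2_to_1}
    return schedule, migration, p1


def _snapshot(reg: _Registry, demes: dict[str, _Deme]):
    import copy

    reg2 = _Registry()
    reg2.pos = reg.pos.copy()
    reg2.s = reg.s.copy()
    reg2.s_raw = reg.s_raw.copy()
    reg2.h = reg.h.copy()
    demes2 = {}
    for p, d in demes.items():
        nd = _Deme(d.H.copy())
        nd.fixed_logw = d.fixed_logw
        nd.fixed_bins = dict(d.fixed_bins)
        demes2[p] = nd
    return reg2, demes2


def run_simulation(
    cfg: SimConfig,
    checkpoints: dict[str, float] | None = None,
) -> dict[str, dict[str, SimStats]]:
    """Run one replicate; returns {checkpoint: {pop_name: SimStats}}.

    Checkpoint labels map to generations *before the end* of the run
    (0 = present).  Schedule: burn-in at the ancestral size for
    ``burnin_mult`` x that size generations, then the demography forward
    in time (ancestral size change, split, migration, recent changes).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    layout = build_genome_layout(cfg.seq_len, cfg.exon_fraction, seed=cfg.seed)
    schedule, migration, root = _build_schedule(cfg)
    total_gens = sum(d for _, d in schedule)
    checkpoints = checkpoints or {"present": 0.0}
    cp_at: dict[int, list[str]] = {}
    for label, back in checkpoints.items():
        cp_at.setdefault(total_gens - int(round(back)), []).append(label)
    reg = _Registry()
    demes: dict[str, _Deme] = {
        root: _Deme(np.zeros((2 * schedule[0][0][root], 0), dtype=np.int8))
    }
    results: dict[str, dict[str, SimStats]] = {}
    _run_schedule(cfg, layout, reg, demes, schedule, migration, root, rng,
                  cp_at, results, gen_start=0)
    for label in checkpoints:
        if label not in results:  # checkpoint at the very end
            results[label] = {
                p: compute_sim_stats(d.H, reg, cfg, d, rng)
                for p, d in demes.items()
            }
    return results


def _run_schedule(cfg, layout, reg, demes, schedule, migration, root, rng,
                  cp_at, results, gen_start):
    """Advance the state through the given schedule (mutating in place)."""
    p_ns = cfg.ns_to_s / (1.0 + cfg.ns_to_s)
    mu_per_hap = cfg.mu * cfg.seq_len
    rec_per_hap = cfg.rec * cfg.seq_len
    gen = gen_start

    def take_checkpoints():
        for label in cp_at.get(gen, []):
            results[label] = {
                p: compute_sim_stats(d.H, reg, cfg, d, rng)
                for p, d in demes.items()
            }

    for sizes_by_pop, duration in schedule:
        for p, n in sizes_by_pop.items():
            if p not in demes:  # split: daughter seeded from the root deme
                src = demes[root]
                child = _Deme(src.H.copy())
                child.fixed_logw = src.fixed_logw
                child.fixed_bins = dict(src.fixed_bins)
                child.resize(n, rng)
                demes[p] = child
            else:
                demes[p].resize(n, rng)
        active = list(sizes_by_pop)
        for _ in range(duration):
            S = reg.n_sites
            n_hap_tot = 2 * sum(sizes_by_pop[p] for p in active)
            # draw this generation's mutations up front so gamete arrays
            # can be allocated once at final width
            n_new = rng.poisson(mu_per_hap * n_hap_tot)
            ppos = rng.uniform(0, cfg.seq_len, size=n_new)
            exonic = layout.is_exonic(ppos)
            ns = exonic & (rng.random(n_new) < p_ns)
            s_raw = np.zeros(n_new)
            s_raw[ns] = -rng.gamma(cfg.dfe.shape, cfg.dfe.mean_s / cfg.dfe.shape,
                                   size=int(ns.sum()))
            s_raw[np.abs(s_raw) < NEUTRAL_S_FLOOR] = 0.0
            if not cfg.track_neutral:
                keep_new = s_raw != 0.0
                ppos, s_raw = ppos[keep_new], s_raw[keep_new]
                n_new = int(keep_new.sum())
            w = {p: _fitness(demes[p].H, reg) for p in active}
            new_H: dict[str, np.ndarray] = {}
            for p in active:
                n_off = sizes_by_pop[p]
                src = next((s for (r, s) in migration
                            if r == p and s in active and migration[(p, s)] > 0),
                           None)
                n_mig = rng.binomial(n_off, migration[(p, src)]) if src else 0
                par_local = rng.choice(
                    demes[p].H.shape[0] // 2, size=2 * (n_off - n_mig),
                    p=w[p] / w[p].sum(),
                )
                gam = _gametes(demes[p].H, par_local, reg.pos, cfg.seq_len,
                               rec_per_hap, rng, extra_cols=n_new)
                if n_mig:
                    par_mig = rng.choice(
                        demes[src].H.shape[0] // 2, size=2 * n_mig,
                        p=w[src] / w[src].sum(),
                    )
                    gam_mig = _gametes(demes[src].H, par_mig, reg.pos,
                                       cfg.seq_len, rec_per_hap, rng,
                                       extra_cols=n_new)
                    gam = np.vstack([gam, gam_mig])
                new_H[p] = gam
            # new mutations land on one random gamete across all demes
            if n_new:
                h_new = dominance_of(s_raw)
                # rescaled |s| capped just below 1 (effectively lethal hom)
                s_sim = np.maximum(s_raw * cfg.s_scale, -1.0 + 1e-9)
                reg.append(ppos, s_sim, s_raw, h_new)
                carriers = rng.integers(0, n_hap_tot, size=n_new)
                offsets = np.cumsum([0] + [new_H[p].shape[0] for p in active])
                owner = np.searchsorted(offsets[1:], carriers, side="right")
                for pi, p in enumerate(active):
                    mine = np.flatnonzero(owner == pi)
                    new_H[p][carriers[mine] - offsets[pi], S + mine] = 1
            for p in active:
                demes[p].H = new_H[p]
            gen += 1
            if gen % 10 == 0:
                _compact(reg, demes, active)
            take_checkpoints()
    return gen


def _compact(reg: _Registry, demes, active):
    """Drop globally lost columns; absorb globally fixed into fixed load."""
    S = reg.n_sites
    if S == 0:
        return
    freq = sum(demes[p].H.sum(axis=0) for p in active)
    n_hap = sum(demes[p].H.shape[0] for p in active)
    fixed = np.flatnonzero(freq == n_hap)
    for i in fixed:
        for p in active:
            demes[p].fixed_logw += np.log1p(reg.s[i])
            for k, (lo, hi) in S_BINS.items():
                if lo <= reg.s_raw[i] < hi:
                    demes[p].fixed_bins[k] += 1
    keep = np.flatnonzero((freq > 0) & (freq < n_hap))
    reg.select(keep)
    for p in active:
        demes[p].H = demes[p].H[:, keep].copy()


def compute_sim_stats(
    H: np.ndarray,
    reg: _Registry,
    cfg: SimConfig,
    deme: _Deme,
    rng: np.random.Generator,
) -> SimStats:
    """Load, heterozygosity, F_ROH and s-bin allele counts for a sample.

    Load is 1 minus mean multiplicative fitness relative to a
    mutation-free genotype (globally fixed deleterious sites included);
    heterozygosity is the mean per-site fraction of heterozygous
    positions; F_ROH sums homozygous tracts (gaps between heterozygous
    positions) at least ``roh_min_bp`` long.
    """
    n_ind = H.shape[0] // 2
    k = min(cfg.sample_n, n_ind)
    sample = np.sort(rng.choice(n_ind, size=k, replace=False))
    G = H[2 * sample] + H[2 * sample + 1]
    sel = np.flatnonzero(reg.s != 0.0)
    if sel.size:
        logw = ((G[:, sel] == 1) @ np.log1p(reg.h[sel] * reg.s[sel])
                + (G[:, sel] == 2) @ np.log1p(reg.s[sel]))
    else:
        logw = np.zeros(k)
    w = np.exp(logw + deme.fixed_logw)
    het_sites = G == 1
    order = np.argsort(reg.pos)
    pos_sorted = reg.pos[order]
    f_vals = []
    for i in range(k):
        hp = pos_sorted[het_sites[i][order]]
        edges = np.concatenate([[0.0], hp, [cfg.seq_len]])
        gaps = np.diff(edges)
        f_vals.append(gaps[gaps >= cfg.roh_min_bp].sum() / cfg.seq_len)
    alleles, freqs = {}, {}
    n_hap_pop = H.shape[0]
    for name, (lo, hi) in S_BINS.items():
        sites = np.flatnonzero((reg.s_raw >= lo) & (reg.s_raw < hi))
        per_ind = float(G[:, sites].sum(axis=1).mean()) if sites.size else 0.0
        alleles[name] = per_ind + 2 * deme.fixed_bins[name]
        freqs[name] = (
            float(H[:, sites].sum() / (n_hap_pop * sites.size))
            if sites.size else 0.0
        )
    return SimStats(
        load=float(1.0 - w.mean()),
        heterozygosity=float(het_sites.sum(axis=1).mean() / cfg.seq_len),
        f_roh=float(np.mean(f_vals)),
        alleles_per_ind=alleles,
        mean_freq=freqs,
        n_segregating=int(reg.n_sites),
    )


def fin_whale_load_scenario(
    migration: bool = True,
    lam: float = 14.25,
    seed: int = 1,
    exon_fraction: float = 0.07,
) -> SimConfig:
    """Desk-scale configuration of the two-population genetic-load
    experiment under the fitted fin-whale demography.

    The segment is λ-rescaled with the genome shrunk in proportion so the
    per-diploid deleterious mutation rate — which controls absolute load —
    is preserved.  λ=14.25 makes the small deme exactly eight diploids
    (no integer-rounding distortion of N·m) while keeping rescaled
    selection coefficients mostly far from the lethal cap.  Neutral
    mutations are not materialised (they never touch fitness); diversity
    statistics come from :func:`fin_whale_neutral_diversity`, which runs
    the matching coalescent at full scale.  The exonic density default is
    calibrated analytically (Haldane's mutation load under this DFE and
    dominance map) to the deleterious-mutation input consistent with the
    large deme's equilibrium load of ~3%; see the methods note.
    """
    from .demography.models import fin_whale_two_pop

    cfg = SimConfig(
        demography=fin_whale_two_pop(migration=migration),
        exon_fraction=exon_fraction,
        seed=seed,
        track_neutral=False,
    )
    return rescale_config(cfg, lam, shrink_genome=True)


def fin_whale_neutral_diversity(
    migration: bool = True,
    n_replicates: int = 10,
    seq_len: float = 2e6,
    sample_n: int = 40,
    seed: int = 1,
    roh_min_bp: float = 1e6,
):
    """Neutral heterozygosity and F_ROH per deme under the *unrescaled*
    fitted two-population model, from coalescent replicates.

    Neutral diversity does not require forward simulation; the coalescent
    gives the exact model expectation without any rescaling artifacts.
    Returns a list of per-replicate dicts
    {pop: {"heterozygosity": ..., "f_roh": ...}}.
    """
    import msprime

    from .demography.models import fin_whale_two_pop

    model = fin_whale_two_pop(migration=migration)
    dem = model.to_msprime()
    out = []
    reps = msprime.sim_ancestry(
        samples={model.pop_names[0]: sample_n, model.pop_names[1]: sample_n},
        demography=dem,
        sequence_length=seq_len,
        recombination_rate=1e-8,
        num_replicates=n_replicates,
        random_seed=seed,
    )
    for r, ts in enumerate(reps):
        ts = msprime.sim_mutations(ts, rate=2.77e-8, random_seed=seed + 7919 * (r + 1))
        rep = {}
        for pid, name in enumerate(model.pop_names):
            samp = ts.samples(population=pid)
            G = ts.genotype_matrix(samples=samp)
            het_mat = G[:, 0::2] != G[:, 1::2]
            het = het_mat.sum(axis=0).mean() / ts.sequence_length
            pos = ts.tables.sites.position
            f_vals = []
            for i in range(het_mat.shape[1]):
                hp = pos[het_mat[:, i]]
                edges = np.concatenate([[0.0], hp, [ts.sequence_length]])
                gaps = np.diff(edges)
                f_vals.append(gaps[gaps >= roh_min_bp].sum() / ts.sequence_length)
            rep[name] = {"heterozygosity": float(het),
                         "f_roh": float(np.mean(f_vals))}
        out.append(rep)
    return out


def run_split_forks(
    cfgs: dict[str, SimConfig],
    n_burnins: int = 3,
    forks_per_burnin: int = 6,
) -> list[dict[str, dict[str, SimStats]]]:
    """Replicates of the post-split era sharing ancestral burn-ins.

    The burn-in plus ancestral epochs (identical across scenario variants,
    e.g. with/without migration) are simulated ``n_burnins`` times; from
    each saved state, ``forks_per_burnin`` independent post-split runs are
    forked per variant.  Forks with the same (burn-in, fork) index share
    the random seed across variants, giving matched pairs for ordering
    comparisons.  Returns a list of {variant: {pop: SimStats}} at the end
    of the run, one entry per fork.
    """
    labels = list(cfgs)
    base = cfgs[labels[0]]
    base.validate()
    sched0, _, root = _build_schedule(base)
    if len(sched0) < 2:
        raise ValueError("fork design needs a multi-epoch schedule")
    pre = sched0[:-1]
    out: list[dict[str, dict[str, SimStats]]] = []
    for b in range(n_burnins):
        layout = build_genome_layout(base.seq_len, base.exon_fraction,
                                     seed=base.seed + b)
        rng = np.random.default_rng(base.seed + 7919 * b)
        reg = _Registry()
        demes = {root: _Deme(np.zeros((2 * pre[0][0][root], 0), dtype=np.int8))}
        _run_schedule(base, layout, reg, demes, pre, {}, root, rng, {}, {}, 0)
        for f in range(forks_per_burnin):
            fork_seed = base.seed + 104729 * b + 131 * f + 7
            fork_out: dict[str, dict[str, SimStats]] = {}
            for lab in labels:
                cfg = cfgs[lab]
                sched_l, mig_l, root_l = _build_schedule(cfg)
                if root_l != root or sched_l[:-1] != pre:
                    raise ValueError(
                        "scenario variants must share the pre-split schedule"
                    )
                reg2, demes2 = _snapshot(reg, demes)
                rng_f = np.random.default_rng(fork_seed)
                _run_schedule(cfg, layout, reg2, demes2, [sched_l[-1]],
                              mig_l, root, rng_f, {}, {}, 0)
                fork_out[lab] = {
                    p: compute_sim_stats(d.H, reg2, cfg, d, rng_f)
                    for p, d in demes2.items()
                }
            out.append(fork_out)
    return out


def named_scenario(name: str, seed: int = 1, lam: float = 14.25) -> SimConfig:
    """Catalogue of simulation scenarios by name.

    * ``enp_3epoch`` — single-population whaling history (expansion then a
      crash to 305 diploids two generations ago);
    * ``twopop_mig`` / ``twopop_nomig`` — the two-deme split with and
      without migration (see :func:`fin_whale_load_scenario`);
    * ``recovery_n1000`` — whaling crash followed by a recovery to 1,000
      diploids (two generations at the bottleneck, eighteen after the
      recovery).
    """
    from .demography.models import fin_whale_enp_3epoch

    if name == "twopop_mig":
        return fin_whale_load_scenario(True, lam=lam, seed=seed)
    if name == "twopop_nomig":
        return fin_whale_load_scenario(False, lam=lam, seed=seed)
    if name == "enp_3epoch":
        dem = fin_whale_enp_3epoch()
    elif name == "recovery_n1000":
        dem = EpochModel.four_epoch(16479, 23913, 305, 1000,
                                    4424 - 20, 2, 18)
    else:
        raise KeyError(f"unknown scenario: {name!r}")
    cfg = SimConfig(demography=dem, exon_fraction=0.07, seed=seed,
                    track_neutral=False)
    return rescale_config(cfg, lam, shrink_genome=True)


def run_replicates(
    cfg: SimConfig,
    checkpoints: dict[str, float] | None = None,
    n_replicates: int | None = None,
) -> list[dict[str, dict[str, SimStats]]]:
    """Independent replicates with per-replicate seeds derived from
    ``cfg.seed`` (seed + replicate index)."""
    n = n_replicates if n_replicates is not None else cfg.replicates
    out = []
    for r in range(n):
        out.append(run_simulation(replace(cfg, seed=cfg.seed + 1000 * r),
                                  checkpoints))
    return out
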