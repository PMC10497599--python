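"""Putatively deleterious variation: mutation-class assignment,
missingness-normalized burdens, and the R_XY / R2_XY relative-accumulation
statistics with weighted block-jackknife uncertainty.

For populations X and Y and per-site derived counts d among n called
haploids, the expected number of derived mutations private in expectation
to X is

    L_X,notY  = sum_i (d_X/n_X) (1 - d_Y/n_Y)

and for derived homozygotes

    L2_X,notY = sum_i [1 - 2 d_X (n_X - d_X) / (n_X (n_X - 1))]
                      [2 d_Y (n_Y - d_Y) / (n_Y (n_Y - 1))]

with R_XY = L_X,notY / L_Y,notX (and likewise R2_XY); both equal 1 when
drift and selection have acted equally in the two populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .dataset import Dataset, MISSING, NEU, SYN, TOL, DEL, LOF, ANNOTATIONS

#: snpEff-style impact mapping used for the robustness re-analysis
IMPACT_OF_CLASS = {LOF: "HIGH", DEL: "MODERATE", TOL: "MODERATE", SYN: "LOW"}


def classify_mutations(
    ds: Dataset, lof_flags: np.ndarray | None = None
) -> np.ndarray:
    """Mutation class per coding site: SYN / TOL / DEL / LOF.

    Nonsynonymous sites with SIFT < 0.05 are deleterious, >= 0.05
    tolerated.  A LOF flag wins over any SIFT score (one class per site,
    the most deleterious effect).  Returns the class-code array; raises if
    a coding site lacks annotation.
    """
    ann = ds.annotation.copy()
    coding = ann != NEU
    if np.isnan(ds.sift_score[coding & (ann != LOF)]).any():
        raise ValueError("coding site without SIFT annotation")
    ns = coding & (ann != SYN) & (ann != LOF)
    ann[ns & (ds.sift_score < 0.05)] = DEL
    ann[ns & (ds.sift_score >= 0.05)] = TOL
    if lof_flags is not None:
        ann[np.asarray(lof_flags, dtype=bool)] = LOF
    return ann


def burden_per_individual(ds: Dataset, classes: np.ndarray | None = None):
    """Derived-allele and derived-homozygote burdens per individual and
    class, normalized by mean called genotypes across individuals.

    Allele counts proxy additive load (h = 0.5); homozygote counts proxy
    recessive load (h = 0).  Each individual's raw count is multiplied by
    (mean called genotypes across individuals) / (its called genotypes).
    Returns dict: class name -> {"alleles": array, "homozygotes": array}.
    """
    classes = ds.annotation if classes is None else np.asarray(classes)
    g = ds.genotypes
    called = g != MISSING
    n_called = called.sum(axis=1).astype(float)
    if (n_called == 0).any():
        raise ValueError("individual with zero called genotypes")
    norm_f = n_called.mean() / n_called
    out = {}
    for code in (SYN, TOL, DEL, LOF):
        sites = classes == code
        gs = g[:, sites]
        alleles = np.where(gs != MISSING, gs, 0).sum(axis=1) * norm_f
        homs = (gs == 2).sum(axis=1) * norm_f
        out[ANNOTATIONS[code]] = {"alleles": alleles, "homozygotes": homs}
    return out


@dataclass
class SiteCounts:
    """Per-site derived and called-haploid counts for two populations."""

    d_x: np.ndarray
    n_x: np.ndarray
    d_y: np.ndarray
    n_y: np.ndarray

    def __post_init__(self) -> None:
        for d, n in ((self.d_x, self.n_x), (self.d_y, self.n_y)):
            if (np.asarray(d) > np.asarray(n)).any() or (np.asarray(d) < 0).any():
                raise ValueError("need 0 <= d <= n at every site")


def site_counts(ds: Dataset, pop_x: str, pop_y: str, sites=None) -> SiteCounts:
    def tally(pop):
        g = ds.genotypes[ds.individuals_of(pop)]
        if sites is not None:
            g = g[:, sites]
        called = g != MISSING
        return (
            np.where(called, g, 0).sum(axis=0).astype(float),
            (2 * called.sum(axis=0)).astype(float),
        )

    dx, nx = tally(pop_x)
    dy, ny = tally(pop_y)
    return SiteCounts(dx, nx, dy, ny)


def l_not_statistics(counts: SiteCounts, per_site: bool = False):
    """Eq.-I/II sums in both directions.

    Sites monomorphic ancestral in both populations contribute nothing to
    the allele sums and are excluded from the homozygote sums (which
    additionally require n >= 2 in both populations); the number of
    excluded homozygote sites is reported.
    """
    dx, nx, dy, ny = counts.d_x, counts.n_x, counts.d_y, counts.n_y
    ok1 = (nx > 0) & (ny > 0) & ((dx > 0) | (dy > 0))
    fx = np.where(ok1, dx / np.maximum(nx, 1), 0.0)
    fy = np.where(ok1, dy / np.maximum(ny, 1), 0.0)
    l_x = fx * (1 - fy)
    l_y = fy * (1 - fx)
    ok2 = ok1 & (nx > 1) & (ny > 1)
    hx = np.where(ok2, 2 * dx * (nx - dx) / np.maximum(nx * (nx - 1), 1), 0.0)
    hy = np.where(ok2, 2 * dy * (ny - dy) / np.maximum(ny * (ny - 1), 1), 0.0)
    l2_x = np.where(ok2, (1 - hx) * hy, 0.0)
    l2_y = np.where(ok2, (1 - hy) * hx, 0.0)
    n_excl = int((ok1 & ~ok2).sum())
    if per_site:
        return l_x, l_y, l2_x, l2_y, n_excl
    return l_x.sum(), l_y.sum(), l2_x.sum(), l2_y.sum(), n_excl


@dataclass
class RxyResult:
    l_x_not_y: float
    l_y_not_x: float
    l2_x_not_y: float
    l2_y_not_x: float
    r_xy: float
    r2_xy: float
    se_r: float
    se_r2: float
    z_r: float
    z_r2: float
    p_r: float
    p_r2: float
    n_blocks: int = 0
    n_excluded_hom_sites: int = 0


def rxy(
    counts: SiteCounts,
    n_blocks: int = 50,
    blocks: np.ndarray | None = None,
) -> RxyResult:
    """R_XY and R2_XY with weighted block-jackknife SE and Z test vs 1.

    ``blocks`` assigns each site to a jackknife block; by default sites
    are split into ``n_blocks`` contiguous equal-count blocks.  Jackknife
    weights are proportional to block site counts.  The Z test compares
    log R against 0 (two-tailed).
    """
    lx, ly, l2x, l2y, n_excl = l_not_statistics(counts, per_site=True)
    n_sites = lx.size
    if blocks is None:
        if n_blocks < 2:
            raise ValueError("need >= 2 jackknife blocks")
        blocks = np.minimum(
            (np.arange(n_sites) * n_blocks) // max(n_sites, 1), n_blocks - 1
        )
    blocks = np.asarray(blocks)
    uniq = np.unique(blocks)
    if uniq.size < 2:
        raise ValueError("need >= 2 jackknife blocks")
    LX, LY, L2X, L2Y = lx.sum(), ly.sum(), l2x.sum(), l2y.sum()
    if LY == 0 or L2Y == 0 or LX == 0 or L2X == 0:
        raise ValueError("zero numerator/denominator in R_XY")
    r = LX / LY
    r2 = L2X / L2Y

    def jackknife(num, den, point):
        """Weighted delete-one-block jackknife SE on the log-ratio scale."""
        n_tot = n_sites
        logs, weights = [], []
        for b in uniq:
            m = blocks == b
            nb = int(m.sum())
            if nb == 0 or nb == n_tot:
                continue
            num_b = num.sum() - num[m].sum()
            den_b = den.sum() - den[m].sum()
            if den_b <= 0 or num_b <= 0:
                continue
            logs.append(np.log(num_b / den_b))
            weights.append(nb)
        logs = np.array(logs)
        w = np.array(weights, dtype=float)
        if logs.size < 2:
            return np.nan
        gblocks = logs.size
        theta = np.log(point)
        h = n_tot / w  # inverse block weight
        ps = h * theta - (h - 1) * logs
        mean_ps = (ps / h).sum() / (1.0 / h).sum()
        # delete-m jackknife variance (unequal block sizes)
        var = np.sum((ps - mean_ps) ** 2 / (h - 1)) / gblocks
        return float(np.sqrt(var))

    se_log_r = jackknife(lx, ly, r)
    se_log_r2 = jackknife(l2x, l2y, r2)
    se_r = se_log_r * r if np.isfinite(se_log_r) else np.nan
    se_r2 = se_log_r2 * r2 if np.isfinite(se_log_r2) else np.nan
    z_r = np.log(r) / se_log_r if se_log_r and np.isfinite(se_log_r) else np.nan
    z_r2 = np.log(r2) / se_log_r2 if se_log_r2 and np.isfinite(se_log_r2) else np.nan
    return RxyResult(
        l_x_not_y=float(LX), l_y_not_x=float(LY),
        l2_x_not_y=float(L2X), l2_y_not_x=float(L2Y),
        r_xy=float(r), r2_xy=float(r2),
        se_r=float(se_r), se_r2=float(se_r2),
        z_r=float(z_r), z_r2=float(z_r2),
        p_r=float(2 * norm.sf(abs(z_r))) if np.isfinite(z_r) else np.nan,
        p_r2=float(2 * norm.sf(abs(z_r2))) if np.isfinite(z_r2) else np.nan,
        n_blocks=int(uniq.size),
        n_excluded_hom_sites=n_excl,
    )


def rxy_by_class(ds: Dataset, pop_x: str, pop_y: str, n_blocks: int = 50):
    """R_XY results per mutation class (SYN, TOL, DEL, LOF)."""
    classes = classify_mutations(ds)
    out = {}
    for code in (SYN, TOL, DEL, LOF):
        sites = classes == code
        if sites.sum() < 2:
            continue
        counts = site_counts(ds, pop_x, pop_y, sites=sites)
        try:
            out[ANNOTATIONS[code]] = rxy(counts, n_blocks=min(n_blocks, int(sites.sum())))
        except ValueError:
            continue
    return out
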