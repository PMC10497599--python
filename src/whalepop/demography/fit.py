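"""Composite-likelihood fitting of demographic models to folded spectra.

The likelihood is the multinomial composite log-likelihood over SFS
classes (sites treated as independent); the monomorphic bin is masked by
default so only the polymorphic shape is fit, and theta is recovered
afterwards by matching the total number of segregating sites
(theta = 4 N_ANC mu L anchors scaled parameters to physical units).

Optimization is derivative-free simplex in log-parameter space with
multi-start: starting points are drawn log-uniformly within the bounds,
mirroring the randomized-restart convergence protocol (top-10 spread of
restart likelihoods is recorded for the convergence criterion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from ..sfs import FoldedSFS
from .expected import expected_sfs_epoch
from .models import EpochModel, ScalingContext


# ---------------------------------------------------------------------------
# model specs: scaled (coalescent-unit) parameterizations of the catalogue
#
# Sizes are relative to N_ANC; times are in units of 2*N_ANC generations.
# The reference model is evaluated with N_ANC = 1/2 so that one coalescent
# time unit equals one generation, making the shape independent of scale.

def _epoch_from_scaled(name: str, p: dict[str, float]) -> EpochModel:
    if name == "1Epoch":
        return EpochModel.one_epoch(0.5)
    if name == "2Epoch":
        return EpochModel.two_epoch(0.5, 0.5 * p["nu"], p["T"])
    if name == "3Epoch":
        return EpochModel.three_epoch(
            0.5, 0.5 * p["nuB"], 0.5 * p["nuF"], p["TB"], p["TF"]
        )
    if name == "4Epoch":
        return EpochModel.four_epoch(
            0.5, 0.5 * p["nuB"], 0.5 * p["nuR"], 0.5 * p["nuF"],
            p["TB"], p["TR"], p["TF"],
        )
    raise KeyError(f"unknown single-population model: {name}")


MODEL_PARAMS = {
    "1Epoch": (),
    "2Epoch": ("nu", "T"),
    "3Epoch": ("nuB", "nuF", "TB", "TF"),
    "4Epoch": ("nuB", "nuR", "nuF", "TB", "TR", "TF"),
}

#: default log-uniform search bounds per scaled parameter
DEFAULT_BOUNDS = {
    "nu": (1e-4, 100.0), "nuB": (1e-4, 100.0), "nuR": (1e-4, 100.0),
    "nuF": (1e-5, 100.0),
    "T": (1e-6, 5.0), "TB": (1e-6, 5.0), "TR": (1e-6, 5.0), "TF": (1e-7, 5.0),
}


@dataclass
class FitResult:
    """Best composite-likelihood point with scaled and physical units."""

    model: str
    params: dict[str, float]          # scaled units (nu, tau)
    log_likelihood: float
    theta: float = np.nan
    n_restarts: int = 1
    top10_spread: float = np.nan      # ll(best) - ll(10th best restart)
    physical: dict[str, float] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    restart_lls: list[float] = field(default_factory=list)


def composite_loglik(
    obs: np.ndarray | FoldedSFS,
    exp: np.ndarray | FoldedSFS,
    mask_monomorphic: bool = True,
) -> float:
    """Multinomial composite log-likelihood sum(obs * log(exp/sum(exp))).

    Cells with zero expected mass but positive observed mass contribute
    -inf (guarded with a floor of 1e-300).
    """
    o = obs.counts if isinstance(obs, FoldedSFS) else np.asarray(obs, dtype=float)
    e = exp.counts if isinstance(exp, FoldedSFS) else np.asarray(exp, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and expected spectra differ in shape")
    o = o.ravel().copy()
    e = e.ravel().copy()
    if mask_monomorphic:
        o, e = o[1:], e[1:]
    tot = e.sum()
    if tot <= 0:
        raise ValueError("expected spectrum has no mass")
    p = np.maximum(e / tot, 1e-300)
    return float(np.sum(o * np.log(p)))


def _epoch_model_from_physical(fit: "FitResult") -> EpochModel:
    ph = fit.physical
    if fit.model == "1Epoch":
        return EpochModel.one_epoch(ph["N_ANC"])
    if fit.model == "2Epoch":
        return EpochModel.two_epoch(ph["N_ANC"], ph["N_CUR"], ph["T"])
    if fit.model == "3Epoch":
        return EpochModel.three_epoch(ph["N_ANC"], ph["N_BOT"], ph["N_CUR"],
                                      ph["T_BOT"], ph["T_CUR"])
    if fit.model == "4Epoch":
        return EpochModel.four_epoch(ph["N_ANC"], ph["N_BOT"], ph["N_REC"],
                                     ph["N_CUR"], ph["T_BOT"], ph["T_REC"],
                                     ph["T_CUR"])
    raise KeyError(fit.model)


def _model_shape(name: str, pvec: np.ndarray, pnames, n: int) -> np.ndarray:
    model = _epoch_from_scaled(name, dict(zip(pnames, pvec)))
    ctx = ScalingContext(mu=1.0, L=1.0, generation_time=1.0)
    sfs = expected_sfs_epoch(model, n, ctx, fold=True, monomorphic="zero")
    return sfs.counts


def fit_model(
    obs: FoldedSFS,
    model: str,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_restarts: int = 20,
    seed: int = 0,
    maxiter: int = 600,
    fixed: dict[str, float] | None = None,
    extra_starts: list[dict[str, float]] | None = None,
) -> FitResult:
    """Multi-start simplex fit of a catalogue model to a folded SFS.

    ``fixed`` pins scaled parameters (e.g. the most recent epoch duration
    of the whaling-era model variants) by collapsing their bounds;
    ``extra_starts`` adds deterministic starting points (used by the
    parametric bootstrap, which seeds one restart at the empirical MLE).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    pnames = MODEL_PARAMS[model]
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    for k, v in (fixed or {}).items():
        bounds[k] = (v, v)
    lo = np.array([bounds[p][0] for p in pnames])
    hi = np.array([bounds[p][1] for p in pnames])
    free = ~np.isclose(lo, hi)
    n = obs.n_haploids
    rng = np.random.default_rng(seed)

    def expand(logp_free):
        full = np.log(lo).copy()
        full[free] = np.clip(logp_free, np.log(lo[free]), np.log(hi[free]))
        return np.exp(full)

    def negll(logp_free):
        shape = _model_shape(model, expand(logp_free), pnames, n)
        try:
            return -composite_loglik(obs, FoldedSFS(n, shape), mask_monomorphic=True)
        except (ValueError, FloatingPointError):
            return np.inf

    if not pnames or not free.any():  # no free shape parameters
        x = np.empty(0)
        best_x = expand(x)
        best_ll = -negll(x)
        lls = [best_ll]
    else:
        starts = [
            np.log(np.clip([st[p] for p in np.array(pnames)[free]],
                           lo[free], hi[free]))
            for st in (extra_starts or [])
        ]
        lls, xs = [], []
        for r in range(n_restarts + len(starts)):
            x0 = (starts[r - n_restarts] if r >= n_restarts
                  else rng.uniform(np.log(lo[free]), np.log(hi[free])))
            res = minimize(
                negll, x0, method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8},
            )
            lls.append(-res.fun)
            xs.append(expand(res.x))
        order = np.argsort(lls)[::-1]
        best_x = xs[order[0]]
        best_ll = lls[order[0]]
    lls_sorted = sorted(lls, reverse=True)
    spread = (
        lls_sorted[0] - lls_sorted[min(9, len(lls_sorted) - 1)]
        if lls_sorted else np.nan
    )
    params = dict(zip(pnames, best_x))
    shape = _model_shape(model, np.asarray(best_x), pnames, n)
    # theta anchor: scale factor matching the observed segregating-site mass
    s_obs = float(np.sum(obs.counts[1:]))
    s_exp = float(np.sum(shape[1:]))
    theta = 2.0 * (s_obs / s_exp) if s_exp > 0 else np.nan
    if not np.isfinite(best_ll):
        raise RuntimeError("all restarts failed; check bounds and data")
    return FitResult(
        model=model,
        params=params,
        log_likelihood=best_ll,
        theta=theta,
        n_restarts=n_restarts,
        top10_spread=spread,
        restart_lls=lls_sorted,
    )


def fit_recent_contraction(
    obs: FoldedSFS,
    ctx: ScalingContext,
    model: str = "3Epoch",
    t_cur_generations: float = 2.0,
    n_restarts: int = 50,
    seed: int = 0,
    n_iter: int = 2,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> FitResult:
    """Fit an epoch model with the most recent epoch duration fixed in
    *generations* (the whaling-era model variants).

    The current size and time of a generations-old contraction lie on a
    likelihood ridge (only their ratio is well constrained by the singleton
    deficit), so the duration is pinned at a known value, e.g. two
    generations.  Because scaled durations are in units of 2*N_ANC
    generations while N_ANC itself comes from the theta anchor, the fix
    is applied self-consistently: fit, re-derive N_ANC from theta, refit.
    """
    t_name = {"2Epoch": "T", "3Epoch": "TF", "4Epoch": "TF"}[model]
    # initial anchor from the parameter-free constant-size model: theta is
    # only weakly model-dependent given the segregating-site total, and the
    # 1Epoch anchor cannot be dragged off by a degenerate multi-epoch fit
    anchor = ctx.n_anc_from_theta(fit_model(obs, "1Epoch").theta)
    n_anc = anchor
    fit = None
    for i in range(n_iter):
        tau = t_cur_generations / (2.0 * n_anc)
        fit = fit_model(obs, model, bounds=bounds, n_restarts=n_restarts,
                        seed=seed + i + 1, fixed={t_name: tau})
        new = ctx.n_anc_from_theta(fit.theta)
        # reject implausible anchor updates (degenerate restart optima)
        n_anc = new if anchor / 3 <= new <= anchor * 3 else n_anc
    return scale_parameters(fit, ctx)


def scale_parameters(fit: FitResult, ctx: ScalingContext) -> FitResult:
    """Convert scaled parameters to physical units in-place and return fit.

    N_ANC = theta/(4 mu L); sizes scale by N_ANC, times by 2 N_ANC
    generations, years by the generation time.
    """
    n_anc = ctx.n_anc_from_theta(fit.theta)
    phys: dict[str, float] = {"N_ANC": n_anc, "theta": fit.theta}
    suffix_map = {"": "CUR", "B": "BOT", "R": "REC", "F": "CUR"}
    for k, v in fit.params.items():
        if k.startswith("nu"):
            phys["N_" + suffix_map[k[2:]]] = v * n_anc
        elif k.startswith("T"):
            name = "T_" + suffix_map[k[1:]] if k != "T" else "T"
            gens = v * 2 * n_anc
            phys[name] = gens
            phys[name + "_years"] = gens * ctx.generation_time
    fit.physical = phys
    return fit


def physical_to_scaled(model: EpochModel, n_anc: float | None = None) -> dict[str, float]:
    """Scaled parameters (nu, tau) of a physical-unit epoch model."""
    n0 = n_anc if n_anc is not None else model.sizes[0]
    pnames = MODEL_PARAMS[f"{model.n_epochs}Epoch"]
    nus = [s / n0 for s in model.sizes[1:]]
    taus = [t / (2 * n0) for t in model.durations]
    return dict(zip(pnames, nus + taus))


def likelihood_ratio_test(simple: FitResult, complex: FitResult, df: int):
    """LRT statistic -2(ll_simple - ll_complex), floored at 0, chi-square p."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = max(-2.0 * (simple.log_likelihood - complex.log_likelihood), 0.0)
    return stat, float(chi2.sf(stat, df))


def parametric_bootstrap_ci(
    fit: FitResult,
    obs: FoldedSFS,
    n_boot: int = 100,
    seed: int = 0,
    n_restarts: int = 5,
    params_of_interest: tuple[str, ...] | None = None,
    ctx: ScalingContext | None = None,
    fixed: dict[str, float] | None = None,
    engine: str = "multinomial",
) -> FitResult:
    """Parametric-bootstrap CIs: point +/- 2 SD of bootstrap re-estimates.

    Engines: ``"multinomial"`` resamples SNP counts from the fitted
    expectation (composite-likelihood noise only; understates uncertainty
    under linkage); ``"coalescent"`` simulates whole spectra under the
    fitted model with recombination (linkage-aware; requires ``ctx``);
    ``"none"`` refits the expectation itself (degenerate engine: residual
    spread reflects optimizer noise only).  Negative lower bounds are
    truncated at 0.  Failed refits are skipped and the success count
    recorded under the ``"n_boot_ok"`` key.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    pnames = MODEL_PARAMS[fit.model]
    keys = params_of_interest or pnames
    n = obs.n_haploids
    shape = _model_shape(fit.model, np.array([fit.params[p] for p in pnames]), pnames, n)
    s_obs = int(round(np.sum(obs.counts[1:])))
    probs = shape[1:] / shape[1:].sum()
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {k: [] for k in keys}
    n_ok = 0
    if engine == "coalescent":
        if ctx is None:
            raise ValueError("coalescent engine needs a ScalingContext")
        if not fit.physical:
            scale_parameters(fit, ctx)
        gen_model = _epoch_model_from_physical(fit)
    for b in range(n_boot):
        if engine == "coalescent":
            from .expected import simulated_sfs_epoch

            boot = simulated_sfs_epoch(
                gen_model, n, ctx, seed=int(rng.integers(1, 2**31 - 1))
            )
        else:
            counts = np.zeros_like(obs.counts)
            if engine == "none":
                counts[1:] = s_obs * probs
            else:
                counts[1:] = rng.multinomial(s_obs, probs)
            boot = FoldedSFS(n, counts)
        try:
            bf = fit_model(boot, fit.model, n_restarts=n_restarts,
                           seed=int(rng.integers(2**31 - 1)), fixed=fixed,
                           extra_starts=[fit.params])
        except RuntimeError:
            continue
        n_ok += 1
        src = bf.params
        if ctx is not None:
            scale_parameters(bf, ctx)
            src = {**bf.params, **bf.physical}
        for k in keys:
            draws[k].append(src[k])
    point = dict(fit.params)
    if ctx is not None and fit.physical:
        point.update(fit.physical)
    ci = {}
    for k in keys:
        sd = float(np.std(draws[k])) if draws[k] else np.nan
        lo = max(point[k] - 2 * sd, 0.0)
        hi = point[k] + 2 * sd
        ci[k] = (lo, hi)
    ci["n_boot_ok"] = (n_ok, n_ok)
    fit.ci = ci
    return fit


def grid_search(
    obs: FoldedSFS,
    fit: FitResult,
    grid_nu: np.ndarray,
    grid_T: np.ndarray,
    nu_name: str = "nuF",
    T_name: str = "TF",
    threshold: float = 2.0,
):
    """Likelihood surface over a (current size, current time) grid.

    Other parameters stay at their fitted values.  Returns the
    log-likelihood matrix and the boolean mask of points within
    ``threshold`` log-units of the grid maximum.
    """
    grid_nu = np.asarray(grid_nu, dtype=float)
    grid_T = np.asarray(grid_T, dtype=float)
    if grid_nu.size == 0 or grid_T.size == 0:
        raise ValueError("grid must be non-empty")
    pnames = MODEL_PARAMS[fit.model]
    n = obs.n_haploids
    ll = np.empty((grid_nu.size, grid_T.size))
    for i, nu in enumerate(grid_nu):
        for j, t in enumerate(grid_T):
            p = dict(fit.params)
            p[nu_name] = nu
            p[T_name] = t
            shape = _model_shape(fit.model, np.array([p[q] for q in pnames]), pnames, n)
            ll[i, j] = composite_loglik(obs, FoldedSFS(n, shape))
    region = ll >= ll.max() - threshold
    return ll, region
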