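"""Configuration-driven orchestration of the full analysis.

Stages: simulate -> filter -> sfs -> fit -> roh/popstats -> load ->
forwardsim.  A YAML config selects stages and parameters; every run
writes a manifest listing each artifact with its SHA-256 and the seeds
used, so reruns with the same config are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import demography, popstats, roh, sfs
from .dataset import FilterConfig
from .deleterious import rxy_by_class
from .forward_sim import SimConfig, fin_whale_load_scenario, run_replicates
from .synthetic import NoiseModel, apply_filter_cascade, assign_annotations, simulate_genotypes
from .vcfio import write_vcf

log = logging.getLogger("whalepop")

DEFAULT_CONFIG = {
    "scenario": "demo_twopop",
    "seed": 1,
    "stages": ["simulate", "filter", "sfs", "fit", "popstats", "roh", "load"],
    "simulate": {
        "n_per_pop": {"ENP": 12, "GOC": 8},
        "seq_len": 2_000_000,
        "mu": 2.77e-8,
        "rec": 1e-8,
    },
    "filter": {"noise": {"mean_depth": 30.0}, "enabled": True},
    "sfs": {"projection": {"ENP": 20, "GOC": 12}},
    "fit": {"model": "2Epoch", "n_restarts": 10},
    "popstats": {"n_perm": 199},
    "roh": {},
    "load": {"n_blocks": 20},
    "forwardsim": {"lambda": 60, "replicates": 2},
}


@dataclass
class PipelineConfig:
    raw: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG))
    outdir: Path = Path("whalepop_run")

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path | None = None):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        merged = {**DEFAULT_CONFIG, **raw}
        return cls(raw=merged, outdir=Path(outdir or merged.get("outdir", "whalepop_run")))

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 1))

    @property
    def stages(self) -> list[str]:
        return list(self.raw.get("stages", []))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; returns the manifest."""
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"scenario": cfg.raw.get("scenario"), "seed": cfg.seed,
                "stages": [], "artifacts": {}}
    stages = cfg.stages
    state: dict = {}

    def record(name: str, path: Path):
        manifest["artifacts"][name] = {
            "path": str(path), "sha256": _sha256(path)
        }

    def stage_done(name):
        manifest["stages"].append(name)
        log.info("stage=%s status=done", name)

    try:
        if "simulate" in stages:
            p = cfg.raw["simulate"]
            model = demography.fin_whale_two_pop()
            # shrink to the configured demo scale
            scale = p.get("demography_scale", 0.01)
            from dataclasses import replace as _rep
            model = _rep(
                model,
                n_anc=model.n_anc * scale, n_anc2=model.n_anc2 * scale,
                n1=model.n1 * scale, n2=max(model.n2 * scale, 4),
                t_a=model.t_a * scale, t_split=model.t_split * scale,
                m_1_to_2=min(model.m_1_to_2 / scale, 0.2),
                m_2_to_1=min(model.m_2_to_1 / scale, 0.2),
            )
            ds = simulate_genotypes(
                model, p["n_per_pop"], p["seq_len"], p["mu"], p["rec"],
                seed=cfg.seed,
            )
            ds = assign_annotations(ds, seed=cfg.seed + 1)
            state["dataset"] = ds
            vcf_path = out / "simulated.vcf"
            write_vcf(ds, vcf_path)
            record("simulated_vcf", vcf_path)
            stage_done("simulate")

        if "filter" in stages and "dataset" in state:
            p = cfg.raw["filter"]
            noise = NoiseModel(**p.get("noise", {})) if p.get("enabled", True) else None
            ds, tallies = apply_filter_cascade(
                state["dataset"], noise, FilterConfig(), seed=cfg.seed + 2
            )
            state["dataset"] = ds
            path = out / "filter_tallies.json"
            path.write_text(json.dumps(tallies, indent=1))
            record("filter_tallies", path)
            stage_done("filter")

        if "sfs" in stages and "dataset" in state:
            ds = state["dataset"]
            p = cfg.raw["sfs"]
            spectra = {}
            for pop, m in p["projection"].items():
                tal = sfs.build_sfs(ds, pop, sites=sfs.neutral_mask(ds))
                spectrum = sfs.project_sfs(tal, m)
                spectrum = sfs.add_monomorphic(spectrum, ds, {pop: m})
                spectra[pop] = spectrum
                path = out / f"sfs_{pop}.txt"
                path.write_text(spectrum.to_dadi_text())
                record(f"sfs_{pop}", path)
            state["spectra"] = spectra
            stage_done("sfs")

        if "fit" in stages and "spectra" in state:
            p = cfg.raw["fit"]
            ds = state["dataset"]
            results = {}
            for pop, spec in state["spectra"].items():
                fit = demography.fit_model(
                    spec, p["model"], n_restarts=p["n_restarts"], seed=cfg.seed
                )
                ctx = demography.ScalingContext(L=ds.seq_len)
                demography.scale_parameters(fit, ctx)
                results[pop] = {
                    "model": fit.model,
                    "log_likelihood": fit.log_likelihood,
                    "params_scaled": {k: float(v) for k, v in fit.params.items()},
                    "params_physical": {k: float(v) for k, v in fit.physical.items()},
                    "top10_spread": float(fit.top10_spread),
                }
            path = out / "demography_fits.json"
            path.write_text(json.dumps(results, indent=1))
            record("demography_fits", path)
            stage_done("fit")

        if "popstats" in stages and "dataset" in state:
            ds = state["dataset"]
            p = cfg.raw["popstats"]
            het = {
                str(i): popstats.genome_wide_heterozygosity(ds, i)
                for i in range(ds.n_individuals)
            }
            fst = popstats.wc_fst(ds, n_perm=p.get("n_perm", 999), seed=cfg.seed)
            path = out / "popstats.json"
            path.write_text(json.dumps({
                "het_per_kb": het,
                "fst": fst.fst, "fst_p": fst.p_value,
                "inflation_factor": fst.inflation_factor,
            }, indent=1))
            record("popstats", path)
            stage_done("popstats")

        if "roh" in stages and "dataset" in state:
            ds = state["dataset"]
            rows = []
            for i in range(ds.n_individuals):
                segs = roh.call_roh(ds, i)
                summ = roh.summarize_roh(segs, ds.seq_len)
                rows.append({"individual": i, "f_roh": summ.f_roh,
                             "n_by_class": summ.n_by_class})
            path = out / "roh.json"
            path.write_text(json.dumps(rows, indent=1))
            record("roh", path)
            stage_done("roh")

        if "load" in stages and "dataset" in state:
            ds = state["dataset"]
            pops = ds.populations
            if len(pops) >= 2:
                res = rxy_by_class(ds, pops[1], pops[0],
                                   n_blocks=cfg.raw["load"].get("n_blocks", 50))
                path = out / "rxy.json"
                path.write_text(json.dumps({
                    cls: {"r_xy": r.r_xy, "r2_xy": r.r2_xy,
                          "p_r": r.p_r, "p_r2": r.p_r2}
                    for cls, r in res.items()
                }, indent=1))
                record("rxy", path)
            stage_done("load")

        if "forwardsim" in stages:
            p = cfg.raw["forwardsim"]
            cfg_sim = fin_whale_load_scenario(
                migration=p.get("migration", True),
                lam=p.get("lambda", 60),
                seed=cfg.seed,
            )
            reps = run_replicates(cfg_sim, n_replicates=p.get("replicates", 2))
            path = out / "forwardsim.json"
            path.write_text(json.dumps([
                {cp: {pop: vars(st) for pop, st in by_pop.items()}
                 for cp, by_pop in rep.items()}
                for rep in reps
            ], indent=1, default=float))
            record("forwardsim", path)
            stage_done("forwardsim")
    except Exception:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
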