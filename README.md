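# whalepop

Population-genomic analysis toolkit for a two-deme baleen-whale system: a
large Eastern North Pacific (ENP) fin-whale population that crashed during
twentieth-century whaling, and a small Gulf of California (GOC) population
kept viable by less than one effective migrant per generation.  The
package re-implements the full analysis chain on synthetic data — no
sequence downloads required — for population geneticists who want to
reproduce, stress-test or extend the inferences.

What it does:

* **Synthetic data** — coalescent genotypes (msprime) under a catalogue of
  demographic models, functional annotation (SYN/TOL/DEL/LOF with SIFT
  scores), genotype-level sequencing noise and the depth/GQ/allele-balance/
  missingness filter cascade.
* **Site frequency spectra** — folded 1D/2D spectra with hypergeometric
  projection P(j | n, d, m) to handle missing genotypes, and the
  monomorphic 0-bin bookkeeping demographic inference needs.
* **Demographic inference** — composite multinomial likelihood over SFS
  classes; analytic expected spectra for piecewise-constant histories
  (E[ξ_i] = μL Σ_k k E[T_k] C(n−i−1,k−2)/C(n−1,k−1), with E[T_k] from
  matrix exponentials of the lineage-count chain); Monte-Carlo expected
  joint spectra for split-with-migration models; multi-start simplex
  fitting, θ = 4N_ANC μL scaling to physical units, likelihood-ratio
  tests, parametric-bootstrap CIs (multinomial or linkage-aware
  coalescent engine) and (N_CUR, T_CUR) grid searches.
* **Diversity and inbreeding** — heterozygosity (genome-wide and 1-Mb
  windows), Weir–Cockerham F_ST with permutation p-values, the 1/(1−F_ST)
  inflation factor, LD pruning, method-of-moments kinship, a two-state
  HMM ROH caller with length classes, F_ROH and the t = 100/(2 E[L] r)
  coalescence dating of ROH classes.
* **Deleterious variation** — mutation-class burdens normalized for
  missing data and the R_XY / R²_XY relative-accumulation statistics with
  weighted block-jackknife errors.
* **Forward simulation** — a Wright–Fisher simulator of deleterious
  variation (gamma DFE, size-dependent dominance, migration), with
  λ-rescaling utilities that preserve θ, ρ, N·s, N·m — and optionally the
  deleterious genomic mutation rate U, which is what absolute genetic
  load depends on.

## Worked example: recovering the whaling crash

Simulate a folded SFS for 44 haploid genomes over 40 Mb of neutral
sequence under the fitted three-epoch ENP history (16,479 → 23,913
diploids 4,424 generations ago, then a crash to 305 diploids two
generations ago), and refit it:

```python
from whalepop.demography import (ScalingContext, fin_whale_enp_3epoch,
                                 simulated_sfs_epoch, fit_recent_contraction)

model = fin_whale_enp_3epoch()            # 16,479 -> 23,913 -> 305 diploids
ctx = ScalingContext(mu=2.77e-8, L=40e6)  # 40 Mb of neutral sequence
obs = simulated_sfs_epoch(model, n=44, ctx=ctx, seed=4)
fit = fit_recent_contraction(obs, ctx, n_restarts=50, seed=4)

print(f"segregating sites: {int(obs.counts[1:].sum())}")
for key in ("N_ANC", "N_BOT", "N_CUR", "T_BOT", "T_CUR", "T_CUR_years"):
    print(f"{key:12s} {fit.physical[key]:12.1f}")
```

Output:

```
segregating sites: 344788
N_ANC             16176.5
N_BOT             23654.3
N_CUR               274.3
T_BOT              4960.5
T_CUR                 2.0
T_CUR_years          51.8
```

The ancestral and expansion sizes come back within ~2 %, and the
two-orders-of-magnitude crash is recovered (274 vs a generating value of
305 diploids) even though only two generations separate it from the
present — the crash time is pinned at two generations because current
size and crash time are otherwise confounded on a likelihood ridge, the
same reason the original analysis ran fixed-time model variants and grid
searches.  A single 40-Mb realization still carries substantial linkage
noise: across independent realizations the point estimate ranges from
roughly 100 to several hundred (use `parametric_bootstrap_ci` with
`engine="coalescent"` for honest uncertainty).

A configuration-driven pipeline covering
simulate → filter → SFS → fit → popstats → ROH → load is exposed both as
a library (`whalepop.pipeline`) and a CLI:

```bash
whalepop all --outdir demo_run --seed 1
whalepop fit --config my_scenario.yaml
```

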