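# geophylocausal

Diachronic causal analysis of environmental effects on traits evolving
along geo-annotated phylogenies.

## The problem

Claims that the physical environment shapes cultural traits — the
motivating case is ambient humidity and the number of lexical tones in a
language — are usually tested on present-day data: one observation per
language, regressed on local climate. But present-day data are the
leaves of a branching historical process. Related lineages inherit both
their traits and (because populations move slowly) their environments,
so leaf-level observations are deeply non-independent, and a single
early "founder" branch that migrates into a different climate zone can
manufacture a strong synchronic correlation out of nothing.

`geophylocausal` implements the full analysis chain for testing such
claims *diachronically*, on a time-calibrated tree whose every node
carries an age and a location:

1. **synthetic data** — pure-birth geo-phylo trees, Brownian dispersal
   with optional founder jumps, smooth space–time humidity fields and
   null/causal trait histories, so the whole chain is testable offline;
2. **bias diagnostics** — the type-I error rate of the naive leaf-level
   regression under a null trait model, and per-node perturbation
   importances;
3. **reconstruction** — Brownian-motion ancestral state reconstruction
   with a fossilised root (exact Gaussian conditioning), Pagel's λ, and
   tensor-spline interpolation of gridded climate;
4. **comparative tests** — Pagel's discrete dependent/independent CTMC
   test and the Brownian evolutionary correlation, the standard
   phylogeny-only controls;
5. **causal models** — two Bayesian models of the per-edge trait change

   ```
   T_desc − T_anc ~ Normal((α + η·H + γ·Gt + ρ·Pt)·dA,  σ0 + β·dA)
   ```

   where `H` is the humidity experienced along the edge, `Gt`/`Pt`
   summarise geographically/phylogenetically close lineages (Model LIN),
   or are replaced by Gaussian-process effects over great-circle and
   cophenetic distance (Model GP). Reconstruction uncertainty enters
   through latent measurement layers, which are marginalised analytically
   and sampled with ensemble MCMC. Savage–Dickey density ratios test
   η = 0; PSIS-LOO compares model variants.

See `docs/methods.md` for the models, priors and numerical choices.

## Worked example

```python
import numpy as np
from geophylocausal.simulate import (SimulationConfig, FounderJump,
                                     TraitModelConfig, simulate_dataset)
from geophylocausal.bias import type1_error_study
from geophylocausal import causal

# a 200-tip tree whose founder jump creates two humidity clusters,
# with a NULL trait history (no humidity effect at all)
cfg = SimulationConfig(n_tips=200, seed=1, founder_jump=FounderJump(),
                       trait=TraitModelConfig(kind="null"))
tree = simulate_dataset(cfg)
humidity = {n: tree.nodes[n].traits["humidity"] for n in tree.node_ids}
traits = {n: tree.nodes[n].traits["trait"] for n in tree.node_ids}

# naive leaf-level regression, 100 simulated null datasets
res = type1_error_study(tree, humidity, n_datasets=100, alpha=0.05, seed=2)
print(f"naive OLS significant in {int(res.rate*100)}/100 null datasets")

# the diachronic causal model on the same data
table = causal.build_node_pair_table(tree, traits, humidity,
                                     phylo_radius_mode="fraction_of_depth")
fit = causal.fit_model(causal.ModelSpec(variant="lin", seed=3), table)
sd = causal.savage_dickey(fit, "eta")
print(f"Savage-Dickey BF10 for the humidity effect: {sd['bf10']:.2f}")
```

Output:

```
naive OLS significant in 71/100 null datasets
Savage-Dickey BF10 for the humidity effect: 0.11
```

Read: the naive synchronic regression declares a humidity effect in 71
of 100 datasets generated with *no* effect (nominal rate: 5) — the
genealogical clustering does that on its own — while the diachronic
model, which regresses per-edge changes on per-edge conditions with
geographic and phylogenetic controls, correctly finds the data ~9×
*against* a humidity effect (BF₁₀ < 1 favours the null).

A full pipeline run (simulate → bias study → comparative tests → LIN/GP
fits → Savage–Dickey + ELPD report, with a digest manifest) is:

```sh
geophylocausal run --config config.yaml --out results/ --seed 1
```

and `geophylocausal archived --data <dir> ...` runs the same chain on a
locally stored tree + node table + humidity grid.

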