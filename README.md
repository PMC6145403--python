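# rdinvade

Forward-time simulation and analysis of wild-type (WT) invasion into
*Tribolium castaneum* populations fixed for the dominant **Reindeer (Rd)**
marker.

## The problem

In a multigenerational invasion assay, 10 WT males are introduced into a
population of 90 Rd adults (50 females, 40 males). Because Rd is a dominant
visible marker, the WT phenotype is only expressed by WT/WT homozygotes:
every first-generation offspring sired by a WT colonist is heterozygous and
therefore invisible, so introgression is scored from generation 2 onward as
the proportion of adults showing the WT phenotype. The question is which
*fitness components* drive the observed invasion: male reproductive success,
female reproductive success, offspring viability, or combinations of them.

`rdinvade` answers this with an individual-based, single-locus forward
simulation of the assay. Each generation, 230 mating slots are filled by
sampling mothers and fathers with replacement; each pair produces 52
offspring under Mendelian inheritance; 30% of offspring survive to
adulthood; and 230 males plus 230 females are recruited into the next
breeding population. A relative-fitness parameter **α** (WT vs Rd; class
weights Rd/Rd = 1, heterozygote = (1+α)/2, WT/WT = α, i.e. sampling
probabilities 1/(α+1) vs α/(α+1) for an Rd/WT pair) can act through any
subset of the three fitness components, giving eight scenarios
(i = neutral … viii = all three) crossed with α ∈ {1.5, 2, 5, 10}. Each
scenario × α cell is run for 500 replicates and summarised by the median and
5–95% quantiles of the WT-homozygote proportion per generation.

The analysis layer compares observed (or synthetic) invasion trajectories
from two sexual-selection regimes (Monogamy vs Polyandry backgrounds,
3 lines × 4 replicate populations each) against the simulated grid: regime
means ± SE per generation, a within-line permutation test of the regime
contrast, and an RMSE-based ranking of which (scenario, α) cell best
explains each regime's trajectory.

## Worked example

```python
import numpy as np
from rdinvade import (GeneratorParams, InvasionModel, SimulationConfig,
                      build_scenario_grid, generate_invasion_dataset)

data = generate_invasion_dataset(
    GeneratorParams(), SimulationConfig(seed=7), np.random.default_rng(7))
model = InvasionModel(data, grid=build_scenario_grid(n_replicates=100))
results = model.fit(n_permutations=1999, seed=7)
print(results.summary())
```

prints

```
Invasion scenario-fit results
==================================

Mean proportion WT phenotype (SE) by regime and generation:
  Monogamy   g2=0.04(0.00)  g3=0.08(0.01)  g4=0.12(0.01)  g5=0.21(0.01)  g6=0.31(0.01)  g7=0.41(0.01)  g8=0.50(0.01)
  Polyandry  g2=0.11(0.01)  g3=0.20(0.02)  g4=0.39(0.02)  g5=0.56(0.02)  g6=0.70(0.01)  g7=0.80(0.01)  g8=0.88(0.01)

Regime difference (Polyandry - Monogamy): g2=+0.07, g3=+0.12, g4=+0.26, g5=+0.35, g6=+0.39, g7=+0.39, g8=+0.38
Largest difference at generation 6 (+0.39)
Within-line permutation test (Monte Carlo, 1999 permutations): statistic=+0.281, p=0.0005

Best-fitting simulations for Monogamy: #1 scenario viii (alpha=1.5, RMSE=0.009), #2 scenario iv (alpha=2, RMSE=0.018), #3 scenario vii (alpha=2, RMSE=0.047)
Best-fitting simulations for Polyandry: #1 scenario viii (alpha=2, RMSE=0.010), #2 scenario v (alpha=5, RMSE=0.031), #3 scenario ii (alpha=10, RMSE=0.097)
```

The synthetic dataset here was generated under scenario viii (all three
fitness components) with α = 1.5 for the Monogamy regime and α = 2 for
Polyandry; the fit ranks exactly those cells first for each regime, the
permutation test detects the regime contrast (p ≈ 0.0005), and the
difference trajectory peaks mid-experiment — the same qualitative structure
seen in the real assay. `results.plot()` overlays the observed trajectories
on the best-fitting simulation bands.

A packaged reference table (`rdinvade.load_table1()`) carries the published
per-generation regime means ± SE of the real 24-population assay for use
with `regime_summary`, `regime_difference` and `scenario_fit`.

## Command line

```bash
rdinvade simulate --scenario all --alpha 1.5,2,5,10 --replicates 500 \
    --survival 0.3 --seed 1 --out summaries.csv
rdinvade generate invasion --seed 1 --out invasion.csv
rdinvade analyze --data invasion.csv --summaries summaries.csv \
    --permutations 10000 --seed 1 --out report.json
```

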