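# carsdm

Bayesian spatial occupancy modelling, climate-change projection with
dispersal constraints, and mitochondrial haplotype summaries — the analysis
toolkit for studying how a range-restricted species (the motivating case is
a desert-breeding storm-petrel of the Sechura/Atacama coast) responds to
environment and climate change, from occurrence records and gridded
covariates to genetic diversity.

## What it computes

**Occupancy model.** For each raster cell *i*,

    Z_i ~ Bernoulli(pi_i),    logit(pi_i) = X_i beta + rho_j(i)

with standardized covariates `X`, fixed effects `beta ~ N(0, 100)`, and an
intrinsic CAR (iCAR) spatial random effect `rho` on the cell-adjacency
graph — conditionally normal around the neighbor mean with variance
`V_rho / n_j`, `V_rho ~ Uniform(0, V_max)`, identified by a sum-to-zero
constraint. The fit is a Polya-Gamma Gibbs sampler (no tuning parameters,
bit-reproducible from a seed); model comparison by DIC.

**Projection.** Posterior-median suitability surfaces on present or future
covariate stacks; binarization at the max-SSS threshold (maximizes
sensitivity + specificity); gain/loss/no-change/no-occupancy change maps;
areas in km² under the South American Albers equal-area conic projection.

**Dispersal constraints.** A MigClim-style colonization simulator on the
0–1000 suitability scale with thresholds (conventionally 300/500/700),
short-distance kernels, and "strong" barrier cells that can neither be
colonized nor transmit; reports the six standard counters (no-dispersal,
unlimited-dispersal, occupied, absent, colonized, decolonized) and
best/worst scenario selection.

**Genetics.** DnaSP-style summaries of small mtDNA alignments under
complete deletion — haplotype collapsing, segregating sites S, Nei's
haplotype diversity H (with sampling variance) and per-site nucleotide
diversity pi — plus a Bandelt-style median-joining haplotype network on
Hamming distances.

**Screening & synthesis.** 1-km great-circle thinning of occurrence
records, stepwise VIF predictor screening (threshold 10), and seeded
generators for landscapes, iCAR fields, occurrences and haplotype
alignments so the whole pipeline runs offline with known ground truth.

## Worked example

```python
import numpy as np
from carsdm import *

stack = make_landscape(LandscapeSpec(20, 30, 4, seed=1))   # 600 cells
graph = build_neighbor_graph(stack)
truth = make_truth(stack, graph, [-1.0, 2.0, -2.0, 1.0, 0.5], 2.0, seed=11)
occ   = simulate_occurrences(stack, truth, seed=21)
fit   = fit_icar_bernoulli(occ["presence"].to_numpy(), stack.design_matrix(),
                           graph, n_iter=20_000, seed=1)
print(posterior_summary(fit).round(3))
```

prints

```
              Mean      SD   Q0.025   Q0.975
Intercept   -0.785   0.161   -1.129   -0.492
x1           1.383   0.336    0.791    2.123
x2          -1.948   0.288   -2.580   -1.458
x3           1.087   0.261    0.634    1.671
x4           0.502   0.244    0.039    1.019
Vrho         1.326   1.127    0.251    4.231
Deviance   456.622  22.901  399.207  488.907
```

Every generating coefficient (−1, 2, −2, 1, 0.5) lies inside its 95%
credible interval, and `Vrho`'s interval covers the generating spatial
variance 2. The `examples/` directory has one script per capability:
model fitting, projection + change accounting, dispersal simulation, and
haplotype summaries; each prints its results with a note on how to read
them. For instance `examples/04_haplotype_summaries.py` builds a
14-sequence, 955-bp alignment with four haplotypes in counts (5, 5, 3, 1)
and prints `S = 17`, `H = 0.747` (Nei variance 0.0043) and the network
edge list.

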