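# nlgrn

Non-linear reverse engineering of gene regulatory networks from time-course
expression data.

The pipeline has two halves. A **top-down** stage infers network structure
with a Gaussian-graphical-model forward search: candidate regulations —
gene→gene first, then product-term (NLT, the elementwise product of two gene
series, standing in for a heterodimer or synergistic pair) → gene — are
scored by chi-square deviance tests of constrained maximum-likelihood
covariance fits (iterative proportional scaling with a Newton polish), added
greedily while significant, and oriented into a DAG. The NLT-edge count is
capped at the gene-edge count so product terms cannot dominate. A
**bottom-up** stage fits a bilinear ODE model on the selected support

```
dx_i/dt = Σ_j α_ij x_j + Σ_{j<k} β_ijk x_j x_k − k_i x_i
```

with a real-coded genetic algorithm (multi-start, elitist, box bounds),
scores fitted models by the root total squared simulation error and by
perturbation-robustness statistics (RA/RSTD under multiplicative parameter
noise, `θ → θ(1 + μ ε)` with μ = 0.4 by default), and simplifies the network
by greedy edge deletion until both error and robustness degrade.

A synthetic module generates ground-truth benchmarks (random sparse DAG +
bilinear parameters, 30-point week-long sampling schedule, multiplicative
log-normal replicate noise) so the whole pipeline is testable offline.

## Modules

| module | contents |
| --- | --- |
| `nlgrn.datamodel` | core types (time grid, dataset, augmented matrix, network, parameters), NLT enumeration, parameter counting, replicate averaging |
| `nlgrn.io` | expression TSV, network edge-table/SIF, parameter documents |
| `nlgrn.efsa` | covariance assembly, IPS/Newton constrained MLE, deviance tests, two-stage forward search, orientation |
| `nlgrn.dynamics` | bilinear ODE right-hand side, adaptive simulation with divergence handling, simulation error |
| `nlgrn.estimation` | GA configuration, single fit, multi-start, normalization |
| `nlgrn.robustness_pruning` | perturbation, RA/RSTD, removal scoring, greedy pruning, trace replay/export |
| `nlgrn.synthetic` | benchmark generator and reference sampling schedule |
| `nlgrn.presets` | the 11-gene hematopoiesis panel and published network shapes used for structural replays |
| `nlgrn.cli` | the `nlgrn` command |

## CLI

```bash
nlgrn synth   --out out/            # synthetic benchmark (data + truth)
nlgrn efsa    --out out/ --data out/expression.tsv
nlgrn fit     --out out/ --data out/expression.tsv --network out/network.tsv
nlgrn robust  --out out/ --data out/expression.tsv --network out/network.tsv --params out/params_rank1.tsv
nlgrn prune   --out out/ --data out/expression.tsv --network out/network.tsv --params out/params_rank1.tsv
nlgrn run-all --out out/            # everything, synthesizing data if none given
```

All commands accept `--config config.yaml` (keys `seed`, `synth`, `efsa`,
`ga`, `robustness`, `prune`, mirroring the config dataclasses) and
`--preset desk|full`. `desk` (default) is a fast scaled-down protocol;
`full` is the classic one (population 300, 1000 generations, 200 restarts,
5000 perturbations — hours of CPU). Every run writes a resolved config
snapshot, a log, and machine-readable summaries next to its artifacts; one
global seed derives all stage seeds.

Note on bounds: the GA's coefficient bounds are per time-unit rates. On an
hours-scale grid spanning a week, bounds of ±3 h⁻¹ diverge almost surely;
scale them by the grid span (the desk preset uses ±0.02).

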