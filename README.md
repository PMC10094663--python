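# phyloattractor

Tools for detecting a **unicellular attractor** in cellular networks: the
tendency of random trajectories and expression activity to concentrate on
the evolutionarily ancient, densely connected core of the protein
interaction network.

The package is aimed at systems biologists working with STRING-style
interactomes, gene-age (phylostratum) annotations, and two-group single-cell
expression data (e.g. cancer vs. normal cells). It provides:

- **Interactome centrality by gene age** — degree, closeness
  (1 / Σ shortest-path lengths) and betweenness (Brandes shortest-path
  traffic) on the confidence-filtered network (edges kept when
  `combined_score > 0.5`), summarized per phylostratum (1 = cellular
  organisms … 17 = Hominidae).
- **Random-walk endpoint simulation** — ensembles of uniform-neighbor walks
  started in the youngest stratum; endpoint counts per stratum are
  normalized by the stratum's gene number. On a connected non-bipartite
  graph the endpoint law of long walks converges to the stationary
  distribution π(v) = deg(v)/2|E|, so an old dense core attracts walk
  endpoints exactly in proportion to its excess degree — the closed form
  that serves as the package's primary oracle.
- **Expression fold profiles** — quantile normalization + log2, per-gene
  log2 group folds (cancer − normal, invasive − non-invasive,
  polyploid − diploid), per-stratum(-bin) profiles with optional exclusion
  of the ZF-C2H2 zinc-finger set, analysis-of-means (ANOM) decision limits,
  and gene-set stratum composition with its Spearman age trend.
- **Contrast enrichment over a GO-like DAG** — annotations propagated so a
  gene belongs to a term if annotated to any descendant; each term's mean
  fold is contrasted with the total-gene-set mean; two-tailed significance
  by Monte-Carlo random sampling (size-matched subsets drawn without
  replacement, pool replaced between samples); Benjamini–Hochberg q-values.
- **Synthetic data generators** — age-layered core-periphery networks
  (preferential attachment or duplication–divergence), stratified expression
  with a planted per-stratum fold gradient ("gradual atavism"), and random
  GO DAGs with planted enriched terms, so the whole analysis is reproducible
  and testable without external downloads.
- **A pipeline driver** — one TOML config, staged TSV outputs with fixed
  9-decimal formatting, and a JSON manifest with digests, so identical
  config + seed give byte-identical results.

## Worked example

Grow an age-layered network with a planted old-core degree gradient and ask
where random walks started among the youngest proteins end up:

```python
from scipy import stats
from phyloattractor import (
    NetworkGenConfig, WalkConfig, gen_network, run_ensemble,
)

net, smap = gen_network(NetworkGenConfig(n_per_stratum=[100] * 17, m=3, seed=42))
dist = run_ensemble(
    net, smap,
    WalkConfig(n_repeats=10_000, walk_length=200, start_stratum=17, seed=42),
)
for s in (1, 2, 3, 9, 17):
    print(f"stratum {s:2d}  endpoints {dist.raw_counts[s]:5d}  "
          f"normalized {dist.normalized[s]:.3f}")
rho, p = stats.spearmanr(range(1, 18), [dist.normalized[s] for s in range(1, 18)])
print(f"Spearman rho vs stratum index: {rho:.3f} (p = {p:.2e})")
```

prints

```
stratum  1  endpoints  2173  normalized 21.730
stratum  2  endpoints  1024  normalized 10.240
stratum  3  endpoints   838  normalized 8.380
stratum  9  endpoints   439  normalized 4.390
stratum 17  endpoints   264  normalized 2.640
Spearman rho vs stratum index: -0.988 (p = 1.63e-13)
```

Although every walk starts in stratum 17, after 200 steps more than a fifth
of them end on a stratum-1 protein: per gene, ancient strata collect about
an order of magnitude more endpoints than young ones, and the normalized
frequency declines monotonically with stratum index — the unicellular
attractor signature. The same analyses run from the shell:

```sh
phylo-attractor simulate network --seed 42 --out-dir fixtures/
phylo-attractor walk --edges fixtures/edges.tsv --strata fixtures/strata.tsv \
    --length 1000 --repeats 10000 --start-stratum 17 --seed 42 --out dist.tsv
phylo-attractor run --config analysis.toml       # full pipeline + manifest
```

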