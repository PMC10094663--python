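# Methods

This note documents the models, estimators and numerical choices behind
`phyloattractor`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Identifiers and input contracts

All components share one string identifier space: network nodes, stratum-map
keys, expression-table rows and GO annotations must already use the same
identifiers. No identifier mapping is performed. Network nodes missing from
the stratum map stay in the graph but are excluded from per-stratum
summaries, with the excluded count logged. Edge confidence in (0, 1] (or
STRING-style 0–1000 integers, detected from the maximum and divided by
1000) acts purely as a filter — edges are kept when the score is *strictly*
greater than the threshold (default 0.5) — and never as a path weight: all
path lengths are hop counts.

## Centrality

Degree is the unweighted count of direct interactions. Closeness is the raw
reciprocal of the summed hop distances from a node to every node it can
reach; on disconnected graphs the sum runs over the node's component only,
since the reciprocal form is undefined for unreachable pairs (component
sizes are logged; a classic (k−1)/Σd normalized variant is available behind
a flag, default off, because published interactome analyses differ on
this). Betweenness is unweighted shortest-path betweenness with unordered
pairs counted once and endpoints excluded. When several geodesics tie, the
default follows Brandes fractional credit; a `count-all` tie policy (each
geodesic contributes 1) is available because verbal definitions of
"number of shortest paths passing through" are ambiguous on ties, and the
chosen policy is recorded with the output. Per-stratum summaries report
mean, standard error (0 for singleton strata) and n.

## Random-walk ensemble

A walk starts at a uniformly chosen protein of the start stratum (default
17) and takes `walk_length` uniform-neighbor steps; revisits are allowed,
and only the final node is tallied, by its stratum. Endpoint counts are
normalized by the number of stratum-mapped nodes present in the filtered
network; a per-stratum gene-count table can be supplied to normalize
against an external universe instead. An isolated start terminates at
itself and is counted in `n_dead_end_terminations`.

On any connected non-bipartite graph the endpoint law converges to
π(v) = deg(v)/2|E|, so the normalized per-stratum frequency converges to
(mean stratum degree)/2|E|. This closed form is the module's primary
oracle: the attractor signal is exactly the excess degree of the ancient
core. Defaults (10,000 repeats; length grids from 5 to 10,000; start
stratum 17) follow the study design the package implements. Length sweeps
derive per-length seeds stably from the master seed and report the total
variation between successive endpoint profiles as a convergence diagnostic;
profiles stabilize by roughly 30 steps on the synthetic networks.

Randomness is counter-based: step *t* draws its uniforms from a Philox
stream keyed by (master seed, *t*), and walk *i* reads element *i*. Tallies
are therefore bit-reproducible and independent of how repeats are batched
or ordered.

## Expression folds and profiles

Quantile normalization replaces every cell's sorted value vector with the
across-cell mean of sorted vectors; ties receive the mean of the tied
reference quantiles via average-rank interpolation, matching limma's
`normalizeQuantiles(ties=TRUE)`, against which the implementation is
cross-checked in the test suite. A log2(x+1) transform follows; for
continuous intensity data a flag drops the +1 offset. Folds are per-gene
differences of group means on the log2 scale, oriented so that positive
means up in the first-named group (cancer, invasive, polyploid); the
orientation is recorded in output metadata. Genes with zero variance are
retained (their fold is defined and contributes nothing to contrasts).
Precomputed fold tables (e.g. polyploid/diploid contrasts) can be read
directly, bypassing normalization.

Stratum profiles average a per-gene value over stratum bins; the default
bins {1}, {2}, {3}, {4–6}, {7–9}, {10–17} keep the ancient peak strata
separate and follow the three-phase shape (peak / plateau / decline) the
analysis is designed to resolve, and are fully configurable. Empty bins are
reported with n = 0 and NaN mean rather than dropped. When an exclusion set
(e.g. ZF-C2H2, InterPro IPR036236) is given, profiles with and without the
set are produced so the two series can be overlaid. A weighted
least-squares slope of bin means against bin midpoints quantifies the age
gradient.

ANOM compares each stratum mean with the grand mean using decision limits
grand ± h·s_p·sqrt(1/n_i − 1/N), with pooled within-stratum s_p and h a
Bonferroni-adjusted t quantile t(1 − α/2k, N − k); a Monte-Carlo mode
calibrates h from the permutation distribution of the maximum standardized
deviation instead, for users who prefer an exact family level. The normal
approximation is slightly conservative (simulated familywise null rate
≈ 0.046 at α = 0.05 with 17 strata of 60). Strata with fewer than 2 genes
are excluded with a warning.

Gene-set stratum composition reports the fraction of a set's mapped genes
per stratum (or, behind a flag, the fraction of each stratum's genes that
are in the set) together with the Spearman correlation of that profile with
stratum index 1..17. Note the null sd of this correlation is about 0.25
regardless of set size — the ranks of 17 near-tied proportions are random —
so only |r| well above 0.5 indicates a real age trend.

## Contrast enrichment

Direct GO annotations are propagated up the acyclic term hierarchy in
child-before-parent topological order, so a term's gene set is the union of
its own and all descendants' direct annotations (cycles raise an error
naming an offending term). For each term with at least `min_size` measured
genes (defaults follow the conventional cutoffs: >20 for processes, >10 for
components), the statistic is the *fold difference*: the term's mean value
minus the mean over all measured genes. The baseline universe is the set of
measured genes, and category genes remain in the sampling pool.

Significance: `n_samples` (default 20,000) size-matched subsets are drawn
from the universe without replacement within a sample, with full
replacement between samples. Each tail probability uses add-one smoothing,
p_tail = (1 + hits)/(1 + n_samples), so p is never 0, and the two-tailed p
is min(1, 2·min(p_upper, p_lower)) — twice the smaller probability that a
random sample mean reaches the category mean. On the five-value toy
universe {1,2,3,4,10} with category {4,10} this reproduces the exact
enumeration value 2/10. The sampler uses index rejection when
k(k−1) ≤ n (duplicate probability bounded away from 1) and a random-key
partial ranking otherwise; both are deterministic given the per-term
substream, which is derived from the master seed and a stable term
ordering so results do not depend on evaluation order. Multiple testing is
corrected by Benjamini–Hochberg step-up (Benjamini–Yekutieli behind a
flag), named in the output.

## Synthetic data: what it emulates and what it does not

The network generator adds nodes in stratum order (oldest first) and
attaches each newcomer by degree-preferential attachment (default) or
duplication–divergence, so earlier strata accumulate degree. This plants
the core-periphery age gradient — the ground truth against which the
centrality and walk analyses are property-tested — and confidence scores
are drawn in (0.5, 1] so fixtures survive the default filter unchanged
(an optional sub-threshold edge fraction exercises the filter). The
generator makes no attempt to match human stratum sizes or real STRING
degree distributions; passing tests demonstrate that the estimators recover
planted structure, not that any particular biological network has it.

The expression generator gives gene g of stratum s a log2 baseline
(default 8 − 0.15(s−1), mimicking higher ancient-gene expression) plus a
planted group effect δ(s) for group-A cells, under lognormal (default
σ = 0.5 log2 units) or negative-binomial noise, with 50 cells per group by
default. The planted "gradual atavism" gradient δ(s) = 0.5 − 0.03(s−1) is
used in the recovery experiments. Gradient recovery is assessed on folds
computed from log-scale data directly: quantile normalization forces every
cell to a common distribution and therefore removes the common shift and
compresses the between-group signal, so the QN path preserves the sign and
ordering of the gradient but attenuates its magnitude — a property of
quantile normalization itself, visible in the tests. Real single-cell data
add dropout, library-size and batch structure that the generator does not
model.

The GO generator builds a random DAG (each non-root term takes 1–2 parents
among strictly shallower terms, acyclic by construction) with Bernoulli
direct annotations. Planted terms are leaves off the root whose gene sets
are reserved *before* random annotation, so the planted ground truth is
unambiguous; a helper shifts those genes' values by a chosen δ.

## Pipeline and determinism

The driver runs network → centrality → walks → folds → profile/ANOM →
enrichment from one TOML config. Stage seeds derive from the master seed by
sha256(master:stage) reduced below 2³¹. All real numbers are written with
fixed 9-decimal formatting, making byte-identical reruns the determinism
contract; the JSON manifest records config, input digests, per-stage output
paths, row counts and sha256 digests, and marks partial completion if a
stage fails.

## Problem sizes in the shipped experiments

The test-suite and acceptance-script experiments use scales chosen to make
the statistical checks sharp while staying desk-sized: 100 random graphs of
≤ 50 nodes for exact oracle equivalence; a 200-node network with 100,000
walks of 1000 steps for the stationary-law check (observed total variation
≈ 0.017, dominated by multinomial noise, against the 0.02 bound); 20
networks of 1700 nodes for the attractor rank-correlation experiment;
universes of 500–2000 genes with 999–20,000 samplings for the contrast-test
calibrations (the planted-recovery runs use 2000 samplings, whose add-one
p floor of ~10⁻³ already pins the planted term's q well below 0.05); and
1000 ANOM null simulations. Larger inputs are handled by the same code
paths; the walk ensemble is vectorized and runs ~10⁸ steps in seconds.

## Known limitations

- No identifier mapping: STRING protein IDs must already match the gene
  IDs of the stratum map and expression tables.
- Closeness and betweenness are exact, not approximated; very large
  interactomes (≫10⁵ nodes) will be slow in the betweenness step.
- The `count-all` betweenness tie policy is quadratic in memory per node
  block and intended for moderate graphs.
- The contrast test assumes exchangeability of genes under the null; gene
  dependence (co-expression) is not modeled, as in any permutation-based
  enrichment.
- The OBO adapter reads `is_a` edges only; other relation types
  (`part_of`, regulates) are ignored.
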