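# Methods

## Overview

`ewdense` implements an edge-weighted dense module search over a
protein–protein interaction (PPI) background, integrating two data
modalities per module: gene-level GWAS association (node weights) and
two-condition differential co-expression from a genetic reference panel of
mouse strains (edge weights).  The surrounding pipeline — probe-level
responsiveness filtering, probeset collapse, homolog mapping, mega-module
merging, hub calling, and independent-GWAS validation — reproduces the
standard preparation and follow-up for such a search.  This note records
the model, its assumptions, the defaults, and the design choices made
where the procedure was genuinely open.

## Weights and the module score

* **Node weight** `z_i = Φ⁻¹(1 − p_i)` with p clipped to
  `[1e-16, 1 − 1e-16]`.  Strictly decreasing in p, finite everywhere.
* **Edge weight** (default `fisher` mode)
  `w = |atanh(r_t) − atanh(r_c)| / sqrt(1/(n_t−3) + 1/(n_c−3))`,
  correlations clipped to ±(1 − 1e-12) before the transform.  The Fisher-z
  standardization puts the differential-co-expression signal on a z-like
  scale commensurate with the node weights; a plain `|r_t − r_c|` mode
  (`raw`) is exposed for sensitivity analysis.  A zero-variance gene's
  correlations are treated as 0 and the event is logged.
* **Balance** `λ = mean|w| / (mean|z| + mean|w|)`, computed once over the
  full background before any search, so that `λ·mean|z| = (1−λ)·mean|w|`:
  the expected per-element contributions of nodes and edges to the score
  are equal, preventing either modality from dominating.
* **Raw score** `S_m = λ(Σz)/√k + (1−λ)(Σw)/√m`, edge term absent when
  m = 0.

The score composition and λ formula are this package's own fixing of a
procedure that is often left to library internals; they follow directly
from the equal-contribution rationale above.

## Standardization

`S_n = (S_m − μ₀)/σ₀` against random same-size modules.  Two estimators:

* **analytic** (default, used inside the greedy loop): member weights are
  treated as i.i.d. draws from the background populations, giving
  `μ₀ = λ√k·μ_z + (1−λ)√m·μ_w` and the size-free
  `σ₀ = sqrt(λ²σ_z² + (1−λ)²σ_w²)` (the /√k, /√m normalizations cancel
  the size dependence of the variance).  Population moments use ddof = 0.
* **montecarlo**: mean and sd (ddof = 1) of the raw score over B random
  modules of k nodes + m edges, cached per (k, m).

On 500-gene synthetic networks the two agree to a median |ΔS_n| of about
0.01 at B = 20,000; per-step permutation inside the greedy loop would be
computationally prohibitive for no accuracy gain.

## Greedy growth

From every seed gene, all background genes adjacent to the current module
(neighbor distance d = 1 by default) are evaluated with all their edges
into the module; the candidate maximizing S_n is admitted if
`S_n(new) ≥ S_n(old)·(1 + r)` with growth rate r = 0.005.  The
multiplicative rule is ill-posed at S_n ≤ 0, where the additive margin
`S_n(new) ≥ S_n(old) + |S_n(old)|·r` is used instead.  Ties break to the
higher node weight, then the lexicographically smaller symbol, making the
search fully deterministic.  Modules below 5 genes (configurable) are not
reported.  An independently coded step-by-step oracle in the test suite
confirms exact agreement on hundreds of exhaustively evaluated small
graphs.

## Permutation significance and null models

Each module's S_m is compared with B (default 1,000) random modules of the
same size using the `(1 + exceedances)/(B + 1)` estimator (never exactly
zero); Benjamini–Hochberg across modules, significance at q < 0.05.

Two null samplers are provided:

* **unconstrained** (default): k nodes and m edges drawn uniformly without
  replacement, independently — cheap, and consistent with the analytic
  moments.
* **connected**: random connected k-node subgraphs grown by uniform
  frontier expansion, scored with their own induced edges.

For connected, module-like gene sets the unconstrained null is very
slightly conservative (on null synthetic data the mean empirical p is
≈ 0.52 rather than 0.50), because the joint distribution of a connected
subgraph's node sum, edge sum and edge count differs from independent
draws beyond its mean.  The connected null is exchangeable with such sets
by construction and yields exactly uniform p-values under the null; the
calibration tests use it.  The default remains unconstrained because it is
orders of magnitude cheaper, the bias is negligible at the q < 0.05
decision boundary, and it matches the analytic standardization.

Null-subset sampling is vectorized in `_sampling.py`: rejection sampling
with replacement when the birthday-collision bound is small, chunked
random-key argpartition otherwise — exact uniform without-replacement
sampling either way.

## Mega-modules and hubs

Significant modules merge iteratively while any pair overlaps strictly
more than 80% of the smaller module: the maximal-overlap pair merges
(gene union, induced background edges) and the scan restarts — restarting
after every merge is the chosen semantics for the underspecified
"iterative" merge, and the always-merge-the-max rule makes the result
order-independent for transitive overlap clusters and deterministic
otherwise.  Ties between pairs go to the larger summed S_n, then the
lexicographically smallest union member.  Mega-modules are rescored with
the identical score/standardization/permutation machinery (MM-S_n) and
named from a fixed label list by score rank.

Centralities within each mega-module: connectivity k_i = induced degree;
eigencentrality = leading eigenvector of the induced adjacency by power
iteration on A + I (the +I shift removes the period-2 oscillation on
bipartite subgraphs without changing the Perron vector), tolerance 1e-10,
max-normalized to 1.  On a disconnected induced subgraph the dominant
component carries the mass (logged).  Hub rule: EC > 0.2 and k_i at or
above the module's 75th degree percentile (linear-interpolation quantile —
the quartile convention was not otherwise determined).

## Validation

* **Nominal genes**: validation-GWAS p < 0.001 (strict), optionally
  restricted to the background.
* **Overrepresentation**: per mega-module containing > 1 nominal gene,
  B = 10,000 uniform same-size gene sets from the background universe
  (random gene sets, not connected subgraphs — only the size constraint is
  imposed); significance at 0.05/n.  Both readings of n are exposed:
  mega-modules actually tested (default, matching the per-region usage
  `α = 0.05/2`, `0.05/3`) or all mega-modules.
* **Score regression**: OLS of each mega-module's mean validation p
  (over genes present in the validation study; absences are logged and
  excluded) on MM-S_n; per-region significance at 0.05/3 ≈ 0.017
  (Bonferroni over three brain regions).
* **Mega-module overlap**: hypergeometric tail P(X ≥ overlap).
* **Functional ORA**: one-sided hypergeometric per annotation set against
  the universe, kept iff p < 0.01, ≥ 3 hit genes, set size ≤ 1000;
  Bonferroni within annotation category.

## Responsiveness preprocessing

Per-strain S-scores are approximately standard normal under the
no-response null; per strain the two-sided normal p is combined across the
panel with Fisher's method (df = 2 × strains).  The permutation empirical
p (default 1,000 permutations) shuffles S-scores across probesets
independently within each strain, which preserves every strain's score
distribution while breaking probeset identity.  A sign-flip null is *not*
usable here: the two-sided per-strain p depends on |S| only, so flipping
signs never changes the statistic.  The within-strain shuffle is
calibrated on null panels (empirical p uniform) and is slightly
conservative when a large fraction of probesets is truly responsive, since
their scores enter the permutation pool.  Empirical p uses (b+1)/(B+1);
q is Benjamini–Hochberg within region, and a probeset is responsive if
q < 0.1 in *any* region.

Probesets collapse to one per gene by maximum mean RMA over all strains of
the region, control and treatment pooled (the pooling is this package's
reading of "region-specific maximum"); ties go to the smallest probeset
id.  Homolog mapping drops unmapped genes; colliding sources resolve to
the higher mean RMA.  The background network is the PPI induced on
PPI ∩ GWAS ∩ expression genes with isolated nodes removed — a degree-0
gene can never join an edge-weighted module.

## Synthetic data: what it emulates and what it does not

The generator mirrors the reference study conditions: a ~30-strain
two-condition panel (defaults 30+30), a scale-free PPI (Barabási–Albert,
3 edges per new node, 2,000 genes) with a planted 50-gene connected
subgraph densified to edge density 0.25, GWAS p-values Beta(0.1, 1) on
planted genes and uniform elsewhere, a planted correlation shift
delta_rho = 0.6 on top of a baseline correlation 0.1 via a latent factor
loaded only in the treatment condition (guaranteeing a valid covariance
for any admissible target), probe-level S-scores N(3, 1) for planted-gene
probesets versus N(0, 1) otherwise, two probesets per gene, and a
validation GWAS whose signal covers half the planted set.  Baseline
correlation, planted density, and per-gene RMA baselines (N(8, 1)) are
this package's realism choices where no external value existed.  Gene
symbols are synthetic (`G000001`…) with an identity homolog map so the
mapping code path runs unchanged.

Not emulated: probe-level microarray intensities, eQTL structure, SNP LD,
region-to-region expression differences, and — deliberately — responsive
background genes: only planted genes carry S-score signal, so after the
q < 0.1 filter the end-to-end pipeline's background collapses to roughly
the planted set.  The full pipeline therefore exercises the plumbing and
the null behavior, while the statistical properties of the search
(recovery, calibration, regression direction) are studied at the network
level without the probe filter.  Passing tests show the machinery is
correct and calibrated on data with these simplifications; they do not
show that real microarray noise, annotation error, or PPI ascertainment
bias are handled.

## Problem sizes and numerics

The test suite and acceptance script use 300–2,000-gene networks,
200–1,000 permutations, and 10–20 seeded replicates — sizes at which every
claimed property is measurable with comfortable Monte-Carlo margins on a
single CPU.  All randomness flows from one seed through named substreams
(`_sampling.spawn_rng`); reruns are bit-identical.  Degenerate inputs
fail loudly: empty p-value lists, p outside (0, 1], fewer than 4 strains
per condition, zero-variance weight populations, edgeless mega-modules,
empty universe intersections.

## Known limitations

* The analytic standardization ignores without-replacement corrections
  and weight dependence among edges sharing a gene; the Monte-Carlo mode
  and the connected null quantify both effects (small at these sizes).
* Greedy search returns one module per seed and no global optimum
  guarantee; heavily overlapping output is expected and handled by the
  merge stage.
* Neighbor distance d > 1 admits candidates without forcing connecting
  paths, so modules can become disconnected; the default d = 1 never does.
* The merge stage is O(M²) in the number of significant modules per pass;
  tens of thousands of modules would need a sparser overlap index.
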