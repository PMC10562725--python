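# Methods

## Model and procedure

`persimod` treats an undirected PPI network G = (V, E) as the 1-skeleton of
a simplicial complex K: genes are 0-simplices, interactions 1-simplices,
and every (k+1)-clique a k-simplex (the flag, or clique, complex). Each
GWAS hit gene v carries an association p-value p(v); the δ-sublevel complex

    W_δ = { σ = [v₀,…,v_k] ∈ K : p(vᵢ) ≤ δ for all i }

grows with δ and forms a filtration. Equivalently, every simplex enters at
the maximum value of its vertices (lower-star / vertex-function
convention): this is the unique rule for which the sublevel sets of the
vertex function are exactly the induced clique complexes, so filtering the
graph and filtering the complex commute. Non-edges of the PPI network never
enter at any threshold — there is no Rips-style completion between
non-interacting proteins.

Homology is computed with ℤ/2ℤ coefficients by left-to-right column
reduction of the boundary matrix in filtration order. Ties in the order are
broken deterministically by (value, dimension, lexicographic vertex tuple),
so diagrams, pairings and representatives are identical across runs and
platforms. Alongside the reduced matrix R we maintain the basis-change
matrix V (R = D·V): a finite pair's representative cycle is the destroyer's
reduced boundary column (its pivot is the birth simplex, so the
representative's maximum filtration value equals the birth), and an
essential class's representative is the creator's V-column. In dimension 1
the V-column of a creator edge is precisely the unique cycle formed by that
edge plus the union-find forest path between its endpoints — a tight,
geometrically meaningful loop, with no extra cycle-minimization step.

### Zero-persistence bars

Under the max-vertex convention an edge between a newly appearing vertex
and an older one enters at the new vertex's own value, so almost every
vertex is absorbed into an older component the instant it is born. These
birth-equals-death pairs carry no topological information and are dropped
by default (`keep_zero_bars` retains them); with them dropped, the dim-0
diagram consists of the genuinely separate components (essential bars) plus
the occasional positive bar where two existing components are merged later
by a connector gene. Betti curves use the half-open convention
(birth ≤ δ < death) and are unaffected by the zero-bar choice.

### Truncation dimension

A simplex stream truncated at dimension `maxdim` decides homology reliably
in dimensions 0..maxdim−1: a creator of dimension maxdim might be killed by
an absent (maxdim+1)-cell, so those creators are discarded rather than
reported as essential. The CLI default is maxdim = 3 so that the absence of
2-dimensional holes is a checkable statement; the library default for
loop-level analyses is maxdim = 2.

### Log-scale p-values

All filtration values are carried as log₁₀ p, never raw p, because
published GWAS meta-analysis p-values reach ~1e-695 and underflow IEEE
doubles. `parse_pvalue` splits mantissa and exponent textually
(`decimal.Decimal`), giving log₁₀ p exact to ~1e-15 relative error at any
magnitude. Persistence pairings are invariant under any strictly increasing
transform of the vertex values, so the log-scale choice cannot change which
classes exist or persist — this invariance is asserted by a dedicated
property test and the acceptance battery.

## Persistent disease modules

The n-th persistent disease module is the union of the n-dimensional holes
that persist over all thresholds. For n = 0 this is defined as the largest
connected component of the hit-induced subnetwork: every final component is
formally essential, but the small ones are excluded by convention, matching
the classical observable-disease-module definition. For n ≥ 1 the module is
the union of representative cycles of the essential classes. Homology
representatives are not unique; the deterministic reduction order fixes
them reproducibly, and the module metadata records this caveat.

## Degree-preserving null

Significance is assessed by resampling node sets that match the hit genes'
degree profile. Nodes are partitioned into geometric base-2 degree bins
[1], [2,3], [4,7], …; bins holding fewer than `min_bin_size` nodes
(default 10) are merged with the next lower bin, because exact-degree
matching is infeasible for hubs whose degrees are unique. Per repetition,
the sampler draws without replacement, per bin, as many nodes as the seed
set holds there, then assigns filtration values. The default assignment
permutes the observed log₁₀-p multiset onto the sampled nodes, preserving
the p-value spectrum while randomizing topology; a "threshold" mode (all
nodes at the significance cutoff) is available behind a flag. The network
itself is never rewired — randomization is over node selection, matching
the hypothesis that the observed genes occupy a topologically special
position.

The z-score is (observed − mean)/σ with the population standard deviation
of the null sample. The empirical p-value is add-one smoothed and
right-tailed, (1 + #{samples ≥ observed})/(1 + n_reps), so it can never be
exactly 0 at finite repetitions; larger-than-chance modules are the
one-sided hypothesis. The default is 1,000 repetitions.

Because module sizes are integers, the empirical p is discrete and
(with ties) conservative; on small networks its distribution under the
null is slightly sub-uniform. The calibration check (below) uses a 60-seed
profile on a 300-node network, where the statistic spreads over enough
values that a Kolmogorov–Smirnov test at α = 0.01 does not detect the
discreteness, but individual reruns of the calibration at other seeds can
produce KS p-values near that boundary. This is a property of add-one
empirical p-values on discrete statistics, not a defect of the sampler.

## Enrichment

Over-representation of a module's genes against user-supplied GMT
collections uses the hypergeometric upper tail P(X ≥ k) with parameters
(N = universe, K = term∩universe, n = query), Benjamini–Hochberg adjusted
across terms (significance at adjusted p < 0.05). The natural universe is
the full set of PPI network genes — the background from which a module is
drawn — and is configurable. No live database queries are made; users
supply GMT snapshots, keeping results reproducible and offline.

## Synthetic studies

The generator emulates the features of real inputs that the pipeline is
sensitive to, with ground-truth manifests:

- **Scale-free topology.** Preferential-attachment growth from an initial
  complete graph on m+1 nodes; each later node attaches to m distinct
  existing nodes with probability proportional to degree, giving
  C(m+1,2) + (n−m−1)·m edges, a connected graph and a heavy-tailed degree
  distribution, as in consolidated human interactomes.
- **Planted chordless cycles.** Fresh L-cycles (L ≥ 4) attached to the
  network by a single bridge edge. Single-bridge attachment keeps each
  cycle chordless (no triangle fill-in) and adds no new loop, so each
  planted cycle contributes exactly one essential 1-dimensional class and
  its recovery can be asserted exactly.
- **Planted connected component.** A breadth-first ball of existing nodes
  marked as hits — ground truth for LCC detection.
- **Hit p-values.** Uniform in log₁₀ space on [−100, log₁₀ 5×10⁻⁸] by
  default, reflecting the many-orders-of-magnitude spread of real
  association p-values; jittered to distinctness. Background hits default
  to ~4% of nodes, sparse enough that spurious loops rarely touch planted
  ones.

Default study conditions (n = 250, m = 2, cycles 4–6, 20-node component,
10 background hits) are small enough that the full pipeline runs in
milliseconds yet large enough that nontrivial background topology occurs.
What passing synthetic tests does **not** show: real interactomes have
higher clustering, community structure and ascertainment biases than
preferential-attachment graphs, and real GWAS mapping noise (multi-gene
loci, LD) is only modeled through the mapping rules, not simulated at the
variant level.

## Validation protocol and problem sizes

The acceptance battery (tests/test_acceptance.py, recomputed by
scripts/acceptance.py) runs at desk scale:

1. reduction-vs-oracle Betti equality on 200 random filtered clique
   complexes (≤ 14 nodes, maxdim 3) at every filtration value, against a
   dense GF(2) Gaussian-elimination oracle that shares no code with the
   reduction;
2. exact planted-cycle recovery on 20 scale-free studies (n = 200–300,
   k ∈ 1..5 cycles of lengths 4–7);
3. monotone-transform invariance of the pairing on 50 instances;
4. dim-0 consistency (essential count = component count; module = LCC) on
   100 instances;
5. null calibration: 200 replicates of seed sets drawn from the null
   itself (n_reps = 100), KS uniformity at α = 0.01;
6. closed-form checks of the hypergeometric tail, BH, z and empirical-p
   formulas against exhaustive enumeration and hand arithmetic.

The dense oracle is guarded at ~5,000 simplices; beyond that the reduction
algorithm is the only supported path.

## Numerical choices and degenerate inputs

- The +∞ death of essential classes is `math.inf` in memory and the string
  `"inf"` in CSV output; no large sentinel numbers appear anywhere.
- Sparse reduction columns are Python sets with symmetric-difference
  updates; the complexity is adequate for hit sets of a few hundred genes
  (the intended regime), not for whole-interactome filtrations.
- Empty hit tables, hit genes absent from the network, and empty modules
  are all legal and produce empty outputs with informative logs rather than
  errors.
- LCC ties are broken by the lexicographically smallest member node;
  simplex-order ties by (value, dim, lexicographic tuple); both choices are
  arbitrary but fixed, and recorded here.

## Known limitations

- Representative cycles (and hence dim ≥ 1 module composition) depend on
  the filtration order; other valid orders can select homologous but
  different cycles.
- Degree preservation is binned, not exact; hub seeds are matched to other
  high-degree nodes, not to equal-degree nodes.
- Gene symbols are matched case-sensitively after whitespace trimming, with
  no alias resolution; catalog multi-gene fields are split on commas and
  " - ", and the at-most-two-genes locus rule is applied to the resulting
  distinct list.
- Weighted-edge filtrations, multiparameter persistence, seed-expanding
  module detection and variant-level genetics are out of scope.
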