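# Methods

## The biclustering model

Given a real-valued matrix A over rows X and columns Y (amplitude
Ā = max − min over observed cells), a bicluster B = (I, J) with coherency
across rows follows `a_ij = k_j + γ_i + η_ij`: a column-wise expected value
`k_j` (the pattern φ), a per-row adjustment `γ_i`, and noise
`η_ij ∈ [−δ/2, δ/2]`. The coherency strength δ is not stored; it is implied
by the discretization alphabet, δ = Ā/|L|, and reported as a derived field
(`SymbolicDataset.coherency_strength`). Coherency across columns is the
same model on the transposed matrix (`orientation="columns"`).

The five coherency assumptions differ in the per-row term: none (constant),
integer shift (additive), rational scale (multiplicative), sign
(symmetric), or a shared ordering of the columns by value
(order-preserving). The plaid assumption (cumulative overlap effects) is
deliberately not implemented; requesting it raises `NotImplementedError`.

## Mapping stage

The pipeline is fixed: normalize → discretize → noise handler →
uninformative-element removal.

* **Normalization** (default: per row) standardizes observed values to mean
  0, sd 1; zero-variance units map to all zeros and missing cells pass
  through.
* **Discretization** (default: Gaussian) places the |L|−1 interior cutoffs
  at the k/|L| quantiles of a normal fitted to *all* observed values by
  sample mean/sd. The overall fit (rather than per-row fits) is chosen
  because the default row normalization already makes rows comparable; on
  normal data it yields approximately balanced symbol frequencies. The
  alternative `fixed_range` uses equal-width bins over mean ± 3 sd with
  outliers clamped into the end bins (the ±3 sd rule is this package's
  concrete choice of outlier exclusion). `none` accepts data already coded
  as alphabet integers.
* **Alphabets**: non-symmetric {0…|L|−1}; symmetric odd
  {−(|L|−1)/2 … +(|L|−1)/2}; symmetric even omits 0 so that multiplicative
  scales remain closed over the symbol set. Consistency rules: additive
  models with symmetries need odd |L|, multiplicative ones even |L|.
  Symmetries default to "dynamic": enabled exactly when the input contains
  negative values.
* **Multi-item noise handler** (default: off, boundary fraction 0.25 when
  on): an element with value c in bin [a, b] also receives the adjacent
  bin's symbol on the near side iff min(b−c, c−a)/(b−a) < 0.25. Two edge
  policies are interpretation choices: (1) at the outermost boundaries of
  the alphabet no symbol is added (there is no adjacent bin); (2) because
  Gaussian bins are unbounded outward, the outer bin edges are taken as the
  observed data extremes so the relative-distance rule stays well defined
  in the end bins.
* **Missings**: `remove` (default) keeps missing cells item-free so they
  simply contribute no evidence; `replace` imputes by row mean with
  column-mean and overall-mean fallbacks — a deliberately simple imputer
  (activating the noise handler absorbs most imputation error). For
  network data `remove` is the meaningful option: absent edges are absent
  evidence, not zeros.
* **Uninformative elements**: `zero_entries` deletes the 0 symbol (weak
  interactions, unchanged expression); `differential` keeps the ⌊|L|/3⌋
  most extreme symbols at each end (e.g. {−3, −2, 2, 3} at |L| = 6).

## Transactions and mining

Rows become transactions of items `item = column_index·|L| + symbol_rank`,
so columns and symbols decode from items without side tables. Assumption
mappings:

* **additive** — one transaction variant per whole-row shift
  γ ∈ {−(|L|−1) … |L|−1} for which every cell keeps at least one shifted
  symbol inside L, tagged with γ. Enumerating in-alphabet shifts is
  equivalent, on noise-free data, to iteratively mining pattern
  differences, and is simpler to verify against oracles.
* **multiplicative** — variants per admissible rational scale; candidate
  scales are the ratios of the row's first nonzero symbol to each nonzero
  alphabet symbol, kept when every cell divides to an in-alphabet integer.
* **symmetric** — each row contributes itself (c = 1) and its sign-flipped
  copy (c = −1).
* **order-preserving** — each row becomes its column indexes sorted by
  primary symbol ascending, with equal-symbol columns in one tie group;
  |L| therefore balances co-occurrence (large groups at small |L|) against
  precedence information.

Miners: level-wise tid-list Apriori, vertical tidset DFS (Eclat),
FP-growth over an annotated prefix tree, prefix-preserving closure
extension over tidsets ("charm_tid"), a diffset-based vertical search with
a closure filter ("charm_diffsets"; the tidset and diffset encodings are
one engine contract and must produce identical closed sets), a maximal
filter on top ("charm_mfi"), and prefix-projected sequence search
(PrefixSpan; "indexspan" adds an item-frequency index prune) with a
closed-sequence filter ("bide"). Internals are deliberately conventional:
the contract, enforced by the test suite, is exact agreement with
brute-force lattice/subsequence enumeration on hundreds of seeded random
databases. Patterns assigning two symbols to one column (possible under
multi-items) are discarded at emission, since a bicluster has one expected
value per column. Output order is descending support, then lexicographic —
results are deterministic.

Sequence containment is defined over tie groups: pattern items map to
non-decreasing group positions, so two columns tied in a row support
either relative order. Closedness for sequences means no frequent proper
supersequence (flat-subsequence relation) with an identical support set.

## Derivation and canonical forms

A mined pattern yields J (decoded columns), φ (decoded symbols), and
I = deduplicated originating rows of its supporting variants; patterns
narrower than `min_cols` (default 4; "auto" = ⌈√|Y|⌉) are dropped.
Shifted/scaled pattern copies describe the same submodule, so additive
patterns are canonicalized by shifting min(φ) onto the alphabet minimum
(a module over rows (6,5,6,5) and (2,1,2,1) reports φ = (1,0,1,0) with
γ = (5,1), not φ = (2,1,2,1) with γ = (4,0)), and multiplicative patterns
by dividing out the gcd of their entries; duplicate (I, J) pairs then
collapse. A row supporting a pattern through several variants keeps the
smallest |γ| (resp. scale closest to 1, sign +1).

Per-cell quality: a present cell is *noisy* when its symbol set misses the
model's expected value; for order-preserving biclusters a row's noisy count
is the minimum number of cells to drop to make its symbols non-decreasing
along φ (longest non-decreasing subsequence). `missing_fraction` and
`noisy_fraction` are these counts over |I|·|J|.

## Iterative search

Support starts at ⌈0.25·|X|⌉ and shrinks by the factor 0.75 (never less
than one row per step, floor 2) until the stopping criterion holds — the
schedule itself is a package design choice; the criteria are: minimum
number of biclusters found in the current iteration (default, 50), minimum
covered fraction of observed cells by the accumulated solution, or a target
support fraction. If the floor is reached first, the best-effort solution
is returned with a logged warning. Between iterations (default 2), 25% of
the covered cells — ranked by how many biclusters cover them, ties broken
by a seeded uniform draw — are masked to missing, forcing later iterations
onto new regions. The bicluster count is evaluated per iteration because
each iteration is a fresh search of the masked data; coverage is a
whole-solution property and is evaluated globally.

## Closing

* **Merging** (default: heuristic): pairs whose shared elements reach the
  overlap threshold (by default the quality level, 0.8) relative to the
  *smaller* pair member are fused into the union. The min-denominator means
  a sub-bicluster always overlaps its superset at 100% and is absorbed —
  equivalent to filtering it. The heuristic sweeps pairs in size order to a
  fixpoint; the combinatorial option re-examines all pairs exhaustively
  ("multi_support_fim" is an alias of the combinatorial closure). When the
  symbolic data is available, a fusion is vetoed if the merged bicluster's
  noisy or missing fraction would exceed 1 − quality.
* **Filtering** (after merging; default: 40% dissimilar elements):
  processing in size-descending order, a bicluster is removed iff it shares
  more than 1 − min_dissimilar of its own elements (or rows/columns) with a
  strictly larger retained bicluster — above 60% shared at the default,
  above 80% at the 20% setting.
* **Extension/reduction**: greedy row-then-column growth while the combined
  noisy + missing fraction stays within 1 − quality, then worst-first
  removal at a fixpoint. Candidate rows get the adjustment minimizing
  mismatches; candidate columns the majority base symbol.
* **Significance**: the annotated p-value is an explicit stand-in model —
  the binomial upper tail of observing ≥ |I| of |X| rows containing φ, with
  per-row probability the product of empirical column-wise symbol
  frequencies (independence across columns, adjustments ignored);
  order-preserving modules use a uniform-orderings null, 1/|J|!. The
  output labels it as a stand-in. No multiplicity correction is applied
  across the solution.

## Networks

A weighted network maps to a dataset with rows = source nodes and
columns = target nodes (one shared index when the node sets overlap,
disjoint axes for bipartite graphs); cells are edge weights and absent
edges are missing, stored sparsely so memory is proportional to the edge
count. Modules with up to (1 − quality) missing interactions pass
`module_quality_check` (the check takes the symbolic view of the network
dataset, which is where noisy/missing fractions are defined). Negative
interaction weights trigger the dynamic symmetric alphabet automatically.

## Synthetic data

The generator plants blocks following the coherency model in symbol space:
background cells are uniform over the alphabet (or standard normal for
discretization tests), block cells are `k_j` plus the assumption's per-row
term plus `noise_rate · U(−δ/2, δ/2)` with δ = one symbol width, and
`missing_rate` of block cells (an exact count) are masked. Defaults follow
the study conditions used throughout the tests: 100×30 matrices, |L| = 5,
one planted 25×8 block, noise and missing 0; networks use 500 nodes at 1%
background density with a 20×20 module.

Two generator choices matter for interpretation. First, planted patterns
are canonical (additive: min k_j at the alphabet minimum; multiplicative:
gcd 1), so recovered adjustments are comparable to planted ones. Second,
because additive/multiplicative variant enumeration shifts or scales
*whole rows*, the off-block cells of planted rows are drawn from the subset
of symbols that keeps the planted shift/scale admissible for the row. Real
expression data has no such guarantee: a row whose full dynamic range spans
the alphabet admits only the identity shift, hiding additive submodules.
Passing recovery tests therefore demonstrate correctness of the
mapping–mining–derivation chain under the model's own assumptions, not
robustness to arbitrary row contexts; the noise-degradation tests (recovery
non-increasing over noise rates 0/0.1/0.2) probe the realistic regime. The
generator also does not emulate count-distribution features of sequencing
data (negative binomial dispersion, library-size effects).

For the sparse-network recovery setting (20% missing interactions), the
closed-pattern stage can only return fragments — with 20 columns each
present with probability 0.8, the expected number of columns shared by all
20 module rows is 20·0.8²⁰ ≈ 0.2 — so the module is reassembled by greedy
extension at quality 0.8; the test asserts a best-match element-Jaccard of
at least 0.5 plus a passing quality check, which is what the noise-tolerant
pipeline can guarantee there, rather than exact recovery.

## Numerical and scale choices

Problem sizes in the test suite (≤ 100×30 matrices, 500-node networks,
8-transaction oracle databases repeated 200×) were chosen so the full suite
completes in well under a minute while still exercising every
miner/assumption pair against exhaustive enumeration. Tolerances: exact
integer equality wherever the model is discrete (patterns, adjustments,
thresholds); 1e−9 for floating-point moments; quality comparisons use a
1e−12 slack to keep boundary cases (e.g. exactly 20% missing at quality
0.8) inside the tolerance. Degenerate inputs: all-equal data discretizes to
a single symbol; zero-variance normalization units map to zeros; fully
missing datasets are rejected where an operation needs values. p-values
are clipped into (0, 1] at the smallest positive float.

## Known limitations

* Additive/multiplicative variant enumeration is whole-row; see above.
* The combinatorial merge strategy differs from the heuristic only in
  candidate ordering at ties; both run to a fixpoint.
* The significance model ignores per-row adjustments and column
  dependence, and assumes rows i.i.d.; relative to a fixed-column-margin
  permutation null its tail is conservative (larger p-values). It is a
  ranking aid, not calibrated inference.
* Order-preserving noise accounting is row-wise (longest non-decreasing
  subsequence), which is one of several defensible conventions.
* No data-partitioning mode for matrices beyond ~10⁶ cells; searches are
  exact and single-threaded.
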