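# Methods

## Model

A mutation tree `T` is a rooted tree whose nodes are the mutations; under
the infinite sites assumption, ancestry in `T` implies containment of cell
populations. For sample `p` and mutation `i`, let `f[p,i]` be the fraction
of cells carrying `i`. Validity of `T` is expressed by the sum condition

    (SC)   f[p,i] >= Σ_{j ∈ children(i)} f[p,j]   for all p, i,

with all `f[p,i] ∈ [0,1]`. Variant reads are binomial,
`a[p,i] ~ Bin(d[p,i], f[p,i])`, so the tree log-likelihood is

    L(A,D | T) = max_{F ⊨ (SC)} Σ_{p,i} [ a log f + (d−a) log(1−f) ],

dropping binomial coefficients (constant in `F` and `T`). Heterozygous
diploid variant allele frequencies would introduce a factor 1/2; inputs
are assumed already converted to cell fractions.

The ρ-solution space `T(ρ)`, for ρ ∈ [0,1], is the set of trees `T` with
`L(T) ≥ L(T_max) + ln ρ` (log domain). The backbone of `T` on a subset `S`
is the projection `T[S]`: each node of `S` is attached to its nearest
strict ancestor inside `S`; nodes with no such ancestor become roots of a
backbone forest.

## Likelihood fitter

The inner maximization is concave and separable across samples. We
reparameterize by clone fractions `u`: with `M[i,j] = 1` iff `i` is an
ancestor of or equal to `j`, setting `f = M u` makes (SC) equivalent to
`u ≥ 0`, `Σ u ≤ 1` per sample. For each sample whose naive frequencies
`f̂ = a/d` already satisfy (SC) the optimum is `F = f̂` (closed form). Only
violating samples are solved numerically, with SciPy's SLSQP on the
negated log-likelihood in `u`-space (box bounds `[0,1]`, one linear
inequality), warm-started from `u0 = clip(f̂ − Σ_children f̂, 1e-4, ∞)`
rescaled onto the simplex. Frequencies are clamped away from {0,1} by
1e-9 inside the objective to keep logs finite.

SLSQP exit status 8 ("positive directional derivative for linesearch")
occurs occasionally near the optimum; fits returning it agree with
multi-start references to ~1e-7 in log-likelihood, so statuses {0, 8} are
treated as converged. Any other status triggers one deterministic retry
from the uniform interior point. This substitutes a dependency-free SciPy
solver for a general-purpose convex-programming library; accuracy was
checked against exhaustive multi-start optimization on random instances.

Likelihood comparisons (ρ-cuts, ties) use an absolute log-domain slack of
1e-6 to absorb solver tolerance.

For a single sample and a chain (path) tree, the fit reduces to weighted
antitonic regression of `f̂` along the chain; the solver is cross-checked
against pool-adjacent-violators isotonic regression in the test suite.

## Enumeration

Mutations are ordered by decreasing `Σ_p f̂[p,i]` (ties keep input column
order). The ℓ-constrained enumeration processes the length-ℓ prefix
incrementally: each retained backbone on the first k−1 mutations is
expanded by inserting mutation k, candidates are deduplicated, fitted, and
those within `ln ρ` of the round's best are retained. Two expansion
operators are available: `small` (new root, new leaf under each node, or
splitting each edge; `2k` candidates per tree) and `big` (additionally the
new node may adopt any subset of an attachment point's children;
`1 + Σ_j 2^{|children(j)|}` candidates). The τ-constrained variant runs
the same sweep and stops before the round whose retained count would
exceed τ. Beam search retains the top `w` trees by likelihood each round
(ties broken by a canonical string key) and returns full-size trees.

## Brute-force oracle

For n ≤ 8 mutations, all `n^(n−1)` rooted labeled trees are generated via
Prüfer sequences. To avoid fitting every tree, each tree gets an upper
bound `L(F̂) − Σ gains` over a greedy vertex-disjoint matching of its
edges, where `gain(i,j)` is the closed-form binomial loss of pooling the
constraint `f_i ≥ f_j` (pooled rate `(a_i+a_j)/(d_i+d_j)` where violated).
Trees are fitted in decreasing bound order and the scan stops once the
bound falls below `best + ln ρ − slack`; this prune is exact (it is
verified against a prune-free exhaustive fit in the tests). Optimal
subsets for a given ℓ (or budget τ) are found by scanning all
`C(n, ℓ)` subsets of the projected space.

## Simulation

`simulate_instance(SimulationConfig(n, m, depth_mean, dirichlet_alpha,
seed))`:

1. truth tree uniform over all `n^(n−1)` rooted labeled trees (uniform
   Prüfer sequence + uniform root);
2. clone fractions `U`: one symmetric Dirichlet(α) draw of length n+1 per
   sample (the extra coordinate is the mutation-free population), so
   frequencies `F = U Mᵀ` satisfy (SC) exactly and the root has `f = 1`;
3. depths `D ~ Poisson(depth_mean)` i.i.d.;
4. reads `A ~ Binomial(D, F)`.

Defaults: `depth_mean = 100`, `dirichlet_alpha = 1` (uniform on the
simplex; exposed as a parameter since there is no canonical choice). A
single seeded NumPy generator is consumed in the fixed order tree → U →
D → A, so instances are reproducible per seed. The generator has no
copy-number events, no sequencing-error model beyond binomial sampling,
and no clustered mutations (clusters enter only through input
aggregation).

## Distances and recall

For trees on the same node set, with `anc(i)` the reflexive ancestor set:

* **PC** — Jaccard distance of directed edge sets.
* **AD** — Jaccard distance of strict ancestor–descendant pair sets.
* **CASet** — mean over unordered pairs `{i,j}` of the Jaccard distance of
  the common-ancestor sets `anc(i) ∩ anc(j)` (two empty sets count as
  distance 0).
* **DISC** — mean over ordered pairs `(i,j)` of the Jaccard distance of
  the distinguishing sets `anc(i) \ anc(j)`.

PC and AD extend to backbone forests; CASet and DISC require trees with at
least two nodes. Backbone recall of an inferred set against an oracle
space is the fraction of distinct projections `T[S]`, over trees of the
space, that appear in the inferred set.

## Cluster aggregation

Given a mutation→cluster map, each cluster's per-sample depth is the
median member depth (half-up rounding) and its variant count is that depth
times the mean member naive frequency, rounded half-up and capped at the
depth.

## Study design in `scripts/acceptance.py` and the acceptance tests

Problem sizes were chosen so the brute-force oracle is exact yet fast:
20 instances with n=6 (6⁵ = 7,776 trees per space), m=2, depth mean 100,
α=1, ρ=0.9. Reported quantities are the medians of the per-instance
approximation ratios (heuristic vs brute force) for ℓ ∈ 2..6 and
τ ∈ {1,2,5}. The statistical tests additionally check backbone recall
against oracle projections on fresh instances and beam-search recovery of
the truth tree at depth 10⁴ (n=8, m=5, width 10); a recovery counts any
tree tied for the top likelihood within the 1e-6 slack, because exact ties
make the top-1 ordering an artifact of the deterministic tie-break.

## Limitations

* The oracle is exponential; it is capped at n ≤ 8.
* SLSQP is a local solver; the problem is concave so local = global, but
  convergence is to tolerance ~1e-8, absorbed by the 1e-6 likelihood
  slack.
* No copy-number correction: inputs must already be cell fractions.
* Heuristics carry no optimality guarantee; near-optimality is only
  demonstrated empirically at small n where the oracle applies.
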