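# Methods

## Model

The clustering model is standard fuzzy c-means (FCM).  Data X = {x_1 … x_n}
⊂ R^p are partitioned among c prototypes V = (v_1 … v_c) by minimising

    J(X; U, V) = Σ_{k=1..n} Σ_{i=1..c} u_ik^m · D_ik²,
    D_ik² = (x_k − v_i)ᵀ(x_k − v_i),

over membership matrices U = [u_ik] with u_ik ∈ [0, 1], Σ_i u_ik = 1 per
sample, and 0 < Σ_k u_ik < n per cluster.  The fuzzifier m ∈ (1, ∞)
controls membership softness; m → 1 approaches hard k-means, large m
flattens memberships.  For fixed V the optimal memberships are

    u_ik = 1 / Σ_j (D_ik²/D_jk²)^{1/(m−1)}     (all D_jk² > 0),

and when a sample coincides with one or more centers (I_k = {i : D_ik = 0}
non-empty) the entire unit mass is placed on I_k, split uniformly when
|I_k| > 1 — uniformity is our tie-break; only the sum is constrained by the
model.  A squared distance at or below 1e-12 is routed through this
degenerate branch rather than the power law, which would otherwise overflow
for m close to 1; above the guard, ratios are normalised by the column
minimum before exponentiation, so no intermediate can overflow for any
m > 1.

Because the objective is additive over samples, `partitioned_objective`
evaluates J in contiguous row chunks and sums the partial values — the
single-process equivalent of a map/reduce fitness evaluation.  Equality
with the monolithic value is exact up to floating-point summation order;
tests allow 1e-9 relative.

## Local baseline: alternating optimisation

`fcm_refine` / `FuzzyCMeans` implement classic FCM: alternate the
membership update above with the weighted-mean center update
v_i = Σ_k u_ik^m x_k / Σ_k u_ik^m until |ΔJ| < tol (default 1e-9) or
max_iter (default 100) sweeps.  Each half-step minimises J exactly in one
block of variables, so the J trajectory is non-increasing; the suite
asserts this to 1e-12 per step.  A cluster whose fuzzy mass underflows to
zero is re-seeded from a random data point and the event logged.

## The immune evolutionary optimiser

`MIEAClustering` / `run_miea` search prototype space globally.  A
chromosome is the row-major flattening of V (length l = c·p); fitness is
f = 1/(J + 1), a strictly decreasing bijection from J ∈ [0, ∞) onto (0, 1],
where J is evaluated with the exact membership update above (centers are
never updated by the FCM formula inside the evolutionary loop — they come
from chromosomes only).  Per generation:

1. fitness-proportionate (roulette) or linear-rank selection, with
   replacement, of pop_size parents;
2. pairwise crossover with probability p_c (one-point tail swap by default;
   two-point and uniform variants available);
3. per-gene mutation with probability p_m: the gene is re-drawn uniformly
   within its feature's observed [min, max].  Bit inversion has no
   real-coded meaning, so "reversal" of a gene is realised as re-randomisation;
   an order-only segment-reversal operator is available behind
   `mutation_op="segment_reversal"`;
4. vaccination: with per-individual probability p_v, overwrite the
   offspring's genes at the vaccine positions with the elite's values, then
   accept the result only if fitness did not drop (immune selection, greedy
   — its antecedents use annealing acceptance; greedy satisfies the same
   anti-degradation goal and is deterministic, hence testable);
5. elitism: the elite re-enters unchanged, replacing the worst individual,
   making the elite objective history monotone non-increasing.

The vaccine holds ⌈vaccine_fraction · l⌉ distinct gene positions sampled
uniformly from the elite; it is re-extracted whenever the elite improves,
and otherwise refreshed with per-generation probability p_u so a stagnant
elite still donates varying fragments.

All randomness flows from one `random_state` through a single numpy
Generator; identical inputs and seed give bit-identical results.

### Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| m (fuzzifier) | 2.0 | conventional operating point |
| pop_size | 30 | enough diversity for c·p ≤ ~20 genes at low cost |
| p_c | 0.95 | top of the customary [0.75, 0.95] crossover band |
| p_m | 1e-2 | top of the customary [1e-3, 1e-2] per-gene band; center chromosomes are short (l = c·p, often < 10), so lower rates leave most offspring without any new gene material and the search cannot refine centers within a realistic generation budget |
| p_v | 0.3 | vaccination probability per offspring |
| p_u | 0.5 | vaccine refresh probability when the elite is unchanged |
| vaccine_fraction | 0.25 | elite genes donated per vaccine |
| tau / patience | 0 / 10 | stall stop: quit once \|ΔJ_elite\| < tau for `patience` consecutive generations.  Default tau = 0 disables it: elite improvements arrive in bursts separated by long gaps (tens of generations under weak fitness-proportionate pressure — f = 1/(J+1) compresses ratios toward 1 when J is large), so any positive default truncates runs mid-descent.  Early stopping is opt-in. |
| max_gens | 100 | default generation budget |

`1 ≤ c ≤ n − 1` is enforced; all genes stay inside their feature's observed
range under every operator (closure property, tested).

## Synthetic data

`generate_mixture` draws labelled isotropic Gaussian mixtures: per-cluster
means, standard deviations (zero allowed — the separable limit), mixing
weights, and optionally appended uniform[0, 1] noise features that carry no
class signal (for feature-weighting tests).  Per-cluster counts follow the
weights deterministically by largest-remainder apportionment (rows then
shuffled), so small-n fixtures are exact: n = c with uniform weights yields
one copy of each mean.  The generator emulates the geometry the estimators
are tested on — compact isotropic clusters with controllable overlap — and
deliberately not the features of real clinical tables: correlated or
discrete attributes, class imbalance beyond the mixing weights, outliers,
or informative missingness.  Passing tests therefore demonstrate correct
mechanics and recovery under the stated geometry, not performance on any
particular clinical dataset.

Study fixtures used throughout tests and the acceptance script, chosen as
representative desk-scale conditions: a tight 3-cluster mixture (means
(0,0), (5,5), (0,5), σ = 0.2, n = 300) for parameter recovery; an
overlapping 4-cluster mixture (corners of a 6×6 square, σ = 1.0, n = 400)
for the optimiser comparison; a 1-D two-class separation (means 0 and 3,
σ = 0.3) plus one pure-noise feature, n = 600, for Relief.

## Relief feature weighting

Classic Relief: sample an instance R (without replacement when the sample
budget allows), find its nearest hit (same class) and nearest miss (other
class) by Euclidean distance over all min-max-scaled features, and update
each feature's weight by diff(d, R, miss) − diff(d, R, hit) with diff the
absolute scaled difference; weights are averaged over the sampled
instances, so they lie in [−1, 1].  Because the score depends on the
sample, 20 independent runs (seeds base_seed + r) are averaged before
pruning by threshold (remove w < t) or bottom-k (remove the k smallest,
ties dropping the lower index first).  Requires ≥ 2 classes with ≥ 2
members each.  The binary hit/miss formulation is intentional; multi-class
generalisations (ReliefF) are out of scope.

## External validation

`contingency` cross-tabulates reference classes i against produced clusters
j.  Per pair, recall r = n_ij/n_i and precision p = n_ij/n_j combine into
F(i,j) = 2rp/(r+p) (0 when both are 0); the dataset score is the
class-size-weighted best per-class value, F = Σ_i (n_i/n)·max_j F(i,j),
bounded by 1.  Majority-mapping accuracy assigns each cluster its most
frequent class: Σ_j max_i n_ij / n.  Fuzzy partitions are hardened by
argmax over membership columns (lowest index on ties) before evaluation.
Empty clusters are skipped in the per-class maxima.  ARI/NMI are exposed
only as auxiliary cross-checks.

## Numerical and design notes

* Min-max scaling maps constant features to 0 and returns the (min, max)
  pair per feature so prototypes can be mapped back to original units.
* Missing values: the `?` marker; policy explicit (`drop_row` default, or
  `mean_impute`); a non-`?` unparseable cell is an error naming row and
  column.  Class labels are re-coded to contiguous integers in
  first-appearance order for stable contingency tables.
* Chunked evaluation uses contiguous row blocks; membership columns depend
  only on their own sample, so chunking is exact up to summation order.

## Known limitations

* The evolutionary search samples center space; it has no local gradient
  step.  It therefore approaches, but does not attain, the precision of a
  converged alternating-optimisation run: on landscapes where single-start
  FCM reliably reaches the global basin, fully converged FCM ends with a
  slightly lower J (a few percent at 100 generations, fractions of a
  percent with long budgets), while the evolutionary search's value is the
  better choice only when local descent gets trapped.  Equivalently, on a
  zero-spread (separable) mixture the optimiser recovers the label
  partition perfectly but does not drive J below ~1 in data units, whereas
  FCM reaches the degenerate optimum J ≈ 0 exactly.  A Lamarckian hybrid
  (periodic FCM refinement of the elite) would remove this gap but is
  deliberately not part of the algorithm, whose centers come from
  chromosomes only.
* Fitness-proportionate selection on f = 1/(J+1) loses pressure as J grows
  with n (all fitness values crowd toward 0); rank selection is provided
  and preferable for large datasets.
* c is fixed a priori; there is no automatic model selection, no
  possibilistic or kernelised variants, and no distributed execution — the
  chunked objective is a single-process equivalence demonstration.
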