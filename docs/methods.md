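# Methods

This note documents the model, the numerical and design choices, and what
the synthetic benchmark does and does not establish.

## Proximity measure

The node association used throughout is, for ordered pair (i, j), i ≠ j,

    prox(i, j) = A_ij + Σ_k  A_ik/(W_i − A_ij) · A_kj/W_k · min(A_ik, A_kj),

with W_i the total outgoing weight of i and k ranging over common
neighbours. Assumptions built into this form:

* Direct links transfer evidence in full; indirect influence is
  probabilistic, so a two-step path is discounted by the product of the two
  step probabilities. The i-side probability excludes the direct i→j link
  from the normalisation (a node deciding how to reach j "spends" its
  remaining outgoing weight).
* The min(A_ik, A_kj) factor caps an indirect path's contribution by its
  weaker step, so one heavy link cannot compensate for a feeble one.
* The measure is local (radius two). It is cheap — the implementation
  accumulates, for each common neighbour k, an outer product over k's in-
  and out-neighbours, then applies the pair-dependent denominator once —
  but it cannot see structure beyond shared neighbourhoods.

The measure is **not symmetric** on undirected networks: the denominator
W_i − A_ij depends on the endpoint's strength, so prox(i, j) = prox(j, i)
only when strengths are equal (strength-regular graphs). Tests assert
symmetry exactly there; everywhere else both directions are kept and summed
where an undirected quantity is needed. Consequently the supernode network
of an undirected level is generally directed-valued; it is stored as
undirected only when the averaged matrix happens to be symmetric.

Degenerate inputs: a node with zero outgoing strength contributes no
outgoing proximity; pairs with neither a direct link nor a common neighbour
are not stored (sparse contract), so they never enter the z-score
population; whenever the indirect sum is non-empty the denominator is
provably positive (A_ik > 0 implies W_i ≥ A_ij + A_ik).

## z-score filtering

All stored proximities of a level are standardised with the population
(ddof = 0) mean and SD, and pairs with z below the threshold are dropped;
the keep rule is closed (z ≥ t) and the default threshold is 0. If the SD
is zero every pair is kept — discarding the whole of a uniform network is
never useful. Both directions of a directed network are pooled into one
population.

On an unweighted bottom level the population is strongly bimodal (direct
links near weight 1 versus faint indirect-only pairs), so any threshold in
roughly [−0.3, +2] reduces the graph to its direct links; on the weighted
abstract levels the distribution is continuous and the threshold bites
smoothly — which is why information loss from a high threshold shows up
first at the higher levels, ultimately as isolated supernodes (modules with
no surviving link, kept as flagged singletons).

## Backbone and partitioning

The backbone is a maximum-weight spanning forest (Kruskal on the
symmetrised filtered proximities) with fully deterministic tie-breaking:
weight descending, then lexicographic endpoints. Determinism here is what
makes whole-pyramid runs reproducible, and is the reason a ~30-line Kruskal
is used instead of networkx's (which breaks ties by insertion order);
networkx and exhaustive enumeration serve as test oracles.

Partitioning removes backbone links one at a time. A removal is admissible
only if the complete resulting module set satisfies, for every module pair,
S_intra(M_a) > S_inter(M_a, M_b) and S_intra(M_b) > S_inter(M_a, M_b),
where the sums run over ordered pairs of the *filtered proximity network*
(the tree only limits which splits are reachable). Because a module that
merely shrinks can only lose inter-module weight, only the two modules
created by a candidate cut need checking — against each other and against
every other current module — which keeps the check O(k) per candidate on
top of per-module prefix-sum tables (each candidate module is a contiguous
interval in DFS order, so all intra/inter sums come from 2-D and row-wise
prefix sums).

Among admissible links the weakest (smallest symmetrised backbone weight)
is removed first, ties broken by the smaller S_inter of the created pair,
then lexicographic endpoints. Rationale: Kruskal admits weak inter-module
bridges last, so the weakest tree links are exactly the natural module
boundaries. Two alternatives were evaluated and rejected: checking
admissibility only between the two modules a cut creates (with a global
repair pass afterwards) over-fragments — locally admissible slivers
accumulate and the repair cascade can merge the whole level back into a
handful of blobs; and preferring the cut with minimal S_inter peels off
weakly attached fragments rather than cutting along boundaries.

A final validation pass re-checks all module pairs and would merge
violators smallest-violation-first; with the global admissibility check it
is a no-op by construction and retained as a safety net. Pairs with
S_inter = 0 are exempt (modules in different components of the filtered
graph must not merge); a singleton whose every inter sum is zero is kept
and flagged as an isolated supernode.

## Abstraction and the pyramid loop

Supernode weights average the **unfiltered** proximities,
prox_super(M_a, M_b) = Σ prox(m, n) / (|M_a|·|M_b|): the threshold is a
search-space reduction, and zeroing weak module pairs here would silently
disconnect the upper levels. The supernode network becomes the next level's
adjacency and the loop recomputes the proximity on it.

Levels are built bottom-up; reported numbering puts level 1 at the top. The
top level is the one whose partition yields a single module (matching the
convention in which a five-level hierarchy has module counts like
207/72/16/3/1); no extra trivial level is appended above it. The loop stops
on success (single supernode), on stall (a round that does not coarsen —
module count equal to node count, reported via a flag rather than an
exception, since a partition-refusing network is a legitimate outcome), or
at a safety cap of 50 levels.

## Synthetic benchmark

The generator plants an L-level nested partition (defaults: branching
4/4/4, leaf size 10, hence 640 nodes and 4×160 / 16×40 / 64×10 modules) and
draws each unordered pair independently with probability p_d = c·ρ^d, where
d is the pair's hierarchical distance (0 = same bottom module, D = no
shared module) and ρ ∈ (0, 1] is the cohesion knob — smaller ρ concentrates
edges inside bottom modules; ρ = 1 collapses to Erdős–Rényi. The constant c
is calibrated in closed form so the expected edge count matches the target
density (default 0.0225; at the defaults p_0 ≈ 0.456); a calibration that
would need p_0 > 1 is rejected with advice. Density sweeps thin a generated
network by removing uniformly random links down to an exact link count, so
the sweep is noiseless in density.

What the generator emulates: planted nested communities with geometrically
decaying cross-module connectivity at a controlled global density, the
standard substrate for hierarchy-recovery validation. What it does not:
degree heterogeneity (all nodes are statistically identical), weighted or
directed edges (unit weights only), overlapping modules, and noise in the
planted structure itself. Passing recovery tests therefore demonstrates
correct mechanics on clean hierarchical topology, not robustness on
real-data artefacts such as hubs or missing links.

A regime caveat, measured with this package: under this tier law at
ρ = 0.25 and density 0.0225, sampling noise makes within-module proximity
sums overlap with sibling inter sums, and the planted bottom partition
itself violates the module criterion in a handful of module pairs per
realisation — so no criterion-faithful partitioner can recover all 64
bottom modules exactly there. Recovery is essentially exact once within-
module cohesion dominates (ρ ≈ 0.16 at this density, near the p_0 ≤ 1
calibration boundary ρ ≈ 0.154), as the worked example's smaller benchmark
also shows. The mapping between this ρ and cohesion parameters used
elsewhere in the literature is not one-to-one.

## Evaluation

Partition agreement is NMI = 2·I(P;Q)/(H(P)+H(Q)) (natural logs), computed
via scikit-learn's arithmetic-mean normalisation, with explicit
conventions at zero entropy: two all-in-one partitions score 1, and an
all-in-one against anything structured scores 0, so the trivial partition
never scores well. A recovered pyramid is compared level-by-level to the
planted truth: recovered levels are the flattened memberships with more
than one module, ordered top to bottom and top-aligned with the truth
levels; if the pyramid is shallower than the truth, the deepest recovered
level is reused and the comparison flagged rather than silently realigned.

## Enrichment analytics

Module enrichment is the upper-tail hypergeometric probability (scipy
survival function; exact closed form of the random-assignment null) of the
overlap between a module and each annotation category, over a user-supplied
node→category table with an explicit background (default: all annotated
nodes). The minimum raw p per module is reported by default; Bonferroni
across the categories tested is available behind a flag. p-DecreaseRatio =
(min(pv_a, pv_b) − pv_ab)/min(pv_a, pv_b) is positive exactly when a merge
beats both parents. The proximity sign test enumerates all unordered pairs
of abstract-network links with strictly different proximities, counts a
success when the stronger link's merge has the larger p-DecreaseRatio, and
reports the one-sided exact binomial p against 1/2 (default significance
level 0.01); ratio ties contribute no trial, links touching unannotated
modules are skipped, and fewer than two comparable links yields a defined
insufficient-data result. An optional cap bounds the number of comparisons
on large levels.

## Problem sizes used in the test suite

Unit and property tests run on fixtures of up to ~14 nodes where exhaustive
oracles (all spanning trees, all cut subsets, full hypergeometric
enumeration) are affordable. The benchmark-level checks build pyramids on
640-node ensembles of 10 networks per condition (the sweep harness default;
the full 30-network protocol is a flag away), which keeps one pyramid build
well under a second via the vectorised proximity and prefix-sum
partitioning.

## Known limitations

* Radius-two proximity cannot separate modules whose distinction only
  appears beyond shared neighbourhoods.
* The divisive search is greedy over tree links; it returns a
  criterion-feasible partition but not a certified optimum, and the result
  can depend on the (deterministic) cut order.
* Modules never overlap.
* On unweighted networks, thresholds in a wide band around 0 are equivalent
  at the bottom level (see the bimodality note above), so threshold sweeps
  mostly probe the upper levels.
* An extra near-top level can appear when filtering disconnects a small
  abstract network whose modules are genuinely inter-linked; it is reported
  as-is rather than suppressed.
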