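# Methods

This note records the models, conventions and numerical choices behind
retroplan, in the spirit of a methods appendix: what each component assumes,
which knobs matter, and what the synthetic test universes do and do not show
about real retrosynthesis.

## Molecules, templates and identity

Molecules are canonicalized with RDKit; identity, hashing and stock
membership all use the **full 27-character InChI key**, so stereoisomers and
isotopologues stay distinct. No tautomer or charge standardization is
applied before key computation — callers whose stocks are standardized
differently should pre-standardize their inputs.

A retro template is a reaction SMARTS with exactly one product-side pattern
(`product >> reactants`), validated at load time. Template application
over-generates by design: outcomes that fail RDKit sanitization are dropped
and counted, outcomes regenerating the product are dropped (the first line
of cycle defense), and reactant tuples with identical InChI-key multisets
are de-duplicated. Reactants within a tuple are ordered lexicographically by
canonical SMILES and the tuples themselves sorted, so application is fully
deterministic. A single product pattern may emit several fragments; each
fragment becomes its own reactant molecule, which is what makes the
reactant-count filter well defined (expected count = number of
reactant-side patterns declared by the SMARTS).

Fingerprints are Morgan (circular), radius 2, 2048 bits — the standard
choice; only relative Tanimoto values matter downstream.

## Priors and policies

Trained single-step models are deliberately out of scope; the
`PriorModel` contract replaces them. Two implementations ship:

- **Frequency prior** — template probability proportional to its literature
  example count (`n_examples`), molecule-independent; all-zero counts fall
  back to uniform with a warning. This captures the empirical fact that
  heavily-exampled templates dominate predicted routes.
- **Lookup prior** — exact InChI-key lookup returning a stored probability
  vector, the analogue of augmenting predictions from a reaction database;
  unknown molecules get no proposals.

Proposal selection keeps at most `top_k` (default 50) templates and
truncates at cumulative probability `cutoff_cumulative` (default 0.995).
The cumulative rule is **inclusive** — the proposal whose inclusion first
reaches the cutoff is kept — guaranteeing at least one proposal whenever any
prior is positive (this matters for flat priors). Combining strategies in
`"all"` mode re-sorts the union by raw prior *without rescaling*: priors
from different strategies are not on a common scale, so rescaling would
manufacture information; each proposal records its originating strategy id
instead. `"first"` mode queries later strategies only for molecules the
earlier ones left empty.

Proposals are lazy (template application deferred until the search
instantiates them) and memoized per (strategy id, InChI key); a batched
`get_actions` call per search state implements sibling expansion with one
prior evaluation per distinct molecule. Caching is observably side-effect
free: searches with caching on and off produce identical serialized results,
which the suite asserts.

The feasibility filter's default cutoff is 0.05 and configurable; without a
learned feasibility model the CLI wires the proposal prior in as the score,
which demotes only the long tail.

## Search

All engines share `max_transforms` (default 6), a per-molecule count of
retro steps from the target; molecules at the cap are frozen (kept in the
state for scoring, no longer expandable) rather than discarded. The cycle
guard is per path: a reaction is rejected if any reactant's key equals the
product's or any ancestor's key on the path from the target. A branch
terminates at the stock: purchasable molecules are never expanded further.

**MCTS** uses the super-node state (the multiset of all remaining
molecules, ordered by InChI key). One iteration = select (UCT, exploration
constant 1.4, ties to the earliest-created child) → expand one child →
greedy rollout → backpropagate. The reward is the **terminal** rollout
state's score (the maximum score along the rollout is a plausible
alternative; the terminal value was chosen for its simpler conservation
semantics). Rollout nodes are not persisted. Every solved state encountered
— tree child or rollout terminus — is recorded as a route. A node whose
proposals are exhausted without an admissible reaction is a dead end and
backpropagates reward 0. Visit conservation (root visits = completed
iterations) is asserted by the suite. The engine contains no random number
generator: given a configuration, the search is deterministic, and the
`seed` field exists to derive per-target seeds in batch runs.

**Retro\*** is the zero-heuristic variant: reaction cost
`−ln(max(prior, 1e-10))`, molecule value 0 when unexpanded or in stock.
Each iteration expands the shallowest unexpanded molecule of the current
minimum-cost partial route and updates cost bounds bottom-up along the
ancestor chain. With the admissible zero heuristic, the first fully-proven
minimum-cost partial route is globally optimal; the suite checks this
against a brute-force enumerator's minimum. The AND/OR structure is kept as
a tree (a molecule reached along two paths appears twice) so the path cycle
guard stays exact; at desk scale the duplication is immaterial.

**Breadth-first search** expands every unsolved molecule level by level to
the depth bound and then enumerates all solved routes (capped at
`route_limit`, default 5000, against combinatorial blow-up); on universes
small enough to exhaust, it is the reference enumeration.

The time limit is checked between iterations only, so runs bounded by
`iteration_limit` are reproducible regardless of machine speed.

## Scoring and ranking

The default node/route score is the bounded linear form
`w_stock·frac + w_len·(1 − min(d, L)/L)` with `w_stock = 0.95`,
`w_len = 0.05`, `L = max_transforms` — monotone in both arguments, exactly 1
for a solved zero-step state, exactly 0 for an unsolved state at maximum
depth. For finished routes the depth term uses the longest linear sequence.
A sigmoidal depth squash would serve equally; the linear form was chosen for
its testable closed form.

Badowski-style costing is the simplest additive instantiation: a flat cost
per reaction (default 1) plus a flat penalty per unavailable leaf (default
10); when stock prices are available they may replace the penalty
(`use_prices`). A molecule present in several priced sources is costed at
the minimum price. Route extraction ranks by score descending, solved before
unsolved at equal score, then fewer steps, then first-found order, after
de-duplication by serialized form.

## Routes, edit distance and clustering

Route JSON uses nested `"type": "mol" | "reaction"` objects with
`"children"` arrays; children are serialized in a canonical sorted order, so
serialization is byte-stable and equality is serialization equality; unknown
keys survive round trips. "Convergent" is defined structurally: some
reaction joins at least two branches that each contain further reactions.

The tree edit distance is Zhang–Shasha on ordered trees with children placed
in a canonical deterministic order first, making the result invariant to
child enumeration order. Costs: insertion/deletion 1 per node; substitution
`1 − Tanimoto` of Morgan fingerprints for molecule pairs, `1 − Tanimoto` of
RDKit reaction difference fingerprints for reaction pairs, 1 for mixed-kind
pairs. All three choices (fingerprint kind, ordered-tree assumption, child
ordering) are configurable divergence points; note that under these costs a
route differing in one starting material also differs in the reaction above
it, so the minimal edit script contains two substitutions. The suite checks
the metric axioms (non-negativity, symmetry, identity of indiscernibles on
serialized forms, triangle inequality) on sampled route triples.

Clustering is agglomerative with average linkage on the precomputed distance
matrix; the cluster count is chosen in `[2, min(max_k, n−1)]` (default
`max_k = 8`) by maximum silhouette on the same distances — the selection
criterion had to be fixed somewhere, and silhouette is the standard choice
for precomputed metrics. Degenerate inputs (fewer than two routes, or an
all-zero distance matrix) collapse to a single cluster; exactly two distinct
routes are forced to two clusters. Labels are contiguous integers in order
of first appearance.

## Batch CLI and determinism

The CLI processes targets in file order, appends one JSON-lines record per
target, and atomically rewrites a checkpoint (temp file + rename) after
each, storing a digest of the effective configuration; resuming under a
changed configuration is refused. Per-target seeds derive from
`base seed + line index`, so output does not depend on which subset of
targets a given invocation processes: resumed output concatenates to exactly
the uninterrupted bytes. To keep that guarantee, **output records contain
only deterministic fields** — wall-clock timings go to the log on standard
error, not the output file, and the `stats` command treats search time as
optional.

## The synthetic universes: what they show and what they do not

`toyverse` uses real (simple) organic chemistry — amide and ester formation,
Williamson ether synthesis, biaryl coupling — with forward/retro SMARTS
pairs that are exact inverses, so template application, fingerprints,
filters and replay are exercised end to end rather than mocked. Building
blocks are drawn from a fixed catalogue of amines, acids, alcohols, halides
and boronic acids; a third of the slots go to bifunctional linkers so that
multi-step targets remain composable. Template example counts are sampled
uniformly in [1, 1000] to exercise frequency priors and example-count
distribution summaries. Defaults (12 blocks, depth 3, branching 2) keep the
universes small enough for exhaustive enumeration, which is what makes the
oracle-equivalence checks possible.

These universes lack the properties that make industrial retrosynthesis
hard: template libraries of four families instead of tens of thousands,
no stereochemistry or protecting-group chemistry, no conflicting template
scales, and stocks of a dozen rather than millions of compounds. Passing
tests therefore demonstrate algorithmic correctness (route sets, optimal
costs, determinism, metric axioms), not chemical quality of predicted
routes. Known limitations follow directly: route scoring remains a crude
proxy for synthesizability, the frequency prior ignores the query molecule
entirely, and the AND/OR tree (rather than graph) representation trades
node sharing for an exact path cycle guard.

## Problem sizes

Test and acceptance runs use universes of 12 building blocks, planted depth
≤ 3, 5–20 targets, with MCTS at 400–1000 iterations, breadth-first search to
depth 3, and Retro\* given a 5000-iteration proof budget — sizes at which
the brute-force enumerator stays exact and the full suite completes in
seconds.
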