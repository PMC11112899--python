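# retroplan

Template-based multi-step retrosynthesis planning as a library and batch CLI.

Given a target molecule, retroplan recursively disconnects it into simpler
precursors by applying retrosynthetic reaction templates (reaction SMARTS
written in the retro direction, `product >> reactants`) inside a tree search,
until every branch terminates at a purchasable building block held in a
*stock* (an in-memory set of InChI keys, optionally constrained by maximum
price and minimum amount). The result is a ranked collection of synthetic
routes — bipartite trees alternating molecule and reaction nodes — together
with route metrics, scores, and a tree-edit-distance clustering.

## What it implements

**Expansion and filter policies.** An expansion strategy proposes ranked
retro reactions for a molecule. The built-in template expansion ranks a
template library with a pluggable prior model — a frequency prior
proportional to each template's literature example count, or an exact-match
lookup table keyed by InChI key — keeps the `top_k` best and truncates at a
cumulative-probability cutoff. Multiple strategies combine either as the
union of all proposals (`"all"`) or as a per-molecule first-non-empty
fallback (`"first"`). Filter strategies veto proposals: a reactant-count
filter rejects reactions whose reactant count disagrees with the template,
and a score-based feasibility filter rejects reactions below a cutoff.

**Search engines.** Three stock-terminated engines share the same expansion
pipeline, per-path cycle guard and per-molecule depth cap (`max_transforms`):

- **MCTS** (default) on the *super-node* representation: each node holds the
  whole multiset of remaining molecules. Selection follows UCT,
  `Q + c·sqrt(ln N / n)`; expansion instantiates the highest-prior untried
  proposal; a greedy policy-guided rollout yields the reward
  `w_s·f + w_l·(1 − min(d, L)/L)`, with `f` the fraction of molecules in
  stock and `d` the transform depth (defaults `w_s = 0.95`, `w_l = 0.05`).
- **Retro\*** (zero-heuristic variant) — best-first search on an AND/OR tree
  minimizing the additive route cost `Σ −ln(prior)`; because the zero
  heuristic is admissible, the first fully-proven minimum-cost partial route
  is globally optimal.
- **Breadth-first search** — exhaustive level-by-level expansion that
  enumerates every solved route within the depth bound.

**Route analysis.** Routes serialize to a nested JSON schema
(`"type": "mol" | "reaction"`), carry per-reaction template metadata, and
support metrics (step count, longest linear sequence, starting-material
count, convergence), Badowski-style additive costing (flat cost per reaction
plus a penalty or price per unavailable leaf), multi-source stock
availability profiles, and clustering: an ordered tree edit distance
(Zhang–Shasha) with `1 − Tanimoto` substitution costs on Morgan / reaction
difference fingerprints, followed by average-linkage agglomerative
clustering with the cluster count chosen by maximum silhouette.

**Synthetic universes.** `retroplan.toyverse` composes targets *forward*
from a catalogue of simple building blocks using four classic reactions
(amide, ester, Williamson ether, biaryl coupling), each paired with its exact
inverse retro template — so every generated target ships with a planted
ground-truth route, and the whole pipeline is testable end to end with no
external data. It also emits adversarial template libraries (guaranteed
dead-end decoys and a reactant-count violator) to exercise the filters.

## Worked example

```python
import retroplan as rp
from retroplan.search import SearchConfig

universe = rp.generate_universe(n_blocks=12, depth=3, branching=2, seed=42, n_targets=20)
templates = universe.template_library()
expansion = rp.TemplateExpansion(templates, rp.frequency_prior(templates))
stock = universe.stock()

target = universe.targets[0]
config = SearchConfig(algorithm="mcts", iteration_limit=1000, time_limit=0.0, top_routes=10)
result = rp.mcts_search(target.molecule, config, expansion, [], stock)

print(f"target: {target.molecule.smiles}")
print(f"solved: {result.solved} after {result.iterations_used} iterations")
best = result.routes.routes[0]
metrics = rp.compute_metrics(best)
print(f"best route: {metrics.n_steps} steps, LLS {metrics.longest_linear_sequence}, "
      f"{metrics.n_starting_materials} starting materials")
for rxn in best.reaction_nodes():
    print("  step:", rxn.metadata["reaction_smiles"], f"({rxn.metadata['template_label']})")

labels, k = rp.cluster_routes(result.routes, max_k=8)
print(f"{len(result.routes)} routes fall into {k} clusters: {labels}")
```

prints

```
target: O=C(COC(=O)COC(=O)CO)NC1CCCCC1
solved: True after 1000 iterations
best route: 3 steps, LLS 2, 4 starting materials
  step: O=C(CO)NC1CCCCC1.O=C(O)COC(=O)CO>>O=C(COC(=O)COC(=O)CO)NC1CCCCC1 (ester formation)
  step: O=C(O)CO.O=C(O)CO>>O=C(O)COC(=O)CO (ester formation)
  step: NC1CCCCC1.O=C(O)CO>>O=C(CO)NC1CCCCC1 (amide formation)
10 routes fall into 3 clusters: [0, 1, 2, 2, 0, 1, 2, 0, 2, 1]
```

The target is disconnected in three steps — an ester coupling of two
fragments, each made in one further step — ending at four purchasable
building blocks; the ten extracted routes group into three structurally
distinct families.

### Batch CLI

```bash
retroplan plan --config config.yml --targets targets.smi \
               --output out.jsonl --checkpoint ckpt.json --seed 1
retroplan expand --config config.yml --smiles "CC(=O)NC"
retroplan stats --input out.jsonl
```

`plan` appends one JSON-lines record per target and checkpoints after each,
so a killed run resumes exactly where it stopped; fixed-seed output is
byte-identical, interrupted or not. `expand` performs a single-step
expansion; `stats` aggregates a finished output file (percent solved, route
metric means, unique templates used).

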