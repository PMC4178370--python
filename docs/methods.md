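# Methods

This note documents the model the package implements, the choices made where
the design was genuinely open, and what the tests do and do not establish.

## Network model

A `MetabolicNetwork` is a registry of compartments, metabolites, pools,
reactions and pathways with secondary indices (case-insensitive name/synonym
lookup, pool→reactions, reaction→pathways). Pools are unique per
(metabolite, compartment) pair and are created on demand
(`get_or_create_pool`), mirroring the automatic pool creation of a curation
editor. `validate()` sweeps the whole registry — referential integrity, pool
uniqueness, acyclic compartment chains, at least one substrate and product
per reaction — and runs in every test.

Design choices:

* **Subtree semantics for compartment containment.** Asking for the pools of
  a reaction "at the liver cell" also returns pools in the nested cytosol and
  mitochondrion; sibling compartments see nothing.
* **Enzymes are name strings on reactions**, not pools: enzyme observations
  attach an availability to a name, not a concentration to a pool. A reaction
  with several enzyme names is treated as requiring all of them (a complex),
  so one unavailable member silences it.
* **Pathway multi-compartment instantiation** is a set of compartments on the
  pathway, not duplicated reaction copies.
* **Pathway collapse** produces a synthetic irreversible reaction
  (inputs → outputs, no enzymes, tagged with the source pathway). Collapses
  whose input and output pool sets overlap are rejected as self-loops.
  Irreversibility is a deliberate default: a lumped pathway is used as a
  directed feed into the analysis.
* **Connectivity** of a subnetwork is judged on the bipartite pool–reaction
  graph over participation (substrate/product) edges only; a regulator edge
  does not make a subnetwork connected.
* Deterministic ordering (name, then id) everywhere results are returned.

Two schema-like entities mentioned in curated databases are deliberately not
modeled: free-form "physiological states", and ratio regulation (e.g. a high
NAD/NADH ratio acting as an activator); neither has a defined semantics to
implement.

## Labels, rules and scenarios

Pool labels are the ordered set `unavailable < available < accumulated <
severely_accumulated`. Concentrations map to labels against a
`ReferenceRange` (low/high/severe_high, all positive, strictly increasing)
with closed lower and closed upper bounds on the normal band: below *low* →
unavailable, `[low, high]` → available, `(high, severe_high]` → accumulated,
above → severely accumulated. The cut-point convention (boundaries inclusive
toward the milder label) is our choice; reference-database lookups do not
define one.

A scenario assigns every reaction a flux of 0 or 1 — an active reversible
reaction additionally carries one direction, and scenarios differing only in
direction are distinct — and every pool one label. Consistency is the
conjunction of rules R1–R6 plus observation agreement:

| rule | statement |
|------|-----------|
| R1 | active ⇒ every direction-appropriate substrate ≥ substrate threshold (default `available`) |
| R2 | any catalysing enzyme observed unavailable ⇒ inactive |
| R3 | active ⇒ no inhibitor ≥ blocking threshold (default `accumulated`) |
| R4 | pool `unavailable` ⇒ no active producer |
| R5 | pool ≥ `accumulated` ⇒ ≥ 1 active producer, unless boundary |
| R6 | non-boundary pool ≥ `available` with an active consumer ⇒ ≥ 1 active producer |

Optionally (off by default) an active reaction with activator participants
needs at least one activator ≥ `available`. All thresholds and the activator
flag ship as data (`ActivationConditionSet`) with separate defaults for
transport reactions and per-reaction overrides, so the rule set is explicit
and user-replaceable rather than hard-coded.

Additional semantic decisions:

* `severely_accumulated` does not block consumption; it only strengthens the
  producer requirement by implying `accumulated`. No blocking semantics for
  substrate excess is defined anywhere we could anchor one.
* **Boundary pools** — pools touched by network reactions outside the
  selected subnetwork, plus any pools the caller flags — are exempt from the
  producer-existence rules R5/R6. A selected subnetwork is an open system;
  without this exemption a collapsed glycolysis feeding a TCA selection, or
  dietary ammonia entering the urea cycle, could never be active.

## Enumeration: Expansion and Merge

Partial assignments are *flow graphs* (label map, status map, frontier of
unassigned neighbors). The engine starts with one single-pool flow graph per
observation (or one empty graph when there are none), merges them — the
disjoint observation singletons join into a single seed — and then alternates
expansion and merge phases until every graph is total:

* **Expansion** takes each incomplete graph and branches its next frontier
  entity over every value whose partial assignment is not *definitely*
  inconsistent. The three-valued reading is essential: a rule that evaluates
  to unknown on the partial assignment never prunes; only definite violation
  does. Each assignment is checked locally (the rules touching the newly
  assigned entity), which is inductively complete because every rule's last-
  assigned participant triggers its full check.
* **Frontier policy.** The next entity is chosen by minimum remaining values:
  the frontier entity with the fewest surviving candidate assignments goes
  first, so forced assignments and dead ends propagate before any true
  branching. This keeps the live population essentially equal to the final
  scenario count (naive orderings overshoot by an order of magnitude on the
  same inputs). Ties fall to the oldest frontier entry in breadth-first mode
  and the newest in depth-first mode; in depth-first mode a seed may instead
  randomize tie-breaks. Both strategies provably enumerate the same set, and
  a property test asserts it.
* **Merge** inside the engine unions graphs with disjoint domains (the
  initial observation join) and deduplicates graphs with equal domains.
  The standalone `merge()` operation implements the general
  agree-on-overlap union greedily over canonically sorted pairs; for
  partially overlapping families that greedy choice is order-sensitive in
  corner cases, which is why the engine restricts itself to the two
  meaning-preserving cases.
* The population size is checked against a **cap** (default 10 000) after
  every phase; overflow raises a capacity error naming the cap. The output
  space genuinely grows exponentially in the number of unobserved pools, so
  a guard is part of the method, not an implementation detail.

Scenarios are extracted from the total graphs, canonicalized (inactive
reversible reactions get the forward direction), filtered once more by the
full consistency check, and sorted lexicographically over reaction names'
statuses, then pool labels.

`brute_force_scenarios` is the independent oracle: it iterates every
reaction-status combination and, exploiting that rules R1 and R3–R6
decompose per pool once statuses are fixed, takes the product of per-pool
admissible label sets, then filters with the same `is_consistent` predicate.
It is guarded to ≤ 15 reactions and ≤ 15 pools. `count_scenarios` computes
the same sum-of-products without materializing anything; it is exact when the
activator requirement is off (the default) and an upper bound otherwise.

## Queries

Reactions are adjacent when they share a metabolite pool; all five
neighborhood queries are breadth-first searches over that graph (or the
bipartite pool–reaction graph for metabolite distances, counted in reaction
hops). Traversal ignores direction — reversibility makes directed distance
ill-defined — and works on pools, so a metabolite shared across compartments
connects nothing. "Pathways within *n* steps of a pathway" anchors distance
0 at sharing a reaction. An optional currency-metabolite exclusion removes
cofactor hubs from the adjacency; it can only shrink results. Pathway-to-
pathway distance in reaction hops (rather than pathway hops) is an
interpretation; the alternative is not well defined for overlapping pathways.

## SBML import and serialization

The reader handles SBML core, levels 1–3, namespace-agnostically (built on
lxml). Dialect workarounds, each emitting exactly one warning per instance:
species without a `compartment` attribute go to a synthetic default
compartment named `cell`; untyped modifiers default to the activator role
unless an override map assigns `enzyme` or `inhibitor`; reaction `notes`
bodies are scanned line-wise for `SUBSYSTEM:`/`PATHWAY:`/`GROUP:` keys
(case-insensitive) to recover pathway grouping — any other `KEY: value` line
warns and is ignored. The legacy `outside` attribute reconstructs the
compartment hierarchy. A reaction referencing an undeclared species is fatal
(no partial network is returned); reactions without both a reactant and a
product (exchange stubs) are skipped with a warning. Transport reactions are
recognized purely from participant compartments, since SBML encodes nothing
else to recognize them by.

The native format is canonical JSON (sorted keys, id-sorted entity lists,
trailing newline): `write ∘ read ∘ write` is byte-stable and round-trips are
lossless. Reading validates structurally with path-qualified errors; the
shipped `docs/network.schema.json` documents the layout. GraphML export
writes typed nodes (metabolite/reaction/compartment), containment edges,
role-typed regulator edges, reversible flags, thick/thin activity weights
when a scenario is supplied, and duplicates configured currency metabolites
per participating reaction. The default currency list (H2O, ATP, ADP, NAD,
NADH, NADP, NADPH, CO2, Pi, H+) extends the canonical water/NAD/ATP examples;
there is no principled connectivity threshold to derive one from.

## Fixtures: what they emulate and what they do not

* **Urea-cycle network** — liver cell ⊃ cytosol ⊃ mitochondrion; the Urea
  Cycle pathway with its seven reactions (carbamoyl phosphate synthetase I,
  ornithine transcarbamoylase, argininosuccinate synthetase,
  argininosuccinate lyase, arginase, plus the ornithine-in and
  citrulline-out mitochondrial transporters) and two stub pathways (purine
  and pyrimidine biosynthesis) sharing the cytosolic aspartate and
  mitochondrial carbamoyl-phosphate pools. Cofactor participants (ATP,
  HCO3⁻, AMP, H2O) are omitted so the subnetwork stays inside the
  brute-force guard; the carbon/nitrogen skeleton is canonical.
* **TCA + collapsed glycolysis** — an 8-reaction TCA pathway that starts at
  pyruvate dehydrogenase and lumps fumarase with malate dehydrogenase into
  one closing step (the cycle stays closed with oxaloacetate regenerated),
  plus a toy 2-reaction glycolysis collapsed into a single synthetic
  reaction from cytosolic D-Glucose to mitochondrial pyruvate (glycolysis
  and pyruvate import lumped, which is what makes the selection connected).
  Observations: D-Glucose available in the cytosol; Citrate Synthase
  unavailable.
* **Eight sample bundles** — ready-to-run inputs over these two networks
  (healthy profiles, an OTC deficiency, an arginase block, accumulation
  patterns). They are this package's own designs emulating the kind of
  sample inputs a hosted tool offers; no equivalence to any published bundle
  set is claimed. The urea bundles flag ammonia, urea, fumarate, phosphate
  and cytosolic ornithine as boundary pools — the cycle's physiological
  exchange points.
* **Random networks** — seeded, connected by construction (each reaction
  after the first reuses an already-wired pool), with 3–12 reactions, a
  comparable number of metabolites, occasional reversibility (15%),
  regulators (15%) and enzymes (50%). `make_random_case` additionally draws
  2–4 observations and sometimes an unavailable enzyme, and skips draws
  whose exact scenario count exceeds 3000 so that test cases stay
  exhaustively enumerable; the skip is deterministic in the seed.

Passing tests on these fixtures establish the engine's correctness against
an independent oracle and the advertised invariants. They do not establish
performance or biological fidelity at genome scale: real reconstructions
have thousands of reactions, heavy cofactor coupling and messy annotations,
and the enumeration's output space makes whole-network runs infeasible by
design — the intended use is small, observation-rich subnetworks.

## Numerical and procedural choices

* Scenario cap default 10 000; test and acceptance sweeps raise it to 100 000
  where exhaustive comparison is the point.
* Oracle sweeps use 200 seeded random cases; monotonicity uses 50;
  strategy agreement uses the 8 bundles plus 20 random cases. These sizes
  keep the default suite fast while exercising every branch of the rule set.
* Tie-breaks are lexicographic by entity name, then id; identical inputs and
  seed give byte-identical serialized output.
* Degenerate inputs: empty subnetworks, empty selections, self-loop
  collapses, conflicting observations on one pool, negative step counts and
  malformed documents all raise typed validation errors rather than
  degrading silently.

## Known limitations

* The rule set instantiates steady-state reasoning at the qualitative level
  only; no stoichiometric coefficients, no flux magnitudes, no
  thermodynamics.
* The activator requirement is all-or-nothing per reaction and off by
  default; graded activation is not expressible.
* `merge()` on arbitrary overlapping flow-graph families resolves greedily
  (documented above); the engine never relies on that case.
* SBML write-back is not implemented (import only), and the fbc/groups
  extension packages are ignored.
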