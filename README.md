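# smda

A toolkit for compartmentalized metabolic networks: an in-memory data model
with SBML import, the classic pathway/reaction/metabolite neighborhood
queries, and a steady-state metabolic dynamics analysis (SMDA) engine that
enumerates **every** reaction activation scenario consistent with a set of
metabolite and enzyme observations.

## Who this is for

Metabolomics gives you a profile — some metabolites normal, some depleted,
some piled up — and a curated network tells you which reactions could have
produced that profile. Quantitative methods (FBA, MCA) answer with one
optimal flux vector; SMDA instead answers the *first-step* question a wet-lab
researcher actually asks: *which activation patterns of my subnetwork are
even compatible with what I measured?* The output is the complete set of
qualitative steady-state hypotheses, each assigning every reaction flux
0 (inactive) or 1 (active) and every metabolite pool one of four ordered
labels:

```
unavailable < available < accumulated < severely_accumulated
```

## The model in brief

* A network is a compartment hierarchy (e.g. liver cell ⊃ cytosol ⊃
  mitochondrion), metabolites with synonyms, **metabolite pools** (one
  metabolite in one compartment — the unit observations attach to), reactions
  with role-typed participants (substrate / product / activator / inhibitor)
  and enzyme names, and pathways. A reaction whose substrate and product
  pools span two compartments is a transport reaction.
* Observed concentrations are mapped to the four labels against a local
  reference-range table (below *low* → unavailable; [*low*, *high*] →
  available; (*high*, *severe_high*] → accumulated; beyond → severely
  accumulated).
* A **scenario** is a total assignment of statuses and labels that satisfies
  the steady-state rule set: an active reaction needs its (direction-
  appropriate) substrates available and no blocking inhibitor; a reaction
  whose enzyme is observed unavailable is inactive; an unavailable pool has
  no active producer; an accumulated pool needs an active producer; a pool
  consumed by an active reaction needs a producer — unless it is a *boundary
  pool* of the open subnetwork. The rule parameters ship as data
  (`ActivationConditionSet`) and can be overridden per reaction.
* Enumeration runs as an **Expansion/Merge** iteration over partial
  assignments (*flow graphs*), with three-valued (Kleene) logic deciding
  which partial branches are already definitely inconsistent. A brute-force
  enumerator over total assignments provides an independent oracle for small
  networks, and a configurable cap guards against the (provably exponential)
  output space.

## Worked example

The built-in fixtures reproduce a textbook liver-cell setting. Browsing the
urea cycle and running the TCA-cycle analysis with glycolysis collapsed to a
single glucose → pyruvate reaction:

```python
from smda import (connected_pathways, enumerate_scenarios,
                  pools_of_reaction, reactions_of_pathway)
from smda.fixtures import make_tca_glycolysis_input, make_urea_cycle_network

net = make_urea_cycle_network()
print(len(reactions_of_pathway(net, "Urea Cycle")))
print([p.name for p in pools_of_reaction(net, "ornithine transcarbamoylase",
                                         "mitochondrion")])
print([p.name for p in connected_pathways(net, "Urea Cycle")])

sub, obs, enzyme_obs = make_tca_glycolysis_input()
scenarios = enumerate_scenarios(sub, obs, enzyme_obs)
print(len(scenarios))
print(all(s.reaction_status["cs"].flux == 0 for s in scenarios))
```

prints

```
7
['Carbamoyl phosphate[mitochondrion]', 'Citrulline[mitochondrion]',
 'Ornithine[mitochondrion]', 'Phosphate[mitochondrion]']
['Purine Biosynthesis', 'Pyrimidine Biosynthesis']
2432
True
```

The urea cycle holds its seven reactions (five enzymatic steps plus the two
mitochondrial transporters); ornithine transcarbamoylase touches exactly four
mitochondrial pools; two biosynthetic pathways connect to the cycle through
shared pools. The analysis input — one available D-Glucose observation in
the cytosol and Citrate Synthase reported unavailable — admits 2432
consistent scenarios, and the enzyme report forces the citrate synthase
reaction inactive in every single one of them.

## Command line

```bash
smda fixture generate --name urea_cycle --out urea.json
smda stats urea.json
smda query --network urea.json --type 1 --from "Urea Cycle" --n 1
smda smda --network urea.json --pathway "Urea Cycle" \
     --boundary "Ammonia@mitochondrion" --obs profile.tsv --out scenarios.json
smda viz-export --network urea.json --pathway "Urea Cycle" --out urea.graphml
smda convert reconstruction.xml network.json
```

Exit codes: 0 success, 2 validation/usage error, 3 scenario-cap overflow.
Observation tables are CSV/TSV (`metabolite`, `compartment_path`, and
`concentration`+`units` or `label`); enzyme tables are `enzyme`,
`availability`. GraphML exports mark inhibitor/activator edges, reversible
reactions and active/inactive status (thick/thin), and duplicate currency
metabolites (ATP, NADH, H2O, ...) per reaction so hub metabolites do not turn
the drawing into a hairball.

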