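# boolrd

**Reprogramming-determinant detection by differential stability analysis of
Boolean gene regulatory networks.**

Experiments keep showing that switching a cell from one stable phenotype to
another (differentiation, transdifferentiation, dedifferentiation) needs only
a handful of key genes — a reprogramming cocktail — even though the full
transcriptional programs involve hundreds. `boolrd` finds those key genes,
the *reprogramming determinants* (RDs), from two inputs only: a signed gene
regulatory network (GRN) and binarized expression profiles of the initial
and final phenotypes. No candidate gene list is required.

## The model

A GRN is a signed digraph: `u → v` (activation) or `u ⊣ v` (inhibition),
over genes and miRNAs. Dynamics are Boolean and synchronous with an
inhibitor-dominant rule:

```
x_v(t+1) = 1   iff  no inhibitor of v is active at t
                and (some activator of v is active at t,
                     or v has no activators)        # default-ON convention
```

Stable cellular phenotypes are identified with the *fixed points*
(attractors) of this map. Multistability requires **positive circuits** —
elementary cycles with an even number of inhibitions (a double-negative
toggle switch is the canonical example). The analysis proceeds in three
steps:

1. **Attractors.** Enumerate all fixed points (exhaustive 2^n scan for small
   n, complete constraint backtracking for large n) and match them to the
   two phenotype profiles.
2. **DEPCs.** Enumerate all elementary circuits (Johnson's algorithm,
   self-loops included). A positive circuit is a *differentially expressed
   positive circuit* (DEPC) for the attractor pair iff every one of its
   genes changes value between the attractors **and** both restricted
   states are fixed points of the circuit in isolation. DEPCs are the
   stability elements forming the barrier between the two phenotypes.
3. **RDs.** Find the minimum number of DEPCs whose perturbation flips the
   network (feasibility checked by simulation), cover them with a minimal
   set of genes (greedy, branching on ties to collect every alternative),
   then drop genes of circuits that are slaved to other perturbed circuits.
   Each candidate is validated by a two-phase simulation: clamp the genes
   to their final-attractor values until the clamped system settles,
   release the clamps, and require the free dynamics to rest in the final
   attractor. Only validated minimal combinations are reported, with the
   stimulus direction (activate/repress) per gene.

A literature-derived network whose attractors do not match the profiles can
first be **contextualized**: an estimation-of-distribution evolutionary
algorithm prunes inconsistent interactions, maximizing the fraction of
measured gene states explained by the best attractor pair (that fraction is
also the reliability score of the predictions).

## Worked example: epithelial → mesenchymal transition

The package ships a reconstruction of the EMT regulatory core (7 nodes,
17 interactions): mutual repression between the EMT inducers SNAI1/ZEB1/ZEB2
and the miRNAs MIR200/MIR203/MIR34, SNAI1 activating the ZEBs, and all three
inducers repressing E-cadherin (CDH1).

```python
from boolrd.examples import emt_core_network, emt_profiles
from boolrd.io import write_network, write_profiles
write_network(emt_core_network(), "emt.sif")
write_profiles(emt_profiles(), "emt_profiles.tsv")
```

```bash
boolrd run emt.sif emt_profiles.tsv -o out/
```

prints

```json
{
  "contextualization_score": 1.0,
  "n_attractors": 2,
  "initial_attractor": 1,
  "final_attractor": 0,
  "profile_match": 1.0,
  "n_circuits": 12,
  "n_positive_circuits": 12,
  "n_depcs": 12,
  "rd_combinations": [
    {"genes": ["SNAI1"], "stimulus": {"SNAI1": "activate"}}
  ]
}
```

Read: the network is bistable; its two attractors match the epithelial and
mesenchymal profiles perfectly (score 1.0, so the predictions are reliable);
all 12 elementary circuits are positive and all 12 are differentially
expressed between the phenotypes; and a single perturbation — sustained
activation of SNAI1 — is sufficient to drive the epithelial attractor into
the mesenchymal one. Every other subcommand (`attractors`, `circuits`,
`depcs`, `rds`, `contextualize`, `generate`, `study`) exposes one pipeline
stage; see `boolrd --help`.

The same analysis from Python:

```python
from boolrd import find_reprogramming_determinants
from boolrd.examples import emt_core_network, emt_profiles

combos = find_reprogramming_determinants(emt_core_network(), profiles=emt_profiles())
print([sorted(c.genes) for c in combos])   # [['SNAI1']]
```

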