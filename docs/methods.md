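# Methods

## Model and assumptions

`boolrd` models a gene regulatory network as a signed digraph (activation
`+1`, inhibition `−1`; at most one edge per ordered pair; self-loops
allowed) with deterministic synchronous Boolean dynamics under an
inhibitor-dominant rule: a node is active at `t+1` iff none of its
inhibitors is active at `t` and its activator requirement holds. All
interactions are equally strong — no kinetics, no dose, no delay — so the
model is suitable for describing stable steady states, not transient
biology. Stable phenotypes are identified with fixed points; cyclic
attractors are deliberately out of scope (transitions through oscillatory
states are not analyzed, and miRNAs that would only add negative feedback
are filtered out for the same reason, see below).

**Default-ON convention.** The inhibitor-dominant rule as usually phrased
leaves open what happens to a node regulated *only* by inhibitors. Reading
the activator clause literally ("at least one activator is active") would
pin every such node OFF permanently, which destroys the bistability of
inhibition-dominated networks — a double-negative toggle switch would have
a single attractor, and the EMT core (15 of its 17 interactions are
inhibitions) would lose its two phenotype attractors. We therefore treat
the activator clause as vacuously true for nodes with no activators: they
are ON exactly when all their inhibitors are silent. `default_on=False`
restores the literal rule everywhere it is accepted. Unregulated nodes
(no incoming edges at all) are ordinarily removed by iterative pruning
before analysis; if left in, they are constant-ON under the convention,
and strict mode turns them into an error instead.

## Attractor enumeration

Two complete strategies, equivalent by construction and by test:

* **exhaustive** (default up to 20 nodes, refused above 25): vectorized
  scan of all 2^n states in chunks of ≤ 2^18, using the activation and
  inhibition adjacency matrices.
* **backtracking** (any size): depth-first assignment of node values with
  one consistency constraint per node (its value must equal its update
  from its regulators). Variables are statically ordered by a greedy
  heuristic that completes constraints as early as possible; partial
  assignments are pruned the moment a constraint becomes unsatisfiable
  (e.g. a node set to 1 with a known-active inhibitor). At full depth the
  checks are exact, so the search enumerates exactly the fixed points.

Attractor ids index the lexicographically sorted state vectors (node order
= sorted names), so ids are reproducible across runs and machines.

Profile matching scores an ordered attractor pair by the mean, over the
initial and final profiles, of the fraction of measured genes whose
attractor value equals the profile value; ties break to smallest ids. The
same number is the contextualization score.

## Circuits and DEPCs

Elementary circuits come from Johnson's algorithm (`networkx.simple_cycles`,
which emits self-loops as length-1 cycles); each cycle is rotated to start
at its smallest node and carries its edge signs. A circuit is **positive**
iff its inhibition count is even — the parity convention under which a
double-negative loop is positive and a single self-inhibition negative. A
configurable cap (default 100 000) guards against combinatorial blow-up and
raises rather than truncating silently.

A positive circuit of an isolated ring has exactly two fixed points, which
are bitwise complements determined by the sign pattern; a negative ring has
none (parity contradiction). `ring_fixed_points` computes them by
propagating a trial value around the ring and checking closure.

A **DEPC** for an ordered attractor pair is a positive circuit such that
(i) every circuit gene differs between the attractors and (ii) both
restricted states are fixed points of the circuit in isolation. Criterion
(ii) is evaluated on the ring alone (only circuit edges), making it
independent of external regulators; since the two ring fixed points are
complements, a circuit passing (i) and (ii) always has its final state
equal to the complement of its initial state. Circuits sharing all nodes
but differing in edges count as distinct DEPCs.

**miRNA filter.** When enriching a network with miRNA interactions from
interaction databases, a miRNA is kept only if it lies on at least one
positive elementary circuit of the augmented network. miRNAs on no circuit
(missing incoming or outgoing links) carry no stability information;
miRNAs only on negative circuits would introduce oscillatory motifs whose
real behavior depends on kinetic parameters a Boolean model does not have.

## Reprogramming-determinant search

Given a transition (ordered attractor pair), the search runs in four
validated stages, every feasibility question answered by simulating the
dynamics rather than by topology alone:

1. **Minimal DEPC subsets.** Subsets of the transition's DEPCs are tried in
   increasing size; a subset is feasible iff clamping *all* genes of *all*
   its circuits to their final-attractor values achieves the transition.
   All feasible subsets of the first feasible size are kept. If nothing
   works, the error reports the closest final state reached for diagnosis.
2. **Gene covers.** Each minimal DEPC subset is covered one gene per
   circuit: repeatedly pick the gene occurring in the most untargeted
   circuits, branching into every tied choice so all alternative covers
   are collected (branch count capped, default 10 000).
3. **Redundancy pruning.** For a validated combination, genes are dropped
   (ascending lexicographic order, sweeping until stable) whenever the
   transition still succeeds without them — this removes targets inside
   circuits that are slaved to other perturbed circuits.
4. **Minimality certification.** Clamped Boolean dynamics are not monotone
   in the clamp set, so deletion-stability does not by itself rule out a
   smaller successful subset; for combinations of ≤ 5 genes every proper
   subset is checked exhaustively and inclusion-minimal passing subsets
   replace the combination. Finally only inclusion-minimal sets across all
   alternatives are emitted, ordered by size then lexicographically, each
   re-validated.

**Clamp semantics.** A perturbation is a *transient* clamp by default:
phase 1 holds the target genes at their final-attractor values until the
clamped system reaches a fixed point (a cycle or an exhausted step budget
fails); phase 2 releases the clamps and requires the free dynamics to rest
exactly in the final attractor. This mirrors a reprogramming stimulus that
is applied and withdrawn, and makes "stabilize the final phenotype" a real
check rather than an assumption. `permanent_clamp=True` instead compares
the clamped steady state itself — both readings are available because
published descriptions of perturbation protocols rarely state the clamp
duration. The step budget (`step_cap`, default 1000) exists only as a
safety net; synchronous trajectories on these networks settle in far fewer
steps, and hitting the cap is reported as failure, never as success.

The minimum-DEPC selection could be phrased as an integer
program; with DEPC counts in the tens, size-ordered exhaustive subset
search with the simulation as feasibility oracle is exact and fast, and an
ILP backend could be slotted behind the same interface if ever needed.

## Contextualization (EDA pruning)

Candidates are edge-removal masks. Each sampled candidate is scored by
removing the masked edges, iteratively pruning newly unregulated nodes,
enumerating attractors and taking the profile-match score (0 if fewer than
two attractors remain). Per-edge removal probabilities (init 0.1) are
re-estimated from the elite fraction of each generation; positive circuits
are additionally sampled as units through per-circuit retention
probabilities, coupled into the edge distribution by scaling an edge's
keep-probability by the mean retention of the positive circuits it belongs
to (the two distributions are both named in the literature on this
algorithm family, their coupling is our design choice). Probabilities are
clipped to `[p_min, 1 − p_min]` (default 0.02) to keep exploration alive.
The unpruned network is always evaluated first, so an already-consistent
network is returned unchanged, the reported best is the best ever seen
(history is non-decreasing), and the loop stops early at score 1.0.
Defaults — population 50, elite fraction 0.2, learning rate 0.3,
100 generations — are sized for the ≤ 40-gene regime and are all
config-exposed; results are exactly reproducible given a seed. Networks
without any circuit are rejected: the method assesses interactions through
their effect on stability and has nothing to say about acyclic parts
(which is also why unregulated genes are pruned beforehand).

## Network generation and the ensemble study

`extract_subnetwork` mimics greedy-neighbor benchmark extraction: grow from
a (seeded) start node by repeatedly adding the outside node with the most
directed edges into or out of the current set, ties broken uniformly at
random, and return the induced subgraph with self-loops retained. The
exact greedy variant of the original extraction tool is not published;
"most connections to the current set" with uniform tie-breaking is our
reading, and self-loops never count toward connectivity.

`random_signed_network` draws digraphs with exact node/edge/self-loop/
inhibition counts and rejection-samples until the result has at least one
positive circuit and at least two fixed points, so every generated network
can exercise the full pipeline. Defaults for the study ensemble — 20–40
genes, 2.4 edges per gene, 40% inhibition, self-loops on 10% of genes —
approximate the density and sign balance of bacterial transcriptional
networks (a documented 25-node benchmark example has 60 interactions,
i.e. 2.4 per node) while remaining fully self-contained. What this
generator does *not* reproduce: the scale-free out-degree distribution,
operon structure and global regulators of a real transcriptional network,
or correlated sign patterns; conclusions from the ensemble therefore
characterize the algorithm, not any organism.

The study enumerates each network's attractors (backtracking mode), takes
all ordered attractor pairs (sampled down to 30 per network when a network
has very many attractors; at most 64 attractors considered), and runs the
full RD pipeline per pair with a DEPC-subset size cap of 3 (the search
exits at the first feasible size, so the cap only bounds the cost of
provably hard pairs). Per pair it records DEPC existence, RD success and
the minimal RD size; per network, the fraction of genes that are RDs for
some analyzed transition. At the default scale (50 networks) the study
runs in well under a minute on one CPU.

On this ensemble, DEPC existence holds for essentially every ordered
attractor pair, while DEPC-targeted perturbation succeeds for ~95% of
pairs rather than all of them: in the failing pairs some differing genes
lie on positive circuits that are not DEPCs (their restricted states are
not stable in isolation) and are not slaved to any DEPC, so no DEPC
perturbation — transient or permanent, of any subset size — can flip them.
Whether such pairs arise depends on the ensemble's topology; the mean RD
gene fraction (~12% here) is likewise ensemble-dependent.

## Degenerate inputs and tie-breaks

* Duplicate (source, target) edges with conflicting signs are an input
  error, never silently resolved; identical duplicates are idempotent.
* Node names are case-preserved and matched exactly; an optional
  normalization (uppercase, strip `hsa-`) is available for miRNA tables.
  miRNA node kind is inferred from the name (`MIR…`, `miR…`, `let-7…`).
* Dual-sign (`+-`) and unknown (`?`) rows of regulator tables are dropped
  by default (the Boolean model has no dual-sign edges); a flag coerces
  them to one sign instead.
* All orderings that affect output are deterministic: sorted node names,
  lexicographic attractor ids, circuits sorted by (length, node tuple),
  RD combinations by (size, gene tuple).

## Known limitations

* One gene per circuit: a weak interaction inside a circuit could require
  perturbing it at several points; the RD definition used here targets
  each DEPC at a single gene.
* Fixed points only: phenotypes realized as cyclic attractors, and
  transitions through them, are not analyzed.
* The DEPC barrier picture is a very good but not universal approximation:
  rare attractor pairs exist (see the ensemble numbers above) where no
  DEPC perturbation achieves the transition even though clamping all
  differing genes does.
* Profiles must arrive binarized; thresholding raw expression data is the
  caller's responsibility.
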