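"""Reprogramming-determinant (RD) search.

RDs are minimal gene sets whose perturbation drives the network from the
initial attractor to the final one.  The search targets the differential
stability elements (DEPCs): find the minimum number of DEPCs whose combined
perturbation achieves the transition, cover those circuits with as few genes
as possible (branching on ties to collect every alternative), then prune
genes made redundant by circuits that are regulated by other circuits.
Every step is validated by simulating the synchronous dynamics under the
perturbation, so an emitted combination is a certified reprogramming
protocol of the Boolean model, not a topological guess.

Perturbations are transient clamps by default: each target gene is held at
its final-attractor value until the clamped system settles, the clamp is
released, and the transition counts only if the free dynamics then rests in
the final attractor — mirroring a reprogramming cocktail that is applied and
withdrawn.  ``permanent_clamp=True`` keeps the clamp on and compares the
clamped steady state instead.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .attractors import Attractor, enumerate_attractors, match_attractors_to_profiles
from .circuits import Circuit, enumerate_elementary_circuits
from .depc import DEPC, detect_depcs
from .dynamics import BooleanDynamics, simulate_to_attractor
from .network import ExpressionProfilePair, SignedNetwork


class TransitionUnreachableError(RuntimeError):
    """No DEPC subset of any size achieved the transition.

    Carries the best partial match (closest final state reached) for
    diagnosis.
    """

    def __init__(self, message: str, best_state=None, best_match: float = 0.0):
        super().__init__(message)
        self.best_state = best_state
        self.best_match = best_match


@dataclass(frozen=True)
class TransitionSpec:
    """Ordered attractor pair: where the cell is and where it should go."""

    initial: Attractor
    final: Attractor

    def __post_init__(self) -> None:
        if self.initial.bits == self.final.bits:
            raise ValueError("initial and final attractors must differ")

    def clamp_value(self, gene: str) -> int:
        return self.final[gene]


@dataclass(frozen=True)
class RDCombination:
    """A validated minimal set of reprogramming determinants.

    ``clamps`` maps each gene to its final-attractor value (the direction of
    the required stimulus); ``covered_depcs`` are the ids of the transition's
    DEPCs containing at least one of the genes.
    """

    genes: FrozenSet[str]
    clamps: Tuple[Tuple[str, int], ...]
    covered_depcs: Tuple[int, ...]
    validated: bool

    def clamp_dict(self) -> Dict[str, int]:
        return dict(self.clamps)

    def stimulus(self) -> Dict[str, str]:
        return {g: ("activate" if v else "repress") for g, v in self.clamps}


def verify_transition(
    network: SignedNetwork,
    transition: TransitionSpec,
    clamps: Dict[str, int],
    step_cap: int = 1000,
    permanent_clamp: bool = False,
    dynamics: Optional[BooleanDynamics] = None,
) -> bool:
    """Simulate the perturbation and check it lands in the final attractor.

    Phase 1 runs from the initial attractor with ``clamps`` held until the
    clamped system reaches a fixed point; phase 2 releases the clamps and
    lets the free dynamics settle.  True iff phase 2 rests exactly in the
    final attractor.  Cycles or exhausted step budgets in either phase fail.
    With ``permanent_clamp`` the clamped steady state itself is compared.
    """
    dyn = dynamics or BooleanDynamics(network)
    traj = simulate_to_attractor(
        network, transition.initial.state, clamp=clamps, step_cap=step_cap, dynamics=dyn
    )
    if traj.terminal != "fixed_point":
        return False
    if permanent_clamp:
        return traj.final_state == transition.final.bits
    free = simulate_to_attractor(
        network, traj.final_dict(), clamp=None, step_cap=step_cap, dynamics=dyn
    )
    return free.terminal == "fixed_point" and free.final_state == transition.final.bits


def _final_match(state: Tuple[int, ...], final: Attractor) -> float:
    return sum(1 for a, b in zip(state, final.bits) if a == b) / len(state)


def _clamps_for_genes(genes: Sequence[str], transition: TransitionSpec) -> Dict[str, int]:
    return {g: transition.clamp_value(g) for g in genes}


def minimal_depc_sets(
    network: SignedNetwork,
    transition: TransitionSpec,
    depcs: Sequence[DEPC],
    step_cap: int = 1000,
    permanent_clamp: bool = False,
    max_size: Optional[int] = None,
    dynamics: Optional[BooleanDynamics] = None,
) -> List[Tuple[int, ...]]:
    """All minimum-cardinality DEPC subsets whose full perturbation succeeds.

    Subsets are searched by increasing size; clamping every gene of every
    circuit in a subset (to final-attractor values) is the feasibility test.
    Returns the successful subsets of the first size at which any succeeds,
    as tuples of indices into ``depcs``.  Raises
    :class:`TransitionUnreachableError` if no subset of any admissible size
    works, reporting the closest final state reached.
    """
    if not depcs:
        raise ValueError("no DEPCs supplied")
    dyn = dynamics or BooleanDynamics(network)
    limit = len(depcs) if max_size is None else min(max_size, len(depcs))
    for k in range(1, limit + 1):
        hits: List[Tuple[int, ...]] = []
        for combo in itertools.combinations(range(len(depcs)), k):
            genes: Set[str] = set()
            for i in combo:
                genes.update(depcs[i].genes)
            clamps = _clamps_for_genes(sorted(genes), transition)
            if verify_transition(
                network, transition, clamps, step_cap, permanent_clamp, dyn
            ):
                hits.append(combo)
        if hits:
            return hits
    # diagnosis pass: how close did single-circuit perturbations get?
    best_state, best_match = None, -1.0
    for d in depcs:
        clamps = _clamps_for_genes(sorted(set(d.genes)), transition)
        traj = simulate_to_attractor(
            network, transition.initial.state, clamp=clamps,
            step_cap=step_cap, dynamics=dyn,
        )
        m = _final_match(traj.final_state, transition.final)
        if m > best_match:
            best_state, best_match = traj.final_state, m
    raise TransitionUnreachableError(
        f"no DEPC subset (size <= {limit}) achieves the transition; "
        f"best partial match {best_match:.2f} of final-attractor genes",
        best_state=best_state,
        best_match=max(best_match, 0.0),
    )


def minimal_gene_combinations(
    depc_sets: Sequence[Sequence[DEPC]],
    max_branches: Optional[int] = 10_000,
) -> List[FrozenSet[str]]:
    """Greedy one-gene-per-circuit covers of each minimal DEPC set.

    Repeatedly picks the gene present in the most still-untargeted circuits;
    ties split the computation into branches, one per tied gene, so every
    alternative cover the greedy heuristic can reach is collected.  Results
    from all sets and branches are deduplicated and ordered (size, then
    lexicographic).
    """
    if not depc_sets:
        raise ValueError("no DEPC sets supplied")
    results: Set[FrozenSet[str]] = set()

    for depc_set in depc_sets:
        gene_lists = [tuple(d.genes) for d in depc_set]

        def rec(untargeted: FrozenSet[int], chosen: FrozenSet[str]) -> None:
            if not untargeted:
                results.add(chosen)
                return
            if max_branches is not None and len(results) >= max_branches:
                return
            counts = Counter(g for i in untargeted for g in set(gene_lists[i]))
            top = max(counts.values())
            for g in sorted(g for g, c in counts.items() if c == top):
                rec(
                    frozenset(i for i in untargeted if g not in gene_lists[i]),
                    chosen | {g},
                )

        rec(frozenset(range(len(gene_lists))), frozenset())

    return sorted(results, key=lambda s: (len(s), tuple(sorted(s))))


def prune_redundant_targets(
    network: SignedNetwork,
    transition: TransitionSpec,
    genes: Sequence[str],
    step_cap: int = 1000,
    permanent_clamp: bool = False,
    dynamics: Optional[BooleanDynamics] = None,
) -> FrozenSet[str]:
    """Drop clamps that the remaining ones make unnecessary.

    Genes are tried in ascending lexicographic order; a gene whose removal
    leaves the transition successful is dropped permanently, and the sweep
    repeats until no single removal succeeds.  Targets inside circuits that
    are slaved to other perturbed circuits disappear here.  The input
    combination must itself pass :func:`verify_transition`.
    """
    dyn = dynamics or BooleanDynamics(network)
    current = sorted(set(genes))
    if not verify_transition(
        network, transition, _clamps_for_genes(current, transition),
        step_cap, permanent_clamp, dyn,
    ):
        raise ValueError("combination does not achieve the transition; nothing to prune")
    changed = True
    while changed and len(current) > 1:
        changed = False
        for g in list(current):
            trial = [x for x in current if x != g]
            if verify_transition(
                network, transition, _clamps_for_genes(trial, transition),
                step_cap, permanent_clamp, dyn,
            ):
                current = trial
                changed = True
    return frozenset(current)


def _minimalize(
    network: SignedNetwork,
    transition: TransitionSpec,
    genes: FrozenSet[str],
    step_cap: int,
    permanent_clamp: bool,
    dyn: BooleanDynamics,
    subset_limit: int = 5,
) -> List[FrozenSet[str]]:
    """Replace a combination by its minimal successful subsets.

    Clamped dynamics are not monotone in the clamp set, so single-gene
    pruning alone cannot certify that no smaller subset works; for small
    combinations every proper subset is checked exhaustively.
    """
    if len(genes) > subset_limit:
        return [genes]
    ordered = sorted(genes)
    passing: List[FrozenSet[str]] = []
    for k in range(1, len(ordered)):
        for sub in itertools.combinations(ordered, k):
            if verify_transition(
                network, transition, _clamps_for_genes(sub, transition),
                step_cap, permanent_clamp, dyn,
            ):
                fs = frozenset(sub)
                if not any(p < fs for p in passing):
                    passing.append(fs)
    return passing if passing else [genes]


def find_reprogramming_determinants(
    network: SignedNetwork,
    profiles: Optional[ExpressionProfilePair] = None,
    transition: Optional[TransitionSpec] = None,
    attractor_mode: str = "auto",
    step_cap: int = 1000,
    circuit_cap: Optional[int] = 100_000,
    permanent_clamp: bool = False,
    max_depc_set_size: Optional[int] = None,
    max_branches: Optional[int] = 10_000,
    circuits: Optional[Sequence[Circuit]] = None,
) -> List[RDCombination]:
    """Full pipeline: attractors → circuits → DEPCs → minimal validated RDs.

    The transition is given either directly or through a phenotype profile
    pair (the best-matching attractor pair is used).  Returns every
    alternative validated minimal combination, ordered by size then
    lexicographically.  If no greedy gene cover passes simulation, the full
    gene set of a successful minimal DEPC subset is pruned down instead, so
    a validated combination is returned whenever some DEPC subset works.
    """
    dyn = BooleanDynamics(network)
    if transition is None:
        if profiles is None:
            raise ValueError("either profiles or an explicit transition is required")
        profiles.check_against(network)
        attractors = enumerate_attractors(network, mode=attractor_mode, dynamics=dyn)
        a_i, a_f, _score = match_attractors_to_profiles(attractors, profiles)
        transition = TransitionSpec(a_i, a_f)
    if circuits is None:
        circuits = enumerate_elementary_circuits(network, cap=circuit_cap)
    depcs = detect_depcs(network, circuits, transition.initial, transition.final)
    if not depcs:
        raise TransitionUnreachableError(
            "no DEPC exists between the two attractors; the transition has no "
            "differential stability element to target"
        )
    depc_sets_idx = minimal_depc_sets(
        network, transition, depcs, step_cap, permanent_clamp,
        max_size=max_depc_set_size, dynamics=dyn,
    )
    depc_sets = [[depcs[i] for i in idx] for idx in depc_sets_idx]
    candidates = minimal_gene_combinations(depc_sets, max_branches=max_branches)

    validated: Set[FrozenSet[str]] = set()
    for cand in candidates:
        clamps = _clamps_for_genes(sorted(cand), transition)
        if verify_transition(network, transition, clamps, step_cap, permanent_clamp, dyn):
            pruned = prune_redundant_targets(
                network, transition, sorted(cand), step_cap, permanent_clamp, dyn
            )
            for minimal in _minimalize(
                network, transition, pruned, step_cap, permanent_clamp, dyn
            ):
                validated.add(minimal)
    if not validated:
        # greedy covers all failed: fall back to the full gene sets of the
        # successful DEPC subsets and prune them down
        for depc_set in depc_sets:
            genes: Set[str] = set()
            for d in depc_set:
                genes.update(d.genes)
            pruned = prune_redundant_targets(
                network, transition, sorted(genes), step_cap, permanent_clamp, dyn
            )
            for minimal in _minimalize(
                network, transition, pruned, step_cap, permanent_clamp, dyn
            ):
                validated.add(minimal)

    # keep only inclusion-minimal combinations across alternatives
    final_sets = [
        s for s in validated if not any(o < s for o in validated if o != s)
    ]
    out: List[RDCombination] = []
    for s in sorted(final_sets, key=lambda s: (len(s), tuple(sorted(s)))):
        clamps = tuple(sorted(_clamps_for_genes(sorted(s), transition).items()))
        covered = tuple(i for i, d in enumerate(depcs) if set(d.genes) & s)
        out.append(RDCombination(s, clamps, covered, validated=True))
    return out
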