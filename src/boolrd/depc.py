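"""Differentially expressed positive circuits (DEPCs).

A positive circuit is a DEPC for an ordered attractor pair when (i) every
one of its genes changes value between the two attractors, and (ii) the
circuit's restricted states in both attractors are fixed points of the
circuit considered in isolation (only the ring edges, each node read off its
single upstream ring neighbor).  Such circuits are the stability elements
that hold each phenotype in place, so they are the targets whose
perturbation can carry the network across the barrier between attractors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

from .attractors import Attractor
from .circuits import Circuit
from .network import ACTIVATION, SignedNetwork


def ring_fixed_points(circuit: Circuit) -> Set[Tuple[int, ...]]:
    """Fixed points of a circuit in isolation, as tuples over ``circuit.nodes``.

    On the isolated ring each node copies (activation) or negates
    (inhibition) its upstream neighbor, so a state is fixed iff it is
    consistent along every edge and around the closure.  Positive circuits
    have exactly two such states (mutual complements); negative circuits
    have none.  An activating self-loop yields {(0,), (1,)}, an inhibiting
    one the empty set.
    """
    n = len(circuit.nodes)
    out: Set[Tuple[int, ...]] = set()
    for first in (0, 1):
        state = [first]
        ok = True
        for k in range(n):
            nxt = state[k] if circuit.signs[k] == ACTIVATION else 1 - state[k]
            if k == n - 1:
                if nxt != state[0]:
                    ok = False
            else:
                state.append(nxt)
        if ok:
            out.add(tuple(state))
    return out


@dataclass(frozen=True)
class DEPC:
    """A positive circuit differentially expressed between two attractors."""

    circuit: Circuit
    state_initial: Tuple[int, ...]  # aligned with circuit.nodes
    state_final: Tuple[int, ...]

    @property
    def genes(self) -> Tuple[str, ...]:
        return self.circuit.nodes

    def initial_dict(self) -> Dict[str, int]:
        return dict(zip(self.circuit.nodes, self.state_initial))

    def final_dict(self) -> Dict[str, int]:
        return dict(zip(self.circuit.nodes, self.state_final))


def detect_depcs(
    network: SignedNetwork,
    circuits: Sequence[Circuit],
    attractor_initial: Attractor,
    attractor_final: Attractor,
) -> List[DEPC]:
    """All DEPCs of ``circuits`` for the ordered attractor pair.

    Circuits are screened in their deterministic enumeration order; a
    circuit qualifies iff it is positive, all its nodes differ between the
    attractors, and both restricted states are isolated-ring fixed points.
    """
    if attractor_initial.bits == attractor_final.bits:
        raise ValueError(
            "identical initial and final attractors: no differential expression"
        )
    init = attractor_initial.state
    fin = attractor_final.state
    out: List[DEPC] = []
    for c in circuits:
        if not c.is_positive:
            continue
        if not all(init[g] != fin[g] for g in c.nodes):
            continue
        fps = ring_fixed_points(c)
        s_i = tuple(init[g] for g in c.nodes)
        s_f = tuple(fin[g] for g in c.nodes)
        if s_i in fps and s_f in fps:
            out.append(DEPC(c, s_i, s_f))
    return out
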