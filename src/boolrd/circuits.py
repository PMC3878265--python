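"""Elementary circuit detection and sign classification.

An elementary circuit is a directed cycle in which no node repeats except
the implicit closure; self-loops count as length-1 circuits.  A circuit is
*positive* iff it contains an even number of inhibitory edges — the parity
rule under which a double-negative toggle switch is positive.  Positive
circuits are the necessary stability elements for multistability; negative
circuits drive oscillations.

Enumeration delegates to Johnson's algorithm (:func:`networkx.simple_cycles`,
which emits self-loops); results are rotation-canonicalized and ordered
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice
from typing import Iterable, List, Optional, Sequence, Tuple

import networkx as nx

from .network import INHIBITION, SignedNetwork


class CircuitExplosionError(RuntimeError):
    """More elementary circuits than the configured cap."""


@dataclass(frozen=True)
class Circuit:
    """An elementary cycle with its edge signs.

    ``nodes`` is rotated to start at the lexicographically smallest member;
    ``signs[k]`` is the sign of the edge from ``nodes[k]`` to
    ``nodes[(k+1) % len]``.  A self-loop has one node and one sign.
    """

    nodes: Tuple[str, ...]
    signs: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.signs) or not self.nodes:
            raise ValueError("circuit needs one sign per node (closing edge included)")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("elementary circuit cannot repeat a node")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def edges(self) -> Tuple[Tuple[str, str, int], ...]:
        n = len(self.nodes)
        return tuple(
            (self.nodes[k], self.nodes[(k + 1) % n], self.signs[k]) for k in range(n)
        )

    @property
    def n_inhibitions(self) -> int:
        return sum(1 for s in self.signs if s == INHIBITION)

    @property
    def sign(self) -> str:
        return "positive" if self.n_inhibitions % 2 == 0 else "negative"

    @property
    def is_positive(self) -> bool:
        return self.n_inhibitions % 2 == 0


def circuit_sign(circuit: Circuit) -> str:
    """``positive`` iff the number of inhibitory edges is even."""
    return circuit.sign


def _canonical(cycle: Sequence[str], network: SignedNetwork) -> Circuit:
    """Rotate a node cycle to start at its smallest node and attach signs."""
    k = min(range(len(cycle)), key=lambda i: cycle[i])
    nodes = tuple(cycle[k:]) + tuple(cycle[:k])
    n = len(nodes)
    signs = tuple(network.sign(nodes[i], nodes[(i + 1) % n]) for i in range(n))
    return Circuit(nodes, signs)


def enumerate_elementary_circuits(
    network: SignedNetwork, cap: Optional[int] = 100_000
) -> List[Circuit]:
    """All elementary circuits of the signed digraph, self-loops included.

    Deterministic order: by length, then by node sequence.  Raises
    :class:`CircuitExplosionError` when more than ``cap`` circuits exist
    (combinatorial blow-up guard); ``cap=None`` disables the guard.
    """
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from((u, v) for u, v, _ in network.edges)
    it = nx.simple_cycles(g)
    if cap is None:
        raw = list(it)
    else:
        raw = list(islice(it, cap + 1))
        if len(raw) > cap:
            raise CircuitExplosionError(
                f"network has more than {cap} elementary circuits; "
                f"raise the cap or reduce the network"
            )
    circuits = {_canonical(c, network) for c in raw}
    return sorted(circuits, key=lambda c: (len(c), c.nodes))


def circuits_through(circuits: Iterable[Circuit], node: str) -> List[Circuit]:
    return [c for c in circuits if node in c.nodes]


def filter_mirnas(
    network: SignedNetwork,
    candidate_mirna_edges: Iterable[Tuple[str, str, int]] = (),
    cap: Optional[int] = 100_000,
) -> SignedNetwork:
    """Keep a miRNA only if it lies on at least one positive circuit.

    ``candidate_mirna_edges`` (miRNA regulators/targets from interaction
    databases) are first merged into the network; any new endpoint whose
    name looks miRNA-like is marked as such.  A miRNA that sits on no
    elementary circuit at all (missing incoming or outgoing links) or only
    on negative circuits is removed together with its edges: negative
    feedback through an unmeasured miRNA would only add poorly constrained
    oscillatory dynamics to the Boolean model.
    """
    augmented = network.copy()
    for u, v, s in candidate_mirna_edges:
        augmented.add_edge(u, v, s)
    mirnas = set(augmented.mirnas())
    if not mirnas:
        return augmented
    circuits = enumerate_elementary_circuits(augmented, cap=cap)
    stabilizing = set()
    for c in circuits:
        if c.is_positive:
            stabilizing.update(set(c.nodes) & mirnas)
    keep = [n for n in augmented.nodes if n not in mirnas or n in stabilizing]
    return augmented.subnetwork(keep)
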