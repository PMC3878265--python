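"""Signed Boolean gene regulatory network model.

A GRN is a directed graph whose edges carry a sign: ``+1`` for activation,
``-1`` for inhibition.  Nodes are genes or miRNAs.  States are total 0/1
assignments; the update rule is inhibitor-dominant (see :mod:`boolrd.dynamics`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, Mapping, Optional, Tuple

import networkx as nx

ACTIVATION = 1
INHIBITION = -1

_MIRNA_RE = re.compile(r"^(hsa-)?(mir|let)[-0-9]", re.IGNORECASE)


class NetworkFormatError(ValueError):
    """Malformed network/profile input (bad row, contradictory edge...)."""


class ConflictingEdgeError(NetworkFormatError):
    """The same ordered (source, target) pair declared with both signs."""


def infer_kind(name: str) -> str:
    """Guess node kind from its name: ``mirna`` for miRNA-style names, else ``gene``."""
    return "mirna" if _MIRNA_RE.match(name) else "gene"


class SignedNetwork:
    """Directed graph with signed edges and gene/miRNA node kinds.

    At most one edge per ordered (source, target) pair; re-adding an edge
    with the opposite sign raises :class:`ConflictingEdgeError`.  Self-loops
    are permitted.
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()

    # -- construction -----------------------------------------------------

    def add_node(self, name: str, kind: Optional[str] = None) -> None:
        if kind is None:
            kind = self._g.nodes[name]["kind"] if name in self._g else infer_kind(name)
        elif kind not in ("gene", "mirna"):
            raise ValueError(f"unknown node kind {kind!r}")
        self._g.add_node(name, kind=kind)

    def add_edge(self, source: str, target: str, sign: int) -> None:
        if sign not in (ACTIVATION, INHIBITION):
            raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
        if self._g.has_edge(source, target):
            old = self._g[source][target]["sign"]
            if old != sign:
                raise ConflictingEdgeError(
                    f"contradictory duplicate edge ({source}, {target}): "
                    f"declared with both signs"
                )
            return
        for n in (source, target):
            if n not in self._g:
                self.add_node(n)
        self._g.add_edge(source, target, sign=sign)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[str, str, int]],
        nodes: Iterable[str] = (),
        kinds: Optional[Mapping[str, str]] = None,
    ) -> "SignedNetwork":
        net = cls()
        for n in nodes:
            net.add_node(n, (kinds or {}).get(n))
        for u, v, s in edges:
            net.add_edge(u, v, s)
        if kinds:
            for n, k in kinds.items():
                if n in net:
                    net.add_node(n, k)
        return net

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> Tuple[str, ...]:
        """Node names in sorted order (the canonical state-vector order)."""
        return tuple(sorted(self._g.nodes))

    @property
    def edges(self) -> Tuple[Tuple[str, str, int], ...]:
        return tuple(
            sorted((u, v, d["sign"]) for u, v, d in self._g.edges(data=True))
        )

    def kind(self, name: str) -> str:
        return self._g.nodes[name]["kind"]

    def mirnas(self) -> Tuple[str, ...]:
        return tuple(n for n in self.nodes if self.kind(n) == "mirna")

    def __contains__(self, name: str) -> bool:
        return name in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return (
            f"<SignedNetwork {self._g.number_of_nodes()} nodes, "
            f"{self._g.number_of_edges()} edges>"
        )

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_edge(self, source: str, target: str) -> bool:
        return self._g.has_edge(source, target)

    def sign(self, source: str, target: str) -> int:
        return self._g[source][target]["sign"]

    def activators(self, node: str) -> Tuple[str, ...]:
        return tuple(
            sorted(u for u in self._g.predecessors(node) if self._g[u][node]["sign"] == ACTIVATION)
        )

    def inhibitors(self, node: str) -> Tuple[str, ...]:
        return tuple(
            sorted(u for u in self._g.predecessors(node) if self._g[u][node]["sign"] == INHIBITION)
        )

    def in_degree(self, node: str) -> int:
        return self._g.in_degree(node)

    def graph(self) -> nx.DiGraph:
        """The underlying networkx DiGraph (a copy; mutations do not propagate)."""
        return self._g.copy()

    # -- derived networks --------------------------------------------------

    def copy(self) -> "SignedNetwork":
        net = SignedNetwork()
        net._g = self._g.copy()
        return net

    def subnetwork(self, nodes: Iterable[str]) -> "SignedNetwork":
        """Induced subgraph on ``nodes`` (all internal edges, signs kept)."""
        keep = set(nodes)
        missing = keep - set(self._g.nodes)
        if missing:
            raise KeyError(f"nodes not in network: {sorted(missing)}")
        net = SignedNetwork()
        net._g = self._g.subgraph(keep).copy()
        return net

    def without_edges(self, edges: Iterable[Tuple[str, str]]) -> "SignedNetwork":
        net = self.copy()
        for u, v in edges:
            if net._g.has_edge(u, v):
                net._g.remove_edge(u, v)
        return net


def prune_unregulated(network: SignedNetwork) -> SignedNetwork:
    """Iteratively remove nodes without incoming edges.

    Returns the maximal subnetwork in which every node has in-degree >= 1
    (possibly empty).  The input network is left untouched.  Removing a node
    can strip its targets of their last regulator, so removal iterates to a
    fixed point.
    """
    g = network._g.copy()
    while True:
        dead = [n for n, d in g.in_degree() if d == 0]
        if not dead:
            break
        g.remove_nodes_from(dead)
    net = SignedNetwork()
    net._g = g
    return net


BooleanState = Dict[str, int]
"""Total assignment node name -> {0, 1}."""


def state_tuple(network: SignedNetwork, state: Mapping[str, int]) -> Tuple[int, ...]:
    """State as a bit tuple in the network's sorted node order."""
    return tuple(int(state[n]) for n in network.nodes)


def state_dict(network: SignedNetwork, bits: Iterable[int]) -> BooleanState:
    nodes = network.nodes
    bits = tuple(bits)
    if len(bits) != len(nodes):
        raise ValueError(f"state has {len(bits)} bits for {len(nodes)} nodes")
    return {n: int(b) for n, b in zip(nodes, bits)}


@dataclass(frozen=True)
class ExpressionProfilePair:
    """Binarized expression of the initial and final phenotypes.

    Both profiles are partial maps over the same measured gene set (miRNAs
    are typically unmeasured).  Values are already thresholded to {0, 1}.
    """

    initial: Mapping[str, int]
    final: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.initial) != set(self.final):
            raise ValueError("initial and final profiles must share the same measured genes")
        for prof in (self.initial, self.final):
            bad = {g: v for g, v in prof.items() if v not in (0, 1)}
            if bad:
                raise ValueError(f"profile values must be 0/1, got {bad}")

    @property
    def measured(self) -> Tuple[str, ...]:
        return tuple(sorted(self.initial))

    def restricted_to(self, network: SignedNetwork) -> "ExpressionProfilePair":
        keep = [g for g in self.initial if g in network]
        return ExpressionProfilePair(
            initial={g: self.initial[g] for g in keep},
            final={g: self.final[g] for g in keep},
        )

    def check_against(self, network: SignedNetwork) -> None:
        missing = set(self.initial) - set(network.nodes)
        if missing:
            raise ValueError(f"measured genes absent from network: {sorted(missing)}")
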