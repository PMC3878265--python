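"""Synchronous Boolean dynamics under the inhibitor-dominant rule.

A gene becomes active iff none of its inhibitors is active and its activator
requirement holds: at least one activator active, or — for genes regulated
only by inhibitors — vacuously (the *default-ON* convention, which preserves
the bistability of inhibition-dominated networks such as double-negative
toggle switches).  Setting ``default_on=False`` restores the literal rule in
which a gene with no active activator is always inactive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .network import BooleanState, SignedNetwork


class UnregulatedNodeError(ValueError):
    """A node without regulators reached the update rule in strict mode."""


class BooleanDynamics:
    """Compiled synchronous update map for a :class:`SignedNetwork`.

    Precomputes per-node activator/inhibitor index lists over the sorted
    node order so that stepping a state is a tight loop.  States are bit
    tuples in that order.
    """

    def __init__(self, network: SignedNetwork, default_on: bool = True, strict: bool = False):
        self.network = network
        self.default_on = default_on
        self.nodes: Tuple[str, ...] = network.nodes
        self.index: Dict[str, int] = {n: i for i, n in enumerate(self.nodes)}
        self.act: List[Tuple[int, ...]] = []
        self.inh: List[Tuple[int, ...]] = []
        for n in self.nodes:
            a = tuple(self.index[u] for u in network.activators(n))
            i = tuple(self.index[u] for u in network.inhibitors(n))
            if strict and not a and not i and not default_on:
                raise UnregulatedNodeError(
                    f"node {n!r} has no regulators; prune unregulated nodes or "
                    f"enable the default-ON convention"
                )
            self.act.append(a)
            self.inh.append(i)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def update_node(self, state: Sequence[int], i: int) -> int:
        """Next value of node ``i`` given the full current ``state``."""
        for j in self.inh[i]:
            if state[j]:
                return 0
        acts = self.act[i]
        if acts:
            for j in acts:
                if state[j]:
                    return 1
            return 0
        return 1 if self.default_on else 0

    def step(self, state: Sequence[int]) -> Tuple[int, ...]:
        """One synchronous step: every node updated from the same input state."""
        return tuple(self.update_node(state, i) for i in range(self.n))

    def step_clamped(
        self, state: Sequence[int], clamp: Mapping[int, int]
    ) -> Tuple[int, ...]:
        nxt = list(self.step(state))
        for i, v in clamp.items():
            nxt[i] = v
        return tuple(nxt)

    def is_fixed_point(self, state: Sequence[int]) -> bool:
        return self.step(state) == tuple(state)

    def to_dict(self, state: Sequence[int]) -> BooleanState:
        return {n: int(b) for n, b in zip(self.nodes, state)}

    def to_tuple(self, state: Mapping[str, int]) -> Tuple[int, ...]:
        return tuple(int(state[n]) for n in self.nodes)


def boolean_update(
    network: SignedNetwork,
    state: Mapping[str, int],
    node: str,
    default_on: bool = True,
    strict: bool = False,
) -> int:
    """Inhibitor-dominant update of a single node.

    Returns 1 iff no inhibitor of ``node`` is active in ``state`` and the
    activator clause holds (some activator active, or no activators under
    the default-ON convention).
    """
    if node not in network:
        raise KeyError(node)
    acts = network.activators(node)
    inhs = network.inhibitors(node)
    if not acts and not inhs and strict and not default_on:
        raise UnregulatedNodeError(f"node {node!r} has no incoming edges (unpruned input node)")
    if any(state[u] for u in inhs):
        return 0
    if acts:
        return 1 if any(state[u] for u in acts) else 0
    return 1 if default_on else 0


def synchronous_step(
    network: SignedNetwork, state: Mapping[str, int], default_on: bool = True
) -> BooleanState:
    """Update every node simultaneously from the same input state."""
    dyn = BooleanDynamics(network, default_on=default_on)
    return dyn.to_dict(dyn.step(dyn.to_tuple(state)))


@dataclass(frozen=True)
class Trajectory:
    """Synchronous trajectory: visited states and how it ended.

    ``terminal`` is ``fixed_point`` when the last state maps to itself (under
    the clamp, if any), ``cycle`` when the successor of the last state was
    visited earlier, and ``step_cap`` when the step budget ran out.
    """

    states: Tuple[Tuple[int, ...], ...]
    terminal: str  # fixed_point | cycle | step_cap
    nodes: Tuple[str, ...]

    @property
    def final_state(self) -> Tuple[int, ...]:
        return self.states[-1]

    def final_dict(self) -> BooleanState:
        return {n: int(b) for n, b in zip(self.nodes, self.final_state)}


def simulate_to_attractor(
    network: SignedNetwork,
    start: Mapping[str, int],
    clamp: Optional[Mapping[str, int]] = None,
    step_cap: int = 1000,
    default_on: bool = True,
    dynamics: Optional[BooleanDynamics] = None,
) -> Trajectory:
    """Run the synchronous dynamics from ``start`` until it settles.

    Clamped nodes are held at their clamp value throughout (including in the
    start state).  Stops at a fixed point of the clamped system, at the first
    revisit of an earlier state (a cycle), or after ``step_cap`` steps.
    """
    dyn = dynamics or BooleanDynamics(network, default_on=default_on)
    clamp_idx: Dict[int, int] = {}
    if clamp:
        for name, v in clamp.items():
            if name not in dyn.index:
                raise KeyError(f"clamped node {name!r} not in network")
            clamp_idx[dyn.index[name]] = int(v)
    state = list(dyn.to_tuple(start))
    for i, v in clamp_idx.items():
        state[i] = v
    state = tuple(state)

    seen = {state: 0}
    states = [state]
    for _ in range(step_cap):
        nxt = dyn.step_clamped(state, clamp_idx) if clamp_idx else dyn.step(state)
        if nxt == state:
            return Trajectory(tuple(states), "fixed_point", dyn.nodes)
        if nxt in seen:
            states.append(nxt)
            return Trajectory(tuple(states), "cycle", dyn.nodes)
        seen[nxt] = len(states)
        states.append(nxt)
        state = nxt
    return Trajectory(tuple(states), "step_cap", dyn.nodes)
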