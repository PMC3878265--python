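"""Fixed-point attractor enumeration for synchronous Boolean GRNs.

Only fixed points are enumerated: a stable cellular phenotype is identified
with a steady state of the synchronous dynamics, and transitions involving
cyclic attractors are out of scope.  Two complete strategies are provided —
vectorized exhaustive scan of all 2^n states for small networks, and
depth-first constraint backtracking for larger ones — and their equivalence
on small networks is a tested property.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .dynamics import BooleanDynamics
from .network import BooleanState, ExpressionProfilePair, SignedNetwork

EXHAUSTIVE_LIMIT = 25  # 2^n state scans beyond this are refused


class TooManyNodesError(ValueError):
    """Exhaustive enumeration requested above the 2^n scan limit."""


@dataclass(frozen=True)
class Attractor:
    """A fixed point of the synchronous dynamics.

    ``bits`` is the state in sorted-node order; ``id`` is the rank of the
    state vector in lexicographic order over all attractors of the network,
    so ids are stable across runs.
    """

    id: int
    nodes: Tuple[str, ...]
    bits: Tuple[int, ...]

    @property
    def state(self) -> BooleanState:
        return {n: int(b) for n, b in zip(self.nodes, self.bits)}

    def __getitem__(self, node: str) -> int:
        return self.bits[self.nodes.index(node)]

    def restrict(self, names: Sequence[str]) -> Tuple[int, ...]:
        idx = {n: i for i, n in enumerate(self.nodes)}
        return tuple(self.bits[idx[n]] for n in names)


def _exhaustive_fixed_points(dyn: BooleanDynamics) -> List[Tuple[int, ...]]:
    """Scan all 2^n states with vectorized updates (chunked)."""
    n = dyn.n
    if n == 0:
        return [()]
    act = np.zeros((n, n), dtype=np.float32)
    inh = np.zeros((n, n), dtype=np.float32)
    has_act = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in dyn.act[i]:
            act[i, j] = 1.0
        for j in dyn.inh[i]:
            inh[i, j] = 1.0
        has_act[i] = bool(dyn.act[i])
    noact_default = (~has_act) & dyn.default_on

    found: List[Tuple[int, ...]] = []
    total = 1 << n
    chunk = min(total, 1 << 18)
    # bit j of the state integer holds node j (little-endian)
    weights = (1 << np.arange(n)).astype(np.int64)
    for lo in range(0, total, chunk):
        codes = np.arange(lo, min(lo + chunk, total), dtype=np.int64)
        S = ((codes[:, None] & weights[None, :]) > 0).astype(np.float32)
        inh_hit = S @ inh.T > 0.5
        act_hit = S @ act.T > 0.5
        nxt = (~inh_hit) & (act_hit | noact_default[None, :])
        fixed = np.all(nxt == (S > 0.5), axis=1)
        for row in S[fixed]:
            found.append(tuple(int(b) for b in row))
    return found


def _backtracking_fixed_points(dyn: BooleanDynamics) -> List[Tuple[int, ...]]:
    """Complete DFS over node assignments with constraint propagation.

    One constraint per node v: s[v] must equal the inhibitor-dominant update
    of v.  Partial assignments are pruned as soon as a constraint becomes
    unsatisfiable; at a full assignment the checks are exact, so the search
    returns exactly the fixed points.
    """
    n = dyn.n
    if n == 0:
        return [()]
    cons_vars = [frozenset((v,) + dyn.act[v] + dyn.inh[v]) for v in range(n)]
    cons_of_var: List[List[int]] = [[] for _ in range(n)]
    for c, vs in enumerate(cons_vars):
        for x in vs:
            cons_of_var[x].append(c)

    # assignment order: greedily pick the variable completing the most
    # constraints, to trigger exact checks as early as possible
    remaining = [len(vs) for vs in cons_vars]
    assigned = [False] * n
    order: List[int] = []
    for _ in range(n):
        best, best_key = -1, None
        for x in range(n):
            if assigned[x]:
                continue
            completes = sum(1 for c in cons_of_var[x] if remaining[c] == 1)
            nearly = sum(1 for c in cons_of_var[x] if remaining[c] == 2)
            key = (completes, nearly, len(cons_of_var[x]), -x)
            if best_key is None or key > best_key:
                best, best_key = x, key
        order.append(best)
        assigned[best] = True
        for c in cons_of_var[best]:
            remaining[c] -= 1

    s = [-1] * n
    default_on = dyn.default_on
    act, inh = dyn.act, dyn.inh
    out: List[Tuple[int, ...]] = []

    def consistent(v: int) -> bool:
        sv = s[v]
        if sv == -1:
            return True
        if sv == 1:
            for j in inh[v]:
                if s[j] == 1:
                    return False
            a = act[v]
            if a:
                if all(s[j] == 0 for j in a):
                    return False
            elif not default_on:
                return False
        else:
            if all(s[j] == 0 for j in inh[v]):  # all inhibitors known OFF
                a = act[v]
                if not a:
                    if default_on:
                        return False
                elif any(s[j] == 1 for j in a):
                    return False
        return True

    def dfs(depth: int) -> None:
        if depth == n:
            out.append(tuple(s))
            return
        x = order[depth]
        for b in (0, 1):
            s[x] = b
            if all(consistent(c) for c in cons_of_var[x]):
                dfs(depth + 1)
        s[x] = -1

    dfs(0)
    return out


def enumerate_attractors(
    network: SignedNetwork,
    mode: str = "auto",
    default_on: bool = True,
    dynamics: Optional[BooleanDynamics] = None,
) -> List[Attractor]:
    """All fixed points of the synchronous dynamics, in lexicographic order.

    ``mode`` is ``exhaustive`` (scan all 2^n states; refused above
    25 nodes), ``backtracking`` (constraint DFS, any size), or ``auto``
    (exhaustive up to 20 nodes, backtracking beyond).  Both modes are
    complete; ids index the lexicographically sorted state vectors.
    """
    dyn = dynamics or BooleanDynamics(network, default_on=default_on)
    n = dyn.n
    if mode == "auto":
        mode = "exhaustive" if n <= 20 else "backtracking"
    if mode == "exhaustive":
        if n > EXHAUSTIVE_LIMIT:
            raise TooManyNodesError(
                f"{n} nodes exceeds the exhaustive 2^n scan limit "
                f"({EXHAUSTIVE_LIMIT}); use mode='backtracking' or reduce the network"
            )
        states = _exhaustive_fixed_points(dyn)
    elif mode == "backtracking":
        states = _backtracking_fixed_points(dyn)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    states = sorted(set(states))
    return [Attractor(i, dyn.nodes, bits) for i, bits in enumerate(states)]


def _profile_match(attractor: Attractor, profile: Mapping[str, int]) -> float:
    state = attractor.state
    hits = sum(1 for g, v in profile.items() if state[g] == v)
    return hits / len(profile)


def match_attractors_to_profiles(
    attractors: Sequence[Attractor],
    profiles: ExpressionProfilePair,
) -> Tuple[Attractor, Attractor, float]:
    """Best (initial, final) attractor pair for a phenotype profile pair.

    Scores every ordered pair of distinct attractors by the mean, over the
    initial and final profiles, of the fraction of measured genes whose
    attractor value equals the profile value.  Ties break to the smallest
    (initial id, final id).
    """
    if not profiles.initial:
        raise ValueError("empty expression profiles")
    if len(attractors) < 2:
        raise ValueError(
            "fewer than 2 attractors: the network cannot represent both phenotypes"
        )
    best: Optional[Tuple[float, int, int]] = None
    for a in attractors:
        for b in attractors:
            if a.id == b.id:
                continue
            score = 0.5 * (
                _profile_match(a, profiles.initial) + _profile_match(b, profiles.final)
            )
            key = (-score, a.id, b.id)
            if best is None or key < best:
                best = key
    score, ai, bi = -best[0], best[1], best[2]
    lookup: Dict[int, Attractor] = {a.id: a for a in attractors}
    return lookup[ai], lookup[bi], score
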