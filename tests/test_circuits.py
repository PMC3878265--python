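"""Elementary circuit enumeration, sign classification, miRNA filtering."""

import numpy as np
import pytest

from boolrd import (
    ACTIVATION,
    INHIBITION,
    Circuit,
    CircuitExplosionError,
    SignedNetwork,
    circuit_sign,
    enumerate_elementary_circuits,
    filter_mirnas,
)
from boolrd.examples import emt_mirna_subnetwork
from boolrd.netgen import random_signed_network


def brute_force_circuits(network):
    """Independent oracle: enumerate elementary cycles by DFS over paths."""
    nodes = network.nodes
    succ = {n: [] for n in nodes}
    for u, v, _ in network.edges:
        succ[u].append(v)
    found = set()

    def dfs(start, path, on_path):
        for v in succ[path[-1]]:
            if v == start:
                k = min(range(len(path)), key=lambda i: path[i])
                found.add(tuple(path[k:]) + tuple(path[:k]))
            elif v not in on_path and v > start:
                # only search cycles whose smallest node is `start`
                dfs(start, path + [v], on_path | {v})

    for s in nodes:
        dfs(s, [s], {s})
    return found


class TestEnumeration:
    def test_toggle_single_positive_circuit(self, toggle):
        cs = enumerate_elementary_circuits(toggle)
        assert len(cs) == 1
        c = cs[0]
        assert len(c) == 2 and c.n_inhibitions == 2 and c.sign == "positive"

    def test_emt_mirna_subgraph_two_node_circuits(self):
        # the published 12-inhibition miRNA wiring closes 5 mutual-repression
        # loops, each a double-negative (positive) circuit
        cs = enumerate_elementary_circuits(emt_mirna_subnetwork())
        two = [c for c in cs if len(c) == 2]
        assert len(two) == 5
        assert all(c.sign == "positive" for c in two)

    def test_self_loops_are_length_one_circuits(self):
        net = SignedNetwork.from_edges(
            [("a", "a", ACTIVATION), ("b", "b", INHIBITION), ("a", "b", ACTIVATION)]
        )
        cs = enumerate_elementary_circuits(net)
        assert [(c.nodes, c.sign) for c in cs] == [
            (("a",), "positive"),
            (("b",), "negative"),
        ]

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(11)
        for i in range(20):
            n = int(rng.integers(3, 11))
            sl = int(rng.integers(0, 3))
            m = int(rng.integers(n, min(n * (n - 1) + sl, 3 * n) + 1))
            net = random_signed_network(
                n, m, n_self_loops=sl, seed=i,
                require_multistable=False,
            )
            johnson = {c.nodes for c in enumerate_elementary_circuits(net)}
            assert johnson == brute_force_circuits(net)

    def test_canonical_under_relabeling(self):
        net = random_signed_network(7, 16, seed=5, require_multistable=False)
        sig = sorted(
            (len(c), c.n_inhibitions) for c in enumerate_elementary_circuits(net)
        )
        rng = np.random.default_rng(2)
        perm = dict(zip(net.nodes, rng.permutation(net.nodes)))
        relabeled = SignedNetwork.from_edges(
            [(perm[u], perm[v], s) for u, v, s in net.edges]
        )
        sig2 = sorted(
            (len(c), c.n_inhibitions) for c in enumerate_elementary_circuits(relabeled)
        )
        assert sig == sig2

    def test_positive_plus_negative_is_total(self, emt):
        cs = enumerate_elementary_circuits(emt)
        pos = sum(1 for c in cs if c.sign == "positive")
        neg = sum(1 for c in cs if c.sign == "negative")
        assert pos + neg == len(cs)

    def test_cap_guard(self, emt):
        with pytest.raises(CircuitExplosionError, match="5"):
            enumerate_elementary_circuits(emt, cap=5)


class TestSignRule:
    @pytest.mark.parametrize(
        "signs,expected",
        [
            ((ACTIVATION, ACTIVATION, INHIBITION), "negative"),
            ((INHIBITION, INHIBITION), "positive"),
            ((INHIBITION,) * 4, "positive"),
            ((ACTIVATION,), "positive"),
            ((INHIBITION,), "negative"),
        ],
    )
    def test_inhibition_parity(self, signs, expected):
        names = tuple("abcdefgh"[: len(signs)])
        assert circuit_sign(Circuit(names, signs)) == expected


class TestMirnaFilter:
    def test_double_negative_mirna_retained(self):
        net = SignedNetwork.from_edges(
            [("SNAI1", "MIR203", INHIBITION), ("MIR203", "SNAI1", INHIBITION)]
        )
        kept = filter_mirnas(net)
        assert "MIR203" in kept

    def test_mirna_without_incoming_edges_removed(self):
        # outgoing-only: cannot lie on any circuit
        net = SignedNetwork.from_edges(
            [
                ("a", "b", INHIBITION),
                ("b", "a", INHIBITION),
                ("MIR155", "a", INHIBITION),
            ]
        )
        kept = filter_mirnas(net)
        assert "MIR155" not in kept
        assert set(kept.nodes) == {"a", "b"}

    def test_negative_feedback_mirna_removed(self):
        net = SignedNetwork.from_edges(
            [("g", "MIR1", ACTIVATION), ("MIR1", "g", INHIBITION)]
        )
        kept = filter_mirnas(net)
        assert "MIR1" not in kept

    def test_candidate_edges_merged_then_filtered(self, toggle):
        kept = filter_mirnas(
            toggle,
            candidate_mirna_edges=[
                ("a", "MIR9", INHIBITION),
                ("MIR9", "a", INHIBITION),
                ("MIR124", "b", INHIBITION),  # no incoming: dropped
            ],
        )
        assert "MIR9" in kept and "MIR124" not in kept
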