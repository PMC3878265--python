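"""Network generation and the in-silico validation study."""

import pytest

from boolrd import (
    ACTIVATION,
    INHIBITION,
    SignedNetwork,
    StudyConfig,
    enumerate_attractors,
    enumerate_elementary_circuits,
    extract_subnetwork,
    random_signed_network,
    run_insilico_study,
)
from boolrd.netgen import GenerationError


def star(n_leaves=5):
    edges = [("hub", f"leaf{i}", ACTIVATION) for i in range(n_leaves)]
    return SignedNetwork.from_edges(edges)


class TestExtraction:
    def test_full_size_returns_whole_network(self, emt):
        assert extract_subnetwork(emt, len(emt), seed=0) == emt

    def test_star_picks_center_plus_one_leaf(self):
        src = star()
        sub = extract_subnetwork(src, 2, seed=0, start="hub")
        assert "hub" in sub and len(sub) == 2 and sub.n_edges() == 1

    def test_induced_subgraph_keeps_all_internal_edges(self, emt):
        sub = extract_subnetwork(emt, 5, seed=3)
        for u, v, s in emt.edges:
            if u in sub and v in sub:
                assert sub.sign(u, v) == s

    def test_self_loops_retained(self):
        src = star()
        src.add_edge("hub", "hub", INHIBITION)
        sub = extract_subnetwork(src, 2, seed=1, start="hub")
        assert sub.has_edge("hub", "hub")

    def test_same_seed_same_subnetwork(self, emt):
        s1 = extract_subnetwork(emt, 4, seed=9)
        s2 = extract_subnetwork(emt, 4, seed=9)
        assert s1 == s2

    def test_disconnected_source_errors(self):
        src = SignedNetwork.from_edges(
            [("a", "b", ACTIVATION), ("c", "d", ACTIVATION)]
        )
        with pytest.raises(GenerationError, match="disconnected"):
            extract_subnetwork(src, 3, seed=0, start="a")


class TestRandomNetwork:
    def test_two_gene_all_inhibition_is_the_toggle(self):
        # the only multistable 2-gene, 2-edge, all-inhibition digraph
        net = random_signed_network(2, 2, inhibition_fraction=1.0, n_self_loops=0, seed=0)
        assert net.edges == (
            ("g00", "g01", INHIBITION),
            ("g01", "g00", INHIBITION),
        )

    def test_zero_inhibition_fraction(self):
        net = random_signed_network(
            6, 12, inhibition_fraction=0.0, seed=1, require_multistable=False
        )
        assert all(s == ACTIVATION for _, _, s in net.edges)

    def test_exact_counts(self):
        net = random_signed_network(
            8, 20, inhibition_fraction=0.5, n_self_loops=3, seed=2,
            require_multistable=False,
        )
        assert len(net) == 8 and net.n_edges() == 20
        assert sum(1 for u, v, _ in net.edges if u == v) == 3
        assert sum(1 for *_, s in net.edges if s == INHIBITION) == 10

    def test_seed_reproducibility(self):
        n1 = random_signed_network(10, 24, seed=5)
        n2 = random_signed_network(10, 24, seed=5)
        assert n1 == n2

    def test_multistability_guarantee(self):
        for seed in range(5):
            net = random_signed_network(12, 29, seed=seed)
            assert len(enumerate_attractors(net)) >= 2
            assert any(
                c.is_positive for c in enumerate_elementary_circuits(net)
            )

    def test_impossible_parameters_error(self):
        with pytest.raises(ValueError):
            random_signed_network(2, 9, seed=0)


class TestStudy:
    def test_toggle_ensemble_rd_fraction_is_one(self):
        # 2-gene all-inhibition networks are toggles: both genes are RDs
        # across the two transitions, so the RD fraction is 1 per network
        cfg = StudyConfig(
            n_networks=4,
            size_range=(2, 2),
            edges_per_node=1.0,
            inhibition_fraction=1.0,
            self_loop_fraction=0.0,
            seed=0,
        )
        report = run_insilico_study(cfg)
        ok = report.networks[report.networks.status == "ok"]
        assert len(ok) == 4
        assert (ok.rd_fraction == 1.0).all()
        assert report.summary["depc_existence_fraction"] == 1.0
        assert report.summary["transition_success_fraction"] == 1.0
        assert report.summary["mean_min_rd_size"] == 1.0

    def test_report_shape_and_determinism(self):
        cfg = StudyConfig(n_networks=3, size_range=(8, 12), seed=11)
        r1 = run_insilico_study(cfg)
        r2 = run_insilico_study(cfg)
        assert r1.transitions.equals(r2.transitions)
        assert r1.networks.equals(r2.networks)
        # one row per analyzed ordered attractor pair
        ok = r1.networks[r1.networks.status == "ok"]
        assert r1.transitions.groupby("network").size().sum() == ok.n_pairs_analyzed.sum()

    def test_single_attractor_networks_recorded_not_fatal(self):
        # unreachable multistability at tiny size -> generation failures are
        # logged rows, never exceptions
        cfg = StudyConfig(
            n_networks=2, size_range=(3, 3), edges_per_node=1.0,
            inhibition_fraction=0.0, self_loop_fraction=0.0, seed=2,
        )
        report = run_insilico_study(cfg)
        assert set(report.networks.status) <= {"ok", "no-pair"} or any(
            "generation" in s for s in report.networks.status
        )
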