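"""Test-network generation and the in-silico validation study.

Two sources of networks:

* greedy-neighbor subnetwork extraction from a large source network (a
  RegulonDB-style transcriptional network), mimicking how benchmark GRNs
  are carved out of a well-characterized organism's regulatory map while
  keeping self-regulations; and
* self-contained random signed digraphs with prescribed size, edge count,
  inhibition fraction and self-loop count, rejection-sampled until they are
  genuinely multistable (>= 1 positive circuit and >= 2 fixed points), so
  the whole pipeline can be exercised without any external data.

:func:`run_insilico_study` replays the validation protocol: generate an
ensemble, enumerate each network's attractors, and for every ordered
attractor pair check DEPC existence and run the full RD pipeline, reporting
per-transition outcomes and ensemble summary statistics (DEPC-existence and
transition-success fractions, mean RD gene fraction, mean min/max RD set
sizes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .attractors import enumerate_attractors
from .circuits import CircuitExplosionError, enumerate_elementary_circuits
from .network import ACTIVATION, INHIBITION, SignedNetwork
from .rd import (
    TransitionSpec,
    TransitionUnreachableError,
    find_reprogramming_determinants,
)


class GenerationError(RuntimeError):
    """Could not generate a network satisfying the constraints."""


def extract_subnetwork(
    source: SignedNetwork,
    size: int,
    seed: Optional[int] = None,
    start: Optional[str] = None,
) -> SignedNetwork:
    """Greedy-neighbor extraction of an induced subnetwork of ``size`` nodes.

    Starts from ``start`` (or a random node) and repeatedly adds the
    outside node with the most edges (either direction, self-loops aside)
    to the current set; ties break uniformly at random under ``seed``.
    The returned network is the induced subgraph, self-loops retained.
    """
    nodes = source.nodes
    if not 1 <= size <= len(nodes):
        raise ValueError(f"size {size} out of range 1..{len(nodes)}")
    rng = np.random.default_rng(seed)
    if start is None:
        start = nodes[int(rng.integers(len(nodes)))]
    elif start not in source:
        raise KeyError(start)

    # conn[n] = number of directed edges between outside node n and the
    # chosen set (self-loops excluded from the connectivity score)
    conn: Dict[str, int] = {n: 0 for n in nodes}
    chosen = {start}
    edges_by_node: Dict[str, List[Tuple[str, str]]] = {n: [] for n in nodes}
    for u, v, _ in source.edges:
        if u != v:
            edges_by_node[u].append((u, v))
            edges_by_node[v].append((u, v))
    for u, v in edges_by_node[start]:
        other = v if u == start else u
        conn[other] += 1

    while len(chosen) < size:
        candidates = [n for n in nodes if n not in chosen and conn[n] > 0]
        if not candidates:
            raise GenerationError(
                f"source network disconnected: only {len(chosen)} nodes reachable, "
                f"{size} requested"
            )
        top = max(conn[n] for n in candidates)
        tied = sorted(n for n in candidates if conn[n] == top)
        pick = tied[int(rng.integers(len(tied)))]
        chosen.add(pick)
        for u, v in edges_by_node[pick]:
            other = v if u == pick else u
            if other not in chosen:
                conn[other] += 1
    return source.subnetwork(chosen)


def random_signed_network(
    n_genes: int,
    n_edges: int,
    inhibition_fraction: float = 0.4,
    n_self_loops: int = 0,
    seed: Optional[int] = None,
    require_multistable: bool = True,
    max_tries: int = 500,
    circuit_cap: int = 50_000,
) -> SignedNetwork:
    """Random signed digraph with exactly the requested counts.

    ``n_self_loops`` nodes receive a self-edge; the remaining edges are
    drawn without replacement among distinct ordered pairs.  The number of
    inhibitions is ``round(inhibition_fraction * n_edges)``.  With
    ``require_multistable`` the draw is rejected and resampled until the
    network has at least one positive circuit and at least two fixed-point
    attractors, so the RD pipeline is exercisable on the result.
    """
    if n_edges > n_genes * n_genes:
        raise ValueError("more edges than ordered node pairs")
    if n_self_loops > min(n_genes, n_edges):
        raise ValueError("more self-loops than nodes or edges")
    rng = np.random.default_rng(seed)
    names = [f"g{i:02d}" for i in range(n_genes)]
    n_pairs = n_edges - n_self_loops
    if n_pairs > n_genes * (n_genes - 1):
        raise ValueError("too many non-self edges for the node count")
    n_inh = int(round(inhibition_fraction * n_edges))

    for _ in range(max_tries):
        loop_nodes = rng.choice(n_genes, size=n_self_loops, replace=False)
        # sample distinct ordered pairs (u != v)
        pair_codes = rng.choice(n_genes * (n_genes - 1), size=n_pairs, replace=False)
        edges: List[Tuple[str, str]] = [(names[i], names[i]) for i in loop_nodes]
        for code in pair_codes:
            u, r = divmod(int(code), n_genes - 1)
            v = r if r < u else r + 1
            edges.append((names[u], names[v]))
        signs = np.full(n_edges, ACTIVATION)
        inh_idx = rng.choice(n_edges, size=n_inh, replace=False)
        signs[inh_idx] = INHIBITION
        net = SignedNetwork.from_edges(
            [(u, v, int(s)) for (u, v), s in zip(edges, signs)], nodes=names
        )
        if not require_multistable:
            return net
        try:
            circuits = enumerate_elementary_circuits(net, cap=circuit_cap)
        except CircuitExplosionError:
            continue
        if not any(c.is_positive for c in circuits):
            continue
        attractors = enumerate_attractors(net, mode="backtracking")
        if len(attractors) >= 2:
            return net
    raise GenerationError(
        f"no multistable network found in {max_tries} draws; "
        f"adjust edge count, inhibition fraction or self-loop count"
    )


@dataclass
class StudyConfig:
    """In-silico study parameters.

    Defaults mirror the validation regime: networks of 20-40 genes with
    E. coli-like density (~2.4 interactions per gene, ~40% inhibition,
    self-regulation on ~10% of genes).
    """

    n_networks: int = 50
    size_range: Tuple[int, int] = (20, 40)
    edges_per_node: float = 2.4
    inhibition_fraction: float = 0.4
    self_loop_fraction: float = 0.1
    seed: Optional[int] = None
    circuit_cap: int = 20_000
    max_pairs_per_network: int = 30
    max_attractors: int = 64
    max_depc_set_size: int = 3
    max_branches: int = 200
    step_cap: int = 1000


@dataclass
class StudyReport:
    transitions: pd.DataFrame   # one row per analyzed ordered attractor pair
    networks: pd.DataFrame      # one row per network
    summary: Dict[str, float]


def run_insilico_study(
    config: Optional[StudyConfig] = None,
    source: Optional[SignedNetwork] = None,
) -> StudyReport:
    """Generate an ensemble and run the full RD pipeline on every transition.

    Networks come from ``source`` via greedy extraction when given,
    otherwise from :func:`random_signed_network`.  For each network all
    fixed points are enumerated; for every ordered attractor pair (sampled
    down to ``max_pairs_per_network`` when the pair count explodes) the
    pipeline records whether a DEPC exists and whether a validated RD
    combination was found, plus the minimal RD set size.  Per-network
    failures are logged in the report, never fatal.
    """
    cfg = config or StudyConfig()
    rng = np.random.default_rng(cfg.seed)
    t_rows: List[dict] = []
    n_rows: List[dict] = []

    made = 0
    attempts = 0
    while made < cfg.n_networks and attempts < 10 * cfg.n_networks:
        attempts += 1
        net_seed = int(rng.integers(2**31 - 1))
        size = int(rng.integers(cfg.size_range[0], cfg.size_range[1] + 1))
        try:
            if source is not None:
                net = extract_subnetwork(source, size, seed=net_seed)
            else:
                net = random_signed_network(
                    size,
                    n_edges=int(round(cfg.edges_per_node * size)),
                    inhibition_fraction=cfg.inhibition_fraction,
                    n_self_loops=int(round(cfg.self_loop_fraction * size)),
                    seed=net_seed,
                    circuit_cap=cfg.circuit_cap,
                )
        except GenerationError as err:
            n_rows.append({"network": made, "size": size, "status": f"generation: {err}"})
            continue
        made += 1
        net_id = made - 1
        row = {
            "network": net_id,
            "size": len(net),
            "n_edges": net.n_edges(),
            "status": "ok",
            "n_attractors": 0,
            "n_pairs_analyzed": 0,
            "rd_fraction": np.nan,
            "min_rd_size": np.nan,
            "max_rd_size": np.nan,
        }
        try:
            circuits = enumerate_elementary_circuits(net, cap=cfg.circuit_cap)
            attractors = enumerate_attractors(net, mode="backtracking")
        except CircuitExplosionError as err:
            row["status"] = f"circuit cap: {err}"
            n_rows.append(row)
            continue
        row["n_attractors"] = len(attractors)
        if len(attractors) < 2:
            row["status"] = "no-pair"
            n_rows.append(row)
            continue
        if len(attractors) > cfg.max_attractors:
            attractors = attractors[: cfg.max_attractors]
        pairs = [
            (a, b) for a in attractors for b in attractors if a.id != b.id
        ]
        if len(pairs) > cfg.max_pairs_per_network:
            idx = rng.choice(len(pairs), size=cfg.max_pairs_per_network, replace=False)
            pairs = [pairs[i] for i in sorted(idx)]

        rd_genes: set = set()
        sizes: List[int] = []
        for a, b in pairs:
            trans = TransitionSpec(a, b)
            t_row = {
                "network": net_id,
                "initial": a.id,
                "final": b.id,
                "n_depcs": 0,
                "depc_exists": False,
                "rd_success": False,
                "min_rd_size": np.nan,
                "n_alternatives": 0,
            }
            try:
                combos = find_reprogramming_determinants(
                    net,
                    transition=trans,
                    circuits=circuits,
                    step_cap=cfg.step_cap,
                    max_depc_set_size=cfg.max_depc_set_size,
                    max_branches=cfg.max_branches,
                )
            except TransitionUnreachableError as err:
                # distinguish "no DEPC" from "DEPC subsets all failed"
                from .depc import detect_depcs

                depcs = detect_depcs(net, circuits, a, b)
                t_row["n_depcs"] = len(depcs)
                t_row["depc_exists"] = bool(depcs)
                t_rows.append(t_row)
                continue
            t_row["depc_exists"] = True
            t_row["rd_success"] = True
            t_row["n_depcs"] = len(
                {i for combo in combos for i in combo.covered_depcs}
            )
            t_row["min_rd_size"] = min(len(c.genes) for c in combos)
            t_row["n_alternatives"] = len(combos)
            sizes.append(int(t_row["min_rd_size"]))
            for c in combos:
                rd_genes.update(c.genes)
            t_rows.append(t_row)

        row["n_pairs_analyzed"] = len(pairs)
        row["rd_fraction"] = len(rd_genes) / len(net)
        if sizes:
            row["min_rd_size"] = min(sizes)
            row["max_rd_size"] = max(sizes)
        n_rows.append(row)

    transitions = pd.DataFrame(t_rows)
    networks = pd.DataFrame(n_rows)
    ok = networks[networks["status"] == "ok"] if len(networks) else networks
    n_pairs = len(transitions)
    summary = {
        "n_networks": float(len(ok)),
        "n_transitions": float(n_pairs),
        "depc_existence_fraction": (
            float(transitions["depc_exists"].mean()) if n_pairs else np.nan
        ),
        "transition_success_fraction": (
            float(transitions["rd_success"].mean()) if n_pairs else np.nan
        ),
        "mean_rd_fraction": float(ok["rd_fraction"].mean()) if len(ok) else np.nan,
        "mean_min_rd_size": float(ok["min_rd_size"].mean()) if len(ok) else np.nan,
        "mean_max_rd_size": float(ok["max_rd_size"].mean()) if len(ok) else np.nan,
    }
    return StudyReport(transitions, networks, summary)
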