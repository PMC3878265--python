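"""Network contextualization by evolutionary edge pruning.

Literature-derived GRNs mix interactions observed in different cell types
and conditions, so their attractors rarely match the phenotypes under
study.  Contextualization removes the inconsistent interactions: an
estimation-of-distribution algorithm (EDA) samples edge-removal masks,
scores each pruned network by how well its best attractor pair explains the
initial/final expression profiles, and re-estimates per-edge removal
probabilities (and per-positive-circuit retention probabilities — circuits
are the stability units, so they are sampled as units too) from the elite
candidates.  The score is the fraction of measured genes whose attractor
values agree with the profiles, averaged over the two phenotypes; it is
also the reliability indicator reported to the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .attractors import enumerate_attractors, match_attractors_to_profiles
from .circuits import enumerate_elementary_circuits
from .network import ExpressionProfilePair, SignedNetwork, prune_unregulated


def contextualization_score(
    network: SignedNetwork,
    profiles: ExpressionProfilePair,
    attractor_mode: str = "auto",
) -> float:
    """Fraction of measured gene states explained by the best attractor pair.

    0.0 when the network has fewer than two attractors (it cannot represent
    two distinct phenotypes at all).
    """
    if len(network) == 0:
        return 0.0
    restricted = profiles.restricted_to(network)
    if not restricted.initial:
        return 0.0
    attractors = enumerate_attractors(network, mode=attractor_mode)
    if len(attractors) < 2:
        return 0.0
    _, _, score = match_attractors_to_profiles(attractors, restricted)
    return score


@dataclass
class ContextualizerConfig:
    """EDA hyperparameters (defaults sized for <= 40-gene networks)."""

    population: int = 50
    elite_fraction: float = 0.2
    learning_rate: float = 0.3
    generations: int = 100
    p_min: float = 0.02          # probability floor/ceiling, keeps exploration alive
    init_removal_prob: float = 0.1
    seed: Optional[int] = None
    attractor_mode: str = "auto"


@dataclass
class ContextualizationResult:
    network: SignedNetwork
    removed_edges: Tuple[Tuple[str, str], ...]
    score: float
    history: List[float] = field(default_factory=list)  # best-so-far per generation


def contextualize(
    network: SignedNetwork,
    profiles: ExpressionProfilePair,
    config: Optional[ContextualizerConfig] = None,
) -> ContextualizationResult:
    """Prune edges until the attractors explain the phenotype profiles.

    Candidate = subset of edges to delete.  After deletion, newly
    unregulated nodes are iteratively pruned before scoring (an edge removal
    can orphan a node, and unregulated nodes carry no stability
    information).  The empty mask is always evaluated first, so an
    already-consistent network is returned unchanged, and the best candidate
    ever seen is returned (elitism: the history is non-decreasing).  Stops
    early at a perfect score.  Fully reproducible given ``config.seed``.
    """
    cfg = config or ContextualizerConfig()
    circuits = enumerate_elementary_circuits(network)
    if not circuits:
        raise ValueError(
            "network has no circuit: contextualization operates on stability "
            "and cannot assess interactions outside circuits"
        )
    rng = np.random.default_rng(cfg.seed)
    edges = [(u, v) for u, v, _ in network.edges]
    m = len(edges)
    edge_index = {e: i for i, e in enumerate(edges)}
    pos_circuits = [c for c in circuits if c.is_positive]
    circuit_edges = [
        [edge_index[(u, v)] for u, v, _ in c.edges] for c in pos_circuits
    ]
    circuits_of_edge: List[List[int]] = [[] for _ in range(m)]
    for ci, eidx in enumerate(circuit_edges):
        for e in eidx:
            circuits_of_edge[e].append(ci)

    p_remove = np.full(m, cfg.init_removal_prob)
    r_keep = np.ones(len(pos_circuits))  # per-positive-circuit retention prob

    def score_mask(mask: np.ndarray) -> float:
        pruned = network.without_edges([edges[i] for i in np.flatnonzero(mask)])
        pruned = prune_unregulated(pruned)
        return contextualization_score(
            pruned, profiles, attractor_mode=cfg.attractor_mode
        )

    def build(mask: np.ndarray) -> ContextualizationResult:
        removed = tuple(edges[i] for i in np.flatnonzero(mask))
        pruned = prune_unregulated(network.without_edges(removed))
        return ContextualizationResult(pruned, removed, best_score, history)

    history: List[float] = []
    empty = np.zeros(m, dtype=bool)
    best_mask, best_score = empty, score_mask(empty)

    n_elite = max(1, int(round(cfg.elite_fraction * cfg.population)))
    for _ in range(cfg.generations):
        if best_score >= 1.0:
            break
        # effective keep prob couples the two distributions: an edge survives
        # with its own keep probability scaled by the mean retention of the
        # positive circuits it participates in
        keep = 1.0 - p_remove
        for e in range(m):
            if circuits_of_edge[e]:
                keep[e] *= float(np.mean([r_keep[c] for c in circuits_of_edge[e]]))
        p_eff = np.clip(1.0 - keep, cfg.p_min, 1.0 - cfg.p_min)

        masks = rng.random((cfg.population, m)) < p_eff[None, :]
        scores = np.array([score_mask(mk) for mk in masks])
        order = np.argsort(-scores, kind="stable")
        elite = masks[order[:n_elite]]
        gen_best = int(order[0])
        if scores[gen_best] > best_score:
            best_score = float(scores[gen_best])
            best_mask = masks[gen_best].copy()
        history.append(best_score)

        lr = cfg.learning_rate
        p_remove = (1 - lr) * p_remove + lr * elite.mean(axis=0)
        p_remove = np.clip(p_remove, cfg.p_min, 1.0 - cfg.p_min)
        if pos_circuits:
            intact = np.array(
                [
                    np.mean([not mk[eidx].any() for mk in elite])
                    for eidx in circuit_edges
                ]
            )
            r_keep = np.clip((1 - lr) * r_keep + lr * intact, cfg.p_min, 1.0)

    return build(best_mask)
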