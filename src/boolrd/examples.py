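"""Small reference networks used in docs, tests and demos.

All networks are built programmatically.  The EMT network is a *synthetic
reconstruction*: its twelve miRNA interactions are the published
epithelial-mesenchymal-transition miRNA wiring (double-negative feedback
loops between SNAI1/ZEB1/ZEB2 and MIR200/MIR203/MIR34), and the five
gene-gene interactions complete the published EMT core topology (SNAI1
activates ZEB1/ZEB2; SNAI1, ZEB1 and ZEB2 repress the epithelial marker
CDH1).  It reproduces the documented regulatory-core statistics — 7 nodes,
17 interactions (2 activations, 15 inhibitions), 12 positive and 0 negative
circuits — and has exactly the epithelial and mesenchymal phenotypes as its
two attractors.
"""

from __future__ import annotations

from typing import List, Tuple

from .network import ACTIVATION, INHIBITION, ExpressionProfilePair, SignedNetwork


def toggle_switch(a: str = "a", b: str = "b") -> SignedNetwork:
    """Double-negative toggle: the canonical bistable motif."""
    return SignedNetwork.from_edges(
        [(a, b, INHIBITION), (b, a, INHIBITION)],
        kinds={a: "gene", b: "gene"},
    )


def signed_ring(signs: List[int], prefix: str = "r") -> SignedNetwork:
    """Ring r0 -> r1 -> ... -> r0 with the given edge signs."""
    n = len(signs)
    names = [f"{prefix}{i}" for i in range(n)]
    edges = [(names[i], names[(i + 1) % n], signs[i]) for i in range(n)]
    return SignedNetwork.from_edges(edges, kinds={m: "gene" for m in names})


def negative_two_ring() -> SignedNetwork:
    """a activates b, b inhibits a: the canonical oscillator, no fixed point."""
    return SignedNetwork.from_edges([("a", "b", ACTIVATION), ("b", "a", INHIBITION)])


def double_toggle_chain() -> SignedNetwork:
    """Two toggles where the first drives the second (a master circuit).

    (a, b) is a toggle; (c, d) is a toggle additionally driven by a
    (a activates c), so flipping the upstream toggle flips the downstream
    one too.
    """
    return SignedNetwork.from_edges(
        [
            ("a", "b", INHIBITION),
            ("b", "a", INHIBITION),
            ("c", "d", INHIBITION),
            ("d", "c", INHIBITION),
            ("a", "c", ACTIVATION),
            ("b", "d", ACTIVATION),
        ]
    )


def parallel_toggles() -> SignedNetwork:
    """Two independent toggles: both circuits must be perturbed to flip both."""
    return SignedNetwork.from_edges(
        [
            ("a", "b", INHIBITION),
            ("b", "a", INHIBITION),
            ("c", "d", INHIBITION),
            ("d", "c", INHIBITION),
        ]
    )


# -- EMT ------------------------------------------------------------------

EMT_MIRNA_EDGES: Tuple[Tuple[str, str, int], ...] = (
    ("MIR200", "ZEB1", INHIBITION),
    ("MIR200", "ZEB2", INHIBITION),
    ("MIR203", "SNAI1", INHIBITION),
    ("MIR203", "ZEB2", INHIBITION),
    ("MIR34", "SNAI1", INHIBITION),
    ("SNAI1", "MIR200", INHIBITION),
    ("SNAI1", "MIR203", INHIBITION),
    ("SNAI1", "MIR34", INHIBITION),
    ("ZEB1", "MIR200", INHIBITION),
    ("ZEB1", "MIR203", INHIBITION),
    ("ZEB2", "MIR200", INHIBITION),
    ("ZEB2", "MIR203", INHIBITION),
)

EMT_GENE_EDGES: Tuple[Tuple[str, str, int], ...] = (
    ("SNAI1", "ZEB1", ACTIVATION),
    ("SNAI1", "ZEB2", ACTIVATION),
    ("SNAI1", "CDH1", INHIBITION),
    ("ZEB1", "CDH1", INHIBITION),
    ("ZEB2", "CDH1", INHIBITION),
)

_EMT_KINDS = {
    "SNAI1": "gene",
    "ZEB1": "gene",
    "ZEB2": "gene",
    "CDH1": "gene",
    "MIR200": "mirna",
    "MIR203": "mirna",
    "MIR34": "mirna",
}


def emt_core_network() -> SignedNetwork:
    """Synthetic reconstruction of the EMT regulatory core (7 nodes, 17 edges).

    Double-negative feedback between the EMT inducers (SNAI1, ZEB1, ZEB2)
    and their miRNA antagonists (MIR200, MIR203, MIR34), SNAI1 activating
    the ZEBs, and all three inducers repressing E-cadherin (CDH1).
    Bistable: the epithelial attractor (inducers OFF, miRNAs and CDH1 ON)
    and the mesenchymal attractor (the complement).
    """
    return SignedNetwork.from_edges(
        EMT_MIRNA_EDGES + EMT_GENE_EDGES, kinds=_EMT_KINDS
    )


def emt_mirna_subnetwork() -> SignedNetwork:
    """Just the twelve published miRNA interactions of the EMT example."""
    kinds = {k: v for k, v in _EMT_KINDS.items() if k != "CDH1"}
    return SignedNetwork.from_edges(EMT_MIRNA_EDGES, kinds=kinds)


def emt_profiles(include_mirnas: bool = False) -> ExpressionProfilePair:
    """Epithelial (initial) vs mesenchymal (final) binarized profiles.

    miRNAs are unmeasured by default, as in a typical mRNA expression
    experiment.
    """
    initial = {"SNAI1": 0, "ZEB1": 0, "ZEB2": 0, "CDH1": 1}
    final = {"SNAI1": 1, "ZEB1": 1, "ZEB2": 1, "CDH1": 0}
    if include_mirnas:
        for m in ("MIR200", "MIR203", "MIR34"):
            initial[m] = 1
            final[m] = 0
    return ExpressionProfilePair(initial=initial, final=final)
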