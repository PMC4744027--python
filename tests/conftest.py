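"""Shared fixtures: small simulated communities and helper builders."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import barcodiv as bd


def substitution_tree(tree: bd.TimeTree, mu: float) -> bd.TimeTree:
    """Scale a time tree into expected-substitution units."""
    out = tree.clone()
    for node in out.tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is not None:
            node.edge.length *= mu
    return out


@dataclass
class SimBundle:
    params: bd.SimParams
    truth: bd.CommunityTruth
    tree: bd.TimeTree
    aln: bd.Alignment
    morpho: bd.Partition
    meta: object


def make_bundle(params: bd.SimParams) -> SimBundle:
    truth = bd.simulate_community(params)
    tree = bd.simulate_genealogy(truth, params)
    aln = bd.simulate_sequences(tree, params)
    morpho = bd.corrupt_morphospecies(
        truth, params.split_rate, params.lump_rate, params.seed,
        species_order=bd.species_tip_order(tree, truth),
    )
    return SimBundle(params, truth, tree, aln, morpho,
                     bd.metadata_frame(truth, morpho))


@pytest.fixture(scope="session")
def small_sim() -> SimBundle:
    """12 species / 30 specimens with study-like abundance structure."""
    return make_bundle(bd.SimParams(n_species=12, n_specimens=30, seed=42))


@pytest.fixture(scope="session")
def tiny_aln() -> bd.Alignment:
    return bd.Alignment(
        ("s1", "s2", "s3", "s4"),
        ("ACGTACGT", "ACGTACGA", "ACGTACGA", "TTTTACGT"),
    )
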