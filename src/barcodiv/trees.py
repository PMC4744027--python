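"""Rooted time/substitution trees and mean-path-length ultrametricization.

Trees are carried as :class:`dendropy.Tree` objects wrapped in a small
:class:`TimeTree` dataclass recording whether branch lengths are
time-proportional (ultrametric) or expected substitutions. Tip labels are
specimen ids.

Tree-based delimitation needs an ultrametric input; when only a
substitution tree is available, :func:`ultrametricize_mpl` applies mean
path length (MPL) smoothing: each node's age is the mean root-free path
length from the node to its descendant tips, child ages are clamped to
their parent's age, and all ages are rescaled so the root sits at age 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import dendropy

ULTRAMETRIC_RTOL = 1e-6


@dataclass
class TimeTree:
    """Rooted tree with branch lengths; tips labelled by specimen id."""

    tree: dendropy.Tree
    ultrametric: bool = False
    _ages: Dict[int, float] | None = field(default=None, repr=False)

    def __post_init__(self):
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    # ------------------------------------------------------------------ #
    @property
    def tip_labels(self) -> List[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def depths(self) -> Dict[str, float]:
        """Root-to-tip path lengths keyed by tip label."""
        out = {}
        for leaf in self.tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out

    def root_age(self) -> float:
        return max(self.depths().values())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        depths = list(self.depths().values())
        root = max(depths)
        if root == 0:
            return False
        return all(abs(d - root) <= rtol * root for d in depths)

    def node_ages(self) -> Dict[dendropy.Node, float]:
        """Ages (distance above the tips) for an ultrametric tree."""
        root = self.root_age()
        ages: Dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                ages[node] = root
            else:
                ages[node] = ages[node.parent_node] - (node.edge.length or 0.0)
        return ages

    def clone(self) -> "TimeTree":
        return TimeTree(self.tree.clone(depth=1), self.ultrametric)

    # ------------------------------------------------------------------ #
    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.as_newick())

    def as_newick(self) -> str:
        return (
            self.tree.as_string(schema="newick", suppress_rooting=True).strip()
            + "\n"
        )


def read_newick(source: str | Path) -> TimeTree:
    """Read a rooted newick tree; internal support values are discarded."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    tree = dendropy.Tree.get(
        file=io.StringIO(text),
        schema="newick",
        suppress_internal_node_taxa=True,
        rooting="force-rooted",
    )
    for node in tree.preorder_internal_node_iter():
        node.label = None  # support values, irrelevant downstream
    tt = TimeTree(tree)
    tt.ultrametric = tt.is_ultrametric()
    return tt


def from_newick_string(text: str) -> TimeTree:
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        rooting="force-rooted",
    )
    tt = TimeTree(tree)
    tt.ultrametric = tt.is_ultrametric()
    return tt


def ultrametricize_mpl(tree: TimeTree) -> TimeTree:
    """Mean-path-length smoothing with the root rescaled to age 1.

    Node age = mean node-to-tip path length over the node's descendant
    tips; ages are clamped so no child is older than its parent, then all
    ages are divided by the root age.
    """
    work = tree.tree.clone(depth=1)
    # bottom-up: (sum of tip path lengths, tip count) per node
    stats: Dict[dendropy.Node, tuple] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            stats[node] = (0.0, 1)
        else:
            tot, cnt = 0.0, 0
            for child in node.child_nodes():
                s, c = stats[child]
                tot += s + c * (child.edge.length or 0.0)
                cnt += c
            stats[node] = (tot, cnt)
    ages: Dict[dendropy.Node, float] = {}
    for node in work.preorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
            continue
        tot, cnt = stats[node]
        age = tot / cnt
        parent = node.parent_node
        if parent is not None:
            age = min(age, ages[parent])  # clamp: child not older than parent
        ages[node] = age
    root_age = ages[work.seed_node]
    if root_age <= 0:
        raise ValueError("degenerate tree: zero root-to-tip path everywhere")
    for node in work.preorder_node_iter():
        ages[node] /= root_age
        if node.parent_node is not None:
            node.edge.length = ages[node.parent_node] - ages[node]
    return TimeTree(work, ultrametric=True)
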