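"""Maximum-likelihood Poisson tree processes (PTP) species delimitation.

PTP works directly on a tree whose branch lengths are expected numbers of
substitutions, so no ultrametricization is needed. A configuration is a
*cut set*: an antichain of nodes (species roots) covering every tip. All
branches strictly inside a species subtree form the coalescent
(within-species) class, every other branch the speciation class; each
class's lengths are modelled as exponential with its own rate, estimated
by maximum likelihood (rate = count / sum). The profile log-likelihood of
a class with ``k`` branches summing to ``S`` is ``k (log(k / S) - 1)``; an
empty class contributes nothing.

The search starts from the one-species configuration (every branch
within-species) and greedily replaces a species root by its children while
the likelihood improves, with seeded random restarts; trees of at most 12
tips are solved by exhaustive enumeration of all cut sets instead, which
doubles as an oracle for the greedy search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .partition import Partition
from .trees import TimeTree

EXACT_TIP_LIMIT = 12
_EPS = 1e-12


def _class_loglik(total: float, count: int) -> float:
    if count == 0:
        return 0.0
    total = max(total, _EPS)
    return count * (math.log(count / total) - 1.0)


def _config_loglik(within_sum, within_n, between_sum, between_n) -> float:
    return _class_loglik(within_sum, within_n) + _class_loglik(
        between_sum, between_n
    )


@dataclass(frozen=True)
class PtpFit:
    speciation_rate: float
    coalescent_rate: float
    cut_nodes: Tuple[str, ...]  # species roots, named by their smallest tip
    logL: float
    n_entities: int
    partition: Partition
    degenerate: bool = False

    def to_dict(self) -> Dict[str, float]:
        return {
            "speciation_rate": self.speciation_rate,
            "coalescent_rate": self.coalescent_rate,
            "logL": self.logL,
            "n_entities": self.n_entities,
            "degenerate": self.degenerate,
        }


class _PtpSearch:
    def __init__(self, tree: TimeTree):
        self.tree = tree
        self.root = tree.tree.seed_node
        self.edge_len: Dict[object, float] = {}
        self.subtree_sum: Dict[object, float] = {}
        self.subtree_edges: Dict[object, int] = {}
        self.total_sum = 0.0
        self.total_n = 0
        for node in tree.tree.postorder_node_iter():
            length = node.edge.length or 0.0
            if node.parent_node is not None:
                self.edge_len[node] = length
                self.total_sum += length
                self.total_n += 1
            s, k = 0.0, 0
            for child in node.child_nodes():
                s += self.subtree_sum[child] + self.edge_len[child]
                k += self.subtree_edges[child] + 1
            self.subtree_sum[node] = s
            self.subtree_edges[node] = k

    # ------------------------------------------------------------------ #
    def loglik_of_cut(self, cut: List[object]) -> float:
        w_sum = sum(self.subtree_sum[r] for r in cut)
        w_n = sum(self.subtree_edges[r] for r in cut)
        return _config_loglik(
            w_sum, w_n, self.total_sum - w_sum, self.total_n - w_n
        )

    def greedy(self, rng: np.random.Generator, n_random_splits: int) -> List[object]:
        cut = [self.root]
        w_sum, w_n = self.total_sum, self.total_n
        # optional randomized prefix to diversify restarts
        for _ in range(n_random_splits):
            internal = [i for i, r in enumerate(cut) if not r.is_leaf()]
            if not internal:
                break
            i = int(rng.integers(len(internal)))
            r = cut.pop(internal[i])
            for child in r.child_nodes():
                w_sum -= self.edge_len[child]
                w_n -= 1
                cut.append(child)
        # best-improvement greedy node splitting
        while True:
            best_gain, best_i = 0.0, None
            base = _config_loglik(
                w_sum, w_n, self.total_sum - w_sum, self.total_n - w_n
            )
            for i, r in enumerate(cut):
                if r.is_leaf():
                    continue
                d_sum = sum(self.edge_len[c] for c in r.child_nodes())
                d_n = len(r.child_nodes())
                cand = _config_loglik(
                    w_sum - d_sum,
                    w_n - d_n,
                    self.total_sum - (w_sum - d_sum),
                    self.total_n - (w_n - d_n),
                )
                gain = cand - base
                if gain > best_gain + 1e-12:
                    best_gain, best_i = gain, i
            if best_i is None:
                return cut
            r = cut.pop(best_i)
            for child in r.child_nodes():
                w_sum -= self.edge_len[child]
                w_n -= 1
                cut.append(child)

    def exhaustive(self) -> List[object]:
        best_cut, best_ll = None, -math.inf

        def configs(node):
            yield [node]
            if not node.is_leaf():
                children = node.child_nodes()

                def cross(idx):
                    if idx == len(children):
                        yield []
                        return
                    for head in configs(children[idx]):
                        for tail in cross(idx + 1):
                            yield head + tail

                yield from cross(0)

        for cut in configs(self.root):
            ll = self.loglik_of_cut(cut)
            if ll > best_ll + 1e-12 or (
                abs(ll - best_ll) <= 1e-12
                and best_cut is not None
                and len(cut) < len(best_cut)
            ):
                best_cut, best_ll = cut, ll
        return best_cut


def _cut_to_partition(cut: List[object]) -> Partition:
    mapping = {}
    for i, r in enumerate(cut):
        tips = (
            [r.taxon.label]
            if r.is_leaf()
            else [leaf.taxon.label for leaf in r.leaf_iter()]
        )
        for t in tips:
            mapping[t] = f"tmp{i}"
    return Partition(mapping).relabeled("P")


def fit_ptp(
    tree: TimeTree,
    seed: int = 0,
    n_restarts: int = 10,
    search: str = "auto",
) -> PtpFit:
    """Fit the two-class PTP model and return the ML delimitation.

    ``search``: "exhaustive" (all cut sets; required <= 12 tips), "greedy"
    (seeded restarts), or "auto" (exhaustive when the tree allows it).
    """
    n_tips = tree.n_tips
    if n_tips < 3:
        raise ValueError("PTP needs at least 3 tips")
    state = _PtpSearch(tree)
    lengths = np.array(list(state.edge_len.values()))
    if np.allclose(lengths, lengths[0]):
        # no rate shift is detectable: flag and return a single species
        part = Partition.from_blocks([tree.tip_labels], ["P1"])
        rate = 1.0 / max(float(lengths.mean()), _EPS)
        return PtpFit(
            speciation_rate=rate,
            coalescent_rate=rate,
            cut_nodes=(min(tree.tip_labels),),
            logL=state.loglik_of_cut([state.root]),
            n_entities=1,
            partition=part,
            degenerate=True,
        )
    if search == "auto":
        search = "exhaustive" if n_tips <= EXACT_TIP_LIMIT else "greedy"
    if search == "exhaustive":
        if n_tips > 20:
            raise ValueError("exhaustive PTP search is limited to small trees")
        cut = state.exhaustive()
    elif search == "greedy":
        rng = np.random.default_rng(seed)
        best_cut, best_ll = None, -math.inf
        n_internal = max(1, n_tips - 1)
        for restart in range(n_restarts):
            # random prefixes span the whole configuration depth so the
            # greedy can escape the poor neighbourhood of the root start
            depth = restart * n_internal // max(1, n_restarts - 1)
            cand = state.greedy(rng, n_random_splits=depth)
            ll = state.loglik_of_cut(cand)
            if ll > best_ll + 1e-12 or (
                abs(ll - best_ll) <= 1e-12
                and best_cut is not None
                and len(cand) < len(best_cut)
            ):
                best_cut, best_ll = cand, ll
        cut = best_cut
    else:
        raise ValueError(f"unknown search mode {search!r}")

    w_sum = sum(state.subtree_sum[r] for r in cut)
    w_n = sum(state.subtree_edges[r] for r in cut)
    b_sum, b_n = state.total_sum - w_sum, state.total_n - w_n
    coal_rate = w_n / max(w_sum, _EPS) if w_n else float("nan")
    spec_rate = b_n / max(b_sum, _EPS) if b_n else float("nan")
    part = _cut_to_partition(cut)
    names = tuple(
        sorted(
            min(
                [r.taxon.label]
                if r.is_leaf()
                else [leaf.taxon.label for leaf in r.leaf_iter()]
            )
            for r in cut
        )
    )
    return PtpFit(
        speciation_rate=spec_rate,
        coalescent_rate=coal_rate,
        cut_nodes=names,
        logL=state.loglik_of_cut(cut),
        n_entities=len(cut),
        partition=part,
    )
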