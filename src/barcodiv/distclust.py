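"""Distance-space species delimitation.

Two methods operate directly on pairwise sequence differences:

* **Threshold clustering** — specimens whose uncorrected distance falls
  strictly below a threshold (3% by default; 5% and 7.5% are common
  alternatives) are joined, and clusters are the connected components of
  the resulting graph (single-linkage transitive closure).

* **Statistical-parsimony networks** — haplotypes are joined while the
  mutational path between them stays short enough that it is free from
  homoplasy with a stated confidence (95% by default). Every connected
  component is a "network", even when it holds a single haplotype.

The connection limit is computed from a finite-sites uniform-hit model: if
``j`` substitutions strike a sequence of ``m`` sites independently and
uniformly, the connection is homoplasy-free exactly when all hits land on
distinct sites, with probability ``P(j) = prod_{i=1}^{j-1} (1 - i/m)``.
The limit is the largest ``j`` whose ``P(j)`` still reaches the confidence
level. A fixed ``max_steps`` override is accepted for users who want to
reproduce the limit printed by a particular network program.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .partition import Partition
from .seqs import DistanceMatrix, HaplotypeTable

PRESET_THRESHOLDS = {"3%": 0.03, "5%": 0.05, "7.5%": 0.075}


def _components_partition(ids, adjacency: np.ndarray, prefix: str) -> Partition:
    graph = csr_matrix(adjacency)
    _, labels = connected_components(graph, directed=False)
    mapping = {sid: f"tmp{c}" for sid, c in zip(ids, labels)}
    return Partition(mapping).relabeled(prefix)


def cluster_by_threshold(D: DistanceMatrix, threshold: float = 0.03) -> Partition:
    """Single-linkage clusters: components of the graph with an edge for
    every pair at distance strictly below ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    adj = D.values < threshold
    np.fill_diagonal(adj, False)
    return _components_partition(D.ids, adj, "D")


@dataclass(frozen=True)
class ConnectionLimit:
    """Maximum number of mutational steps for joining haplotypes."""

    max_steps: int
    confidence: float = 0.95
    seq_length: int = 658

    def __post_init__(self):
        if self.max_steps < 0:
            raise ValueError("max_steps must be >= 0")


def parsimony_probability(j: int, seq_length: int) -> float:
    """P that ``j`` uniform hits on ``seq_length`` sites are all distinct."""
    if j < 1:
        return 1.0
    i = np.arange(1, j, dtype=float)
    return float(np.prod(1.0 - i / seq_length))


def connection_limit(
    seq_length: int, confidence: float = 0.95, max_steps: int | None = None
) -> ConnectionLimit:
    """Largest step count whose parsimonious-connection probability still
    reaches ``confidence``; pass ``max_steps`` to pin a fixed limit."""
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    if max_steps is not None:
        return ConnectionLimit(int(max_steps), confidence, seq_length)
    j = 1
    while j < seq_length and parsimony_probability(j + 1, seq_length) >= confidence:
        j += 1
    return ConnectionLimit(j, confidence, seq_length)


def parsimony_networks(
    H: HaplotypeTable, D_h: DistanceMatrix, limit: ConnectionLimit
) -> Partition:
    """Join haplotypes that are at most ``limit.max_steps`` mutational steps
    apart; networks are the connected components, mapped back to specimens.

    ``D_h`` must hold integer step counts (raw mismatches) between the
    haplotype representatives, ordered like the table's haplotype indices.
    """
    steps = D_h.values
    if not np.allclose(steps, np.round(steps)):
        raise ValueError("step matrix must contain integer mutational steps")
    if D_h.n != H.n_haplotypes:
        raise ValueError("step matrix size does not match haplotype count")
    steps = np.round(steps).astype(int)
    adj = steps <= limit.max_steps
    np.fill_diagonal(adj, False)
    graph = csr_matrix(adj)
    _, labels = connected_components(graph, directed=False)
    mapping = {
        sid: f"tmp{labels[h]}" for sid, h in H.haplotype_of_specimen.items()
    }
    return Partition(mapping).relabeled("N")
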