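"""Distance threshold clustering and statistical-parsimony networks."""

import math

import numpy as np
import pytest

import barcodiv as bd
from barcodiv.distclust import ConnectionLimit, parsimony_probability
from barcodiv.seqs import DistanceMatrix


def matrix(ids, vals):
    return DistanceMatrix(tuple(ids), np.array(vals, dtype=float))


def dfs_components(ids, adjacency):
    """Independent depth-first-search component oracle."""
    seen, comps = set(), []
    for start in range(len(ids)):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(w for w in range(len(ids)) if adjacency[v][w])
        seen |= comp
        comps.append(frozenset(ids[v] for v in comp))
    return frozenset(comps)


class TestThresholdClustering:
    def test_transitive_closure_by_hand(self):
        d = matrix("abc", [[0, 0.02, 0.10], [0.02, 0, 0.02], [0.10, 0.02, 0]])
        part = bd.cluster_by_threshold(d, 0.03)
        assert part.n_groups == 1

    def test_all_distant_pairs_stay_singletons(self):
        d = matrix("abc", [[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        assert bd.cluster_by_threshold(d, 0.03).n_groups == 3

    def test_cluster_count_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(4, 15))
            v = rng.random((n, n)) * 0.2
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            d = matrix([f"s{i}" for i in range(n)], v)
            assert (
                bd.cluster_by_threshold(d, 0.075).n_groups
                <= bd.cluster_by_threshold(d, 0.03).n_groups
            )

    def test_strict_inequality_at_threshold(self):
        d = matrix("ab", [[0, 0.03], [0.03, 0]])
        assert bd.cluster_by_threshold(d, 0.03).n_groups == 2

    def test_matches_dfs_component_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n = int(rng.integers(3, 30))
            v = rng.random((n, n)) * 0.08
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            ids = [f"s{i}" for i in range(n)]
            d = matrix(ids, v)
            part = bd.cluster_by_threshold(d, 0.03)
            adj = (v < 0.03) & ~np.eye(n, dtype=bool)
            assert part.block_set() == dfs_components(ids, adj)

    def test_invalid_threshold_rejected(self):
        d = matrix("ab", [[0, 0.1], [0.1, 0]])
        with pytest.raises(ValueError):
            bd.cluster_by_threshold(d, 1.5)


class TestConnectionLimit:
    def test_limit_non_increasing_in_confidence(self):
        limits = [
            bd.connection_limit(658, c).max_steps for c in (0.80, 0.90, 0.95, 0.99)
        ]
        assert limits == sorted(limits, reverse=True)

    def test_longer_sequences_allow_more_steps(self):
        assert (
            bd.connection_limit(1316, 0.95).max_steps
            >= bd.connection_limit(658, 0.95).max_steps
        )

    def test_matches_direct_summation_oracle(self):
        # same expression evaluated independently via log-gamma factorials:
        # P(j) = prod_{i=1}^{j-1} (m-i)/m = (m-1)! / ((m-j)! * m^(j-1))
        m, conf = 658, 0.95

        def oracle_prob(j):
            return math.exp(
                math.lgamma(m) - math.lgamma(m - j + 1) - (j - 1) * math.log(m)
            )

        j = 1
        while oracle_prob(j + 1) >= conf:
            j += 1
        assert bd.connection_limit(m, conf).max_steps == j
        for steps in range(1, 20):
            assert parsimony_probability(steps, m) == pytest.approx(
                oracle_prob(steps)
            )

    def test_fixed_override_accepted(self):
        assert bd.connection_limit(658, 0.95, max_steps=10).max_steps == 10

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bd.connection_limit(0, 0.95)
        with pytest.raises(ValueError):
            ConnectionLimit(-1)


class TestParsimonyNetworks:
    def _haplotypes(self, seqs):
        aln = bd.Alignment(tuple(f"s{i}" for i in range(len(seqs))), tuple(seqs))
        return bd.collapse_haplotypes(aln)

    def test_close_haplotypes_join_one_network(self):
        h = self._haplotypes(["AAAA", "AAAT"])
        steps = bd.mismatch_step_matrix(h.alignment())
        part = bd.parsimony_networks(h, steps, ConnectionLimit(10))
        assert part.n_groups == 1

    def test_chain_connects_through_intermediate(self):
        ids = ["a", "b", "c"]
        vals = np.array([[0, 8, 16], [8, 0, 8], [16, 8, 0]], dtype=float)
        h = self._haplotypes(["AAAA", "AATA", "TTTT"])  # placeholder topology
        d = DistanceMatrix(tuple(ids), vals)
        part = bd.parsimony_networks(h, d, ConnectionLimit(10))
        assert part.n_groups == 1  # a-b and b-c within limit; a-c joins via chain

    def test_isolated_haplotype_is_singleton_network(self):
        h = self._haplotypes(["AAAAAAAAAA", "AAAAAAAAAT", "TTTTTTTTTT"])
        steps = bd.mismatch_step_matrix(h.alignment())
        part = bd.parsimony_networks(h, steps, ConnectionLimit(3))
        assert part.n_groups == 2
        assert 1 in [len(b) for b in part.blocks]

    def test_network_count_non_increasing_in_max_steps(self):
        rng = np.random.default_rng(11)
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(12)]
        h = self._haplotypes(seqs)
        steps = bd.mismatch_step_matrix(h.alignment())
        counts = [
            bd.parsimony_networks(h, steps, ConnectionLimit(k)).n_groups
            for k in (2, 5, 10, 20)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_non_integer_step_matrix_rejected(self):
        h = self._haplotypes(["AAAA", "AATT"])
        bad = DistanceMatrix(("a", "b"), np.array([[0.0, 1.5], [1.5, 0.0]]))
        with pytest.raises(ValueError, match="integer"):
            bd.parsimony_networks(h, bad, ConnectionLimit(10))
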