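"""Morphospecies vs MOTU congruence accounting.

Reproduces the split/lump bookkeeping used to compare parataxonomic
morphospecies with molecular delimitations: perfect matches, split and
lumped reference groups, and the identity
perfect + split + lumped - both = reference groups.
"""

import barcodiv as bd

params = bd.SimParams(n_species=25, n_specimens=60, seed=8)
truth = bd.simulate_community(params)
tree = bd.simulate_genealogy(truth, params)
aln = bd.simulate_sequences(tree, params)
morpho = bd.corrupt_morphospecies(
    truth, params.split_rate, params.lump_rate, params.seed,
    species_order=bd.species_tip_order(tree, truth),
)
clusters = bd.cluster_by_threshold(bd.p_distance_matrix(aln), 0.03)

rep = bd.compare_partitions(morpho, clusters)
print(f"morphospecies:        {rep.n_ref_groups}")
print(f"distance clusters:    {rep.n_test_groups}")
print(f"perfect matches:      {rep.n_perfect_matches}"
      f"  ({rep.n_perfect_nonsingleton} non-singleton)")
print(f"split morphospecies:  {rep.n_split_ref}")
print(f"lumped morphospecies: {rep.n_lumped_ref}")
print(f"both:                 {rep.n_both_split_and_lumped}")
print(f"accuracy:             {rep.accuracy_percent:.2f}%")
check = (rep.n_perfect_matches + rep.n_split_ref + rep.n_lumped_ref
         - rep.n_both_split_and_lumped)
print(f"identity check:       {check} == {rep.n_ref_groups}")

mat = bd.pairwise_match_matrix(
    {"morphospecies": morpho, "clusters": clusters,
     "truth": truth.true_partition}
)
print("\npairwise perfect-match matrix (morpho / clusters / truth):")
print(mat)

# The diagonal holds each partition's group count; off-diagonal entries
# count groups delimited identically by the two methods.
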