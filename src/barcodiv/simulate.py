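"""Synthetic communities with known ground truth.

The generator emulates the structure of a singleton-heavy tropical insect
barcoding survey: a few hundred species with a geometric-series rank
abundance (about half the species represented by a single specimen),
sampled at three elevational levels with near-complete turnover, a
genealogy combining a Yule species tree with Kingman coalescents inside
species, COI-like 658-bp alignments evolved under Jukes-Cantor, and
parataxonomic morphospecies labels perturbed by split and lump errors.

Every stage draws from its own generator seeded deterministically from
``SimParams.seed``, so identical parameters reproduce identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .partition import Partition
from .seqs import Alignment
from .trees import TimeTree

ELEVATIONS = (1000, 2000, 3000)
STAGE_COMMUNITY, STAGE_GENEALOGY, STAGE_SEQUENCES, STAGE_MORPHO = 1, 2, 3, 4
_SINGLETON_BAND = 0.05
_CALIBRATION_CAP = 60
_COAL_HEADROOM = 0.95  # within-species TMRCA capped below the attachment age


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults emulate the study community."""

    n_species: int = 266
    n_specimens: int = 674
    abundance_model: Tuple[str, object] = ("geometric", None)
    target_singleton_fraction: float = 0.526
    speciation_rate: float = 1.0
    within_species_coalescent_scale: float = 0.015
    mutation_rate: float = 0.15
    alignment_length: int = 658
    n_levels: int = 3
    turnover_prob: float = 0.92
    split_rate: float = 0.10
    lump_rate: float = 0.10
    min_species_age_fraction: float = 0.15
    level_weights: Tuple[float, ...] = (0.23, 0.55, 0.22)
    units_per_level: int = 6  # per standardized collection method
    extra_methods: Tuple[str, ...] = ("light", "malaise")
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        for name in ("speciation_rate", "within_species_coalescent_scale",
                     "mutation_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("target_singleton_fraction", "turnover_prob",
                     "split_rate", "lump_rate", "min_species_age_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_levels < 1 or self.n_levels > len(ELEVATIONS):
            raise ValueError("n_levels must be between 1 and 3")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([stage, self.seed])


@dataclass(frozen=True)
class CommunityTruth:
    """Ground truth for one simulated community."""

    species_count: int
    abundances: Tuple[int, ...]
    true_partition: Partition
    level_of_species: Tuple[int, ...]       # primary elevation per species
    levels_of_species: Tuple[Tuple[int, ...], ...]  # all levels occupied
    sampling_unit_of_specimen: Dict[str, str]
    unit_table: Dict[str, Tuple[int, str]]  # unit -> (level, method)
    species_labels: Tuple[str, ...]
    seed: int

    def __post_init__(self):
        if sum(self.abundances) != len(self.sampling_unit_of_specimen):
            raise ValueError("abundances do not sum to the specimen count")
        if any(a < 1 for a in self.abundances):
            raise ValueError("every abundance must be >= 1")
        sizes = sorted(len(b) for b in self.true_partition.blocks)
        if sizes != sorted(self.abundances):
            raise ValueError("partition blocks do not match the abundance vector")

    @property
    def n_specimens(self) -> int:
        return int(sum(self.abundances))

    @property
    def specimen_ids(self) -> List[str]:
        return sorted(self.sampling_unit_of_specimen)

    def specimens_of_species(self, label: str) -> List[str]:
        return sorted(self.true_partition.block(label))

    def singleton_fraction(self) -> float:
        return sum(1 for a in self.abundances if a == 1) / self.species_count


# --------------------------------------------------------------------------- #
# community
# --------------------------------------------------------------------------- #


def _geometric_abundances(s: int, n: int, k: float) -> np.ndarray:
    """Motomura geometric-series rank abundances rounded to total ``n``."""
    ranks = np.arange(s)
    w = k * (1 - k) ** ranks
    w /= w.sum()
    raw = w * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    # smallest-abundance species forced to one specimen
    while (counts < 1).any():
        i = np.argmin(counts)
        j = np.argmax(counts)
        counts[i] += 1
        counts[j] -= 1
    return counts


def _calibrated_abundances(params: SimParams) -> np.ndarray:
    s, n = params.n_species, params.n_specimens
    target = params.target_singleton_fraction
    if n < s:
        raise ValueError("n_specimens must be at least n_species")
    lo, hi = 1e-4, 0.999
    best, best_gap = None, np.inf
    for _ in range(_CALIBRATION_CAP):
        k = (lo + hi) / 2
        counts = _geometric_abundances(s, n, k)
        frac = (counts == 1).mean()
        gap = abs(frac - target)
        if gap < best_gap:
            best, best_gap = counts, gap
        if gap <= _SINGLETON_BAND:
            return counts
        if frac < target:
            lo = k  # steeper series -> more singletons
        else:
            hi = k
    achieved = (best == 1).mean()
    raise ValueError(
        "could not reach the target singleton fraction "
        f"{target:.3f} within +/-{_SINGLETON_BAND}; best achieved {achieved:.3f}"
    )


def simulate_community(params: SimParams) -> CommunityTruth:
    """Draw abundances, elevation levels and sampling units."""
    rng = params.rng(STAGE_COMMUNITY)
    model, arg = params.abundance_model
    if model == "explicit":
        counts = np.asarray(arg, dtype=int)
        if len(counts) != params.n_species or (counts < 1).any():
            raise ValueError("explicit abundance vector is invalid")
    elif model == "geometric":
        if arg is not None:
            counts = _geometric_abundances(
                params.n_species, params.n_specimens, float(arg)
            )
        else:
            counts = _calibrated_abundances(params)
    else:
        raise ValueError(f"unknown abundance model {model!r}")

    s = params.n_species
    n = int(counts.sum())
    width = max(4, len(str(n)))
    swidth = max(3, len(str(s)))
    species_labels = tuple(f"T{i + 1:0{swidth}d}" for i in range(s))
    specimen_ids = [f"SP{i + 1:0{width}d}" for i in range(n)]

    # species -> specimens
    group_of = {}
    pos = 0
    for label, a in zip(species_labels, counts):
        for sp in specimen_ids[pos:pos + a]:
            group_of[sp] = label
        pos += a
    partition = Partition(group_of)

    # elevation levels with near-complete turnover
    levels = ELEVATIONS[: params.n_levels]
    weights = np.asarray(params.level_weights[: params.n_levels], dtype=float)
    weights /= weights.sum()
    primary = rng.choice(len(levels), size=s, p=weights)
    confined = rng.random(s) < params.turnover_prob
    levels_of = []
    for i in range(s):
        if confined[i] or len(levels) == 1:
            levels_of.append((levels[primary[i]],))
        else:
            neighbor = primary[i] + 1 if primary[i] + 1 < len(levels) else primary[i] - 1
            levels_of.append(tuple(sorted((levels[primary[i]], levels[neighbor]))))
    level_of_species = tuple(levels[primary[i]] for i in range(s))

    # sampling units: standardized methods plus occasional trap samples
    unit_table: Dict[str, Tuple[int, str]] = {}
    units_at_level: Dict[int, List[str]] = {lv: [] for lv in levels}
    from .richness import STANDARD_METHODS

    for lv in levels:
        for method in STANDARD_METHODS:
            for i in range(params.units_per_level):
                u = f"L{lv}_{method}{i + 1}"
                unit_table[u] = (lv, method)
                units_at_level[lv].append(u)
        for method in params.extra_methods:
            u = f"L{lv}_{method}1"
            unit_table[u] = (lv, method)
            units_at_level[lv].append(u)

    unit_of: Dict[str, str] = {}
    pos = 0
    for i, (label, a) in enumerate(zip(species_labels, counts)):
        occupied = levels_of[i]
        for sp in specimen_ids[pos:pos + a]:
            lv = occupied[int(rng.integers(len(occupied)))]
            pool = units_at_level[lv]
            unit_of[sp] = pool[int(rng.integers(len(pool)))]
        pos += a

    return CommunityTruth(
        species_count=s,
        abundances=tuple(int(c) for c in counts),
        true_partition=partition,
        level_of_species=level_of_species,
        levels_of_species=tuple(levels_of),
        sampling_unit_of_specimen=unit_of,
        unit_table=unit_table,
        species_labels=species_labels,
        seed=params.seed,
    )


# --------------------------------------------------------------------------- #
# genealogy
# --------------------------------------------------------------------------- #


def _yule_species_tree(labels: Sequence[str], params: SimParams,
                       rng: np.random.Generator) -> dendropy.Tree:
    import random as _random

    pyrng = _random.Random(int(rng.integers(2**31 - 1)))
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=params.speciation_rate,
        death_rate=0.0,
        num_extant_tips=len(labels),
        rng=pyrng,
    )
    # shuffle species onto tips so abundance rank is independent of topology
    leaves = list(tree.leaf_node_iter())
    shuffled = list(labels)
    perm = rng.permutation(len(shuffled))
    for leaf, idx in zip(leaves, perm):
        leaf.taxon.label = shuffled[idx]
    return tree


def _node_ages(tree: dendropy.Tree) -> Dict[dendropy.Node, float]:
    depths: Dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[node] = (depths[parent] + (node.edge.length or 0.0)) if parent else 0.0
    max_depth = max(d for n, d in depths.items() if n.is_leaf())
    return {n: max_depth - d for n, d in depths.items()}


def _normalize_and_floor(tree: dendropy.Tree, floor: float) -> None:
    """Rescale the species tree so the root sits at age 1, then push every
    speciation event above ``floor`` (emulating well-differentiated,
    deeply divergent sympatric species)."""
    ages = _node_ages(tree)
    root_age = ages[tree.seed_node]
    if root_age <= 0:
        raise ValueError("degenerate species tree")
    new_age = {}
    for node, a in ages.items():
        rel = a / root_age
        new_age[node] = 0.0 if node.is_leaf() else floor + (1 - floor) * rel
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = new_age[node.parent_node] - new_age[node]


def _kingman_subtree(
    specimens: Sequence[str],
    ne: float,
    rng: np.random.Generator,
    tns: dendropy.TaxonNamespace,
) -> Tuple[dendropy.Node, float]:
    """Pure Kingman coalescent over the specimens; returns (MRCA, TMRCA)."""
    active: List[Tuple[dendropy.Node, float]] = []
    for sp in specimens:
        node = dendropy.Node(taxon=tns.require_taxon(label=sp))
        active.append((node, 0.0))
    t = 0.0
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(ne / (j * (j - 1) / 2.0))
        i1, i2 = sorted(rng.choice(j, size=2, replace=False))
        n2, a2 = active.pop(i2)
        n1, a1 = active.pop(i1)
        parent = dendropy.Node()
        parent.add_child(n1)
        n1.edge.length = t - a1
        parent.add_child(n2)
        n2.edge.length = t - a2
        active.append((parent, t))
    node, tmrca = active[0]
    return node, tmrca


def simulate_genealogy(truth: CommunityTruth, params: SimParams) -> TimeTree:
    """Yule species tree with Kingman coalescents grafted inside species.

    The species tree is normalized to root age 1 (with a documented age
    floor on speciation events); each within-species subtree is strictly
    younger than the start of its species' terminal branch.
    """
    if truth.n_specimens < 2:
        raise ValueError("genealogy needs at least 2 specimens")
    rng = params.rng(STAGE_GENEALOGY)
    ne = params.within_species_coalescent_scale / 2.0

    if truth.species_count == 1:
        tns = dendropy.TaxonNamespace()
        specimens = truth.specimens_of_species(truth.species_labels[0])
        root, tmrca = _kingman_subtree(specimens, max(ne, 1e-9), rng, tns)
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node = root
        # normalize the pure coalescent root to age 1
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = (node.edge.length or 0.0) / tmrca
        return TimeTree(tree, ultrametric=True)

    sp_tree = _yule_species_tree(truth.species_labels, params, rng)
    _normalize_and_floor(sp_tree, params.min_species_age_fraction)
    ages = _node_ages(sp_tree)
    tns = sp_tree.taxon_namespace
    for leaf in list(sp_tree.leaf_node_iter()):
        label = leaf.taxon.label
        specimens = truth.specimens_of_species(label)
        attach_age = ages[leaf.parent_node]
        if len(specimens) == 1:
            leaf.taxon.label = specimens[0]
            continue
        subtree, tmrca = _kingman_subtree(specimens, ne, rng, tns)
        if tmrca >= _COAL_HEADROOM * attach_age:
            scale = _COAL_HEADROOM * attach_age / tmrca
            _rescale_subtree(subtree, scale)
            tmrca *= scale
        leaf.taxon = None
        leaf.edge.length = attach_age - tmrca
        for child in list(subtree.child_nodes()):
            leaf.add_child(child)
    return TimeTree(sp_tree, ultrametric=True)


def _rescale_subtree(root: dendropy.Node, scale: float) -> None:
    for node in root.preorder_iter():
        if node is not root and node.edge.length is not None:
            node.edge.length *= scale


def species_tip_order(tree: TimeTree, truth: CommunityTruth) -> List[str]:
    """Species labels in the order their first specimen appears along the
    genealogy's tips (the adjacency used for lumping errors)."""
    species_of = truth.true_partition.group_of_specimen
    seen: List[str] = []
    for tip in tree.tip_labels:
        sp = species_of[tip]
        if sp not in seen:
            seen.append(sp)
    return seen


# --------------------------------------------------------------------------- #
# sequences
# --------------------------------------------------------------------------- #


def simulate_sequences(tree: TimeTree, params: SimParams) -> Alignment:
    """Evolve an alignment along the tree under Jukes-Cantor.

    The root sequence is uniform random; on a branch of duration ``t`` each
    site changes with probability ``(3/4)(1 - exp(-4 mu t / 3))`` and picks
    one of the three other bases uniformly. Sequences are emitted already
    aligned (no indels).
    """
    if params.mutation_rate < 0:
        raise ValueError("mutation_rate must be >= 0")
    rng = params.rng(STAGE_SEQUENCES)
    L = params.alignment_length
    mu = params.mutation_rate
    seq_of: Dict[object, np.ndarray] = {}
    root = tree.tree.seed_node
    seq_of[root] = rng.integers(0, 4, size=L, dtype=np.int8)
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        p_change = 0.75 * (1.0 - np.exp(-4.0 * mu * t / 3.0))
        parent_seq = seq_of[node.parent_node]
        seq = parent_seq.copy()
        hits = rng.random(L) < p_change
        if hits.any():
            shift = rng.integers(1, 4, size=int(hits.sum()), dtype=np.int8)
            seq[hits] = (seq[hits] + shift) % 4
        seq_of[node] = seq
    bases = np.array(list("ACGT"))
    ids, seqs = [], []
    for leaf in tree.tree.leaf_node_iter():
        ids.append(leaf.taxon.label)
        seqs.append("".join(bases[seq_of[leaf]]))
    order = np.argsort(ids)
    return Alignment(
        tuple(np.array(ids)[order]), tuple(np.array(seqs)[order])
    )


# --------------------------------------------------------------------------- #
# morphospecies error
# --------------------------------------------------------------------------- #


def corrupt_morphospecies(
    truth: CommunityTruth,
    split_rate: float,
    lump_rate: float,
    seed: int,
    species_order: Optional[Sequence[str]] = None,
) -> Partition:
    """Parataxonomic morphospecies labels with split and lump errors.

    Each multi-specimen species is split into two labels with probability
    ``split_rate`` (random bipartition of its specimens); disjoint
    consecutive pairs of species — consecutive in ``species_order``, a
    proxy for morphological similarity of close relatives (pass the
    genealogy's tip order) — are merged with probability ``lump_rate``.
    """
    if not 0 <= split_rate <= 1 or not 0 <= lump_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng([STAGE_MORPHO, seed])
    order = list(species_order) if species_order else list(truth.species_labels)
    if sorted(order) != sorted(truth.species_labels):
        raise ValueError("species_order must be a permutation of the species")

    labels_of_species: Dict[str, List[str]] = {}
    mapping: Dict[str, str] = {}
    for sp_label in order:
        members = truth.specimens_of_species(sp_label)
        if len(members) >= 2 and rng.random() < split_rate:
            sides = rng.integers(0, 2, size=len(members))
            while sides.min() == sides.max():  # both halves must be non-empty
                sides = rng.integers(0, 2, size=len(members))
            la, lb = f"M_{sp_label}a", f"M_{sp_label}b"
            for m, s in zip(members, sides):
                mapping[m] = la if s == 0 else lb
            labels_of_species[sp_label] = [la, lb]
        else:
            lab = f"M_{sp_label}"
            for m in members:
                mapping[m] = lab
            labels_of_species[sp_label] = [lab]

    # lump disjoint consecutive pairs: the second species of a pair merges
    # into the first split-label of the first
    for i in range(0, len(order) - 1, 2):
        if rng.random() < lump_rate:
            first, second = order[i], order[i + 1]
            target = labels_of_species[first][0]
            absorbed = set(labels_of_species[second])
            for m, lab in mapping.items():
                if lab in absorbed:
                    mapping[m] = target
    return Partition(mapping).relabeled("M")


# --------------------------------------------------------------------------- #
# export
# --------------------------------------------------------------------------- #


def metadata_frame(truth: CommunityTruth, morphospecies: Partition) -> pd.DataFrame:
    """Specimen table: id, true species, morphospecies, unit, level, method."""
    rows = []
    for sp in truth.specimen_ids:
        unit = truth.sampling_unit_of_specimen[sp]
        level, method = truth.unit_table[unit]
        rows.append(
            {
                "specimen_id": sp,
                "true_species": truth.true_partition.label_of(sp),
                "morphospecies": morphospecies.label_of(sp),
                "sampling_unit": unit,
                "level": level,
                "method": method,
            }
        )
    return pd.DataFrame(rows)


def write_simulation(
    outdir: str | Path,
    truth: CommunityTruth,
    tree: TimeTree,
    aln: Alignment,
    morphospecies: Partition,
    params: SimParams,
) -> Dict[str, Path]:
    """Write FASTA, newick, metadata TSV and a JSON truth summary."""
    from .seqs import write_alignment

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "alignment.fasta",
        "tree": outdir / "genealogy.nwk",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
    }
    write_alignment(aln, paths["fasta"])
    tree.write_newick(paths["tree"])
    metadata_frame(truth, morphospecies).to_csv(
        paths["metadata"], sep="\t", index=False
    )
    summary = {
        "seed": truth.seed,
        "n_species": truth.species_count,
        "n_specimens": truth.n_specimens,
        "singleton_fraction": truth.singleton_fraction(),
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(params).items()
        },
    }
    paths["truth"].write_text(json.dumps(summary, indent=2, default=str))
    return paths
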