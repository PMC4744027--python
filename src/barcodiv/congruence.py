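"""Congruence accounting between specimen partitions.

Compares a reference partition (typically morphospecies) with a test
partition (a MOTU type): a reference group is a *perfect match* when some
test group contains exactly the same specimens, *split* when its specimens
are spread over two or more test groups, and *lumped* when a test group
mixes its specimens with those of another reference group. A group can be
split and lumped at the same time, so

    perfect + split + lumped - both = number of reference groups

holds as an exact identity.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Sequence

import numpy as np

from .partition import Partition, check_same_specimens


def round_half_up(x: float, decimals: int = 2) -> float:
    """Half-up rounding used for reported percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CongruenceReport:
    n_ref_groups: int
    n_test_groups: int
    n_perfect_matches: int
    n_perfect_nonsingleton: int
    n_split_ref: int
    n_lumped_ref: int
    n_both_split_and_lumped: int
    accuracy_percent: float
    ratio_test_vs_ref: float
    singleton_count_test: int
    doubleton_count_test: int

    def to_dict(self) -> Dict[str, float]:
        return asdict(self)


def compare_partitions(ref: Partition, test: Partition) -> CongruenceReport:
    """Classify every reference group as perfect / split / lumped / both."""
    check_same_specimens(ref, test)
    test_blocks = test.block_set()
    ref_of = ref.group_of_specimen
    perfect = split = lumped = both = perfect_nonsingleton = 0
    for block in ref.blocks:
        test_labels = {test.label_of(sp) for sp in block}
        is_split = len(test_labels) >= 2
        is_lumped = any(
            any(ref_of[other] != ref.label_of(next(iter(block)))
                for other in test.block(lbl))
            for lbl in test_labels
        )
        if block in test_blocks:
            perfect += 1
            if len(block) >= 2:
                perfect_nonsingleton += 1
        if is_split:
            split += 1
        if is_lumped:
            lumped += 1
        if is_split and is_lumped:
            both += 1
    return CongruenceReport(
        n_ref_groups=ref.n_groups,
        n_test_groups=test.n_groups,
        n_perfect_matches=perfect,
        n_perfect_nonsingleton=perfect_nonsingleton,
        n_split_ref=split,
        n_lumped_ref=lumped,
        n_both_split_and_lumped=both,
        accuracy_percent=100.0 * perfect / ref.n_groups,
        ratio_test_vs_ref=test.n_groups / ref.n_groups,
        singleton_count_test=test.singleton_count(),
        doubleton_count_test=test.doubleton_count(),
    )


def pairwise_match_matrix(
    partitions: Dict[str, Partition]
) -> "np.ndarray":
    """Symmetric matrix of perfectly matching group counts.

    Diagonal holds each partition's group count; entry (i, j) the number of
    blocks delimited identically by methods i and j. Row/column order is the
    dict's insertion order.
    """
    names = list(partitions)
    parts = [partitions[n] for n in names]
    first = parts[0]
    for p in parts[1:]:
        check_same_specimens(first, p)
    block_sets = [p.block_set() for p in parts]
    k = len(parts)
    mat = np.zeros((k, k), dtype=int)
    for i in range(k):
        mat[i, i] = parts[i].n_groups
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = len(block_sets[i] & block_sets[j])
    return mat


@dataclass(frozen=True)
class MotuSummary:
    n_groups: int
    n_singletons: int
    n_doubleton_pairs: int
    n_doubleton_specimens: int
    singleton_fraction_percent: float


def motu_summary(p: Partition) -> MotuSummary:
    """Group counts plus singleton/doubleton accounting for one partition."""
    singles = p.singleton_count()
    pairs = p.doubleton_count()
    return MotuSummary(
        n_groups=p.n_groups,
        n_singletons=singles,
        n_doubleton_pairs=pairs,
        n_doubleton_specimens=2 * pairs,
        singleton_fraction_percent=round_half_up(100.0 * singles / p.n_groups, 1),
    )


def report_rows(reports: Dict[str, CongruenceReport]) -> List[Sequence]:
    """TSV-ready rows mirroring the published split/lump overview table."""
    header = ["quantity", *reports]
    rows: List[Sequence] = [header]
    fields = [
        ("Species number", "n_test_groups"),
        ("Number of singleton specimens", "singleton_count_test"),
        ("Number of doubleton pairs", "doubleton_count_test"),
        ("Ratio MOTU vs reference", "ratio_test_vs_ref"),
        ("Perfect matches", "n_perfect_matches"),
        ("Perfect matches that are not singletons", "n_perfect_nonsingleton"),
        ("Accuracy (%)", "accuracy_percent"),
        ("Split reference groups", "n_split_ref"),
        ("Lumped reference groups", "n_lumped_ref"),
        ("Both split and lumped", "n_both_split_and_lumped"),
    ]
    for label, attr in fields:
        row = [label]
        for rep in reports.values():
            v = getattr(rep, attr)
            if attr == "accuracy_percent":
                v = round_half_up(v, 2)
            elif attr == "ratio_test_vs_ref":
                v = round_half_up(v, 2)
            row.append(v)
        rows.append(row)
    return rows
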