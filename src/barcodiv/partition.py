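"""Specimen partitions: the common currency of every delimitation method.

A :class:`Partition` assigns every specimen to exactly one group — a
morphospecies, a haplotype network, a distance cluster, a GMYC or a PTP
entity. All downstream congruence and richness code consumes this one type.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from typing import Dict, FrozenSet, List, Tuple


class Partition:
    """An assignment of specimens to disjoint, non-empty groups.

    Parameters
    ----------
    group_of_specimen:
        Mapping from specimen id to group label. Labels may be any hashable
        (strings in practice).
    """

    def __init__(self, group_of_specimen: Mapping[str, str]):
        if not group_of_specimen:
            raise ValueError("partition must contain at least one specimen")
        self._group_of: Dict[str, str] = dict(group_of_specimen)
        blocks: Dict[str, set] = {}
        for sp, g in self._group_of.items():
            blocks.setdefault(g, set()).add(sp)
        self._blocks: Dict[str, FrozenSet[str]] = {
            g: frozenset(members) for g, members in blocks.items()
        }

    # ------------------------------------------------------------------ #
    @classmethod
    def from_blocks(cls, blocks: Iterable[Iterable[str]],
                    labels: Iterable[str] | None = None) -> "Partition":
        blocks = [list(b) for b in blocks]
        if labels is None:
            labels = [f"g{i}" for i in range(len(blocks))]
        mapping: Dict[str, str] = {}
        for label, members in zip(labels, blocks, strict=True):
            if not members:
                raise ValueError("empty block in partition")
            for sp in members:
                if sp in mapping:
                    raise ValueError(f"specimen {sp!r} appears in two blocks")
                mapping[sp] = label
        return cls(mapping)

    # ------------------------------------------------------------------ #
    @property
    def group_of_specimen(self) -> Dict[str, str]:
        return dict(self._group_of)

    @property
    def specimens(self) -> FrozenSet[str]:
        return frozenset(self._group_of)

    @property
    def labels(self) -> List[str]:
        return sorted(self._blocks, key=str)

    @property
    def blocks(self) -> List[FrozenSet[str]]:
        """Blocks in deterministic order (sorted by label)."""
        return [self._blocks[g] for g in self.labels]

    def block(self, label: str) -> FrozenSet[str]:
        return self._blocks[label]

    def label_of(self, specimen: str) -> str:
        return self._group_of[specimen]

    @property
    def n_groups(self) -> int:
        return len(self._blocks)

    def block_sizes(self) -> List[int]:
        return sorted(len(b) for b in self._blocks.values())

    def singleton_count(self) -> int:
        return sum(1 for b in self._blocks.values() if len(b) == 1)

    def doubleton_count(self) -> int:
        """Number of groups with exactly two specimens (pairs, not specimens)."""
        return sum(1 for b in self._blocks.values() if len(b) == 2)

    def block_set(self) -> FrozenSet[FrozenSet[str]]:
        return frozenset(self._blocks.values())

    def relabeled(self, prefix: str) -> "Partition":
        """Deterministically relabel groups ``<prefix><k>`` ordered by the
        smallest specimen id each block contains."""
        ordered = sorted(self._blocks.values(), key=lambda b: min(b))
        width = max(1, len(str(len(ordered))))
        mapping = {}
        for k, members in enumerate(ordered, start=1):
            label = f"{prefix}{k:0{width}d}"
            for sp in members:
                mapping[sp] = label
        return Partition(mapping)

    # ------------------------------------------------------------------ #
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.block_set() == other.block_set()

    def __hash__(self):  # pragma: no cover - partitions used in sets rarely
        return hash(self.block_set())

    def __len__(self) -> int:
        return len(self._group_of)

    def __repr__(self) -> str:
        return f"Partition({len(self)} specimens, {self.n_groups} groups)"

    # ------------------------------------------------------------------ #
    def to_rows(self, method: str) -> List[Tuple[str, str, str]]:
        """Rows ``(specimen_id, method, group_label)`` for TSV export."""
        return [(sp, method, self._group_of[sp]) for sp in sorted(self._group_of)]


def check_same_specimens(a: Partition, b: Partition) -> None:
    """Raise ValueError listing the symmetric difference if specimen sets differ."""
    if a.specimens != b.specimens:
        diff = sorted(a.specimens ^ b.specimens)
        raise ValueError(
            "partitions cover different specimen sets; symmetric difference: "
            + ", ".join(diff[:20])
            + ("..." if len(diff) > 20 else "")
        )
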