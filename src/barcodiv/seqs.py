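"""Alignment handling: FASTA I/O, uncorrected distances, haplotype collapsing.

Distances are uncorrected ("p") distances as used by threshold clustering of
COI barcodes: mismatches divided by comparable sites. Sites holding a gap or
any IUPAC ambiguity code in either sequence of a pair are excluded pairwise
(policy ``pairwise_deletion``); ``complete_deletion`` drops such columns
alignment-wide before any comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

IUPAC_DNA = set("ACGTRYSWKMBDHVN-")
_BASES = "ACGT"
# byte codes: A,C,G,T -> 0..3; anything ambiguous/gap -> 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i


@dataclass(frozen=True)
class Alignment:
    """Equal-length DNA sequences, one per specimen, ids unique."""

    ids: Tuple[str, ...]
    sequences: Tuple[str, ...]

    def __post_init__(self):
        if not self.ids:
            raise ValueError("alignment is empty")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {', '.join(dupes)}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            ref = len(self.sequences[0])
            bad = [i for i, s in zip(self.ids, self.sequences) if len(s) != ref]
            raise ValueError(
                "ragged alignment; records differing from first record's "
                f"length {ref}: {', '.join(bad)}"
            )
        for sid, seq in zip(self.ids, self.sequences):
            bad_chars = set(seq) - IUPAC_DNA
            if bad_chars:
                raise ValueError(
                    f"record {sid!r} contains non-IUPAC characters: "
                    f"{''.join(sorted(bad_chars))}"
                )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n(self) -> int:
        return len(self.ids)

    def sequence_of(self, sid: str) -> str:
        return self.sequences[self.ids.index(sid)]

    def encoded(self) -> np.ndarray:
        """(n, L) uint8 matrix; A,C,G,T -> 0..3, gap/ambiguity -> 255."""
        raw = np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(self.n, self.length)
        return _CODE[raw]

    def subset(self, ids: Sequence[str]) -> "Alignment":
        idx = {i: k for k, i in enumerate(self.ids)}
        return Alignment(tuple(ids), tuple(self.sequences[idx[i]] for i in ids))


def read_alignment(path: str | Path) -> Alignment:
    """Read and validate an aligned FASTA file (sequences upper-cased)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    return Alignment(ids, seqs)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.sequences)
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


# --------------------------------------------------------------------------- #
# distances
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise values with a zero diagonal."""

    ids: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )


def _pair_counts(enc: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Pairwise (mismatches, comparable sites) over A/C/G/T positions only.

    Chunked over rows so the (n, n, L) broadcast never materialises.
    """
    n, L = enc.shape
    valid = enc != 255
    mism = np.zeros((n, n), dtype=np.int64)
    comp = np.zeros((n, n), dtype=np.int64)
    chunk = max(1, int(4e7 // (n * L + 1)) or 1)
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        both = valid[start:stop, None, :] & valid[None, :, :]
        diff = (enc[start:stop, None, :] != enc[None, :, :]) & both
        comp[start:stop] = both.sum(axis=2)
        mism[start:stop] = diff.sum(axis=2)
    return mism, comp


def p_distance_matrix(
    aln: Alignment, policy: str = "pairwise_deletion"
) -> DistanceMatrix:
    """Uncorrected pairwise distances: mismatches / comparable sites.

    A pair with zero comparable sites gets distance 0 with a logged warning.
    """
    if aln.n < 2:
        raise ValueError("p-distance needs at least two records")
    enc = _prepare_encoded(aln, policy)
    mism, comp = _pair_counts(enc)
    empty = (comp == 0) & ~np.eye(aln.n, dtype=bool)
    if empty.any():
        logger.warning(
            "%d specimen pairs share no comparable sites; their distance is "
            "defined as 0",
            int(empty.sum()) // 2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(comp > 0, mism / np.maximum(comp, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(aln.ids, d)


def mismatch_step_matrix(
    aln: Alignment, policy: str = "pairwise_deletion"
) -> DistanceMatrix:
    """Absolute mutational steps: raw mismatch counts on comparable sites."""
    if aln.n < 2:
        raise ValueError("step matrix needs at least two records")
    enc = _prepare_encoded(aln, policy)
    mism, _ = _pair_counts(enc)
    return DistanceMatrix(aln.ids, mism.astype(float))


def _prepare_encoded(aln: Alignment, policy: str) -> np.ndarray:
    enc = aln.encoded()
    if policy == "pairwise_deletion":
        return enc
    if policy == "complete_deletion":
        keep = (enc != 255).all(axis=0)
        return enc[:, keep]
    raise ValueError(f"unknown ambiguity policy {policy!r}")


# --------------------------------------------------------------------------- #
# haplotypes
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class HaplotypeTable:
    """Specimens collapsed to unique sequences (strict string identity)."""

    haplotype_of_specimen: Dict[str, int]
    representative_sequence: Tuple[str, ...]
    representative_specimen: Tuple[str, ...]

    @property
    def n_haplotypes(self) -> int:
        return len(self.representative_sequence)

    def specimens_of(self, h: int) -> List[str]:
        return sorted(
            s for s, k in self.haplotype_of_specimen.items() if k == h
        )

    def to_partition(self) -> "Partition":
        from .partition import Partition

        mapping = {
            s: f"h{k}" for s, k in self.haplotype_of_specimen.items()
        }
        return Partition(mapping).relabeled("H")

    def alignment(self) -> Alignment:
        """One representative record per haplotype."""
        return Alignment(self.representative_specimen, self.representative_sequence)


def collapse_haplotypes(aln: Alignment, policy: str = "strict") -> HaplotypeTable:
    """Group specimens whose sequences are exactly identical strings.

    Sequences differing only at gap/ambiguity sites are *not* merged; this
    keeps the haplotype count independent of record order.
    """
    if policy != "strict":
        raise ValueError(f"unknown haplotype policy {policy!r}")
    # assign dense indices in order of the lexicographically sorted sequences
    # so the table is invariant under record reordering
    uniq = sorted(set(aln.sequences))
    index = {s: k for k, s in enumerate(uniq)}
    hap_of = {sid: index[seq] for sid, seq in zip(aln.ids, aln.sequences)}
    reps: List[str] = []
    for seq in uniq:
        members = [sid for sid, s in zip(aln.ids, aln.sequences) if s == seq]
        reps.append(min(members))
    return HaplotypeTable(hap_of, tuple(uniq), tuple(reps))
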