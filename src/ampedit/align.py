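"""Read containers, quality filtering, and global read-to-amplicon alignment.

Alignment is global with affine gap penalties (match +2, mismatch -4,
gap open -10, gap extend -1). A read whose fraction of identical aligned
bases over ``max(len(read), len(ref))`` falls below the identity floor
(default 0.6) is counted as unaligned and excluded from ``aligned_total``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align

from .refs import AmpliconRef

MATCH = 2
MISMATCH = -4
GAP_OPEN = -10
GAP_EXTEND = -1
IDENTITY_FLOOR = 0.6


@dataclass(frozen=True)
class Read:
    """A sequencing read with per-base Phred qualities."""

    name: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities lengths differ")

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities)


def quality_filter(reads: list[Read], min_mean_q: float = 30.0) -> list[Read]:
    """Retain reads with mean Phred quality >= ``min_mean_q``, order preserved."""
    return [r for r in reads if r.mean_quality >= min_mean_q]


@dataclass(frozen=True)
class ReadAlignment:
    """Alignment of one read to the amplicon, in reference coordinates.

    ``calls`` holds, for every reference position, the read base aligned
    there or ``'-'`` where the read has a deletion. ``insertions`` are
    ``(inter_base_ref_coord, inserted_sequence)``; ``deletions`` are
    half-open reference intervals; ``substitutions`` are reference
    positions where the aligned read base differs from the reference.
    """

    score: float
    identity: float
    aligned: bool
    calls: str
    insertions: tuple[tuple[int, str], ...]
    deletions: tuple[tuple[int, int], ...]
    substitutions: tuple[int, ...]

    def has_indel_overlapping(self, start: int, end: int) -> bool:
        """Any indel touching window [start, end)? Insertions at a window
        boundary count as overlapping (conservative)."""
        for pos, _ in self.insertions:
            if start <= pos <= end:
                return True
        for d0, d1 in self.deletions:
            if d0 < end and d1 > start:
                return True
        return False


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


@lru_cache(maxsize=200_000)
def _align_cached(read_seq: str, ref_seq: str) -> ReadAlignment:
    aln = _ALIGNER.align(ref_seq, read_seq)[0]
    ref_blocks, read_blocks = aln.aligned

    calls = ["-"] * len(ref_seq)
    insertions: list[tuple[int, str]] = []
    deletions: list[tuple[int, int]] = []
    substitutions: list[int] = []
    matches = 0

    prev_ref_end = 0
    prev_read_end = 0
    for (r0, r1), (q0, q1) in zip(ref_blocks, read_blocks):
        # gap before this block: deletion (ref advances) and/or insertion
        if r0 > prev_ref_end:
            deletions.append((prev_ref_end, r0))
        if q0 > prev_read_end:
            insertions.append((r0, read_seq[prev_read_end:q0]))
        for i in range(r1 - r0):
            b = read_seq[q0 + i]
            calls[r0 + i] = b
            if b == ref_seq[r0 + i]:
                matches += 1
            else:
                substitutions.append(r0 + i)
        prev_ref_end, prev_read_end = r1, q1
    if prev_ref_end < len(ref_seq):
        deletions.append((prev_ref_end, len(ref_seq)))
    if prev_read_end < len(read_seq):
        insertions.append((len(ref_seq), read_seq[prev_read_end:]))

    identity = matches / max(len(ref_seq), len(read_seq))
    return ReadAlignment(
        score=float(aln.score),
        identity=identity,
        aligned=identity >= IDENTITY_FLOOR,
        calls="".join(calls),
        insertions=tuple(insertions),
        deletions=tuple(deletions),
        substitutions=tuple(substitutions),
    )


def align_read(read: Read | str, ref: AmpliconRef) -> ReadAlignment:
    """Globally align a read to the amplicon reference.

    Results are memoized on the read sequence: amplicon read sets are
    highly redundant, so repeated sequences align once.
    """
    seq = read if isinstance(read, str) else read.sequence
    if not seq:
        raise ValueError("read is empty")
    return _align_cached(seq, ref.sequence)
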