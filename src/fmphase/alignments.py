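"""Parsed alignment container shared by the coverage, junction and phasing stages.

A long read spanning a rearrangement junction is represented by an aligner
as a primary record plus supplementary records (``SA``-tagged split
alignments).  :class:`AlignedRead` regroups those records per read id into
ordered :class:`AlignmentBlock` s carrying both reference coordinates and the
block's interval on the read as sequenced, which is what junction
classification walks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pysam

_CLIP_OPS = {4, 5}  # S, H


@dataclass
class AlignmentBlock:
    """One SAM record of a (possibly chimeric) read.

    ``qstart``/``qend`` are the 0-based half-open interval the block covers
    on the read *as sequenced* (original read orientation), so blocks of one
    read are disjoint and sortable along the read.
    """

    ref_start: int  # 1-based inclusive
    ref_end: int
    reverse: bool
    qstart: int
    qend: int
    supplementary: bool
    record: pysam.AlignedSegment
    region: str | None = None
    _pairs: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start + 1

    @property
    def query_span(self) -> int:
        return self.qend - self.qstart

    def _aligned_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(ref positions 1-based, offsets into the stored record sequence)."""
        if self._pairs is None:
            pairs = self.record.get_aligned_pairs(matches_only=True)
            q = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
            r = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs)) + 1
            self._pairs = (r, q)
        return self._pairs

    def base_at(self, ref_pos: int) -> str | None:
        """Read base aligned to a reference position (reference strand), or None."""
        if not self.ref_start <= ref_pos <= self.ref_end:
            return None
        r, q = self._aligned_pairs()
        i = np.searchsorted(r, ref_pos)
        if i >= r.size or r[i] != ref_pos:
            return None  # deletion in the read
        seq = self.record.query_sequence
        if seq is None:
            return None
        base = seq[int(q[i])]
        return base if base in "ACGT" else None


@dataclass
class AlignedRead:
    """All alignment blocks of one read, ordered along the read."""

    name: str
    length: int
    blocks: list[AlignmentBlock]

    def sort_blocks(self) -> None:
        self.blocks.sort(key=lambda b: b.qstart)

    def regions(self) -> set[str]:
        return {b.region for b in self.blocks if b.region is not None}

    def base_at(self, ref_pos: int) -> str | None:
        """Base at a reference position; ambiguous across blocks -> None."""
        calls = {b.base_at(ref_pos) for b in self.blocks}
        calls.discard(None)
        if len(calls) == 1:
            return calls.pop()
        return None

    def reversed_view(self) -> "AlignedRead":
        """The same alignments as read from the opposite sequencing strand."""
        L = self.length
        blocks = [
            AlignmentBlock(
                ref_start=b.ref_start,
                ref_end=b.ref_end,
                reverse=not b.reverse,
                qstart=L - b.qend,
                qend=L - b.qstart,
                supplementary=b.supplementary,
                record=b.record,
                region=b.region,
            )
            for b in self.blocks
        ]
        read = AlignedRead(self.name, L, blocks)
        read.sort_blocks()
        return read


def _block_from_record(rec: pysam.AlignedSegment) -> AlignmentBlock:
    cig = rec.cigartuples or []
    left = 0
    for op, n in cig:
        if op in _CLIP_OPS:
            left += n
        else:
            break
    right = 0
    for op, n in reversed(cig):
        if op in _CLIP_OPS:
            right += n
        else:
            break
    qalen = rec.query_alignment_length
    qstart = right if rec.is_reverse else left
    return AlignmentBlock(
        ref_start=rec.reference_start + 1,
        ref_end=rec.reference_end,
        reverse=rec.is_reverse,
        qstart=qstart,
        qend=qstart + qalen,
        supplementary=rec.is_supplementary,
        record=rec,
    )


def group_reads(records: Iterable[pysam.AlignedSegment]) -> tuple[list[AlignedRead], int]:
    """Group primary + supplementary records per read id.

    Secondary alignments are ignored; unmapped records are counted and
    skipped.  Returns (reads, n_unmapped).
    """
    by_name: dict[str, list[pysam.AlignedSegment]] = {}
    n_unmapped = 0
    for rec in records:
        if rec.is_unmapped:
            n_unmapped += 1
            continue
        if rec.is_secondary:
            continue
        key = rec.query_name
        if rec.is_paired:
            key = f"{rec.query_name}/{1 if rec.is_read1 else 2}"
        by_name.setdefault(key, []).append(rec)
    reads = []
    for name, recs in by_name.items():
        blocks = [_block_from_record(r) for r in recs]
        length = max(_read_length(r) for r in recs)
        read = AlignedRead(name, length, blocks)
        read.sort_blocks()
        reads.append(read)
    return reads, n_unmapped


def _read_length(rec: pysam.AlignedSegment) -> int:
    cig = rec.cigartuples or []
    total = rec.query_alignment_length
    for op, n in cig:
        if op in _CLIP_OPS:
            total += n
    return total


def read_sam(path: str) -> Iterator[pysam.AlignedSegment]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        yield from fh


def load_reads(path: str) -> tuple[list[AlignedRead], int]:
    return group_reads(read_sam(path))
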