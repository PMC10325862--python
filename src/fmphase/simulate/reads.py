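"""Simulated long-read and short-read alignments against the un-rearranged reference.

Reads are drawn from the built sample chromosomes and *placed* on the
reference through the truth projection map rather than run through an
aligner: a read overlapping k projection segments yields k SAM records (one
primary plus supplementary records carrying ``SA`` tags), with
match/soft-clip CIGARs, exactly the representation an aligner produces for a
rearrangement-spanning chimeric read.  Substitution errors are i.i.d. per
base; there are no indels, so every reference column a record covers
corresponds to one read base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .genome import Haplotype, ProjectionBlock, ReadTruth, SimConfig, TruthSet, revcomp

MAPQ = 60


@dataclass(frozen=True)
class SimAlignment:
    """One alignment block of a simulated read, in final read orientation."""

    ref_start: int  # 1-based inclusive
    ref_end: int
    reverse: bool
    qstart: int  # 0-based half-open interval on the read as sequenced
    qend: int
    region: str
    copy_index: int


def _project_read(
    hap: Haplotype, read_s: int, read_e: int, flip: bool
) -> list[SimAlignment]:
    """Split a sample interval into reference alignment blocks."""
    L = read_e - read_s + 1
    out = []
    for b in hap.blocks_overlapping(read_s, read_e):
        os, oe = max(read_s, b.sample_start), min(read_e, b.sample_end)
        qstart, qend = os - read_s, oe - read_s + 1
        if b.inverted:
            ref_lo, ref_hi = b.sample_to_ref(oe), b.sample_to_ref(os)
            reverse = True
        else:
            ref_lo, ref_hi = b.sample_to_ref(os), b.sample_to_ref(oe)
            reverse = False
        if flip:
            qstart, qend = L - qend, L - qstart
            reverse = not reverse
        out.append(
            SimAlignment(ref_lo, ref_hi, reverse, qstart, qend, b.region, b.copy_index)
        )
    out.sort(key=lambda a: a.qstart)
    return out


def _truth_blocks(hap: Haplotype, read_s: int, read_e: int) -> list[ProjectionBlock]:
    out = []
    for b in hap.blocks_overlapping(read_s, read_e):
        os, oe = max(read_s, b.sample_start), min(read_e, b.sample_end)
        if b.inverted:
            lo, hi = b.sample_to_ref(oe), b.sample_to_ref(os)
        else:
            lo, hi = b.sample_to_ref(os), b.sample_to_ref(oe)
        out.append(ProjectionBlock(os, oe, lo, hi, b.inverted, b.region, b.copy_index))
    return out


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < error_rate
    n = int(mask.sum())
    if n:
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        idx = np.searchsorted(np.sort(lut), arr[mask])
        shift = rng.integers(1, 4, size=n)
        arr[mask] = lut[(idx + shift) % 4]
    return arr.tobytes().decode()


def sam_header(region_map) -> pysam.AlignmentHeader:
    _, span_end = region_map.span
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": region_map.chrom, "LN": int(span_end)}],
        }
    )


def _cigar(aln: SimAlignment, read_len: int) -> list[tuple[int, int]]:
    mlen = aln.qend - aln.qstart
    if aln.reverse:
        left, right = read_len - aln.qend, aln.qstart
    else:
        left, right = aln.qstart, read_len - aln.qend
    ops = []
    if left:
        ops.append((4, left))
    ops.append((0, mlen))
    if right:
        ops.append((4, right))
    return ops


def _cigar_str(ops: list[tuple[int, int]]) -> str:
    sym = {0: "M", 4: "S"}
    return "".join(f"{n}{sym[op]}" for op, n in ops)


def _records_for_read(
    name: str,
    read_seq: str,
    alignments: list[SimAlignment],
    header: pysam.AlignmentHeader,
    chrom: str,
) -> list[pysam.AlignedSegment]:
    L = len(read_seq)
    primary_idx = max(range(len(alignments)), key=lambda i: alignments[i].qend - alignments[i].qstart)
    sa_parts = []
    for aln in alignments:
        sa_parts.append(
            f"{chrom},{aln.ref_start},{'-' if aln.reverse else '+'},"
            f"{_cigar_str(_cigar(aln, L))},{MAPQ},0"
        )
    rc = revcomp(read_seq)
    records = []
    for i, aln in enumerate(alignments):
        rec = pysam.AlignedSegment(header)
        rec.query_name = name
        rec.reference_id = 0
        rec.reference_start = aln.ref_start - 1
        rec.mapping_quality = MAPQ
        flag = 0
        if aln.reverse:
            flag |= 16
        if i != primary_idx:
            flag |= 2048
        rec.flag = flag
        rec.cigartuples = _cigar(aln, L)
        rec.query_sequence = rc if aln.reverse else read_seq
        if len(alignments) > 1:
            others = ";".join(sa_parts[j] for j in range(len(alignments)) if j != i)
            rec.set_tag("SA", others + ";")
        records.append(rec)
    return records


# --------------------------------------------------------------------------
# Long reads


def simulate_long_reads(
    cfg: SimConfig, truth: TruthSet, rng: np.random.Generator | None = None
) -> list[pysam.AlignedSegment]:
    """Draw long reads from both chromosomes and emit split SAM records.

    Reads start uniformly along each haplotype; lengths are log-normal
    (median ``read_length_median``), truncated at the chromosome end.  Each
    chromosome is sampled at half the configured total depth.  Truth entries
    are recorded in ``truth.reads``.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 1])
    header = sam_header(cfg.region_map)
    chrom = cfg.region_map.chrom
    records: list[pysam.AlignedSegment] = []
    mu = np.log(cfg.read_length_median)
    for ci, hap in enumerate(truth.haplotypes):
        L = len(hap.sequence)
        target = L * cfg.long_read_depth / 2.0
        total = 0.0
        i = 0
        while total < target:
            length = int(np.exp(rng.normal(mu, cfg.read_length_sigma)))
            length = max(cfg.min_read_length, length)
            # starts may overhang the left edge (clipped below) so coverage
            # is stationary along the chromosome rather than edge-tapered
            start = int(rng.integers(2 - length, L + 1))
            end = min(L, start + length - 1)
            start = max(1, start)
            if end - start + 1 < cfg.min_read_length:
                continue
            name = f"L{ci}_{i}"
            i += 1
            total += end - start + 1
            flip = bool(rng.integers(0, 2))
            seq = hap.sequence[start - 1 : end]
            if flip:
                seq = revcomp(seq)
            seq = _mutate(seq, cfg.error_rate, rng)
            alignments = _project_read(hap, start, end, flip)
            records.extend(_records_for_read(name, seq, alignments, header, chrom))
            truth.reads[name] = ReadTruth(
                read_id=name,
                chrom_index=ci,
                sample_start=start,
                sample_end=end,
                blocks=_truth_blocks(hap, start, end),
            )
    return records


# --------------------------------------------------------------------------
# Short reads


def _merge_native(alignments: list[SimAlignment]) -> list[SimAlignment]:
    """Merge read-adjacent blocks that are reference-contiguous on one strand.

    Consecutive projection segments that are neighbours in the reference
    (native adjacencies) would never split a real alignment; only true
    rearrangement junctions clip reads.
    """
    merged: list[SimAlignment] = []
    for aln in sorted(alignments, key=lambda a: a.qstart):
        if merged:
            prev = merged[-1]
            contiguous = (
                prev.reverse == aln.reverse
                and aln.qstart == prev.qend
                and (
                    (not aln.reverse and aln.ref_start == prev.ref_end + 1)
                    or (aln.reverse and aln.ref_end == prev.ref_start - 1)
                )
            )
            if contiguous:
                merged[-1] = SimAlignment(
                    ref_start=min(prev.ref_start, aln.ref_start),
                    ref_end=max(prev.ref_end, aln.ref_end),
                    reverse=prev.reverse,
                    qstart=prev.qstart,
                    qend=aln.qend,
                    region=prev.region,
                    copy_index=prev.copy_index,
                )
                continue
        merged.append(aln)
    return merged


def simulate_short_reads(
    cfg: SimConfig, truth: TruthSet, rng: np.random.Generator | None = None
) -> list[pysam.AlignedSegment]:
    """Paired-end short reads; junction-crossing mates are soft-clipped.

    A mate overlapping several projection segments is aligned to the segment
    holding most of it (the rest soft-clipped), which reproduces the abrupt
    per-base depth step short reads show at duplication breakpoints.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 2])
    header = sam_header(cfg.region_map)
    chrom = cfg.region_map.chrom
    rl = cfg.short_read_length
    records: list[pysam.AlignedSegment] = []
    for ci, hap in enumerate(truth.haplotypes):
        L = len(hap.sequence)
        n_frags = int(round(L * cfg.short_read_depth / 2.0 / (2 * rl)))
        for i in range(n_frags):
            frag = int(max(2 * rl, rng.normal(cfg.insert_mean, cfg.insert_sd)))
            start = int(rng.integers(1, max(2, L - frag + 1)))
            frag = min(frag, L - start + 1)
            if frag < 2 * rl:
                continue
            name = f"S{ci}_{i}"
            mates = [
                (start, start + rl - 1, False, 64),
                (start + frag - rl, start + frag - 1, True, 128),
            ]
            mate_recs = []
            for ms, me, flip, mate_flag in mates:
                seq = hap.sequence[ms - 1 : me]
                if flip:
                    seq = revcomp(seq)
                seq = _mutate(seq, cfg.error_rate, rng)
                alignments = _merge_native(_project_read(hap, ms, me, flip))
                best = max(alignments, key=lambda a: a.qend - a.qstart)
                rec = pysam.AlignedSegment(header)
                rec.query_name = name
                rec.reference_id = 0
                rec.reference_start = best.ref_start - 1
                rec.mapping_quality = MAPQ
                flag = 1 | mate_flag
                if best.reverse:
                    flag |= 16
                rec.flag = flag
                rec.cigartuples = _cigar(best, rl)
                rec.query_sequence = revcomp(seq) if best.reverse else seq
                mate_recs.append(rec)
            a, b = mate_recs
            a.flag |= 32 if b.is_reverse else 0
            b.flag |= 32 if a.is_reverse else 0
            a.next_reference_id = b.next_reference_id = 0
            a.next_reference_start = b.reference_start
            b.next_reference_start = a.reference_start
            records.extend(mate_recs)
    return records


@dataclass(frozen=True)
class SpanRecord:
    """Alignment span only -- duck-typed stand-in for depth computations."""

    reference_start: int  # 0-based
    reference_end: int  # exclusive
    is_unmapped: bool = False
    is_secondary: bool = False

    @property
    def reference_length(self) -> int:
        return self.reference_end - self.reference_start


def simulate_short_read_spans(
    cfg: SimConfig, truth: TruthSet, rng: np.random.Generator | None = None
) -> list[SpanRecord]:
    """Aligned spans of the paired short reads, without SAM record overhead.

    Follows the same placement model as :func:`simulate_short_reads` (each
    mate aligned to its majority projection segment, remainder clipped), so
    depth tracks agree statistically; useful for high-depth breakpoint
    refinement where building full records would dominate the run time.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 2])
    rl = cfg.short_read_length
    out: list[SpanRecord] = []
    for hap in truth.haplotypes:
        L = len(hap.sequence)
        n_frags = int(round(L * cfg.short_read_depth / 2.0 / (2 * rl)))
        frags = np.maximum(
            2 * rl, rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_frags)
        ).astype(int)
        starts = rng.integers(1, max(2, L - frags.max() + 1), size=n_frags)
        for start, frag in zip(starts.tolist(), frags.tolist()):
            frag = min(frag, L - start + 1)
            if frag < 2 * rl:
                continue
            for ms, me in ((start, start + rl - 1), (start + frag - rl, start + frag - 1)):
                alignments = _merge_native(_project_read(hap, ms, me, False))
                best = max(alignments, key=lambda a: a.qend - a.qstart)
                out.append(SpanRecord(best.ref_start - 1, best.ref_end))
    return out


def write_sam(records, region_map, path, sort: bool = True) -> None:
    """Write records as headered plain-text SAM (coordinate-sorted by default)."""
    header = sam_header(region_map)
    if sort:
        records = sorted(records, key=lambda r: (r.reference_start, r.query_name))
        hd = header.to_dict()
        hd["HD"]["SO"] = "coordinate"
        header = pysam.AlignmentHeader.from_dict(hd)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            out = rec
            if rec.header is not header:
                out = pysam.AlignedSegment.from_dict(rec.to_dict(), header)
            fh.write(out)


def depth_track(records, region_map) -> np.ndarray:
    """Per-base aligned depth over the reference span (index 0 = span start)."""
    span_start, span_end = region_map.span
    n = span_end - span_start + 1
    diff = np.zeros(n + 1, dtype=np.int64)
    for rec in records:
        s = rec.reference_start - (span_start - 1)
        e = s + rec.reference_length
        s, e = max(0, s), min(n, e)
        if e > s:
            diff[s] += 1
            diff[e] -= 1
    return np.cumsum(diff[:-1])


def simulate_short_read_depth(
    cfg: SimConfig, truth: TruthSet, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[pysam.AlignedSegment]]:
    """Short-read depth track over reference coordinates, plus the SAM records."""
    records = simulate_short_reads(cfg, truth, rng)
    return depth_track(records, cfg.region_map), records
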