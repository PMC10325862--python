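"""Junction-spanning read detection and orientation classification.

Long reads crossing a rearrangement junction split into two alignment
blocks landing in different locus regions.  A read is shortlisted when it
aligns to two of the five named regions; the block pair at the junction is
then classified by the ends of the regions it joins:

* type ``A`` -- forward Dup1 block leaving at Dup1.END joined to a reverse
  Dup2 block entering at Dup2.END (``START-DUP1-END-END-DUP2-START``);
* type ``B`` -- reverse Dup1 block leaving at Dup1.START joined to a forward
  Dup2 block entering at Dup2.START (``END-DUP1-START-START-DUP2-END``);
* ``native`` -- a same-strand Dup1 -> Int -> Dup2 traversal (the wild-type
  adjacency path);
* ``unclassified`` -- anything else (with the reason recorded).

Classification is strand-symmetric: a read and its reverse-complement
reading produce the same call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .alignments import AlignedRead, AlignmentBlock
from .locus import Adjacency, END, JUNCTION_A, JUNCTION_B, RegionMap, START, enumerate_adjacencies, ARRANGEMENT_N

NATIVE_ADJACENCIES = {
    Adjacency(a.left, a.right) for a in enumerate_adjacencies(ARRANGEMENT_N)
}


@dataclass
class JunctionCall:
    read_id: str
    type: str  # "A" | "B" | "native" | "unclassified"
    signature: str = ""
    reason: str = ""
    blocks: tuple | None = None


# --------------------------------------------------------------------------
# Region labelling


def assign_blocks(
    reads: Iterable[AlignedRead],
    region_map: RegionMap,
    min_block: int = 200,
    min_overlap_frac: float = 0.8,
) -> list[AlignedRead]:
    """Label each alignment block with the locus region holding it.

    A block gets a region label when at least ``min_overlap_frac`` of it
    lies inside that region and the block is at least ``min_block`` long;
    blocks straddling a native region border take the majority region's
    label.  Blocks outside the locus stay unlabelled.
    """
    out = []
    for read in reads:
        for block in read.blocks:
            block.region = _label_block(block, region_map, min_block, min_overlap_frac)
        out.append(read)
    return out


def _label_block(
    block: AlignmentBlock, region_map: RegionMap, min_block: int, min_overlap_frac: float
) -> str | None:
    if block.ref_span < min_block:
        return None
    overlaps = {}
    for region in region_map.regions:
        rs, re_ = region_map.interval(region)
        ov = min(block.ref_end, re_) - max(block.ref_start, rs) + 1
        if ov > 0:
            overlaps[region] = ov
    if not overlaps:
        return None
    best = max(overlaps, key=overlaps.get)
    frac = overlaps[best] / block.ref_span
    if frac >= min_overlap_frac:
        return best
    if sum(overlaps.values()) == block.ref_span:
        # wholly inside the locus straddling native borders: majority region
        return best
    return None


def find_spanning_reads(
    reads: Iterable[AlignedRead], regions: tuple[str, str]
) -> list[AlignedRead]:
    """Reads with labelled blocks in both named regions."""
    r1, r2 = regions
    return [rd for rd in reads if r1 in rd.regions() and r2 in rd.regions()]


# --------------------------------------------------------------------------
# Classification


def _exit_end(block: AlignmentBlock) -> tuple[str, int]:
    """(region end label, coordinate) at the block's read-exit side."""
    if block.reverse:
        return START, block.ref_start
    return END, block.ref_end


def _entry_end(block: AlignmentBlock) -> tuple[str, int]:
    if block.reverse:
        return END, block.ref_end
    return START, block.ref_start


def _end_label(region: str, coord: int, region_map: RegionMap, tol: int) -> str | None:
    rs, re_ = region_map.interval(region)
    if abs(coord - rs) <= tol:
        return START
    if abs(coord - re_) <= tol:
        return END
    return None


def _block_signature(block: AlignmentBlock) -> str:
    """Traversal direction of a block: forward reads run START->END."""
    ent, ext = (END, START) if block.reverse else (START, END)
    return f"{ent}-{block.region.upper()}-{ext}"


def _mirrored_signature(block: AlignmentBlock) -> str:
    """Block signature as read from the opposite strand."""
    ent, ext = (START, END) if block.reverse else (END, START)
    return f"{ent}-{block.region.upper()}-{ext}"


def classify_junction(
    read: AlignedRead, region_map: RegionMap, end_tolerance: int = 100
) -> JunctionCall:
    """Classify a Dup1/Dup2-spanning read by its junction orientation."""
    blocks = sorted(
        (b for b in read.blocks if b.region is not None), key=lambda b: b.qstart
    )
    dup_regions = {b.region for b in blocks} & {"Dup1", "Dup2"}
    if dup_regions != {"Dup1", "Dup2"}:
        return JunctionCall(read.name, "unclassified", reason="missing Dup1 or Dup2 block")

    # adjacent Dup1-Dup2 pair in read order; normalise to Dup1 first
    pair = None
    for b1, b2 in zip(blocks, blocks[1:]):
        if {b1.region, b2.region} == {"Dup1", "Dup2"}:
            pair = (b1, b2)
            break
    if pair is None:
        if _is_native_traversal(blocks):
            sig = "|".join(_block_signature(b) for b in blocks)
            return JunctionCall(read.name, "native", signature=sig)
        return JunctionCall(
            read.name, "unclassified", reason="Dup1 and Dup2 blocks not junction-adjacent"
        )

    b1, b2 = pair
    # the junction joins the earlier block's read-exit end to the later
    # block's read-entry end; canonical adjacency comparison makes the call
    # independent of which strand the read was sequenced from
    if b1.region == "Dup1":
        exit_label = _end_label("Dup1", _exit_end(b1)[1], region_map, end_tolerance)
        entry_label = _end_label("Dup2", _entry_end(b2)[1], region_map, end_tolerance)
        sig = f"{_block_signature(b1)}|{_block_signature(b2)}"
    else:
        # Dup2 first: present the signature in the mirrored (Dup1-first) frame
        exit_label = _end_label("Dup1", _entry_end(b2)[1], region_map, end_tolerance)
        entry_label = _end_label("Dup2", _exit_end(b1)[1], region_map, end_tolerance)
        sig = f"{_mirrored_signature(b2)}|{_mirrored_signature(b1)}"
    if exit_label is None or entry_label is None:
        return JunctionCall(
            read.name,
            "unclassified",
            signature=sig,
            reason=f"junction-side endpoint > {end_tolerance} bp from a region border",
            blocks=pair,
        )
    adjacency = Adjacency.canonical(("Dup1", exit_label), ("Dup2", entry_label))
    if adjacency == JUNCTION_A:
        jtype = "A"
    elif adjacency == JUNCTION_B:
        jtype = "B"
    elif Adjacency(adjacency.left, adjacency.right) in NATIVE_ADJACENCIES:
        jtype = "native"
    else:
        jtype = "unclassified"
    reason = "" if jtype != "unclassified" else "end combination matches no known junction"
    return JunctionCall(read.name, jtype, signature=sig, reason=reason, blocks=pair)


def _is_native_traversal(blocks: Sequence[AlignmentBlock]) -> bool:
    """True for a same-strand Dup1 -> Int -> Dup2 (or reverse) walk."""
    labels = [b.region for b in blocks]
    strands = {b.reverse for b in blocks}
    if len(strands) != 1:
        return False
    for order in (["Dup1", "Int", "Dup2"], ["Dup2", "Int", "Dup1"]):
        for i in range(len(labels) - 2):
            if labels[i : i + 3] == order:
                return True
    return False


def classify_reads(
    reads: Iterable[AlignedRead], region_map: RegionMap, end_tolerance: int = 100
) -> list[JunctionCall]:
    """Classify every Dup1/Dup2-spanning read in a labelled read set."""
    spanning = find_spanning_reads(reads, ("Dup1", "Dup2"))
    return [classify_junction(r, region_map, end_tolerance) for r in spanning]


def junction_support_table(calls: Iterable[JunctionCall]) -> dict[str, int]:
    """Counts per junction type; feeds carrier classification."""
    counts = Counter(c.type for c in calls)
    return {t: counts.get(t, 0) for t in ("A", "B", "native", "unclassified")}
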