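"""Read-backed haplotype extension across the duplicated regions.

Both copies of a duplicated region align to the same reference interval, so
the copies cannot be separated by position -- only by allele linkage.  The
procedure:

1. pile up long-read base counts along the region (``pileup_counts``);
2. shortlist candidate heterozygous sites -- exactly two bases with at
   least ``min_allele_reads`` supporting reads each; sites with three or
   more such bases are set aside as potentially tri-allelic
   (``call_het_sites``);
3. label every read by the base it carries at each candidate site
   (``label_reads``);
4. from a seed site, repeatedly find the nearest site whose 4x4
   base-combination count matrix against the current frontier cleanly
   separates the two haplotypes with at least ``min_pair_reads`` reads each
   (``pair_matrix`` / ``extend_haplotypes``);
5. anchor each extended haplotype to the neighbouring-region context
   carried by the reads holding its terminal alleles
   (``anchor_haplotypes``).

A diploid carrier sample has three copy-haplotype classes over a duplicated
region; :func:`phase_region` handles that by one level of recursive
splitting -- re-running extension on the reads of any haplotype whose
junction anchors come out ambiguous.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alignments import AlignedRead
from .locus import RegionMap, REGION_NAMES, CopyContext, UNKNOWN

BASES = "ACGT"
_BASE_CODE = {ord(b): i for i, b in enumerate(BASES)}


@dataclass
class SiteCounts:
    """Per-position base support (ambiguous calls excluded from base counts)."""

    pos: int
    counts: dict
    depth: int

    def supported(self, min_reads: int) -> list[str]:
        return [b for b in BASES if self.counts.get(b, 0) >= min_reads]


@dataclass
class HetSite:
    pos: int
    allele1: str  # lexicographically smaller
    allele2: str

    @property
    def alleles(self) -> tuple[str, str]:
        return self.allele1, self.allele2


@dataclass
class PairMatrix:
    """4x4 read-sharing counts between two sites: M[b1][b2] = reads with b1@p, b2@q."""

    p: int
    q: int
    m: dict

    def count(self, b1: str, b2: str) -> int:
        return self.m.get(b1, {}).get(b2, 0)

    def total(self) -> int:
        return sum(sum(row.values()) for row in self.m.values())

    def row(self, b1: str) -> dict:
        return self.m.get(b1, {})


@dataclass
class PhasedHaplotype:
    """One haplotype over a duplicated region: ordered (position, allele) calls.

    ``left_anchor``/``right_anchor`` are ``(region, inverted?)`` in the
    region-forward frame, None when no anchor evidence exists; when two
    contexts both reach the support floor the candidates are listed and the
    end is marked ambiguous.
    """

    region: str
    sites: list[tuple[int, str]]
    support: list[dict] = field(default_factory=list)
    chain_break_left: bool = False
    chain_break_right: bool = False
    left_anchor: tuple | None = None
    right_anchor: tuple | None = None
    left_candidates: list = field(default_factory=list)
    right_candidates: list = field(default_factory=list)

    @property
    def positions(self) -> list[int]:
        return [p for p, _ in self.sites]

    @property
    def ambiguous(self) -> bool:
        return len(self.left_candidates) > 1 or len(self.right_candidates) > 1

    def allele_at(self, pos: int) -> str | None:
        for p, a in self.sites:
            if p == pos:
                return a
        return None

    def context(self) -> CopyContext:
        left = self.left_anchor if self.left_anchor is not None else UNKNOWN
        right = self.right_anchor if self.right_anchor is not None else UNKNOWN
        return CopyContext(self.region, left, right)


# --------------------------------------------------------------------------
# Pileup and het-site calling


def pileup_counts(reads: Iterable[AlignedRead], lo: int, hi: int) -> list[SiteCounts]:
    """Base-support counts for every position of [lo, hi] (1-based inclusive).

    Zero-coverage positions are emitted with zero counts.  Deletions and
    non-ACGT calls contribute to depth but not to base counts.
    """
    n = hi - lo + 1
    counts = np.zeros((4, n), dtype=np.int64)
    depth = np.zeros(n, dtype=np.int64)
    for read in reads:
        for b in read.blocks:
            if b.ref_end < lo or b.ref_start > hi:
                continue
            r, q = b._aligned_pairs()
            seq = b.record.query_sequence
            if seq is None:
                continue
            mask = (r >= lo) & (r <= hi)
            if not mask.any():
                continue
            ridx = (r[mask] - lo).astype(np.int64)
            qidx = q[mask]
            raw = np.frombuffer(seq.encode(), dtype=np.uint8)[qidx]
            depth[ridx] += 1
            for code, bi in _BASE_CODE.items():
                sel = raw == code
                if sel.any():
                    counts[bi, ridx[sel]] += 1
    out = []
    for i in range(n):
        out.append(
            SiteCounts(
                pos=lo + i,
                counts={BASES[j]: int(counts[j, i]) for j in range(4) if counts[j, i]},
                depth=int(depth[i]),
            )
        )
    return out


def call_het_sites(
    counts: Sequence[SiteCounts], min_allele_reads: int = 10
) -> tuple[list[HetSite], dict]:
    """Candidate heterozygous sites plus an exclusion report.

    A site is kept iff exactly two bases reach ``min_allele_reads``; sites
    where three or more bases reach it are excluded as potentially
    tri-allelic and reported.
    """
    het: list[HetSite] = []
    tri: list[int] = []
    for sc in counts:
        sup = sc.supported(min_allele_reads)
        if len(sup) == 2:
            a, b = sorted(sup)
            het.append(HetSite(sc.pos, a, b))
        elif len(sup) >= 3:
            tri.append(sc.pos)
    return het, {"tri_allelic": tri, "n_candidates": len(het)}


def label_reads(
    reads: Iterable[AlignedRead], sites: Sequence[HetSite]
) -> dict[int, dict[str, set]]:
    """Per site, the read-id set supporting each base.

    Reads with a deletion or ambiguous call at a site are omitted there; a
    read with a sequencing error appears in the erroneous base's set (noise
    the pair matrices must tolerate).
    """
    labels: dict[int, dict[str, set]] = {
        s.pos: {b: set() for b in BASES} for s in sites
    }
    positions = np.asarray([s.pos for s in sites], dtype=np.int64)
    for read in reads:
        calls: dict[int, set] = {}
        for b in read.blocks:
            if positions.size == 0:
                break
            i0 = np.searchsorted(positions, b.ref_start)
            i1 = np.searchsorted(positions, b.ref_end, side="right")
            for pos in positions[i0:i1].tolist():
                base = b.base_at(pos)
                if base is not None:
                    calls.setdefault(pos, set()).add(base)
        for pos, bases in calls.items():
            # a read whose blocks cover the same position twice with
            # disagreeing bases (both copies of a duplicated region) is
            # uninformative there and dropped
            if len(bases) == 1:
                labels[pos][bases.pop()].add(read.name)
    return labels


def pair_matrix(p: int, q: int, labels: dict[int, dict[str, set]]) -> PairMatrix:
    """Count reads supporting each of the 16 base combinations at two sites."""
    if p == q:
        raise ValueError("pair_matrix needs two distinct sites")
    m: dict[str, dict[str, int]] = {}
    for b1, reads1 in labels[p].items():
        if not reads1:
            continue
        row = {}
        for b2, reads2 in labels[q].items():
            n = len(reads1 & reads2)
            if n:
                row[b2] = n
        if row:
            m[b1] = row
    return PairMatrix(p, q, m)


# --------------------------------------------------------------------------
# Haplotype extension


def _acceptable_step(
    mat: PairMatrix,
    frontier_alleles: tuple[str, str],
    min_pair_reads: int,
    max_noise_frac: float,
) -> tuple[str, str, dict] | None:
    """Check whether a candidate site cleanly extends both haplotypes.

    For each current haplotype allele (a row of the matrix) the best cell
    must reach ``min_pair_reads`` and dominate every other cell of its row
    by ``1/max_noise_frac``; the two accepted cells must disagree, otherwise
    the site cannot distinguish the haplotypes.
    """
    picks = []
    for allele in frontier_alleles:
        row = mat.row(allele)
        if not row:
            return None
        best_base = max(row, key=row.get)
        best = row[best_base]
        if best < min_pair_reads:
            return None
        for other, cnt in row.items():
            if other != best_base and cnt > max_noise_frac * best:
                return None
        picks.append((best_base, best))
    (b1, c1), (b2, c2) = picks
    if b1 == b2:
        return None
    return b1, b2, {"cells": {frontier_alleles[0]: c1, frontier_alleles[1]: c2}}


def extend_haplotypes(
    seed: HetSite,
    candidates: Sequence[HetSite],
    labels: dict[int, dict[str, set]],
    min_pair_reads: int = 5,
    max_noise_frac: float = 0.2,
) -> tuple[PhasedHaplotype, PhasedHaplotype]:
    """Grow the two haplotypes outward from a seed site in both directions.

    From the current frontier the nearest candidate whose pair matrix passes
    the support-and-dominance rule is accepted and becomes the new frontier;
    unacceptable sites are skipped.  When no acceptable site remains in a
    direction but skipped candidates do, the haplotypes are flagged as
    fragments on that side.
    """
    if seed.allele1 == seed.allele2:
        raise ValueError("seed site is not biallelic")
    region = None  # region name attached later by phase_region
    h1_sites = [(seed.pos, seed.allele1)]
    h2_sites = [(seed.pos, seed.allele2)]
    support: list[dict] = []
    breaks = {"left": False, "right": False}
    for direction in ("right", "left"):
        frontier_pos = seed.pos
        frontier_alleles = (seed.allele1, seed.allele2)
        if direction == "right":
            pool = sorted(
                (c for c in candidates if c.pos > seed.pos), key=lambda c: c.pos
            )
        else:
            pool = sorted(
                (c for c in candidates if c.pos < seed.pos),
                key=lambda c: -c.pos,
            )
        while pool:
            accepted = None
            # scan outward from the frontier; ties cannot arise within a
            # direction (positions are unique)
            for idx, cand in enumerate(pool):
                mat = pair_matrix(frontier_pos, cand.pos, labels)
                step = _acceptable_step(mat, frontier_alleles, min_pair_reads, max_noise_frac)
                if step is not None:
                    accepted = (idx, cand, step)
                    break
            if accepted is None:
                if pool:
                    breaks[direction] = True
                break
            idx, cand, (b1, b2, info) = accepted
            entry = {"from": frontier_pos, "to": cand.pos, **info}
            support.append(entry)
            if direction == "right":
                h1_sites.append((cand.pos, b1))
                h2_sites.append((cand.pos, b2))
            else:
                h1_sites.insert(0, (cand.pos, b1))
                h2_sites.insert(0, (cand.pos, b2))
            frontier_pos = cand.pos
            frontier_alleles = (b1, b2)
            pool = pool[idx + 1 :]
    h1 = PhasedHaplotype(
        region="",
        sites=sorted(h1_sites),
        support=support,
        chain_break_left=breaks["left"],
        chain_break_right=breaks["right"],
    )
    h2 = PhasedHaplotype(
        region="",
        sites=sorted(h2_sites),
        support=list(support),
        chain_break_left=breaks["left"],
        chain_break_right=breaks["right"],
    )
    return h1, h2


# --------------------------------------------------------------------------
# Anchoring


def _region_frame_neighbors(
    read: AlignedRead,
    region: str,
    region_map: RegionMap,
    end_tolerance: int,
    min_overlap: int,
    at_pos: int | None = None,
) -> dict[str, tuple[str, bool]]:
    """Neighbouring-region evidence of one read, in the region-forward frame.

    Returns a dict with optional ``left`` / ``right`` entries of
    ``(neighbour region, inverted?)``.  Two ways a read shows a neighbour:
    its region block itself continues across a native border (one long
    alignment block), or a split block adjacent in read order starts at the
    border (a junction, or an aligner that split at the native border).

    ``at_pos`` restricts the evidence to the block covering that reference
    position -- essential for reads whose alignment visits *both* copies of
    a duplicated region, where each copy sits in a different context.
    """
    rs, re_ = region_map.interval(region)
    out: dict[str, tuple[str, bool]] = {}
    blocks = sorted(read.blocks, key=lambda b: b.qstart)
    eligible = []
    for i, b in enumerate(blocks):
        if not (b.ref_start <= re_ and b.ref_end >= rs):
            continue
        if b.region is not None and b.region != region:
            continue
        if at_pos is not None and not (b.ref_start <= at_pos <= b.ref_end):
            continue
        eligible.append(i)
    if at_pos is not None and len(eligible) > 1:
        # the read's alignment visits the position through more than one
        # copy of the region: its context evidence is ambiguous
        return {}
    for i in eligible:
        b = blocks[i]
        # same-block native continuation
        if b.ref_start <= rs - min_overlap:
            out.setdefault("left", (_ref_neighbor(region, "left"), False))
        if b.ref_end >= re_ + min_overlap:
            out.setdefault("right", (_ref_neighbor(region, "right"), False))
        # split continuation across a junction / border
        prev_b = blocks[i - 1] if i > 0 else None
        next_b = blocks[i + 1] if i + 1 < len(blocks) else None
        if not b.reverse:
            read_left, read_right = prev_b, next_b
            flip = False
        else:
            read_left, read_right = next_b, prev_b
            flip = True
        if read_left is not None and read_left.region:
            if abs(b.ref_start - rs) <= end_tolerance:
                inv = read_left.reverse != b.reverse
                out.setdefault("left", (read_left.region, inv))
        if read_right is not None and read_right.region:
            if abs(b.ref_end - re_) <= end_tolerance:
                inv = read_right.reverse != b.reverse
                out.setdefault("right", (read_right.region, inv))
    return out


def _ref_neighbor(region: str, side: str) -> str:
    i = REGION_NAMES.index(region)
    return REGION_NAMES[i - 1] if side == "left" else REGION_NAMES[i + 1]


def anchor_haplotypes(
    haplotypes: Sequence[PhasedHaplotype],
    reads_by_id: dict[str, AlignedRead],
    labels: dict[int, dict[str, set]],
    region_map: RegionMap,
    min_anchor_reads: int = 5,
    end_tolerance: int = 100,
    min_overlap: int = 200,
) -> list[PhasedHaplotype]:
    """Attach neighbour-region contexts to each haplotype end.

    For each end, the reads carrying the terminal allele vote with the
    context they extend into; a context reaching ``min_anchor_reads`` and
    holding a strict majority becomes the anchor.  Several supported
    contexts mark the end ambiguous (the haplotype mixes copy classes and
    should be split); none leaves the end unanchored.
    """
    for hap in haplotypes:
        if not hap.sites:
            continue
        for side in ("left", "right"):
            pos, allele = hap.sites[0] if side == "left" else hap.sites[-1]
            votes: Counter = Counter()
            for rid in labels[pos][allele]:
                read = reads_by_id.get(rid)
                if read is None:
                    continue
                nb = _region_frame_neighbors(
                    read, hap.region, region_map, end_tolerance, min_overlap, at_pos=pos
                )
                if side in nb:
                    votes[nb[side]] += 1
            supported = [ctx for ctx, n in votes.items() if n >= min_anchor_reads]
            if side == "left":
                hap.left_candidates = supported
                hap.left_anchor = supported[0] if len(supported) == 1 else None
            else:
                hap.right_candidates = supported
                hap.right_anchor = supported[0] if len(supported) == 1 else None
    return list(haplotypes)


# --------------------------------------------------------------------------
# Region-level pipeline


@dataclass
class RegionPhasing:
    """Everything phased for one duplicated region."""

    region: str
    het_sites: list[HetSite]
    report: dict
    haplotypes: list[PhasedHaplotype]
    seed: HetSite | None = None

    def contexts(self) -> list[CopyContext]:
        return [h.context() for h in self.haplotypes if h.sites]

    def support_table(self):
        """Audit trail: one row per accepted extension step of each haplotype."""
        import pandas as pd

        rows = []
        for i, hap in enumerate(self.haplotypes):
            for step in hap.support:
                rows.append(
                    {
                        "region": self.region,
                        "haplotype": i,
                        "from_pos": step["from"],
                        "to_pos": step["to"],
                        **{f"reads_{k}": v for k, v in step.get("cells", {}).items()},
                    }
                )
        return pd.DataFrame(rows)


def write_phased_vcf(
    phasings: Sequence[RegionPhasing], region_map: RegionMap, path: str
) -> None:
    """Phased calls over the duplicated regions as a VCF with PS tags.

    Each region whose phasing resolved exactly two haplotypes contributes
    its defining sites as phased genotypes (one phase set per region, PS =
    region start).  Regions with more or fewer resolved haplotypes (e.g. a
    heterozygous carrier's three copy classes) are skipped -- their calls
    do not form a diploid genotype column.
    """
    import pysam

    header = pysam.VariantHeader()
    _, span_end = region_map.span
    header.contigs.add(region_map.chrom, length=int(span_end))
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
    header.add_sample("sample")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for ph in phasings:
            if len(ph.haplotypes) != 2:
                continue
            h1, h2 = ph.haplotypes
            ps = region_map.interval(ph.region)[0]
            a2 = dict(h2.sites)
            for pos, allele1 in h1.sites:
                allele2 = a2.get(pos)
                if allele2 is None or allele2 == allele1:
                    continue
                rec = vcf.new_record(
                    contig=region_map.chrom,
                    start=pos - 1,
                    stop=pos,
                    alleles=(allele1, allele2),
                )
                rec.samples["sample"]["GT"] = (0, 1)
                rec.samples["sample"].phased = True
                rec.samples["sample"]["PS"] = int(ps)
                vcf.write(rec)


def select_seed_site(
    sites: Sequence[HetSite],
    labels: dict[int, dict[str, set]],
    reads_by_id: dict[str, AlignedRead],
    region: str,
    region_map: RegionMap,
    min_pair_reads: int = 5,
    end_tolerance: int = 100,
    min_overlap: int = 200,
    min_balance: float = 0.25,
    skip: set | None = None,
) -> HetSite | None:
    """The het site nearest a region border whose both alleles have
    border-crossing read support -- the automated stand-in for picking a
    seed by eye in a genome browser.

    Sites whose minor allele carries less than ``min_balance`` of the major
    allele's reads are passed over: a genuine copy-differentiating site is
    roughly balanced, while a pileup of sequencing errors is not.
    """
    rs, re_ = region_map.interval(region)
    ranked = sorted(sites, key=lambda s: min(s.pos - rs, re_ - s.pos))
    for site in ranked:
        if skip and site.pos in skip:
            continue
        n1 = len(labels[site.pos][site.allele1])
        n2 = len(labels[site.pos][site.allele2])
        if min(n1, n2) < min_balance * max(n1, n2, 1):
            continue
        ok = True
        for allele in site.alleles:
            n = 0
            for rid in labels[site.pos][allele]:
                read = reads_by_id.get(rid)
                if read is None:
                    continue
                nb = _region_frame_neighbors(
                    read, region, region_map, end_tolerance, min_overlap, at_pos=site.pos
                )
                if nb:
                    n += 1
            if n < min_pair_reads:
                ok = False
                break
        if ok:
            return site
    return None


def _n_region_blocks(read: AlignedRead, lo: int, hi: int) -> int:
    return sum(1 for b in read.blocks if b.ref_start <= hi and b.ref_end >= lo)


def _haplotype_read_sets(
    haplotypes: Sequence[PhasedHaplotype], labels: dict[int, dict[str, set]]
) -> list[set]:
    """Assign reads to haplotypes by majority vote over chain sites."""
    out = []
    all_votes: dict[str, list[int]] = {}
    for hi, hap in enumerate(haplotypes):
        for pos, allele in hap.sites:
            for rid in labels[pos][allele]:
                all_votes.setdefault(rid, [0] * len(haplotypes))[hi] += 1
    sets: list[set] = [set() for _ in haplotypes]
    for rid, votes in all_votes.items():
        best = max(range(len(votes)), key=lambda i: votes[i])
        if votes[best] > 0 and votes.count(votes[best]) == 1:
            sets[best].add(rid)
    return sets


def phase_region(
    reads: Sequence[AlignedRead],
    region: str,
    region_map: RegionMap,
    min_allele_reads: int = 10,
    min_pair_reads: int = 5,
    max_noise_frac: float = 0.2,
    min_anchor_reads: int = 5,
    end_tolerance: int = 100,
    _split_depth: int = 1,
) -> RegionPhasing:
    """Pileup -> het sites -> seeded extension -> anchoring for one region.

    If an extended haplotype ends up with ambiguous junction anchors (it
    mixes copy classes -- the situation in a diploid carrier/wild-type
    heterozygote, where three copy classes share the interval), extension is
    re-run once restricted to that haplotype's reads.
    """
    lo, hi = region_map.interval(region)
    counts = pileup_counts(reads, lo, hi)
    het, report = call_het_sites(counts, min_allele_reads)
    reads_by_id = {r.name: r for r in reads}
    result = RegionPhasing(region=region, het_sites=het, report=report, haplotypes=[])
    if not het:
        return result
    labels = label_reads(reads, het)
    # retry with the next seed candidate if a chain refuses to extend (the
    # chosen site can still be an error pileup or covered by one copy only)
    tried: set[int] = set()
    h1 = h2 = None
    for _ in range(3):
        seed = select_seed_site(
            het, labels, reads_by_id, region, region_map, min_pair_reads,
            end_tolerance, skip=tried,
        )
        if seed is None:
            seed = next((s for s in het if s.pos not in tried), None)
        if seed is None:
            break
        tried.add(seed.pos)
        result.seed = seed
        h1, h2 = extend_haplotypes(seed, het, labels, min_pair_reads, max_noise_frac)
        if len(h1.sites) > 1 or len(het) == 1:
            break
    if h1 is None:
        return result
    h1.region = h2.region = region
    haplotypes = [h1, h2]
    anchor_haplotypes(
        haplotypes, reads_by_id, labels, region_map, min_anchor_reads, end_tolerance
    )

    if _split_depth > 0:
        final: list[PhasedHaplotype] = []
        read_sets = _haplotype_read_sets(haplotypes, labels)
        for hap, rset in zip(haplotypes, read_sets):
            if not hap.ambiguous:
                final.append(hap)
                continue
            # reads whose alignment visits the region twice straddle two
            # copies; they would smuggle a third copy class into the subset
            sub_reads = [
                reads_by_id[r]
                for r in rset
                if r in reads_by_id
                and _n_region_blocks(reads_by_id[r], lo, hi) <= 1
            ]
            sub = phase_region(
                sub_reads,
                region,
                region_map,
                # dropping a copy class leaves the remaining classes at
                # full depth, so the allele-support floor stays unchanged
                min_allele_reads,
                min_pair_reads,
                max_noise_frac,
                min_anchor_reads,
                end_tolerance,
                _split_depth=0,
            )
            resolved = [h for h in sub.haplotypes if h.sites and not h.ambiguous]
            if len(resolved) >= 2:
                final.extend(resolved)
            else:
                final.append(hap)
        result.haplotypes = final
    else:
        result.haplotypes = haplotypes
    return result
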