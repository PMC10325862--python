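"""Diploid rearranged-genome construction with a planted truth set.

A simulated sample is a pair of locus arrangements (e.g. ``Fm_2``/``N``).
Each chromosome's sequence is built by concatenating region sequences from a
random base reference in arrangement order (reverse-complementing inverted
segments), together with a *projection map* -- a piecewise monotone map from
sample coordinates to signed reference intervals -- which is the ground truth
for every downstream alignment.

Heterozygous-site planting follows a single-founder model for carrier
arrangements: the rearrangement arose once, so every chromosome carrying the
same carrier arrangement shares one realisation of copy-specific alleles,
while wild-type chromosomes receive independent variants.  Inside a
duplicated region each *copy* of the region is its own allele class; this is
what makes copy-specific haplotypes separable by read-backed phasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..locus import (
    Arrangement,
    RegionMap,
    SCALED_MAP,
    Segment,
    enumerate_adjacencies,
    get_arrangement,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def random_reference(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


# --------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the locus-scale simulation (1/10-scale defaults).

    Depths are total sample depths; each of the two chromosomes is sequenced
    at half the configured depth, so a duplicated region reaches the expected
    1.5x (carrier/wild-type heterozygote) or 2x (carrier homozygote) relative
    depth seen in short-read carriers.
    """

    seed: int = 0
    region_map: RegionMap = SCALED_MAP
    arrangements: tuple[str, str] = ("Fm_2", "Fm_2")
    #: heterozygous-site density inside Dup1/Dup2 (the study observed ~1%)
    het_density_dup: float = 0.01
    #: chromosome-level heterozygosity outside the duplicated regions
    het_density_outside: float = 0.003
    #: long reads: log-normal lengths, median ~20 kb
    long_read_depth: float = 60.0
    read_length_median: float = 20000.0
    read_length_sigma: float = 0.55
    min_read_length: int = 300
    error_rate: float = 0.02
    #: short reads
    short_read_depth: float = 30.0
    short_read_length: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 40.0

    def validate(self) -> None:
        for r in (self.het_density_dup, self.het_density_outside, self.error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.long_read_depth <= 0 or self.short_read_depth <= 0:
            raise ValueError("depths must be positive")
        if self.read_length_median < 50:
            raise ValueError("read length distribution must have mass >= 50 bp")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


# --------------------------------------------------------------------------
# Projection map


@dataclass(frozen=True)
class ProjectionBlock:
    """One arrangement segment realised on a sample chromosome.

    Coordinates are 1-based inclusive.  ``sample_start..sample_end`` on the
    built chromosome maps to ``ref_start..ref_end`` on the reference;
    ``inverted`` blocks map sample position ``s`` to
    ``ref_end - (s - sample_start)``.
    """

    sample_start: int
    sample_end: int
    ref_start: int
    ref_end: int
    inverted: bool
    region: str
    copy_index: int

    def sample_to_ref(self, s: int) -> int:
        if not self.sample_start <= s <= self.sample_end:
            raise ValueError("sample position outside block")
        off = s - self.sample_start
        return self.ref_end - off if self.inverted else self.ref_start + off

    def ref_to_sample(self, r: int) -> int:
        if not self.ref_start <= r <= self.ref_end:
            raise ValueError("reference position outside block")
        off = r - self.ref_start
        return self.sample_end - off if self.inverted else self.sample_start + off


@dataclass
class Haplotype:
    """A built chromosome: sequence + projection map + allele-class labels."""

    arrangement: Arrangement
    lineage: str
    sequence: str
    blocks: list[ProjectionBlock]

    def blocks_overlapping(self, s_start: int, s_end: int) -> list[ProjectionBlock]:
        """Projection blocks overlapping sample interval [s_start, s_end]."""
        return [b for b in self.blocks if b.sample_start <= s_end and b.sample_end >= s_start]

    def ref_positions_of(self, ref_pos: int, region: str) -> list[tuple[ProjectionBlock, int]]:
        """All (block, sample position) images of a reference position."""
        out = []
        for b in self.blocks:
            if b.region == region and b.ref_start <= ref_pos <= b.ref_end:
                out.append((b, b.ref_to_sample(ref_pos)))
        return out


def build_haplotype_sequence(
    region_map: RegionMap, arrangement: Arrangement, base_genome: str, lineage: str | None = None
) -> Haplotype:
    """Assemble one chromosome from the reference per the arrangement.

    ``base_genome`` covers the region-map span (index 0 = span start).
    """
    span_start, span_end = region_map.span
    if len(base_genome) < span_end - span_start + 1:
        raise ValueError("base genome does not cover the region map span")
    pieces: list[str] = []
    blocks: list[ProjectionBlock] = []
    cursor = 1
    copy_counter: dict[str, int] = {}
    for seg in arrangement.segments:
        rstart, rend = region_map.interval(seg.region)
        sub = base_genome[rstart - span_start : rend - span_start + 1]
        if seg.inverted:
            sub = revcomp(sub)
        idx = copy_counter.get(seg.region, 0)
        copy_counter[seg.region] = idx + 1
        blocks.append(
            ProjectionBlock(
                sample_start=cursor,
                sample_end=cursor + len(sub) - 1,
                ref_start=rstart,
                ref_end=rend,
                inverted=seg.inverted,
                region=seg.region,
                copy_index=idx,
            )
        )
        pieces.append(sub)
        cursor += len(sub)
    return Haplotype(
        arrangement=arrangement,
        lineage=lineage or arrangement.name,
        sequence="".join(pieces),
        blocks=blocks,
    )


# --------------------------------------------------------------------------
# Truth set


@dataclass(frozen=True)
class PlantedSite:
    """One planted polymorphic site, copy-aware.

    ``class_alleles`` maps an allele-class key ``(lineage, region,
    copy_index)`` to the base carried by that copy.  For sites outside the
    duplicated regions the class key is ``(lineage, region, 0)``.
    """

    pos: int
    region: str
    ref_allele: str
    alt_allele: str
    class_alleles: dict

    def allele_of(self, lineage: str, region: str, copy_index: int) -> str:
        return self.class_alleles[(lineage, region, copy_index)]


@dataclass
class ReadTruth:
    read_id: str
    chrom_index: int
    sample_start: int
    sample_end: int
    blocks: list[ProjectionBlock] = field(default_factory=list)


@dataclass
class TruthSet:
    config: SimConfig
    region_map: RegionMap
    haplotypes: list[Haplotype]
    planted_sites: list[PlantedSite]
    reads: dict = field(default_factory=dict)  # read id -> ReadTruth

    @property
    def breakpoints(self) -> dict[str, tuple[int, int]]:
        return {
            r: self.region_map.interval(r) for r in ("Dup1", "Dup2")
        }

    def novel_adjacencies(self) -> set:
        out = set()
        for h in self.haplotypes:
            out |= {a for a in enumerate_adjacencies(h.arrangement) if a.novel}
        return out

    def het_sites_in(self, region: str) -> list[PlantedSite]:
        return [s for s in self.planted_sites if s.region == region]

    def read_class(self, read_id: str, region: str) -> tuple | None:
        """Allele-class key of the copy a read traverses in ``region``."""
        truth = self.reads[read_id]
        lineage = self.haplotypes[truth.chrom_index].lineage
        for b in truth.blocks:
            if b.region == region:
                return (lineage, region, b.copy_index)
        return None

    def switch_errors(self, sites: list[tuple[int, str]], region: str) -> int:
        """Minimal number of truth-class switches explaining a phased chain.

        Each (position, allele) call is compatible with the set of planted
        allele classes carrying that base; a perfectly phased haplotype
        follows a single class, so the minimal number of times the running
        compatible set empties out counts the switch errors.  Calls at
        positions that were never planted are ignored.
        """
        by_pos = {s.pos: s for s in self.planted_sites if s.region == region}
        current: set | None = None
        switches = 0
        for pos, allele in sites:
            site = by_pos.get(pos)
            if site is None:
                continue
            compat = {
                key for key, base in site.class_alleles.items() if base == allele
            }
            if not compat:
                continue  # an erroneous call, not a switch
            if current is None:
                current = compat
                continue
            inter = current & compat
            if inter:
                current = inter
            else:
                switches += 1
                current = compat
        return switches

    def to_dict(self) -> dict:
        return {
            "arrangements": [h.arrangement.name for h in self.haplotypes],
            "breakpoints": {k: list(v) for k, v in self.breakpoints.items()},
            "planted_sites": [
                {
                    "pos": s.pos,
                    "region": s.region,
                    "ref": s.ref_allele,
                    "alt": s.alt_allele,
                    "classes": {
                        f"{lin}:{reg}:{ci}": b for (lin, reg, ci), b in s.class_alleles.items()
                    },
                }
                for s in self.planted_sites
            ],
        }


# --------------------------------------------------------------------------
# Het-site planting


def _lineages(cfg: SimConfig) -> list[str]:
    """Per-chromosome lineage labels (carrier founders are shared)."""
    out = []
    for i, name in enumerate(cfg.arrangements):
        out.append(name if name != "N" else f"N{i}")
    return out


def plant_het_sites(
    cfg: SimConfig, haplotypes: list[Haplotype], rng: np.random.Generator
) -> list[PlantedSite]:
    """Choose polymorphic positions and assign copy-specific alleles.

    Inside Dup1/Dup2 every distinct (lineage, copy) of the region is an
    allele class; alleles are drawn independently per class subject to the
    site being genuinely polymorphic (not all classes equal).  Outside the
    duplicated regions, sites are planted only where the two chromosome
    lineages differ, one class per lineage.
    """
    region_map = cfg.region_map
    sites: list[PlantedSite] = []

    # allele classes per region
    for region in ("Flank1", "Dup1", "Int", "Dup2", "Flank2"):
        dup = region in ("Dup1", "Dup2")
        density = cfg.het_density_dup if dup else cfg.het_density_outside
        classes: list[tuple] = []
        seen = set()
        for h in haplotypes:
            for b in h.blocks:
                if b.region != region:
                    continue
                key = (h.lineage, region, b.copy_index)
                if key not in seen:
                    seen.add(key)
                    classes.append(key)
        if len(classes) < 2 or density <= 0:
            continue  # monomorphic by construction
        rstart, rend = region_map.interval(region)
        length = rend - rstart + 1
        n_sites = rng.binomial(length, density)
        if n_sites == 0:
            continue
        positions = np.sort(rng.choice(length, size=n_sites, replace=False)) + rstart
        for pos in positions.tolist():
            # reference base from the base genome via any forward image
            ref_base = _ref_base(haplotypes, region, pos)
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            while True:
                assign = rng.integers(0, 2, size=len(classes))
                if 0 < assign.sum() < len(classes):
                    break
            class_alleles = {
                key: (alt if a else ref_base) for key, a in zip(classes, assign)
            }
            sites.append(
                PlantedSite(
                    pos=int(pos),
                    region=region,
                    ref_allele=ref_base,
                    alt_allele=str(alt),
                    class_alleles=class_alleles,
                )
            )
    sites.sort(key=lambda s: s.pos)
    return sites


def _ref_base(haplotypes: list[Haplotype], region: str, pos: int) -> str:
    h = haplotypes[0]
    for b in h.blocks:
        if b.region == region and b.ref_start <= pos <= b.ref_end:
            s = b.ref_to_sample(pos)
            base = h.sequence[s - 1]
            return _COMP[base] if b.inverted else base
    raise ValueError(f"position {pos} not covered by {region}")


def _apply_planted_alleles(haplotypes: list[Haplotype], sites: list[PlantedSite]) -> None:
    """Edit built sequences in place so each copy carries its planted allele."""
    for h in haplotypes:
        seq = list(h.sequence)
        for site in sites:
            for b, s_pos in h.ref_positions_of(site.pos, site.region):
                key = (h.lineage, site.region, b.copy_index)
                allele = site.class_alleles.get(key)
                if allele is None:
                    continue
                seq[s_pos - 1] = _COMP[allele] if b.inverted else allele
        h.sequence = "".join(seq)


# --------------------------------------------------------------------------
# Top-level sample builder


def build_diploid_sample(cfg: SimConfig) -> tuple[str, TruthSet]:
    """Build the reference span and a diploid sample with planted truth.

    Returns ``(base_genome, truth)``; ``truth.haplotypes`` holds the two
    chromosome sequences (identical objects are NOT shared even when the two
    chromosomes carry the same founder arrangement -- sequences are equal
    strings instead).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    span_start, span_end = cfg.region_map.span
    base_genome = random_reference(rng, span_end - span_start + 1)

    lineages = _lineages(cfg)
    built: dict[str, Haplotype] = {}
    haplotypes: list[Haplotype] = []
    for name, lineage in zip(cfg.arrangements, lineages):
        if lineage in built:  # shared carrier founder: equal sequence
            src = built[lineage]
            haplotypes.append(
                Haplotype(src.arrangement, lineage, src.sequence, src.blocks)
            )
            continue
        h = build_haplotype_sequence(cfg.region_map, get_arrangement(name), base_genome, lineage)
        built[lineage] = h
        haplotypes.append(h)

    # planting operates on distinct lineages once, then copies shared sequence
    distinct = list(built.values())
    sites = plant_het_sites(cfg, distinct, rng)
    _apply_planted_alleles(distinct, sites)
    for i, h in enumerate(haplotypes):
        h.sequence = built[h.lineage].sequence

    truth = TruthSet(
        config=cfg,
        region_map=cfg.region_map,
        haplotypes=haplotypes,
        planted_sites=sites,
    )
    return base_genome, truth
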