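"""Geometry and rearrangement model of the fibromelanosis (Fm) locus.

The locus is described as five named, contiguous reference intervals --
``Flank1, Dup1, Int, Dup2, Flank2`` -- on chicken chromosome 20.  A candidate
locus structure (an :class:`Arrangement`) is an ordered list of oriented
segment tokens drawn from those five names; the wild-type arrangement ``N``
lists each region once, forward.  Carrier arrangements duplicate ``Dup1`` and
``Dup2`` and invert copies, which creates *novel adjacencies* (junctions)
between segment ends that are not neighbours in the reference.

Two junctions are diagnostic of carriers:

* junction ``A`` -- ``Dup1`` end joined to the end of an inverted ``Dup2``;
* junction ``B`` -- the start of an inverted ``Dup1`` joined to ``Dup2`` start.

Three published carrier scenarios (``Fm_1``, ``Fm_2``, ``Fm_3``) share this
junction set but differ in segment order, hence in the *copy contexts* (left
and right neighbours) of each ``Dup1``/``Dup2`` copy.  Read-backed phasing
observes those contexts, and :func:`scenario_consistency` turns them into
verdicts on candidate arrangements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

REGION_NAMES = ("Flank1", "Dup1", "Int", "Dup2", "Flank2")

START = "START"
END = "END"


class UnknownRegionError(KeyError):
    """A region name absent from the RegionMap / Arrangement was requested."""


# --------------------------------------------------------------------------
# RegionMap


@dataclass(frozen=True)
class RegionMap:
    """Five named, contiguous 1-based inclusive intervals on one chromosome."""

    chrom: str
    regions: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        missing = [r for r in REGION_NAMES if r not in self.regions]
        if missing:
            raise ValueError(f"RegionMap missing regions: {missing}")
        prev_end = None
        for name in REGION_NAMES:
            start, end = self.regions[name]
            if end < start:
                raise ValueError(f"{name}: end {end} < start {start}")
            if prev_end is not None and start != prev_end + 1:
                raise ValueError(
                    f"{name} starts at {start}, expected {prev_end + 1} "
                    "(regions must tile the locus)"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.regions[REGION_NAMES[0]][0], self.regions[REGION_NAMES[-1]][1]

    def interval(self, region: str) -> tuple[int, int]:
        try:
            return self.regions[region]
        except KeyError as exc:
            raise UnknownRegionError(region) from exc

    def length(self, region: str) -> int:
        start, end = self.interval(region)
        return end - start + 1

    def region_at(self, pos: int) -> str | None:
        """Region containing 1-based position ``pos``, or None outside the locus."""
        for name in REGION_NAMES:
            start, end = self.regions[name]
            if start <= pos <= end:
                return name
        return None

    def to_bed(self) -> str:
        """BED (0-based half-open) text, one line per region."""
        lines = []
        for name in REGION_NAMES:
            start, end = self.regions[name]
            lines.append(f"{self.chrom}\t{start - 1}\t{end}\t{name}")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "regions": {n: list(self.regions[n]) for n in REGION_NAMES},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegionMap":
        return cls(d["chrom"], {k: (int(v[0]), int(v[1])) for k, v in d["regions"].items()})

    @classmethod
    def from_yaml(cls, text: str) -> "RegionMap":
        return cls.from_dict(yaml.safe_load(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


#: GRCg6a coordinates of the locus (chromosome 20).
GRCG6A_MAP = RegionMap(
    chrom="20",
    regions={
        "Flank1": (10263555, 10766771),
        "Dup1": (10766772, 10894151),
        "Int": (10894152, 11306685),
        "Dup2": (11306686, 11477501),
        "Flank2": (11477502, 11980000),
    },
)

#: 1/10-scale map used by the synthetic-data module (coordinates arbitrary).
SCALED_MAP = RegionMap(
    chrom="chr20s",
    regions={
        "Flank1": (1, 50000),
        "Dup1": (50001, 62738),
        "Int": (62739, 103991),
        "Dup2": (103992, 121072),
        "Flank2": (121073, 171072),
    },
)


def region_length(region_map: RegionMap, region: str) -> int:
    """Length in bp of a named region (1-based inclusive convention)."""
    return region_map.length(region)


# --------------------------------------------------------------------------
# Arrangement


@dataclass(frozen=True)
class Segment:
    region: str
    inverted: bool = False

    def flipped(self) -> "Segment":
        return Segment(self.region, not self.inverted)

    def __str__(self) -> str:
        return ("inv-" if self.inverted else "") + self.region


@dataclass(frozen=True)
class Arrangement:
    """One haploid description of the locus: ordered oriented segments."""

    name: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = self.segments
        if not segs:
            raise ValueError("empty arrangement")
        first, last = segs[0], segs[-1]
        if first != Segment("Flank1") or last != Segment("Flank2"):
            raise ValueError(
                "arrangement must start with forward Flank1 and end with forward Flank2"
            )
        for mid in (Segment("Flank1"), Segment("Flank2")):
            if sum(s.region == mid.region for s in segs) != 1:
                raise ValueError(f"{mid.region} must appear exactly once")

    def copy_number(self, region: str) -> int:
        return sum(s.region == region for s in self.segments)

    def copy_numbers(self) -> dict[str, int]:
        return {r: self.copy_number(r) for r in REGION_NAMES}

    def length(self, region_map: RegionMap) -> int:
        return sum(region_map.length(s.region) for s in self.segments)

    def reversed_(self) -> "Arrangement":
        """Full reversal: reverse segment order and flip every orientation.

        The result violates the Flank1-first invariant, so it is returned as a
        raw segment tuple for adjacency-invariance checks.
        """
        return tuple(s.flipped() for s in reversed(self.segments))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "segments": [[s.region, "inverted" if s.inverted else "forward"] for s in self.segments],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Arrangement":
        segs = tuple(
            Segment(r, o in ("inverted", "inv", "-")) for r, o in d["segments"]
        )
        return cls(d["name"], segs)

    @classmethod
    def from_yaml(cls, text: str) -> "Arrangement":
        return cls.from_dict(yaml.safe_load(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def __str__(self) -> str:
        return f"{self.name}: " + " + ".join(str(s) for s in self.segments)


def _arr(name: str, spec: Sequence[tuple[str, bool]]) -> Arrangement:
    return Arrangement(name, tuple(Segment(r, i) for r, i in spec))


#: Wild-type (non-carrier) arrangement.
ARRANGEMENT_N = _arr(
    "N",
    [("Flank1", False), ("Dup1", False), ("Int", False), ("Dup2", False), ("Flank2", False)],
)

#: Carrier scenario Fm_1: single duplication-inversion event; the middle
#: (Dup2 + Int + Dup1) block is inverted, so only the first Dup1 copy and the
#: last Dup2 copy sit in wild-type orientation/context.
ARRANGEMENT_FM1 = _arr(
    "Fm_1",
    [
        ("Flank1", False),
        ("Dup1", False),
        ("Dup2", True),
        ("Int", True),
        ("Dup1", True),
        ("Dup2", False),
        ("Flank2", False),
    ],
)

#: Carrier scenario Fm_2 (the arrangement supported by the phased haplotypes):
#: the distal Dup1 + Int + Dup2 + Flank2 block is wild-type-like, while the
#: proximal block carries an extra Dup1 copy and an inverted Dup2 copy.
ARRANGEMENT_FM2 = _arr(
    "Fm_2",
    [
        ("Flank1", False),
        ("Dup1", False),
        ("Dup2", True),
        ("Dup1", False),
        ("Int", False),
        ("Dup2", False),
        ("Flank2", False),
    ],
)

#: Carrier scenario Fm_3: wild-type-like proximal block, rearranged distal block.
ARRANGEMENT_FM3 = _arr(
    "Fm_3",
    [
        ("Flank1", False),
        ("Dup1", False),
        ("Int", False),
        ("Dup2", False),
        ("Dup1", True),
        ("Dup2", False),
        ("Flank2", False),
    ],
)

BUILTIN_ARRANGEMENTS: dict[str, Arrangement] = {
    a.name: a for a in (ARRANGEMENT_N, ARRANGEMENT_FM1, ARRANGEMENT_FM2, ARRANGEMENT_FM3)
}


def get_arrangement(name: str) -> Arrangement:
    try:
        return BUILTIN_ARRANGEMENTS[name]
    except KeyError as exc:
        raise UnknownRegionError(f"unknown arrangement {name!r}") from exc


# --------------------------------------------------------------------------
# Adjacencies


@dataclass(frozen=True, order=True)
class Adjacency:
    """An orientation-free junction between two segment ends.

    ``left``/``right`` are ``(region-name, 'START'|'END')`` pairs.  An
    adjacency read along the opposite strand swaps the two ends; the
    canonical form stores the lexicographically smaller ordering, so a
    junction and its mirror compare equal.
    """

    left: tuple[str, str]
    right: tuple[str, str]
    novel: bool = field(default=False, compare=False)

    @classmethod
    def canonical(cls, left: tuple[str, str], right: tuple[str, str], novel: bool = False):
        if right < left:
            left, right = right, left
        return cls(left, right, novel)

    def __str__(self) -> str:
        tag = " [novel]" if self.novel else ""
        return f"{self.left[0]}.{self.left[1]} <-> {self.right[0]}.{self.right[1]}{tag}"


#: The two carrier-diagnostic junctions of the locus.
JUNCTION_A = Adjacency.canonical(("Dup1", END), ("Dup2", END), novel=True)
JUNCTION_B = Adjacency.canonical(("Dup1", START), ("Dup2", START), novel=True)


def _segment_ends(seg: Segment) -> tuple[tuple[str, str], tuple[str, str]]:
    """(left-facing end, right-facing end) of a segment as laid on the arrangement."""
    if seg.inverted:
        return (seg.region, END), (seg.region, START)
    return (seg.region, START), (seg.region, END)


def _adjacencies_of(segments: Sequence[Segment]) -> set[Adjacency]:
    out: set[Adjacency] = set()
    for a, b in zip(segments, segments[1:]):
        _, a_right = _segment_ends(a)
        b_left, _ = _segment_ends(b)
        out.add(Adjacency.canonical(a_right, b_left))
    return out


def enumerate_adjacencies(arrangement: Arrangement | Sequence[Segment]) -> set[Adjacency]:
    """Canonical adjacency set of an arrangement, novel-flagged vs wild type."""
    segments = (
        arrangement.segments if isinstance(arrangement, Arrangement) else tuple(arrangement)
    )
    native = _adjacencies_of(ARRANGEMENT_N.segments)
    out = set()
    for adj in _adjacencies_of(segments):
        out.add(Adjacency(adj.left, adj.right, novel=adj not in native))
    return out


def novel_adjacencies(arrangement: Arrangement) -> set[Adjacency]:
    return {a for a in enumerate_adjacencies(arrangement) if a.novel}


# --------------------------------------------------------------------------
# Copy contexts

#: Sentinel left/right neighbour values.
BOUNDARY = None  # outside the modelled locus
UNKNOWN = "?"  # observed context with no anchor evidence on this side

Neighbor = "tuple[str, bool] | None | str"


def _flip_neighbor(n):
    if n is BOUNDARY or n == UNKNOWN:
        return n
    region, inverted = n
    return (region, not inverted)


@dataclass(frozen=True)
class CopyContext:
    """Canonical neighbourhood of one copy of a region in an arrangement.

    Stored with the copy read in its forward orientation: ``left`` and
    ``right`` are ``(neighbour-region, inverted?)`` pairs, ``None`` at the
    locus boundary, or :data:`UNKNOWN` for an unanchored observed side.
    Reading a copy along the reverse strand yields the same canonical
    context.
    """

    region: str
    left: object
    right: object

    @classmethod
    def canonical(cls, region: str, left, right, copy_inverted: bool = False):
        if copy_inverted:
            left, right = _flip_neighbor(right), _flip_neighbor(left)
        return cls(region, left, right)

    def matches(self, other: "CopyContext") -> bool:
        """True if self (possibly with UNKNOWN sides) is compatible with other."""
        if self.region != other.region:
            return False
        for a, b in ((self.left, other.left), (self.right, other.right)):
            if a == UNKNOWN or b == UNKNOWN:
                continue
            if a != b:
                return False
        return True

    @property
    def anchored(self) -> bool:
        return self.left != UNKNOWN and self.right != UNKNOWN

    def __str__(self) -> str:
        def fmt(n):
            if n is BOUNDARY:
                return "|"
            if n == UNKNOWN:
                return "?"
            region, inverted = n
            return ("inv-" if inverted else "") + region

        return f"({fmt(self.left)} | {self.region} | {fmt(self.right)})"


def copy_contexts(arrangement: Arrangement, region: str) -> list[CopyContext]:
    """Canonical context of every copy of ``region``, in arrangement order."""
    segs = arrangement.segments
    out = []
    for i, seg in enumerate(segs):
        if seg.region != region:
            continue
        left = BOUNDARY if i == 0 else (segs[i - 1].region, segs[i - 1].inverted)
        right = BOUNDARY if i == len(segs) - 1 else (segs[i + 1].region, segs[i + 1].inverted)
        if seg.inverted:
            # normalise neighbour orientations to the copy's forward frame
            left = None if left is None else (left[0], left[1])
            right = None if right is None else (right[0], right[1])
        out.append(CopyContext.canonical(region, left, right, copy_inverted=seg.inverted))
    return out


def all_copy_contexts(arrangement: Arrangement, regions: Iterable[str] = ("Dup1", "Dup2")) -> set[CopyContext]:
    out: set[CopyContext] = set()
    for r in regions:
        out.update(copy_contexts(arrangement, r))
    return out


# --------------------------------------------------------------------------
# Scenario consistency


@dataclass
class ScenarioVerdict:
    arrangement: str
    consistent: bool
    matched: list[CopyContext]
    violated: list[CopyContext]
    #: candidate contexts with no matching observation (empty => exact fit)
    unexplained: list[CopyContext]
    uninformative: bool = False

    @property
    def exact(self) -> bool:
        return self.consistent and not self.unexplained


def scenario_consistency(
    observed: Iterable[CopyContext],
    candidates: Sequence[Arrangement],
    regions: Iterable[str] = ("Dup1", "Dup2"),
) -> list[ScenarioVerdict]:
    """Test each candidate arrangement against observed copy contexts.

    A candidate is *consistent* iff every observed context matches one of its
    copy contexts (canonical comparison; observed sides may be UNKNOWN).  The
    ``unexplained`` list additionally records candidate contexts that no
    observation matches, which lets a caller prefer exact fits when the
    observation set is believed complete.
    """
    observed = list(observed)
    verdicts = []
    for cand in candidates:
        cand_ctx = sorted(all_copy_contexts(cand, regions), key=str)
        matched, violated = [], []
        for obs in observed:
            if any(obs.matches(c) for c in cand_ctx):
                matched.append(obs)
            else:
                violated.append(obs)
        unexplained = [c for c in cand_ctx if not any(o.matches(c) for o in observed)]
        verdicts.append(
            ScenarioVerdict(
                arrangement=cand.name,
                consistent=not violated,
                matched=matched,
                violated=violated,
                unexplained=unexplained,
                uninformative=not observed,
            )
        )
    return verdicts


# --------------------------------------------------------------------------
# Diploid genotypes


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of arrangements describing a diploid sample."""

    hap1: Arrangement
    hap2: Arrangement

    @property
    def name(self) -> str:
        return f"{self.hap1.name}/{self.hap2.name}"

    def contexts(self, regions: Iterable[str] = ("Dup1", "Dup2")) -> set[CopyContext]:
        return all_copy_contexts(self.hap1, regions) | all_copy_contexts(self.hap2, regions)

    def copy_number(self, region: str) -> int:
        return self.hap1.copy_number(region) + self.hap2.copy_number(region)


def default_genotype_candidates() -> list[Genotype]:
    """All unordered pairs over the built-in arrangements."""
    names = ["N", "Fm_1", "Fm_2", "Fm_3"]
    out = []
    for i, a in enumerate(names):
        for b in names[i:]:
            out.append(Genotype(get_arrangement(a), get_arrangement(b)))
    return out


@dataclass
class GenotypeVerdict:
    genotype: str
    consistent: bool
    exact: bool
    violated: list[CopyContext]
    unexplained: list[CopyContext]


def genotype_consistency(
    observed: Iterable[CopyContext],
    candidates: Sequence[Genotype] | None = None,
    regions: Iterable[str] = ("Dup1", "Dup2"),
) -> list[GenotypeVerdict]:
    """Like :func:`scenario_consistency` but against diploid context unions."""
    observed = list(observed)
    if candidates is None:
        candidates = default_genotype_candidates()
    verdicts = []
    for g in candidates:
        ctx = sorted(g.contexts(regions), key=str)
        violated = [o for o in observed if not any(o.matches(c) for c in ctx)]
        unexplained = [c for c in ctx if not any(o.matches(c) for o in observed)]
        verdicts.append(
            GenotypeVerdict(
                genotype=g.name,
                consistent=not violated,
                exact=not violated and not unexplained,
                violated=violated,
                unexplained=unexplained,
            )
        )
    return verdicts


def infer_genotype(
    observed: Iterable[CopyContext],
    candidates: Sequence[Genotype] | None = None,
) -> tuple[str | None, list[GenotypeVerdict]]:
    """Best genotype call: the unique exact fit, else None with all verdicts."""
    verdicts = genotype_consistency(observed, candidates)
    exact = [v for v in verdicts if v.exact]
    if len(exact) == 1:
        return exact[0].genotype, verdicts
    return None, verdicts
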