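"""End-to-end locus resolution: reads -> junctions -> phasing -> scenario.

Mirrors the analysis walk used to resolve the rearrangement: classify the
sample as carrier/non-carrier from short-read depth and junction coverage,
phase copy-specific haplotypes over both duplicated regions from the long
reads, anchor them to neighbouring-region contexts, and keep the candidate
genotype whose copy-context set the observations match exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignments import group_reads
from .coverage import CarrierCall, classify_carrier, window_coverage
from .junctions import assign_blocks, classify_reads, junction_support_table
from .locus import CopyContext, Genotype, GenotypeVerdict, RegionMap, infer_genotype
from .phasing import RegionPhasing, phase_region


@dataclass
class LocusResult:
    carrier: CarrierCall | None
    junction_table: dict
    phasings: dict
    observed_contexts: list[CopyContext]
    genotype: str | None
    verdicts: list[GenotypeVerdict] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "carrier": None if self.carrier is None else self.carrier.carrier,
            "junctions": self.junction_table,
            "genotype": self.genotype,
            "contexts": [str(c) for c in self.observed_contexts],
            "consistent_genotypes": [v.genotype for v in self.verdicts if v.consistent],
        }


def resolve_locus(
    long_records,
    region_map: RegionMap,
    short_records=None,
    candidates: list[Genotype] | None = None,
    min_allele_reads: int = 10,
    min_pair_reads: int = 5,
    end_tolerance: int = 100,
) -> LocusResult:
    """Run the full inference on one sample's alignments.

    ``long_records``/``short_records`` are iterables of pysam records (or
    SAM paths handled by the caller).  Short reads are optional; without
    them the carrier call is junction-only.
    """
    reads, _ = group_reads(long_records)
    assign_blocks(reads, region_map)
    calls = classify_reads(reads, region_map, end_tolerance)
    table = junction_support_table(calls)

    carrier = None
    if short_records is not None:
        _, span_end = region_map.span
        profile = window_coverage(short_records, region_map.chrom, span_end)
        carrier = classify_carrier(profile, region_map, table)

    phasings: dict[str, RegionPhasing] = {}
    observed: list[CopyContext] = []
    for region in ("Dup1", "Dup2"):
        ph = phase_region(
            reads,
            region,
            region_map,
            min_allele_reads=min_allele_reads,
            min_pair_reads=min_pair_reads,
            end_tolerance=end_tolerance,
        )
        phasings[region] = ph
        for ctx in ph.contexts():
            if ctx.anchored and ctx not in observed:
                observed.append(ctx)

    genotype, verdicts = infer_genotype(observed, candidates)
    return LocusResult(
        carrier=carrier,
        junction_table=table,
        phasings=phasings,
        observed_contexts=observed,
        genotype=genotype,
        verdicts=verdicts,
    )
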