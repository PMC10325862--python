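"""Synthetic data: rearranged diploid genomes, simulated alignments, panels."""

from .genome import (
    SimConfig,
    TruthSet,
    Haplotype,
    ProjectionBlock,
    PlantedSite,
    build_diploid_sample,
    build_haplotype_sequence,
    plant_het_sites,
    random_reference,
    revcomp,
)
from .reads import (
    simulate_long_reads,
    simulate_short_reads,
    simulate_short_read_depth,
    simulate_short_read_spans,
    depth_track,
    sam_header,
    write_sam,
)
from .panel import (
    PanelConfig,
    SweepConfig,
    MaskConfig,
    simulate_panel,
    simulate_masks,
    write_bed,
)


def simulate_sample(cfg: SimConfig):
    """Build a diploid sample and both read sets; returns (truth, long, short)."""
    _, truth = build_diploid_sample(cfg)
    long_reads = simulate_long_reads(cfg, truth)
    short_reads = simulate_short_reads(cfg, truth)
    return truth, long_reads, short_reads


__all__ = [
    "SimConfig",
    "TruthSet",
    "Haplotype",
    "ProjectionBlock",
    "PlantedSite",
    "build_diploid_sample",
    "build_haplotype_sequence",
    "plant_het_sites",
    "random_reference",
    "revcomp",
    "simulate_long_reads",
    "simulate_short_reads",
    "simulate_short_read_depth",
    "simulate_short_read_spans",
    "simulate_sample",
    "depth_track",
    "sam_header",
    "write_sam",
    "PanelConfig",
    "SweepConfig",
    "MaskConfig",
    "simulate_panel",
    "simulate_masks",
    "write_bed",
]
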