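"""Shared fixtures: simulated samples are expensive, so they are session-scoped."""

from __future__ import annotations

import pysam
import pytest

from fmphase.alignments import group_reads
from fmphase.junctions import assign_blocks
from fmphase.locus import SCALED_MAP
from fmphase.simulate import SimConfig, build_diploid_sample, sam_header, simulate_long_reads, simulate_short_reads


@pytest.fixture(scope="session")
def fm2_hom():
    """Carrier homozygote with both read sets."""
    cfg = SimConfig(seed=11, arrangements=("Fm_2", "Fm_2"))
    _, truth = build_diploid_sample(cfg)
    long_r = simulate_long_reads(cfg, truth)
    short_r = simulate_short_reads(cfg, truth)
    return cfg, truth, long_r, short_r


@pytest.fixture(scope="session")
def fm2_het():
    """Carrier/wild-type heterozygote, long reads only."""
    cfg = SimConfig(seed=12, arrangements=("Fm_2", "N"))
    _, truth = build_diploid_sample(cfg)
    long_r = simulate_long_reads(cfg, truth)
    return cfg, truth, long_r


@pytest.fixture(scope="session")
def n_hom():
    """Wild-type sample with both read sets."""
    cfg = SimConfig(seed=13, arrangements=("N", "N"))
    _, truth = build_diploid_sample(cfg)
    long_r = simulate_long_reads(cfg, truth)
    short_r = simulate_short_reads(cfg, truth)
    return cfg, truth, long_r, short_r


@pytest.fixture(scope="session")
def fm2_hom_reads(fm2_hom):
    """Grouped, region-labelled long reads of the carrier homozygote."""
    cfg, truth, long_r, _ = fm2_hom
    reads, _ = group_reads(long_r)
    assign_blocks(reads, cfg.region_map)
    return reads


@pytest.fixture(scope="session")
def n_hom_reads(n_hom):
    cfg, truth, long_r, _ = n_hom
    reads, _ = group_reads(long_r)
    assign_blocks(reads, cfg.region_map)
    return reads


def make_record(
    name: str,
    ref_start: int,
    match_len: int,
    clip_left: int = 0,
    clip_right: int = 0,
    reverse: bool = False,
    supplementary: bool = False,
    header: pysam.AlignmentHeader | None = None,
) -> pysam.AlignedSegment:
    """Hand-built SAM record on the scaled reference (1-based ref_start)."""
    header = header or sam_header(SCALED_MAP)
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.reference_id = 0
    rec.reference_start = ref_start - 1
    rec.mapping_quality = 60
    flag = 0
    if reverse:
        flag |= 16
    if supplementary:
        flag |= 2048
    rec.flag = flag
    cig = []
    if clip_left:
        cig.append((4, clip_left))
    cig.append((0, match_len))
    if clip_right:
        cig.append((4, clip_right))
    rec.cigartuples = cig
    rec.query_sequence = "A" * (clip_left + match_len + clip_right)
    return rec
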