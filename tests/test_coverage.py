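"""Windowed coverage, boundary detection, bp refinement, carrier calls."""

import numpy as np
import pytest

from fmphase.coverage import (
    BreakpointCall,
    classify_carrier,
    detect_boundaries,
    per_base_depth,
    refine_breakpoint,
    window_coverage,
)
from fmphase.locus import SCALED_MAP
from fmphase.simulate import SimConfig, build_diploid_sample, simulate_short_reads

from conftest import make_record

SPAN = SCALED_MAP.span[1]


class TestWindowCoverage:
    def test_read_spanning_two_windows_counts_in_both(self):
        recs = [make_record("r1", 950, 200)]  # covers 950..1149: windows 0 and 1
        prof = window_coverage(recs, "chr20s", 3000, window_size=1000)
        assert prof.counts[0] == 1 and prof.counts[1] == 1 and prof.counts[2] == 0

    def test_window_size_floor(self):
        with pytest.raises(ValueError):
            window_coverage([], "chr20s", 3000, window_size=50)

    def test_empty_alignments_warn_and_zero(self):
        with pytest.warns(UserWarning):
            prof = window_coverage([], "chr20s", 5000)
        assert prof.counts.sum() == 0

    def test_uniform_wildtype_profile_near_one(self, n_hom):
        cfg, _, _, short_r = n_hom
        prof = window_coverage(short_r, cfg.region_map.chrom, SPAN)
        norm = prof.normalized[:-1]  # last window is partial
        frac = np.mean((norm > 0.8) & (norm < 1.2))
        assert frac >= 0.95

    def test_carrier_duplicated_windows_near_two(self, fm2_hom):
        cfg, _, _, short_r = fm2_hom
        prof = window_coverage(short_r, cfg.region_map.chrom, SPAN)
        dup1 = prof.mean_normalized(*cfg.region_map.interval("Dup1"))
        assert 1.8 < dup1 < 2.2


class TestDetectBoundaries:
    def test_carrier_vs_control_finds_all_four_boundaries(self, fm2_hom, n_hom):
        cfg, _, _, case_sr = fm2_hom
        _, _, _, ctrl_sr = n_hom
        case = window_coverage(case_sr, cfg.region_map.chrom, SPAN)
        ctrl = window_coverage(ctrl_sr, cfg.region_map.chrom, SPAN)
        calls = detect_boundaries(case, [ctrl])
        truths = [
            SCALED_MAP.interval("Dup1")[0],
            SCALED_MAP.interval("Dup1")[1] + 1,
            SCALED_MAP.interval("Dup2")[0],
            SCALED_MAP.interval("Dup2")[1] + 1,
        ]
        assert len(calls) == 4
        for call, t in zip(sorted(calls, key=lambda c: c.position), truths):
            assert abs(call.position - t) <= 1000
        sides = [c.side for c in sorted(calls, key=lambda c: c.position)]
        assert sides == ["rise", "fall", "rise", "fall"]

    def test_wildtype_vs_wildtype_finds_nothing(self, n_hom):
        cfg, _, _, short_r = n_hom
        prof = window_coverage(short_r, cfg.region_map.chrom, SPAN)
        assert detect_boundaries(prof, [prof]) == []

    def test_shared_step_is_suppressed(self, fm2_hom):
        cfg, _, _, short_r = fm2_hom
        prof = window_coverage(short_r, cfg.region_map.chrom, SPAN)
        # the carrier profile used as its own control: every jump is shared
        assert detect_boundaries(prof, [prof]) == []

    def test_no_controls_flags_low_confidence(self, fm2_hom):
        cfg, _, _, short_r = fm2_hom
        prof = window_coverage(short_r, cfg.region_map.chrom, SPAN)
        calls = detect_boundaries(prof)
        assert calls and all(c.low_confidence for c in calls)


class TestRefineBreakpoint:
    def _ideal_records(self, step_at: int, lo: int, hi: int, d1: int, d2: int):
        """Single-base reads producing a perfect depth step at step_at."""
        recs = []
        i = 0
        for pos in range(lo, hi + 1):
            depth = d1 if pos < step_at else d2
            for _ in range(depth):
                recs.append(make_record(f"i{i}", pos, 1))
                i += 1
        return recs

    def test_noiseless_step_recovered_exactly(self):
        recs = self._ideal_records(5000, 4000, 6600, 3, 6)
        call = BreakpointCall("chr20s", 5400, "rise", 1.0, 2.0)
        refined = refine_breakpoint(recs, call, window_size=500)
        assert refined.refined and refined.position == 5000

    def test_step_at_window_edge_found(self):
        recs = self._ideal_records(6000, 4000, 8000, 3, 6)
        call = BreakpointCall("chr20s", 6001, "rise", 1.0, 2.0)
        refined = refine_breakpoint(recs, call, window_size=1000)
        assert refined.position == 6000

    def test_never_leaves_search_radius(self):
        recs = self._ideal_records(5000, 3000, 7000, 3, 6)
        call = BreakpointCall("chr20s", 6500, "rise", 1.0, 2.0)
        refined = refine_breakpoint(recs, call, window_size=250)
        assert abs(refined.position - 6500) <= 500

    def test_flat_profile_kept_unrefined(self):
        recs = self._ideal_records(99999, 4000, 6000, 3, 3)  # no step
        call = BreakpointCall("chr20s", 5000, "rise", 1.0, 1.0)
        refined = refine_breakpoint(recs, call, window_size=500)
        assert not refined.refined and refined.position == 5000

    def test_simulated_carrier_refines_within_read_length(self, fm2_hom, n_hom):
        cfg, _, _, case_sr = fm2_hom
        _, _, _, ctrl_sr = n_hom
        case = window_coverage(case_sr, cfg.region_map.chrom, SPAN)
        ctrl = window_coverage(ctrl_sr, cfg.region_map.chrom, SPAN)
        truths = sorted(
            [
                SCALED_MAP.interval("Dup1")[0],
                SCALED_MAP.interval("Dup1")[1] + 1,
                SCALED_MAP.interval("Dup2")[0],
                SCALED_MAP.interval("Dup2")[1] + 1,
            ]
        )
        calls = sorted(detect_boundaries(case, [ctrl]), key=lambda c: c.position)
        assert len(calls) == 4
        for call, t in zip(calls, truths):
            refined = refine_breakpoint(case_sr, call, window_size=1000)
            assert refined.refined
            assert abs(refined.position - t) <= cfg.short_read_length

    def test_confidence_grows_with_depth(self):
        confs = []
        for d in (3, 12):
            recs = self._ideal_records(5000, 4500, 5500, d, 2 * d)
            call = BreakpointCall("chr20s", 5100, "rise", 1.0, 2.0)
            confs.append(refine_breakpoint(recs, call, window_size=250).confidence)
        assert confs[1] >= confs[0]


class TestClassifyCarrier:
    def test_carrier_homozygote_meets_both_criteria(self, fm2_hom):
        cfg, _, _, short_r = fm2_hom
        prof = window_coverage(short_r, cfg.region_map.chrom, SPAN)
        call = classify_carrier(prof, cfg.region_map, {"A": 10, "B": 8})
        assert call.carrier and call.depth_criterion and call.junction_criterion
        assert not call.discordant

    def test_wildtype_is_non_carrier(self, n_hom):
        cfg, _, _, short_r = n_hom
        prof = window_coverage(short_r, cfg.region_map.chrom, SPAN)
        call = classify_carrier(prof, cfg.region_map, {"A": 0, "B": 0})
        assert not call.carrier

    def test_heterozygote_called_by_junctions_despite_subthreshold_depth(self):
        cfg = SimConfig(seed=44, arrangements=("Fm_2", "N"))
        _, truth = build_diploid_sample(cfg)
        short_r = simulate_short_reads(cfg, truth)
        prof = window_coverage(short_r, cfg.region_map.chrom, SPAN)
        call = classify_carrier(prof, cfg.region_map, {"A": 6, "B": 5})
        # relative depth ~1.5x sits below the 1.6x depth threshold: the
        # junction reads are the deciding evidence
        assert call.carrier and call.junction_criterion
        assert not call.depth_criterion and call.discordant

    def test_depth_without_junctions_is_discordant_non_carrier(self, fm2_hom):
        cfg, _, _, short_r = fm2_hom
        prof = window_coverage(short_r, cfg.region_map.chrom, SPAN)
        call = classify_carrier(prof, cfg.region_map, {"A": 0, "B": 0})
        assert not call.carrier and call.discordant and call.depth_criterion


def test_carrier_panel_classified_without_error():
    """10 carriers (hom and het) and 10 non-carriers, all called correctly at 30x."""
    from fmphase.alignments import group_reads
    from fmphase.junctions import assign_blocks, classify_reads, junction_support_table
    from fmphase.simulate import simulate_long_reads

    genotypes = [("Fm_2", "Fm_2")] * 5 + [("Fm_2", "N")] * 5 + [("N", "N")] * 10
    for k, arrangements in enumerate(genotypes):
        cfg = SimConfig(seed=500 + k, arrangements=arrangements)
        _, truth = build_diploid_sample(cfg)
        reads, _ = group_reads(simulate_long_reads(cfg, truth))
        assign_blocks(reads, cfg.region_map)
        table = junction_support_table(classify_reads(reads, cfg.region_map))
        prof = window_coverage(
            simulate_short_reads(cfg, truth), cfg.region_map.chrom, SPAN
        )
        call = classify_carrier(prof, cfg.region_map, table)
        assert call.carrier == ("Fm_2" in arrangements), (k, arrangements, call)


def test_per_base_depth_matches_construction():
    recs = [make_record("a", 100, 50), make_record("b", 120, 50)]
    d = per_base_depth(recs, 100, 180)
    assert d[0] == 1 and d[25] == 2 and d[60] == 1 and d[75] == 0
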