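"""Synthetic genome construction, read simulation and panel generation."""

import numpy as np
import pytest

from fmphase.locus import ARRANGEMENT_FM2, ARRANGEMENT_N, SCALED_MAP
from fmphase.popgen import hudson_fst
from fmphase.simulate import (
    PanelConfig,
    SimConfig,
    SweepConfig,
    build_diploid_sample,
    build_haplotype_sequence,
    depth_track,
    plant_het_sites,
    random_reference,
    revcomp,
    simulate_long_reads,
    simulate_panel,
    simulate_short_read_depth,
)


class TestHaplotypeConstruction:
    def test_wildtype_sequence_is_the_reference_span(self):
        rng = np.random.default_rng(0)
        genome = random_reference(rng, SCALED_MAP.span[1])
        hap = build_haplotype_sequence(SCALED_MAP, ARRANGEMENT_N, genome)
        assert hap.sequence == genome
        for b in hap.blocks:
            assert not b.inverted
            assert b.sample_start == b.ref_start  # identity projection

    def test_fm2_length_is_sum_of_copy_lengths(self):
        rng = np.random.default_rng(0)
        genome = random_reference(rng, SCALED_MAP.span[1])
        hap = build_haplotype_sequence(SCALED_MAP, ARRANGEMENT_FM2, genome)
        # 2 x 12,738 + 2 x 17,081 + 41,253 + 2 x 50,000
        assert len(hap.sequence) == 200_891
        assert len(hap.sequence) == ARRANGEMENT_FM2.length(SCALED_MAP)

    @pytest.mark.parametrize("arr", [ARRANGEMENT_N, ARRANGEMENT_FM2])
    def test_projection_round_trip(self, arr):
        rng = np.random.default_rng(1)
        genome = random_reference(rng, SCALED_MAP.span[1])
        hap = build_haplotype_sequence(SCALED_MAP, arr, genome)
        for s in rng.integers(1, len(hap.sequence) + 1, size=50).tolist():
            blocks = hap.blocks_overlapping(s, s)
            assert len(blocks) == 1
            b = blocks[0]
            r = b.sample_to_ref(s)
            assert b.ref_to_sample(r) == s

    def test_inverted_segment_is_reverse_complemented(self):
        rng = np.random.default_rng(2)
        genome = random_reference(rng, SCALED_MAP.span[1])
        hap = build_haplotype_sequence(SCALED_MAP, ARRANGEMENT_FM2, genome)
        inv = [b for b in hap.blocks if b.inverted][0]
        sub = hap.sequence[inv.sample_start - 1 : inv.sample_end]
        ref_sub = genome[inv.ref_start - 1 : inv.ref_end]
        assert sub == revcomp(ref_sub)


class TestHetPlanting:
    def test_density_matches_binomial_expectation(self):
        cfg = SimConfig(seed=21, arrangements=("Fm_2", "Fm_2"))
        _, truth = build_diploid_sample(cfg)
        n = len(truth.het_sites_in("Dup1"))
        expect = 0.01 * SCALED_MAP.length("Dup1")  # ~127
        assert abs(n - expect) <= 3 * np.sqrt(expect)

    def test_zero_density_plants_nothing(self):
        cfg = SimConfig(
            seed=3, arrangements=("Fm_2", "Fm_2"), het_density_dup=0.0, het_density_outside=0.0
        )
        _, truth = build_diploid_sample(cfg)
        assert truth.planted_sites == []

    def test_copies_carry_copy_specific_alleles(self):
        cfg = SimConfig(seed=4, arrangements=("Fm_2", "Fm_2"))
        _, truth = build_diploid_sample(cfg)
        for site in truth.het_sites_in("Dup1"):
            alleles = set(site.class_alleles.values())
            assert alleles == {site.ref_allele, site.alt_allele}
            assert len(site.class_alleles) == 2  # one founder, two copies

    def test_het_genotype_has_three_dup_classes(self):
        cfg = SimConfig(seed=5, arrangements=("Fm_2", "N"))
        _, truth = build_diploid_sample(cfg)
        site = truth.het_sites_in("Dup1")[0]
        assert len(site.class_alleles) == 3

    def test_carrier_founder_shared_across_chromosomes(self):
        cfg = SimConfig(seed=6, arrangements=("Fm_2", "Fm_2"))
        _, truth = build_diploid_sample(cfg)
        assert truth.haplotypes[0].sequence == truth.haplotypes[1].sequence


class TestLongReads:
    def test_error_free_wildtype_reads_match_reference(self):
        cfg = SimConfig(
            seed=7, arrangements=("N", "N"), error_rate=0.0,
            het_density_dup=0.0, het_density_outside=0.0, long_read_depth=4,
        )
        base, truth = build_diploid_sample(cfg)
        recs = simulate_long_reads(cfg, truth)
        for rec in recs[:50]:
            sub = base[rec.reference_start : rec.reference_start + rec.reference_length]
            assert rec.query_alignment_sequence == sub

    def test_junction_read_splits_with_correct_strands(self, fm2_hom):
        cfg, truth, long_r, _ = fm2_hom
        # find a read crossing the Dup1.END junction (truth blocks Dup1+Dup2)
        found = 0
        for rt in truth.reads.values():
            regions = [b.region for b in rt.blocks]
            for i in range(len(rt.blocks) - 1):
                a, b = rt.blocks[i], rt.blocks[i + 1]
                if {a.region, b.region} == {"Dup1", "Dup2"}:
                    assert a.inverted != b.inverted  # inversion junction
                    found += 1
        assert found > 0

    def test_sam_records_reconstruct_truth_blocks(self, fm2_hom):
        cfg, truth, long_r, _ = fm2_hom
        by_name = {}
        for rec in long_r:
            by_name.setdefault(rec.query_name, []).append(rec)
        rng = np.random.default_rng(0)
        names = rng.choice(list(by_name), size=60, replace=False)
        for name in names:
            recs = by_name[name]
            got = sorted((r.reference_start + 1, r.reference_end) for r in recs)
            want = sorted((b.ref_start, b.ref_end) for b in truth.reads[name].blocks)
            assert got == want

    def test_mean_depth_near_target(self, fm2_hom):
        # per-chromosome mean coverage (sample coordinates) hits depth/2;
        # regional means fluctuate more because 20 kb reads autocorrelate
        # coverage over spans comparable to the scaled regions
        cfg, truth, long_r, _ = fm2_hom
        for ci, hap in enumerate(truth.haplotypes):
            L = len(hap.sequence)
            total = sum(
                rt.sample_end - rt.sample_start + 1
                for rt in truth.reads.values()
                if rt.chrom_index == ci
            )
            mean = total / L
            assert abs(mean - cfg.long_read_depth / 2) / (cfg.long_read_depth / 2) < 0.1

    def test_depth_conservation(self, fm2_hom):
        cfg, truth, long_r, _ = fm2_hom
        total = sum(r.reference_length for r in long_r)
        span = cfg.region_map.span[1]
        mean_copy = sum(len(h.sequence) for h in truth.haplotypes) / (2 * span)
        assert abs(total / span - cfg.long_read_depth * mean_copy) / (
            cfg.long_read_depth * mean_copy
        ) < 0.05

    def test_byte_identical_reruns(self, tmp_path):
        from fmphase.simulate import write_sam

        out = []
        for rep in range(2):
            cfg = SimConfig(seed=42, arrangements=("Fm_2", "N"))
            _, truth = build_diploid_sample(cfg)
            recs = simulate_long_reads(cfg, truth)
            path = tmp_path / f"{rep}.sam"
            write_sam(recs, cfg.region_map, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_degenerate_read_length_rejected(self):
        cfg = SimConfig(seed=0, read_length_median=20.0)
        with pytest.raises(ValueError):
            cfg.validate()


class TestShortReadDepth:
    def test_wildtype_profile_is_flat(self, n_hom):
        cfg, truth, _, short_r = n_hom
        track = depth_track(short_r, cfg.region_map)
        lo, hi = cfg.region_map.interval("Dup1")
        dup1 = track[lo:hi].mean()
        f_lo, f_hi = cfg.region_map.interval("Flank1")
        flank = track[f_lo + 1000 : f_hi].mean()
        assert abs(dup1 / flank - 1.0) < 0.1

    def test_carrier_homozygote_doubles_duplicated_depth(self, fm2_hom):
        cfg, truth, _, short_r = fm2_hom
        track = depth_track(short_r, cfg.region_map)
        lo, hi = cfg.region_map.interval("Dup1")
        dup1 = track[lo + 500 : hi - 500].mean()
        assert abs(dup1 - 2 * cfg.short_read_depth) / (2 * cfg.short_read_depth) < 0.1

    def test_depth_step_is_breakpoint_localised(self, fm2_hom):
        cfg, truth, _, short_r = fm2_hom
        track = depth_track(short_r, cfg.region_map)
        lo, _ = cfg.region_map.interval("Dup1")
        rl = cfg.short_read_length
        before = track[lo - 5 * rl : lo - rl].mean()
        after = track[lo + rl : lo + 5 * rl].mean()
        assert after / before > 1.7  # the step happens within +-read length


class TestPanel:
    def test_null_panel_fst_near_zero(self):
        p = simulate_panel(PanelConfig(seed=31))
        h1 = p.haplotypes[p.haplotype_rows("KADK")]
        h2 = p.haplotypes[p.haplotype_rows("CHIN")]
        assert abs(hudson_fst(h1, h2)) < 0.01

    def test_opposite_fixation_gives_fst_one(self):
        from fmphase.popgen import HaplotypePanel

        H = np.zeros((8, 10), dtype=np.int8)
        H[4:, :] = 1
        panel = HaplotypePanel(
            "1",
            np.arange(1, 11) * 100,
            H,
            ["a0", "a1", "b0", "b1"],
            {"a0": "A", "a1": "A", "b0": "B", "b1": "B"},
        )
        h1 = panel.haplotypes[panel.haplotype_rows("A")]
        h2 = panel.haplotypes[panel.haplotype_rows("B")]
        assert hudson_fst(h1, h2) == pytest.approx(1.0)

    def test_sweep_depresses_target_population_diversity(self):
        ok = 0
        for seed in range(5):
            sw = SweepConfig(population="KADK", center=525_000, width=50_000, frequency=0.95)
            p = simulate_panel(PanelConfig(seed=seed, sweep=sw))
            rows = p.haplotype_rows("KADK")
            in_w = (p.positions >= 500_001) & (p.positions <= 550_000)
            out_w = ~in_w
            H = p.haplotypes[rows]
            n = H.shape[0]
            c_in = H[:, in_w].sum(axis=0)
            c_out = H[:, out_w].sum(axis=0)
            pi_in = np.sum(2 * c_in * (n - c_in) / (n * (n - 1))) / max(in_w.sum(), 1)
            pi_out = np.sum(2 * c_out * (n - c_out) / (n * (n - 1))) / max(out_w.sum(), 1)
            if pi_in < 0.2 * pi_out:
                ok += 1
        assert ok >= 4

    def test_sweep_frequency_bounds_enforced(self):
        with pytest.raises(ValueError):
            SweepConfig(population="KADK", center=1, width=10, frequency=1.5)

    def test_panel_is_polymorphic_and_phased_shape(self):
        cfg = PanelConfig(seed=33, n_sites=500)
        p = simulate_panel(cfg)
        assert p.haplotypes.shape[0] == 2 * sum(cfg.n_diploids)
        counts = p.haplotypes.sum(axis=0)
        assert ((counts > 0) & (counts < p.n_haplotypes)).all()
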