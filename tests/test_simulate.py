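"""Synthetic cohort generator: determinism, count law, truth profiles, dilution."""

import numpy as np
import pytest

from plasmacnv.catalog import CNVCatalog, CatalogRecord, default_catalog
from plasmacnv.genome import GenomeSpec, default_genome
from plasmacnv.profile import normalize_counts
from plasmacnv.simulate import (
    CNVEvent,
    CohortConfig,
    GroupConfig,
    SimParams,
    TruthProfile,
    _copy_numbers,
    draw_tumor_profile,
    simulate_case,
    simulate_cohort,
    simulate_panel,
)

from conftest import build_grid


class TestPanel:
    def test_seed_determinism(self, full_grid):
        a = simulate_panel(full_grid, 3, seed=7)
        b = simulate_panel(full_grid, 3, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.counts, y.counts)

    def test_totals_in_expected_range(self, full_grid):
        panel = simulate_panel(full_grid, 10, seed=2)
        totals = np.array([p.total_reads for p in panel])
        assert np.all(totals >= 18e6 * 0.9)
        assert np.all(totals <= 28e6 * 1.1)

    def test_minimum_size_enforced(self, full_grid):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_panel(full_grid, 1, seed=0)

    def test_poisson_limit_and_overdispersion(self, toy_grid):
        # one fixed bin over replicate samples with depth and GC bias held
        # fixed: var/mean -> 1 as r -> inf, far above 1 at the default r = 1000
        def var_over_mean(r):
            params = SimParams(dispersion=r, reads_range=(3e5, 3e5), gc_slope_sd=0.0)
            rng = np.random.default_rng(42)
            vals = [
                simulate_panel(toy_grid, 2, params, seed=rng)[0].counts[5]
                for _ in range(250)
            ]
            vals = np.array(vals, dtype=float)
            return vals.var(ddof=1) / vals.mean()

        assert 0.8 <= var_over_mean(1e12) <= 1.2
        assert var_over_mean(1000.0) > 2.0


class TestTruthProfiles:
    def test_certain_record_always_included(self, toy_genome):
        cat = CNVCatalog([CatalogRecord("1q", "gain", 0.01, 1.0)])
        for seed in range(10):
            truth = draw_tumor_profile(cat, toy_genome, 0.1, seed=seed)
            assert len(truth.events) == 1
            ev = truth.events[0]
            assert (ev.chrom, ev.start, ev.end, ev.copy) == (
                "chr1", 5_000_000, 10_000_000, 3,
            )

    def test_zero_frequency_no_focal_gives_neutral_profile(self, toy_genome):
        cat = CNVCatalog([CatalogRecord("1q", "gain", 0.01, 0.0)])
        truth = draw_tumor_profile(cat, toy_genome, 0.1, focal_rate=0.0, seed=0)
        assert truth.events == []

    def test_arm_event_frequency_matches_catalog(self):
        # inclusion of 8q gain across 1000 draws ~ Binomial(1000, 0.75)
        cat = default_catalog()
        genome = default_genome()
        freq = cat.get("8q", "gain").frequency
        hits = 0
        rng = np.random.default_rng(99)
        for _ in range(1000):
            truth = draw_tumor_profile(cat, genome, 0.1, seed=rng)
            arm = genome.arm("8q")
            hits += any(
                e.chrom == "chr8" and e.start == arm.start and e.copy == 3
                for e in truth.events
            )
        se = np.sqrt(freq * (1 - freq) / 1000)
        assert abs(hits / 1000 - freq) < 3 * se

    def test_tumor_fraction_bounds_enforced(self):
        with pytest.raises(ValueError, match="tumor fraction"):
            TruthProfile(1.2, [])

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TruthProfile(
                0.1,
                [
                    CNVEvent("chr1", 0, 5_000_000, 3),
                    CNVEvent("chr1", 4_000_000, 8_000_000, 1),
                ],
            )


class TestCopyAssignment:
    def test_majority_overlap_rule(self, toy_grid):
        # 1 Mb bins; event spans 1.6-3.4 Mb: bin 1-2 Mb overlapped 40% (stays
        # diploid), bin 2-3 Mb fully covered, bin 3-4 Mb overlapped 40%
        truth = TruthProfile(0.5, [CNVEvent("chr1", 1_600_000, 3_400_000, 3)])
        copy = _copy_numbers(toy_grid, truth)
        assert copy[1] == 2   # 40% overlap: stays diploid
        assert copy[2] == 3   # fully covered
        assert copy[3] == 2   # 40% overlap: stays diploid
        truth2 = TruthProfile(0.5, [CNVEvent("chr1", 1_400_000, 2_000_000, 1)])
        assert _copy_numbers(toy_grid, truth2)[1] == 1  # 60% overlap: takes copy


class TestCaseDilution:
    def test_tf_zero_matches_neutral_draw(self, full_grid):
        truth = TruthProfile(0.0, [CNVEvent("chr4", 0, 50_000_000, 3)])
        a = simulate_case(full_grid, truth, seed=3)
        b = simulate_case(full_grid, TruthProfile(0.0, []), seed=3)
        assert np.array_equal(a.counts, b.counts)

    def test_case_stream_matches_panel_stream(self, full_grid):
        # a tf=0 case consumes the RNG identically to the first panel sample
        a = simulate_case(full_grid, TruthProfile(0.0, []), seed=3)
        b = simulate_panel(full_grid, 2, seed=3)[0]
        assert np.array_equal(a.counts, b.counts)

    def test_full_tumor_copy4_doubles_expected_weight(self, toy_grid):
        truth = TruthProfile(1.0, [CNVEvent("chr1", 0, 10_000_000, 4)])
        from plasmacnv.simulate import _copy_numbers

        copy = _copy_numbers(toy_grid, truth)
        factor = 1.0 + truth.tumor_fraction * (copy - 2.0) / 2.0
        assert np.all(factor[toy_grid.chrom_indices("chr1")] == 2.0)
        assert np.all(factor[toy_grid.chrom_indices("chr2")] == 1.0)

    def test_arm_gain_lifts_mean_value_by_dilution_factor(self, full_grid):
        # tf=0.2 copy-3 gain: mean normalized value on the arm ~ 1.10x neutral,
        # less the renormalization by the inflated total
        genome = full_grid.genome
        arm = genome.arm("8q")
        idx = [
            i
            for i in full_grid.chrom_indices("chr8")
            if full_grid.start[i] >= arm.start and full_grid.usable[i]
        ]
        truth = TruthProfile(0.2, [CNVEvent("chr8", arm.start, arm.end, 3)])
        rng = np.random.default_rng(21)
        ratios = []
        for _ in range(200):
            case = normalize_counts(simulate_case(full_grid, truth, seed=rng))
            neutral = normalize_counts(
                simulate_case(full_grid, TruthProfile(0.0, []), seed=rng)
            )
            ratios.append(case.values[idx].mean() / neutral.values[idx].mean())
        arm_share = len(idx) / full_grid.usable_autosomal.sum()
        expected = 1.10 / (1.0 + 0.10 * arm_share)
        assert np.mean(ratios) == pytest.approx(expected, abs=0.01)

    def test_tf_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            TruthProfile(-0.1, [])


class TestCohort:
    @pytest.fixture
    def tiny_config(self):
        return CohortConfig(
            n_panel=2,
            groups={
                "early": GroupConfig(1, tf_range=(0.2, 0.3), focal_rate=1.0,
                                     stage_label="FIGO I-II", is_case=True),
                "control": GroupConfig(2, stage_label="benign"),
            },
        )

    def test_writes_expected_layout(self, tiny_config, tmp_path):
        out = simulate_cohort(tiny_config, tmp_path / "cohort", seed=5)
        assert (out / "grid.tsv").exists()
        assert len(list((out / "panel").glob("*.tsv"))) == 2
        assert len(list((out / "samples").glob("*.tsv"))) == 3
        manifest = (out / "manifest.tsv").read_text().strip().splitlines()
        assert len(manifest) == 4  # header + 3 subjects
        assert (out / "truth.json").exists()

    def test_byte_determinism(self, tiny_config, tmp_path):
        a = simulate_cohort(tiny_config, tmp_path / "a", seed=5)
        b = simulate_cohort(tiny_config, tmp_path / "b", seed=5)
        for rel in ["manifest.tsv", "truth.json", "samples/early_000.tsv"]:
            assert (a / rel).read_bytes() == (b / rel).read_bytes()

    def test_refuses_to_clobber(self, tiny_config, tmp_path):
        simulate_cohort(tiny_config, tmp_path / "c", seed=5)
        with pytest.raises(FileExistsError):
            simulate_cohort(tiny_config, tmp_path / "c", seed=5)

    def test_empty_group_is_valid(self, tmp_path):
        config = CohortConfig(
            n_panel=2,
            groups={"control": GroupConfig(0, stage_label="benign")},
        )
        out = simulate_cohort(config, tmp_path / "empty", seed=1)
        assert list((out / "samples").glob("*.tsv")) == []

    def test_default_config_mirrors_study_design(self):
        config = CohortConfig()
        n_cases = sum(g.n for g in config.groups.values() if g.is_case)
        n_controls = sum(g.n for g in config.groups.values() if not g.is_case)
        assert (n_cases, n_controls) == (32, 32)
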