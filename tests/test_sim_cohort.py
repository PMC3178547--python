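"""Synthetic-cohort generator: marker maps, truth profiles, observed tables."""

import numpy as np
import pandas as pd
import pytest

from cnloh.genome import CHROM_LENGTHS_BP, make_marker_map
from cnloh.sim_cohort import (CohortConfig, iter_cohort, simulate_cohort,
                              simulate_snp_table, simulate_truth_profile)
from cnloh.state_fit import AllelicState, expected_signals


class TestMarkerMap:
    def test_marker_count_matches_floor_of_length_over_spacing(self):
        mm = make_marker_map({"chr1": 247_000_000}, 12_000)
        assert mm.n_markers("chr1") == 20_583  # floor(247e6 / 12e3)

    def test_total_count_is_sum_of_per_chromosome_floors(self):
        spacing = 70_000
        mm = make_marker_map(marker_spacing_bp=spacing)
        expected = sum(length // spacing for length in CHROM_LENGTHS_BP.values())
        assert mm.n_markers() == expected

    def test_spacing_larger_than_chromosome_gives_zero_markers(self, caplog):
        with caplog.at_level("WARNING"):
            mm = make_marker_map({"chrTiny": 10_000, "chrBig": 1_000_000}, 100_000)
        assert mm.n_markers("chrTiny") == 0
        assert mm.n_markers("chrBig") == 10
        assert any("no markers" in r.message for r in caplog.records)

    def test_non_positive_spacing_rejected(self):
        with pytest.raises(ValueError):
            make_marker_map({"chr1": 1_000_000}, 0)

    def test_positions_strictly_increasing_and_bounded(self):
        mm = make_marker_map(marker_spacing_bp=500_000)
        for chrom, pos in mm.positions.items():
            assert (np.diff(pos) > 0).all()
            assert pos[0] >= 1 and pos[-1] <= mm.lengths_bp[chrom]


class TestTruthProfiles:
    def test_flat_diploid_without_events_is_all_one_one(self, sparse_map, rng):
        prof = simulate_truth_profile("flat_diploid", 0.0, (1, 0, 0), sparse_map, rng)
        assert all(s.state == AllelicState(1, 1) for s in prof.segments)

    def test_degenerate_mixture_yields_only_interstitial_events(self, sparse_map):
        rng = np.random.default_rng(5)
        events = []
        for _ in range(10):
            prof = simulate_truth_profile("flat_diploid", 3.0, (1, 0, 0),
                                          sparse_map, rng)
            events.extend(prof.events)
        assert events and all(e.extent == "INTERSTITIAL" for e in events)

    def test_near_triploid_totals_in_two_to_five_without_breakpoints(self, sparse_map):
        rng = np.random.default_rng(6)
        for _ in range(5):
            prof = simulate_truth_profile("numerical_near_triploid", 0.0,
                                          (1, 0, 0), sparse_map, rng)
            for chrom in sparse_map.autosomes:
                segs = prof.chrom_segments(chrom)
                assert len(segs) == 1  # purely numerical: no intra-chromosome break
                assert segs[0].state.total in {2, 3, 4, 5}

    def test_unknown_profile_type_rejected(self, sparse_map, rng):
        with pytest.raises(ValueError):
            simulate_truth_profile("mystery", 0.0, (1, 0, 0), sparse_map, rng)

    def test_truth_segments_tile_every_chromosome(self, sparse_map):
        rng = np.random.default_rng(7)
        for ptype in ("control", "mycn_segmental", "del11q_segmental",
                      "numerical_near_triploid"):
            prof = simulate_truth_profile(ptype, 2.0, (0.4, 0.3, 0.3),
                                          sparse_map, rng)
            prof.validate_tiling(sparse_map.lengths_bp)  # raises on gap/overlap

    def test_control_events_are_germline_ibd_with_two_plus_zero(self, sparse_map):
        rng = np.random.default_rng(8)
        events = []
        for _ in range(20):
            prof = simulate_truth_profile("control", 0.5, (1, 0, 0), sparse_map, rng)
            events.extend(prof.events)
        assert events
        assert all(e.origin == "germlineIBD" and e.state == AllelicState(2, 0)
                   for e in events)


def _two_state_truth(marker_map, rho):
    """Mostly (1,1) genome with chr20 entirely (2,0); normalization ploidy 2."""
    from cnloh.sim_cohort import TrueSegment, TruthProfile

    segs, events = [], []
    for chrom, length in marker_map.lengths_bp.items():
        state = AllelicState(2, 0) if chrom == "chr20" else AllelicState(1, 1)
        origin = "somatic" if chrom == "chr20" else "background"
        segs.append(TrueSegment(chrom, 1, length, state, origin))
    return TruthProfile("s", "flat_diploid", segs, events, rho=rho)


class TestSnpTable:
    def test_noise_free_balanced_marker_signals(self, sparse_map):
        rng = np.random.default_rng(1)
        truth = _two_state_truth(sparse_map, rho=0.0)
        snp = simulate_snp_table(truth, sparse_map, rng, noise_sd=0.0)
        df = snp.df[snp.df.chrom == "chr1"]
        het = df[df.call == "AB"]
        assert np.allclose(het.total_ratio, 1.0)
        assert np.allclose(het.baf, 0.5)

    def test_contaminated_loh_gives_mirrored_085(self, sparse_map):
        # (2,0) at rho 0.3 with normalization ploidy 2: t = 1, mirrored 0.85
        rng = np.random.default_rng(2)
        truth = _two_state_truth(sparse_map, rho=0.3)
        snp = simulate_snp_table(truth, sparse_map, rng, noise_sd=0.0)
        df = snp.df[snp.df.chrom == "chr20"]
        het_mask_germline = df.call == "AB"  # false hets regenerated by stroma
        assert het_mask_germline.any()
        sub = df[het_mask_germline]
        assert np.allclose(sub.total_ratio, 1.0)
        mirrored = np.maximum(sub.baf, 1 - sub.baf)
        assert np.allclose(mirrored, 0.85)

    def test_pure_normal_limit_looks_diploid_everywhere(self, sparse_map):
        rng = np.random.default_rng(3)
        truth = _two_state_truth(sparse_map, rho=0.999)
        snp = simulate_snp_table(truth, sparse_map, rng, noise_sd=0.0)
        assert np.allclose(snp.df.total_ratio, 1.0, atol=1e-3)
        het = snp.df[snp.df.call == "AB"]
        assert np.allclose(het.baf, 0.5, atol=2e-3)

    def test_ibd_runs_never_called_heterozygous(self, dense_map):
        for rho in (0.0, 0.3, 0.6):
            rng = np.random.default_rng(4)
            truth = simulate_truth_profile("control", 2.0, (1, 0, 0), dense_map,
                                           rng, rho=rho)
            if not truth.events:
                continue
            snp = simulate_snp_table(truth, dense_map, rng, noise_sd=0.0)
            for e in truth.events:
                df = snp.df[(snp.df.chrom == e.chrom) & (snp.df.pos >= e.start_bp)
                            & (snp.df.pos <= e.end_bp)]
                assert (df.call != "AB").all()

    def test_somatic_loh_regenerates_het_calls_from_rho_02(self, sparse_map):
        rng = np.random.default_rng(5)
        truth = _two_state_truth(sparse_map, rho=0.2)
        snp = simulate_snp_table(truth, sparse_map, rng, noise_sd=0.0)
        df = snp.df[snp.df.chrom == "chr20"]
        assert (df.call == "AB").sum() > 0

    def test_contamination_monotonically_erodes_the_mirrored_split(self):
        rhos = np.linspace(0.0, 1.0, 21)
        fracs = [expected_signals((2, 0), r, 2.0)[1] for r in rhos[:-1]]
        assert fracs[0] == 1.0
        assert np.all(np.diff(fracs) < 0)
        assert expected_signals((2, 0), 0.999999, 2.0)[1] == pytest.approx(0.5, abs=1e-5)


class TestCohort:
    def test_cohort_writes_one_table_per_sample(self, tmp_path):
        cfg = CohortConfig(n_tumors=4, n_cell_lines=3, n_controls=2,
                           marker_spacing_bp=2_000_000, seed=9)
        meta = simulate_cohort(cfg, out_dir=tmp_path)
        assert len(meta) == 9
        assert len(list((tmp_path / "snp").glob("*.tsv"))) == 9
        with pytest.raises(FileExistsError):
            simulate_cohort(cfg, out_dir=tmp_path)
        simulate_cohort(cfg, out_dir=tmp_path, overwrite=True)  # no raise

    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = CohortConfig(n_tumors=2, n_cell_lines=3, n_controls=1,
                           marker_spacing_bp=2_000_000, seed=11)
        simulate_cohort(cfg, out_dir=tmp_path / "a")
        simulate_cohort(cfg, out_dir=tmp_path / "b")
        for f in sorted((tmp_path / "a").rglob("*.tsv")):
            g = tmp_path / "b" / f.relative_to(tmp_path / "a")
            assert f.read_bytes() == g.read_bytes()

    def test_realized_event_means_track_configured_rates(self):
        rates = {"tumor": 0.89, "cell_line": 2.4, "control": 0.10}
        cfg = CohortConfig(n_tumors=134, n_cell_lines=10, n_controls=30,
                           event_rate=rates, marker_spacing_bp=2_000_000, seed=13)
        counts = {"tumor": [], "cell_line": [], "control": []}
        for s in iter_cohort(cfg):
            counts[s.meta["group"]].append(len(s.truth.events))
        for grp, lam in rates.items():
            n = len(counts[grp])
            se = np.sqrt(lam / n)
            assert abs(np.mean(counts[grp]) - lam) < 3 * se + 1e-9

    def test_truth_covers_every_marker_exactly_once(self, sparse_map):
        cfg = CohortConfig(n_tumors=2, n_cell_lines=3, n_controls=1,
                           marker_spacing_bp=155_000, seed=21)
        for s in iter_cohort(cfg, marker_map=sparse_map):
            assert len(s.snp.df) == sparse_map.n_markers()
            s.truth.validate_tiling(sparse_map.lengths_bp)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(subtype_mix={"tumor": (0.5, 0.2, 0.2),
                                      "cell_line": (0.05, 0.74, 0.21),
                                      "control": (1.0, 0.0, 0.0)})
        with pytest.raises(ValueError):
            CohortConfig(event_rate={"tumor": -1.0, "cell_line": 2.4,
                                     "control": 0.1})
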