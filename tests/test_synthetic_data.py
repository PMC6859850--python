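import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from codonstab._genetic_code import SENSE_CODONS, STOP_CODONS
from codonstab.pausescore import (expected_frequencies, observed_occupancy,
                                  pause_scores)
from codonstab.synthetic_data import (SimulationConfig, simulate_footprints,
                                      simulate_steady_state,
                                      simulate_timecourse,
                                      simulate_transcriptome,
                                      truth_from_halflives)

SMALL = SimulationConfig(n_transcripts=30, length_range=(50, 80), seed=7)


class TestTranscriptome:
    def test_valid_orfs(self):
        cds, truth = simulate_transcriptome(SMALL)
        for seq in cds.values():
            assert seq.startswith("ATG")
            assert seq[-3:] in STOP_CODONS
            assert len(seq) % 3 == 0
            internal = [seq[i:i + 3] for i in range(3, len(seq) - 3, 3)]
            assert not set(internal) & set(STOP_CODONS)

    def test_determinism_identical_seeds(self):
        cds1, truth1 = simulate_transcriptome(SMALL)
        cds2, truth2 = simulate_transcriptome(SMALL)
        assert cds1 == cds2
        pd.testing.assert_frame_equal(truth1.table, truth2.table)
        pd.testing.assert_series_equal(truth1.codon_weights, truth2.codon_weights)
        tc1 = simulate_timecourse(truth1, SMALL)
        tc2 = simulate_timecourse(truth2, SMALL)
        pd.testing.assert_frame_equal(tc1.counts, tc2.counts)
        fp1 = simulate_footprints(cds1, truth1, 500, SMALL)
        fp2 = simulate_footprints(cds2, truth2, 500, SMALL)
        pd.testing.assert_frame_equal(fp1.reads, fp2.reads)

    def test_different_seed_differs(self):
        cds1, _ = simulate_transcriptome(SMALL)
        cds2, _ = simulate_transcriptome(
            SimulationConfig(n_transcripts=30, length_range=(50, 80), seed=8))
        assert cds1 != cds2

    def test_zero_effect_zero_noise_gives_equal_rates(self):
        cfg = SimulationConfig(n_transcripts=20, beta=0.0, log_k_noise_sd=0.0, seed=1)
        _, truth = simulate_transcriptome(cfg)
        k = truth.table["k_true"].to_numpy()
        assert np.allclose(k, k[0])

    def test_truth_invariants(self):
        _, truth = simulate_transcriptome(SMALL)
        assert (truth.table["k_true"] > 0).all()
        assert truth.table["abundance"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (truth.dwell_multipliers > 0).all()
        assert set(SENSE_CODONS) <= set(truth.codon_weights.index)

    def test_codon_score_correlates_with_log_k_at_target_r2(self):
        """codon_r2=0.5 -> Spearman(score, log k) ~ -0.7, recomputed with an
        independent rank-correlation routine on the emitted truth table."""
        cfg = SimulationConfig(n_transcripts=500, codon_r2=0.5, seed=5)
        _, truth = simulate_transcriptome(cfg)
        r = spearmanr(truth.table["codon_score"],
                      np.log(truth.table["k_true"])).statistic
        assert -0.80 < r < -0.60

    def test_length_range_too_small_errors(self):
        with pytest.raises(ValueError, match="length_range"):
            SimulationConfig(length_range=(5, 20))

    def test_nonmonotone_timepoints_error(self):
        with pytest.raises(ValueError, match="timepoints"):
            SimulationConfig(timepoints=(1.0, 1.0, 2.0))


class TestTimecourse:
    def test_saturation_at_late_timepoint(self):
        truth = truth_from_halflives([np.log(2.0) / 5.0], depth=1e4)  # k = 5/h
        cfg = SimulationConfig(n_transcripts=1, noise_model="none", seed=0)
        tc = simulate_timecourse(truth, cfg)
        y_eq = truth.table["y_eq_true"].iloc[0]
        assert tc.counts.iloc[0, -1] == pytest.approx(y_eq, rel=1e-6)

    def test_half_saturation_at_half_life(self):
        hl = 4.0
        truth = truth_from_halflives([hl], depth=1e4)
        cfg = SimulationConfig(n_transcripts=1, noise_model="none",
                               timepoints=(1.0, 2.0, hl, 8.0), seed=0)
        tc = simulate_timecourse(truth, cfg)
        y_eq = truth.table["y_eq_true"].iloc[0]
        assert tc.counts.iloc[0, 2] == pytest.approx(y_eq / 2.0, rel=1e-12)

    def test_spike_rows_constant_expectation(self):
        cfg = SimulationConfig(n_transcripts=5, noise_model="none", seed=0, depth=1e5)
        _, truth = simulate_transcriptome(cfg)
        tc = simulate_timecourse(truth, cfg)
        dmel = tc.counts.loc[[r for r in tc.spike_rows if "dmel" in r]]
        assert np.allclose(dmel.sum(axis=0), 1e5 * 0.10)

    def test_poisson_moments_match_generating_means(self):
        """Standardized residuals (c - mu)/sqrt(mu) have mean ~0, var ~1."""
        n = 2000
        hls = np.full(n, 6.0)
        depth = 200 * n / 0.8
        truth = truth_from_halflives(hls, depth=depth)
        cfg = SimulationConfig(n_transcripts=n, noise_model="poisson", seed=3,
                               depth=depth)
        tc = simulate_timecourse(truth, cfg)
        t = np.array(cfg.timepoints)
        mu = truth.table["y_eq_true"].to_numpy()[:, None] * \
            (1.0 - np.exp(-np.outer(truth.table["k_true"], t)))
        c = tc.counts.loc[truth.table.index].to_numpy(dtype=float)
        z = (c - mu) / np.sqrt(mu)
        assert abs(z.mean()) < 0.02
        assert abs(z.var() - 1.0) < 0.05


class TestFootprints:
    def test_reads_within_cds_by_default(self):
        cds, truth = simulate_transcriptome(SMALL)
        fp = simulate_footprints(cds, truth, 2000, SMALL)
        lens = fp.reads["transcript_id"].map(lambda t: len(cds[t]))
        assert (fp.reads["five_prime_pos"] >= 0).all()
        assert (fp.reads["five_prime_pos"] + fp.reads["read_length"] <= lens).all()
        assert fp.reads["read_length"].isin([28, 29, 30]).all()

    def test_uniform_dwell_occupancy_tracks_expected(self):
        cfg = SimulationConfig(n_transcripts=50, length_range=(200, 300),
                               dwell_log_range=(1.0, 1.0), seed=4)
        cds, truth = simulate_transcriptome(cfg)
        fp = simulate_footprints(cds, truth, 60_000, cfg)
        obs = observed_occupancy(fp, cds, "A")
        expected = expected_frequencies(fp, cds)
        sense = list(SENSE_CODONS)
        r = spearmanr(obs.obs_freq[sense], expected[sense]).statistic
        assert r > 0.97

    def test_forced_dwell_enrichment_single_transcript(self):
        truth = truth_from_halflives([8.0])
        tid = truth.table.index[0]
        cds = {tid: "ATG" + "AAACCCGGG" * 30 + "TAA"}
        truth.dwell_multipliers.loc["AAA"] = 10.0
        cfg = SimulationConfig(n_transcripts=1, seed=2)
        fp = simulate_footprints(cds, truth, 5000, cfg)
        obs = observed_occupancy(fp, cds, "A")
        # AAA, CCC, GGG equally frequent in the CDS; AAA must dominate the A site
        assert obs.obs_freq["AAA"] > 2.0 * obs.obs_freq["CCC"]

    def test_stop_codon_reachable_only_with_overhang(self):
        cfg = SimulationConfig(n_transcripts=20, seed=6, stop_pause=8.0)
        cds, truth = simulate_transcriptome(cfg)
        fp_default = simulate_footprints(cds, truth, 3000, cfg)
        occ_default = observed_occupancy(fp_default, cds, "A")
        assert occ_default.obs_counts[list(STOP_CODONS)].sum() == 0
        fp_over = simulate_footprints(cds, truth, 3000, cfg, allow_stop_site=True)
        occ_over = observed_occupancy(fp_over, cds, "A")
        assert occ_over.obs_counts[list(STOP_CODONS)].sum() > 0

    def test_terminal_pause_a_site_exceeds_p_site(self):
        """Stop-codon dwell inflation enriches stops in the A site but not P."""
        cfg = SimulationConfig(n_transcripts=30, seed=2, stop_pause=8.0)
        cds, truth = simulate_transcriptome(cfg)
        fp = simulate_footprints(cds, truth, 20_000, cfg, allow_stop_site=True)
        expected = expected_frequencies(fp, cds)
        a = pause_scores(observed_occupancy(fp, cds, "A"), expected)
        p = pause_scores(observed_occupancy(fp, cds, "P"), expected)
        stops = list(STOP_CODONS)
        assert (a.score[stops] > p.score[stops]).all()

    def test_n_reads_must_be_positive(self):
        cds, truth = simulate_transcriptome(SMALL)
        with pytest.raises(ValueError):
            simulate_footprints(cds, truth, 0, SMALL)


class TestSteadyState:
    def test_planted_design_recovered_exactly(self):
        from codonstab.classify import classify_lines
        from codonstab.synthetic_data import planted_pools

        cds, truth = simulate_transcriptome(SMALL)
        steady, expected = simulate_steady_state(truth, SMALL)
        pools = planted_pools(truth)
        for line, other in (("line_A", "line_B"), ("line_B", "line_A")):
            res = classify_lines(steady, pools, line, other)
            exp = expected[f"label_{line}"].reindex(res.index)
            assert (res["label"] == exp).all()

    def test_library_totals_equalized(self):
        _, truth = simulate_transcriptome(SMALL)
        steady, _ = simulate_steady_state(truth, SMALL)
        totals = steady.sum(axis=0)
        assert totals["line_A"] == pytest.approx(totals["line_B"])
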