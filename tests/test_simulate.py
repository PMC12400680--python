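"""Synthetic cohort generator: reproducibility, calibration, duplicates."""

import numpy as np
import pytest

from bcsagree.io import write_score_table
from bcsagree.simulate import (
    CohortConfig,
    RaterModel,
    WeightModel,
    calibrate_weight_model,
    default_config,
    generate_cohort,
    generate_rater_scores,
    generate_truth_and_weights,
    inject_duplicates,
    load_cohort_config,
)
from bcsagree.stats import spearman_rho


class TestTruthAndWeights:
    def test_degenerate_distribution(self):
        cfg = default_config(seed=1, truth_distribution={6: 1.0}, n_duplicate_pairs=0)
        truth, _ = generate_truth_and_weights(cfg)
        assert (truth == 6).all()

    def test_zero_log_sd_gives_perfect_rank_correlation(self):
        cfg = default_config(
            seed=2, weight_model=WeightModel(log_sd=0.0), n_subjects=200,
            n_duplicate_pairs=0,
        )
        truth, weights = generate_truth_and_weights(cfg)
        assert spearman_rho(truth, weights).rho == pytest.approx(1.0)

    def test_default_calibration_near_target(self):
        cfg = default_config(seed=3, n_subjects=10_000, n_duplicate_pairs=0)
        truth, weights = generate_truth_and_weights(cfg)
        assert spearman_rho(truth, weights).rho == pytest.approx(0.73, abs=0.05)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            default_config(truth_distribution={5: 0.5, 6: 0.6})


class TestRaterScores:
    def test_noiseless_raters_reproduce_truth(self):
        truth = [4, 5, 6, 7, 8, 9]
        raters = [RaterModel(r, 0.0, 0.0) for r in "ABC"]
        m = generate_rater_scores(truth, raters, seed=0)
        for r in "ABC":
            assert m.frame[r].tolist() == truth

    def test_extreme_bias_clamped(self):
        m = generate_rater_scores([9, 9], [RaterModel("A", bias=8.0, dispersion=0.0)], seed=0)
        assert m.frame["A"].tolist() == [9, 9]
        m = generate_rater_scores([1, 1], [RaterModel("A", bias=-8.0, dispersion=0.0)], seed=0)
        assert m.frame["A"].tolist() == [1, 1]

    def test_vote_beats_mean_single_rater_agreement(self):
        from bcsagree.consensus import consensus_scores

        rng = np.random.default_rng(5)
        truth = rng.choice([4, 5, 6, 7, 8, 9], size=500)
        raters = [RaterModel(str(i), 0.0, 0.6) for i in range(9)]
        m = generate_rater_scores(truth, raters, seed=6)
        votes = np.array([v.vote for v in consensus_scores(m).values()])
        vote_recovery = (votes == truth).mean()
        single = np.mean([(m.frame[r.rater_id].to_numpy() == truth).mean() for r in raters])
        assert vote_recovery > single


class TestFullCohort:
    def test_reproducible_and_serialized_identically(self, tmp_path):
        a = generate_cohort(default_config(seed=11))
        b = generate_cohort(default_config(seed=11))
        assert a.matrix == b.matrix
        assert (a.truth == b.truth).all()
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_score_table(a.matrix, pa)
        write_score_table(b.matrix, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        a = generate_cohort(default_config(seed=1))
        b = generate_cohort(default_config(seed=2))
        assert a.matrix != b.matrix

    def test_duplicate_injection_counts(self):
        # 46 internet-sourced images + 4 duplicate pairs -> 50 presentations
        cfg = default_config(seed=7, n_subjects=46, n_duplicate_pairs=4)
        assert generate_cohort(cfg).matrix.n_subjects == 50
        # 38 enrolled animals + 2 duplicated photographs -> 40
        cfg = default_config(seed=7, n_subjects=38, n_duplicate_pairs=2)
        cohort = generate_cohort(cfg)
        assert cohort.matrix.n_subjects == 40
        assert len(cohort.registry.pairs) == 2

    def test_registry_consistent_with_matrix_and_cohort(self):
        cohort = generate_cohort(default_config(seed=8))
        present = set(cohort.matrix.subjects)
        assert cohort.registry.members <= present
        for src, dup in cohort.registry.pairs:
            # duplicates carry their source animal's weight and true score
            assert cohort.weights.loc[dup] == cohort.weights.loc[src]
            assert cohort.truth.loc[dup] == cohort.truth.loc[src]

    def test_degenerate_duplicates_score_identically(self):
        raters = tuple(RaterModel(r, 0.0, 0.0) for r in "ABC")
        cfg = default_config(
            seed=9, raters=raters, n_duplicate_pairs=0, duplicate_perturbation={0: 1.0}
        )
        cohort = generate_cohort(cfg)
        cohort = inject_duplicates(cohort, 2, {0: 1.0}, seed=10)
        frame = cohort.matrix.frame
        for src, dup in cohort.registry.pairs:
            assert frame.loc[src].tolist() == frame.loc[dup].tolist()


class TestCalibration:
    def test_target_073_within_band(self):
        _, rho = calibrate_weight_model(0.73, n_calibration=10_000, seed=0)
        assert 0.71 <= rho <= 0.75

    def test_high_target_needs_little_noise(self):
        wm, _ = calibrate_weight_model(0.999, n_calibration=5_000, seed=0, tol=0.0005)
        assert wm.log_sd < 0.02

    def test_log_sd_monotone_in_target(self):
        wm_hi, _ = calibrate_weight_model(0.9, n_calibration=5_000, seed=0)
        wm_lo, _ = calibrate_weight_model(0.5, n_calibration=5_000, seed=0)
        assert wm_lo.log_sd > wm_hi.log_sd

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            calibrate_weight_model(1.5)
        with pytest.raises(ValueError):
            calibrate_weight_model(0.5, truth_distribution={6: 1.0})


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "seed: 42\nn_subjects: 20\nn_duplicate_pairs: 1\n"
            "truth_distribution: {5: 0.5, 7: 0.5}\n"
            "raters:\n  - {rater_id: A, dispersion: 0.4, tier: senior}\n"
            "  - {rater_id: B}\n"
            "weight_model: {intercept: 1.0, slope: 0.1, log_sd: 0.2}\n"
        )
        cfg = load_cohort_config(p)
        assert cfg.seed == 42 and cfg.n_subjects == 20
        assert cfg.raters[0].tier == "senior"
        assert cfg.weight_model.slope == 0.1
        generate_cohort(cfg)  # usable end to end

    def test_seed_is_mandatory(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("n_subjects: 5\n")
        with pytest.raises(ValueError, match="seed"):
            load_cohort_config(p)
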