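import numpy as np
import pytest

from deltacc.correlation import correlation_matrix
from deltacc.panel import changed_pairs, select_panel
from deltacc.simulate import (
    PlantedDEG,
    PlantedPair,
    SyntheticConfig,
    build_target_correlation,
    evaluate_recovery,
    generate_study,
    nearest_psd,
    sample_condition,
)


class TestNearestPsd:
    def test_psd_input_unchanged(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 8))
        corr = np.corrcoef(a)
        assert np.allclose(nearest_psd(corr), corr, atol=1e-10)

    def test_identity_fixed_point(self):
        assert np.allclose(nearest_psd(np.eye(4)), np.eye(4))

    def test_indefinite_matrix_repaired(self):
        # 3x3 equicorrelation at -0.9 has eigenvalue 1 + 2*(-0.9) < 0
        bad = np.full((3, 3), -0.9)
        np.fill_diagonal(bad, 1.0)
        floor = 1e-6
        fixed = nearest_psd(bad, eigen_floor=floor)
        w = np.linalg.eigvalsh(fixed)
        assert w.min() >= 0  # PSD after repair (rescaling may shift the floor)
        assert np.allclose(np.diag(fixed), 1.0)


class TestBuildTarget:
    def test_no_pairs_background_zero_is_identity(self):
        assert np.allclose(build_target_correlation(5, [], 0.0), np.eye(5))

    def test_single_pair_preserved_exactly(self):
        t = build_target_correlation(4, [(0, 1, 0.9)], 0.0)
        assert t[0, 1] == pytest.approx(0.9, abs=1e-9)

    def test_multiple_pairs_with_background_within_drift(self):
        planted = [(0, 1, 0.9), (2, 3, -0.8), (4, 5, 0.0)]
        t = build_target_correlation(10, planted, background_cc=0.1)
        assert np.linalg.eigvalsh(t).min() >= -1e-10
        for i, j, cc in planted:
            assert t[i, j] == pytest.approx(cc, abs=0.02)

    def test_inconsistent_targets_error(self):
        # A~B and A~C near +1 but B~C near -1 cannot be repaired quietly
        planted = [(0, 1, 0.99), (0, 2, 0.99), (1, 2, -0.99)]
        with pytest.raises(ValueError, match="drifted"):
            build_target_correlation(3, planted, 0.0)


class TestSampleCondition:
    def test_deterministic_for_seed(self):
        t = build_target_correlation(5, [(0, 1, 0.7)], 0.0)
        means = np.full(5, 8.0)
        a = sample_condition(t, means, 0.5, 20, seed=11)
        b = sample_condition(t, means, 0.5, 20, seed=11)
        assert np.array_equal(a, b)
        c = sample_condition(t, means, 0.5, 20, seed=12)
        assert not np.array_equal(a, c)

    def test_empirical_correlation_near_target(self):
        t = build_target_correlation(3, [(0, 1, 0.9)], 0.0)
        x = sample_condition(t, np.zeros(3), 1.0, 5000, seed=2)
        r = np.corrcoef(x)[0, 1]
        assert r == pytest.approx(0.9, abs=0.02)

    def test_mean_shift_recovered(self):
        noise_sd, n = 0.5, 400
        t = np.eye(2)
        base = sample_condition(t, np.array([8.0, 8.0]), noise_sd, n, seed=3)
        up = sample_condition(t, np.array([12.0, 8.0]), noise_sd, n, seed=4)
        diff = up[0].mean() - base[0].mean()
        assert abs(diff - 4.0) <= 3 * noise_sd / np.sqrt(n) * np.sqrt(2)

    def test_non_psd_target_errors(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            sample_condition(bad, np.zeros(2), 1.0, 5, seed=0)


def _study_config(**kw):
    defaults = dict(
        n_genes=12,
        n_subjects=10,
        n_replicates=2,
        seed=5,
        planted_pairs=[
            PlantedPair(0, 1, {"Pre": 0.9, "In": 0.0, "Post": 0.0}),
            PlantedPair(2, 3, {"Pre": 0.5, "In": -0.5, "Post": -0.5}),
        ],
        planted_degs=[PlantedDEG(4, 4.0)],
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestGenerateStudy:
    def test_study_shape_matches_design(self):
        # 10 subjects x 2 replicate profiles x 3 time points
        mats, sheet, truth = generate_study(_study_config())
        assert set(mats) == {"Pre", "In", "Post"}
        for m in mats.values():
            assert m.shape == (12, 20)
        assert len(sheet.table) == 60
        assert mats["Pre"].row_ids == mats["In"].row_ids == truth.gene_ids

    def test_zero_planted_pairs_nothing_selectable(self):
        _, _, truth = generate_study(_study_config(planted_pairs=[]))
        assert truth.should_be_selected == set()

    def test_strong_to_weak_pair_marked_selectable(self):
        _, _, truth = generate_study(_study_config())
        assert "G0000--G0001" in truth.should_be_selected  # 0.9 -> 0.0
        assert "G0002--G0003" not in truth.should_be_selected  # moderate flip

    def test_truth_agrees_with_selection_on_noise_free_targets(self):
        from deltacc.correlation import CorrelationMatrix

        cfg = _study_config()
        _, _, truth = generate_study(cfg)
        pre = CorrelationMatrix(truth.gene_ids, truth.target_cc["Pre"], "Pre")
        inf = CorrelationMatrix(truth.gene_ids, truth.target_cc["In"], "In")
        selected = select_panel(changed_pairs(pre, inf))
        assert {p.pair_id for p in selected} == truth.should_be_selected

    def test_deterministic_for_seed(self):
        m1, _, _ = generate_study(_study_config())
        m2, _, _ = generate_study(_study_config())
        assert np.array_equal(m1["In"].values, m2["In"].values)

    def test_planted_deg_shifts_in_condition_mean(self):
        cfg = _study_config(n_subjects=200)
        mats, _, truth = generate_study(cfg)
        diff = mats["In"].values[4].mean() - mats["Pre"].values[4].mean()
        assert diff == pytest.approx(4.0, abs=0.2)
        assert truth.planted_log2fc == {"G0004": 4.0}


class TestEvaluateRecovery:
    def test_perfect_recovery(self):
        cfg = _study_config()
        _, _, truth = generate_study(cfg)
        perfect = [p for p in truth.planted_records if p.pair_id in truth.should_be_selected]
        assert evaluate_recovery(perfect, truth) == (1.0, 0.0)

    def test_empty_selection(self):
        _, _, truth = generate_study(_study_config())
        assert evaluate_recovery([], truth) == (0.0, 0.0)

    def test_undefined_sensitivity_without_planted(self):
        _, _, truth = generate_study(_study_config(planted_pairs=[]))
        sens, fpr = evaluate_recovery([], truth)
        assert np.isnan(sens) and fpr == 0.0

    def test_high_sensitivity_with_strong_transitions_at_n200(self):
        pairs = [
            PlantedPair(2 * k, 2 * k + 1, {"Pre": 0.9, "In": -0.3, "Post": -0.3})
            for k in range(10)
        ] + [
            PlantedPair(20 + 2 * k, 21 + 2 * k, {"Pre": -0.25, "In": 0.9, "Post": 0.9})
            for k in range(10)
        ]
        cfg = SyntheticConfig(
            n_genes=50, n_subjects=100, n_replicates=2, seed=42, planted_pairs=pairs
        )
        mats, _, truth = generate_study(cfg)
        assert len(truth.should_be_selected) == 20
        sel = select_panel(
            changed_pairs(
                correlation_matrix(mats["Pre"], "Pre"),
                correlation_matrix(mats["In"], "In"),
            )
        )
        sens, fpr = evaluate_recovery(sel, truth)
        assert sens >= 0.9
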