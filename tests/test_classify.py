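"""Classifier training, metrics, z-score calibration, one-class screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breedkit import (
    BreedkitError,
    SimulationConfig,
    SnpPanel,
    calibrate_zscore,
    evaluate_metrics,
    predict_new,
    random_genotypes,
    simulate_breeds,
    train,
)
from breedkit.classify import load_model, one_class_check, predictions_frame, save_model

from .conftest import breed_table, genotype_matrix


# ---------------------------------------------------------------------------
# z-score calibration
# ---------------------------------------------------------------------------


class TestCalibrateZscore:
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0, 4.0])
    def test_half_maps_to_half_on_both_branches(self, alpha):
        assert calibrate_zscore(0.5, alpha) == pytest.approx(0.5)
        # just either side of the branch point
        assert calibrate_zscore(0.5 + 1e-12, alpha) == pytest.approx(0.5, abs=1e-9)
        assert calibrate_zscore(0.5 - 1e-12, alpha) == pytest.approx(0.5, abs=1e-9)

    def test_certain_prediction_stays_certain(self):
        assert calibrate_zscore(1.0, 2.0) == 1.0

    def test_high_branch_value(self):
        # t = 0.8^2 / (0.8^2 + 0.2^2) = 0.64 / 0.68
        assert calibrate_zscore(0.8, 2.0) == pytest.approx(0.64 / 0.68, abs=1e-9)

    def test_low_branch_value_mirrors_high_branch_at_alpha_two(self):
        t = 0.04 / 0.68
        expected = t + 2.0 * (0.5 - t)
        assert calibrate_zscore(0.2, 2.0) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.64 / 0.68, abs=1e-9)

    @given(st.floats(min_value=0.505, max_value=1.0))
    @settings(max_examples=60, derandomize=True)
    def test_upper_branch_is_increasing(self, p):
        eps = 1e-4
        if p - eps > 0.5:
            assert calibrate_zscore(p, 2.0) >= calibrate_zscore(p - eps, 2.0)

    def test_alpha_two_mirror_identity_on_grid(self):
        for p in np.linspace(0.01, 0.99, 99):
            assert calibrate_zscore(p, 2.0) == pytest.approx(
                calibrate_zscore(1.0 - p, 2.0), abs=1e-9
            )

    def test_low_branch_can_exceed_one_and_is_clamped(self):
        raw = calibrate_zscore(0.3, 4.0, clamp=False)
        assert raw > 1.0
        assert calibrate_zscore(0.3, 4.0) == 1.0

    def test_invalid_probability_errors(self):
        with pytest.raises(BreedkitError):
            calibrate_zscore(1.2, 2.0)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def auc_oracle(y_bin: np.ndarray, score: np.ndarray) -> float:
    """All-pairs comparison count with midpoint ties."""
    pos = score[y_bin == 1]
    neg = score[y_bin == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEvaluateMetrics:
    def test_perfect_predictions(self):
        y = np.array(["A", "B", "C"])
        proba = np.eye(3)
        acc, kappa, auc, conf = evaluate_metrics(y, y, proba, ["A", "B", "C"])
        assert (acc, kappa, auc) == (1.0, 1.0, 1.0)
        assert (np.diag(conf.values) == 1).all()

    def test_majority_class_predictor_has_zero_kappa(self):
        y = np.array(["A"] * 10 + ["B"] * 10)
        pred = np.array(["A"] * 20)
        proba = np.tile([0.6, 0.4], (20, 1))
        acc, kappa, _, _ = evaluate_metrics(y, pred, proba, ["A", "B"])
        assert acc == pytest.approx(0.5)
        assert kappa == pytest.approx(0.0)

    def test_two_class_macro_auc_is_classic_auc(self):
        rng = np.random.default_rng(3)
        y = rng.choice(["A", "B"], size=40)
        p_b = rng.random(40)
        proba = np.column_stack([1 - p_b, p_b])
        pred = np.where(p_b > 0.5, "B", "A")
        _, _, auc, _ = evaluate_metrics(y, pred, proba, ["A", "B"])
        assert auc == pytest.approx(auc_oracle((y == "B").astype(int), p_b), abs=1e-9)

    def test_macro_auc_matches_all_pairs_oracle_multiclass(self):
        rng = np.random.default_rng(4)
        classes = ["A", "B", "C"]
        y = rng.choice(classes, size=30)
        proba = rng.dirichlet(np.ones(3), size=30)
        pred = np.array(classes)[np.argmax(proba, axis=1)]
        _, _, auc, _ = evaluate_metrics(y, pred, proba, classes)
        expect = np.mean(
            [auc_oracle((y == c).astype(int), proba[:, i])
             for i, c in enumerate(classes)]
        )
        assert auc == pytest.approx(expect, abs=1e-9)

    def test_absent_class_excluded_with_warning(self):
        y = np.array(["A", "A", "B", "B"])
        proba = np.tile([0.5, 0.3, 0.2], (4, 1))
        with pytest.warns(UserWarning, match="absent"):
            _, _, auc, _ = evaluate_metrics(y, y, proba, ["A", "B", "C"])
        assert not np.isnan(auc)

    def test_random_probabilities_give_half_auc(self):
        rng = np.random.default_rng(6)
        n = 4000
        y = rng.choice(["A", "B"], size=n)
        p_b = rng.random(n)
        proba = np.column_stack([1 - p_b, p_b])
        pred = np.where(p_b > 0.5, "B", "A")
        _, _, auc, _ = evaluate_metrics(y, pred, proba, ["A", "B"])
        assert auc == pytest.approx(0.5, abs=0.05)


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def trained_model():
    cfg = SimulationConfig(n_breeds=3, n_per_breed=15, n_snps=400, fst=0.3, seed=20)
    G, breeds, geo, _ = simulate_breeds(cfg)
    panel = SnpPanel(G.snp_ids[:200])
    model, report = train(G, breeds, panel, algorithm="rf", seed=20)
    return G, breeds, geo, model, report


class TestTrain:
    def test_separable_breeds_reach_perfect_cv(self, trained_model):
        _, _, _, _, report = trained_model
        assert report.accuracy == 1.0
        assert report.kappa == 1.0
        assert report.macro_auc == 1.0

    def test_confusion_rows_sum_to_breed_counts(self, trained_model):
        G, breeds, _, _, report = trained_model
        counts = breeds.counts()
        for breed, row_sum in report.confusion.sum(axis=1).items():
            assert row_sum == counts[breed]

    @pytest.mark.parametrize("algorithm", ["knn", "svm", "xgb"])
    def test_other_algorithms_train_and_predict(self, algorithm):
        cfg = SimulationConfig(n_breeds=2, n_per_breed=10, n_snps=100, fst=0.35, seed=21)
        G, breeds, _, _ = simulate_breeds(cfg)
        panel = SnpPanel(G.snp_ids[:50])
        model, report = train(G, breeds, panel, algorithm=algorithm, seed=21)
        assert report.accuracy > 0.8
        results = predict_new(model, G)
        assert len(results) == G.n_individuals

    def test_breed_with_single_individual_errors(self):
        G = genotype_matrix(np.random.default_rng(0).integers(0, 3, size=(5, 10)))
        bt = breed_table(G.individual_ids, ["A", "A", "A", "A", "B"])
        with pytest.raises(BreedkitError):
            train(G, bt, SnpPanel(G.snp_ids[:5]), algorithm="knn")

    def test_panel_snp_missing_from_genotypes_errors(self, trained_model):
        G, breeds, *_ = trained_model
        with pytest.raises(BreedkitError, match="absent"):
            train(G, breeds, SnpPanel(["nope"]), algorithm="rf")

    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(n_breeds=2, n_per_breed=10, n_snps=100, fst=0.3, seed=22)
        G, breeds, _, _ = simulate_breeds(cfg)
        panel = SnpPanel(G.snp_ids[:60])
        m1, r1 = train(G, breeds, panel, algorithm="rf", seed=5)
        m2, r2 = train(G, breeds, panel, algorithm="rf", seed=5)
        assert r1.summary() == r2.summary()
        p1 = predictions_frame(predict_new(m1, G))
        p2 = predictions_frame(predict_new(m2, G))
        pd.testing.assert_frame_equal(p1, p2)


class TestOneClass:
    def test_training_individuals_pass_their_own_breed(self, trained_model):
        G, breeds, _, model, _ = trained_model
        results = predict_new(model, G)
        passed = np.mean([r.one_class_pass for r in results])
        assert passed >= 0.99

    def test_uniform_random_genotypes_rejected(self, trained_model):
        G, _, _, model, _ = trained_model
        rand = random_genotypes(40, G.snps, seed=99)
        results = predict_new(model, rand)
        rejected = np.mean([not r.one_class_pass for r in results])
        assert rejected >= 0.95

    def test_all_missing_row_fails_low_quality(self, trained_model):
        _, _, _, model, _ = trained_model
        row = np.full(len(model.panel), np.nan)
        ok, _, reason = one_class_check(model, row, model.classes[0])
        assert not ok and reason == "low-quality"


class TestPredictNew:
    def test_geo_columns_joined_on_predicted_breed(self, trained_model):
        G, _, geo, model, _ = trained_model
        results = predict_new(model, G, geo)
        for r in results:
            expect = geo.lookup(r.breed)
            assert r.latitude == expect["Latitude"]
            assert r.location == expect["Location"]

    def test_probability_vector_sums_to_one(self, trained_model):
        G, _, _, model, _ = trained_model
        for r in predict_new(model, G):
            assert sum(r.prob_vector.values()) == pytest.approx(1.0, abs=1e-8)
            assert r.z_score == pytest.approx(
                calibrate_zscore(r.probability, model.alpha)
            )

    def test_zero_panel_overlap_errors(self, trained_model):
        G, _, _, model, _ = trained_model
        other = genotype_matrix(np.zeros((2, 3)))
        other.snps["id"] = ["x1", "x2", "x3"]
        with pytest.raises(BreedkitError):
            predict_new(model, other)

    def test_model_round_trips_through_disk(self, trained_model, tmp_path):
        G, _, _, model, _ = trained_model
        save_model(model, tmp_path / "m.bin")
        loaded = load_model(tmp_path / "m.bin")
        a = predictions_frame(predict_new(model, G))
        b = predictions_frame(predict_new(loaded, G))
        pd.testing.assert_frame_equal(a, b)
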