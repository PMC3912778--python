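import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_feature_table, make_rings_table
from ehgkit.classify import (
    DEFAULT_ARTIFACT_FEATURES,
    evaluate,
    holdout_test,
    optimize_svm_params,
    repeated_two_fold_cv,
    sequential_forward_selection,
    single_feature_screen,
    train_classifier,
)
from ehgkit.features import FEATURE_NAMES

KINDS = ("lda", "qda", "svm_rbf")


class TestEvaluate:
    def test_confusion_panel_arithmetic(self):
        y_true = [1] * 10 + [0] * 20
        y_pred = [1] * 9 + [0] + [0] * 19 + [1]
        m = evaluate(np.array(y_pred), np.array(y_true))
        assert m["sensitivity"] == pytest.approx(90.0)
        assert m["specificity"] == pytest.approx(95.0)
        assert m["ppv"] == pytest.approx(90.0)
        assert m["npv"] == pytest.approx(95.0)
        assert m["accuracy"] == pytest.approx(100 * 28 / 30)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        m = evaluate(y, y)
        assert all(v == pytest.approx(100.0) for v in m.values())

    def test_complement_predictions(self):
        y = np.array([0, 1, 0, 1])
        m = evaluate(1 - y, y)
        assert m["accuracy"] == 0.0
        assert m["sensitivity"] == 0.0

    def test_metric_identities_on_random_predictions(self, rng):
        y_true = rng.integers(0, 2, 200)
        y_true[:2] = [0, 1]
        y_pred = rng.integers(0, 2, 200)
        m = evaluate(y_pred, y_true)
        tp = np.sum((y_pred == 1) & (y_true == 1))
        fp = np.sum((y_pred == 1) & (y_true == 0))
        tn = np.sum((y_pred == 0) & (y_true == 0))
        assert m["accuracy"] == pytest.approx(100 * (tp + tn) / 200)
        if tp + fp:
            assert m["ppv"] / 100 * (tp + fp) == pytest.approx(tp)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([1, 0]), np.array([1, 1]))


class TestTrainClassifier:
    @pytest.mark.parametrize("kind", KINDS)
    def test_separated_blobs_are_learned(self, kind, rng):
        table = make_feature_table(200, rng, separation=6.0)
        model = train_classifier(kind, table)
        y_true = (table["label"] == "artifacted").astype(int).to_numpy()
        acc = evaluate(model.predict(table), y_true)["accuracy"]
        assert acc >= 99.0

    def test_nonlinear_boundary_needs_nonlinear_model(self, rng):
        table = make_rings_table(150, rng)
        accs = {
            kind: repeated_two_fold_cv(table, kind, ["E3", "RA"], reps=5,
                                       seed=0).summary["accuracy"][0]
            for kind in KINDS
        }
        assert accs["qda"] >= accs["lda"] + 20
        assert accs["svm_rbf"] >= accs["lda"] + 20

    def test_degenerate_single_point_classes(self):
        rows = []
        for _ in range(3):
            rows.append({**{f: 0.0 for f in FEATURE_NAMES}, "label": "nonartifacted"})
            rows.append({**{f: 1.0 for f in FEATURE_NAMES}, "label": "artifacted"})
        table = pd.DataFrame(rows)
        model = train_classifier("qda", table)
        probe = pd.DataFrame([{f: 0.9 for f in FEATURE_NAMES}])
        assert model.predict(probe)[0] == 1  # nearer the artifacted mean


class TestRepeatedTwoFoldCV:
    def test_separable_table(self, rng):
        table = make_feature_table(60, rng, separation=8.0)
        rep = repeated_two_fold_cv(table, "lda", reps=50, seed=3)
        mean, sd = rep.summary["accuracy"]
        assert mean >= 99.0
        assert sd <= 1.0

    def test_permuted_labels_fall_to_chance(self, rng):
        table = make_feature_table(90, rng, separation=6.0)
        table = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled = table.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        rep = repeated_two_fold_cv(shuffled, "lda", reps=20, seed=3)
        majority = 50.0  # balanced table
        assert rep.summary["accuracy"][0] == pytest.approx(majority, abs=3.0)

    def test_reproducible_with_seed(self, rng):
        table = make_feature_table(30, rng)
        r1 = repeated_two_fold_cv(table, "qda", reps=1, seed=11)
        r2 = repeated_two_fold_cv(table, "qda", reps=1, seed=11)
        pd.testing.assert_frame_equal(r1.per_rep, r2.per_rep)
        pd.testing.assert_frame_equal(r1.per_fold, r2.per_fold)

    def test_tiny_class_rejected(self, rng):
        table = make_feature_table(30, rng)
        table = pd.concat([table[table.label == "nonartifacted"],
                           table[table.label == "artifacted"].head(1)])
        with pytest.raises(ValueError):
            repeated_two_fold_cv(table, "lda", reps=2, seed=0)


class TestSvmOptimization:
    def test_beats_coarse_grid(self, rng):
        table = make_feature_table(40, rng, separation=3.0)
        c, g = optimize_svm_params(table, ["E3", "RA"], seed=5)

        def cv_err(cc, gg):
            rep = repeated_two_fold_cv(table, "svm_rbf", ["E3", "RA"], reps=2,
                                       seed=5, hyperparams={"C": cc, "gamma": gg})
            return 100.0 - rep.summary["accuracy"][0]

        best_grid = min(
            cv_err(cc, gg)
            for cc in np.logspace(-2, 2, 5)
            for gg in np.logspace(-3, 1, 5)
        )
        assert cv_err(c, g) <= best_grid + 2.0

    def test_deterministic(self, rng):
        table = make_feature_table(30, rng)
        assert optimize_svm_params(table, seed=2) == optimize_svm_params(table, seed=2)

    def test_constant_feature_terminates(self, rng):
        table = make_feature_table(20, rng)
        table["E3"] = 1.0
        c, g = optimize_svm_params(table, ["E3"], seed=0, maxiter=15)
        assert np.isfinite([c, g]).all()


class TestSingleFeatureScreen:
    def test_informative_feature_wins(self, rng):
        table = make_feature_table(60, rng, informative=("MD_bs",), separation=5.0)
        screen = single_feature_screen(table, kinds=("lda", "qda"), reps=5, seed=0)
        for kind in ("lda", "qda"):
            assert screen[kind].idxmax() == "MD_bs"

    def test_noise_feature_near_chance(self, rng):
        table = make_feature_table(60, rng, informative=("MD_bs",), separation=5.0)
        screen = single_feature_screen(table, kinds=("lda",), reps=10, seed=0)
        assert abs(screen.loc["E1", "lda"] - 50.0) <= 5.0

    def test_duplicated_features_identical(self, rng):
        table = make_feature_table(40, rng, informative=("E3",), separation=4.0)
        table["RA"] = table["E3"]
        screen = single_feature_screen(table, kinds=("lda",), reps=5, seed=0)
        assert screen.loc["E3", "lda"] == screen.loc["RA", "lda"]


class TestSequentialForwardSelection:
    def three_feature_table(self, rng):
        # A and B carry complementary signal, C is pure noise
        n = 120
        rows = []
        for label, shift in (("nonartifacted", 0.0), ("artifacted", 2.5)):
            for _ in range(n):
                a = rng.normal() + shift
                b = rng.normal() + shift * 0.8
                rows.append({"E3": a, "RA": b, "En": rng.normal(),
                             "label": label})
        return pd.DataFrame(rows)

    def exhaustive_best(self, table, kind, candidates, reps, seed):
        best, best_err = None, np.inf
        for k in range(1, len(candidates) + 1):
            for combo in itertools.combinations(candidates, k):
                rep = repeated_two_fold_cv(table, kind, list(combo),
                                           reps=reps, seed=seed)
                err = 100.0 - rep.summary["accuracy"][0]
                if err < best_err - 1e-12:
                    best, best_err = set(combo), err
        return best, best_err

    def test_matches_exhaustive_search(self, rng):
        table = self.three_feature_table(rng)
        cands = ["E3", "RA", "En"]
        sfs = sequential_forward_selection(table, "lda", cands, reps=10, seed=4)
        best, best_err = self.exhaustive_best(table, "lda", cands, reps=10, seed=4)
        assert sfs.error_trace[-1] <= best_err + 0.5
        assert set(sfs.selected) == best

    def test_noise_candidates_stay_out(self, rng):
        n = 80
        rows = [{"E1": rng.normal(), "E2": rng.normal(), "En": rng.normal(),
                 "label": lab}
                for lab in ("nonartifacted", "artifacted") for _ in range(n)]
        table = pd.DataFrame(rows)
        sfs = sequential_forward_selection(table, "lda", ["E1", "E2", "En"],
                                           reps=10, seed=0)
        assert len(sfs.selected) <= 1

    def test_never_worse_than_best_single(self, rng):
        table = self.three_feature_table(rng)
        sfs = sequential_forward_selection(table, "qda", ["E3", "RA", "En"],
                                           reps=10, seed=1)
        singles = [
            100.0 - repeated_two_fold_cv(table, "qda", [f], reps=10,
                                         seed=1).summary["accuracy"][0]
            for f in ["E3", "RA", "En"]
        ]
        assert sfs.error_trace[-1] <= min(singles) + 1e-9

    def test_preset_features_are_a_subset_of_the_eleven(self):
        assert set(DEFAULT_ARTIFACT_FEATURES) <= set(FEATURE_NAMES)


class TestHoldout:
    def test_same_distribution_matches_cv(self, rng):
        train = make_feature_table(120, rng, separation=4.0, n_groups=8)
        test = make_feature_table(40, rng, separation=4.0, n_groups=2)
        test["group_id"] += 100
        cv_acc = repeated_two_fold_cv(train, "qda", reps=10,
                                      seed=0).summary["accuracy"][0]
        held = holdout_test("qda", train, test)
        assert abs(held["accuracy"] - cv_acc) <= 5.0

    def test_group_overlap_rejected(self, rng):
        train = make_feature_table(20, rng)
        test = make_feature_table(10, rng)
        with pytest.raises(ValueError, match="leakage"):
            holdout_test("lda", train, test)

    def test_empty_test_rejected(self, rng):
        train = make_feature_table(20, rng)
        with pytest.raises(ValueError, match="empty"):
            holdout_test("lda", train, train.head(0))
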