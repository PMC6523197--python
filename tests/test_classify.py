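"""Classification layer: feature assembly, classifier oracles, LOSO
integrity, subset search and temporal generalization."""

import numpy as np
import pandas as pd
import pytest

import taskphysio as tp
from conftest import gaussian_feature_table
from oracles import knn1_predict, lda_two_class_predict


def feature_row(subject, trial, condition, value=0.0):
    row = {"subject_id": subject, "trial": trial, "condition": condition}
    row.update({f: value for f in tp.FEATURE_NAMES})
    return row


class TestAssembleFeatures:
    def test_full_cohort_row_count(self):
        rows = [feature_row(f"S{s}", 1, c, value=s)
                for s in range(16) for c in tp.CONDITIONS]
        df = tp.assemble_features(rows)
        assert len(df) == 64
        assert list(df.columns[3:]) == list(tp.FEATURE_NAMES)

    def test_bad_row_dropped_with_remainder_kept(self):
        rows = [feature_row(f"S{s}", 1, c) for s in range(2)
                for c in tp.CONDITIONS]
        rows[3]["TVSymp"] = float("nan")
        df = tp.assemble_features(rows)
        assert len(df) == 7

    def test_duplicate_key_rejected(self):
        rows = [feature_row("S1", 1, "BL"), feature_row("S1", 1, "BL")]
        with pytest.raises(tp.ConfigError):
            tp.assemble_features(rows)

    def test_empty_table_rejected(self):
        with pytest.raises(tp.ConfigError):
            tp.assemble_features([])


class TestFitPredict:
    def test_knn_identity_match(self):
        df = gaussian_feature_table(4, 1, seed=0)
        train = df
        test = df[df["subject_id"] == "S00"]
        preds = tp.fit_predict(tp.ClassifierSpec("KNN"), train, test,
                               tp.FEATURE_NAMES)
        assert np.array_equal(preds, test["condition"].to_numpy())

    def test_knn_matches_bruteforce_oracle(self, rng):
        """k=1 predictions equal the exhaustive-distance oracle on a
        50-sample instance (same train-fold standardization)."""
        df = gaussian_feature_table(13, 1, seed=3, sd=2.0)
        train = df[df["subject_id"] != "S00"].iloc[:46]
        test = df[df["subject_id"] == "S00"]
        preds = tp.fit_predict(tp.ClassifierSpec("KNN"), train, test,
                               tp.FEATURE_NAMES)
        Xtr = train[list(tp.FEATURE_NAMES)].to_numpy()
        Xte = test[list(tp.FEATURE_NAMES)].to_numpy()
        mu, sd = Xtr.mean(0), Xtr.std(0)
        oracle = knn1_predict((Xtr - mu) / sd, train["condition"].to_numpy(),
                              (Xte - mu) / sd)
        assert np.array_equal(preds, oracle)

    def test_lda_matches_closed_form_two_gaussians(self, rng):
        """LDA agrees with the plug-in pooled-covariance discriminant on
        200 well-separated two-class points."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = np.vstack([rng.normal([0, 0], 1.0, size=(100, 2)),
                       rng.normal([3, 2], 1.0, size=(100, 2))])
        y = np.array(["A"] * 100 + ["B"] * 100)
        Xq = rng.normal([1.5, 1.0], 2.0, size=(200, 2))
        lda = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        assert np.array_equal(lda.predict(Xq),
                              lda_two_class_predict(X, y, Xq))

    def test_mqda_matches_mahalanobis_oracle(self, rng):
        X = np.vstack([rng.normal([0, 0], [1.0, 2.0], size=(40, 2)),
                       rng.normal([4, 1], [0.5, 1.0], size=(40, 2))])
        y = np.array(["A"] * 40 + ["B"] * 40)
        Xq = rng.normal([2, 0.5], 2.0, size=(50, 2))
        clf = tp.MahalanobisQDA().fit(X, y)
        preds = clf.predict(Xq)
        oracle = []
        for x in Xq:
            dists = []
            for c in ("A", "B"):
                Xc = X[y == c]
                mu = Xc.mean(0)
                cov = np.cov(Xc, rowvar=False)
                cov += 1e-6 * np.trace(cov) / 2 * np.eye(2)
                dists.append((x - mu) @ np.linalg.inv(cov) @ (x - mu))
            oracle.append("A" if dists[0] < dists[1] else "B")
        assert np.array_equal(preds, np.asarray(oracle))

    def test_gsvm_hyperparameters_echoed(self):
        spec = tp.ClassifierSpec("GSVM")
        assert spec.metadata() == {"family": "GSVM", "C": 1.0, "gamma": 2.6}

    def test_empty_subset_rejected(self):
        df = gaussian_feature_table(3, 1, seed=1)
        with pytest.raises(tp.ConfigError):
            tp.fit_predict(tp.ClassifierSpec("KNN"), df, df, ())

    def test_unknown_family_rejected(self):
        with pytest.raises(tp.ConfigError):
            tp.ClassifierSpec("RF")


class TestLOSO:
    def test_fold_bookkeeping(self):
        df = gaussian_feature_table(16, 1, seed=2)
        cv = tp.loso_cv(df, tp.ClassifierSpec("KNN"))
        assert cv.confusion.sum() == 64
        assert np.array_equal(cv.confusion.sum(axis=1), np.full(4, 16))
        assert cv.accuracy == pytest.approx(
            np.trace(cv.confusion) / cv.confusion.sum())
        assert len(cv.predicted_labels) == 64

    def test_separable_classes_classified_perfectly(self):
        means = {c: np.full(8, 50.0 * i)
                 for i, c in enumerate(tp.CONDITIONS)}
        df = gaussian_feature_table(8, 1, seed=4, means=means, sd=0.5)
        for family in ("KNN", "LSVM", "LDA"):
            cv = tp.loso_cv(df, tp.ClassifierSpec(family))
            assert cv.accuracy == 1.0

    def test_two_subject_minimum(self):
        df = gaussian_feature_table(2, 1, seed=5)
        cv = tp.loso_cv(df, tp.ClassifierSpec("KNN"))
        assert set(cv.subjects) == {"S00", "S01"}

    def test_missing_class_in_training_fold_raises(self):
        df = gaussian_feature_table(2, 1, seed=6)
        df = df[~((df["subject_id"] == "S01") & (df["condition"] != "BL"))]
        with pytest.raises(tp.ConfigError):
            tp.loso_cv(df, tp.ClassifierSpec("KNN"))

    def test_predictions_do_not_depend_on_other_test_rows(self):
        """Non-leakage: a fold's prediction for one sample is unchanged when
        the other test-fold samples are removed."""
        df = gaussian_feature_table(6, 1, seed=7, sd=3.0)
        train = df[df["subject_id"] != "S00"]
        test = df[df["subject_id"] == "S00"]
        full = tp.fit_predict(tp.ClassifierSpec("LSVM"), train, test,
                              tp.FEATURE_NAMES)
        single = tp.fit_predict(tp.ClassifierSpec("LSVM"), train,
                                test.iloc[[2]], tp.FEATURE_NAMES)
        assert single[0] == full[2]

    def test_train_fold_statistics_only(self):
        """Shifting every test-fold value leaves the fitted model untouched:
        predictions move with the shift, not with retrained statistics."""
        means = {c: np.full(8, 10.0 * i) for i, c in enumerate(tp.CONDITIONS)}
        df = gaussian_feature_table(5, 1, seed=8, means=means, sd=0.1)
        train = df[df["subject_id"] != "S00"]
        test = df[df["subject_id"] == "S00"].copy()
        base = tp.fit_predict(tp.ClassifierSpec("KNN"), train, test,
                              tp.FEATURE_NAMES)
        shifted = test.copy()
        shifted[list(tp.FEATURE_NAMES)] += 0.01  # negligible vs class gaps
        again = tp.fit_predict(tp.ClassifierSpec("KNN"), train, shifted,
                               tp.FEATURE_NAMES)
        assert np.array_equal(base, again)


class TestSubsetSearch:
    def test_enumerates_255_subsets(self):
        df = gaussian_feature_table(4, 1, seed=9)
        results = tp.subset_search(df, tp.ClassifierSpec("KNN"))
        assert len(results) == 255
        assert len({r.feature_subset for r in results}) == 255

    def test_planted_informative_feature_recovered(self, rng):
        """One condition-coding feature among 7 pure-noise features must
        appear in the winning subset."""
        rows = []
        for s in range(12):
            for c in tp.CONDITIONS:
                row = {"subject_id": f"S{s:02d}", "trial": 1, "condition": c}
                noise = rng.normal(0, 1, size=8)
                row.update(dict(zip(tp.FEATURE_NAMES, noise)))
                row["TVSymp"] = 10.0 * tp.CONDITIONS.index(c) + rng.normal(0, 0.3)
                rows.append(row)
        df = tp.assemble_features(rows)
        best = tp.subset_search(df, tp.ClassifierSpec("KNN"))[0]
        assert "TVSymp" in best.feature_subset

    def test_tie_break_prefers_fewer_features(self, rng):
        rows = []
        for s in range(8):
            for c in tp.CONDITIONS:
                row = {"subject_id": f"S{s:02d}", "trial": 1, "condition": c}
                row.update({f: 5.0 * tp.CONDITIONS.index(c)
                            + rng.normal(0, 0.05) for f in tp.FEATURE_NAMES})
                rows.append(row)
        df = tp.assemble_features(rows)
        best = tp.subset_search(df, tp.ClassifierSpec("KNN"))[0]
        assert best.accuracy == 1.0
        assert len(best.feature_subset) == 1
        assert best.feature_subset == ("SCL",)  # canonical order tie-break


class TestTemporalGeneralization:
    def test_twelve_trials_give_eleven_accuracies(self):
        df = gaussian_feature_table(4, 12, seed=10)
        tg = tp.temporal_generalization(df, tp.ClassifierSpec("KNN"))
        assert list(tg["trial"]) == list(range(2, 13))

    def test_missing_trial_one_rejected(self):
        df = gaussian_feature_table(4, 3, seed=11)
        with pytest.raises(tp.ConfigError):
            tp.temporal_generalization(df[df["trial"] > 1],
                                       tp.ClassifierSpec("KNN"))

    def test_stationary_cohort_keeps_accuracy(self):
        """Without drift, later-trial accuracy stays at the trial-1 level."""
        means = {c: np.full(8, 8.0 * i) for i, c in enumerate(tp.CONDITIONS)}
        df = gaussian_feature_table(8, 6, seed=12, means=means, sd=1.0)
        tg = tp.temporal_generalization(df, tp.ClassifierSpec("KNN"))
        assert tg["accuracy"].min() > 0.9

    def test_separation_collapse_lowers_late_accuracy(self):
        """Shrinking condition separation in late trials drops accuracy."""
        means = {c: np.full(8, 8.0 * i) for i, c in enumerate(tp.CONDITIONS)}
        df = gaussian_feature_table(8, 6, seed=13, means=means, sd=1.0)
        grand = np.mean([m for m in means.values()], axis=0)
        late = df["trial"] >= 5
        shrunk = (df.loc[late, list(tp.FEATURE_NAMES)].to_numpy()
                  - grand) * 0.05 + grand
        df.loc[late, list(tp.FEATURE_NAMES)] = shrunk
        tg = tp.temporal_generalization(df, tp.ClassifierSpec("KNN"))
        early = tg[tg["trial"] < 5]["accuracy"].mean()
        latacc = tg[tg["trial"] >= 5]["accuracy"].mean()
        assert latacc < early
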