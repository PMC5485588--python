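import numpy as np
import pandas as pd
import pytest

from grape import (
    BatchSpec,
    GeneratorConfig,
    NearestTemplateClassifier,
    balance_classes,
    cross_validate,
    enumerate_dataset_splits,
    fit_class_templates,
    generate_cohort,
    generate_gmt,
    predict_labels,
)


class TestFitClassTemplates:
    def test_single_sample_templates_equal_their_profiles(self, small_expr):
        labels = pd.Series({"s1": "up", "s2": "down"})
        cts = fit_class_templates(small_expr[["s1", "s2"]], labels,
                                  list(small_expr.index), "grape")
        assert cts.templates["up"].probability.tolist() == [1.0] * 6
        assert cts.templates["down"].probability.tolist() == [0.0] * 6

    def test_centroid_is_the_mean(self):
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0]}, index=["a", "b"])
        cts = fit_class_templates(m, pd.Series({"s1": "c", "s2": "c"}),
                                  ["a", "b"], "centroid")
        assert cts.templates["c"].tolist() == [2.0, 3.0]

    def test_requested_class_without_samples_is_error(self, small_expr):
        labels = pd.Series({"s1": "x", "s2": "x", "s3": "x"})
        with pytest.raises(ValueError, match="no training samples"):
            fit_class_templates(small_expr, labels, list(small_expr.index),
                                "grape", classes=["x", "ghost"])


class TestPredict:
    def test_identical_sample_wins_rank_method(self, small_expr):
        labels = pd.Series({"s1": "up", "s2": "down"})
        cts = fit_class_templates(small_expr[["s1", "s2"]], labels,
                                  list(small_expr.index), "dirac")
        pred, ties = predict_labels(small_expr[["s1"]], cts)
        assert pred.tolist() == ["up"] and not ties[0]

    def test_equidistant_tie_goes_to_first_label_and_is_flagged(self):
        m = pd.DataFrame({"t1": [0.0, 1.0], "t2": [2.0, 3.0]}, index=["a", "b"])
        cts = fit_class_templates(m, pd.Series({"t1": "zed", "t2": "ant"}),
                                  ["a", "b"], "centroid")
        query = pd.DataFrame({"q": [1.0, 2.0]}, index=["a", "b"])  # midpoint
        pred, ties = predict_labels(query, cts)
        assert pred.tolist() == ["ant"] and bool(ties[0])

    def test_centroid_sample_equal_to_centroid(self):
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0], "s3": [9.0, 0.0]},
                         index=["a", "b"])
        cts = fit_class_templates(m, pd.Series({"s1": "c1", "s2": "c1", "s3": "c2"}),
                                  ["a", "b"], "centroid")
        query = pd.DataFrame({"q": [2.0, 3.0]}, index=["a", "b"])
        pred, _ = predict_labels(query, cts)
        assert pred.tolist() == ["c1"]


class TestEstimator:
    def test_fit_predict_roundtrip(self, two_class_cohort):
        expr, ann = two_class_cohort
        clf = NearestTemplateClassifier(genes=list(expr.index[:10]),
                                        method="grape", random_state=0)
        clf.fit(expr.T, ann["label"])
        assert list(clf.classes_) == ["alpha", "beta"]
        pred = clf.predict(expr.T)
        assert (pred == ann["label"].to_numpy()).mean() > 0.9
        assert clf.tie_flags_.shape == (expr.shape[1],)

    def test_single_class_rejected(self, two_class_cohort):
        expr, ann = two_class_cohort
        clf = NearestTemplateClassifier()
        with pytest.raises(ValueError, match="2 classes"):
            clf.fit(expr.T, ["same"] * expr.shape[1])


class TestCrossValidate:
    def test_perfectly_separable_classes_hit_accuracy_one(self):
        cfg = GeneratorConfig(seed=5, n_genes=20, n_per_class=20,
                              class_orders={"A": list(range(20)),
                                            "B": list(range(19, -1, -1))},
                              flip_noise=0.0)
        expr, ann = generate_cohort(cfg)
        sets = {"pw": list(expr.index)}
        for method in ("grape", "dirac", "centroid"):
            cv = cross_validate(expr, ann["label"], sets, method,
                                repeats=2, folds=5, seed=1)
            assert cv.accuracy["pw"] == 1.0

    def test_permuted_labels_give_chance_accuracy(self):
        cfg = GeneratorConfig(seed=6, n_genes=15, n_per_class=35,
                              class_orders=4, flip_noise=0.05)
        expr, ann = generate_cohort(cfg)
        sets = {"pw": list(expr.index[:10])}
        rng = np.random.default_rng(0)
        accs = []
        for seed in range(10):
            permuted = pd.Series(rng.permutation(ann["label"].to_numpy()),
                                 index=ann.index)
            cv = cross_validate(expr, permuted, sets, "grape",
                                repeats=2, folds=5, seed=seed)
            accs.append(cv.accuracy["pw"])
        assert abs(np.mean(accs) - 0.25) < 0.1

    def test_stratification_arithmetic(self):
        cfg = GeneratorConfig(seed=7, n_genes=10, n_per_class=35, class_orders=4,
                              flip_noise=0.1)
        expr, ann = generate_cohort(cfg)
        cv = cross_validate(expr, ann["label"], {"pw": list(expr.index)},
                            "dirac", repeats=1, folds=5, seed=2)
        one_fold = cv.assignments.query("repeat == 0 and fold == 0")
        counts = one_fold.groupby("true")["sample"].count()
        assert (counts == 7).all()  # 35 per class / 5 folds

    def test_class_smaller_than_folds_is_error(self, two_class_cohort):
        expr, ann = two_class_cohort
        labels = ann["label"].copy()
        labels.iloc[:38] = "alpha"  # leaves 2 "beta"
        with pytest.raises(ValueError, match="smaller than fold count"):
            cross_validate(expr, labels, {"pw": list(expr.index)}, folds=5)

    def test_identical_seed_reproduces_bit_exact(self, two_class_cohort, pathway_sets):
        expr, ann = two_class_cohort
        kw = dict(method="grape", repeats=2, folds=4, seed=9,
                  deterministic_ties=True)
        cv1 = cross_validate(expr, ann["label"], pathway_sets, **kw)
        cv2 = cross_validate(expr, ann["label"], pathway_sets, **kw)
        pd.testing.assert_series_equal(cv1.accuracy, cv2.accuracy)
        pd.testing.assert_frame_equal(cv1.assignments, cv2.assignments)

    def test_rank_cv_invariant_under_monotone_transform_centroid_not(self):
        cfg = GeneratorConfig(seed=8, n_genes=15, n_per_class=15, class_orders=2,
                              flip_noise=0.2)
        expr, ann = generate_cohort(cfg)
        sets = {"pw": list(expr.index)}
        transformed = expr.apply(np.exp)
        for method in ("grape", "dirac"):
            a = cross_validate(expr, ann["label"], sets, method,
                               repeats=2, folds=3, seed=4)
            b = cross_validate(transformed, ann["label"], sets, method,
                               repeats=2, folds=3, seed=4)
            assert a.accuracy["pw"] == b.accuracy["pw"]
            assert (a.assignments["pred"] == b.assignments["pred"]).all()
        # the centroid baseline is sensitive to the same transform
        a = cross_validate(expr, ann["label"], sets, "centroid",
                           repeats=2, folds=3, seed=4)
        b = cross_validate(transformed, ann["label"], sets, "centroid",
                           repeats=2, folds=3, seed=4)
        assert not (a.assignments["pred"] == b.assignments["pred"]).all()

    def test_rank_methods_beat_centroid_across_distorted_batches(self):
        """Train on one batch, test on a monotone-distorted, gene-shifted one."""
        diffs = []
        for seed in range(10):
            cfg = GeneratorConfig(
                seed=300 + seed, n_genes=40, n_per_class=40, class_orders=2,
                flip_noise=0.15,
                batch_specs=(BatchSpec("b0"),
                             BatchSpec("b1", shift_sd=1.0, distortion="exp")))
            expr, ann = generate_cohort(cfg)
            train = ann.index[ann["batch"] == "b0"]
            test = ann.index[ann["batch"] == "b1"]
            genes = list(generate_gmt(1, (15, 15), list(expr.index),
                                      np.random.default_rng(seed)).values())[0]
            accs = {}
            for method in ("grape", "centroid"):
                cts = fit_class_templates(expr[train], ann.loc[train, "label"],
                                          genes, method,
                                          rng=np.random.default_rng(1))
                pred, _ = predict_labels(expr[test], cts, np.random.default_rng(2))
                accs[method] = float(np.mean(pred == ann.loc[test, "label"].to_numpy()))
            assert accs["grape"] >= accs["centroid"]
            diffs.append(accs["grape"] - accs["centroid"])
        assert np.mean(diffs) > 0


class TestSplitsAndBalancing:
    @pytest.mark.parametrize("n_tissues,expected", [(1, 2), (2, 4), (3, 8)])
    def test_split_counts(self, n_tissues, expected):
        tissue_of = {}
        for t in range(n_tissues):
            tissue_of[f"ds{t}a"] = f"tissue{t}"
            tissue_of[f"ds{t}b"] = f"tissue{t}"
        splits = enumerate_dataset_splits(tissue_of)
        assert len(splits) == expected
        for train, test in splits:
            assert set(train) | set(test) == set(tissue_of)
            assert not set(train) & set(test)

    def test_unpaired_tissue_is_error(self):
        with pytest.raises(ValueError, match="exactly 2"):
            enumerate_dataset_splits({"a": "lung", "b": "lung", "c": "colon"})

    def test_balance_subsamples_each_class(self, two_class_cohort):
        expr, ann = two_class_cohort
        sub, labels = balance_classes(expr, ann["label"], 7,
                                      np.random.default_rng(0))
        assert labels.value_counts().tolist() == [7, 7]
        assert sub.shape[1] == 14

    def test_balance_keeps_smallest_class_intact(self, two_class_cohort):
        expr, ann = two_class_cohort
        sub, labels = balance_classes(expr, ann["label"], 20,
                                      np.random.default_rng(0))
        assert sorted(labels.index) == sorted(ann.index)

    def test_balance_insufficient_is_error(self, two_class_cohort):
        expr, ann = two_class_cohort
        with pytest.raises(ValueError, match="cannot draw"):
            balance_classes(expr, ann["label"], 21, np.random.default_rng(0))
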