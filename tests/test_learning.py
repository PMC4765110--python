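import inspect

import numpy as np
import pandas as pd
import pytest

from orthoscreen.cluster_io import Provenance
from orthoscreen.features import FEATURE_NAMES
from orthoscreen.learning import (
    DatasetSpec,
    SplitSpec,
    TrainedModel,
    assemble_dataset,
    evaluate,
    feature_ablation,
    filter_clusters,
    learning_curve,
    split,
    train,
)

NH_TYPES = (
    Provenance.NH_RANDOM,
    Provenance.NH_EVOLVED_0,
    Provenance.NH_EVOLVED_25,
    Provenance.NH_EVOLVED_50,
)


def blob_table(n: int, seed: int = 0, separation: float = 3.0) -> pd.DataFrame:
    """Synthetic two-class feature table with Gaussian class blobs."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack(
        [
            rng.normal(0.0, 1.0, size=(half, len(FEATURE_NAMES))),
            rng.normal(separation, 1.0, size=(n - half, len(FEATURE_NAMES))),
        ]
    )
    table = pd.DataFrame(X, columns=FEATURE_NAMES)
    table.insert(0, "cluster_id", [f"c{i}" for i in range(n)])
    table["label"] = ["H"] * half + ["NH"] * (n - half)
    return table


class _ConstantEstimator:
    """Predicts a fixed class; used to probe evaluation contracts."""

    def __init__(self, label: str):
        self.label = label

    def predict(self, X):
        return np.array([self.label] * len(X))


class TestDatasetSpec:
    def test_equal_composition_has_five_equal_classes(self):
        counts = DatasetSpec(scheme="EQUAL", n_total=500).class_counts()
        assert sorted(counts.values()) == [100] * 5

    def test_prop_composition_is_half_h_and_equal_nh_quarters(self):
        counts = DatasetSpec(scheme="PROP", n_total=400).class_counts()
        assert counts[Provenance.H_SYNTH] == 200
        assert all(counts[t] == 50 for t in NH_TYPES)

    def test_indivisible_totals_are_rejected(self):
        with pytest.raises(ValueError):
            DatasetSpec(scheme="EQUAL", n_total=501).class_counts()


class TestAssembleDataset:
    def test_equal_histogram_from_generated_pools(self, tiny_pools):
        spec = DatasetSpec(scheme="EQUAL", n_total=25, seed=1)
        table = assemble_dataset(
            tiny_pools[Provenance.H_SYNTH],
            {t: tiny_pools[t] for t in NH_TYPES},
            spec,
        )
        histogram = table["provenance"].value_counts()
        assert sorted(histogram) == [5] * 5
        assert set(table["label"]) == {"H", "NH"}
        assert (table.loc[table["provenance"] == "H_SYNTH", "label"] == "H").all()

    def test_prop_histogram_from_generated_pools(self, tiny_pools):
        spec = DatasetSpec(scheme="PROP", n_total=24, seed=2)
        table = assemble_dataset(
            tiny_pools[Provenance.H_SYNTH],
            {t: tiny_pools[t] for t in NH_TYPES},
            spec,
        )
        histogram = table["provenance"].value_counts()
        assert histogram["H_SYNTH"] == 12
        assert all(histogram[t.value] == 3 for t in NH_TYPES)

    def test_zero_total_gives_an_empty_table(self, tiny_pools):
        spec = DatasetSpec(scheme="EQUAL", n_total=0)
        table = assemble_dataset(
            tiny_pools[Provenance.H_SYNTH],
            {t: tiny_pools[t] for t in NH_TYPES},
            spec,
        )
        assert table.empty

    def test_shortfall_error_names_the_missing_class(self, tiny_pools):
        spec = DatasetSpec(scheme="EQUAL", n_total=500)
        with pytest.raises(ValueError, match="NH_RANDOM"):
            assemble_dataset(
                tiny_pools[Provenance.H_SYNTH],
                {t: tiny_pools[t] for t in NH_TYPES},
                spec,
            )


class TestSplit:
    def test_eleven_thousand_rows_split_8800_1100_1100(self):
        table = pd.DataFrame({"label": ["H", "NH"] * 5500, "x": 0.0})
        tr, va, te = split(table, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (8800, 1100, 1100)

    def test_ten_rows_split_8_1_1(self):
        table = pd.DataFrame({"label": ["H"] * 10, "x": range(10)})
        tr, va, te = split(table, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    def test_split_is_a_partition_of_the_input(self):
        table = blob_table(53, seed=3)
        tr, va, te = split(table, SplitSpec(seed=4))
        ids = pd.concat([tr, va, te])["cluster_id"]
        assert sorted(ids) == sorted(table["cluster_id"])
        assert ids.nunique() == len(table)

    def test_bad_fractions_are_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_frac=0.7, valid_frac=0.1, test_frac=0.1)


class TestTrain:
    def test_random_forest_fits_a_separable_table_perfectly(self):
        table = blob_table(60, seed=5, separation=8.0)
        model = train("random_forest", table, seed=0)
        assert evaluate(model, table).accuracy == 1.0

    def test_same_seed_gives_identical_predictions(self):
        table = blob_table(80, seed=6, separation=1.0)
        m1 = train("mlp", table, seed=9)
        m2 = train("mlp", table, seed=9)
        assert np.array_equal(m1.predict(table), m2.predict(table))

    def test_single_class_table_is_rejected(self):
        table = blob_table(20, seed=7)
        table["label"] = "NH"
        with pytest.raises(ValueError):
            train("logistic", table)

    def test_unknown_kind_is_rejected(self):
        with pytest.raises(ValueError):
            train("boosted_stumps", blob_table(20, seed=8))

    def test_stacking_tracks_its_base_learners_on_easy_data(self):
        # the meta-classifier should not fall far behind a strong base
        diffs = []
        for seed in (0, 1):
            data = blob_table(150, seed=seed, separation=2.0)
            tr, va, _ = split(data, SplitSpec(seed=seed))
            base_acc = evaluate(train("logistic", tr, seed=seed), va).accuracy
            stack_acc = evaluate(
                train("stack_with_lr", tr, seed=seed), va
            ).accuracy
            diffs.append(stack_acc - base_acc)
        assert np.mean(diffs) >= -0.02

    def test_schema_mismatch_is_reported_with_missing_columns(self):
        table = blob_table(40, seed=10)
        model = train("random_forest", table, seed=0)
        with pytest.raises(ValueError, match="aliscore"):
            model.predict(table.drop(columns=["aliscore"]))


class TestEvaluate:
    def test_perfect_predictor_has_unit_accuracy_and_clean_confusion(self):
        table = blob_table(40, seed=11, separation=9.0)
        model = train("random_forest", table, seed=1)
        report = evaluate(model, table)
        assert report.accuracy == 1.0
        off_diag = report.confusion.to_numpy()[~np.eye(2, dtype=bool)]
        assert (off_diag == 0).all()

    def test_constant_predictor_on_balanced_table_scores_half(self):
        table = blob_table(40, seed=12)
        model = TrainedModel(kind="constant", estimator=_ConstantEstimator("H"))
        assert evaluate(model, table).accuracy == 0.5

    def test_confusion_counts_sum_to_the_instance_count(self):
        table = blob_table(47, seed=13, separation=1.0)
        model = train("naive_bayes", table, seed=0)
        assert evaluate(model, table).n_instances == 47


class TestLearningCurve:
    def test_degenerate_curve_equals_plain_train_and_evaluate(self):
        data = blob_table(60, seed=14, separation=2.0)
        tr, va, _ = split(data, SplitSpec(seed=1))
        curve = learning_curve(
            "random_forest", tr, va, fractions=(1.0,), n_bootstrap=1, seed=21
        )
        direct = evaluate(train("random_forest", tr, seed=21), va).accuracy
        assert curve.loc[0, "mean_accuracy"] == pytest.approx(direct)

    def test_default_replicate_count_is_one_hundred(self):
        sig = inspect.signature(learning_curve)
        assert sig.parameters["n_bootstrap"].default == 100

    def test_more_data_does_not_hurt_beyond_the_envelope(self):
        data = blob_table(220, seed=15, separation=1.5)
        tr, va, _ = split(data, SplitSpec(seed=2))
        curve = learning_curve(
            "random_forest",
            tr,
            va,
            fractions=(0.05, 1.0),
            n_bootstrap=10,
            seed=3,
        )
        small, big = curve.iloc[0], curve.iloc[1]
        assert big["mean_accuracy"] >= small["mean_accuracy"] - (
            small["sd_accuracy"] + big["sd_accuracy"] + 1e-9
        )

    def test_fractions_outside_unit_interval_are_rejected(self):
        data = blob_table(30, seed=16)
        with pytest.raises(ValueError):
            learning_curve("random_forest", data, data, fractions=(0.0, 1.0))


class TestFeatureAblation:
    def test_one_row_per_feature(self):
        data = blob_table(60, seed=17, separation=3.0)
        tr, va, _ = split(data, SplitSpec(seed=4))
        result = feature_ablation("random_forest", tr, va, seed=5)
        assert len(result) == len(FEATURE_NAMES)
        assert set(result["feature"]) == set(FEATURE_NAMES)

    def test_constant_feature_scores_near_the_majority_rate(self):
        data = blob_table(80, seed=18, separation=5.0)
        data["aliscore"] = 1.0  # kill the signal in one feature
        tr, va, _ = split(data, SplitSpec(seed=5))
        result = feature_ablation("random_forest", tr, va, seed=6).set_index(
            "feature"
        )
        majority = va["label"].value_counts(normalize=True).max()
        assert abs(result.loc["aliscore", "accuracy"] - majority) < 0.2

    def test_single_features_do_not_beat_the_full_model_by_much(self):
        data = blob_table(100, seed=19, separation=2.0)
        tr, va, _ = split(data, SplitSpec(seed=6))
        full = evaluate(train("random_forest", tr, seed=7), va).accuracy
        ablation = feature_ablation("random_forest", tr, va, seed=7)
        assert ablation["accuracy"].max() <= full + 0.1


class TestFilterClusters:
    def test_always_homology_model_removes_nothing(self, tiny_pools):
        clusters = tiny_pools[Provenance.NH_RANDOM][:4]
        model = TrainedModel(kind="constant", estimator=_ConstantEstimator("H"))
        result = filter_clusters(model, clusters)
        assert result.removed == []
        assert len(result.kept) == 4

    def test_kept_plus_removed_covers_the_input(self, tiny_pools, tiny_feature_table):
        model = train("random_forest", tiny_feature_table, seed=2)
        clusters = (
            tiny_pools[Provenance.H_SYNTH][:5]
            + tiny_pools[Provenance.NH_EVOLVED_0][:5]
        )
        result = filter_clusters(model, clusters)
        assert len(result.kept) + len(result.removed) == len(clusters)
        assert len(result.manifest) == len(clusters)

    def test_trained_stack_removes_most_random_decoys(
        self, tiny_pools, tiny_feature_table
    ):
        model = train("stack_with_lr", tiny_feature_table, seed=3)
        h = tiny_pools[Provenance.H_SYNTH][:10]
        nh = tiny_pools[Provenance.NH_RANDOM][:10]
        result = filter_clusters(model, h + nh)
        removed_ids = {c.cluster_id for c in result.removed}
        nh_removed = sum(c.cluster_id in removed_ids for c in nh)
        assert nh_removed >= 9
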