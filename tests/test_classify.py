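"""Splitting, mesh features, metrics, training, importance and aggregation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from sersstroma import (
    DataError,
    SpectralCube,
    WavenumberAxis,
    cohen_kappa,
    confusion_matrix,
    evaluate,
    mesh_features,
    patient_aggregate,
    patient_prediction,
    permutation_importance,
    stratified_split,
    train_models,
)
from sersstroma.annotate import RoiMesh


class TestStratifiedSplit:
    def test_study_cohort_class_balance_over_seeds(self):
        """14 DCIS + 32 IBC into 4 sets: 3-4 DCIS and 8 IBC per set."""
        patients = {f"D{i}": "DCIS" for i in range(14)}
        patients.update({f"I{i}": "IBC" for i in range(32)})
        for seed in range(20):
            plan = stratified_split(patients, 4, seed=seed)
            for s in range(4):
                members = plan.patients_in(s)
                n_dcis = sum(patients[p] == "DCIS" for p in members)
                n_ibc = len(members) - n_dcis
                assert n_dcis in (3, 4)
                assert n_ibc == 8

    def test_four_patients_four_singleton_sets(self):
        patients = {"A": "DCIS", "B": "DCIS", "C": "IBC", "D": "IBC"}
        plan = stratified_split(patients, 4, seed=1)
        assert sorted(len(plan.patients_in(s)) for s in range(4)) == [1, 1, 1, 1]

    def test_deterministic_per_seed(self):
        patients = {f"P{i}": ("DCIS" if i % 3 else "IBC") for i in range(12)}
        a = stratified_split(patients, 4, seed=5)
        b = stratified_split(patients, 4, seed=5)
        assert a.assignments == b.assignments

    def test_patient_disjoint_and_complete(self):
        patients = {f"P{i}": ("DCIS" if i < 5 else "IBC") for i in range(17)}
        plan = stratified_split(patients, 4, seed=2)
        all_members = [p for s in range(4) for p in plan.patients_in(s)]
        assert sorted(all_members) == sorted(patients)


class TestMeshFeatures:
    def test_uniform_cube_features_equal_window_channel_count(self):
        axis = WavenumberAxis(300, 1200, 2)
        cube = SpectralCube(np.ones((4, 4, len(axis))), axis.values,
                            metadata={"patient_id": "P"})
        mesh = RoiMesh(x=[0, 1], y=[2, 3], patient_id="P", diagnosis="IBC")
        table = mesh_features(cube, mesh, wavenumbers=[480, 722], halfwidth=10.0)
        # closed +/-10 window on a 2 cm^-1 grid holds 11 channels
        assert np.allclose(table[["wn_480", "wn_722"]].to_numpy(), 11.0)

    def test_wavenumber_outside_axis_rejected(self):
        axis = WavenumberAxis(300, 1200, 2)
        cube = SpectralCube(np.ones((4, 4, len(axis))), axis.values)
        mesh = RoiMesh(x=[0], y=[0], patient_id="P", diagnosis="IBC")
        with pytest.raises(DataError):
            mesh_features(cube, mesh, wavenumbers=[1504], halfwidth=10.0)

    def test_stroma_features_ordered_by_diagnosis_at_480(self, processed_cohort):
        """Mean 480 cm^-1 stroma feature: IBC cohort > DCIS cohort."""
        from sersstroma.pipeline import stroma_feature_table

        feats = stroma_feature_table(processed_cohort, wavenumbers=[480])
        by = feats.groupby("diagnosis")["wn_480"].mean()
        assert by["IBC"] > by["DCIS"]


class TestCohenKappa:
    def test_perfect_diagonal_is_one(self):
        assert cohen_kappa([[5, 0], [0, 7]]) == pytest.approx(1.0)

    def test_reported_confusion_counts_give_096(self):
        """7 errors of 2819 invasive meshes, 13 of 298 DCIS meshes -> 0.96."""
        kappa = cohen_kappa([[2812, 7], [13, 285]])
        assert round(kappa, 2) == 0.96

    def test_random_assignment_expectation_near_zero(self):
        rng = np.random.default_rng(3)
        kappas = []
        for _ in range(200):
            y_true = rng.choice(["a", "b"], 300, p=[0.3, 0.7])
            y_pred = rng.choice(["a", "b"], 300, p=[0.5, 0.5])
            kappas.append(cohen_kappa(confusion_matrix(y_true, y_pred, ("a", "b"))))
        assert abs(np.mean(kappas)) < 0.02

    def test_matches_bruteforce_on_random_matrices(self):
        """kappa equals an independent expected-agreement computation, 1000 cases."""
        rng = np.random.default_rng(4)
        for _ in range(1000):
            k = rng.integers(2, 5)
            m = rng.integers(0, 50, (k, k))
            if m.sum() == 0 or m.sum(0).max() == m.sum() or m.sum(1).max() == m.sum():
                continue
            total = m.sum()
            p_o = sum(m[i, i] for i in range(k)) / total
            p_e = sum(m[i, :].sum() * m[:, i].sum() for i in range(k)) / total**2
            if p_e >= 1:
                continue
            expected = (p_o - p_e) / (1 - p_e)
            assert cohen_kappa(m) == pytest.approx(expected, rel=1e-12)

    def test_matches_sklearn_on_labelled_data(self):
        rng = np.random.default_rng(5)
        y_true = rng.choice(["DCIS", "IBC"], 500)
        y_pred = rng.choice(["DCIS", "IBC"], 500)
        conf = confusion_matrix(y_true, y_pred)
        assert cohen_kappa(conf) == pytest.approx(
            cohen_kappa_score(y_true, y_pred), rel=1e-12)

    def test_degenerate_marginals_convention(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert cohen_kappa([[4, 0], [0, 0]]) == 0.0


def _separable_table(rng, n_patients=12, meshes=25, sep=6.0):
    rows = []
    for i in range(n_patients):
        diag = "DCIS" if i < n_patients // 2 else "IBC"
        shift = 0.0 if diag == "DCIS" else sep
        x = rng.normal(shift, 1.0, (meshes, 3))
        for m in range(meshes):
            rows.append({"patient_id": f"P{i}", "diagnosis": diag,
                         "wn_480": x[m, 0], "wn_974": x[m, 1], "wn_382": x[m, 2]})
    return pd.DataFrame(rows)


class TestTrainEvaluate:
    def test_separable_features_reach_kappa_one(self):
        rng = np.random.default_rng(6)
        table = _separable_table(rng)
        report = train_models(table, algorithms=["nb", "knn"], seed=0)
        for fam in ("nb", "knn"):
            assert report.models[fam].cv_kappa == pytest.approx(1.0)

    def test_label_permutation_null_kappa_near_zero(self):
        """Patient-permuted labels: CV kappa within +/-0.1 of 0."""
        rng = np.random.default_rng(7)
        table = _separable_table(rng, n_patients=16, meshes=30)
        kappas = []
        for rep in range(10):
            perm = table.copy()
            perm["diagnosis"] = rng.permutation(perm["diagnosis"].to_numpy())
            report = train_models(perm, algorithms=["nb"], seed=rep)
            kappas.append(report.models["nb"].cv_kappa)
        assert abs(np.mean(kappas)) < 0.1

    def test_evaluation_refuses_training_patients(self):
        rng = np.random.default_rng(8)
        table = _separable_table(rng)
        report = train_models(table, algorithms=["nb"], seed=0)
        with pytest.raises(DataError, match="overlap"):
            evaluate(report.models["nb"], table)

    def test_all_correct_predictions_score_one(self):
        rng = np.random.default_rng(9)
        train = _separable_table(rng, n_patients=8)
        held = _separable_table(rng, n_patients=6, sep=6.0)
        held["patient_id"] = "H" + held["patient_id"]
        report = train_models(train, algorithms=["nb"], seed=0)
        er = evaluate(report.models["nb"], held)
        assert er.accuracy == pytest.approx(1.0)
        assert er.kappa == pytest.approx(1.0)

    def test_reported_confusion_accuracy_at_two_decimals(self):
        conf = np.array([[2812, 7], [13, 285]])
        accuracy = np.trace(conf) / conf.sum()
        assert round(accuracy, 2) == 0.99

    def test_weighted_f1_equals_plain_f1_when_balanced(self):
        from sklearn.metrics import f1_score

        rng = np.random.default_rng(10)
        y_true = np.array(["IBC", "DCIS"] * 50)
        y_pred = rng.choice(["IBC", "DCIS"], 100)
        weighted = f1_score(y_true, y_pred, average="weighted")
        macro = f1_score(y_true, y_pred, average="macro")
        assert weighted == pytest.approx(macro)

    def test_empty_grid_rejected(self):
        rng = np.random.default_rng(11)
        table = _separable_table(rng)
        with pytest.raises(DataError, match="grid"):
            train_models(table, algorithms=["nb"], grids={"nb": []}, seed=0)


class TestPermutationImportance:
    def test_single_informative_feature_dominates(self):
        rng = np.random.default_rng(12)
        table = _separable_table(rng, n_patients=10, meshes=30)
        # make wn_974 and wn_382 pure noise
        table["wn_974"] = rng.normal(0, 1, len(table))
        table["wn_382"] = rng.normal(0, 1, len(table))
        report = train_models(table, algorithms=["rf"], seed=0)
        imp = permutation_importance(report.models["rf"], table, n_repeats=5, seed=0)
        assert imp.iloc[0]["feature"] == "wn_480"
        assert imp.iloc[0]["importance"] > 0.5

    def test_importances_sum_to_one(self):
        rng = np.random.default_rng(13)
        table = _separable_table(rng)
        report = train_models(table, algorithms=["rf"], seed=0)
        imp = permutation_importance(report.models["rf"], table, n_repeats=3, seed=1)
        assert imp["importance"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_feature_gets_zero(self):
        rng = np.random.default_rng(14)
        table = _separable_table(rng)
        table["wn_382"] = 1.0
        report = train_models(table, algorithms=["rf"], seed=0)
        imp = permutation_importance(report.models["rf"], table, n_repeats=3, seed=1)
        assert imp.set_index("feature").loc["wn_382", "importance"] == 0.0


class TestPatientAggregate:
    # printed mesh counts and the arithmetic they imply
    PRINTED = [
        ("IBC-1", "IBC", 157, 4, 0.975, "IBC"),
        ("IBC-2", "IBC", 1398, 3, 0.998, "IBC"),
        ("IBC-3", "IBC", 579, 0, 1.000, "IBC"),
        ("IBC-4", "IBC", 185, 5, 0.974, "IBC"),
        ("IBC-5", "IBC", 228, 0, 1.000, "IBC"),
        ("IBC-6", "IBC", 54, 0, 1.000, "IBC"),
        ("IBC-7", "IBC", 2111, 1, 1.000, "IBC"),  # counts imply 0.9995 -> 1.000
        ("DCIS-1", "DCIS", 6, 138, 0.042, "DCIS"),
        ("DCIS-2", "DCIS", 1, 49, 0.020, "DCIS"),
        ("DCIS-3", "DCIS", 0, 98, 0.000, "DCIS"),
    ]

    @pytest.mark.parametrize("case,diag,n_ibc,n_dcis,ratio,category", PRINTED)
    def test_published_counts_reproduce_ratios_and_categories(
            self, case, diag, n_ibc, n_dcis, ratio, category):
        pred = patient_prediction(n_ibc, n_dcis)
        assert pred["ratio_ibc"] == pytest.approx(ratio, abs=5e-4)
        assert pred["predicted_category"] == category

    def test_zero_meshes_rejected(self):
        with pytest.raises(DataError):
            patient_prediction(0, 0)

    def test_aggregate_counts_from_mesh_frame(self):
        preds = pd.DataFrame({
            "patient_id": ["A"] * 5 + ["B"] * 4,
            "predicted": ["IBC"] * 4 + ["DCIS"] + ["DCIS"] * 4,
            "true": ["IBC"] * 5 + ["DCIS"] * 4,
        })
        agg = patient_aggregate(preds).set_index("patient_id")
        assert agg.loc["A", "n_pred_ibc"] == 4
        assert agg.loc["A", "predicted_category"] == "IBC"
        assert agg.loc["A", "mesh_accuracy"] == pytest.approx(0.8)
        assert agg.loc["B", "predicted_category"] == "DCIS"
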