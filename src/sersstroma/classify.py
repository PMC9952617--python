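"""Mesh-level supervised classification and patient aggregation.

Features are band intensities (+/-10 cm^-1 accumulation) at the selected
marker wavenumbers, one row per stromal mesh cell. Patients are randomly
stratified into class-balanced, patient-disjoint sets; models from six
algorithm families are tuned by patient-disjoint 3-fold cross-validated
grid search maximizing Cohen's kappa; the winning model is evaluated on the
held-out patient set and mesh predictions are aggregated per patient by the
fraction of meshes called invasive (category = IBC iff ratio > 0.5).

Patient-level leakage is impossible by construction: folds and splits are
assigned at the patient level, and evaluation refuses tables containing
training patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.metrics import f1_score, precision_score, recall_score

from .annotate import RoiMesh
from .core import DataError, SpectralCube
from .preprocess import band_image
from .synthgen import DEFAULT_FEATURE_WAVENUMBERS

__all__ = [
    "CLASSES",
    "ALGORITHM_FAMILIES",
    "DEFAULT_GRIDS",
    "SplitPlan",
    "FittedModel",
    "TrainReport",
    "EvalReport",
    "stratified_split",
    "mesh_features",
    "feature_columns",
    "train_models",
    "cohen_kappa",
    "confusion_matrix",
    "evaluate",
    "permutation_importance",
    "patient_aggregate",
    "patient_prediction",
]

#: Class order used in confusion matrices: rows/columns are (IBC, DCIS),
#: mirroring the reporting convention of the reference tables.
CLASSES = ("IBC", "DCIS")

ALGORITHM_FAMILIES = ("l1", "svm", "rf", "xgb", "knn", "nb")

#: Small published-default hyperparameter grids per family. The grids are a
#: shipped configuration, not a tuned quantity; any reasonable grid point
#: should land in the same performance regime on separable data.
DEFAULT_GRIDS: Mapping[str, list[dict]] = {
    "l1": [{"C": 0.1}, {"C": 1.0}, {"C": 10.0}],
    "svm": [{"C": 1.0}, {"C": 10.0}],
    "rf": [{"max_depth": None}, {"max_depth": 10}],
    "xgb": [{"max_depth": 3}, {"max_depth": 6}],
    "knn": [{"n_neighbors": 5}, {"n_neighbors": 15}],
    "nb": [{}],
}


def _make_estimator(family: str, params: dict, seed: int):
    if family == "l1":
        est = LogisticRegression(
            penalty="l1", solver="liblinear", max_iter=2000,
            random_state=seed, **params,
        )
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if family == "svm":
        est = SVC(kernel="rbf", gamma="scale", random_state=seed, **params)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if family == "rf":
        return RandomForestClassifier(
            n_estimators=100, random_state=seed, n_jobs=1, **params
        )
    if family == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=100, learning_rate=0.3, eval_metric="logloss",
            tree_method="hist", random_state=seed, n_jobs=1, verbosity=0,
            **params,
        )
    if family == "knn":
        est = KNeighborsClassifier(**params)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if family == "nb":
        return GaussianNB(**params)
    raise DataError(f"unknown algorithm family {family!r}")


# ---------------------------------------------------------------------------
# splitting


@dataclass
class SplitPlan:
    """Patient-disjoint assignment of each patient to one of n_sets sets."""

    assignments: dict[str, int]
    n_sets: int
    evaluation_set: int

    def patients_in(self, set_index: int) -> list[str]:
        return sorted(p for p, s in self.assignments.items() if s == set_index)

    @property
    def evaluation_patients(self) -> list[str]:
        return self.patients_in(self.evaluation_set)

    @property
    def training_patients(self) -> list[str]:
        return sorted(
            p for p, s in self.assignments.items() if s != self.evaluation_set
        )


def stratified_split(
    patients: Mapping[str, str] | pd.DataFrame,
    n_sets: int = 4,
    seed: int = 0,
) -> SplitPlan:
    """Random class-balanced split of patients into n_sets disjoint sets.

    ``patients`` maps patient id to diagnosis (or is a DataFrame with
    ``patient_id`` and ``diagnosis`` columns). Within each class, patients
    are shuffled and dealt round-robin, so per-set class counts differ by at
    most one. The last set is designated the evaluation set.
    """
    if isinstance(patients, pd.DataFrame):
        mapping = dict(zip(patients["patient_id"], patients["diagnosis"]))
    else:
        mapping = dict(patients)
    if n_sets < 1 or n_sets > len(mapping):
        raise DataError(
            f"cannot split {len(mapping)} patients into {n_sets} sets"
        )
    classes = sorted(set(mapping.values()))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    assignments: dict[str, int] = {}
    offset = 0
    for cls in classes:
        members = sorted(p for p, d in mapping.items() if d == cls)
        rng.shuffle(members)
        for i, p in enumerate(members):
            assignments[p] = (i + offset) % n_sets
        # stagger the round-robin start so small classes don't all pile
        # their remainders into set 0
        offset += len(members) % n_sets
    return SplitPlan(assignments=assignments, n_sets=n_sets, evaluation_set=n_sets - 1)


# ---------------------------------------------------------------------------
# features


def feature_columns(wavenumbers: Sequence[float] = DEFAULT_FEATURE_WAVENUMBERS) -> list[str]:
    return [f"wn_{wn:g}" for wn in wavenumbers]


def mesh_features(
    cube: SpectralCube,
    mesh: RoiMesh,
    wavenumbers: Sequence[float] = DEFAULT_FEATURE_WAVENUMBERS,
    halfwidth: float = 10.0,
) -> pd.DataFrame:
    """Band-intensity feature vector for every mesh cell of one patient.

    Each feature is the band_image value (sum over channels within
    +/- halfwidth) at one selected wavenumber, sampled at the cell's pixel.
    """
    if len(mesh) == 0:
        raise DataError("mesh has no cells")
    cols: dict[str, np.ndarray] = {}
    for wn in wavenumbers:
        img = band_image(cube, float(wn), halfwidth)
        cols[f"wn_{wn:g}"] = img.values[mesh.y, mesh.x]
    out = pd.DataFrame(cols)
    out.insert(0, "patient_id", mesh.patient_id)
    out.insert(1, "diagnosis", mesh.diagnosis)
    out.insert(2, "x", mesh.x)
    out.insert(3, "y", mesh.y)
    return out


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    feats = [c for c in table.columns if c.startswith("wn_")]
    if not feats:
        raise DataError("feature table has no wn_* columns")
    x = table[feats].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("feature table contains missing or non-finite values")
    y = (table["diagnosis"].to_numpy() == "IBC").astype(int)
    groups = table["patient_id"].to_numpy()
    return x, y, groups


# ---------------------------------------------------------------------------
# metrics


def confusion_matrix(y_true, y_pred, order: Sequence[str] = CLASSES) -> np.ndarray:
    """Counts[i, j] = true order[i] predicted as order[j]."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    k = len(order)
    out = np.zeros((k, k), dtype=int)
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            out[i, j] = int(np.sum((y_true == a) & (y_pred == b)))
    return out


def cohen_kappa(confusion) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e).

    Expected agreement p_e comes from the products of the row and column
    marginals. Degenerate marginals with p_e = 1 return 0 by convention,
    with a warning.
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DataError("confusion matrix must be square")
    if np.any(m < 0) or np.any(m != np.floor(m)):
        raise DataError("confusion matrix must hold nonnegative integer counts")
    total = m.sum()
    if total <= 0:
        raise DataError("confusion matrix must have a positive total")
    p_o = np.trace(m) / total
    p_e = float(np.sum(m.sum(axis=0) * m.sum(axis=1)) / total**2)
    if p_e >= 1.0:
        warnings.warn(
            "degenerate marginals (p_e = 1); kappa defined 0 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _weighted_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            "accuracy": float(np.mean(y_true == y_pred)),
            "f1": float(f1_score(y_true, y_pred, average="weighted", zero_division=0)),
            "precision": float(
                precision_score(y_true, y_pred, average="weighted", zero_division=0)
            ),
            "recall": float(
                recall_score(y_true, y_pred, average="weighted", zero_division=0)
            ),
        }


# ---------------------------------------------------------------------------
# training


@dataclass
class FittedModel:
    family: str
    estimator: object
    best_params: dict
    cv_kappa: float
    cv_metrics: dict[str, float]
    cv_confusion: np.ndarray
    train_patients: frozenset[str] = field(default_factory=frozenset)

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        pred = np.asarray(self.estimator.predict(x)).astype(int)
        return np.where(pred == 1, "IBC", "DCIS")


@dataclass
class TrainReport:
    models: dict[str, FittedModel]
    cv_table: pd.DataFrame

    def best_family(self) -> str:
        return max(self.models, key=lambda f: self.models[f].cv_kappa)


def _patient_folds(
    groups: np.ndarray, y: np.ndarray, k_folds: int, seed: int
) -> np.ndarray:
    """Patient-level, class-stratified fold ids for each mesh row.

    Redraws (new child seed) if some fold ends up single-class.
    """
    patients = pd.DataFrame({"patient_id": groups, "y": y}).drop_duplicates("patient_id")
    ss = np.random.SeedSequence(seed)
    for attempt in range(10):
        rng = np.random.default_rng(ss.spawn(1)[0])
        fold_of: dict[str, int] = {}
        for cls in np.unique(patients["y"]):
            members = sorted(patients.loc[patients["y"] == cls, "patient_id"])
            rng.shuffle(members)
            for i, p in enumerate(members):
                fold_of[p] = i % k_folds
        fold_ids = np.array([fold_of[g] for g in groups])
        ok = all(
            np.unique(y[fold_ids == f]).size == 2 for f in range(k_folds)
        )
        if ok:
            return fold_ids
    raise DataError("could not draw patient-disjoint folds with both classes present")


def train_models(
    train_table: pd.DataFrame,
    algorithms: Iterable[str] | None = None,
    k_folds: int = 3,
    grids: Mapping[str, list[dict]] | None = None,
    seed: int = 0,
) -> TrainReport:
    """Grid search per family, maximizing mean CV Cohen's kappa.

    Cross-validation folds are patient-disjoint and class-stratified at the
    patient level. For each family the hyperparameter set with the highest
    mean test-fold kappa wins and is refit on the full training table. The
    CV report records per-family mean metrics and the pooled test-fold
    confusion matrix of the winning parameters.
    """
    algorithms = list(algorithms) if algorithms is not None else list(ALGORITHM_FAMILIES)
    grids = grids or DEFAULT_GRIDS
    x, y, groups = _xy(train_table)
    if np.unique(y).size < 2:
        raise DataError("training table must contain both classes")
    fold_ids = _patient_folds(groups, y, k_folds, seed)
    fit_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31)

    models: dict[str, FittedModel] = {}
    rows = []
    for family in algorithms:
        grid = grids.get(family, [{}])
        if not grid:
            raise DataError(f"empty hyperparameter grid for family {family!r}")
        best = None
        for params in grid:
            fold_kappas = []
            pooled_true: list[np.ndarray] = []
            pooled_pred: list[np.ndarray] = []
            for f in range(k_folds):
                est = _make_estimator(family, params, fit_seed)
                tr, te = fold_ids != f, fold_ids == f
                est.fit(x[tr], y[tr])
                pred = np.asarray(est.predict(x[te])).astype(int)
                conf = confusion_matrix(
                    np.where(y[te] == 1, "IBC", "DCIS"),
                    np.where(pred == 1, "IBC", "DCIS"),
                )
                fold_kappas.append(cohen_kappa(conf))
                pooled_true.append(y[te])
                pooled_pred.append(pred)
            mean_kappa = float(np.mean(fold_kappas))
            if best is None or mean_kappa > best[0]:
                best = (
                    mean_kappa,
                    params,
                    np.concatenate(pooled_true),
                    np.concatenate(pooled_pred),
                )
        assert best is not None
        mean_kappa, params, yt, yp = best
        yt_lab = np.where(yt == 1, "IBC", "DCIS")
        yp_lab = np.where(yp == 1, "IBC", "DCIS")
        cv_conf = confusion_matrix(yt_lab, yp_lab)
        cv_metrics = _weighted_metrics(yt_lab, yp_lab)
        final = _make_estimator(family, params, fit_seed)
        final.fit(x, y)
        models[family] = FittedModel(
            family=family,
            estimator=final,
            best_params=params,
            cv_kappa=mean_kappa,
            cv_metrics=cv_metrics,
            cv_confusion=cv_conf,
            train_patients=frozenset(groups.tolist()),
        )
        rows.append(
            {
                "family": family,
                "best_params": str(params),
                "cv_kappa": mean_kappa,
                "cv_pooled_kappa": cohen_kappa(cv_conf),
                **{f"cv_{k}": v for k, v in cv_metrics.items()},
            }
        )
    table = pd.DataFrame(rows).sort_values("cv_kappa", ascending=False).reset_index(drop=True)
    return TrainReport(models=models, cv_table=table)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    kappa: float
    accuracy: float
    f1: float
    precision: float
    recall: float
    confusion: np.ndarray
    predictions: pd.DataFrame  # patient_id, true, predicted per mesh

    @property
    def n_meshes(self) -> int:
        return int(self.confusion.sum())


def evaluate(model: FittedModel, eval_table: pd.DataFrame) -> EvalReport:
    """Mesh-level evaluation on held-out patients.

    Hard error if any evaluation patient was seen in training (leakage
    guard). Reports Cohen's kappa, accuracy and class-support-weighted
    F1 / precision / recall, plus the confusion matrix in (IBC, DCIS) order.
    """
    x, y, groups = _xy(eval_table)
    overlap = set(groups.tolist()) & set(model.train_patients)
    if overlap:
        raise DataError(
            f"evaluation patients overlap training patients: {sorted(overlap)}"
        )
    pred = model.predict_labels(x)
    true = np.where(y == 1, "IBC", "DCIS")
    conf = confusion_matrix(true, pred)
    metrics = _weighted_metrics(true, pred)
    return EvalReport(
        kappa=cohen_kappa(conf),
        accuracy=metrics["accuracy"],
        f1=metrics["f1"],
        precision=metrics["precision"],
        recall=metrics["recall"],
        confusion=conf,
        predictions=pd.DataFrame(
            {"patient_id": groups, "true": true, "predicted": pred}
        ),
    )


def permutation_importance(
    model: FittedModel,
    table: pd.DataFrame,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation feature importance as normalized mean kappa drop.

    Each feature column is permuted ``n_repeats`` times; the mean drop in
    Cohen's kappa (clipped at zero; a constant feature scores exactly zero)
    is normalized so the importances sum to 1, and features are returned in
    descending order.
    """
    x, y, _ = _xy(table)
    feats = [c for c in table.columns if c.startswith("wn_")]
    true = np.where(y == 1, "IBC", "DCIS")
    base = cohen_kappa(confusion_matrix(true, model.predict_labels(x)))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    drops = np.zeros(len(feats))
    for j in range(len(feats)):
        if np.unique(x[:, j]).size < 2:
            drops[j] = 0.0
            continue
        acc = 0.0
        for _ in range(n_repeats):
            xp = x.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            acc += base - cohen_kappa(confusion_matrix(true, model.predict_labels(xp)))
        drops[j] = max(acc / n_repeats, 0.0)
    total = drops.sum()
    if total > 0:
        shares = drops / total
    else:
        shares = np.full(len(feats), 1.0 / len(feats))
    out = pd.DataFrame({"feature": feats, "importance": shares})
    return out.sort_values("importance", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# patient aggregation


def patient_prediction(n_pred_ibc: int, n_pred_dcis: int) -> dict:
    """Aggregate mesh counts into a patient-level call.

    ratio_ibc = n_pred_ibc / total (reported at 3 decimals); the category is
    IBC iff the unrounded ratio exceeds 0.5.
    """
    n_pred_ibc, n_pred_dcis = int(n_pred_ibc), int(n_pred_dcis)
    if n_pred_ibc < 0 or n_pred_dcis < 0:
        raise DataError("mesh counts must be nonnegative")
    total = n_pred_ibc + n_pred_dcis
    if total == 0:
        raise DataError("patient has zero predicted meshes")
    ratio = n_pred_ibc / total
    return {
        "n_pred_ibc": n_pred_ibc,
        "n_pred_dcis": n_pred_dcis,
        "ratio_ibc": round(ratio, 3),
        "predicted_category": "IBC" if ratio > 0.5 else "DCIS",
    }


def patient_aggregate(mesh_predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-patient mesh counts, IBC ratio and predicted category.

    ``mesh_predictions`` needs ``patient_id`` and ``predicted`` columns
    (values "IBC"/"DCIS"); a ``true`` column, if present, is carried
    through.
    """
    if mesh_predictions.empty:
        raise DataError("no mesh predictions to aggregate")
    rows = []
    for pid, grp in mesh_predictions.groupby("patient_id", sort=True):
        n_ibc = int((grp["predicted"] == "IBC").sum())
        n_dcis = int((grp["predicted"] == "DCIS").sum())
        rec = {"patient_id": pid, **patient_prediction(n_ibc, n_dcis)}
        if "true" in grp.columns:
            rec["diagnosis"] = grp["true"].iloc[0]
            rec["mesh_accuracy"] = float(
                np.mean(grp["predicted"] == grp["true"])
            )
        rows.append(rec)
    return pd.DataFrame(rows)
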