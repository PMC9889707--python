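"""Blood-sample -> (dose) -> product-phenotype classification.

Products are grouped into k broad phenotypes (k-means on z-scored product
features, k = 5 by default, chosen where cluster assignment explains > 90%
of the feature variance), and classifiers are trained to predict a
product's phenotype cluster from its donor's *blood* features plus the
stimulation dose (pg/cell).  Five algorithm families are assessed: random
forest, multi-layer perceptron, decision tree, Gaussian naive Bayes and
k-nearest neighbours, each grid-search-tuned on a 70% training partition
and scored by stratified tenfold cross-validation plus a held-out 30% test
accuracy.  Healthy and patient strata are modelled separately.

Cluster labels are computed once on all products before the train/test
split (the labelling step precedes partitioning; the mild leakage this
implies is a property of the protocol and is documented).  The random
forest defaults are pinned to a tuned configuration: 800 trees, Gini
impurity, min 2 samples per leaf, min 2 samples to split, max depth 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .gating import is_feature_column, split_train_test

RF_PARAMS = dict(
    n_estimators=800,
    criterion="gini",
    min_samples_leaf=2,
    min_samples_split=2,
    max_depth=10,
)

DEFAULT_ALGORITHMS = (
    "random_forest",
    "mlp",
    "decision_tree",
    "naive_bayes",
    "nearest_neighbors",
)


@dataclass
class ProductClusterModel:
    k: int
    centroids: np.ndarray
    labels: dict[str, int]  # sample_id -> cluster label in 1..k
    variance_explained: float  # between-cluster / total sum of squares

    def label_series(self, sample_ids) -> pd.Series:
        return pd.Series([self.labels[s] for s in sample_ids], index=sample_ids)


def _feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in table.columns if is_feature_column(c)]
    return table[cols].to_numpy(dtype=float), cols


def cluster_products(
    product_features: pd.DataFrame, k: int = 5, seed: int = 0
) -> ProductClusterModel:
    """Seeded k-means over z-scored product feature rows (one stratum)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    x, _ = _feature_matrix(product_features)
    if k > len(x):
        raise ValueError(f"k={k} exceeds the {len(x)} products")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(x)
    total_ss = float(((x - x.mean(axis=0)) ** 2).sum())
    explained = 1.0 - km.inertia_ / total_ss if total_ss > 0 else 0.0
    labels = {
        str(sid): int(a) + 1
        for sid, a in zip(product_features["sample_id"], assign)
    }
    return ProductClusterModel(
        k=k, centroids=km.cluster_centers_, labels=labels, variance_explained=explained
    )


@dataclass
class KSelection:
    k: int | None  # None when no candidate clears the threshold
    trace: dict[int, float]
    threshold: float


def choose_k_by_variance(
    product_features: pd.DataFrame,
    k_candidates=(2, 3, 4, 5, 6, 7, 8),
    threshold: float = 0.9,
    seed: int = 0,
) -> KSelection:
    """Smallest k whose cluster assignment explains > threshold of the
    total feature variance (between-cluster / total sum of squares)."""
    trace = {
        int(k): cluster_products(product_features, k=int(k), seed=seed).variance_explained
        for k in k_candidates
    }
    for k in sorted(trace):
        if trace[k] > threshold:
            return KSelection(k=k, trace=trace, threshold=threshold)
    return KSelection(k=None, trace=trace, threshold=threshold)


def build_classifier_rows(
    blood_features: pd.DataFrame, product_features: pd.DataFrame
) -> pd.DataFrame:
    """One row per product: the donor's blood feature vector plus that
    product's stimulation dose (pg/cell).  Blood features are typically
    z-scored by the caller first."""
    feature_cols = [c for c in blood_features.columns if is_feature_column(c)]
    rows = product_features[["sample_id", "donor_id", "dose_pg_per_cell"]].merge(
        blood_features[["donor_id"] + feature_cols], on="donor_id", how="left"
    )
    if rows[feature_cols].isna().any().any():
        missing = sorted(
            set(product_features["donor_id"]) - set(blood_features["donor_id"])
        )
        raise KeyError(f"no blood sample for donor(s) {missing}")
    return rows


def _algorithm_spec(seed: int, rf_n_estimators: int = 800) -> dict[str, tuple[object, dict]]:
    rf_params = dict(RF_PARAMS, n_estimators=rf_n_estimators)
    return {
        "random_forest": (
            RandomForestClassifier(random_state=seed, **rf_params),
            {"max_depth": [5, 10], "max_features": ["sqrt", None]},
        ),
        "mlp": (
            MLPClassifier(max_iter=3000, random_state=seed),
            {"hidden_layer_sizes": [(32,), (64,)]},
        ),
        "decision_tree": (
            DecisionTreeClassifier(random_state=seed),
            {"max_depth": [3, 5, 10, None]},
        ),
        "naive_bayes": (GaussianNB(), {}),
        "nearest_neighbors": (
            KNeighborsClassifier(),
            {"n_neighbors": [1, 3, 5]},
        ),
    }


@dataclass
class AlgorithmReport:
    algorithm: str
    cv_mean: float
    cv_sd: float
    test_accuracy: float
    best_params: dict


@dataclass
class ClassifierReport:
    per_algorithm: dict[str, AlgorithmReport]
    feature_names: list[str]
    importances: pd.Series | None  # fitted random-forest importances
    n_train: int
    n_test: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_train": self.n_train,
            "n_test": self.n_test,
            "seed": self.seed,
            "algorithms": {
                name: {
                    "cv_mean": rep.cv_mean,
                    "cv_sd": rep.cv_sd,
                    "test_accuracy": rep.test_accuracy,
                    "best_params": {k: str(v) for k, v in rep.best_params.items()},
                }
                for name, rep in sorted(self.per_algorithm.items())
            },
            "importances": (
                {k: float(v) for k, v in self.importances.items()}
                if self.importances is not None
                else None
            ),
        }


def _design(table: pd.DataFrame, dose_only: bool = False) -> tuple[np.ndarray, list[str]]:
    cols = [] if dose_only else [c for c in table.columns if is_feature_column(c)]
    cols = cols + ["dose_pg_per_cell"]
    return table[cols].to_numpy(dtype=float), cols


def _stratified_split(
    table: pd.DataFrame, y: np.ndarray, train_fraction: float, seed: int
):
    """70/30 split; re-drawn (logged) until every class appears in training."""
    idx = pd.DataFrame({"_row": np.arange(len(table))})
    for attempt in range(50):
        tr, te = split_train_test(idx, train_fraction, seed + attempt)
        if set(y[tr["_row"]]) == set(y):
            if attempt > 0:
                warnings.warn(
                    f"re-drew train/test split {attempt} time(s) to cover all classes"
                )
            return tr["_row"].to_numpy(), te["_row"].to_numpy()
    raise ValueError("could not draw a split covering every class")


def _cv_splitter(y_train: np.ndarray, seed: int, n_folds: int = 10) -> StratifiedKFold:
    smallest = int(np.bincount(pd.factorize(y_train)[0]).min())
    n_splits = max(2, min(n_folds, smallest))
    if n_splits < n_folds:
        warnings.warn(
            f"reduced CV folds to {n_splits}: smallest class has {smallest} members"
        )
    return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)


def train_classifiers(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    algorithms=DEFAULT_ALGORITHMS,
    seed: int = 0,
    train_fraction: float = 0.7,
    dose_only: bool = False,
    grid_search: bool = True,
    rf_n_estimators: int = 800,
) -> ClassifierReport:
    """Tune and score the classifier battery for one stratum.

    ``table`` carries one row per product: the donor's blood features plus
    ``dose_pg_per_cell`` (features are expected already standardised by the
    caller).  Rows are partitioned at random without donor restriction.
    ``grid_search=False`` skips tuning and scores the pinned defaults
    (useful for repeated permutation baselines); ``rf_n_estimators`` scales
    the forest for the same reason.
    """
    y = np.asarray(labels)
    x, cols = _design(table, dose_only=dose_only)
    tr, te = _stratified_split(table, y, train_fraction, seed)
    x_tr, y_tr, x_te, y_te = x[tr], y[tr], x[te], y[te]
    cv = _cv_splitter(y_tr, seed)
    spec = _algorithm_spec(seed, rf_n_estimators)
    per: dict[str, AlgorithmReport] = {}
    importances = None
    for name in algorithms:
        if name not in spec:
            raise ValueError(f"unknown algorithm {name!r}")
        estimator, grid = spec[name]
        if not grid_search:
            grid = {}
        search = GridSearchCV(estimator, grid, cv=cv, scoring="accuracy")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter
            search.fit(x_tr, y_tr)
        scores = np.array(
            [
                search.cv_results_[f"split{i}_test_score"][search.best_index_]
                for i in range(cv.get_n_splits())
            ]
        )
        per[name] = AlgorithmReport(
            algorithm=name,
            cv_mean=float(scores.mean()),
            cv_sd=float(scores.std(ddof=0)),
            test_accuracy=float(search.best_estimator_.score(x_te, y_te)),
            best_params=dict(search.best_params_),
        )
        if name == "random_forest":
            importances = feature_importance(search.best_estimator_, cols)
    return ClassifierReport(
        per_algorithm=per,
        feature_names=cols,
        importances=importances,
        n_train=len(tr),
        n_test=len(te),
        seed=seed,
    )


def feature_importance(forest, feature_names: list[str]) -> pd.Series:
    """Impurity-based importances, normalised to sum 1 and ranked."""
    if not hasattr(forest, "feature_importances_"):
        raise TypeError("feature importance requires a fitted forest model")
    imp = np.asarray(forest.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=feature_names).sort_values(ascending=False)


def top_features_excluding_dose(importances: pd.Series, n: int = 5) -> pd.Series:
    return importances.drop(labels=["dose_pg_per_cell"], errors="ignore").head(n)


@dataclass
class AblationResult:
    full_accuracy: float
    dose_only_accuracy: float

    @property
    def difference(self) -> float:
        return self.full_accuracy - self.dose_only_accuracy


def dose_only_ablation(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    algorithm: str = "random_forest",
    seed: int = 0,
    train_fraction: float = 0.7,
    grid_search: bool = True,
    rf_n_estimators: int = 800,
) -> AblationResult:
    """Same classifier, same folds and split, full features vs dose alone.

    Both arms share the seed, so fold assignments and the 70/30 partition are
    identical; the reported difference isolates the value of the blood
    phenotype beyond stimulation dose.
    """
    kwargs = dict(
        algorithms=(algorithm,), seed=seed, train_fraction=train_fraction,
        grid_search=grid_search, rf_n_estimators=rf_n_estimators,
    )
    full = train_classifiers(table, labels, dose_only=False, **kwargs)
    dose = train_classifiers(table, labels, dose_only=True, **kwargs)
    return AblationResult(
        full_accuracy=full.per_algorithm[algorithm].cv_mean,
        dose_only_accuracy=dose.per_algorithm[algorithm].cv_mean,
    )


def status_classifier(
    product_features: pd.DataFrame,
    statuses: pd.Series | np.ndarray,
    seed: int = 0,
) -> float:
    """Tenfold-CV accuracy of healthy-vs-patient from product phenotype alone."""
    y = np.asarray(statuses)
    if np.unique(y).size < 2:
        raise ValueError("both statuses must be present")
    x, _ = _feature_matrix(product_features)
    cv = _cv_splitter(y, seed)
    forest = RandomForestClassifier(random_state=seed, **RF_PARAMS)
    scores = []
    for tr, te in cv.split(x, y):
        forest.fit(x[tr], y[tr])
        scores.append(forest.score(x[te], y[te]))
    return float(np.mean(scores))
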