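"""Nested leave-one-out cross-validated recurrence-risk classification.

The protocol, per outer fold (one patient left out):

1. standardize features on the development rows only;
2. Isolation-Forest outlier removal (5% contamination) on the dev rows;
3. MRMR filter selection down to ``mrmr_k`` features;
4. class-imbalance handling: SMOTE for classifiers without class
   weighting (LDA, KNN), inverse-frequency class weights otherwise
   (SVMs, random forest);
5. exhaustive hyperparameter grid search, each grid point scored by
   forward sequential feature selection (``sfs_k`` features) under an
   inner leave-one-out loop on balanced accuracy;
6. final refit on the full development set, probability score for the
   held-out patient.

The left-out patient never influences any statistic, selection or
resampling of its own fold.  Scores from all n folds are thresholded at
0.5 and aggregated into a single confusion matrix.

The public surface is statsmodels-like: build a
:class:`RecurrenceModel` from a feature matrix, ``fit()`` it, and read
estimates and diagnostics off the returned :class:`RecurrenceResults`.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import IsolationForest, RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .config import PipelineConfig
from .metrics import ConfusionCounts, MetricsReport, compute_metrics

__all__ = [
    "ClassifierSpec",
    "FoldResult",
    "RecurrenceModel",
    "RecurrenceResults",
    "default_classifier_specs",
    "reduced_classifier_specs",
    "standardize_fit_apply",
    "isolation_forest_outliers",
    "mrmr_select",
    "smote_oversample",
    "sfs_forward",
    "inner_model_search",
    "nested_loocv_run",
    "complexity_sweep",
    "synthetic_feature_cohort",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# classifier registry


@dataclass
class ClassifierSpec:
    """One classifier family: constructor, hyperparameter grid, imbalance mode.

    ``grid`` maps parameter name to candidate values ordered from
    simplest to most complex, so that the first-wins tie rule of the
    grid search also prefers the simpler model.
    """

    kind: str
    grid: dict[str, tuple]
    supports_class_weight: bool
    builder: Callable[..., Any]

    def __post_init__(self) -> None:
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")

    def grid_points(self) -> list[dict[str, Any]]:
        out: list[dict[str, Any]] = [{}]
        for key in self.grid:
            out = [{**d, key: v} for d in out for v in self.grid[key]]
        return out

    def build(self, params: dict[str, Any], seed: int, final: bool = False):
        return self.builder(params, seed, final)


def _svc_builder(kernel: str):
    def build(params: dict[str, Any], seed: int, final: bool):
        return SVC(
            kernel=kernel,
            class_weight="balanced",
            random_state=seed,
            **params,
        )

    return build


def default_classifier_specs() -> dict[str, ClassifierSpec]:
    """The five classifier families with modest grids sized to n ~ 31."""
    return {
        "lda": ClassifierSpec(
            "lda",
            grid={},
            supports_class_weight=False,
            builder=lambda p, s, f: LinearDiscriminantAnalysis(solver="svd", **p),
        ),
        "knn": ClassifierSpec(
            "knn",
            grid={"n_neighbors": (3, 5, 7)},
            supports_class_weight=False,
            builder=lambda p, s, f: KNeighborsClassifier(**p),
        ),
        "svm-linear": ClassifierSpec(
            "svm-linear",
            grid={"C": (0.1, 1.0, 10.0, 100.0)},
            supports_class_weight=True,
            builder=_svc_builder("linear"),
        ),
        "svm-rbf": ClassifierSpec(
            "svm-rbf",
            grid={"C": (0.1, 1.0, 10.0, 100.0), "gamma": ("scale", 0.01, 0.1)},
            supports_class_weight=True,
            builder=_svc_builder("rbf"),
        ),
        "rf": ClassifierSpec(
            "rf",
            grid={"n_estimators": (100, 300), "max_depth": (2, 3, None)},
            supports_class_weight=True,
            builder=lambda p, s, f: RandomForestClassifier(
                class_weight="balanced", random_state=s, **p
            ),
        ),
    }


def reduced_classifier_specs() -> dict[str, ClassifierSpec]:
    """Trimmed grids for desk-scale experiments and permutation studies."""
    specs = default_classifier_specs()
    specs["knn"] = replace(specs["knn"], grid={"n_neighbors": (3, 5)})
    specs["svm-linear"] = replace(specs["svm-linear"], grid={"C": (1.0, 10.0)})
    specs["svm-rbf"] = replace(
        specs["svm-rbf"], grid={"C": (1.0, 10.0), "gamma": ("scale",)}
    )
    specs["rf"] = replace(
        specs["rf"], grid={"n_estimators": (50,), "max_depth": (3, None)}
    )
    return specs


# ---------------------------------------------------------------------------
# preprocessing blocks


def standardize_fit_apply(
    dev: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray, np.ndarray]:
    """Z-score using development-set statistics only (no leakage).

    Zero-variance features get sd replaced by 1 and are flagged.
    Returns ``(dev_t, test_t, mean, sd, flagged)``.
    """
    dev = np.asarray(dev, dtype=float)
    if dev.shape[0] < 2:
        raise ValueError("development set needs at least 2 rows")
    mean = dev.mean(axis=0)
    sd = dev.std(axis=0)
    flagged = sd == 0
    sd_safe = np.where(flagged, 1.0, sd)
    dev_t = (dev - mean) / sd_safe
    test_t = None if test is None else (np.asarray(test, float) - mean) / sd_safe
    return dev_t, test_t, mean, sd_safe, flagged


def isolation_forest_outliers(
    dev: np.ndarray,
    y: np.ndarray | None = None,
    contamination: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Indices of development rows retained after Isolation-Forest screening.

    The ``ceil(contamination * n)`` most anomalous rows are removed,
    unless removal would empty a class, in which case that class's
    removals are skipped (with a warning).
    """
    dev = np.asarray(dev, dtype=float)
    n = dev.shape[0]
    if contamination <= 0:
        return np.arange(n)
    if n < 10:
        raise ValueError("need at least 10 rows for outlier screening")
    n_remove = int(np.ceil(contamination * n))
    forest = IsolationForest(random_state=seed)
    forest.fit(dev)
    scores = forest.score_samples(dev)  # lower = more anomalous
    candidates = np.argsort(scores, kind="stable")[:n_remove]
    removed = np.zeros(n, dtype=bool)
    removed[candidates] = True
    if y is not None:
        y = np.asarray(y).astype(int)
        for cls in np.unique(y):
            if not np.any((y == cls) & ~removed):
                logger.warning(
                    "outlier removal would empty class %s; skipping its removals",
                    cls,
                )
                removed &= y != cls
    return np.nonzero(~removed)[0]


def mrmr_select(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    feature_names: Sequence[str] | None = None,
    eps: float = 1e-12,
) -> list[int] | list[str]:
    """Greedy maximal-relevance minimal-redundancy feature selection.

    Relevance is the one-way ANOVA F statistic against the binary class;
    redundancy the mean absolute Pearson correlation with the features
    already chosen; the next pick maximizes ``relevance / (redundancy +
    eps)``.  Ties break toward the lower feature index.  Returns indices,
    or names when ``feature_names`` is given.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n_feat = X.shape[1]
    if k > n_feat:
        raise ValueError("k exceeds the number of features")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        relevance, _ = f_classif(X, y)
    relevance = np.nan_to_num(relevance, nan=0.0, posinf=np.finfo(float).max / 4)

    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Xc = (X - X.mean(axis=0)) / sd_safe
    n = X.shape[0]

    selected: list[int] = []
    red_sum = np.zeros(n_feat)
    remaining = np.ones(n_feat, dtype=bool)
    for _ in range(k):
        if not selected:
            score = relevance.copy()
        else:
            score = relevance / (red_sum / len(selected) + eps)
        score[~remaining] = -np.inf
        pick = int(np.argmax(score))
        selected.append(pick)
        remaining[pick] = False
        corr = np.abs(Xc.T @ Xc[:, pick]) / n
        corr[sd == 0] = 0.0
        red_sum += corr
    if feature_names is not None:
        return [feature_names[i] for i in selected]
    return selected


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling by interpolation between
    minority-class nearest neighbors; output classes are balanced."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X.copy(), y.copy()
    if n_min < 2:
        raise ValueError("minority class needs at least 2 samples for SMOTE")
    rng = np.random.default_rng(seed)
    minority_X = X[y == minority]
    k = min(k_neighbors, n_min - 1)
    d2 = np.sum((minority_X[:, None, :] - minority_X[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.argsort(d2, axis=1, kind="stable")[:, :k]
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, n_new)
    pick = nn_idx[base, rng.integers(0, k, n_new)]
    u = rng.uniform(0, 1, n_new)[:, None]
    synthetic = minority_X[base] + u * (minority_X[pick] - minority_X[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# inner loop


def _inner_loocv_bacc(
    X: np.ndarray, y: np.ndarray, make_clf: Callable[[], Any]
) -> float:
    """Balanced accuracy of aggregated leave-one-out predictions."""
    n = len(y)
    preds = np.full(n, -1)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        ytr = y[tr]
        if len(np.unique(ytr)) < 2:
            logger.warning("inner fold %d has a single-class training set", i)
            continue
        clf = make_clf()
        try:
            clf.fit(X[tr], ytr)
        except ValueError as exc:  # e.g. too few samples for the estimator
            logger.warning("inner fold %d unfittable (%s); skipped", i, exc)
            continue
        preds[i] = int(clf.predict(X[i : i + 1])[0])
    ok = preds >= 0
    if not np.any(ok):
        return 0.0
    counts = ConfusionCounts.from_predictions(y[ok], preds[ok])
    rec = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else 0.0
    return (rec + spec) / 2


def sfs_forward(
    X: np.ndarray,
    y: np.ndarray,
    make_clf: Callable[[], Any],
    k: int,
) -> tuple[list[int], float]:
    """Forward sequential feature selection under inner-LOOCV balanced
    accuracy.  Ties break toward the lower feature index.  Returns the
    selected column indices and the final inner score."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n_feat = X.shape[1]
    if k > n_feat:
        raise ValueError("k exceeds the number of candidate features")
    selected: list[int] = []
    best_score = -np.inf
    for _ in range(k):
        scores = np.full(n_feat, -np.inf)
        for j in range(n_feat):
            if j in selected:
                continue
            cols = selected + [j]
            scores[j] = _inner_loocv_bacc(X[:, cols], y, make_clf)
        pick = int(np.argmax(scores))  # argmax takes the first (lowest index) tie
        selected.append(pick)
        best_score = float(scores[pick])
    return selected, best_score


def inner_model_search(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    cfg: PipelineConfig,
    seed: int = 0,
    sfs_k: int | None = None,
) -> tuple[Any, dict[str, Any], list[int], float]:
    """Exhaustive grid search; each grid point is scored by SFS +
    inner-LOOCV balanced accuracy.  Ties keep the earlier (simpler) grid
    point.  Returns the refitted final model, the chosen parameters, the
    selected feature columns and the best inner score."""
    if X.shape[0] < 3:
        raise ValueError("development set too small (need >= 3 rows)")
    k = sfs_k if sfs_k is not None else cfg.sfs_k
    best: tuple[float, dict, list[int]] | None = None
    for params in spec.grid_points():
        make = lambda p=params: spec.build(p, seed, final=False)
        feats, score = sfs_forward(X, y, make, k)
        if best is None or score > best[0]:
            best = (score, params, feats)
    assert best is not None
    score, params, feats = best
    final = spec.build(params, seed, final=True)
    final.fit(X[:, feats], y)
    return final, params, feats, score


# ---------------------------------------------------------------------------
# outer loop


@dataclass
class FoldResult:
    index: int
    patient_id: str
    selected_features: list[str]
    params: dict[str, Any]
    score: float
    prediction: int
    y_true: int
    inner_balanced_accuracy: float


@dataclass
class RecurrenceResults:
    """Aggregated nested-LOOCV output for one classifier."""

    classifier: str
    folds: list[FoldResult]
    counts: ConfusionCounts
    metrics: MetricsReport
    feature_frequency: dict[str, int]
    config: PipelineConfig
    n_features: int

    @property
    def scores(self) -> np.ndarray:
        return np.array([f.score for f in self.folds])

    @property
    def y_true(self) -> np.ndarray:
        return np.array([f.y_true for f in self.folds])

    def summary(self) -> str:
        m = self.metrics
        r = m.rounded()
        lines = [
            f"Nested LOOCV results - classifier: {self.classifier}",
            f"  outer folds: {len(self.folds)}   features per model: {self.n_features}",
            f"  confusion: TP={self.counts.tp} FP={self.counts.fp} "
            f"TN={self.counts.tn} FN={self.counts.fn}",
            "  metric                value     95% CI",
        ]
        for name in m.METRIC_ORDER:
            lo, hi = m.ci.get(name, (float("nan"), float("nan")))
            if name in ("auroc", "auprc"):
                lines.append(f"  {name:<20}  {r[name]:>6}    ({lo:.2f}-{hi:.2f})")
            else:
                lines.append(f"  {name:<20}  {r[name]:>5}%    ({lo:.0f}-{hi:.0f})")
        top = sorted(self.feature_frequency.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
        lines.append("  most frequently selected features:")
        for name, cnt in top:
            lines.append(f"    {cnt:>3}x  {name}")
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "classifier": self.classifier,
            "counts": vars(self.counts),
            "metrics": self.metrics.as_dict(),
            "ci": {k: list(v) for k, v in self.metrics.ci.items()},
            "feature_frequency": self.feature_frequency,
            "n_features": self.n_features,
            "folds": [
                {
                    "index": f.index,
                    "patient_id": f.patient_id,
                    "selected_features": f.selected_features,
                    "params": {k: str(v) for k, v in f.params.items()},
                    "score": f.score,
                    "prediction": f.prediction,
                    "y_true": f.y_true,
                    "inner_balanced_accuracy": f.inner_balanced_accuracy,
                }
                for f in self.folds
            ],
        }
        return json.dumps(payload, indent=2)


class RecurrenceModel:
    """Recurrence-risk classification model over a radiomics feature matrix.

    Parameters
    ----------
    X : DataFrame of shape (patients, features)
        Feature columns only (see :meth:`from_feature_matrix` to build
        from a matrix that still carries ``odxrs``/``label`` columns).
    y : array-like of 0/1
        1 = intermediate-to-high recurrence risk, 0 = low risk.
    classifier : str or ClassifierSpec
    config : PipelineConfig
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: Sequence[int],
        classifier: str | ClassifierSpec = "svm-rbf",
        config: PipelineConfig | None = None,
        specs: dict[str, ClassifierSpec] | None = None,
    ) -> None:
        self.X = pd.DataFrame(X).astype(float)
        self.y = np.asarray(y).astype(int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")
        if len(self.y) < 4:
            raise ValueError("need at least 4 patients")
        self.config = config or PipelineConfig()
        registry = specs or default_classifier_specs()
        if isinstance(classifier, ClassifierSpec):
            self.spec = classifier
        else:
            if classifier not in registry:
                raise ValueError(f"unknown classifier {classifier!r}")
            self.spec = registry[classifier]

    @classmethod
    def from_feature_matrix(
        cls,
        df: pd.DataFrame,
        classifier: str | ClassifierSpec = "svm-rbf",
        config: PipelineConfig | None = None,
        specs: dict[str, ClassifierSpec] | None = None,
    ) -> "RecurrenceModel":
        """Build from a matrix whose non-feature columns are ``odxrs``/``label``."""
        y = df["label"].to_numpy()
        X = df.drop(columns=[c for c in ("odxrs", "label") if c in df.columns])
        return cls(X, y, classifier=classifier, config=config, specs=specs)

    # -- fitting ------------------------------------------------------------

    def _run_fold(
        self, i: int, sfs_k: int
    ) -> FoldResult:
        cfg = self.config
        n = len(self.y)
        dev_idx = np.setdiff1d(np.arange(n), [i])
        ydev = self.y[dev_idx]
        if len(np.unique(ydev)) < 2:
            raise RuntimeError(f"fold {i}: development set lost a class")
        seeds = np.random.SeedSequence([cfg.seed, i]).generate_state(3) % (2**31 - 1)

        Xdev = self.X.iloc[dev_idx].to_numpy()
        Xtest = self.X.iloc[[i]].to_numpy()
        Xdev_t, Xtest_t, _, _, _ = standardize_fit_apply(Xdev, Xtest)

        if cfg.contamination > 0 and len(dev_idx) >= 10:
            keep = isolation_forest_outliers(
                Xdev_t, ydev, cfg.contamination, seed=int(seeds[0])
            )
            Xdev_t, ydev = Xdev_t[keep], ydev[keep]

        k = min(cfg.mrmr_k, Xdev_t.shape[1])
        mrmr_cols = mrmr_select(Xdev_t, ydev, k)
        Xsel = Xdev_t[:, mrmr_cols]
        Xtest_sel = Xtest_t[:, mrmr_cols]

        if not self.spec.supports_class_weight and np.bincount(ydev).min() >= 2:
            Xfit, yfit = smote_oversample(
                Xsel, ydev, cfg.smote_k_neighbors, seed=int(seeds[1])
            )
        else:
            if not self.spec.supports_class_weight:
                logger.warning(
                    "fold %d: singleton minority class, SMOTE skipped", i
                )
            Xfit, yfit = Xsel, ydev

        model, params, feats, inner_score = inner_model_search(
            Xfit, yfit, self.spec, cfg, seed=int(seeds[2]), sfs_k=sfs_k
        )
        if hasattr(model, "predict_proba"):
            score = float(model.predict_proba(Xtest_sel[:, feats])[0, 1])
        else:
            # margin classifiers: logistic squash of the signed margin keeps
            # the 0.5 threshold consistent with the decision boundary
            margin = float(model.decision_function(Xtest_sel[:, feats])[0])
            score = 1.0 / (1.0 + np.exp(-margin))
        pred = int(score >= cfg.decision_threshold)
        names = [self.X.columns[mrmr_cols[f]] for f in feats]
        return FoldResult(
            index=i,
            patient_id=str(self.X.index[i]),
            selected_features=names,
            params=params,
            score=score,
            prediction=pred,
            y_true=int(self.y[i]),
            inner_balanced_accuracy=inner_score,
        )

    def fit(self, sfs_k: int | None = None) -> RecurrenceResults:
        """Run the full nested LOOCV and aggregate the test predictions."""
        k = sfs_k if sfs_k is not None else self.config.sfs_k
        folds = [self._run_fold(i, k) for i in range(len(self.y))]
        preds = np.array([f.prediction for f in folds])
        counts = ConfusionCounts.from_predictions(self.y, preds)
        scores = np.array([f.score for f in folds])
        metrics = compute_metrics(counts, scores=scores, labels=self.y)
        freq = Counter()
        for f in folds:
            freq.update(f.selected_features)
        return RecurrenceResults(
            classifier=self.spec.kind,
            folds=folds,
            counts=counts,
            metrics=metrics,
            feature_frequency=dict(freq),
            config=self.config,
            n_features=k,
        )

    def complexity_sweep(
        self, n_features_range: tuple[int, int] | None = None
    ) -> tuple[pd.DataFrame, dict[int, RecurrenceResults]]:
        """One full nested LOOCV per model size over ``complexity_range``.

        Returns a metric table indexed by the number of selected
        features, plus the per-size results objects.
        """
        lo, hi = n_features_range or self.config.complexity_range
        results = {}
        rows = []
        for k in range(lo, hi + 1):
            res = self.fit(sfs_k=k)
            results[k] = res
            rows.append({"n_features": k, **res.metrics.as_dict()})
        table = pd.DataFrame(rows).set_index("n_features")
        return table, results


# -- functional wrappers mirroring the protocol names ----------------------


def nested_loocv_run(
    df: pd.DataFrame,
    classifier: str = "svm-rbf",
    config: PipelineConfig | None = None,
    specs: dict[str, ClassifierSpec] | None = None,
) -> RecurrenceResults:
    return RecurrenceModel.from_feature_matrix(
        df, classifier=classifier, config=config, specs=specs
    ).fit()


def complexity_sweep(
    df: pd.DataFrame,
    classifier: str = "svm-rbf",
    config: PipelineConfig | None = None,
    specs: dict[str, ClassifierSpec] | None = None,
) -> pd.DataFrame:
    table, _ = RecurrenceModel.from_feature_matrix(
        df, classifier=classifier, config=config, specs=specs
    ).complexity_sweep()
    return table


# ---------------------------------------------------------------------------
# feature-level synthetic cohorts (fast pipeline testing)


def synthetic_feature_cohort(
    n_low: int = 10,
    n_high: int = 21,
    n_features: int = 150,
    n_informative: int = 2,
    effect_size: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A feature matrix drawn directly at the patient level.

    Features are standard normal; the first ``n_informative`` are
    shifted by ``effect_size`` standard deviations in the high-risk
    class (margin-texture analog of the class effect).  Returns a
    DataFrame with ``odxrs`` and ``label`` columns followed by features.
    """
    rng = np.random.default_rng(seed)
    n = n_low + n_high
    y = np.array([0] * n_low + [1] * n_high)
    X = rng.standard_normal((n, n_features))
    X[y == 1, :n_informative] += effect_size
    odxrs = np.where(y == 1, rng.integers(16, 36, n), rng.integers(1, 16, n))
    cols = [f"f{i:04d}" for i in range(n_features)]
    df = pd.DataFrame(X, columns=cols, index=[f"P{i:03d}" for i in range(n)])
    df.insert(0, "label", y)
    df.insert(0, "odxrs", odxrs)
    df.index.name = "patient_id"
    return df
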