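"""Genotype classifiers over allelic-dose features.

Features are either per-variant allelic doses (0 = no-call, 1 = variant
absent, 2 = heterozygous, 3 = homozygous alternate) or per-gene counts of
carried variants. Four classifier families are supported — logistic
regression (LR), support-vector classifier (SVC), random forest (RF) and
gradient-boosted trees (GbRF) — each tuned by stratified K-fold
cross-validated grid search on the discovery cohort with accuracy as the
selection metric, retrained on the full discovery cohort, and evaluated once
on the held-out validation cohort. Extreme cases are the positive class.

Dose codes are standardised (fit on training folds only) for the linear /
kernel models; tree models consume raw codes. ROC-AUC uses class
probabilities for the soft classifiers and the decision function for SVC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import (
    ConfigurationError,
    ContractError,
    LookupError_,
    StratificationError,
)
from .simulate import Cohort, HET, HOMALT, NOCALL

MODEL_FAMILIES = ("LR", "SVC", "RF", "GbRF")

# Modest default grids: the CV stays deterministic and desk-scale while still
# exercising the regularisation / capacity axes that matter for n ~ 100.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "LR": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
    "SVC": {"clf__kernel": ["linear", "rbf"], "clf__C": [0.1, 1.0, 10.0]},
    "RF": {"clf__n_estimators": [200], "clf__max_depth": [2, 4, None]},
    "GbRF": {
        "clf__n_estimators": [100, 200],
        "clf__learning_rate": [0.05, 0.1],
        "clf__max_depth": [2, 3],
    },
}


@dataclass
class MLDesign:
    """Cross-validated grid-search design for one classifier family."""

    model_family: str
    hyperparameter_grid: dict[str, list] = field(default_factory=dict)
    k_folds: int = 5
    seed: int = 0
    selection_metric: str = "accuracy"  # fixed: highest mean CV accuracy wins

    def __post_init__(self):
        if self.model_family not in MODEL_FAMILIES:
            raise ConfigurationError(
                f"unknown model family {self.model_family!r}; "
                f"choose from {MODEL_FAMILIES}"
            )
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be >= 2")
        if not self.hyperparameter_grid:
            self.hyperparameter_grid = DEFAULT_GRIDS[self.model_family]


def encode_allelic_dose(cohort: Cohort, features: list[str]) -> pd.DataFrame:
    """Samples x features matrix of allelic-dose codes {0, 1, 2, 3}.

    0 = no call, 1 = variant absent (hom-ref), 2 = heterozygous,
    3 = homozygous alternate — i.e. internal genotype code + 1 with no-calls
    mapped to 0.
    """
    missing = [f for f in features if f not in cohort._variant_index]
    if missing:
        raise LookupError_(f"features not in cohort panel: {missing[:5]}")
    sub = cohort.subset_variants(features)
    g = sub.genotypes.astype(np.int64)
    dose = np.where(g == NOCALL, 0, g + 1)
    return pd.DataFrame(dose, index=cohort.sample_ids, columns=features)


def encode_gene_counts(
    cohort: Cohort, genes: list[str], variant_map: dict[str, list[str]]
) -> pd.DataFrame:
    """Samples x genes matrix of carried-variant counts within each gene.

    A variant is carried when the genotype is het or hom-alt; no-calls
    contribute zero.
    """
    cols = {}
    for gene in genes:
        vids = variant_map.get(gene, [])
        if not vids:
            raise ConfigurationError(f"gene {gene} has an empty variant list")
        sub = cohort.subset_variants(vids)
        carried = np.isin(sub.genotypes, (HET, HOMALT))
        cols[gene] = carried.sum(axis=1)
    return pd.DataFrame(cols, index=cohort.sample_ids, columns=genes)


def labels_to_binary(labels: np.ndarray) -> np.ndarray:
    """Cases are the positive class (1); controls negative (0)."""
    return (np.asarray(labels) == "case").astype(int)


def build_estimator(family: str, seed: int):
    """Fresh estimator pipeline for a model family (scaling where it matters)."""
    if family == "LR":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=5000, random_state=seed)),
            ]
        )
    if family == "SVC":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", SVC(random_state=seed))]
        )
    if family == "RF":
        return Pipeline([("clf", RandomForestClassifier(random_state=seed))])
    if family == "GbRF":
        return Pipeline([("clf", GradientBoostingClassifier(random_state=seed))])
    raise ConfigurationError(f"unknown model family {family!r}")


def _check_folds(y: np.ndarray, k: int) -> None:
    pos, neg = int(y.sum()), int((1 - y).sum())
    if min(pos, neg) < k:
        raise StratificationError(
            f"cannot stratify {k} folds with class counts case={pos}, "
            f"control={neg}"
        )


def cv_grid_search(
    design: MLDesign, X: pd.DataFrame, y: np.ndarray
) -> tuple[dict, dict, object]:
    """Stratified K-fold grid search on the discovery cohort.

    Scores each grid point by mean left-out-fold accuracy; selects the argmax
    (ties go to the first point in deterministic grid order) and retrains the
    winner on the entire discovery set. Returns
    ``(best_params, cv_metrics, fitted_model)``; deterministic given
    ``design.seed``.
    """
    y = np.asarray(y)
    _check_folds(y, design.k_folds)
    cv = StratifiedKFold(
        n_splits=design.k_folds, shuffle=True, random_state=design.seed
    )
    search = GridSearchCV(
        build_estimator(design.model_family, design.seed),
        design.hyperparameter_grid,
        scoring="accuracy",
        cv=cv,
        refit=True,
    )
    search.fit(X.to_numpy(dtype=float), y)
    best_params = {k.removeprefix("clf__"): v for k, v in search.best_params_.items()}
    # CV AUC of the winning configuration on the same folds, for reporting
    cv_auc = cross_val_score(
        search.best_estimator_, X.to_numpy(dtype=float), y,
        scoring="roc_auc", cv=cv,
    ).mean()
    cv_metrics = {
        "cv_accuracy": float(search.best_score_),
        "cv_auc": float(cv_auc),
    }
    return best_params, cv_metrics, search.best_estimator_


def model_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous scores: class-1 probability, or SVC's decision function."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def evaluate_on_validation(
    model, X_val: pd.DataFrame, y_val: np.ndarray, train_features: list[str] | None = None
) -> dict:
    """Held-out metrics on the validation cohort (positive class = case)."""
    if train_features is not None:
        diff = set(train_features) ^ set(X_val.columns)
        if diff or list(train_features) != list(X_val.columns):
            raise ContractError(
                f"validation features differ from training features; "
                f"symmetric difference: {sorted(diff)[:10]}"
            )
    y_val = np.asarray(y_val)
    x = X_val.to_numpy(dtype=float)
    pred = model.predict(x)
    scores = model_scores(model, x)
    fpr, tpr, _ = roc_curve(y_val, scores)
    return {
        "accuracy": float(accuracy_score(y_val, pred)),
        "precision": float(precision_score(y_val, pred, zero_division=0)),
        "recall": float(recall_score(y_val, pred, zero_division=0)),
        "f1": float(f1_score(y_val, pred, zero_division=0)),
        "auc": float(roc_auc_score(y_val, scores)),
        "roc_curve": {"fpr": fpr.tolist(), "tpr": tpr.tolist()},
    }


def run_ml(
    X_disc: pd.DataFrame,
    y_disc: np.ndarray,
    X_val: pd.DataFrame,
    y_val: np.ndarray,
    families: tuple[str, ...] = MODEL_FAMILIES,
    k_folds: int = 5,
    seed: int = 0,
    grids: dict[str, dict] | None = None,
) -> dict:
    """Full ML stage: per-family CV grid search, then held-out evaluation.

    Returns a report mapping family -> chosen hyperparameters, CV metrics and
    validation metrics (including ROC points).
    """
    report = {}
    for family in families:
        design = MLDesign(
            model_family=family,
            hyperparameter_grid=(grids or {}).get(family, {}),
            k_folds=k_folds,
            seed=seed,
        )
        best_params, cv_metrics, model = cv_grid_search(design, X_disc, y_disc)
        val_metrics = evaluate_on_validation(
            model, X_val, y_val, train_features=list(X_disc.columns)
        )
        report[family] = {
            "hyperparameters": best_params,
            **cv_metrics,
            **val_metrics,
        }
    return report
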