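"""Treated-vs-untreated nucleus classification from morphology features.

A binary logistic regression on the standard nuclear feature vector
(volumes, intensities, eccentricity, solidity, Euler number, inertia
tensor eigenvalues) evaluated by the area under the ROC curve on a held-out
stratified split.  Standardization is fit on the training split only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

#: Nuclear features used by the classifier.
FEATURE_COLUMNS = (
    "volume",
    "volume_filled",
    "volume_convex",
    "volume_bbox",
    "intensity_mean",
    "intensity_max",
    "intensity_min",
    "eccentricity",
    "solidity",
    "euler_number",
    "inertia_tensor_eigvals_0",
    "inertia_tensor_eigvals_1",
    "inertia_tensor_eigvals_2",
)


@dataclass
class ClassifierResult:
    """Fitted model, held-out AUC and standardized coefficients."""

    auc: float
    coefficients: pd.Series  # per-feature standardized coefficients
    intercept: float
    roc: pd.DataFrame  # fpr, tpr, threshold
    n_train: int
    n_test: int
    dropped_features: tuple[str, ...] = ()
    test_scores: np.ndarray | None = None  # decision scores on the held-out split


def build_feature_matrix(
    nuclei: pd.DataFrame,
    label_col: str = "treated",
    feature_cols: tuple[str, ...] = FEATURE_COLUMNS,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Extract the feature matrix and binary labels, dropping rows with NaNs."""
    cols = [c for c in feature_cols if c in nuclei.columns]
    missing = set(feature_cols) - set(cols)
    if missing:
        logger.warning("feature columns absent from table: %s", sorted(missing))
    sub = nuclei[cols + [label_col]].dropna()
    return sub[cols], sub[label_col].to_numpy()


def split_train_test(
    features: pd.DataFrame,
    labels: np.ndarray,
    train_fraction: float = 0.8,
    seed: int | None = None,
):
    """Stratified random train/test split (default 80/20), seeded."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to split")
    return train_test_split(
        features, labels,
        train_size=train_fraction, stratify=labels, random_state=seed,
    )


def train_eval_logistic(
    X_train: pd.DataFrame,
    X_test: pd.DataFrame,
    y_train: np.ndarray,
    y_test: np.ndarray,
    C: float = 100.0,
) -> ClassifierResult:
    """Fit an L2 logistic regression on standardized features; AUC on the test set.

    Constant feature columns (zero variance on the training split) are
    dropped with a warning.  ``C`` is the inverse regularization strength;
    the default is weak regularization.
    """
    variances = X_train.var(axis=0).to_numpy()
    keep = variances > 0
    dropped = tuple(np.asarray(X_train.columns)[~keep])
    if dropped:
        logger.warning("dropping constant feature column(s): %s", list(dropped))
    cols = list(np.asarray(X_train.columns)[keep])
    scaler = StandardScaler().fit(X_train[cols])
    Ztr = scaler.transform(X_train[cols])
    Zte = scaler.transform(X_test[cols])
    model = LogisticRegression(penalty="l2", C=C, max_iter=5000)
    model.fit(Ztr, y_train)
    scores = model.decision_function(Zte)
    auc = float(roc_auc_score(y_test, scores))
    fpr, tpr, thr = roc_curve(y_test, scores)
    return ClassifierResult(
        auc=auc,
        coefficients=pd.Series(model.coef_[0], index=cols).sort_values(
            key=np.abs, ascending=False
        ),
        intercept=float(model.intercept_[0]),
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        n_train=len(X_train),
        n_test=len(X_test),
        dropped_features=dropped,
        test_scores=scores,
    )


def classify_contrast(
    nuclei: pd.DataFrame,
    label_col: str = "treated",
    train_fraction: float = 0.8,
    seed: int | None = None,
    C: float = 100.0,
) -> ClassifierResult:
    """Convenience wrapper: feature extraction, 80/20 split, fit, AUC."""
    X, y = build_feature_matrix(nuclei, label_col=label_col)
    X_train, X_test, y_train, y_test = split_train_test(X, y, train_fraction, seed)
    return train_eval_logistic(X_train, X_test, y_train, y_test, C=C)
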