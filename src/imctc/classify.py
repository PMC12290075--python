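"""Immunofluorescence rare-cell calling: CK threshold, CD45 classifier,
CTC enumeration.

Candidate CTCs are nucleated cells whose mean cytokeratin (CK) signal rises
more than 6 population standard deviations above the slide-wide mean.  CK+
cells are then split into CD45+/CK+ and CD45-/CK+ phenotypes by a logistic
regression on mean CD45 intensity, trained on a human-annotated subset
(two-thirds train split, 5-fold cross-validation repeated 5 times) and
applied to the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from .errors import InsufficientDataError, InvalidStateError

__all__ = [
    "ClassifierModel",
    "call_ck_positive",
    "fit_cd45_classifier",
    "classify_cd45",
    "enumerate_ctc",
    "summarize_counts",
    "CD45_POS",
    "CD45_NEG",
]

CD45_POS = "CD45+/CK+"
CD45_NEG = "CD45-/CK+"

# Ridge penalty lambda ~ 1e-6 keeps coefficients finite under perfect
# separation (sklearn's C is the inverse regularisation strength).
_RIDGE_C = 1e6


def call_ck_positive(table: pd.DataFrame) -> pd.Series:
    """Per-cell CK positivity: mean CK strictly greater than the slide-wide
    mean plus 6 slide-wide population standard deviations.

    The slide statistics are computed over all cells on the slide (candidate
    cells included).  Slides with a single cell are rejected.
    """
    if {"slide", "mean_ck"} - set(table.columns):
        raise ValueError("table needs 'slide' and 'mean_ck' columns")
    sizes = table.groupby("slide")["mean_ck"].size()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise InsufficientDataError(f"slides with fewer than 2 cells: {bad}")
    grp = table.groupby("slide")["mean_ck"]
    thresh = grp.transform("mean") + 6.0 * grp.transform(lambda s: s.std(ddof=0))
    return table["mean_ck"] > thresh


@dataclass
class ClassifierModel:
    """Logistic model on mean CD45 intensity with its CV record."""

    intercept: float = 0.0
    coef: float = 0.0
    cv_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    cv_mean_accuracy: float = float("nan")
    test_accuracy: float = float("nan")
    train_fraction: float = 2 / 3
    folds: int = 5
    repeats: int = 5
    seed: int = 0
    fitted: bool = False

    def predict_proba(self, cd45: np.ndarray) -> np.ndarray:
        """P(CD45+ | mean CD45 intensity)."""
        if not self.fitted:
            raise InvalidStateError("classifier has not been fitted")
        z = self.intercept + self.coef * np.asarray(cd45, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))

    def to_json(self, path) -> None:
        payload = {
            "intercept": self.intercept,
            "coef": self.coef,
            "cv_mean_accuracy": self.cv_mean_accuracy,
            "test_accuracy": self.test_accuracy,
            "train_fraction": self.train_fraction,
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
            "cv_table": self.cv_table.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            payload = json.load(fh)
        cv = pd.DataFrame(payload.pop("cv_table"))
        return cls(cv_table=cv, fitted=True, **payload)


def fit_cd45_classifier(
    labeled: pd.DataFrame,
    train_fraction: float = 2 / 3,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the CD45 logistic classifier on annotated cells.

    The labeled set is split (stratified) into a training fraction and a
    held-out test set; repeated stratified k-fold CV accuracy is estimated on
    the training split, the final model is refit on the whole training split,
    and held-out accuracy is reported.
    """
    if "annotation" not in labeled.columns or "mean_cd45" not in labeled.columns:
        raise ValueError("table needs 'annotation' and 'mean_cd45' columns")
    y = (labeled["annotation"] == CD45_POS).to_numpy()
    if y.all() or not y.any():
        raise ValueError("both annotation classes must be present")
    X = labeled["mean_cd45"].to_numpy(dtype=float).reshape(-1, 1)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, stratify=y, random_state=seed
    )
    counts = np.bincount(y_tr.astype(int), minlength=2)
    if counts.min() < folds:
        raise InsufficientDataError(
            f"need >= {folds} training cells per class, got {counts.tolist()}"
        )
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    rows = []
    for split_idx, (tr, va) in enumerate(cv.split(X_tr, y_tr)):
        clf = LogisticRegression(C=_RIDGE_C)
        clf.fit(X_tr[tr], y_tr[tr])
        acc = float((clf.predict(X_tr[va]) == y_tr[va]).mean())
        rows.append(
            {
                "repeat": split_idx // folds + 1,
                "fold": split_idx % folds + 1,
                "accuracy": acc,
            }
        )
    cv_table = pd.DataFrame(rows)
    final = LogisticRegression(C=_RIDGE_C)
    final.fit(X_tr, y_tr)
    model = ClassifierModel(
        intercept=float(final.intercept_[0]),
        coef=float(final.coef_[0, 0]),
        cv_table=cv_table,
        cv_mean_accuracy=float(cv_table["accuracy"].mean()),
        train_fraction=train_fraction,
        folds=folds,
        repeats=repeats,
        seed=seed,
        fitted=True,
    )
    model.test_accuracy = float(
        (classify_cd45(model, pd.DataFrame({"mean_cd45": X_te[:, 0]})) == y_te).mean()
    )
    return model


def classify_cd45(model: ClassifierModel, table: pd.DataFrame) -> pd.Series:
    """CD45 positivity per cell: predicted probability strictly above 0.5
    (a cell exactly on the decision boundary is called CD45-)."""
    p = model.predict_proba(table["mean_cd45"].to_numpy(dtype=float))
    return pd.Series(p > 0.5, index=table.index, name="cd45_positive")


def summarize_counts(
    n_ck_positive: int, n_cd45_positive: int, volume_ml: float
) -> dict[str, float]:
    """Per-mL CTC enumeration from raw counts."""
    if volume_ml <= 0:
        raise ValueError("volume_ml must be positive")
    if n_cd45_positive > n_ck_positive:
        raise ValueError("CD45+/CK+ count cannot exceed the CK+ count")
    frac = n_cd45_positive / n_ck_positive if n_ck_positive > 0 else float("nan")
    return {
        "ck_pos_per_ml": n_ck_positive / volume_ml,
        "cd45_pos_ck_pos_per_ml": n_cd45_positive / volume_ml,
        "cd45_neg_ck_pos_per_ml": (n_ck_positive - n_cd45_positive) / volume_ml,
        "cd45_pos_fraction_of_ck_pos": frac,
    }


def enumerate_ctc(
    ck_positive: pd.Series, cd45_positive: pd.Series, volume_ml: float
) -> dict[str, float]:
    """CTC counts and fractions per mL from per-cell CK/CD45 calls.

    ``cd45_positive`` is evaluated within the CK+ subset; the CD45+ fraction
    of CK+ is NaN when no cell is CK+.
    """
    ck = ck_positive.astype(bool)
    cd45 = cd45_positive.astype(bool)
    n_ck = int(ck.sum())
    n_both = int((ck & cd45).sum())
    return summarize_counts(n_ck, n_both, volume_ml)
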