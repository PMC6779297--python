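"""Per-cell-line RBF-kernel SVM classifiers on Morgan fingerprint bits.

One binary classifier is trained per cell line on its balanced
sensitive/resistant compound sets, with fingerprints (radius 8, 1024 bits by
default) as features.  C and gamma are chosen by grid search with internal
stratified cross-validation on accuracy.  Cell lines with fewer than
``min_per_class`` compounds in either class are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .balancing import (
    DEFAULT_BALANCE_RATIO,
    DEFAULT_WARD_HEIGHT,
    BalancingReport,
    balance_classes,
)
from .curation import LCLADatabase, RESISTANT, SENSITIVE
from .errors import DimensionError, TrainingError
from .fingerprints import Fingerprint, morgan_fingerprint
from .fishing import Prediction

__all__ = [
    "CellLineSVM",
    "default_grid",
    "small_grid",
    "ml_eligible_cells",
    "train_cell_svm",
    "predict_cell_svm",
    "train_all_cell_svms",
]

DEFAULT_MIN_PER_CLASS = 20


@dataclass
class CellLineSVM:
    """A trained RBF-SVM for one cell line plus its provenance."""

    cell_line_id: str
    model: SVC = field(repr=False)
    C: float
    gamma: float
    cv_accuracy: float
    training_ids: list[str]
    radius: int
    n_bits: int
    balancing: BalancingReport | None = None


def default_grid() -> dict[str, list[float]]:
    """Standard RBF-SVM grid: C in 2^-5..2^15, gamma in 2^-15..2^3, step 2^2."""
    return {
        "C": [2.0**e for e in range(-5, 16, 2)],
        "gamma": [2.0**e for e in range(-15, 4, 2)],
    }


def small_grid() -> dict[str, list[float]]:
    """Coarse 3x3 grid for quick runs and large sweeps."""
    return {"C": [1.0, 2.0**5, 2.0**10], "gamma": [2.0**-7, 2.0**-3, 2.0]}


def ml_eligible_cells(db: LCLADatabase, min_per_class: int = DEFAULT_MIN_PER_CLASS) -> list[str]:
    """Cell lines with at least min_per_class compounds in EACH class."""
    return [
        cell
        for cell, (sens, res) in db.per_cell_index.items()
        if len(sens) >= min_per_class and len(res) >= min_per_class
    ]


def train_cell_svm(
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int = 5,
    grid: dict[str, list[float]] | None = None,
    seed: int = 0,
    cell_line_id: str = "",
    training_ids: list[str] | None = None,
    radius: int = 8,
    n_bits: int | None = None,
) -> CellLineSVM:
    """Grid-search and fit an RBF SVM on fingerprint rows.

    X is (n_compounds, n_bits) of 0/1; y holds the two class labels.  The
    grid point with the best internal cross-validated accuracy wins; the
    final model is refit on all rows.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_bits is None:
        n_bits = X.shape[1]
    classes = np.unique(y)
    if classes.size < 2:
        raise TrainingError(f"need two classes to train, got {classes.tolist()}")
    grid = grid or default_grid()
    n_min_class = min(np.sum(y == c) for c in classes)
    folds = max(2, min(cv_folds, int(n_min_class)))
    search = GridSearchCV(
        SVC(kernel="rbf"),
        param_grid=grid,
        scoring="accuracy",
        cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed),
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    return CellLineSVM(
        cell_line_id=cell_line_id,
        model=search.best_estimator_,
        C=float(search.best_params_["C"]),
        gamma=float(search.best_params_["gamma"]),
        cv_accuracy=float(search.best_score_),
        training_ids=list(training_ids or []),
        radius=radius,
        n_bits=n_bits,
    )


def predict_cell_svm(
    model: CellLineSVM, fp: Fingerprint, compound_id: str = "query"
) -> Prediction:
    """Label one fingerprint; score is the signed decision-function value."""
    if fp.n_bits != model.n_bits:
        raise DimensionError(
            f"fingerprint has {fp.n_bits} bits, model expects {model.n_bits}"
        )
    x = fp.bits.astype(float)[None, :]
    label = str(model.model.predict(x)[0])
    score = float(model.model.decision_function(x)[0])
    return Prediction(compound_id, model.cell_line_id, score, label, "svm")


def train_all_cell_svms(
    db: LCLADatabase,
    radius: int = 8,
    n_bits: int = 1024,
    min_per_class: int = DEFAULT_MIN_PER_CLASS,
    ratio: float = DEFAULT_BALANCE_RATIO,
    height: float = DEFAULT_WARD_HEIGHT,
    grid: dict[str, list[float]] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    fp_cache: dict[str, Fingerprint] | None = None,
    restrict_to: set[str] | None = None,
) -> dict[str, CellLineSVM]:
    """Balance and train one SVM per ML-eligible cell line.

    ``restrict_to`` limits training compounds to the given ids (the
    cross-validation driver passes each fold's training partition).
    """
    cache = fp_cache if fp_cache is not None else {}

    def fp_of(cid: str) -> Fingerprint:
        if cid not in cache:
            cache[cid] = morgan_fingerprint(db.compounds[cid], radius, n_bits)
        return cache[cid]

    models: dict[str, CellLineSVM] = {}
    for cell, (sens, res) in db.per_cell_index.items():
        if restrict_to is not None:
            sens = [c for c in sens if c in restrict_to]
            res = [c for c in res if c in restrict_to]
        if len(sens) < min_per_class or len(res) < min_per_class:
            continue
        lookup = {c: fp_of(c) for c in [*sens, *res]}
        bal_sens, bal_res, report = balance_classes(
            sens, res, lookup, ratio=ratio, height=height, cell_line_id=cell
        )
        ids = [*bal_sens, *bal_res]
        X = np.stack([lookup[c].bits for c in ids]).astype(float)
        y = np.array([SENSITIVE] * len(bal_sens) + [RESISTANT] * len(bal_res))
        model = train_cell_svm(
            X,
            y,
            cv_folds=cv_folds,
            grid=grid,
            seed=seed,
            cell_line_id=cell,
            training_ids=ids,
            radius=radius,
            n_bits=n_bits,
        )
        model.balancing = report
        models[cell] = model
    return models
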