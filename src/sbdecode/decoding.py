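"""Leakage-aware state decoding: splits, SMOTE, scaling, tuning, evaluation.

Two split regimes mirror the two scientific questions. Within-participant
splits are chronological (first 40% train, 40–50% eval, 50–90% train,
90–100% eval — i.e. the first 80% of each half of the recording trains and
the last 20% evaluates), with the train-side row adjacent to every
train/eval junction removed so neighbouring epochs never cross the split.
Across-participant splits assign whole participants at random, so no
individual contributes to both sides.

Four classifier families are supported: L1-regularized logistic regression
(the primary, interpretable model), RBF-kernel SVC, random forest, and
Gaussian naive Bayes. Hyper-parameters are tuned by grid search with
stratified 5-fold CV on the training side only; standard scaling is fit on
the (rebalanced) training rows only. Class rebalancing uses SMOTE applied
separately per split side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .parcellation import feature_columns

__all__ = [
    "SplitPlan",
    "DecodeResult",
    "within_participant_split",
    "across_participant_split",
    "SMOTESampler",
    "smote_balance",
    "StateDecoder",
    "fit_and_evaluate",
    "feature_importance",
    "DEFAULT_GRIDS",
]

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "lr": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "svc": {"C": [0.01, 0.1, 1.0, 10.0, 100.0],
            "gamma": [0.001, 0.01, 0.1, 1.0]},
    "rf": {"n_estimators": [100, 300], "max_depth": [None, 5, 10],
           "min_samples_split": [2, 10]},
    "gnb": {},
}


@dataclass(frozen=True)
class SplitPlan:
    """Row-index sets defining train/eval membership with leakage guards."""

    train_indices: NDArray[np.int64]
    eval_indices: NDArray[np.int64]
    mode: str  # "within" | "across"
    removed_indices: NDArray[np.int64] = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )

    def __post_init__(self) -> None:
        tr, ev = set(self.train_indices.tolist()), set(self.eval_indices.tolist())
        if tr & ev:
            raise ValueError("train and eval index sets overlap")
        if set(self.removed_indices.tolist()) & (tr | ev):
            raise ValueError("removed rows must not appear in train or eval")


def within_participant_split(table: pd.DataFrame) -> SplitPlan:
    """Chronological 40/10/40/10 layout with junction-row removal.

    The table must contain a single participant's rows sorted by
    ``epoch_idx``. The recording is split in half; in each half the first
    80% of rows train and the last 20% evaluate. At every junction between a
    train block and an eval block the train-side adjacent row is dropped, so
    no eval row is chronologically adjacent to a train row.
    """
    if table["participant"].nunique() != 1:
        raise ValueError("within-participant split expects a single participant")
    idx = np.asarray(table["epoch_idx"])
    if not np.all(np.diff(idx) > 0):
        raise ValueError("rows must be sorted by chronological epoch_idx")
    n = len(table)
    if n < 20:
        raise ValueError("need at least 20 rows for the 40/10/40/10 split")
    b1, b2, b3 = int(0.4 * n), int(0.5 * n), int(0.9 * n)
    train = list(range(0, b1)) + list(range(b2, b3))
    evaluation = list(range(b1, b2)) + list(range(b3, n))
    removed = {b1 - 1, b2, b3 - 1}
    train = np.array(sorted(set(train) - removed), dtype=np.int64)
    return SplitPlan(
        train_indices=train,
        eval_indices=np.array(evaluation, dtype=np.int64),
        mode="within",
        removed_indices=np.array(sorted(removed), dtype=np.int64),
    )


def across_participant_split(
    table: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> SplitPlan:
    """Random participant-level assignment; ~80% of participants train.

    All rows of a participant share the assignment, so no individual ever
    appears on both sides. The training count is round-half-up of
    ``train_fraction × n_participants``, clipped so both sides are non-empty.
    """
    participants = table["participant"].unique()
    if len(participants) < 2:
        raise ValueError("across-participant split needs ≥ 2 participants")
    rng = np.random.default_rng(seed)
    order = rng.permutation(participants)
    n_train = int(np.floor(train_fraction * len(participants) + 0.5))
    n_train = min(max(n_train, 1), len(participants) - 1)
    train_ids = set(order[:n_train].tolist())
    is_train = table["participant"].isin(train_ids).to_numpy()
    return SplitPlan(
        train_indices=np.flatnonzero(is_train).astype(np.int64),
        eval_indices=np.flatnonzero(~is_train).astype(np.int64),
        mode="across",
    )


class SMOTESampler(BaseEstimator):
    """Synthetic minority oversampling (SMOTE).

    Each synthetic observation is a convex combination of a minority row and
    one of its ``k_neighbors`` nearest minority neighbours (Euclidean
    metric), so every synthetic point lies on a segment between two original
    minority rows. Already-balanced input passes through unchanged. If the
    minority class has ≤ ``k_neighbors`` members, k is reduced with a
    warning.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int | None = None):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(
        self, X: NDArray[np.float64], y: NDArray
    ) -> tuple[NDArray[np.float64], NDArray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.shape[0] < 2:
            raise ValueError("SMOTE requires both classes to be present")
        if classes.shape[0] > 2:
            raise ValueError("only binary rebalancing is supported")
        if counts[0] == counts[1]:
            return X, y
        minority = classes[np.argmin(counts)]
        n_extra = int(abs(counts[0] - counts[1]))
        Xm = X[y == minority]
        k = self.k_neighbors
        if Xm.shape[0] <= k:
            k = Xm.shape[0] - 1
            warnings.warn(
                f"minority class has only {Xm.shape[0]} rows; "
                f"reducing SMOTE k_neighbors to {k}",
                stacklevel=2,
            )
        if k < 1:
            raise ValueError("minority class too small for SMOTE (needs ≥ 2 rows)")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
        neighbors = nn.kneighbors(Xm, return_distance=False)[:, 1:]
        rng = np.random.default_rng(self.random_state)
        base = rng.integers(0, Xm.shape[0], size=n_extra)
        pick = neighbors[base, rng.integers(0, k, size=n_extra)]
        lam = rng.uniform(0.0, 1.0, size=(n_extra, 1))
        synthetic = Xm[base] + lam * (Xm[pick] - Xm[base])
        X_out = np.vstack([X, synthetic])
        y_out = np.concatenate([y, np.full(n_extra, minority, dtype=y.dtype)])
        return X_out, y_out


def smote_balance(
    X: NDArray[np.float64],
    y: NDArray,
    k_neighbors: int = 5,
    seed: int | None = None,
) -> tuple[NDArray[np.float64], NDArray]:
    """Functional wrapper around :class:`SMOTESampler`."""
    return SMOTESampler(k_neighbors=k_neighbors, random_state=seed).fit_resample(X, y)


def _make_classifier(family: str, seed: int | None):
    if family == "lr":
        # liblinear with l1_ratio=1.0 is pure L1 (lasso-style sparsity)
        return LogisticRegression(
            solver="liblinear", l1_ratio=1.0, random_state=seed, max_iter=1000
        )
    if family == "svc":
        return SVC(kernel="rbf", random_state=seed)
    if family == "rf":
        return RandomForestClassifier(random_state=seed)
    if family == "gnb":
        return GaussianNB()
    raise ValueError(f"unknown classifier family {family!r}")


class StateDecoder(BaseEstimator, ClassifierMixin):
    """Scaling + grid-searched classifier with train-side-only statistics.

    Parameters
    ----------
    family
        ``"lr"`` (L1 logistic regression, the primary model), ``"svc"``
        (RBF kernel), ``"rf"`` or ``"gnb"``.
    hyper_grid
        Grid-search space; ``None`` selects :data:`DEFAULT_GRIDS`
        (decade-spaced C/gamma, small forest grid, empty for GNB). Ties in
        CV accuracy resolve to the earliest grid point, so grids are ordered
        simplest-first (smallest C first).
    cv_folds
        Stratified CV folds for the grid search (default 5).
    """

    def __init__(
        self,
        family: str = "lr",
        hyper_grid: dict[str, list] | None = None,
        cv_folds: int = 5,
        random_state: int | None = None,
    ):
        self.family = family
        self.hyper_grid = hyper_grid
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X: NDArray[np.float64], y: NDArray) -> "StateDecoder":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        self.classes_ = np.unique(y)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        grid = self.hyper_grid if self.hyper_grid is not None else DEFAULT_GRIDS[self.family]
        base = _make_classifier(self.family, self.random_state)
        if grid:
            cv = StratifiedKFold(
                n_splits=self.cv_folds, shuffle=True, random_state=self.random_state
            )
            search = GridSearchCV(base, grid, scoring="accuracy", cv=cv, refit=True)
            search.fit(Xs, y)
            self.best_params_ = dict(search.best_params_)
            self.classifier_ = search.best_estimator_
        else:
            self.best_params_ = {}
            self.classifier_ = clone(base).fit(Xs, y)
        if self.family == "lr":
            self.coef_ = self.classifier_.coef_.ravel().copy()
        return self

    def predict(self, X: NDArray[np.float64]) -> NDArray:
        check_is_fitted(self, "classifier_")
        return self.classifier_.predict(self.scaler_.transform(X))

    def decision_function(self, X: NDArray[np.float64]) -> NDArray[np.float64]:
        check_is_fitted(self, "classifier_")
        Xs = self.scaler_.transform(X)
        if hasattr(self.classifier_, "decision_function"):
            return self.classifier_.decision_function(Xs)
        proba = self.classifier_.predict_proba(Xs)
        with np.errstate(divide="ignore"):
            return np.log(proba[:, 1]) - np.log(proba[:, 0])

    def score(self, X: NDArray[np.float64], y: NDArray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


@dataclass
class DecodeResult:
    """Evaluation-side outcome of one decoding task.

    ``accuracy`` is the fraction correct on the evaluation rows as
    constructed (including SMOTE-balanced rows when evaluation-side
    rebalancing is on). ``k_correct``/``n_eval`` are the *inference* counts
    fed to the binomial test: the class-balanced accuracy over original
    (non-synthetic) evaluation rows, expressed on a variance-matched
    effective sample size, so duplicated synthetic information never
    inflates statistical evidence.
    """

    accuracy: float
    n_eval: int
    k_correct: int
    predictions: pd.DataFrame  # columns: true, predicted, score, synthetic
    best_hyperparams: dict
    family: str
    coefficients: pd.Series | None = None  # per-feature LR weights

    def __post_init__(self) -> None:
        if not 0 <= self.accuracy <= 1:
            raise ValueError("accuracy must lie in [0, 1]")
        if (self.coefficients is not None) != (self.family == "lr"):
            raise ValueError("coefficients present iff family is 'lr'")


def fit_and_evaluate(
    split: SplitPlan,
    table: pd.DataFrame,
    contrast: tuple[str, str],
    family: str = "lr",
    feature_prefix: str | None = None,
    hyper_grid: dict[str, list] | None = None,
    cv_folds: int = 5,
    smote_eval: bool = True,
    seed: int | None = None,
) -> DecodeResult:
    """Train on the split's training rows and score on its evaluation rows.

    Rows are filtered to the two contrast states; each side is SMOTE-balanced
    separately (the evaluation-side balancing follows the original protocol
    and can be disabled with ``smote_eval=False``); scaling and tuning see
    training data only. Statistical inference counts are always derived from
    original evaluation rows: the class-balanced real-row accuracy on an
    effective n with matching binomial variance (harmonic mean construction),
    so synthetic rows and class imbalance cannot distort the chance-level
    test.
    """
    cols = feature_columns(table, feature_prefix)
    if not cols:
        raise ValueError(f"no feature columns with prefix {feature_prefix!r}")
    state = table["state"].to_numpy()
    in_contrast = np.isin(state, contrast)

    def side(indices: NDArray[np.int64]) -> tuple[NDArray, NDArray]:
        rows = indices[in_contrast[indices]]
        return table.iloc[rows][cols].to_numpy(dtype=float), state[rows]

    X_tr, y_tr = side(split.train_indices)
    X_ev, y_ev = side(split.eval_indices)
    for name, y_side in (("train", y_tr), ("eval", y_ev)):
        present = set(np.unique(y_side))
        if not set(contrast) <= present:
            raise ValueError(f"{name} side is missing contrast states {set(contrast) - present}")
    X_tr, y_tr = smote_balance(X_tr, y_tr, seed=seed)
    n_real = len(y_ev)
    if smote_eval:
        X_ev, y_ev = smote_balance(X_ev, y_ev, seed=None if seed is None else seed + 1)
    synthetic = np.arange(len(y_ev)) >= n_real
    decoder = StateDecoder(
        family=family, hyper_grid=hyper_grid, cv_folds=cv_folds, random_state=seed
    ).fit(X_tr, y_tr)
    pred = decoder.predict(X_ev)
    score = decoder.decision_function(X_ev)
    # class-balanced accuracy over real rows → variance-matched binomial counts
    per_class_acc, inv_n = [], 0.0
    for cls in contrast:
        real_cls = (~synthetic) & (y_ev == cls)
        per_class_acc.append(float(np.mean(pred[real_cls] == cls)))
        inv_n += 1.0 / real_cls.sum()
    balanced_real = float(np.mean(per_class_acc))
    n_binom = max(1, int(round(4.0 / inv_n)))
    k_binom = min(n_binom, max(0, int(round(balanced_real * n_binom))))
    coefs = None
    if family == "lr":
        coefs = pd.Series(decoder.coef_, index=cols, name="coefficient")
    return DecodeResult(
        accuracy=float(np.mean(pred == y_ev)),
        n_eval=n_binom,
        k_correct=k_binom,
        predictions=pd.DataFrame(
            {"true": y_ev, "predicted": pred, "score": score, "synthetic": synthetic}
        ),
        best_hyperparams=decoder.best_params_,
        family=family,
        coefficients=coefs,
    )


def feature_importance(result: DecodeResult) -> pd.DataFrame:
    """Features ranked by absolute logistic-regression coefficient.

    Signed values are preserved: a negative weight means the feature is
    lower (after scaling) in the class the model's positive logit favours.
    """
    if result.family != "lr" or result.coefficients is None:
        raise ValueError("feature importance is defined for the 'lr' family only")
    order = result.coefficients.abs().sort_values(ascending=False, kind="stable").index
    ranked = result.coefficients.loc[order]
    return pd.DataFrame({"feature": ranked.index, "coefficient": ranked.values})
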