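"""Z-score normalization (train-only statistics) and LASSO feature selection.

Selection runs once on the full joint table (all sequences together): an
L1-penalized logistic regression whose penalty is chosen by stratified
10-fold cross-validation minimizing the binomial deviance; the selected
features are those with a nonzero coefficient at the chosen penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .datatypes import SEQUENCES


@dataclass
class NormalizationModel:
    """Per-feature mean/sd learned from training rows only."""

    mean: pd.Series
    sd: pd.Series
    kept_columns: list[str]
    dropped_columns: list[str]


@dataclass
class SelectionResult:
    """Outcome of the penalized selection."""

    c_chosen: float  # inverse regularization strength at the CV optimum
    selected: list[str]
    coefficients: pd.Series  # nonzero coefficients, indexed by feature name
    intercept: float


def zscore_fit(train: pd.DataFrame) -> NormalizationModel:
    """Learn per-column mean and sd; zero-variance columns are dropped."""
    if len(train) < 2:
        raise ValueError("need at least 2 training rows")
    mean = train.mean()
    sd = train.std(ddof=0)
    dropped = list(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance column(s)")
    kept = [c for c in train.columns if c not in dropped]
    return NormalizationModel(mean[kept], sd[kept], kept, dropped)


def zscore_apply(model: NormalizationModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Apply training statistics to any rows (no leakage by construction)."""
    return (rows[model.kept_columns] - model.mean) / model.sd


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    n_cs: int = 30,
) -> SelectionResult:
    """L1 logistic selection with stratified k-fold CV over the penalty grid.

    ``X`` should already be normalized. The penalty minimizing the mean CV
    binomial deviance (neg_log_loss) is retained, and features with nonzero
    coefficients there are returned in column order.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("y must contain both classes")
    if counts.min() < folds:
        raise ValueError(f"need at least {folds} patients per class for {folds}-fold CV")

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=np.logspace(-3, 2, n_cs),
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=2000,
        refit=True,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)  # sklearn CV-attribute transition
        model.fit(X.to_numpy(), y)
    coef = pd.Series(model.coef_.ravel(), index=X.columns)
    nonzero = coef[coef != 0]
    return SelectionResult(
        c_chosen=float(model.C_[0]),
        selected=list(nonzero.index),
        coefficients=nonzero,
        intercept=float(model.intercept_[0]),
    )


def assemble_row(selected_values: dict[str, float]) -> pd.Series:
    """Canonically ordered row of selected features: sequence-major
    (T1W, T2W, T1C, FLAIR), original column order within each sequence.

    Raises if the selection is empty (a weaker penalty is needed).
    """
    if not selected_values:
        raise ValueError("empty selection: rerun selection with a weaker penalty")
    from .extract import FEATURE_NAMES_107

    canon = {n: i for i, n in enumerate(FEATURE_NAMES_107)}

    def key(name: str):
        for rank, seq in enumerate(SEQUENCES):
            if name.startswith(seq + "_"):
                suffix = name[len(seq) + 1 :]
                return (rank, canon.get(suffix, len(canon)), suffix)
        return (len(SEQUENCES), len(canon), name)

    ordered = sorted(selected_values, key=key)
    return pd.Series({n: selected_values[n] for n in ordered})


def assemble_table(table: pd.DataFrame, selected: list[str]) -> pd.DataFrame:
    """Selected-feature table in canonical sequence-major order."""
    dummy = {name: 0.0 for name in selected}
    order = list(assemble_row(dummy).index)
    return table[order].copy()
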