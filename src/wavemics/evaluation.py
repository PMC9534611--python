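"""Classifier benchmarking: repeated stratified cross-validation over the
(filter bank x classifier) grid, best-cell selection, DeLong's paired ROC
test, and the percent-increase comparison rows.

Eight classifier families are compared: SVM, Naive Bayes, multilayer
perceptron, decision tree, AdaBoost, k-nearest neighbours, logistic
regression and random forest, each with fixed documented hyperparameters.
Every fold re-fits the z-score normalization on its training part only, so
no statistic leaks from held-out rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIER_FAMILIES = ("SVM", "NB", "MLP", "DT", "ADA", "KNN", "LR", "RF")

#: positive class for F1 and ROC scores (label 1 = the larger, primary-tumor class)
POSITIVE_LABEL = 1


def make_classifier(family: str, seed: int = 0):
    """Fixed, documented default hyperparameters per family."""
    if family == "SVM":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    if family == "NB":
        return GaussianNB()
    if family == "MLP":
        return MLPClassifier(hidden_layer_sizes=(50,), max_iter=500, random_state=seed)
    if family == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if family == "ADA":
        return AdaBoostClassifier(n_estimators=100, random_state=seed)
    if family == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    if family == "LR":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if family == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown classifier family {family!r}; valid: {CLASSIFIER_FAMILIES}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous score of the positive class: probability when available,
    otherwise the decision-function margin."""
    if hasattr(model, "predict_proba"):
        idx = list(model.classes_).index(POSITIVE_LABEL)
        return model.predict_proba(X)[:, idx]
    return model.decision_function(X)


@dataclass
class EvalResult:
    """Per-(repeats x folds) metric records plus pooled first-repeat scores."""

    records: pd.DataFrame  # columns: repeat, fold, accuracy, auc, f1
    pooled_scores: np.ndarray  # first repeat, aligned to the input rows
    pooled_y: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(self.records["accuracy"].mean())

    @property
    def mean_auc(self) -> float:
        return float(self.records["auc"].mean())

    @property
    def mean_f1(self) -> float:
        return float(self.records["f1"].mean())

    def mean(self, metric: str) -> float:
        return float(self.records[metric].mean())


def repeated_cv(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    family: str,
    folds: int = 5,
    repeats: int = 100,
    seed: int = 0,
) -> EvalResult:
    """Repeated stratified k-fold evaluation of one classifier family.

    Repeat r uses fold seed ``seed + r``; within each fold the features are
    z-scored with training statistics only. The returned means average over
    all repeats x folds; the first repeat's held-out scores are pooled over
    folds for the paired ROC test.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("y must be binary")
    if counts.min() < folds:
        raise ValueError(f"each class needs at least {folds} members")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")

    recs = []
    pooled_scores = np.zeros(len(y))
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for f, (tr, te) in enumerate(skf.split(X, y)):
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (X[tr] - mu) / sd
            Xte = (X[te] - mu) / sd
            model = make_classifier(family, seed=seed + r)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(Xtr, y[tr])
            pred = model.predict(Xte)
            score = _scores(model, Xte)
            recs.append(
                {
                    "repeat": r,
                    "fold": f,
                    "accuracy": accuracy_score(y[te], pred),
                    "auc": roc_auc_score(y[te] == POSITIVE_LABEL, score),
                    "f1": f1_score(y[te], pred, pos_label=POSITIVE_LABEL),
                }
            )
            if r == 0:
                pooled_scores[te] = score
    return EvalResult(pd.DataFrame(recs), pooled_scores, y.copy())


@dataclass
class EvalGrid:
    """(filter bank | 'none') x classifier family -> EvalResult."""

    cells: dict[tuple[str, str], EvalResult] = field(default_factory=dict)

    @property
    def banks(self) -> list[str]:
        return sorted({b for b, _ in self.cells if b != "none"})

    @property
    def families(self) -> list[str]:
        seen = []
        for _, f in self.cells:
            if f not in seen:
                seen.append(f)
        return seen

    def n_wavelet_cells(self) -> int:
        return sum(1 for b, _ in self.cells if b != "none")

    def metric_table(self, metric: str) -> pd.DataFrame:
        """banks x families table of one metric mean (wavelet cells only)."""
        data = {
            fam: {b: self.cells[(b, fam)].mean(metric) for b in self.banks}
            for fam in self.families
        }
        return pd.DataFrame(data).loc[self.banks]

    def plain_table(self) -> pd.DataFrame:
        """families x metrics table for the no-wavelet model."""
        rows = {}
        for (b, fam), res in self.cells.items():
            if b == "none":
                rows[fam] = {
                    "accuracy": res.mean_accuracy,
                    "auc": res.mean_auc,
                    "f1": res.mean_f1,
                }
        return pd.DataFrame(rows).T


def evaluate_grid(
    plain_table: pd.DataFrame,
    profiles: dict[str, pd.DataFrame],
    y: np.ndarray,
    families: tuple[str, ...] = CLASSIFIER_FAMILIES,
    folds: int = 5,
    repeats: int = 100,
    seed: int = 0,
) -> EvalGrid:
    """Evaluate every classifier on the plain features and on each filter
    bank's profile table. Rows of every table must align with ``y``."""
    y = np.asarray(y)
    grid = EvalGrid()
    feature_cols = [c for c in plain_table.columns if c != "label"]
    if len(plain_table) != len(y):
        raise ValueError("plain table rows misaligned with y")
    for fam in families:
        grid.cells[("none", fam)] = repeated_cv(
            plain_table[feature_cols], y, fam, folds, repeats, seed
        )
    for bank, prof in profiles.items():
        if len(prof) != len(y):
            raise ValueError(f"profile table for bank {bank!r} misaligned with y")
        cols = [c for c in prof.columns if c != "label"]
        for fam in families:
            grid.cells[(bank, fam)] = repeated_cv(prof[cols], y, fam, folds, repeats, seed)
    return grid


def select_best(grid: EvalGrid) -> tuple[str, str]:
    """Best wavelet (bank, classifier) cell: argmax mean AUC, ties broken by
    accuracy, then F1, then lexicographically smaller bank id."""
    wavelet_cells = [(b, f) for (b, f) in grid.cells if b != "none"]
    if not wavelet_cells:
        raise ValueError("grid has no wavelet cells")

    def sort_key(cell):
        res = grid.cells[cell]
        # negate bank id ordering via tuple trick: maximize metrics, minimize id
        return (res.mean_auc, res.mean_accuracy, res.mean_f1)

    best_val = max(sort_key(c) for c in wavelet_cells)
    tied = [c for c in wavelet_cells if sort_key(c) == best_val]
    return min(tied)  # lexicographic (bank, family)


def delong_test(scores1: np.ndarray, scores2: np.ndarray, y: np.ndarray) -> float:
    """DeLong's two-sided test for two correlated ROC curves.

    ``scores1``/``scores2`` are the two models' continuous scores on the same
    subjects; ``y`` the binary truth. Identical score vectors give p = 1.
    """
    y = np.asarray(y)
    s1, s2 = np.asarray(scores1, float), np.asarray(scores2, float)
    if not (np.all(np.isfinite(s1)) and np.all(np.isfinite(s2))):
        raise ValueError("scores must be finite")
    pos, neg = y == POSITIVE_LABEL, y != POSITIVE_LABEL
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    aucs, v01s, v10s = [], [], []
    for s in (s1, s2):
        x, yneg = s[pos], s[neg]
        # structural components of the Mann-Whitney estimator
        psi = (x[:, None] > yneg[None, :]).astype(float) + 0.5 * (
            x[:, None] == yneg[None, :]
        )
        aucs.append(psi.mean())
        v10s.append(psi.mean(axis=1))  # per positive subject
        v01s.append(psi.mean(axis=0))  # per negative subject
    aucs = np.array(aucs)
    S10 = np.cov(np.vstack(v10s))
    S01 = np.cov(np.vstack(v01s))
    var = (S10 / m + S01 / n)
    se2 = var[0, 0] + var[1, 1] - 2 * var[0, 1]
    if se2 <= 0:
        return 1.0
    z = (aucs[0] - aucs[1]) / np.sqrt(se2)
    return float(2.0 * stats.norm.sf(abs(z)))


def percent_increase(wavelet_metric: float, plain_metric: float) -> float:
    """Signed percent change 100*(wavelet - plain)/plain, one decimal."""
    if plain_metric <= 0:
        raise ValueError("plain metric must be positive")
    return round(100.0 * (wavelet_metric - plain_metric) / plain_metric, 1)


def comparison_rows(grid: EvalGrid, metric: str = "auc", alpha: float = 0.05) -> pd.DataFrame:
    """Per-classifier comparison of the best wavelet cell against the plain
    model on one metric, with DeLong significance on pooled fold scores."""
    rows = {}
    for fam in grid.families:
        plain = grid.cells.get(("none", fam))
        if plain is None:
            continue
        bank_cells = {b: grid.cells[(b, fam)] for b in grid.banks}
        top = max(res.mean(metric) for res in bank_cells.values())
        best_bank = min(b for b, res in bank_cells.items() if res.mean(metric) == top)
        best = bank_cells[best_bank]
        p = delong_test(best.pooled_scores, plain.pooled_scores, plain.pooled_y)
        rows[fam] = {
            "best_bank": best_bank,
            "wavelet": best.mean(metric),
            "plain": plain.mean(metric),
            "pct_increase": percent_increase(best.mean(metric), plain.mean(metric)),
            "p_value": p,
            "significant": p < alpha,
        }
    return pd.DataFrame(rows).T
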