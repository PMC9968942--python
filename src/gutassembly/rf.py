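"""Random-forest discrimination of sites with Gini importance ranking.

Protocol: features are relative abundances at the chosen rank; a stratified
70/30 train/test split; a forest of 500 trees (the default) trained on the
training set; held-out AUC from predicted class probabilities; and a
repeated stratified 10-fold x 5 cross-validated AUC on the full data
reported alongside (published AUCs are sometimes one and sometimes the
other). Class imbalance is handled by stratification only — no resampling.
All stochastic components (split, folds, forest) derive from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score, train_test_split

from .tables import CountTable, aggregate_by_rank


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr,
                             "threshold": self.thresholds})


def roc_curve(scores, labels, positive=None) -> RocCurve:
    """ROC points (threshold sweep) and trapezoid AUC.

    ``scores`` are probabilities (or any monotone score) for the positive
    class; ``positive`` defaults to the lexicographically larger label. The
    AUC equals the Mann–Whitney U statistic divided by n_pos * n_neg.
    """
    from sklearn import metrics

    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("ROC needs exactly two classes in the labels")
    positive = classes[-1] if positive is None else positive
    y = (labels == positive).astype(int)
    fpr, tpr, thr = metrics.roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


@dataclass
class RfResult:
    """Random-forest site discrimination at one taxonomic rank."""

    rank: str | None
    importances: pd.DataFrame     # taxon, gini, rank (1 = most important)
    auc_test: float               # held-out 30% test set
    roc: RocCurve
    cv_auc_mean: float            # repeated stratified k-fold on all data
    cv_auc_scores: np.ndarray
    n_trees: int
    test_size: float
    cv_folds: int
    cv_repeats: int
    seed: int


def rf_discriminate(
    table: CountTable,
    rank: str | None = None,
    seed: int = 0,
    n_trees: int = 500,
    test_size: float = 0.3,
    cv_folds: int = 10,
    cv_repeats: int = 5,
) -> RfResult:
    """Train and evaluate the site classifier; rank taxa by Gini importance.

    Features are relative abundances with taxa in canonical (sorted) order,
    so importances do not depend on the incoming row order. Gini
    importances come from the forest trained on the 70% training split;
    the cross-validated AUC uses fresh forests on the full data.
    """
    if rank is not None:
        table = aggregate_by_rank(table, rank)
    order = sorted(table.taxon_ids)
    X = table.relative_abundance().loc[order].T.to_numpy()
    y = table.meta["site"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("site discrimination needs exactly two classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples for a stratified split")
    if counts.min() < cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {cv_folds} folds; "
            "stratified folds would lose a class — reduce cv_folds"
        )
    s_split, s_forest, s_cv = (int(v % (2 ** 31)) for v in
                               np.random.SeedSequence(seed).generate_state(3))

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=s_split
    )
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=s_forest)
    forest.fit(X_tr, y_tr)
    positive = forest.classes_[-1]
    proba = forest.predict_proba(X_te)[:, -1]
    roc = roc_curve(proba, y_te, positive=positive)

    cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats,
                                 random_state=s_cv)
    cv_scores = cross_val_score(
        RandomForestClassifier(n_estimators=n_trees, random_state=s_forest),
        X, y, scoring="roc_auc", cv=cv,
    )

    imp = pd.DataFrame({"taxon": order, "gini": forest.feature_importances_})
    imp["rank"] = imp["gini"].rank(ascending=False, method="first").astype(int)
    imp = imp.sort_values("rank").reset_index(drop=True)
    return RfResult(
        rank=getattr(table, "rank", None),
        importances=imp,
        auc_test=roc.auc,
        roc=roc,
        cv_auc_mean=float(cv_scores.mean()),
        cv_auc_scores=np.asarray(cv_scores),
        n_trees=n_trees,
        test_size=test_size,
        cv_folds=cv_folds,
        cv_repeats=cv_repeats,
        seed=seed,
    )
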