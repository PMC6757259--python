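"""Classification-based feature-importance analysis of deleteriousness.

Genes are labelled deleterious when their CRISPR score falls below a cutoff
computed as the midpoint between the lowest CS of the non-essential genes and
the highest CS of the essential genes. Four classifier families that expose
feature importances (linear max-margin SVM, random forest, AdaBoost,
decision tree) are trained on three features — heteromer status, log2 mRNA
expression and log2 interaction-partner count — over repeated random 60/40
train/test splits with bootstrap class balancing on the training portion,
and evaluated by rank-based ROC AUC on the held-out 40%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "DeleteriousnessCutoff",
    "ModelReport",
    "compute_cutoff",
    "label_targets",
    "balance_by_bootstrap",
    "rank_auc",
    "evaluate_models",
    "MODEL_FAMILIES",
]

MODEL_FAMILIES = ("linear_svm", "random_forest", "adaboost", "decision_tree")


@dataclass(frozen=True)
class DeleteriousnessCutoff:
    """CS cutoff c = (min CS of non-essential + max CS of essential) / 2."""

    cutoff: float
    min_cs_nonessential: float
    max_cs_essential: float


@dataclass
class ModelReport:
    """Per-model AUC (mean +/- sd over runs) and normalized importances."""

    auc_mean: Dict[str, float]
    auc_sd: Dict[str, float]
    importances: Dict[str, Dict[str, float]]
    n_runs: int
    seed: int
    feature_names: tuple
    extra: Dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.auc_mean:
            row = {"model": m, "auc_mean": self.auc_mean[m], "auc_sd": self.auc_sd[m]}
            row.update({f"imp_{f}": v for f, v in self.importances[m].items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def top_feature(self, model: str) -> str:
        imp = self.importances[model]
        return max(imp, key=imp.get)


def compute_cutoff(
    cs: pd.Series, essential: set, nonessential: set
) -> DeleteriousnessCutoff:
    """Midpoint between the non-essential minimum and the essential maximum CS."""
    ess = cs.loc[cs.index.intersection(pd.Index(sorted(essential)))].dropna()
    non = cs.loc[cs.index.intersection(pd.Index(sorted(nonessential)))].dropna()
    if ess.empty or non.empty:
        raise ValueError("essential and non-essential sets must both be scored")
    lo_non = float(non.min())
    hi_ess = float(ess.max())
    return DeleteriousnessCutoff(cutoff=(lo_non + hi_ess) / 2.0,
                                 min_cs_nonessential=lo_non, max_cs_essential=hi_ess)


def label_targets(cs: pd.Series, cutoff: DeleteriousnessCutoff) -> pd.Series:
    """Binary target: deleterious iff CS strictly below the cutoff.

    A gene exactly at the cutoff is non-deleterious (strict inequality).
    """
    y = (cs < cutoff.cutoff).astype(int)
    y.name = "deleterious"
    n1, n0 = int(y.sum()), int((1 - y).sum())
    logger.info("labelled %d deleterious / %d non-deleterious genes", n1, n0)
    return y


def balance_by_bootstrap(
    features: pd.DataFrame, y: pd.Series, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Balance classes by resampling the larger class, with replacement,
    down to the smaller class's size; the smaller class is kept whole."""
    classes = y.value_counts()  # sorted by count, descending
    if len(classes) < 2:
        raise ValueError("need two classes to balance")
    big, small = classes.index[0], classes.index[1]
    if classes.min() < 5:
        logger.warning("smallest class has only %d members", classes.min())
    idx_small = y.index[y == small]
    idx_big = y.index[y == big]
    take = rng.choice(idx_big.to_numpy(), size=len(idx_small), replace=True)
    idx = np.concatenate([idx_small.to_numpy(), take])
    return features.loc[idx], y.loc[idx]


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC by the rank (Mann-Whitney) method, ties handled by mid-ranks."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, float)
    pos = y_true == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes in the test set")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _make_model(name: str, seed: int):
    if name == "linear_svm":
        return LinearSVC(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown model family {name!r}")


def _importances(name: str, model, X_train: np.ndarray) -> np.ndarray:
    if name == "linear_svm":
        # absolute coefficients on z-scored features
        imp = np.abs(model.coef_).ravel()
    else:
        imp = np.asarray(model.feature_importances_, float)
    total = imp.sum()
    return imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))


def evaluate_models(
    features: pd.DataFrame,
    y: pd.Series,
    seed: int = 0,
    n_splits: int = 5,
    test_size: float = 0.4,
    n_bootstrap: int = 2,
    strict_kfold: bool = False,
) -> ModelReport:
    """Train the four classifier families and report AUC and importances.

    Default protocol: ``n_splits`` repeated random splits holding out
    ``test_size`` of the genes, with ``n_bootstrap`` bootstrap-balanced
    training sets per split (balancing applied to the training portion only,
    so the held-out set is untouched). ``strict_kfold=True`` switches to a
    plain 5-fold partition instead of repeated 60/40 splits. Importances are
    impurity-based for the tree models and absolute standardized coefficients
    for the linear model, normalized to sum to one. Identical seeds give
    identical reports.
    """
    if set(y.unique()) - {0, 1}:
        raise ValueError("y must be binary 0/1")
    if y.nunique() < 2:
        raise ValueError("single-class target; nothing to classify")
    feats = features.loc[y.index]
    names = tuple(features.columns)
    rng = np.random.default_rng(seed)

    if strict_kfold:
        from sklearn.model_selection import StratifiedKFold

        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        split_iter = [(feats.index[tr], feats.index[te])
                      for tr, te in splitter.split(feats, y)]
    else:
        split_iter = []
        for s in range(n_splits):
            for attempt in range(20):
                tr, te = train_test_split(
                    feats.index, test_size=test_size,
                    random_state=int(rng.integers(2**31 - 1)), stratify=y,
                )
                if y.loc[tr].nunique() == 2 and y.loc[te].nunique() == 2:
                    break
                logger.info("single-class fold redrawn (attempt %d)", attempt + 1)
            split_iter.append((tr, te))

    aucs = {m: [] for m in MODEL_FAMILIES}
    imps = {m: [] for m in MODEL_FAMILIES}
    for tr_idx, te_idx in split_iter:
        X_te = feats.loc[te_idx].to_numpy(float)
        y_te = y.loc[te_idx].to_numpy()
        for _ in range(n_bootstrap):
            Xb, yb = balance_by_bootstrap(feats.loc[tr_idx], y.loc[tr_idx], rng)
            Xb_arr = Xb.to_numpy(float)
            mu, sd = Xb_arr.mean(axis=0), Xb_arr.std(axis=0)
            sd[sd == 0] = 1.0
            for m in MODEL_FAMILIES:
                model = _make_model(m, int(rng.integers(2**31 - 1)))
                if m == "linear_svm":
                    model.fit((Xb_arr - mu) / sd, yb.to_numpy())
                    scores = model.decision_function((X_te - mu) / sd)
                else:
                    model.fit(Xb_arr, yb.to_numpy())
                    scores = model.predict_proba(X_te)[:, 1]
                aucs[m].append(rank_auc(y_te, scores))
                imps[m].append(_importances(m, model, Xb_arr))

    auc_mean = {m: float(np.mean(v)) for m, v in aucs.items()}
    auc_sd = {m: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for m, v in aucs.items()}
    importances = {}
    for m in MODEL_FAMILIES:
        mean_imp = np.mean(imps[m], axis=0)
        mean_imp = mean_imp / mean_imp.sum()
        importances[m] = {f: float(v) for f, v in zip(names, mean_imp)}
    return ModelReport(
        auc_mean=auc_mean,
        auc_sd=auc_sd,
        importances=importances,
        n_runs=len(split_iter) * n_bootstrap,
        seed=seed,
        feature_names=names,
    )
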