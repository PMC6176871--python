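"""Cross-species cell-type label transfer with random forests.

Human/mouse (or any two-species) expression is reconciled through a strict
one-to-one ortholog bijection (multi-mapping rows removed, minimum 75%
sequence identity).  Training classes are balanced by down-sampling the
majority clusters and SMOTE up-sampling of minority clusters (interpolation
between same-class nearest neighbors, k = 5).  Features are pruned by
recursive feature elimination with 10-fold cross-validation; the final
forest uses 1000 trees with mtry = floor(sqrt(p)).  Evaluation reports
row-normalized confusion matrices, one-vs-rest AUCs from vote fractions,
and per-cluster marker-specificity profiles comparable across species.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger("stromatlas")


@dataclass
class RFParams:
    ntree: int = 1000
    mtry_rule: str = "sqrt"
    cv_folds: int = 10
    smote_k: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.ntree < 1 or self.cv_folds < 2:
            raise ValueError("ntree must be >= 1 and cv_folds >= 2")


@dataclass
class ClassifierModel:
    forest: RandomForestClassifier
    features: list
    classes: list
    params: RFParams
    oob_error: float | None = None
    metadata: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise ValueError(f"query lacks {len(missing)} model features, "
                             f"e.g. {missing[:5]}")
        return self.forest.predict(X[self.features].to_numpy())

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise ValueError(f"query lacks {len(missing)} model features, "
                             f"e.g. {missing[:5]}")
        return self.forest.predict_proba(X[self.features].to_numpy())


# ---------------------------------------------------------------------------
# ortholog filtering
# ---------------------------------------------------------------------------

def filter_orthologs(omap: pd.DataFrame, min_identity: float = 75.0) -> pd.DataFrame:
    """Reduce an ortholog map to a high-identity one-to-one bijection.

    Only ``one2one`` rows survive; rows with any available directional
    identity below ``min_identity`` are dropped (conservative: the minimum
    of the two directions must reach the cutoff); genes still mapping more
    than once are removed so the result is a bijection.
    """
    required = {"gene_A", "gene_B", "homology_class"}
    if not required.issubset(omap.columns):
        raise ValueError(f"ortholog map missing columns {required - set(omap.columns)}")
    m = omap[omap["homology_class"] == "one2one"].copy()
    for col in ("pct_identity_AtoB", "pct_identity_BtoA"):
        if col in m.columns:
            m = m[m[col].isna() | (m[col] >= min_identity)]
    m = m[~m["gene_A"].duplicated(keep=False)]
    m = m[~m["gene_B"].duplicated(keep=False)]
    return m.reset_index(drop=True)


# ---------------------------------------------------------------------------
# class balancing (down-sampling + SMOTE)
# ---------------------------------------------------------------------------

def balance_classes(features: np.ndarray, labels, target_per_class=None,
                    smote_k: int = 5, seed: int = 0):
    """Equalize class sizes by down-sampling and SMOTE up-sampling.

    Majority classes are down-sampled without replacement to the target
    (default: the median class size); minority classes are up-sampled with
    synthetic points ``x + lam * (x_nn - x)``, ``lam ~ U(0, 1)``, where
    ``x_nn`` is one of the ``smote_k`` Euclidean nearest same-class
    neighbors.  Returns ``(features, labels)`` with exactly equal counts.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 members for SMOTE")
    target = int(target_per_class if target_per_class is not None
                 else np.median(counts))
    out_X, out_y = [], []
    for cl, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == cl)
        Xc = X[idx]
        if cnt >= target:
            pick = rng.choice(cnt, target, replace=False)
            out_X.append(Xc[pick])
        else:
            k = smote_k
            if k >= cnt:
                warnings.warn(f"smote_k={smote_k} clamped to {cnt - 1} "
                              f"for class {cl!r}")
                k = cnt - 1
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            _, nbrs = nn.kneighbors(Xc)          # col 0 = self
            need = target - cnt
            base = rng.integers(0, cnt, need)
            pick_nn = nbrs[base, rng.integers(1, k + 1, need)]
            lam = rng.uniform(0.0, 1.0, need)[:, None]
            synth = Xc[base] + lam * (Xc[pick_nn] - Xc[base])
            out_X.append(np.vstack([Xc, synth]))
        out_y.append(np.repeat(cl, target))
    return np.vstack(out_X), np.concatenate(out_y)


# ---------------------------------------------------------------------------
# recursive feature elimination with cross-validation
# ---------------------------------------------------------------------------

def rfe_select(features: np.ndarray, labels, params: RFParams | None = None,
               sizes_schedule=None, feature_names=None):
    """Recursive feature elimination: drop lowest-importance features stepwise.

    At each size in the (descending) schedule, a forest ranks the surviving
    features by impurity importance, the lowest are dropped, and the subset
    is scored by stratified 10-fold CV accuracy.  The selected set is the
    *smallest* size whose CV accuracy lies within one SD of the best.
    Returns ``(selected feature names, survey DataFrame)``.
    """
    params = params or RFParams()
    params.validate()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    p = X.shape[1]
    names = np.asarray(feature_names if feature_names is not None
                       else np.arange(p))
    if X.shape[0] < params.cv_folds:
        raise ValueError("fewer cells than CV folds")
    schedule = sorted(set(int(s) for s in (sizes_schedule or [p])),
                      reverse=True)
    if schedule[0] > p:
        raise ValueError("schedule exceeds the feature count")
    current = np.arange(p)
    survey = []
    subsets = {}
    for size in schedule:
        if size < current.size:
            forest = RandomForestClassifier(
                n_estimators=params.ntree, max_features="sqrt",
                random_state=params.seed, n_jobs=1)
            forest.fit(X[:, current], y)
            order = np.argsort(forest.feature_importances_)[::-1]
            current = current[order[:size]]
        cv = StratifiedKFold(params.cv_folds, shuffle=True,
                             random_state=params.seed)
        scores = cross_val_score(
            RandomForestClassifier(n_estimators=params.ntree,
                                   max_features="sqrt",
                                   random_state=params.seed, n_jobs=1),
            X[:, current], y, cv=cv)
        survey.append({"size": size, "cv_mean": float(scores.mean()),
                       "cv_sd": float(scores.std(ddof=1))})
        subsets[size] = current.copy()
    df = pd.DataFrame(survey)
    best = df.loc[df["cv_mean"].idxmax()]
    ok = df[df["cv_mean"] >= best["cv_mean"] - best["cv_sd"]]
    chosen = int(ok["size"].min())
    log.info("rfe_select: chose %d features (best %.3f at %d)", chosen,
             best["cv_mean"], int(best["size"]))
    return names[subsets[chosen]].tolist(), df


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

def train_rf(features, labels, params: RFParams | None = None,
             feature_names=None) -> ClassifierModel:
    """Train the forest: ntree trees, mtry = floor(sqrt(p)), OOB error."""
    params = params or RFParams()
    params.validate()
    if isinstance(features, pd.DataFrame):
        feature_names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        feature_names = list(feature_names if feature_names is not None
                             else range(X.shape[1]))
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    mtry = max(1, int(np.floor(np.sqrt(X.shape[1]))))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        forest = RandomForestClassifier(
            n_estimators=params.ntree, max_features=mtry, oob_score=True,
            random_state=params.seed, n_jobs=1).fit(X, y)
    oob = 1.0 - float(forest.oob_score_)
    return ClassifierModel(forest, feature_names,
                           forest.classes_.tolist(), params, oob_error=oob,
                           metadata={"mtry": mtry, "n_train": len(y)})


def classify_and_confuse(model: ClassifierModel, features: pd.DataFrame,
                         true_labels):
    """Predict and summarize: row-normalized confusion + one-vs-rest AUC.

    Confusion rows (true classes) sum to 1; AUC per class is computed from
    the forest vote fractions against one-vs-rest truth.  Query classes
    absent from the model get confusion rows but no AUC.
    """
    y = np.asarray(true_labels)
    pred = model.predict(features)
    proba = model.predict_proba(features)
    true_classes = list(pd.unique(y))
    conf = pd.DataFrame(0.0, index=true_classes, columns=model.classes)
    for tc in true_classes:
        m = y == tc
        for pc in model.classes:
            conf.loc[tc, pc] = float(np.mean(pred[m] == pc))
    aucs = {}
    for i, cl in enumerate(model.classes):
        truth = (y == cl).astype(int)
        if truth.sum() in (0, len(truth)):
            aucs[cl] = np.nan
            continue
        r = rankdata(proba[:, i])
        n1 = truth.sum()
        aucs[cl] = float((r[truth == 1].sum() - n1 * (n1 + 1) / 2)
                         / (n1 * (len(truth) - n1)))
    return pred, conf, pd.Series(aucs, name="auc")


def feature_specificity(expr: np.ndarray, labels, feature_idx=None) -> pd.DataFrame:
    """One-vs-rest AUC of each feature for each cluster (0.5 = nonspecific).

    ``expr`` is features x cells.  Values above 0.5 mark positive cluster
    markers, below 0.5 negative markers.
    """
    X = np.asarray(expr, dtype=float)
    y = np.asarray(labels)
    rows = feature_idx if feature_idx is not None else np.arange(X.shape[0])
    clusters = list(pd.unique(y))
    out = np.empty((len(rows), len(clusters)))
    for i, g in enumerate(rows):
        r = rankdata(X[g])
        for j, cl in enumerate(clusters):
            m = y == cl
            n1 = int(m.sum())
            n0 = len(y) - n1
            if n1 == 0 or n0 == 0 or np.ptp(X[g]) == 0:
                out[i, j] = 0.5
            else:
                out[i, j] = (r[m].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return pd.DataFrame(out, index=np.asarray(rows), columns=clusters)


def specificity_correlation(spec_a: pd.DataFrame,
                            spec_b: pd.DataFrame) -> pd.Series:
    """Per-cluster Pearson correlation between two species' specificity
    profiles (rows must be aligned ortholog features, columns clusters)."""
    shared = [c for c in spec_a.columns if c in spec_b.columns]
    vals = {}
    for cl in shared:
        a = spec_a[cl].to_numpy()
        b = spec_b[cl].to_numpy()
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            vals[cl] = np.nan
        else:
            vals[cl] = float(pearsonr(a, b)[0])
    return pd.Series(vals, name="specificity_correlation")
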