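"""LASSO-selected NCM predictors of cluster enrichment.

Clusters act as sequence families: each qualifying cluster contributes a
row whose predictors are the mean per-sequence normalized NCM frequencies
over (up to) ``max_members`` sampled members, and whose binary label says
whether the cluster enriched between the compared rounds (ratio above the
minimal two-sequence threshold) or depleted (ratio below 1); intermediate
clusters are excluded and the training set is balanced 1:1 by seeded
downsampling.

The L1 penalty is chosen by stratified cross-validated log-loss with the
one-standard-error rule (most regularized model within one SE of the
best).  Log-odds, 95% CIs and p-values come from an unpenalized refit on
the active set; they are post-selection values and are labeled as such.
Because greedy clustering depends on the visiting order, the whole
selection is repeated over reclusterings and predictors are retained only
when they recur in at least ``stability_min`` of them with a significant
refit p-value.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .clustering import NeighborIndex, cluster_enrichment, greedy_cluster
from .folding import ReferenceBackend
from .ncm import sequence_ncm_profile

__all__ = [
    "ClusterDesign",
    "LassoSelection",
    "SelectedPredictor",
    "BinderModel",
    "cluster_ncm_features",
    "build_design",
    "lasso_select",
    "lasso_path_active_sets",
    "stable_predictors",
    "binder_classifier",
    "enrichment_prediction_auc",
]


@dataclass
class ClusterDesign:
    X: pd.DataFrame  # rows: clusters, columns: NCM labels
    y: pd.Series  # 1 enriched, 0 depleted
    cluster_ids: list[int]


def cluster_ncm_features(cluster, backend=None, max_members: int = 500,
                         seed: int = 0, representation: str = "mfe") -> dict[str, float]:
    """Mean per-sequence normalized NCM frequency vector of a cluster."""
    backend = backend or ReferenceBackend()
    seqs = sorted(cluster.members)
    if len(seqs) > max_members:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(seqs), size=max_members, replace=False)
        seqs = [seqs[i] for i in sorted(idx)]
    acc: Counter = Counter()
    for s in seqs:
        for lab, f in sequence_ncm_profile(s, backend, representation).items():
            acc[lab] += f
    return {lab: v / len(seqs) for lab, v in acc.items()}


def build_design(clusters, round_late: str, round_early: str,
                 round_totals: dict[str, int], backend=None,
                 min_cluster_size: int = 100, max_members: int = 500,
                 seed: int = 0, balance: bool = True) -> ClusterDesign:
    """Assemble the balanced cluster-level design matrix.

    Clusters must exceed ``min_cluster_size`` distinct sequences and hold
    reads from both compared rounds.  Label 1 requires the enrichment
    ratio to exceed the minimal two-sequence threshold strictly; label 0
    requires ratio < 1; anything between is excluded.
    """
    backend = backend or ReferenceBackend()
    rows, labels, ids = [], [], []
    for cl in clusters:
        if cl.size <= min_cluster_size:
            continue
        enr = cluster_enrichment(cl, round_late, round_early, round_totals)
        if enr.label == "enriched":
            y = 1
        elif enr.label == "depleted":
            y = 0
        else:
            continue
        rows.append(cluster_ncm_features(cl, backend, max_members, seed=seed))
        labels.append(y)
        ids.append(cl.cluster_id)
    if not rows:
        raise ValueError("no clusters pass the size and round-presence filters")
    X = pd.DataFrame(rows, index=ids).fillna(0.0).sort_index(axis=1)
    y = pd.Series(labels, index=ids, name="enriched")
    if balance:
        rng = np.random.default_rng(seed)
        pos = y.index[y == 1]
        neg = y.index[y == 0]
        k = min(len(pos), len(neg))
        keep = sorted(
            list(rng.choice(pos, size=k, replace=False))
            + list(rng.choice(neg, size=k, replace=False))
        )
        X, y = X.loc[keep], y.loc[keep]
    return ClusterDesign(X=X, y=y, cluster_ids=list(X.index))


@dataclass
class LassoSelection:
    active: list[str]
    log_odds: dict[str, float]
    ci_95: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    chosen_C: float
    separation: bool = False


def _standardize(X: pd.DataFrame) -> np.ndarray:
    mu = X.values.mean(axis=0)
    sd = X.values.std(axis=0)
    sd[sd == 0] = 1.0
    return (X.values - mu) / sd


def lasso_select(design: ClusterDesign, seed: int = 0, cv: int = 10,
                 Cs=None) -> LassoSelection:
    """L1-penalized predictor selection with an unpenalized refit.

    The penalty is picked by cross-validated log-loss with the 1-SE rule;
    the active (nonzero-coefficient) labels are then refit without
    penalty to obtain log-odds, 95% CIs and (post-selection) p-values.
    """
    X, y = design.X, design.y
    if len(y) < 10:
        raise ValueError("need >= 10 design rows")
    if y.nunique() < 2:
        raise ValueError("both enriched and depleted clusters are required")
    if Cs is None:
        Cs = np.logspace(-2, 3, 20)
    n_splits = min(cv, int(y.value_counts().min()))
    skf = StratifiedKFold(n_splits=max(2, n_splits), shuffle=True,
                          random_state=seed)
    Xs = _standardize(X)
    clf = LogisticRegressionCV(
        Cs=Cs, cv=skf, l1_ratios=[1.0], solver="liblinear",
        scoring="neg_log_loss", refit=False, random_state=seed,
        use_legacy_attributes=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xs, y.values)
    scores = clf.scores_[:, 0, :]  # (n_folds, n_Cs)
    mean = scores.mean(axis=0)
    se = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
    best = int(np.argmax(mean))
    # smallest C (strongest penalty) within one SE of the best mean score
    ok = np.nonzero(mean >= mean[best] - se[best])[0]
    chosen = float(np.asarray(Cs)[ok[0]])
    fit = LogisticRegression(C=chosen, l1_ratio=1.0, solver="liblinear",
                             random_state=seed)
    fit.fit(Xs, y.values)
    active = [c for c, b in zip(X.columns, fit.coef_.ravel()) if b != 0.0]
    sel = LassoSelection(active=active, log_odds={}, ci_95={}, p_values={},
                         chosen_C=chosen)
    if not active:
        return sel
    Xa = sm.add_constant(X[active].values)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y.values, Xa).fit(disp=0, maxiter=200)
            params = res.params[1:]
            ci = res.conf_int()[1:]
            pvals = res.pvalues[1:]
            if not np.all(np.isfinite(res.bse)):
                separation = True
        except Exception:
            separation = True
            params = np.full(len(active), np.nan)
            ci = np.full((len(active), 2), np.nan)
            pvals = np.full(len(active), np.nan)
    for i, lab in enumerate(active):
        if separation and not np.isfinite(params[i]):
            sel.log_odds[lab] = float("nan")
            sel.ci_95[lab] = (float("-inf"), float("inf"))
            sel.p_values[lab] = float("nan")
        else:
            sel.log_odds[lab] = float(params[i])
            lo, hi = float(ci[i][0]), float(ci[i][1])
            if separation:
                lo, hi = float("-inf"), float("inf")
            sel.ci_95[lab] = (lo, hi)
            sel.p_values[lab] = float(pvals[i])
    sel.separation = separation
    return sel


def lasso_path_active_sets(design: ClusterDesign, Cs, seed: int = 0):
    """Active set per penalty value (ascending C = decreasing penalty)."""
    Xs = _standardize(design.X)
    out = []
    for C in Cs:
        fit = LogisticRegression(C=float(C), l1_ratio=1.0, solver="liblinear",
                                 random_state=seed)
        fit.fit(Xs, design.y.values)
        out.append(
            {c for c, b in zip(design.X.columns, fit.coef_.ravel()) if b != 0.0}
        )
    return out


@dataclass
class SelectedPredictor:
    label: str
    log_odds: float
    ci_95: tuple[float, float]
    p_value: float
    stability_count: int
    n_reclusterings: int


def stable_predictors(pools, round_late: str, round_early: str,
                      round_totals: dict[str, int], backend=None,
                      n_reclusterings: int = 5, stability_min: int = 3,
                      p_max: float = 0.01, identity_threshold: float = 0.85,
                      min_cluster_size: int = 100, max_members: int = 500,
                      seed: int = 0) -> list[SelectedPredictor]:
    """Predictors that survive reclustering.

    Reclusters the pools with distinct visiting orders, runs the LASSO
    selection on each, and keeps predictors that are active with a
    significant refit p-value in at least ``stability_min`` reclusterings.
    """
    if n_reclusterings < stability_min:
        raise ValueError("n_reclusterings must be >= stability_min")
    backend = backend or ReferenceBackend()
    seqs = sorted({s for p in pools for s in p.counts})
    index = NeighborIndex(seqs, identity_threshold)
    hits: dict[str, int] = defaultdict(int)
    first_fit: dict[str, tuple[float, tuple[float, float], float]] = {}
    for i in range(n_reclusterings):
        clusters = greedy_cluster(pools, identity_threshold=identity_threshold,
                                  order_seed=seed + i, neighbors=index)
        design = build_design(clusters, round_late, round_early, round_totals,
                              backend=backend, min_cluster_size=min_cluster_size,
                              max_members=max_members, seed=seed + i)
        sel = lasso_select(design, seed=seed + i)
        for lab in sel.active:
            p = sel.p_values.get(lab, float("nan"))
            if np.isfinite(p) and p < p_max:
                hits[lab] += 1
                if lab not in first_fit:
                    first_fit[lab] = (
                        sel.log_odds[lab], sel.ci_95[lab], p,
                    )
    out = []
    for lab in sorted(hits):
        if hits[lab] >= stability_min:
            lo, ci, p = first_fit[lab]
            out.append(
                SelectedPredictor(lab, lo, ci, p, hits[lab], n_reclusterings)
            )
    return out


@dataclass
class BinderModel:
    labels: list[str]  # feature columns actually used
    model: LogisticRegression
    cv_auc: float
    dropped: list[str]

    def features(self, sequences, backend=None) -> np.ndarray:
        backend = backend or ReferenceBackend()
        mat = np.zeros((len(sequences), len(self.labels)))
        for r, s in enumerate(sequences):
            prof = sequence_ncm_profile(s, backend)
            for c, lab in enumerate(self.labels):
                mat[r, c] = prof.get(lab, 0.0)
        return mat

    def predict_proba(self, sequences, backend=None) -> np.ndarray:
        return self.model.predict_proba(self.features(sequences, backend))[:, 1]


def binder_classifier(positives, negatives, predictor_labels, backend=None,
                      seed: int = 0, cv: int = 5) -> BinderModel:
    """Logistic binder-vs-background classifier on NCM frequency features.

    Features are restricted to ``predictor_labels`` (from the enrichment
    or LASSO analysis); all-zero columns are dropped with a warning.
    Returns the fitted model with its stratified cross-validated AUC.
    """
    positives, negatives = list(positives), list(negatives)
    if len(positives) < 5:
        raise ValueError("need >= 5 positive sequences")
    labels = list(predictor_labels)
    backend = backend or ReferenceBackend()
    seqs = positives + negatives
    y = np.array([1] * len(positives) + [0] * len(negatives))
    mat = np.zeros((len(seqs), len(labels)))
    for r, s in enumerate(seqs):
        prof = sequence_ncm_profile(s, backend)
        for c, lab in enumerate(labels):
            mat[r, c] = prof.get(lab, 0.0)
    nonzero = mat.any(axis=0)
    dropped = [lab for lab, keep in zip(labels, nonzero) if not keep]
    if dropped:
        warnings.warn(f"dropping all-zero NCM feature columns: {dropped}")
    kept = [lab for lab, keep in zip(labels, nonzero) if keep]
    mat = mat[:, nonzero]
    if not kept:
        raise ValueError("no informative NCM features remain")
    skf = StratifiedKFold(n_splits=min(cv, min(np.bincount(y))), shuffle=True,
                          random_state=seed)
    model = LogisticRegression(max_iter=1000, random_state=seed)
    aucs = cross_val_score(model, mat, y, cv=skf, scoring="roc_auc")
    model.fit(mat, y)
    return BinderModel(labels=kept, model=model, cv_auc=float(aucs.mean()),
                       dropped=dropped)


def enrichment_prediction_auc(pools, round_mid: str, round_late: str,
                              round_early: str, round_totals: dict[str, int],
                              backend=None, n_reclusterings: int = 5,
                              identity_threshold: float = 0.85,
                              min_cluster_size: int = 100,
                              max_members: int = 500, seed: int = 0) -> float:
    """Whether a model of mid-round enrichment predicts late-round
    enrichment of the same clusters; AUC averaged over reclusterings."""
    backend = backend or ReferenceBackend()
    seqs = sorted({s for p in pools for s in p.counts})
    index = NeighborIndex(seqs, identity_threshold)
    aucs = []
    for i in range(n_reclusterings):
        clusters = greedy_cluster(pools, identity_threshold=identity_threshold,
                                  order_seed=seed + i, neighbors=index)
        by_id = {c.cluster_id: c for c in clusters}
        train = build_design(clusters, round_mid, round_early, round_totals,
                             backend=backend, min_cluster_size=min_cluster_size,
                             max_members=max_members, seed=seed + i)
        test = build_design(clusters, round_late, round_early, round_totals,
                            backend=backend, min_cluster_size=min_cluster_size,
                            max_members=max_members, seed=seed + i,
                            balance=False)
        sel = lasso_select(train, seed=seed + i)
        cols = sel.active or list(train.X.columns)
        model = LogisticRegression(max_iter=1000, random_state=seed + i)
        model.fit(train.X[cols].values, train.y.values)
        Xt = test.X.reindex(columns=cols, fill_value=0.0)
        if test.y.nunique() < 2:
            raise ValueError("test labels are single-class")
        scores = model.predict_proba(Xt.values)[:, 1]
        aucs.append(roc_auc_score(test.y.values, scores))
    return float(np.mean(aucs))
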