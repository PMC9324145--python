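"""The 13 filter/embedded feature selectors and the selection-threshold
rules.

Four families:

* information-theoretic (TI): MIM, MIFS, MRMR, JMI, CMIM — plug-in mutual
  information after equal-width discretization; all but MIM run greedy
  forward selection against the already-selected set S;
* similarity (SIF): Fisher score, Laplacian score (LS, reported as 1 - LS
  so higher is better), ReliefF;
* statistical (STF): F-score (FS) and T-score (TS) for two-class problems;
* sparse/streaming learning (SSL): MCFS (spectral embedding + per-component
  L1 regressions, score = max |coefficient|), Alpha investing (streaming
  logistic deviance test with a wealth-driven threshold), Lasso
  (L1-penalized logistic regression, score = |coefficient|).

Selection rule: Lasso keeps |coefficient| > 0.02; every other method keeps
features whose min-max-normalized score exceeds 0.9; both are truncated to
at most 20 features (ties broken by table column order).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import eigh
from sklearn.linear_model import Lasso as SkLasso, LogisticRegression

__all__ = [
    "SelectorParams", "FeatureSet", "ALL_METHODS",
    "mutual_information", "conditional_mutual_information",
    "score_features_ti", "score_features_sif", "score_features_stf",
    "score_features_ssl", "apply_selection_rule", "select_features",
]

log = logging.getLogger(__name__)

ALL_METHODS = ("CMIM", "JMI", "MIFS", "MIM", "MRMR", "Fisher", "LS",
               "ReliefF", "FS", "TS", "MCFS", "Alpha", "Lasso")

_TI = {"MIM", "MIFS", "MRMR", "JMI", "CMIM"}
_SIF = {"Fisher", "LS", "ReliefF"}
_STF = {"FS", "TS"}
_SSL = {"MCFS", "Alpha", "Lasso"}


@dataclass(frozen=True)
class SelectorParams:
    mi_bins: int = 10
    mifs_beta: float = 0.5
    knn_k: int = 5                  # LS affinity graph and ReliefF neighbors
    relieff_iters: int | None = None  # None: every sample is an anchor
    mcfs_clusters: int = 2
    mcfs_alpha: float = 0.01        # L1 penalty of the component regressions
    alpha_wealth: float = 0.5       # initial wealth of alpha investing
    alpha_bonus: float = 0.25       # wealth earned per admitted feature
    lasso_lambda: float = 1.0       # L1 penalty (C = 1/lambda)
    max_features: int = 20
    score_threshold: float = 0.9
    lasso_coef_threshold: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("mi_bins", "knn_k", "mcfs_clusters", "max_features"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class FeatureSet:
    """One method's selected features (ordered by decreasing score)."""

    method: str
    features: list
    scores: list
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.features) > self.params.get("max_features", 20):
            raise ValueError("feature set exceeds the maximum length")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite selection scores")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"method": self.method, "features": self.features,
                       "scores": [float(s) for s in self.scores],
                       "params": self.params}, fh, indent=2)


# ---------------------------------------------------------------------------
# mutual information primitives

def _discretize_ew(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width discretization to codes 0..bins-1."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return np.zeros(x.size, dtype=np.int64)
    codes = np.floor((x - lo) / (hi - lo) * bins).astype(np.int64)
    return np.clip(codes, 0, bins - 1)


def _codes(y) -> np.ndarray:
    return pd.factorize(np.asarray(y))[0]


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two discrete code vectors."""
    x, y = _codes(x), _codes(y)
    if x.size == 0:
        raise ValueError("empty input")
    joint = np.zeros((x.max() + 1, y.max() + 1))
    np.add.at(joint, (x, y), 1.0)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def conditional_mutual_information(x, y, z) -> float:
    """I(X;Y|Z) = sum_z p(z) I(X;Y | Z=z), plug-in."""
    x, y, z = _codes(x), _codes(y), _codes(z)
    total = 0.0
    n = x.size
    for zv in np.unique(z):
        sel = z == zv
        w = sel.sum() / n
        total += w * mutual_information(x[sel], y[sel])
    return float(total)


# ---------------------------------------------------------------------------
# TI family

def score_features_ti(method: str, table: pd.DataFrame, labels,
                      params: SelectorParams) -> pd.Series:
    """Marginal MI (MIM) or greedy forward selection (MIFS/MRMR/JMI/CMIM).

    Greedy methods return the criterion value each feature had at the step
    it was selected; only the features chosen within ``max_features`` greedy
    steps receive a score.
    """
    if method not in _TI:
        raise ValueError(f"{method} is not an information-theoretic method")
    y = _codes(labels)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    cols = list(table.columns)
    xd = {c: _discretize_ew(table[c].to_numpy(), params.mi_bins) for c in cols}
    rel = {c: mutual_information(xd[c], y) for c in cols}
    if method == "MIM":
        return pd.Series(rel)

    selected: list = []
    scores: dict = {}
    mi_ff: dict = {}      # cache I(fi; fs)
    cmi: dict = {}        # cache I(fi; C | fs)
    while len(selected) < min(params.max_features, len(cols)):
        best_c, best_v = None, -np.inf
        for c in cols:
            if c in scores:
                continue
            if not selected:
                v = rel[c]
            elif method == "MIFS":
                v = rel[c] - params.mifs_beta * sum(
                    mi_ff.setdefault((c, s), mutual_information(xd[c], xd[s]))
                    for s in selected)
            elif method == "MRMR":
                v = rel[c] - np.mean([
                    mi_ff.setdefault((c, s), mutual_information(xd[c], xd[s]))
                    for s in selected])
            elif method == "JMI":
                v = rel[c] - np.mean([
                    rel[c] - cmi.setdefault(
                        (c, s), conditional_mutual_information(xd[c], y, xd[s]))
                    for s in selected])
            else:  # CMIM
                v = min(cmi.setdefault(
                    (c, s), conditional_mutual_information(xd[c], y, xd[s]))
                    for s in selected)
            if v > best_v:
                best_c, best_v = c, v
        selected.append(best_c)
        scores[best_c] = best_v
    return pd.Series({c: scores[c] for c in selected})


# ---------------------------------------------------------------------------
# SIF family

def _fisher_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    n = len(y)
    mu = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c in classes:
        sel = X[y == c]
        if len(sel) < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
        w = len(sel) / n
        between += w * (sel.mean(axis=0) - mu) ** 2
        within += w * sel.var(axis=0)
    return between / np.where(within > 0, within, np.finfo(float).eps)


def _laplacian_scores(X: np.ndarray, k: int) -> np.ndarray:
    """Laplacian score with a k-NN heat-kernel affinity graph; bandwidth =
    squared mean pairwise distance."""
    n = X.shape[0]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    t = np.mean(np.sqrt(d2)) ** 2
    order = np.argsort(d2, axis=1, kind="stable")
    W = np.zeros((n, n))
    for i in range(n):
        for j in order[i, 1:k + 1]:
            w = np.exp(-d2[i, j] / max(t, np.finfo(float).eps))
            W[i, j] = W[j, i] = max(W[i, j], w)
    D = W.sum(axis=1)
    L = np.diag(D) - W
    scores = np.empty(X.shape[1])
    for r in range(X.shape[1]):
        f = X[:, r]
        f = f - (f @ D) / D.sum()
        den = f @ (D * f)
        scores[r] = (f @ L @ f) / den if den > 0 else 1.0
    return scores


def _relieff_scores(X: np.ndarray, y: np.ndarray, k: int,
                    iters: int | None, seed: int) -> np.ndarray:
    """ReliefF weights: range-normalized near-hit/near-miss differences
    averaged over anchors, misses weighted by class priors."""
    n, p = X.shape
    rng = np.random.default_rng(seed)
    rngs = X.max(axis=0) - X.min(axis=0)
    rngs = np.where(rngs > 0, rngs, 1.0)
    Xn = X / rngs
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    anchors = (np.arange(n) if iters is None
               else rng.choice(n, size=min(iters, n), replace=False))
    d = np.sum(np.abs(Xn[:, None, :] - Xn[None, :, :]), axis=-1)
    np.fill_diagonal(d, np.inf)
    w = np.zeros(p)
    for i in anchors:
        ci = y[i]
        hits = np.flatnonzero(y == ci)
        hits = hits[hits != i]
        kh = hits[np.argsort(d[i, hits], kind="stable")[:k]]
        if len(kh):
            w -= np.abs(Xn[i] - Xn[kh]).mean(axis=0)
        for c in classes:
            if c == ci:
                continue
            miss = np.flatnonzero(y == c)
            km = miss[np.argsort(d[i, miss], kind="stable")[:k]]
            if len(km):
                w += (priors[c] / (1 - priors[ci])
                      * np.abs(Xn[i] - Xn[km]).mean(axis=0))
    return w / len(anchors)


def score_features_sif(method: str, table: pd.DataFrame, labels,
                       params: SelectorParams) -> pd.Series:
    if method not in _SIF:
        raise ValueError(f"{method} is not a similarity-based method")
    X = table.to_numpy(dtype=float)
    if method == "Fisher":
        vals = _fisher_scores(X, _codes(labels))
    elif method == "LS":
        # lower Laplacian score = better locality preservation; report 1-LS
        vals = 1.0 - _laplacian_scores(X, params.knn_k)
    else:
        vals = _relieff_scores(X, _codes(labels), params.knn_k,
                               params.relieff_iters, params.seed)
    return pd.Series(vals, index=table.columns)


# ---------------------------------------------------------------------------
# STF family

def score_features_stf(method: str, table: pd.DataFrame, labels) -> pd.Series:
    """F-score and T-score for exactly two classes (positive class = 1)."""
    if method not in _STF:
        raise ValueError(f"{method} is not a statistical method")
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("FS/TS require exactly 2 classes")
    pos, neg = classes.max(), classes.min()
    X = table.to_numpy(dtype=float)
    xp, xn = X[y == pos], X[y == neg]
    mu, mup, mun = X.mean(axis=0), xp.mean(axis=0), xn.mean(axis=0)
    vp, vn = xp.var(axis=0, ddof=1), xn.var(axis=0, ddof=1)
    den = vp + vn
    den = np.where(den > 0, den, np.finfo(float).eps)
    if method == "FS":
        vals = ((mup - mu) ** 2 + (mun - mu) ** 2) / den
    else:
        vals = np.abs(mup - mun) / np.sqrt(den)
    return pd.Series(vals, index=table.columns)


# ---------------------------------------------------------------------------
# SSL family

def _mcfs_scores(X: np.ndarray, params: SelectorParams) -> np.ndarray:
    """Spectral embedding of the sample k-NN graph into ``mcfs_clusters``
    components, one L1 regression per component; score = max |coef|."""
    n = X.shape[0]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    t = np.mean(np.sqrt(d2)) ** 2
    order = np.argsort(d2, axis=1, kind="stable")
    W = np.zeros((n, n))
    for i in range(n):
        for j in order[i, 1:params.knn_k + 1]:
            w = np.exp(-d2[i, j] / max(t, np.finfo(float).eps))
            W[i, j] = W[j, i] = max(W[i, j], w)
    D = W.sum(axis=1)
    L = np.diag(D) - W
    # generalized eigenproblem L v = lambda D v; skip the trivial eigenvector
    vals, vecs = eigh(L, np.diag(np.where(D > 0, D, 1.0)))
    embedding = vecs[:, 1:params.mcfs_clusters + 1]
    scores = np.zeros(X.shape[1])
    sd = X.std(axis=0)
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    for kk in range(embedding.shape[1]):
        reg = SkLasso(alpha=params.mcfs_alpha, max_iter=50000)
        reg.fit(Xs, embedding[:, kk])
        scores = np.maximum(scores, np.abs(reg.coef_))
    return scores


def _logistic_ll(X: np.ndarray, y: np.ndarray) -> float:
    """Maximized log-likelihood of an (unpenalized, multinomial if needed)
    logistic fit; X may have zero columns (intercept-only null model)."""
    y = np.asarray(y)
    if X.shape[1] == 0:
        _, counts = np.unique(y, return_counts=True)
        p = counts / len(y)
        return float(np.sum(counts * np.log(p)))
    clf = LogisticRegression(C=np.inf, max_iter=2000)
    clf.fit(X, y)
    pr = np.clip(clf.predict_proba(X), 1e-12, None)
    col = np.searchsorted(clf.classes_, y)
    return float(np.sum(np.log(pr[np.arange(len(y)), col])))


def _alpha_investing(table: pd.DataFrame, y: np.ndarray,
                     params: SelectorParams) -> pd.Series:
    """Streaming pass over the features in table order.

    At stream position i the candidate is tested by the likelihood-ratio
    (deviance reduction) of adding it to the current logistic model at level
    alpha_i = wealth_i / (2 i), the classic wealth-spreading schedule.
    Admission earns ``alpha_bonus`` wealth, every test spends
    alpha_i/(1 - alpha_i).  Admitted features score their deviance
    reduction; with zero initial wealth nothing is ever admitted.
    """
    wealth = params.alpha_wealth
    selected: list = []
    scores: dict = {}
    ll_cur = _logistic_ll(np.empty((len(y), 0)), y)
    for i, col in enumerate(table.columns, start=1):
        if wealth <= 0 or len(selected) >= params.max_features:
            break
        alpha_i = wealth / (2.0 * i)
        cand = table[selected + [col]].to_numpy(dtype=float)
        ll_new = _logistic_ll(cand, y)
        dev = max(2.0 * (ll_new - ll_cur), 0.0)
        p = stats.chi2.sf(dev, df=1)
        wealth -= alpha_i / (1.0 - alpha_i)
        if p < alpha_i:
            selected.append(col)
            scores[col] = dev
            ll_cur = ll_new
            wealth += params.alpha_bonus
    return pd.Series(scores, dtype=float)


def _lasso_scores(table: pd.DataFrame, y: np.ndarray,
                  params: SelectorParams) -> pd.Series:
    """L1-logistic coefficient magnitudes; multi-class labels are handled
    one-vs-rest with the per-feature max |coefficient| over classes."""
    from sklearn.multiclass import OneVsRestClassifier

    base = LogisticRegression(l1_ratio=1, C=1.0 / params.lasso_lambda,
                              solver="liblinear", random_state=params.seed)
    X = table.to_numpy(dtype=float)
    if np.unique(y).size > 2:
        ovr = OneVsRestClassifier(base).fit(X, y)
        coefs = np.abs(np.vstack([e.coef_ for e in ovr.estimators_])
                       ).max(axis=0)
    else:
        coefs = np.abs(base.fit(X, y).coef_).max(axis=0)
    return pd.Series(coefs, index=table.columns)


def score_features_ssl(method: str, table: pd.DataFrame, labels,
                       params: SelectorParams) -> pd.Series:
    if method not in _SSL:
        raise ValueError(f"{method} is not a sparse/streaming method")
    if method == "MCFS":          # unsupervised: labels are ignored
        return pd.Series(_mcfs_scores(table.to_numpy(dtype=float), params),
                         index=table.columns)
    y = _codes(labels)
    if method == "Alpha":
        return _alpha_investing(table, y, params)
    return _lasso_scores(table, y, params)


# ---------------------------------------------------------------------------
# selection rule and dispatcher

def apply_selection_rule(method: str, scores: pd.Series,
                         params: SelectorParams) -> FeatureSet:
    """Lasso keeps |coef| > 0.02; other methods keep min-max-normalized
    score > 0.9; both truncate to the top ``max_features`` by score with
    ties broken by input (table column) order."""
    scores = scores.astype(float)
    if method == "Lasso":
        kept = scores[scores > params.lasso_coef_threshold]
    else:
        if len(scores) == 0:
            kept = scores
        else:
            lo, hi = scores.min(), scores.max()
            # constant scores carry no selection signal: nothing passes
            normed = (scores - lo) / (hi - lo) if hi > lo else \
                pd.Series(np.zeros(len(scores)), index=scores.index)
            kept = scores[normed > params.score_threshold]
    # stable sort: descending score, input order on ties
    order = np.argsort(-kept.to_numpy(), kind="stable")
    kept = kept.iloc[order].iloc[:params.max_features]
    if kept.empty:
        log.warning("method %s selected no features", method)
    return FeatureSet(method=method, features=list(kept.index),
                      scores=kept.tolist(),
                      params={**asdict(params), "method": method})


def select_features(method: str, table: pd.DataFrame, labels,
                    params: SelectorParams | None = None) -> FeatureSet:
    """Score with the requested method and apply the selection rule."""
    params = params or SelectorParams()
    if method in _TI:
        scores = score_features_ti(method, table, labels, params)
    elif method in _SIF:
        scores = score_features_sif(method, table, labels, params)
    elif method in _STF:
        scores = score_features_stf(method, table, labels)
    elif method in _SSL:
        scores = score_features_ssl(method, table, labels, params)
    else:
        raise ValueError(f"unknown selection method {method!r}")
    return apply_selection_rule(method, scores, params)
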