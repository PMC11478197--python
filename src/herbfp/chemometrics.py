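"""Pattern recognition on the common-peak area matrix.

Implements the chemometric stack from its defining linear algebra rather
than wrapping a vendor tool:

- ``preprocess``: column scaling (center / unit-variance / pareto / none)
  with a retained inverse transform;
- ``pca``: SVD-based principal components with explained-variance fractions
  and a 7-fold row-wise cross-validated Q² (documented approximation);
- ``hca``: agglomerative clustering (squared-Euclidean criterion, Ward
  linkage by default) with silhouette-selected cluster count and Newick
  export;
- ``oplsda``: single-predictive-component orthogonal projections to latent
  structures discriminant analysis with R²X/R²Y/Q², VIP and a label
  permutation test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage, to_tree
from sklearn.metrics import silhouette_score

from .errors import ValidationError

__all__ = [
    "ScaledMatrix",
    "PcaResult",
    "HcaResult",
    "OplsdaResult",
    "PermutationResult",
    "preprocess",
    "pca",
    "hca",
    "oplsda",
    "vip",
    "permutation_test",
]

SCALINGS = ("center", "uv", "pareto", "none")


@dataclass
class ScaledMatrix:
    """A column-scaled matrix with enough state to invert the transform."""

    values: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    scaling: str

    def inverse(self, values: pd.DataFrame | None = None) -> pd.DataFrame:
        v = self.values if values is None else values
        if self.scaling == "none":
            return v.copy()
        if self.scaling == "center":
            return v + self.means
        if self.scaling == "uv":
            return v * self.sds + self.means
        return v * np.sqrt(self.sds) + self.means   # pareto


def preprocess(matrix, scaling: str = "uv") -> ScaledMatrix:
    """Apply a per-column scaling transform.

    Rejects matrices with fewer than 2 rows and, for variance-based
    scalings, zero-variance columns (reported by name).
    """
    if scaling not in SCALINGS:
        raise ValidationError(f"unknown scaling {scaling!r}")
    df = pd.DataFrame(matrix).astype(float)
    if df.shape[0] < 2:
        raise ValidationError("need at least 2 rows")
    if df.isna().any().any():
        raise ValidationError("missing values are the caller's job")
    means = df.mean(axis=0)
    sds = df.std(axis=0, ddof=1)
    if scaling in ("uv", "pareto"):
        bad = list(sds.index[sds == 0])
        if bad:
            raise ValidationError(f"zero-variance columns under {scaling}: {bad}")
    if scaling == "none":
        values = df.copy()
        means = pd.Series(0.0, index=df.columns)
        sds = pd.Series(1.0, index=df.columns)
    elif scaling == "center":
        values = df - means
    elif scaling == "uv":
        values = (df - means) / sds
    else:
        values = (df - means) / np.sqrt(sds)
    return ScaledMatrix(values=values, means=means, sds=sds, scaling=scaling)


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PcaResult:
    scores: pd.DataFrame            # n x k
    loadings: pd.DataFrame          # p x k
    explained: np.ndarray           # fraction per component (all components)
    q2: float
    k: int

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.explained)


def _svd_components(X: np.ndarray, k: int):
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|.| element of each loading positive
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    return U[:, :k], s, Vt[:k]


def pca(scaled: ScaledMatrix, k: int = 2, cv_folds: int = 7) -> PcaResult:
    """SVD principal components of an already-scaled matrix.

    Explained fractions are ``s_i^2 / sum(s^2)``.  Q² is estimated by
    ``cv_folds``-fold row-wise reconstruction cross-validation (held-out
    rows are projected onto the training loadings); this is a documented
    approximation to proprietary element-wise schemes.
    """
    X = scaled.values.to_numpy()
    n, p = X.shape
    if not (1 <= k <= min(n - 1, p)):
        raise ValidationError(f"k must be in [1, {min(n - 1, p)}]")
    U, s, Vt = _svd_components(X, k)
    total = float(np.sum(s ** 2))
    explained = (s ** 2 / total) if total > 0 else np.zeros_like(s)
    scores = pd.DataFrame(
        U * s[:k], index=scaled.values.index,
        columns=[f"PC{j + 1}" for j in range(k)])
    loadings = pd.DataFrame(
        Vt.T, index=scaled.values.columns,
        columns=[f"PC{j + 1}" for j in range(k)])

    folds = min(cv_folds, n)
    press = 0.0
    for f in range(folds):
        test = np.arange(n) % folds == f
        Xtr, Xte = X[~test], X[test]
        if Xtr.shape[0] <= k:
            continue
        _, _, Vt_tr = _svd_components(Xtr, k)
        proj = Xte @ Vt_tr.T @ Vt_tr
        press += float(np.sum((Xte - proj) ** 2))
    tss = float(np.sum(X ** 2))
    q2 = 1.0 - press / tss if tss > 0 else 0.0
    return PcaResult(scores=scores, loadings=loadings,
                     explained=explained, q2=q2, k=k)


# ---------------------------------------------------------------------------
# HCA

@dataclass
class HcaResult:
    linkage: np.ndarray
    labels: pd.Series
    k: int
    silhouettes: dict[int, float]
    leaf_order: list[str]
    heatmap: pd.DataFrame
    newick: str


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = to_tree(Z)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def hca(scaled: ScaledMatrix, linkage_method: str = "ward",
        k: int | None = None, k_range: tuple[int, int] = (2, 6)) -> HcaResult:
    """Agglomerative clustering of the rows.

    Ward linkage minimizes the within-cluster squared-Euclidean variance
    criterion; ``average`` linkage (on squared-Euclidean distances) is the
    alternative.  If ``k`` is None the cluster count is chosen by maximum
    silhouette over ``k_range`` (capped at n-1).
    """
    X = scaled.values.to_numpy()
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 rows")
    if k is not None and (k < 1 or k > n):
        raise ValidationError(f"k must be in [1, {n}]")
    if linkage_method == "ward":
        Z = linkage(X, method="ward")
    else:
        Z = linkage(X, method=linkage_method, metric="sqeuclidean")

    silhouettes: dict[int, float] = {}
    if k is None:
        if float(Z[:, 2].max()) == 0.0:
            k = 1
            labels_arr = np.ones(n, dtype=int)
        else:
            best_k, best_s = None, -np.inf
            for kk in range(max(2, k_range[0]), min(k_range[1], n - 1) + 1):
                lab = fcluster(Z, kk, criterion="maxclust")
                if len(np.unique(lab)) < 2:
                    continue
                s = float(silhouette_score(X, lab))
                silhouettes[kk] = s
                if s > best_s:
                    best_k, best_s = kk, s
            k = best_k if best_k is not None else 1
            labels_arr = (fcluster(Z, k, criterion="maxclust")
                          if k > 1 else np.ones(n, dtype=int))
    else:
        labels_arr = (fcluster(Z, k, criterion="maxclust")
                      if k > 1 else np.ones(n, dtype=int))

    index = list(scaled.values.index)
    order = [index[i] for i in leaves_list(Z)]
    return HcaResult(
        linkage=Z,
        labels=pd.Series(labels_arr, index=index, name="cluster"),
        k=int(k),
        silhouettes=silhouettes,
        leaf_order=order,
        heatmap=scaled.values.loc[order],
        newick=_to_newick(Z, [str(i) for i in index]),
    )


# ---------------------------------------------------------------------------
# OPLS-DA

@dataclass
class OplsdaResult:
    """Fitted one-predictive-component OPLS-DA model."""

    t: np.ndarray                    # predictive scores
    w: np.ndarray                    # predictive weights (unit norm)
    p: np.ndarray                    # predictive X loadings
    q: float                         # y loading
    t_ortho: np.ndarray              # n x n_orthogonal
    w_ortho: np.ndarray              # p x n_orthogonal
    p_ortho: np.ndarray              # p x n_orthogonal
    r2x: float
    r2x_pred: float
    r2y: float
    q2: float
    y_mean: float
    classes: tuple
    feature_names: list[str] = field(default_factory=list)
    sample_names: list[str] = field(default_factory=list)

    @property
    def n_orthogonal(self) -> int:
        return self.w_ortho.shape[1]

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        """Predictive scores for new rows (orthogonal filter then project)."""
        Xf = np.array(X_new, dtype=float, copy=True)
        for a in range(self.n_orthogonal):
            t_o = Xf @ self.w_ortho[:, a]
            Xf -= np.outer(t_o, self.p_ortho[:, a])
        return Xf @ self.w

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return self.transform(X_new) * self.q + self.y_mean


def _encode_y(y) -> tuple[np.ndarray, tuple]:
    arr = np.asarray(y)
    classes = tuple(pd.unique(arr))
    if len(classes) < 2:
        raise ValidationError("constant y rejected")
    if len(classes) == 2:
        return np.where(arr == classes[0], -1.0, 1.0), classes
    if np.issubdtype(arr.dtype, np.number):
        return arr.astype(float), classes
    raise ValidationError("more than two classes not supported")


def _opls_core(X: np.ndarray, yc: np.ndarray, n_orthogonal: int):
    """One round of the O-PLS sequence; returns predictive and orthogonal
    weights/scores/loadings computed on a working copy of X."""
    Xd = np.array(X, dtype=float, copy=True)
    w_os, p_os, t_os = [], [], []
    for _ in range(n_orthogonal):
        w = Xd.T @ yc
        w /= np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) / (w @ w) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd -= np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)
    w = Xd.T @ yc
    w /= np.linalg.norm(w)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    q = (yc @ t) / (t @ t)
    stack = (lambda v: np.column_stack(v) if v
             else np.zeros((X.shape[1], 0)))
    t_stack = (np.column_stack(t_os) if t_os
               else np.zeros((X.shape[0], 0)))
    return w, t, p, q, stack(w_os), stack(p_os), t_stack


def oplsda(scaled: ScaledMatrix, y, n_orthogonal: int = 1,
           cv_folds: int = 7) -> OplsdaResult:
    """Fit OPLS-DA with one predictive and ``n_orthogonal`` orthogonal
    components.

    y must contain exactly two classes (encoded ±1 and centered).  Q² uses
    ``cv_folds``-fold cross-validation with deterministic round-robin fold
    assignment by row order; each fold refits the full model.
    """
    if n_orthogonal < 0:
        raise ValidationError("n_orthogonal must be >= 0")
    X = scaled.values.to_numpy()
    y_num, classes = _encode_y(y)
    if len(y_num) != X.shape[0]:
        raise ValidationError("y length must match rows of X")
    y_mean = float(np.mean(y_num))
    yc = y_num - y_mean

    w, t, p, q, W_o, P_o, T_o = _opls_core(X, yc, n_orthogonal)
    ssx = float(np.sum(X ** 2))
    explained_x = float(np.sum(np.outer(t, p) ** 2))
    explained_o = float(np.sum((T_o @ P_o.T) ** 2)) if T_o.size else 0.0
    r2x_pred = explained_x / ssx if ssx > 0 else 0.0
    r2x = (explained_x + explained_o) / ssx if ssx > 0 else 0.0
    ssy = float(yc @ yc)
    r2y = 1.0 - float(np.sum((yc - t * q) ** 2)) / ssy if ssy > 0 else 0.0

    n = X.shape[0]
    folds = min(cv_folds, n)
    press = 0.0
    for f in range(folds):
        test = np.arange(n) % folds == f
        Xtr, ytr = X[~test], y_num[~test]
        if len(np.unique(ytr)) < 2:
            raise ValidationError("a CV fold removed an entire class")
        ytr_mean = float(np.mean(ytr))
        fit = _opls_core(Xtr, ytr - ytr_mean, n_orthogonal)
        w_f, _, _, q_f, W_of, P_of, _ = fit
        Xte = np.array(X[test], copy=True)
        for a in range(W_of.shape[1]):
            t_o = Xte @ W_of[:, a]
            Xte -= np.outer(t_o, P_of[:, a])
        yhat = Xte @ w_f * q_f + ytr_mean
        press += float(np.sum((y_num[test] - yhat) ** 2))
    q2 = 1.0 - press / ssy if ssy > 0 else 0.0

    return OplsdaResult(
        t=t, w=w, p=p, q=float(q), t_ortho=T_o, w_ortho=W_o, p_ortho=P_o,
        r2x=r2x, r2x_pred=r2x_pred, r2y=r2y, q2=q2, y_mean=y_mean,
        classes=classes,
        feature_names=list(scaled.values.columns),
        sample_names=list(scaled.values.index),
    )


def vip(model: OplsdaResult) -> pd.Series:
    """Variable importance in projection over the predictive component(s).

    With the single predictive component this is
    ``sqrt(p) * |w_j| / ||w||``, so ``mean(VIP^2) == 1`` identically.
    """
    w = model.w
    p_vars = len(w)
    contrib = (w / np.linalg.norm(w)) ** 2
    values = np.sqrt(p_vars * contrib)
    index = (model.feature_names if model.feature_names
             else [f"v{j + 1}" for j in range(p_vars)])
    return pd.Series(values, index=index, name="VIP")


def vip_markers(model: OplsdaResult, threshold: float = 1.0) -> pd.DataFrame:
    """Variables with VIP above threshold, ranked."""
    v = vip(model).sort_values(ascending=False)
    out = v.to_frame()
    out["rank"] = np.arange(1, len(v) + 1)
    return out[out["VIP"] > threshold]


@dataclass
class PermutationResult:
    record: pd.DataFrame            # perm_id, corr, r2y, q2 (id 0 = original)
    r2y_intercept: float
    q2_intercept: float
    original_r2y: float
    original_q2: float
    verdict: bool
    n_permutations: int


def permutation_test(scaled: ScaledMatrix, y, n_perm: int = 200,
                     seed: int = 0, n_orthogonal: int = 1,
                     quantile: float = 0.95) -> PermutationResult:
    """Label permutation test for an OPLS-DA model.

    For each permuted y the model is refit and (|corr(y_perm, y)|, R²Y, Q²)
    recorded.  Intercepts come from least-squares lines of R²Y and Q²
    against |corr| (the original fit is included at |corr| = 1).  The model
    is deemed valid when the Q² intercept is negative and the original R²Y
    and Q² exceed the requested quantile of the permuted values.
    """
    if n_perm < 20:
        raise ValidationError("n_perm must be >= 20")
    y_num, _ = _encode_y(y)
    n = len(y_num)
    rng = np.random.default_rng(seed)

    base = oplsda(scaled, y_num, n_orthogonal=n_orthogonal)

    n_distinct = math.factorial(n)
    rows = [(0, 1.0, base.r2y, base.q2)]
    seen = set()
    attempts = 0
    i = 0
    while i < n_perm:
        perm = rng.permutation(n)
        attempts += 1
        if n_distinct <= n_perm * 2:
            key = tuple(perm)
            if key in seen:
                if attempts > 50 * n_perm:
                    warnings.warn(
                        f"only {len(seen)} distinct permutations available")
                    break
                continue
            seen.add(key)
        y_p = y_num[perm]
        if len(np.unique(y_p)) < 2:
            continue
        sd = y_num.std() * y_p.std()
        corr = abs(float(np.corrcoef(y_p, y_num)[0, 1])) if sd > 0 else 0.0
        try:
            fit = oplsda(scaled, y_p, n_orthogonal=n_orthogonal)
        except ValidationError:
            continue
        i += 1
        rows.append((i, corr, fit.r2y, fit.q2))

    record = pd.DataFrame(rows, columns=["perm_id", "corr", "r2y", "q2"])
    x = record["corr"].to_numpy()
    r2_line = np.polyfit(x, record["r2y"].to_numpy(), 1)
    q2_line = np.polyfit(x, record["q2"].to_numpy(), 1)
    perms = record[record["perm_id"] > 0]
    verdict = bool(
        q2_line[1] < 0
        and base.q2 > float(np.quantile(perms["q2"], quantile))
        and base.r2y > float(np.quantile(perms["r2y"], quantile)))
    return PermutationResult(
        record=record,
        r2y_intercept=float(r2_line[1]),
        q2_intercept=float(q2_line[1]),
        original_r2y=base.r2y,
        original_q2=base.q2,
        verdict=verdict,
        n_permutations=int(record["perm_id"].max()),
    )
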