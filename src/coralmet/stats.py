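"""Univariate and multivariate differential statistics.

Covers the chemometrics workflow of a two-group untargeted metabolomics
study: normality-gated univariate tests with Benjamini-Hochberg correction,
PCA with the 95% Hotelling T-squared ellipse, OPLS-DA (orthogonal
projections to latent structures discriminant analysis) with VIP scores,
stratified k-fold cross-validation (Q2), label-permutation testing,
VIP/p differential screening, Shannon chemical diversity, two-group
unique/shared feature counts, and hypergeometric pathway
over-representation.

OPLS-DA follows the standard single-response O-PLS algorithm: the PLS
weight vector w = X'y/y'y is computed, loadings p of the X-score are split
into a part parallel to w and an orthogonal remainder w_o; the orthogonal
component t_o = X w_o is deflated from X and the step repeats. After the
chosen number of orthogonal components, one predictive component
(t = X w, q = y't/t't) is extracted. The number of orthogonal components
is chosen by cross-validated Q2, stopping at the first decrease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA as _SkPCA
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable
from .preprocess import VarianceScaler

__all__ = [
    "GatedTestResult",
    "gated_test",
    "gated_tests_matrix",
    "adjust_pvalues",
    "PcaResult",
    "PCAHotelling",
    "fit_pca",
    "OPLSDA",
    "fit_oplsda",
    "stratified_folds",
    "cross_validate",
    "compute_vip",
    "PermutationResult",
    "permutation_test",
    "DiffResult",
    "screen_differential",
    "DiversityResult",
    "shannon_diversity",
    "VennResult",
    "venn_counts",
    "pathway_ora",
    "read_pathway_map",
]


# ---------------------------------------------------------------------------
# univariate


@dataclass
class GatedTestResult:
    p_value: float
    test_used: str  # "t_test" | "mann_whitney" | "degenerate"
    shapiro_p: tuple[float, float] = (float("nan"), float("nan"))
    flag: str = ""


def gated_test(
    x: np.ndarray,
    y: np.ndarray,
    alpha_normality: float = 0.05,
    welch: bool = True,
) -> GatedTestResult:
    """Two-sided two-group test gated on Shapiro-Wilk normality.

    If both groups pass normality (Shapiro p >= alpha) an independent
    t-test is used (Welch by default, pooled-variance with ``welch=False``);
    otherwise a Mann-Whitney U test. Each group needs at least 3 values.
    Input that is constant across both groups returns p = 1 with a flag.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 values")
    if np.ptp(np.concatenate([x, y])) == 0:
        return GatedTestResult(1.0, "degenerate", flag="constant input")
    sp = []
    normal = True
    for g in (x, y):
        if np.ptp(g) == 0:
            sp.append(0.0)  # a constant group cannot be called normal
            normal = False
        else:
            pval = float(sps.shapiro(g).pvalue)
            sp.append(pval)
            normal = normal and pval >= alpha_normality
    if normal:
        p = float(sps.ttest_ind(x, y, equal_var=not welch).pvalue)
        return GatedTestResult(p, "t_test", shapiro_p=(sp[0], sp[1]))
    p = float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return GatedTestResult(p, "mann_whitney", shapiro_p=(sp[0], sp[1]))


def gated_tests_matrix(
    X: np.ndarray,
    y01: np.ndarray,
    alpha_normality: float = 0.05,
    log_transform: bool = True,
    welch: bool = True,
) -> list[GatedTestResult]:
    """Column-wise gated tests of a sample x feature matrix.

    With ``log_transform`` (default) intensities are log-transformed before
    testing — multiplicative measurement noise is approximately normal on
    the log scale, so the Shapiro gate then routes most features to the
    t-test. Zeros are offset by half the smallest positive value in the
    matrix so absent features remain testable.
    """
    X = np.asarray(X, float)
    y01 = np.asarray(y01)
    if log_transform:
        pos = X[X > 0]
        offset = (pos.min() / 2.0) if pos.size else 1.0
        X = np.log(X + offset)
    a = X[y01 == 0]
    b = X[y01 == 1]
    return [
        gated_test(a[:, j], b[:, j], alpha_normality, welch=welch)
        for j in range(X.shape[1])
    ]


def adjust_pvalues(p: np.ndarray, method: str = "benjamini_hochberg") -> np.ndarray:
    """Multiple-testing correction (Benjamini-Hochberg step-up by default;
    any statsmodels method name is accepted)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    alias = {"benjamini_hochberg": "fdr_bh", "bonferroni": "bonferroni"}
    return multipletests(p, method=alias.get(method, method))[1]


# ---------------------------------------------------------------------------
# PCA with Hotelling ellipse


@dataclass
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    t2: np.ndarray
    t2_crit: float
    within_ellipse: np.ndarray


class PCAHotelling(BaseEstimator):
    """PCA (SVD) with per-sample Hotelling T-squared and the 95% F-bound.

    T2_i sums the squared scores over the retained components divided by
    their score variances; the critical value is
    k(n^2-1)/(n(n-k)) * F_{alpha}(k, n-k).
    """

    def __init__(self, n_components: int = 2, alpha: float = 0.95):
        self.n_components = n_components
        self.alpha = alpha

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        n = X.shape[0]
        if n < 3:
            raise ValueError("PCA needs at least 3 samples")
        if self.n_components > min(X.shape):
            raise ValueError(
                f"cannot extract {self.n_components} components from {X.shape}"
            )
        pca = _SkPCA(n_components=self.n_components, svd_solver="full")
        self.scores_ = pca.fit_transform(X)
        self.loadings_ = pca.components_.T
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        lam = self.scores_.var(axis=0, ddof=1)
        lam = np.where(lam > 0, lam, np.inf)
        self.t2_ = (self.scores_**2 / lam).sum(axis=1)
        k = self.n_components
        self.t2_crit_ = (
            k * (n**2 - 1) / (n * (n - k)) * sps.f.ppf(self.alpha, k, n - k)
        )
        self.within_ellipse_ = self.t2_ <= self.t2_crit_
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        return np.asarray(X, float) @ self.loadings_


def fit_pca(X: np.ndarray, n_components: int = 2) -> PcaResult:
    """PCA of a unit-variance-scaled sample x feature matrix."""
    m = PCAHotelling(n_components=n_components).fit(X)
    return PcaResult(
        scores=m.scores_,
        loadings=m.loadings_,
        explained_variance_ratio=m.explained_variance_ratio_,
        t2=m.t2_,
        t2_crit=m.t2_crit_,
        within_ellipse=m.within_ellipse_,
    )


# ---------------------------------------------------------------------------
# OPLS-DA


def _encode_labels(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"OPLS-DA needs exactly two classes, got {classes.tolist()}")
    return (y == classes[1]).astype(float), classes


def _opls_core(X: np.ndarray, yc: np.ndarray, n_ortho: int) -> dict:
    """Single-response O-PLS decomposition on a centered/scaled matrix."""
    Xr = X.astype(float).copy()
    ssx_total = float((X**2).sum())
    ssy_total = float((yc**2).sum())
    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho):
        w = Xr.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w = w / nw
        t = Xr @ w
        p = Xr.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-10:
            break
        w_o = w_o / n_o
        t_o = Xr @ w_o
        p_o = Xr.T @ t_o / (t_o @ t_o)
        Xr = Xr - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    w = Xr.T @ yc
    nw = np.linalg.norm(w)
    w = w / nw if nw > 0 else w
    t = Xr @ w
    tt = float(t @ t)
    if tt < 1e-30:
        p = np.zeros_like(w)
        q = 0.0
    else:
        p = Xr.T @ t / tt
        q = float(yc @ t / tt)
    explained_x = sum(float(to @ to) * float(po @ po) for to, po in zip(T_o, P_o))
    explained_x += tt * float(p @ p)
    resid_y = yc - t * q
    return {
        "w": w, "t": t, "p": p, "q": q,
        "w_ortho": W_o, "p_ortho": P_o, "t_ortho": T_o,
        "n_ortho": len(W_o),
        "r2x": explained_x / ssx_total if ssx_total > 0 else 0.0,
        "r2y": 1.0 - float(resid_y @ resid_y) / ssy_total if ssy_total > 0 else 0.0,
    }


def _opls_predict(core: dict, X: np.ndarray) -> np.ndarray:
    Xr = np.asarray(X, float).copy()
    for w_o, p_o in zip(core["w_ortho"], core["p_ortho"]):
        t_o = Xr @ w_o
        Xr = Xr - np.outer(t_o, p_o)
    return (Xr @ core["w"]) * core["q"]


class OPLSDA(BaseEstimator):
    """OPLS-DA classifier/regressor on a two-class response.

    Parameters
    ----------
    n_orthogonal:
        Number of y-orthogonal components, or ``"auto"`` to pick the
        largest count that still increases cross-validated Q2 (stopping at
        the first decrease, up to ``max_ortho``).
    scale:
        Optional internal scaling (``"pareto"``, ``"unit_variance"`` or
        ``None`` when X is pre-scaled). Refit on each training set during
        cross-validation, so scaling statistics never leak across folds.
    k_folds, random_state:
        Stratified cross-validation fold count and fold-assignment seed.

    Fitted attributes use sklearn conventions: ``weights_``, ``scores_``,
    ``loadings_``, ``q_``, ``r2x_``, ``r2y_``, ``q2_``, ``n_orthogonal_``,
    ``vip_``.
    """

    def __init__(
        self,
        n_orthogonal: int | str = "auto",
        max_ortho: int = 5,
        scale: str | None = None,
        k_folds: int = 7,
        random_state: int = 0,
    ):
        self.n_orthogonal = n_orthogonal
        self.max_ortho = max_ortho
        self.scale = scale
        self.k_folds = k_folds
        self.random_state = random_state

    # -- internal helpers ---------------------------------------------------
    def _prepare(self, X):
        X = np.asarray(X, float)
        if self.scale is not None:
            scaler = VarianceScaler(scheme=self.scale).fit(X)
            return scaler.transform(X), scaler, None
        mu = X.mean(axis=0)
        return X - mu, None, mu

    def fit(self, X, y):
        y01, self.classes_ = _encode_labels(y)
        if np.bincount(y01.astype(int)).min() < 2:
            raise ValueError("each class needs at least 2 samples")
        X = np.asarray(X, float)
        if self.n_orthogonal == "auto":
            n_ortho, q2 = self._select_n_ortho(X, y01)
        else:
            n_ortho = int(self.n_orthogonal)
            q2 = cross_validate(
                X, y01, k=self.k_folds, n_ortho=n_ortho,
                scale=self.scale, seed=self.random_state,
            )
        Xs, self._scaler, self._x_mean = self._prepare(X)
        self._y_mean = y01.mean()
        core = _opls_core(Xs, y01 - self._y_mean, n_ortho)
        self._core = core
        self.weights_ = core["w"]
        self.loadings_ = core["p"]
        self.scores_ = core["t"]
        self.q_ = core["q"]
        self.orthogonal_weights_ = np.array(core["w_ortho"]).reshape(-1, Xs.shape[1])
        self.orthogonal_loadings_ = np.array(core["p_ortho"]).reshape(-1, Xs.shape[1])
        self.orthogonal_scores_ = np.array(core["t_ortho"]).reshape(-1, Xs.shape[0])
        self.n_orthogonal_ = core["n_ortho"]
        self.r2x_ = core["r2x"]
        self.r2y_ = core["r2y"]
        self.q2_ = q2
        self.vip_ = compute_vip(self)
        return self

    def _select_n_ortho(self, X, y01) -> tuple[int, float]:
        best_n = 0
        best_q2 = cross_validate(
            X, y01, k=self.k_folds, n_ortho=0, scale=self.scale,
            seed=self.random_state,
        )
        for n_o in range(1, self.max_ortho + 1):
            q2 = cross_validate(
                X, y01, k=self.k_folds, n_ortho=n_o, scale=self.scale,
                seed=self.random_state,
            )
            if q2 > best_q2:
                best_n, best_q2 = n_o, q2
            else:
                break
        return best_n, best_q2

    def decision_function(self, X):
        check_is_fitted(self, "weights_")
        X = np.asarray(X, float)
        if self._scaler is not None:
            Xs = self._scaler.transform(X)
        else:
            Xs = X - self._x_mean
        return _opls_predict(self._core, Xs) + self._y_mean

    def predict(self, X):
        yhat = self.decision_function(X)
        return self.classes_[(yhat >= 0.5).astype(int)]


def fit_oplsda(
    X: np.ndarray, y, n_orthogonal: int | str = "auto", max_ortho: int = 5,
    k_folds: int = 7, random_state: int = 0,
) -> OPLSDA:
    """Fit OPLS-DA on an already Pareto-scaled sample x feature matrix."""
    return OPLSDA(
        n_orthogonal=n_orthogonal, max_ortho=max_ortho, scale=None,
        k_folds=k_folds, random_state=random_state,
    ).fit(X, y)


def stratified_folds(
    y01: np.ndarray, k: int, seed: int = 0
) -> list[np.ndarray]:
    """Deterministic stratified folds: each class's samples are shuffled and
    dealt round-robin, so fold sizes differ by at most one and every
    training set keeps both classes (raises otherwise)."""
    y01 = np.asarray(y01)
    n = len(y01)
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    counter = 0
    for cls in np.unique(y01):
        idx = np.flatnonzero(y01 == cls)
        for i in rng.permutation(idx):
            folds[counter % k].append(int(i))
            counter += 1
    out = [np.sort(np.array(f, dtype=int)) for f in folds if len(f)]
    for f in out:
        train = np.setdiff1d(np.arange(n), f)
        if np.unique(y01[train]).size < 2:
            raise ValueError("a training fold lost one class entirely")
    return out


def cross_validate(
    X: np.ndarray, y, k: int = 7, n_ortho: int = 0,
    scale: str | None = None, seed: int = 0,
) -> float:
    """Cross-validated Q2 = 1 - PRESS/SSY over k stratified folds.

    ``k = n`` reduces to leave-one-out. Scaling (when requested) is refit
    on each training split.
    """
    X = np.asarray(X, float)
    y01 = np.asarray(y, float)
    if set(np.unique(y01)) - {0.0, 1.0}:
        y01, _ = _encode_labels(y)
    n = len(y01)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    press = 0.0
    for test_idx in stratified_folds(y01, k, seed):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xtr, Xte = X[train_idx], X[test_idx]
        ytr = y01[train_idx]
        if scale is not None:
            scaler = VarianceScaler(scheme=scale).fit(Xtr)
            Xtr_s, Xte_s = scaler.transform(Xtr), scaler.transform(Xte)
        else:
            mu = Xtr.mean(axis=0)
            Xtr_s, Xte_s = Xtr - mu, Xte - mu
        core = _opls_core(Xtr_s, ytr - ytr.mean(), n_ortho)
        yhat = _opls_predict(core, Xte_s) + ytr.mean()
        press += float(((y01[test_idx] - yhat) ** 2).sum())
    ssy = float(((y01 - y01.mean()) ** 2).sum())
    return 1.0 - press / ssy


def compute_vip(model: OPLSDA, variant: str = "predictive") -> np.ndarray:
    """Variable importance in projection.

    ``"predictive"`` (default) uses the predictive component only:
    VIP_j = sqrt(p * SSY w_j^2 / SSY) = sqrt(p) |w_j| for the unit-norm
    weight vector, so mean(VIP^2) = 1 exactly. ``"total"`` additionally
    weights orthogonal components by the X-variance they explain (the
    SIMCA-style total-VIP variant).
    """
    check_is_fitted(model, "weights_")
    w = model.weights_
    p = w.size
    if variant == "predictive":
        return np.sqrt(p) * np.abs(w) / np.linalg.norm(w)
    if variant != "total":
        raise ValueError(f"unknown VIP variant {variant!r}")
    core = model._core
    ssy = float(core["t"] @ core["t"]) * core["q"] ** 2
    num = ssy * w**2
    den = ssy
    for w_o, t_o, p_o in zip(core["w_ortho"], core["t_ortho"], core["p_ortho"]):
        ssx_o = float(t_o @ t_o) * float(p_o @ p_o)
        num = num + ssx_o * w_o**2
        den += ssx_o
    vip2 = p * num / den
    return np.sqrt(vip2 / vip2.mean())  # renormalize so mean(VIP^2) = 1


@dataclass
class PermutationResult:
    observed_r2y: float
    observed_q2: float
    r2y_perm: np.ndarray
    q2_perm: np.ndarray
    p_empirical: float
    r2y_intercept: float
    q2_intercept: float
    n_perm: int


def permutation_test(
    X: np.ndarray, y, n_perm: int = 200, seed: int = 0,
    scale: str | None = None, k_folds: int = 7, max_ortho: int = 5,
) -> PermutationResult:
    """Label-permutation validation of an OPLS-DA model.

    The observed model (orthogonal-component count chosen by Q2) is refit
    under ``n_perm`` random label permutations with the same component
    count; the empirical p-value is (1 + #{Q2_perm >= Q2_obs})/(n_perm+1)
    and the R2Y/Q2 intercepts come from regressing each statistic on
    |corr(y_perm, y)| (permutation plot intercepts at zero correlation).
    A drawn permutation that reproduces the original class partition is
    redrawn: it is not a relabeling, only a re-indexing of the same split.
    """
    import warnings as _warnings

    if n_perm < 20:
        _warnings.warn("fewer than 20 permutations give a very coarse p-value")
    y01, _ = _encode_labels(y)
    model = OPLSDA(
        n_orthogonal="auto", max_ortho=max_ortho, scale=scale,
        k_folds=k_folds, random_state=seed,
    ).fit(X, y01)
    n_ortho = model.n_orthogonal_
    rng = np.random.default_rng(seed)
    r2s, q2s, cors = [], [], []
    yc = y01 - y01.mean()
    for _ in range(n_perm):
        yp = rng.permutation(y01)
        while np.array_equal(yp, y01) or np.array_equal(yp, 1 - y01):
            yp = rng.permutation(y01)
        ypc = yp - yp.mean()
        cor = abs(float(yc @ ypc) / (np.linalg.norm(yc) * np.linalg.norm(ypc)))
        Xarr = np.asarray(X, float)
        if scale is not None:
            Xs = VarianceScaler(scheme=scale).fit(Xarr).transform(Xarr)
        else:
            Xs = Xarr - Xarr.mean(axis=0)
        core = _opls_core(Xs, ypc, n_ortho)
        q2 = cross_validate(X, yp, k=k_folds, n_ortho=n_ortho, scale=scale, seed=seed)
        r2s.append(core["r2y"])
        q2s.append(q2)
        cors.append(cor)
    r2s = np.asarray(r2s)
    q2s = np.asarray(q2s)
    cors = np.asarray(cors)
    p_emp = (1.0 + float((q2s >= model.q2_).sum())) / (n_perm + 1.0)

    def _intercept(stat: np.ndarray, observed: float) -> float:
        xs = np.concatenate([cors, [1.0]])
        ys = np.concatenate([stat, [observed]])
        slope, intercept = np.polyfit(xs, ys, 1)
        return float(intercept)

    return PermutationResult(
        observed_r2y=model.r2y_,
        observed_q2=model.q2_,
        r2y_perm=r2s,
        q2_perm=q2s,
        p_empirical=p_emp,
        r2y_intercept=_intercept(r2s, model.r2y_),
        q2_intercept=_intercept(q2s, model.q2_),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# screening, diversity, Venn, ORA


@dataclass
class DiffResult:
    feature_id: str
    vip: float
    p_value: float
    p_adjusted: float
    test_used: str
    direction: str  # "higher_in_A" | "higher_in_B" | ""
    significant: bool


def screen_differential(
    feature_ids: list[str],
    vip: np.ndarray,
    p_adjusted: np.ndarray,
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    p_raw: np.ndarray | None = None,
    test_used: list[str] | None = None,
    vip_thr: float = 1.0,
    p_thr: float = 0.05,
) -> tuple[list[DiffResult], dict]:
    """Screen features significant by both VIP > vip_thr and adjusted
    p < p_thr; direction from the group means. Returns the per-feature
    results and summary counts."""
    n = len(feature_ids)
    arrays = [np.asarray(a, float) for a in (vip, p_adjusted, mean_a, mean_b)]
    if any(a.shape != (n,) for a in arrays):
        raise ValueError("input vectors must align with feature_ids")
    vip, p_adjusted, mean_a, mean_b = arrays
    p_raw = p_adjusted if p_raw is None else np.asarray(p_raw, float)
    results = []
    for i, fid in enumerate(feature_ids):
        sig = bool(vip[i] > vip_thr and p_adjusted[i] < p_thr)
        direction = (
            "higher_in_A" if mean_a[i] > mean_b[i]
            else "higher_in_B" if mean_b[i] > mean_a[i] else ""
        )
        results.append(
            DiffResult(
                feature_id=fid,
                vip=float(vip[i]),
                p_value=float(p_raw[i]),
                p_adjusted=float(p_adjusted[i]),
                test_used=test_used[i] if test_used else "",
                direction=direction,
                significant=sig,
            )
        )
    sig = [r for r in results if r.significant]
    counts = {
        "total_significant": len(sig),
        "higher_in_A": sum(r.direction == "higher_in_A" for r in sig),
        "higher_in_B": sum(r.direction == "higher_in_B" for r in sig),
    }
    return results, counts


@dataclass
class DiversityResult:
    sample_id: str
    H: float  # Shannon index, bits
    n_nonzero: int


def shannon_diversity(
    intensities: np.ndarray, sample_id: str = ""
) -> DiversityResult:
    """Shannon index H = -sum(P_i log2 P_i) of a sample's intensity profile,
    with P_i the share of each detected (positive) feature."""
    v = np.asarray(intensities, float)
    if (v < 0).any():
        raise ValueError("negative intensities")
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError(f"sample {sample_id!r}: all intensities are zero")
    p = pos / pos.sum()
    p = p[p > 0]  # guard against underflow of extreme dynamic ranges
    return DiversityResult(
        sample_id=sample_id,
        H=float(-(p * np.log2(p)).sum()),
        n_nonzero=int(pos.size),
    )


@dataclass
class VennResult:
    unique_to_a: list[str]
    unique_to_b: list[str]
    shared: list[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.unique_to_a), len(self.unique_to_b), len(self.shared)


def venn_counts(table: FeatureTable, detection_floor: float = 0.0) -> VennResult:
    """Features detected (> floor in at least one sample) in only one of the
    two analysis groups versus both."""
    a = table.samples_in_group("A")
    b = table.samples_in_group("B")
    if not a or not b:
        raise ValueError("both analysis groups must be present")
    in_a = (table.intensities[a] > detection_floor).any(axis=1)
    in_b = (table.intensities[b] > detection_floor).any(axis=1)
    ids = table.intensities.index
    return VennResult(
        unique_to_a=list(ids[in_a & ~in_b]),
        unique_to_b=list(ids[in_b & ~in_a]),
        shared=list(ids[in_a & in_b]),
    )


def pathway_ora(
    diff_ids: set[str] | list[str],
    background_ids: set[str] | list[str],
    pathway_map: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per pathway.

    p = P[X >= observed] for X ~ Hypergeom(universe, pathway size, draw
    size). Pathways with no member in the background are skipped (noted in
    the ``note`` column with p = NaN); BH adjustment runs across tested
    pathways only.
    """
    diff = set(diff_ids)
    background = set(background_ids)
    if not diff <= background:
        raise ValueError("differential ids must be a subset of the background")
    rows = []
    for name, members in pathway_map.items():
        in_bg = set(members) & background
        if not in_bg:
            rows.append(
                {"pathway": name, "observed": 0, "pathway_size": 0,
                 "p_value": np.nan, "note": "no members in background"}
            )
            continue
        observed = len(in_bg & diff)
        p = float(
            sps.hypergeom.sf(observed - 1, len(background), len(in_bg), len(diff))
        )
        rows.append(
            {"pathway": name, "observed": observed, "pathway_size": len(in_bg),
             "p_value": p, "note": ""}
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = np.nan
    tested = df["p_value"].notna()
    if tested.any():
        df.loc[tested, "p_adjusted"] = adjust_pvalues(df.loc[tested, "p_value"])
    return df


def read_pathway_map(path) -> dict[str, set[str]]:
    """Read a TSV with columns pathway_id, metabolite_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("pathway map needs columns pathway_id, metabolite_id")
    out: dict[str, set[str]] = {}
    for pw, met in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(pw, set()).add(met)
    return out
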