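"""PCA + exhaustive discriminant-classifier selection for spectral cohorts.

The diagnostic engine: project the (patients x wavelengths) spectral matrix
onto principal components, then search every combination of discriminant
flavor and nonempty subset of the first K PCs (default K=5) for the
classifier with the lowest total prediction error. Six Gaussian
class-conditional flavors are supported, mirroring the classical
discriminant families:

``linear``          pooled full covariance (LDA)
``diaglinear``      pooled diagonal covariance (naive-Bayes LDA)
``pseudolinear``    pooled covariance inverted by Moore-Penrose pseudoinverse
``quadratic``       per-class full covariance (QDA)
``diagquadratic``   per-class diagonal covariance
``pseudoquadratic`` per-class covariance via pseudoinverse

Evaluation supports resubstitution, leave-one-patient-out CV and stratified
k-fold CV; under CV both the PCA projection and the classifier are refit on
each training fold so no information leaks from held-out patients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "FLAVORS",
    "PCAModel",
    "fit_pca",
    "DiscriminantModel",
    "fit_discriminant",
    "ConfusionTable",
    "confusion_from_predictions",
    "ROCCurve",
    "roc_auc",
    "enumerate_candidates",
    "evaluate_candidate",
    "search_candidates",
    "select_best",
]

FLAVORS = (
    "linear",
    "diaglinear",
    "pseudolinear",
    "quadratic",
    "diagquadratic",
    "pseudoquadratic",
)

POSITIVE = "cancer"  # the positive class for sensitivity/ROC conventions


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PCAModel:
    mean: np.ndarray              # (wavelengths,)
    loadings: np.ndarray          # (components, wavelengths), orthonormal rows
    scores: np.ndarray            # (samples, components)
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.loadings.T

    def inverse_transform(self, T: np.ndarray) -> np.ndarray:
        return np.asarray(T, float) @ self.loadings + self.mean


def fit_pca(X: np.ndarray, n_components: int | None = None) -> PCAModel:
    """Mean-centred PCA via SVD.

    Components are ordered by decreasing variance. Sign convention: the
    element of largest magnitude in each loading is made positive, which
    fixes the otherwise arbitrary sign of every component.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_pca needs a 2-D matrix with >= 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("fit_pca input must be finite")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float(np.sum(Xc**2)) / (X.shape[0] - 1)
    if total_var == 0.0:
        raise ValueError("degenerate input: zero variance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps)) if s.size else 0
    k = rank if n_components is None else min(n_components, rank)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # sign convention
    flips = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)])
    flips[flips == 0] = 1.0
    Vt = Vt * flips[:, None]
    U = U * flips[None, :]
    scores = U * s
    evr = (s**2 / (X.shape[0] - 1)) / total_var
    return PCAModel(mean=mean, loadings=Vt, scores=scores, explained_variance_ratio=evr)


# --------------------------------------------------------------------------
# Gaussian discriminants
# --------------------------------------------------------------------------

class SingularCovarianceError(np.linalg.LinAlgError):
    pass


def _log_pdet_and_inv(S: np.ndarray, pseudo: bool, flavor: str):
    """(log pseudo-determinant, inverse) of a covariance matrix."""
    if pseudo:
        w, V = np.linalg.eigh(S)
        tol = max(S.shape) * np.finfo(float).eps * max(w.max(), 0.0)
        keep = w > tol
        if not keep.any():
            # zero covariance: treat as isotropic unit (degenerate but defined)
            return 0.0, np.zeros_like(S)
        logdet = float(np.sum(np.log(w[keep])))
        inv = (V[:, keep] / w[keep]) @ V[:, keep].T
        return logdet, inv
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise SingularCovarianceError(
            f"singular covariance in flavor {flavor!r}; use the pseudo{flavor.replace('diag', '')} "
            "or pseudo variant"
        )
    return float(logdet), np.linalg.inv(S)


@dataclass
class DiscriminantModel:
    """Fitted Gaussian class-conditional discriminant."""

    flavor: str
    classes: list
    priors: np.ndarray
    means: np.ndarray          # (n_classes, d)
    covariances: np.ndarray    # (n_classes, d, d); identical rows for pooled flavors
    _logdets: np.ndarray = field(repr=False, default=None)
    _invs: np.ndarray = field(repr=False, default=None)

    def _discriminant_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        out = np.empty((X.shape[0], len(self.classes)))
        for k in range(len(self.classes)):
            diff = X - self.means[k]
            maha = np.einsum("ij,jk,ik->i", diff, self._invs[k], diff)
            out[:, k] = -0.5 * self._logdets[k] - 0.5 * maha + np.log(self.priors[k])
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self._discriminant_scores(X)
        idx = np.argmax(scores, axis=1)
        return np.asarray(self.classes, dtype=object)[idx]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Posterior class probabilities (softmax of discriminant scores)."""
        scores = self._discriminant_scores(X)
        scores -= scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        return e / e.sum(axis=1, keepdims=True)

    def decision_score(self, X: np.ndarray, positive=POSITIVE) -> np.ndarray:
        """Posterior probability of the positive class (ROC input)."""
        j = self.classes.index(positive)
        return self.predict_proba(X)[:, j]


def fit_discriminant(
    scores: np.ndarray,
    labels,
    flavor: str = "linear",
    priors: str | np.ndarray = "empirical",
) -> DiscriminantModel:
    """Fit one Gaussian discriminant on PC scores.

    linear* flavors pool the within-class covariance (normalised by n - K);
    quadratic* flavors estimate per-class covariance (n_k - 1); diag*
    variants zero the off-diagonal entries; pseudo* variants invert through
    the Moore-Penrose pseudoinverse so singular covariances are handled.
    """
    if flavor not in FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}; choose from {FLAVORS}")
    X = np.atleast_2d(np.asarray(scores, float))
    y = np.asarray(labels, dtype=object)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("both classes must be present to fit a discriminant")
    n, d = X.shape
    K = len(classes)
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    counts = np.array([int((y == c).sum()) for c in classes], dtype=float)
    if isinstance(priors, str) and priors == "empirical":
        pri = counts / n
    elif isinstance(priors, str) and priors == "uniform":
        pri = np.full(K, 1.0 / K)
    else:
        pri = np.asarray(priors, float)
        pri = pri / pri.sum()

    pseudo = flavor.startswith("pseudo")
    diag = flavor.startswith("diag")
    pooled = flavor.endswith("linear")

    if pooled:
        resid = np.vstack([X[y == c] - means[i] for i, c in enumerate(classes)])
        denom = max(n - K, 1)
        S = resid.T @ resid / denom
        if diag:
            S = np.diag(np.diag(S))
        covs = np.repeat(S[None], K, axis=0)
    else:
        covs = np.empty((K, d, d))
        for i, c in enumerate(classes):
            Xi = X[y == c]
            if Xi.shape[0] < 2:
                raise ValueError(
                    f"class {c!r} has fewer than 2 samples; cannot fit {flavor!r}"
                )
            Si = np.cov(Xi, rowvar=False).reshape(d, d)
            if diag:
                Si = np.diag(np.diag(Si))
            covs[i] = Si

    logdets = np.empty(K)
    invs = np.empty_like(covs)
    base = flavor.removeprefix("pseudo").removeprefix("diag")
    for i in range(K):
        logdets[i], invs[i] = _log_pdet_and_inv(covs[i], pseudo, base)
        if pooled:
            # identical pooled matrix: compute once
            logdets[:], invs[:] = logdets[i], invs[i]
            break

    return DiscriminantModel(
        flavor=flavor,
        classes=classes,
        priors=pri,
        means=means,
        covariances=covs,
        _logdets=logdets,
        _invs=invs,
    )


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionTable:
    """2x2 confusion counts with cancer as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def errors(self) -> int:
        return self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")


def confusion_from_predictions(y_true, y_pred, positive=POSITIVE) -> ConfusionTable:
    t = np.asarray(y_true, dtype=object) == positive
    p = np.asarray(y_pred, dtype=object) == positive
    return ConfusionTable(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(decision_scores, labels, positive=POSITIVE) -> ROCCurve:
    """ROC by threshold sweep over the scores; AUC by trapezoid.

    The trapezoidal AUC equals the Mann-Whitney pair statistic with ties
    counted 1/2 (checked as a test invariant).
    """
    y = np.asarray(labels, dtype=object) == positive
    if y.all() or not y.any():
        raise ValueError("both classes required for a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), np.asarray(decision_scores, float))
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


# --------------------------------------------------------------------------
# Exhaustive candidate search
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateSpec:
    flavor: str
    pc_subset: tuple[int, ...]   # 1-based PC indices


def enumerate_candidates(K: int = 5, flavors=FLAVORS) -> list[CandidateSpec]:
    """All (flavor, nonempty PC subset) pairs in deterministic order.

    Flavors iterate in the given order; subsets in ascending binary order
    of their membership mask over PCs 1..K (so {1}, {2}, {1,2}, {3}, ...).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    out = []
    for flavor in flavors:
        for mask in range(1, 2**K):
            subset = tuple(i + 1 for i in range(K) if mask >> i & 1)
            out.append(CandidateSpec(flavor=flavor, pc_subset=subset))
    return out


def _folds(labels, patient_ids, scheme: str, k: int = 5, rng=None):
    """Yield (train_idx, test_idx) partitions at the patient level."""
    n = len(labels)
    idx = np.arange(n)
    if scheme == "resubstitution":
        yield idx, idx
        return
    if scheme == "leave_one_patient_out":
        for i in range(n):
            yield np.delete(idx, i), np.array([i])
        return
    if scheme.startswith("stratified_kfold"):
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=k, shuffle=False)
        y = np.asarray(labels, dtype=object)
        yield from skf.split(idx.reshape(-1, 1), y)
        return
    raise ValueError(f"unknown evaluation scheme {scheme!r}")


def _fold_scores(X, labels, scheme, n_components, k, global_pca):
    """Per-fold (train scores, test scores, train labels, test idx) on PCs 1..K.

    PCA is refit on each training fold by default; ``global_pca=True``
    reproduces the leakier fit-once variant for reproduction studies.
    """
    X = np.asarray(X, float)
    pca_all = fit_pca(X, n_components) if global_pca else None
    for tr, te in _folds(labels, None, scheme, k):
        if global_pca:
            T = pca_all.scores
            yield T[tr], T[te], tr, te
        else:
            pca = fit_pca(X[tr], n_components)
            yield pca.scores, pca.transform(X[te]), tr, te


def evaluate_candidate(
    X: np.ndarray,
    labels,
    candidate: CandidateSpec,
    scheme: str = "leave_one_patient_out",
    n_components: int = 5,
    k: int = 5,
    priors: str = "empirical",
    global_pca: bool = False,
):
    """Evaluate one (flavor, PC subset) candidate under a CV scheme.

    Returns ``(ConfusionTable, decision_scores, y_true)`` with out-of-fold
    predictions pooled; each patient lands in a validation fold exactly
    once. Raises if any training fold lacks a class.
    """
    y = np.asarray(labels, dtype=object)
    cols = np.array(candidate.pc_subset) - 1
    preds = np.empty(len(y), dtype=object)
    dscore = np.empty(len(y))
    seen = np.zeros(len(y), dtype=bool)
    for Ttr, Tte, tr, te in _fold_scores(X, y, scheme, n_components, k, global_pca):
        ytr = y[tr]
        if len(set(ytr.tolist())) < 2:
            raise ValueError("a training fold lacks one of the classes")
        model = fit_discriminant(Ttr[:, cols], ytr, candidate.flavor, priors)
        preds[te] = model.predict(Tte[:, cols])
        dscore[te] = model.decision_score(Tte[:, cols])
        seen[te] = True
    assert seen.all()
    return confusion_from_predictions(y, preds), dscore, y


def _fold_class_stats(T: np.ndarray, y: np.ndarray, classes: list):
    """Full-K per-class means, per-class and pooled covariances, counts."""
    n, d = T.shape
    means, covs, counts = [], [], []
    resid_rows = []
    for c in classes:
        Ti = T[y == c]
        counts.append(Ti.shape[0])
        mu = Ti.mean(axis=0)
        means.append(mu)
        R = Ti - mu
        resid_rows.append(R)
        covs.append(R.T @ R / max(Ti.shape[0] - 1, 1))
    resid = np.vstack(resid_rows)
    pooled = resid.T @ resid / max(n - len(classes), 1)
    return np.array(means), np.array(covs), pooled, np.array(counts, float)


def _predict_from_stats(
    Tte: np.ndarray, means, covs, pooled, counts, cols, flavor, priors_mode, classes
):
    """Predict a candidate's labels for test scores from precomputed fold
    statistics; exactly equivalent to refitting `fit_discriminant` on the
    training slice (covariance of a coordinate subset is the submatrix)."""
    K = len(classes)
    pri = counts / counts.sum() if priors_mode == "empirical" else np.full(K, 1.0 / K)
    pseudo = flavor.startswith("pseudo")
    diag = flavor.startswith("diag")
    pooled_flavor = flavor.endswith("linear")
    base = flavor.removeprefix("pseudo").removeprefix("diag")
    Xte = Tte[:, cols]
    scores = np.empty((Xte.shape[0], K))
    sub_pooled = pooled[np.ix_(cols, cols)]
    if diag:
        sub_pooled = np.diag(np.diag(sub_pooled))
    if pooled_flavor:
        logdet, inv = _log_pdet_and_inv(sub_pooled, pseudo, base)
    for kcls in range(K):
        if not pooled_flavor:
            S = covs[kcls][np.ix_(cols, cols)]
            if diag:
                S = np.diag(np.diag(S))
            logdet, inv = _log_pdet_and_inv(S, pseudo, base)
        diff = Xte - means[kcls][cols]
        maha = np.einsum("ij,jk,ik->i", diff, inv, diff)
        scores[:, kcls] = -0.5 * logdet - 0.5 * maha + np.log(pri[kcls])
    return np.asarray(classes, dtype=object)[np.argmax(scores, axis=1)]


def search_candidates(
    X: np.ndarray,
    labels,
    K: int = 5,
    flavors=FLAVORS,
    scheme: str = "leave_one_patient_out",
    k: int = 5,
    priors: str = "empirical",
    global_pca: bool = False,
) -> pd.DataFrame:
    """Exhaustively evaluate every (flavor, PC-subset) candidate.

    Shares the per-fold PCA and the full-K class statistics across
    candidates: each candidate's class covariance on a PC subset is the
    corresponding submatrix of the full-K covariance, so the search costs
    one PCA plus one stats pass per fold and a small matrix inversion per
    candidate. Equivalent to refitting every candidate from scratch (the
    brute-force route is kept as a test oracle). Returns a DataFrame with
    one row per candidate: flavor, subset, TP/FP/TN/FN and derived metrics.
    """
    y = np.asarray(labels, dtype=object)
    classes = sorted(set(y.tolist()))
    candidates = enumerate_candidates(K, flavors)
    preds = {c: np.empty(len(y), dtype=object) for c in candidates}
    failed: set[CandidateSpec] = set()
    for Ttr, Tte, tr, te in _fold_scores(X, y, scheme, K, k, global_pca):
        ytr = y[tr]
        if len(set(ytr.tolist())) < 2:
            raise ValueError("a training fold lacks one of the classes")
        means, covs, pooled, counts = _fold_class_stats(Ttr, ytr, classes)
        for c in candidates:
            if c in failed:
                continue
            cols = np.array(c.pc_subset) - 1
            try:
                preds[c][te] = _predict_from_stats(
                    Tte, means, covs, pooled, counts, cols, c.flavor, priors, classes
                )
            except (SingularCovarianceError, np.linalg.LinAlgError):
                failed.add(c)
                continue
    rows = []
    for c in candidates:
        if c in failed:
            continue
        ct = confusion_from_predictions(y, preds[c])
        rows.append(
            {
                "flavor": c.flavor,
                "pc_subset": ",".join(map(str, c.pc_subset)),
                "n_pcs": len(c.pc_subset),
                "tp": ct.tp, "fp": ct.fp, "tn": ct.tn, "fn": ct.fn,
                "errors": ct.errors,
                "sensitivity": ct.sensitivity,
                "specificity": ct.specificity,
                "accuracy": ct.accuracy,
            }
        )
    if not rows:
        raise ValueError("no candidate could be evaluated")
    return pd.DataFrame(rows)


def select_best(results: pd.DataFrame) -> pd.Series:
    """Pick the candidate with the lowest total prediction error.

    Ties break toward (1) fewer PCs, (2) earlier flavor in the canonical
    order, (3) lexicographically earlier subset — fully deterministic.
    """
    if results.empty:
        raise ValueError("empty candidate table")
    df = results.copy()
    df["_flavor_rank"] = df["flavor"].map({f: i for i, f in enumerate(FLAVORS)})
    df["_subset_key"] = df["pc_subset"].map(
        lambda s: tuple(int(x) for x in s.split(","))
    )
    df = df.sort_values(
        by=["errors", "n_pcs", "_flavor_rank", "_subset_key"],
        kind="stable",
    )
    best = df.iloc[0].drop(["_flavor_rank", "_subset_key"])
    return best
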