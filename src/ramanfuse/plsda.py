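"""PLS-DA modeling of metabolite feature tables with VIP scoring.

Partial least-squares discriminant analysis treats the binary class label
as a regression response and extracts latent variables (X-variates) that
maximise covariance with it. The implementation is a NIPALS-type PLS1 on
autoscaled abundances. Variable importance in projection (VIP) summarises
each metabolite's contribution across components:

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a )

where SS_a is the response variance explained by component a and p the
number of metabolites; mean(VIP^2) over metabolites is identically 1.

Also here: total-signal (MTIC-style) normalisation of raw abundance
tables, cross-validated classification + ROC, and backward elimination of
the lowest-VIP metabolite to trace panel-size versus AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .discriminant import ConfusionTable, ROCCurve, confusion_from_predictions, roc_auc

__all__ = [
    "FeatureTable",
    "normalize_mtic",
    "PLSDAModel",
    "fit_plsda",
    "vip_scores",
    "crossvalidate_plsda",
    "backward_eliminate",
]

POSITIVE = "cancer"


@dataclass
class FeatureTable:
    """Samples x metabolites abundance matrix with class labels.

    ``data`` is a DataFrame (rows = samples, columns = metabolites,
    nonnegative abundances); ``labels`` a same-index Series with values
    cancer/control; ``annotations`` an optional metabolite -> chemical
    class mapping.
    """

    data: pd.DataFrame
    labels: pd.Series
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data) != len(self.labels):
            raise ValueError("data and labels disagree on sample count")
        if self.data.columns.duplicated().any():
            raise ValueError("metabolite names must be unique")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, metabolites) -> "FeatureTable":
        return replace(self, data=self.data[list(metabolites)])


def normalize_mtic(t: FeatureTable) -> FeatureTable:
    """Scale each sample so its total signal equals the cohort mean total.

    The GC-MS convention: each sample's abundances are multiplied by
    (mean total ion signal across the cohort) / (that sample's total), so
    post-normalisation row totals are all equal to the cohort mean.
    """
    totals = t.data.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total sample(s): {bad}")
    target = float(totals.mean())
    scaled = t.data.mul(target / totals, axis=0)
    return replace(t, data=scaled)


@dataclass
class PLSDAModel:
    """Fitted PLS1 discriminant model on autoscaled X, centred 0/1 response."""

    n_components: int
    metabolites: list[str]
    classes: list[str]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    log_transform: bool
    weights: np.ndarray        # (p, A) NIPALS weights w_a
    x_loadings: np.ndarray     # (p, A) loadings p_a
    y_loadings: np.ndarray     # (A,)   response loadings q_a
    x_scores: np.ndarray       # (n, A) scores t_a
    ss_response: np.ndarray    # (A,) response variance explained per component
    ss_x: np.ndarray           # (A,) X variance captured per component
    threshold: float           # decision cut on the continuous prediction
    coef_: np.ndarray = None   # (p,) regression vector on autoscaled X

    def predict_score(self, data: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Continuous prediction of the (centred) class response."""
        X = np.asarray(data, float)
        if self.log_transform:
            X = np.log1p(X)
        Xs = (X - self.x_mean) / self.x_std
        return Xs @ self.coef_ + self.y_mean

    def predict(self, data) -> np.ndarray:
        score = self.predict_score(data)
        pos, neg = self.classes[0], self.classes[1]
        return np.where(score >= self.threshold, pos, neg)


def fit_plsda(
    t: FeatureTable,
    n_components: int = 2,
    drop_constant: bool = True,
    log_transform: bool = True,
) -> PLSDAModel:
    """NIPALS-type PLS1 against the 0/1 class response.

    Abundances are log1p-transformed by default (metabolite intensities
    are approximately lognormal, and PLS on the raw scale is dominated by
    the skew), then autoscaled (per-metabolite mean 0, SD 1); y is the
    centred 0/1 indicator of the cancer class. For a single response
    NIPALS reduces to the direct sequence w_a = X'y/||X'y||, t_a = Xw_a,
    with X and y deflated after each component. Class prediction
    thresholds the continuous response at the midpoint of the two class
    means of the fitted scores. Constant metabolite columns are dropped
    (with a warning) before autoscaling.
    """
    labels = t.labels.astype(str)
    classes = sorted(set(labels), reverse=True)  # cancer before control
    if len(classes) != 2:
        raise ValueError("PLS-DA requires exactly two classes")
    if POSITIVE in classes:
        classes = [POSITIVE] + [c for c in classes if c != POSITIVE]
    data = t.data
    stds = data.std(axis=0, ddof=1)
    if drop_constant and (stds == 0).any():
        import warnings

        warnings.warn(
            f"dropping {int((stds == 0).sum())} constant metabolite column(s) before autoscaling"
        )
        data = data.loc[:, stds > 0]
        if data.shape[1] == 0:
            raise ValueError("all metabolite columns are constant")
    X = data.to_numpy(dtype=float)
    if log_transform:
        X = np.log1p(X)
    y = (labels == classes[0]).to_numpy(dtype=float)

    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    Xs = (X - x_mean) / x_std
    y_mean = float(y.mean())
    yc = y - y_mean

    n, p = Xs.shape
    rank = np.linalg.matrix_rank(Xs)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    ss_resp = np.zeros(n_components)
    ss_x = np.zeros(n_components)
    Xd, yd = Xs.copy(), yc.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("response variance exhausted; reduce n_components")
        w /= nw
        tvec = Xd @ w
        tt = float(tvec @ tvec)
        pvec = Xd.T @ tvec / tt
        q = float(yd @ tvec) / tt
        Xd = Xd - np.outer(tvec, pvec)
        yd = yd - q * tvec
        W[:, a], P[:, a], Q[a], T[:, a] = w, pvec, q, tvec
        ss_resp[a] = q * q * tt
        ss_x[a] = tt * float(pvec @ pvec)

    # regression vector on autoscaled X: B = W (P'W)^-1 q
    Bstar = W @ np.linalg.solve(P.T @ W, Q)
    fitted = Xs @ Bstar + y_mean
    mu_pos = fitted[y == 1].mean()
    mu_neg = fitted[y == 0].mean()
    threshold = 0.5 * (mu_pos + mu_neg)

    return PLSDAModel(
        n_components=n_components,
        metabolites=list(data.columns),
        classes=classes,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        log_transform=log_transform,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
        ss_response=ss_resp,
        ss_x=ss_x,
        threshold=threshold,
        coef_=Bstar,
    )


def vip_scores(m: PLSDAModel) -> pd.Series:
    """Variable importance in projection per metabolite.

    mean(VIP^2) over the metabolites equals 1 by construction.
    """
    ss = m.ss_response
    if ss.sum() == 0:
        raise ValueError("zero explained response variance; VIP undefined")
    p = len(m.metabolites)
    wn = m.weights / np.linalg.norm(m.weights, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn**2 @ ss) / ss.sum())
    return pd.Series(vip, index=m.metabolites, name="VIP")


def _loo_folds(n: int):
    idx = np.arange(n)
    for i in range(n):
        yield np.delete(idx, i), np.array([i])


def crossvalidate_plsda(
    t: FeatureTable,
    n_components: int = 2,
    scheme: str = "leave_one_out",
    k: int = 5,
    renormalize: bool = True,
    log_transform: bool = True,
    metabolites: list[str] | None = None,
) -> tuple[ConfusionTable, ROCCurve, np.ndarray]:
    """Cross-validated PLS-DA classification.

    Per fold, the MTIC scaling target, autoscaling statistics and the PLS
    model are all refit on the training samples only; held-out samples are
    scaled by the training totals target. Pooled out-of-fold continuous
    predictions feed the ROC. Returns (confusion, roc, oof_scores).

    ``metabolites`` restricts the model to a panel while the per-sample
    normalisation still uses the full profile in ``t`` — total-signal
    scaling is a property of the whole measurement, and normalising within
    a small panel would divide out exactly the shared abundance shifts the
    panel is meant to detect.
    """
    labels = t.labels.astype(str).to_numpy()
    n = t.n_samples
    panel = t.metabolites if metabolites is None else list(metabolites)
    if scheme == "leave_one_out":
        folds = _loo_folds(n)
    elif scheme.startswith("stratified_kfold"):
        from sklearn.model_selection import StratifiedKFold

        folds = StratifiedKFold(n_splits=k, shuffle=False).split(
            np.zeros((n, 1)), labels
        )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    oof_score = np.empty(n)
    oof_pred = np.empty(n, dtype=object)
    for tr, te in folds:
        tr_data = t.data.iloc[tr]
        te_data = t.data.iloc[te]
        if renormalize:
            # full-profile totals, training-fold scaling target
            totals_tr = tr_data.sum(axis=1)
            target = float(totals_tr.mean())
            tr_data = tr_data.mul(target / totals_tr, axis=0)
            te_data = te_data.mul(target / te_data.sum(axis=1), axis=0)
        sub = FeatureTable(
            data=tr_data[panel], labels=t.labels.iloc[tr], annotations=t.annotations
        )
        model = fit_plsda(sub, n_components, log_transform=log_transform)
        te_panel = te_data[model.metabolites]
        oof_score[te] = model.predict_score(te_panel)
        oof_pred[te] = model.predict(te_panel)
    ct = confusion_from_predictions(labels, oof_pred)
    roc = roc_auc(oof_score, labels)
    return ct, roc, oof_score


def backward_eliminate(
    t: FeatureTable,
    n_components: int = 2,
    scheme: str = "leave_one_out",
    min_keep: int = 2,
    refit_vip: bool = True,
) -> pd.DataFrame:
    """Drop the lowest-VIP metabolite step by step, tracking CV AUC.

    At each step the PLS model is refit on the retained metabolites, VIP is
    recomputed (or frozen from the full model with ``refit_vip=False``),
    the lowest-VIP metabolite is removed, and the cross-validated AUC of
    the reduced panel recorded. Returns a DataFrame with one row per panel
    size from p down to ``min_keep``, including the retained metabolite
    list, so the top-k panel for any k is recoverable.
    """
    normalized = normalize_mtic(t)
    retained = list(t.metabolites)
    frozen_order: list[str] | None = None
    if not refit_vip:
        full_vip = vip_scores(fit_plsda(normalized, n_components))
        frozen_order = list(full_vip.sort_values().index)  # ascending importance
    rows = []
    while len(retained) >= min_keep:
        _, roc, _ = crossvalidate_plsda(t, n_components, scheme, metabolites=retained)
        rows.append(
            {
                "n_metabolites": len(retained),
                "auc": roc.auc,
                "retained": ";".join(retained),
            }
        )
        if len(retained) == min_keep:
            break
        if refit_vip:
            vip = vip_scores(fit_plsda(normalized.subset(retained), n_components))
            worst = vip.idxmin()
        else:
            worst = next(m for m in frozen_order if m in retained)
        retained.remove(worst)
    return pd.DataFrame(rows)
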