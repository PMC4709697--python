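"""Accuracy evaluation: marker QC, mean imputation, k-fold and
over-generation validation, adjusted accuracy, bias slope, PCA and
marker-effect comparisons.

Prediction accuracy is the Pearson correlation between validation EBVs
and true breeding values (simulations) or phenotypes (empirical data);
the latter is divided by sqrt(h2) to estimate the TBV correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import KFold

from .genome import ValidationError
from .models import PedigreeBLUP


def qc_filter(
    X: np.ndarray,
    maf_min: float = 0.05,
    call_rate_min: float = 0.70,
    return_report: bool = False,
):
    """Retain markers with call rate > ``call_rate_min`` and minor-allele
    frequency > ``maf_min`` (computed on observed genotypes).

    ``X`` is individuals x markers with NaN for missing; entries otherwise
    in {0, 1, 2}.  Returns (X_filtered, kept_indices[, report]).
    """
    X = np.asarray(X, dtype=float)
    obs = ~np.isnan(X)
    vals = np.where(obs, X, 0.0)
    bad = vals[obs & ((vals < 0) | (vals > 2))] if obs.any() else np.empty(0)
    if bad.size:
        raise ValidationError("genotype entries must be 0/1/2 or missing")
    call_rate = obs.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(obs, X, 0.0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = (call_rate > call_rate_min) & (maf > maf_min)
    if not keep.any():
        raise ValidationError("QC removed every marker")
    report = pd.DataFrame({"maf": maf, "call_rate": call_rate, "kept": keep})
    idx = np.flatnonzero(keep)
    if return_report:
        return X[:, idx], idx, report
    return X[:, idx], idx


def impute_mean(X: np.ndarray) -> np.ndarray:
    """Replace missing genotypes by the column mean of observed values."""
    X = np.asarray(X, dtype=float).copy()
    obs = ~np.isnan(X)
    if (~obs).any():
        counts = obs.sum(axis=0)
        if (counts == 0).any():
            raise ValidationError("fully missing marker column; run QC first")
        means = np.where(obs, X, 0.0).sum(axis=0) / counts
        rows, cols = np.nonzero(~obs)
        X[rows, cols] = means[cols]
    return X


def adjusted_accuracy(r_y_ebv: float, h2: float) -> float:
    """Estimated TBV correlation r(y, EBV) / sqrt(h2)."""
    if h2 <= 0:
        raise ValidationError("h2 must be positive")
    out = r_y_ebv / np.sqrt(h2)
    if abs(out) > 1:
        warnings.warn(f"adjusted accuracy {out:.3f} exceeds 1")
    return float(out)


def bias_slope(y_validation: np.ndarray, ebv_validation: np.ndarray) -> float:
    """OLS slope of observed phenotype on EBV; ~1 for unbiased prediction."""
    ebv = np.asarray(ebv_validation, dtype=float)
    y = np.asarray(y_validation, dtype=float)
    v = np.var(ebv, ddof=1)
    if v == 0:
        raise ValidationError("EBVs are constant; slope undefined")
    return float(np.cov(y, ebv)[0, 1] / v)


def pca(matrix: np.ndarray, n_components: int = 2):
    """Centered SVD-based PCA; returns (scores, explained_variance_ratio)."""
    from sklearn.decomposition import PCA

    M = np.asarray(matrix, dtype=float)
    if np.isnan(M).any():
        raise ValidationError("PCA input must be complete; impute first")
    if M.shape[0] < n_components:
        raise ValidationError("fewer rows than requested components")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(M)
    return scores, model.explained_variance_ratio_


def marker_effect_correlation(fits: dict) -> pd.DataFrame:
    """Pearson correlations of per-marker effect vectors between methods.

    ``fits`` maps method name -> fitted estimator (with marker_effects_)
    or a raw effect vector.  Methods without per-marker effects (e.g.
    G-BLUP by default) should be omitted by the caller.
    """
    vecs = {}
    m = None
    for name, fit in fits.items():
        v = fit if isinstance(fit, np.ndarray) else getattr(fit, "marker_effects_")
        if v is None:
            raise ValidationError(f"{name} has no marker effects")
        v = np.asarray(v, dtype=float)
        if m is None:
            m = v.size
        elif v.size != m:
            raise ValidationError("effect vectors must share the marker panel")
        vecs[name] = v
    names = list(vecs)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va, vb = vecs[a], vecs[b]
            if va.std() == 0 or vb.std() == 0:
                r = np.nan
            else:
                r = np.corrcoef(va, vb)[0, 1]
            out.loc[a, b] = out.loc[b, a] = r
    return out


@dataclass
class CVScheme:
    """k-fold resampling plan: ``n_repeats`` independent random partitions."""

    n_folds: int = 5
    n_repeats: int = 100
    stratify_by_family: bool = False
    seed: int | None = None


def _corr(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _fit_predict(model, X_tr, y_tr, X_va, fam_tr, ids_tr, ids_va):
    est = clone(model)
    if isinstance(est, PedigreeBLUP):
        est.fit(X_tr, y_tr, families=fam_tr, ids=ids_tr)
        return est, est.predict(ids=ids_va)
    est.fit(X_tr, y_tr, families=fam_tr, ids=ids_tr)
    return est, est.predict(X_va)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    models: dict,
    scheme: CVScheme | None = None,
    tbv: np.ndarray | None = None,
    families: np.ndarray | None = None,
    ids: np.ndarray | None = None,
    h2: float | None = None,
    preprocess: bool = False,
) -> pd.DataFrame:
    """k-fold cross-validated prediction accuracy for each model.

    Every repeat draws a fresh random partition; each individual is
    validated exactly once per repeat, and the pooled validation EBVs are
    correlated with TBV (simulations) or with the phenotype (empirical
    mode, when ``tbv`` is None; pass ``h2`` to also report the adjusted
    accuracy).  With ``preprocess=True`` marker QC and mean imputation are
    performed inside each training split and applied to the fold's
    validation markers (no leakage).
    """
    scheme = scheme or CVScheme(n_repeats=1)
    if scheme.n_folds < 2:
        raise ValidationError("need at least 2 folds")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    rng = np.random.default_rng(scheme.seed)
    rows = []
    for rep in range(scheme.n_repeats):
        kf = KFold(scheme.n_folds, shuffle=True,
                   random_state=int(rng.integers(2**31)))
        ebv = {name: np.full(n, np.nan) for name in models}
        for tr, va in kf.split(X):
            X_tr, X_va = X[tr], X[va]
            if preprocess:
                X_tr, kept = qc_filter(X_tr)[:2]
                X_tr = impute_mean(X_tr)
                X_va = X_va[:, kept]
                # fill validation gaps with training column means
                means = X_tr.mean(axis=0)
                miss = np.isnan(X_va)
                X_va = np.where(miss, means, X_va)
            fam_tr = None if families is None else np.asarray(families)[tr]
            ids_tr = None if ids is None else np.asarray(ids)[tr]
            ids_va = None if ids is None else np.asarray(ids)[va]
            for name, model in models.items():
                _, pred = _fit_predict(model, X_tr, y[tr], X_va,
                                       fam_tr, ids_tr, ids_va)
                ebv[name][va] = pred
        truth = tbv if tbv is not None else y
        for name in models:
            e = ebv[name]
            r = _corr(e, truth)
            if np.isnan(r):
                warnings.warn(f"{name}: constant EBVs in repeat {rep}")
                rows.append({"method": name, "repeat": rep, "accuracy": np.nan,
                             "adjusted": np.nan, "slope": np.nan})
                continue
            adj = adjusted_accuracy(r, h2) if (tbv is None and h2) else np.nan
            slope = bias_slope(y, e) if np.var(e) > 0 else np.nan
            rows.append({"method": name, "repeat": rep, "accuracy": r,
                         "adjusted": adj, "slope": slope})
    return pd.DataFrame(rows)


def over_generation_eval(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    tbv_test: np.ndarray,
    models: dict,
    families_train: np.ndarray | None = None,
    ids_train: np.ndarray | None = None,
    ids_test: np.ndarray | None = None,
) -> pd.DataFrame:
    """Train on one generation, predict its descendants, and report the
    correlation of predicted GEBVs with the next generation's TBVs."""
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_train.shape[1] != X_test.shape[1]:
        raise ValidationError("train and test marker panels differ")
    rows = []
    for name, model in models.items():
        _, pred = _fit_predict(model, X_train, y_train, X_test,
                               families_train, ids_train, ids_test)
        rows.append({
            "method": name,
            "accuracy": _corr(pred, tbv_test),
            "slope": np.nan,
        })
    return pd.DataFrame(rows)
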