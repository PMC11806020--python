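"""Multivariate prediction of regional tau from cell-type or gene features.

For each tauopathy dataset, candidate features are ranked by Pearson
correlation with tau and the weakest are pruned (lower 75% for cell types,
lower 50% for gene panels, so the retained pools are comparable in size).
Nested linear models are then built by adding features in rank order — the
"BIC ladder", dimensionality 2 through n+1 counting the intercept — and the
minimum-BIC rung is selected.  A fixed top-5 model (by construction equal to
the ladder's dimensionality-6 rung) and seeded 10-fold cross-validation
complete the model battery; selection frequencies across datasets are
compared between cell-type classes with a chi-squared goodness-of-fit test.

BIC convention: ``-2 ln L + k ln n`` with a Gaussian likelihood at the MLE
variance RSS/n, where k counts the intercept plus slopes (not sigma^2); this
is the standard regression-package convention and is what
:class:`statsmodels.api.OLS` reports.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import KFold

from .coreg import align_dataset
from .types import Atlas, TauopathyDataset

#: Fraction of features retained after correlation ranking, by pool kind.
KEEP_FRACTION = {"types": 0.25, "genes": 0.50}


@dataclass
class LinearModelFit:
    """One fitted regional tau model and its selection provenance."""

    dataset_id: str
    time_point: str
    pool: str
    candidates: list[str]
    selected: list[str]
    coefficients: pd.Series
    r_squared: float
    p: float
    bic: float
    n_regions: int
    ladder: pd.DataFrame | None = None
    cv: dict[str, float] | None = None
    skipped: list[str] = field(default_factory=list)


def rank_and_prune(features: pd.DataFrame, tau: pd.Series,
                   pool: str = "types",
                   keep_fraction: float | None = None) -> list[str]:
    """Order features by descending Pearson R to tau and keep the top fraction.

    The retained count is ``ceil(keep_fraction * n_features)`` (25% for cell
    types, 50% for gene panels by default).  The ordering is invariant to
    affine rescaling of tau.
    """
    if features.shape[1] == 0:
        raise ValueError("empty feature pool")
    if keep_fraction is None:
        if pool not in KEEP_FRACTION:
            raise ValueError(f"unknown pool kind {pool!r}")
        keep_fraction = KEEP_FRACTION[pool]
    common = features.index.intersection(tau.index)
    X = features.loc[common]
    y = tau.loc[common]
    r = X.corrwith(y)
    order = sorted(r.index, key=lambda f: (-r[f] if np.isfinite(r[f]) else np.inf, f))
    n_keep = math.ceil(keep_fraction * len(order))
    return order[:n_keep]


def _ols(X: np.ndarray, y: np.ndarray):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def bic_ladder(features: pd.DataFrame, tau: pd.Series, candidates: list[str],
               dataset_id: str = "", time_point: str = "", pool: str = "types",
               ) -> LinearModelFit:
    """Nested correlation-ranked models scored by BIC; the minimum rung wins.

    Models of dimensionality 2 to ``len(candidates) + 1`` (counting the
    intercept) add candidates in rank order.  A candidate that makes the
    design singular (collinear with the included features) is skipped with a
    warning at that rung.
    """
    common = features.index.intersection(tau.index)
    y = tau.loc[common].to_numpy(dtype=float)
    n = len(common)
    if n <= len(candidates) + 3:
        warnings.warn("few regions relative to model dimensionality; "
                      "larger rungs may be unreliable")
    included: list[str] = []
    skipped: list[str] = []
    rungs = []
    best = None
    for cand in candidates:
        trial = included + [cand]
        X = features.loc[common, trial].to_numpy(dtype=float)
        design = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn(f"skipping collinear feature {cand!r}")
            skipped.append(cand)
            continue
        included = trial
        fit = _ols(X, y)
        rungs.append({"dimensionality": len(included) + 1,
                      "features": tuple(included),
                      "r_squared": float(fit.rsquared),
                      "bic": float(fit.bic),
                      "p": float(fit.f_pvalue)})
        if best is None or fit.bic < best[0]:
            best = (float(fit.bic), list(included), fit)
    if best is None:
        raise ValueError("no fittable model rung (all candidates collinear?)")
    bic, selected, fit = best
    coef = pd.Series(fit.params, index=["intercept", *selected])
    return LinearModelFit(
        dataset_id=dataset_id, time_point=time_point, pool=pool,
        candidates=list(candidates), selected=selected, coefficients=coef,
        r_squared=float(fit.rsquared), p=float(fit.f_pvalue), bic=bic,
        n_regions=n, ladder=pd.DataFrame(rungs), skipped=skipped)


def top_k_model(features: pd.DataFrame, tau: pd.Series, candidates: list[str],
                k: int = 5, dataset_id: str = "", time_point: str = "",
                pool: str = "types") -> LinearModelFit:
    """Single fit on the ``k`` most correlated candidates.

    By construction this equals the BIC ladder's dimensionality-(k+1) rung.
    """
    if k > len(candidates):
        raise ValueError("k exceeds the candidate pool")
    chosen = list(candidates[:k])
    common = features.index.intersection(tau.index)
    X = features.loc[common, chosen].to_numpy(dtype=float)
    y = tau.loc[common].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear top-k design")
    fit = _ols(X, y)
    coef = pd.Series(fit.params, index=["intercept", *chosen])
    return LinearModelFit(
        dataset_id=dataset_id, time_point=time_point, pool=pool,
        candidates=list(candidates), selected=chosen, coefficients=coef,
        r_squared=float(fit.rsquared), p=float(fit.f_pvalue),
        bic=float(fit.bic), n_regions=len(common))


def crossvalidate(features: pd.DataFrame, tau: pd.Series, selected: list[str],
                  folds: int = 10, rng_seed: int = 0) -> dict[str, float]:
    """Seeded 10-fold cross-validation of a selected-feature linear model.

    Regions are shuffled into folds; out-of-fold predictions are pooled, and
    CV R^2, an F-statistic p-value, and a BIC computed from the pooled
    out-of-fold Gaussian log-likelihood are returned.  Folds are reduced with
    a warning when any fold would hold fewer than 2 regions.
    """
    common = features.index.intersection(tau.index)
    n = len(common)
    if n < folds:
        raise ValueError("need at least as many regions as folds")
    if n < 2 * folds:
        new_folds = max(2, n // 2)
        warnings.warn(f"reducing folds from {folds} to {new_folds}")
        folds = new_folds
    X = features.loc[common, selected].to_numpy(dtype=float)
    y = tau.loc[common].to_numpy(dtype=float)
    preds = np.empty(n)
    fold_r2 = []
    kf = KFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    for train, test in kf.split(X):
        fit = _ols(X[train], y[train])
        design = sm.add_constant(X[test], has_constant="add")
        preds[test] = design @ fit.params
        sst = ((y[test] - y[test].mean()) ** 2).sum()
        ssr = ((y[test] - preds[test]) ** 2).sum()
        fold_r2.append(1.0 - ssr / sst if sst > 0 else np.nan)
    rss = float(((y - preds) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    k = len(selected) + 1
    p_feat = len(selected)
    if np.isfinite(r2) and r2 < 1.0 and n - p_feat - 1 > 0:
        F = (r2 / p_feat) / ((1.0 - r2) / (n - p_feat - 1))
        p = float(stats.f.sf(F, p_feat, n - p_feat - 1)) if F > 0 else 1.0
    else:
        p = np.nan
    sigma2 = rss / n if rss > 0 else np.finfo(float).tiny
    llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    bic = -2.0 * llf + k * np.log(n)
    return {"r_squared": float(r2), "p": p, "bic": float(bic),
            "folds": folds, "mean_fold_r_squared": float(np.nanmean(fold_r2))}


def fit_dataset_models(
    features_regional: pd.DataFrame,
    datasets: list[TauopathyDataset],
    atlas: Atlas,
    pool: str = "types",
    k: int = 5,
    folds: int = 10,
    rng_seed: int = 0,
    timepoint: int = -1,
    with_cv: bool = True,
) -> dict[str, dict[str, LinearModelFit]]:
    """BIC-ladder and top-k models for every dataset at one time point.

    ``features_regional`` is features x atlas regions.  Returns, per dataset,
    ``{"bic": fit, "top_k": fit}`` with cross-validation results attached to
    the BIC fit.
    """
    out: dict[str, dict[str, LinearModelFit]] = {}
    for ds in datasets:
        feats, tau = align_dataset(features_regional.T, ds, atlas)
        y = tau.iloc[:, timepoint]
        tp = str(tau.columns[timepoint])
        candidates = rank_and_prune(feats, y, pool=pool)
        fit = bic_ladder(feats, y, candidates, dataset_id=ds.dataset_id,
                         time_point=tp, pool=pool)
        if with_cv:
            fit.cv = crossvalidate(feats, y, fit.selected, folds=folds,
                                   rng_seed=rng_seed)
        kk = min(k, len(candidates))
        top = top_k_model(feats, y, candidates, k=kk,
                          dataset_id=ds.dataset_id, time_point=tp, pool=pool)
        out[ds.dataset_id] = {"bic": fit, "top_k": top}
    return out


def summary_table(fits: dict[str, dict[str, LinearModelFit]],
                  which: str = "bic") -> pd.DataFrame:
    """Per-dataset model statistics (R^2, n selected, BIC, raw and adjusted p)."""
    rows = []
    for ds, pair in fits.items():
        f = pair[which]
        rows.append({"dataset": ds, "r_squared": f.r_squared,
                     "n_features": len(f.selected), "bic": f.bic, "p": f.p,
                     "n_regions": f.n_regions})
    out = pd.DataFrame(rows).set_index("dataset")
    out["p_corr"] = np.minimum(1.0, out["p"] * len(out))
    return out


def selection_statistics(fits: list[LinearModelFit],
                         class_label: dict[str, str],
                         all_features: list[str]
                         ) -> tuple[pd.Series, dict[str, float]]:
    """Selection frequencies and a class-representation chi-squared GOF test.

    Observed counts are how often each class's features appear among selected
    features across fits; expected counts are proportional to class sizes in
    the full feature pool, scaled to the total number of selections.  Classes
    with zero expected count are excluded with a warning.
    """
    if not fits:
        raise ValueError("no fits supplied")
    counts: dict[str, int] = {f: 0 for f in all_features}
    for fit in fits:
        for f in fit.selected:
            counts[f] = counts.get(f, 0) + 1
    freq = pd.Series(counts, name="selection_count").sort_values(ascending=False)

    classes = sorted(set(class_label.values()))
    pool_sizes = {c: sum(1 for f in all_features if class_label.get(f) == c)
                  for c in classes}
    total = int(freq.sum())
    observed, expected, used = [], [], []
    for c in classes:
        if pool_sizes[c] == 0:
            warnings.warn(f"class {c!r} has no features in the pool; excluded")
            continue
        obs = sum(counts.get(f, 0) for f in all_features
                  if class_label.get(f) == c)
        exp = total * pool_sizes[c] / sum(
            pool_sizes[k] for k in classes if pool_sizes[k] > 0)
        observed.append(obs)
        expected.append(exp)
        used.append(c)
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = len(used) - 1
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
    return freq, {"chi2": chi2, "df": df, "p": p,
                  "classes": used, "observed": observed.tolist(),
                  "expected": expected.tolist()}
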