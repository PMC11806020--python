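"""Univariate association of regional features with tau pathology.

Per-feature correlations against end-time-point tau across datasets are
assessed with autocorrelation-preserving surrogate nulls: each null map is a
random permutation of the source map, smoothed with a distance kernel whose
bandwidth is fitted so the surrogate's binned variogram matches the source's,
then rank-remapped back onto the source value multiset (so every surrogate
shares the source's marginal distribution while preserving its spatial
autocorrelation).  Empirical p-values use the add-one correction
``p = (1 + #{|null| >= |obs|}) / (n + 1)``.

Also provided: class-level one-sample and pairwise t-tests on pooled
type-by-dataset correlations, and the risk-gene eigengene (first principal
component of a gene panel's regional expression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from .coreg import align_dataset
from .types import Atlas, TauopathyDataset

# ---------------------------------------------------------------------------
# correlations


def correlate_features(features: pd.DataFrame, tau: pd.Series,
                       method: str = "pearson") -> pd.Series:
    """One correlation per feature column against a tau vector.

    ``features`` is regions x features, sharing its index with ``tau``
    (at least 3 regions).  Constant features (or constant tau) yield NaN.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    common = features.index.intersection(tau.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared regions to correlate")
    X = features.loc[common].to_numpy(dtype=float)
    y = tau.loc[common].to_numpy(dtype=float)
    if method == "spearman":
        X = stats.rankdata(X, axis=0)
        y = stats.rankdata(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Xc * yc[:, None]).sum(axis=0) / denom, np.nan)
    return pd.Series(r, index=features.columns, name="R")


def association_table(
    features_regional: pd.DataFrame,
    datasets: list[TauopathyDataset],
    atlas: Atlas,
    method: str = "pearson",
    timepoint: int = -1,
) -> pd.DataFrame:
    """Tidy per-(feature, dataset) correlations on seed-removed region sets.

    ``features_regional`` is features x atlas regions.  Each dataset is
    projected into its own region space (seed regions removed) before
    correlating against the chosen tau time point (default: last).
    """
    rows = []
    table = features_regional.T  # regions x features
    for ds in datasets:
        feats, tau = align_dataset(table, ds, atlas)
        r = correlate_features(feats, tau.iloc[:, timepoint], method=method)
        for feature, val in r.items():
            rows.append({"feature": feature, "dataset": ds.dataset_id,
                         "time_point": tau.columns[timepoint], "R": val})
    return pd.DataFrame(rows)


def mean_correlation(assoc: pd.DataFrame) -> pd.Series:
    """Mean correlation across datasets, indexed by feature."""
    return assoc.groupby("feature")["R"].mean()


# ---------------------------------------------------------------------------
# variogram-matched surrogate nulls


@dataclass
class SurrogateEnsemble:
    """Surrogate maps plus the variogram diagnostics of their construction."""

    maps: pd.DataFrame          # n_surrogates x n_regions, atlas region columns
    source: pd.Series
    bin_distance: np.ndarray
    source_variogram: np.ndarray
    mean_surrogate_variogram: np.ndarray
    rng_seed: int


def variogram(values: np.ndarray, bin_index: np.ndarray, n_bins: int) -> np.ndarray:
    """Binned empirical variogram: mean of ``0.5 * (x_i - x_j)^2`` per distance bin."""
    diffs = 0.5 * (values[_pair_i(len(values))] - values[_pair_j(len(values))]) ** 2
    return np.bincount(bin_index, weights=diffs, minlength=n_bins) / np.bincount(
        bin_index, minlength=n_bins)


def _pair_i(n: int) -> np.ndarray:
    return np.triu_indices(n, k=1)[0]


def _pair_j(n: int) -> np.ndarray:
    return np.triu_indices(n, k=1)[1]


def _equal_count_bins(d: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each pairwise distance to one of ``n_bins`` equal-count bins."""
    order = np.argsort(d, kind="stable")
    idx = np.empty(len(d), dtype=np.int64)
    idx[order] = np.minimum((np.arange(len(d)) * n_bins) // len(d), n_bins - 1)
    return idx


#: White-noise (nugget) admixture weights tried per surrogate; the nugget
#: term restores short-range variance that kernel smoothing alone removes.
NUGGET_WEIGHTS = (0.0, 0.15, 0.3, 0.5, 0.8)


def make_surrogates(
    source_map: pd.Series,
    region_centroids: pd.DataFrame,
    n_surrogates: int = 10_000,
    rng_seed: int = 0,
    n_bins: int = 25,
    n_bandwidths: int = 20,
) -> SurrogateEnsemble:
    """Variogram-matched spatial surrogate maps of a regional vector.

    Each surrogate is built by (i) randomly permuting the source values,
    (ii) smoothing with a row-normalized Gaussian distance kernel and mixing
    in a white-noise nugget term (candidate bandwidths on a log-spaced grid
    crossed with a small nugget-weight grid; the candidate minimizing the
    relative squared discrepancy between the surrogate's and the source's
    binned variograms wins), and (iii) rank-remapping the values back onto
    the source value multiset, so every surrogate shares the source's
    marginal distribution.  Deterministic for a fixed seed.  Requires at
    least 10 regions (the variogram is unstable below that).
    """
    values = source_map.to_numpy(dtype=float)
    n = len(values)
    if n < 10:
        raise ValueError("need at least 10 regions for variogram-matched surrogates")
    cent = region_centroids.loc[source_map.index].to_numpy(dtype=float)
    d = pdist(cent)
    n_bins = min(n_bins, len(d))
    bin_index = _equal_count_bins(d, n_bins)
    counts = np.bincount(bin_index, minlength=n_bins).astype(float)
    bin_dist = np.bincount(bin_index, weights=d, minlength=n_bins) / counts
    gamma_src = variogram(values, bin_index, n_bins)
    # relative discrepancy needs positive reference bins; a constant map has
    # an all-zero variogram and every candidate fits it exactly
    gamma_ref = np.where(gamma_src > 0, gamma_src, 1.0)

    pos = d[d > 0]
    d_lo = float(pos.min()) if pos.size else 1.0
    d_hi = float(d.max()) if d.max() > 0 else 1.0
    bandwidths = np.geomspace(d_lo / 2.0, d_hi, n_bandwidths)

    from scipy.spatial.distance import squareform
    D2 = squareform(d) ** 2

    rng = np.random.default_rng(rng_seed)
    perms = np.array([rng.permutation(values) for _ in range(n_surrogates)])
    noise = rng.standard_normal(perms.shape)
    sorted_src = np.sort(values)
    ii, jj = _pair_i(n), _pair_j(n)
    # binning operator: (n_pairs x n_bins), column b averages bin-b pairs
    W = np.zeros((len(d), n_bins))
    W[np.arange(len(d)), bin_index] = 1.0 / counts[bin_index]

    best_sse = np.full(n_surrogates, np.inf)
    best_maps = np.empty_like(perms)
    for b in bandwidths:
        K = np.exp(-D2 / (2.0 * b * b))
        K /= K.sum(axis=1, keepdims=True)
        smoothed = perms @ K.T
        sm_sd = smoothed.std(axis=1, keepdims=True)
        sm_z = (smoothed - smoothed.mean(axis=1, keepdims=True)) / \
            np.where(sm_sd > 0, sm_sd, 1.0)
        for w in NUGGET_WEIGHTS:
            candidate = sm_z + w * noise
            # rank-remap onto the source value multiset
            order = np.argsort(candidate, axis=1)
            remapped = np.empty_like(candidate)
            np.put_along_axis(remapped, order, sorted_src[None, :], axis=1)
            gamma = (0.5 * (remapped[:, ii] - remapped[:, jj]) ** 2) @ W
            sse = (((gamma - gamma_src[None, :]) / gamma_ref) ** 2).sum(axis=1)
            better = sse < best_sse
            best_sse[better] = sse[better]
            best_maps[better] = remapped[better]

    maps = pd.DataFrame(best_maps, columns=source_map.index)
    mean_gamma = (0.5 * (best_maps[:, ii] - best_maps[:, jj]) ** 2
                  ).mean(axis=0) @ W
    return SurrogateEnsemble(
        maps=maps, source=source_map, bin_distance=bin_dist,
        source_variogram=gamma_src, mean_surrogate_variogram=mean_gamma,
        rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# surrogate-null test of the mean correlation


def _dataset_projection(dataset: TauopathyDataset, atlas: Atlas,
                        timepoint: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """Weight matrix projecting an atlas-space map into a dataset's seed-removed
    region space, plus the matching tau vector."""
    volume = atlas.region_volume
    atlas_pos = {r: k for k, r in enumerate(atlas.region_ids)}
    rows, tau_vals = [], []
    seeds = set(dataset.seed_region_ids)
    for region in dataset.region_ids:
        if region in seeds:
            continue
        members = [m for m in dataset.mapping_table.get(region, [])
                   if m in atlas_pos]
        if not members:
            continue
        w = np.zeros(atlas.n_regions)
        vols = volume.loc[members].to_numpy().astype(float)
        for m, v in zip(members, vols):
            w[atlas_pos[m]] = v / vols.sum()
        rows.append(w)
        tau_vals.append(dataset.tau.loc[region].iloc[timepoint])
    if len(rows) < 3:
        raise ValueError(f"dataset {dataset.dataset_id}: fewer than 3 usable regions")
    return np.vstack(rows), np.asarray(tau_vals, dtype=float)


def _corr_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with y (NaN-safe for constants)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, Xc @ yc / denom, np.nan)


@dataclass
class NullTestResult:
    feature: str
    observed_mean: float
    p: float
    ci_low: float
    ci_high: float
    null_means: np.ndarray

    @property
    def ci_excludes_observed(self) -> bool:
        return not (self.ci_low <= self.observed_mean <= self.ci_high)


def null_mean_correlation_test(
    feature_map: pd.Series,
    ensemble: SurrogateEnsemble,
    datasets: list[TauopathyDataset],
    atlas: Atlas,
    timepoint: int = -1,
    feature: str = "",
) -> NullTestResult:
    """Two-sided empirical p for a feature's mean-across-datasets correlation.

    The observed statistic is the mean Pearson R between the feature map and
    each dataset's tau (seed-removed, dataset region space).  The null
    distribution repeats the computation for every surrogate map; the same
    datasets enter observed and null means.
    """
    if list(ensemble.maps.columns) != list(feature_map.index):
        raise ValueError("ensemble regions do not match the feature map")
    obs_rs, null_rs = [], []
    S = ensemble.maps.to_numpy(dtype=float)
    x = feature_map.to_numpy(dtype=float)
    for ds in datasets:
        W, tau = _dataset_projection(ds, atlas, timepoint=timepoint)
        obs_rs.append(_corr_rows((W @ x)[None, :], tau)[0])
        null_rs.append(_corr_rows(S @ W.T, tau))
    obs_mean = float(np.nanmean(obs_rs))
    null_means = np.nanmean(np.vstack(null_rs), axis=0)
    n = len(null_means)
    p = (1.0 + np.sum(np.abs(null_means) >= abs(obs_mean))) / (n + 1.0)
    lo, hi = np.percentile(null_means, [2.5, 97.5])
    return NullTestResult(feature=feature, observed_mean=obs_mean, p=float(p),
                          ci_low=float(lo), ci_high=float(hi),
                          null_means=null_means)


def surrogate_significance(
    features_regional: pd.DataFrame,
    datasets: list[TauopathyDataset],
    atlas: Atlas,
    n_surrogates: int = 10_000,
    rng_seed: int = 0,
    timepoint: int = -1,
    n_bins: int = 25,
    n_bandwidths: int = 20,
) -> pd.DataFrame:
    """Per-feature surrogate-null test of the mean correlation across datasets.

    ``features_regional`` is features x atlas regions.  Bonferroni correction
    uses N_tests = number of features: ``p_corr = min(1, p * N_tests)``.
    """
    centroids = atlas.region_centroids()
    rng = np.random.default_rng(rng_seed)
    rows = []
    for feature in features_regional.index:
        fmap = features_regional.loc[feature]
        ens = make_surrogates(fmap, centroids, n_surrogates=n_surrogates,
                              rng_seed=int(rng.integers(2**31 - 1)),
                              n_bins=n_bins, n_bandwidths=n_bandwidths)
        res = null_mean_correlation_test(fmap, ens, datasets, atlas,
                                         timepoint=timepoint, feature=str(feature))
        rows.append({
            "feature": feature, "mean_R": res.observed_mean, "p": res.p,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "ci_excludes_observed": res.ci_excludes_observed,
        })
    out = pd.DataFrame(rows).set_index("feature")
    n_tests = len(out)
    out["p_corr"] = np.minimum(1.0, out["p"] * n_tests)
    out.attrs["N_tests"] = n_tests
    return out


def bonferroni(p: float | np.ndarray, n_tests: int) -> np.ndarray:
    """Bonferroni adjustment ``p_corr = min(1, p * N_tests)``."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * n_tests)


# ---------------------------------------------------------------------------
# class-level statistics


def class_level_tests(assoc: pd.DataFrame, class_label: dict[str, str]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class one-sample t-tests and pairwise class comparisons.

    ``assoc`` is the tidy table from :func:`association_table`; correlations
    are pooled across types and datasets within each class.  Both families are
    Bonferroni-corrected over the tests actually performed.  Zero-variance
    classes are reported as degenerate (NaN t) and classes with fewer than 2
    values are skipped with a warning.
    """
    vals = assoc.dropna(subset=["R"]).copy()
    vals["class"] = vals["feature"].map(class_label)
    groups = {c: g["R"].to_numpy() for c, g in vals.groupby("class")}
    usable = {}
    for c, v in groups.items():
        if len(v) < 2:
            warnings.warn(f"class {c!r} has fewer than 2 values; skipped")
            continue
        usable[c] = v

    one_rows = []
    for c, v in sorted(usable.items()):
        if np.std(v, ddof=1) == 0:
            one_rows.append({"class": c, "n": len(v), "mean_R": float(v.mean()),
                             "t": np.nan, "p": np.nan, "degenerate": True})
        else:
            t, p = stats.ttest_1samp(v, 0.0)
            one_rows.append({"class": c, "n": len(v), "mean_R": float(v.mean()),
                             "t": float(t), "p": float(p), "degenerate": False})
    one = pd.DataFrame(one_rows)
    n1 = int((~one["degenerate"]).sum())
    one["p_corr"] = bonferroni(one["p"], max(n1, 1))

    pair_rows = []
    classes = sorted(usable)
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            va, vb = usable[a], usable[b]
            if np.std(va, ddof=1) == 0 and np.std(vb, ddof=1) == 0:
                pair_rows.append({"class_a": a, "class_b": b, "t": np.nan,
                                  "p": np.nan, "degenerate": True})
                continue
            t, p = stats.ttest_ind(va, vb)
            pair_rows.append({"class_a": a, "class_b": b, "t": float(t),
                              "p": float(p), "degenerate": False})
    pairs = pd.DataFrame(pair_rows)
    if len(pairs):
        n2 = int((~pairs["degenerate"]).sum())
        pairs["p_corr"] = bonferroni(pairs["p"], max(n2, 1))
    return one, pairs


# ---------------------------------------------------------------------------
# risk-gene eigengene


def eigengene(gene_table: pd.DataFrame) -> tuple[pd.Series, float, pd.Series]:
    """First principal component of a regions x genes expression table.

    Genes are standardized before the decomposition.  Returns the regional
    score vector, the fraction of variance explained by PC1, and the gene
    loadings.  The sign is fixed so the loading sum is nonnegative (first
    nonzero loading positive on a zero sum).
    """
    if gene_table.shape[1] < 2 or gene_table.shape[0] < 3:
        raise ValueError("eigengene requires >= 2 genes and >= 3 regions")
    X = gene_table.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant genes")
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} constant genes from eigengene")
    cols = gene_table.columns[keep]
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    if not s.any():
        raise ValueError("rank-0 matrix has no principal component")
    loadings = Vt[0]
    lsum = loadings.sum()
    if lsum < 0 or (lsum == 0 and loadings[np.flatnonzero(loadings)[0]] < 0):
        loadings = -loadings
        U = U.copy()
        U[:, 0] = -U[:, 0]
    scores = pd.Series(U[:, 0] * s[0], index=gene_table.index, name="eigengene")
    explained = float(s[0] ** 2 / (s ** 2).sum())
    return scores, explained, pd.Series(loadings, index=cols, name="loading")
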