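"""Matrix Inversion and Subset Selection (MISS).

Infers voxel-wise cell-type densities ``D`` from a spatial gene-expression
volume ``E`` (genes x voxels) and a cell-type signature matrix ``C``
(genes x types) by solving, voxel by voxel, the nonnegative least-squares
problem ``d_k = argmin_{d>=0} ||e_k - C_red d||^2`` on an informative gene
subset chosen by the MRx3 procedure:

1. *Noise pruning* — genes are scored by the incremental change in total
   reconstruction error when their row joins a running unconstrained
   least-squares design (rank-one normal-equation updates); the noisiest
   10% are removed.
2. *Greedy mRMR selection* — genes are added one at a time maximizing
   relevance / redundancy, where relevance ``F_i`` is the sample variance of
   the gene's (type-normalized) signature row and redundancy is the mean
   absolute Pearson correlation with already-selected genes.
3. *Subset-size choice* — the residual-versus-size curve is scanned and the
   elbow (maximum perpendicular distance to the endpoint chord after min-max
   normalization) picks the working subset size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import nnls

from .types import Atlas, CellDensityMap, GeneSignatureMatrix, VoxelExpressionMap

_EPS_REDUNDANCY = 1e-12


# ---------------------------------------------------------------------------
# normalization


def normalize(C: GeneSignatureMatrix, E: VoxelExpressionMap
              ) -> tuple[GeneSignatureMatrix, VoxelExpressionMap]:
    """Restrict to shared genes; scale E rows to unit max and C columns to unit sum.

    Genes absent from either matrix are dropped before any computation.
    All-zero gene rows / type columns are left untouched with a warning.
    The per-gene multipliers applied to E are recorded on the returned map
    (``gene_scale``) and are reapplied to the signature design rows by the
    reconstruction steps, keeping the voxel-wise inversion scale-consistent.
    """
    shared = sorted(set(C.gene_ids) & set(E.gene_ids))
    if not shared:
        raise ValueError("no genes shared between signature and expression matrices")
    dropped = (set(C.gene_ids) | set(E.gene_ids)) - set(shared)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} genes not present in both matrices")

    Ev = E.values.loc[shared].copy()
    row_max = Ev.max(axis=1)
    zero_rows = row_max == 0
    if zero_rows.any():
        warnings.warn(f"{int(zero_rows.sum())} all-zero gene rows left unnormalized")
    scale = row_max.where(~zero_rows, 1.0)
    Ev = Ev.div(scale, axis=0)
    gene_scale = (1.0 / scale).rename("gene_scale")

    Cv = C.values.loc[shared].copy()
    col_sum = Cv.sum(axis=0)
    zero_cols = col_sum == 0
    if zero_cols.any():
        warnings.warn(f"{int(zero_cols.sum())} all-zero type columns left unnormalized")
    Cv = Cv.div(col_sum.where(~zero_cols, 1.0), axis=1)

    C_norm = GeneSignatureMatrix(Cv, dict(C.class_label),
                                 normalization="column-sum",
                                 marker_genes=dict(C.marker_genes))
    E_norm = VoxelExpressionMap(Ev, E.atlas, normalization="row-max",
                                gene_scale=gene_scale)
    return C_norm, E_norm


# ---------------------------------------------------------------------------
# MRx3 gene selection


@dataclass
class MRx3State:
    """Bookkeeping for one MRx3 run: scores, pruned pool, ordered selection."""

    noise_score: pd.Series
    pruned_pool: list[str]            # G*, gene ids surviving noise pruning
    selected: list[str] = field(default_factory=list)  # S, in selection order
    relevance: pd.Series | None = None                 # F_i on the pruned pool
    chosen_size: int | None = None
    residual_curve: pd.DataFrame | None = None


def _design(C: GeneSignatureMatrix, E: VoxelExpressionMap,
            genes: list[str]) -> np.ndarray:
    """Signature design rows aligned to E, weighted by E's per-gene scale."""
    Cv = C.values.loc[genes].to_numpy(dtype=float)
    if E.gene_scale is not None:
        Cv = Cv * E.gene_scale.loc[genes].to_numpy(dtype=float)[:, None]
    return Cv


def _solve_normal(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve A X = B, falling back to a minimum-norm solve when A is singular."""
    try:
        return cho_solve(cho_factor(A), B)
    except LinAlgError:
        return np.linalg.lstsq(A, B, rcond=None)[0]


def incremental_mse(A: np.ndarray, B: np.ndarray, C: np.ndarray, E: np.ndarray,
                    prev_mse: float, c_row: np.ndarray, e_row: np.ndarray
                    ) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Change in total reconstruction MSE when one gene joins the design.

    ``A = C_S^T C_S`` and ``B = C_S^T E_S`` are the running normal equations of
    the unconstrained least-squares design; the gene contributes rank-one
    updates ``A += c c^T`` and ``B += c e^T``.  The returned score is
    ``||E - C D_hat||_F^2`` (over the full matrices) after minus before.
    Identical (c, e) rows presented to an identical design state receive
    identical scores.
    """
    A2 = A + np.outer(c_row, c_row)
    B2 = B + np.outer(c_row, e_row)
    D_hat = _solve_normal(A2, B2)
    mse = float(np.sum((E - C @ D_hat) ** 2))
    return mse - prev_mse, A2, B2, mse


def score_gene_noise(E: VoxelExpressionMap, C: GeneSignatureMatrix) -> pd.Series:
    """Per-gene incremental noise score (higher = noisier).

    Genes are visited in id order; each gene's score is the change in total
    reconstruction MSE when its row is appended to the running unconstrained
    least-squares design, after which the gene joins the design.  A singular
    running design falls back to a minimum-norm solve for that step.
    """
    genes = sorted(set(C.gene_ids) & set(E.gene_ids))
    if not genes:
        raise ValueError("no shared genes to score")
    Cv = _design(C, E, genes)
    Ev = E.values.loc[genes].to_numpy(dtype=float)
    n_t = Cv.shape[1]
    A = np.zeros((n_t, n_t))
    B = np.zeros((n_t, Ev.shape[1]))
    prev = float(np.sum(Ev ** 2))  # empty design predicts zero everywhere
    scores = np.empty(len(genes))
    for i in range(len(genes)):
        scores[i], A, B, prev = incremental_mse(A, B, Cv, Ev, prev, Cv[i], Ev[i])
    return pd.Series(scores, index=genes, name="noise_score")


def prune_noisy_genes(scores: pd.Series, fraction: float = 0.10) -> list[str]:
    """Drop the noisiest ``fraction`` of genes; keep ``round((1-f)*|G|)``.

    Ties at the cutoff are broken by gene id: among equal scores the
    lexicographically last ids are removed first.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    n_keep = int(round((1 - fraction) * len(scores)))
    order = sorted(scores.index, key=lambda g: (scores[g], g))
    return sorted(order[:n_keep])


def mrmr_select(C_star: GeneSignatureMatrix, n: int,
                pool: list[str] | None = None) -> list[str]:
    """Greedy mRMR selection of ``n`` genes from the pruned pool.

    At each step the gene maximizing ``V_i = F_i / Redund(i|S)`` is added,
    where ``F_i`` is the sample variance of the gene's signature row across
    cell types and ``Redund(i|S)`` is the mean absolute Pearson correlation of
    the gene's row with the rows already in ``S`` (defined as 1 for empty
    ``S``, so the first pick maximizes relevance alone).  Ties break toward
    the lexicographically first gene id.
    """
    genes = sorted(pool) if pool is not None else sorted(C_star.gene_ids)
    if n > len(genes):
        raise ValueError("cannot select more genes than the pool contains")
    X = C_star.values.loc[genes].to_numpy(dtype=float)
    n_t = X.shape[1]
    if n_t < 3:
        raise ValueError("mRMR requires at least 3 cell types for row correlations")

    F = X.var(axis=1, ddof=1)
    # standardized rows for Pearson correlation; constant rows -> zero vector
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0) / np.sqrt(n_t)

    selected: list[int] = []
    redund_sum = np.zeros(len(genes))
    available = np.ones(len(genes), dtype=bool)
    for _ in range(n):
        if selected:
            redund = np.maximum(redund_sum / len(selected), _EPS_REDUNDANCY)
            crit = F / redund
        else:
            crit = F.copy()
        crit = np.where(available, crit, -np.inf)
        pick = int(np.argmax(crit))  # first index wins ties -> gene-id order
        selected.append(pick)
        available[pick] = False
        redund_sum += np.abs(Z @ Z[pick])
    return [genes[i] for i in selected]


def choose_subset_size(
    E: VoxelExpressionMap,
    C: GeneSignatureMatrix,
    candidate_sizes: list[int],
    prune_fraction: float = 0.10,
) -> tuple[int, pd.DataFrame, MRx3State]:
    """Pick the working MRx3 subset size from the residual-versus-size curve.

    Runs the full MRx3 selection once at the largest candidate size, then
    deconvolves nested prefixes and records the total squared residual.  The
    chosen size is the elbow of the min-max-normalized curve (maximum
    perpendicular distance to the chord joining the endpoints; ties and flat
    curves resolve to the smaller size).  A curve that ends higher than it
    starts is pathological and falls back to the global argmin with a warning.
    """
    sizes = sorted(int(s) for s in candidate_sizes)
    if len(sizes) < 1:
        raise ValueError("candidate_sizes must be non-empty")
    C_norm, E_norm = normalize(C, E)
    scores = score_gene_noise(E_norm, C_norm)
    pool = prune_noisy_genes(scores, fraction=prune_fraction)
    if sizes[-1] > len(pool):
        raise ValueError("largest candidate size exceeds the pruned pool")
    order = mrmr_select(C_norm, sizes[-1], pool=pool)

    # residual for a subset = reconstruction error of the FULL pruned pool
    # from densities fitted on the subset alone; it shrinks as the subset
    # grows more informative, which is what the elbow criterion scans
    E_pool = E_norm.restrict(pool)
    pool_design = _design(C_norm, E_pool, pool)
    pool_target = E_pool.values.to_numpy(dtype=float)
    residuals = []
    for s in sizes:
        subset = order[:s]
        D = deconvolve(E_norm.restrict(subset), C_norm.restrict(subset))
        pred = pool_design @ D.values.to_numpy()
        residuals.append(float(((pool_target - pred) ** 2).sum()))
    curve = pd.DataFrame({"size": sizes, "residual": residuals})

    n_G = _elbow(np.asarray(sizes, dtype=float), np.asarray(residuals, dtype=float))
    state = MRx3State(noise_score=scores, pruned_pool=pool, selected=order,
                      chosen_size=int(sizes[n_G]), residual_curve=curve)
    return int(sizes[n_G]), curve, state


def _elbow(x: np.ndarray, y: np.ndarray) -> int:
    """Index of the max-chord-distance point of a residual curve (ties -> smaller)."""
    if len(x) == 1:
        return 0
    if y[-1] > y[0]:
        warnings.warn("non-monotone residual curve; returning global argmin")
        return int(np.argmin(y))
    yr = y[-1] - y[0]
    if yr == 0:  # flat curve: chord rule degenerates, smallest size wins
        return 0
    xn = (x - x[0]) / (x[-1] - x[0])
    yn = (y - y[0]) / yr
    # distance from (xn, yn) to the chord joining (0, 0) and (1, 1)
    dist = np.abs(xn - yn) / np.sqrt(2.0)
    return int(np.argmax(dist))  # argmax returns the first (smallest size) on ties


# ---------------------------------------------------------------------------
# deconvolution and aggregation


def deconvolve(E_red: VoxelExpressionMap, C_red: GeneSignatureMatrix
               ) -> CellDensityMap:
    """Voxel-wise nonnegative least squares: ``d_k = argmin_{d>=0} ||e_k - C d||^2``.

    Voxels are independent (no cross-voxel state); the per-voxel squared
    residual is stored on the returned map.  All-zero voxels yield zero
    densities and zero residual.
    """
    if list(E_red.gene_ids) != list(C_red.gene_ids):
        raise ValueError("expression and signature gene axes must match")
    Cv = _design(C_red, E_red, list(C_red.gene_ids))
    Ev = E_red.values.to_numpy(dtype=float)
    n_t, n_v = Cv.shape[1], Ev.shape[1]
    D = np.zeros((n_t, n_v))
    resid = np.zeros(n_v)
    for k in range(n_v):
        e = Ev[:, k]
        if not e.any():
            continue
        d, rnorm = nnls(Cv, e)
        D[:, k] = d
        resid[k] = rnorm ** 2
    values = pd.DataFrame(D, index=C_red.type_ids, columns=E_red.values.columns)
    residual = pd.Series(resid, index=E_red.values.columns, name="residual")
    return CellDensityMap(values=values, axis="voxel", residual=residual)


def residual_summary(D: CellDensityMap, E: VoxelExpressionMap) -> pd.DataFrame:
    """Raw and expression-magnitude-normalized per-voxel squared residuals."""
    if D.residual is None:
        raise ValueError("density map carries no residuals")
    mag = (E.values.to_numpy(dtype=float) ** 2).sum(axis=0)
    norm = np.divide(D.residual.to_numpy(), mag, out=np.zeros_like(mag),
                     where=mag > 0)
    return pd.DataFrame({"residual": D.residual.to_numpy(), "normalized": norm},
                        index=D.residual.index)


def aggregate_regions(D_voxel: CellDensityMap, atlas: Atlas,
                      grouping: dict[str, list[str]] | None = None
                      ) -> CellDensityMap:
    """Volume-weighted regional mean densities.

    Within the atlas each voxel carries unit weight, so a region's density is
    the mean over its member voxels.  An optional ``grouping`` maps target
    regions onto several atlas regions; their means are combined weighted by
    subregion volume, which conserves volume-weighted totals.
    """
    if D_voxel.axis != "voxel":
        raise ValueError("aggregate_regions expects a voxel-level map")
    V = D_voxel.values.to_numpy(dtype=float)
    if V.shape[1] != atlas.n_voxels:
        raise ValueError("density columns must match atlas voxels")
    n_r = atlas.n_regions
    sums = np.zeros((V.shape[0], n_r))
    for t in range(V.shape[0]):
        sums[t] = np.bincount(atlas.voxel_region, weights=V[t], minlength=n_r)
    vol = atlas.region_volume.to_numpy().astype(float)
    means = sums / vol
    out = pd.DataFrame(means, index=D_voxel.type_ids, columns=atlas.region_ids)

    resid = None
    if D_voxel.residual is not None:
        rsum = np.bincount(atlas.voxel_region,
                           weights=D_voxel.residual.to_numpy(), minlength=n_r)
        resid = pd.Series(rsum / vol, index=atlas.region_ids, name="residual")

    if grouping is not None:
        cols, rcols = {}, {}
        volume = atlas.region_volume
        for target, members in grouping.items():
            missing = set(members) - set(atlas.region_ids)
            if missing:
                raise ValueError(f"unknown atlas regions in grouping: {sorted(missing)}")
            w = volume.loc[members].to_numpy().astype(float)
            cols[target] = (out[members].to_numpy() * w).sum(axis=1) / w.sum()
            if resid is not None:
                rcols[target] = float((resid.loc[members].to_numpy() * w).sum() / w.sum())
        out = pd.DataFrame(cols, index=D_voxel.type_ids)
        resid = pd.Series(rcols, name="residual") if resid is not None else None
    return CellDensityMap(values=out, axis="region", residual=resid)


def regional_mean_expression(E: VoxelExpressionMap, atlas: Atlas) -> pd.DataFrame:
    """Mean expression per region (genes x regions), one unit weight per voxel."""
    V = E.values.to_numpy(dtype=float)
    if V.shape[1] != atlas.n_voxels:
        raise ValueError("expression columns must match atlas voxels")
    vol = atlas.region_volume.to_numpy().astype(float)
    sums = np.vstack([
        np.bincount(atlas.voxel_region, weights=V[g], minlength=atlas.n_regions)
        for g in range(V.shape[0])])
    return pd.DataFrame(sums / vol, index=E.gene_ids, columns=atlas.region_ids)


def validate_against_reference(
    D_regional: CellDensityMap,
    reference_densities: pd.DataFrame,
    type_merge_rules: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of inferred regional densities against a reference.

    ``reference_densities`` is reference-types x regions.  ``type_merge_rules``
    maps each reference type onto one or more inferred types whose densities
    are averaged before correlating (e.g. merging two interneuron subtypes).
    Requires at least 3 shared regions.
    """
    if D_regional.axis != "region":
        raise ValueError("validation requires region-level densities")
    shared = [r for r in reference_densities.columns if r in D_regional.values.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared regions for validation")
    if type_merge_rules is None:
        type_merge_rules = {t: [t] for t in reference_densities.index}
    rows = []
    for ref_type, members in type_merge_rules.items():
        missing = set(members) - set(D_regional.type_ids)
        if missing:
            raise ValueError(f"unknown inferred types: {sorted(missing)}")
        inferred = D_regional.values.loc[members, shared].mean(axis=0).to_numpy()
        ref = reference_densities.loc[ref_type, shared].to_numpy(dtype=float)
        r = _pearson(inferred, ref)
        rows.append({"type": ref_type, "R": r, "n_regions": len(shared)})
    return pd.DataFrame(rows).set_index("type")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)


# ---------------------------------------------------------------------------
# convenience driver


def run_miss(
    C: GeneSignatureMatrix,
    E: VoxelExpressionMap,
    n_genes: int | None = None,
    candidate_sizes: list[int] | None = None,
    prune_fraction: float = 0.10,
) -> tuple[CellDensityMap, CellDensityMap, MRx3State]:
    """Full MISS pass: normalize, select genes, deconvolve, aggregate.

    Either fix the subset size with ``n_genes`` or supply ``candidate_sizes``
    to optimize it on the residual curve.  Returns the voxel-level map, the
    region-level map, and the MRx3 selection state.
    """
    if (n_genes is None) == (candidate_sizes is None):
        raise ValueError("specify exactly one of n_genes or candidate_sizes")
    C_norm, E_norm = normalize(C, E)
    if candidate_sizes is not None:
        n_G, curve, state = choose_subset_size(E, C, candidate_sizes,
                                               prune_fraction=prune_fraction)
        subset = state.selected[:n_G]
    else:
        scores = score_gene_noise(E_norm, C_norm)
        pool = prune_noisy_genes(scores, fraction=prune_fraction)
        n_sel = min(n_genes, len(pool))
        order = mrmr_select(C_norm, n_sel, pool=pool)
        subset = order
        state = MRx3State(noise_score=scores, pruned_pool=pool, selected=order,
                          chosen_size=n_sel)
    D_voxel = deconvolve(E_norm.restrict(subset), C_norm.restrict(subset))
    D_region = aggregate_regions(D_voxel, E.atlas)
    return D_voxel, D_region, state
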