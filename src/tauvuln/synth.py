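"""Synthetic-world generator.

Every downstream stage of the pipeline (deconvolution, association testing,
embedding, model selection, gene-set construction) is exercised against data
produced here, where the ground truth is known by construction:

* an :class:`~tauvuln.types.Atlas` of contiguous regions grown on a 3-D voxel
  grid (a stand-in for a mouse-brain parcellation at 200 um resolution);
* a marker-structured gene signature matrix (genes x cell types) emulating
  trimmed-mean scRNAseq cluster profiles;
* spatially autocorrelated, nonnegative true cell-type density fields;
* a voxel expression volume built by the forward model ``E = C @ D + noise``;
* regional tau burden tables built as noisy linear combinations of a planted
  subset of cell-type densities, with per-dataset injection seed regions.

The generators make no attempt to mimic ISH imaging artifacts, sequencing
read-depth models, or anatomically realistic geometry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .types import (
    CELL_CLASSES,
    Atlas,
    CellDensityMap,
    GeneSignatureMatrix,
    GroundTruth,
    SyntheticWorld,
    TauopathyDataset,
    VoxelExpressionMap,
)

_NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)

#: Coarse region groups assigned by spatial quadrant of the region's seed voxel.
_REGION_GROUPS = ("Hip", "Neo", "Sub", "Tha")


def generate_atlas(n_regions: int, grid_shape: tuple[int, int, int],
                   rng_seed: int = 0) -> Atlas:
    """Tile a 3-D grid with ``n_regions`` contiguous regions.

    Regions are grown from random seed voxels by breadth-first accretion with
    a randomized frontier, which guarantees contiguity and a full tiling.
    Deterministic for a fixed seed.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be positive")
    grid_shape = tuple(int(g) for g in grid_shape)
    n_vox = int(np.prod(grid_shape))
    if n_regions > n_vox:
        raise ValueError(f"cannot tile {n_vox} voxels with {n_regions} regions")
    rng = np.random.default_rng(rng_seed)

    coords = np.indices(grid_shape).reshape(3, -1).T  # C order
    flat_index = np.arange(n_vox).reshape(grid_shape)
    assignment = np.full(n_vox, -1, dtype=np.int64)

    seeds = rng.choice(n_vox, size=n_regions, replace=False)
    frontiers: list[list[int]] = [[] for _ in range(n_regions)]
    for r, v in enumerate(seeds):
        assignment[v] = r
        frontiers[r].append(int(v))

    n_assigned = n_regions
    while n_assigned < n_vox:
        order = rng.permutation(n_regions)
        progressed = False
        for r in order:
            frontier = frontiers[r]
            while frontier:
                j = int(rng.integers(len(frontier)))
                v = frontier[j]
                nbrs = coords[v] + _NEIGHBOR_OFFSETS
                ok = np.all((nbrs >= 0) & (nbrs < np.array(grid_shape)), axis=1)
                nbr_idx = flat_index[tuple(nbrs[ok].T)]
                free = nbr_idx[assignment[nbr_idx] == -1]
                if free.size == 0:
                    # exhausted voxel: drop from frontier
                    frontier[j] = frontier[-1]
                    frontier.pop()
                    continue
                pick = int(free[rng.integers(free.size)])
                assignment[pick] = r
                frontier.append(pick)
                n_assigned += 1
                progressed = True
                break
        if not progressed:  # pragma: no cover - cannot happen on a connected grid
            raise RuntimeError("region growing stalled")

    region_ids = [f"R{r:03d}" for r in range(n_regions)]
    region_names = [f"region-{r:03d}" for r in range(n_regions)]
    half = np.array(grid_shape[:2]) / 2.0
    groups = {}
    for r, v in enumerate(seeds):
        quad = int(coords[v][0] >= half[0]) * 2 + int(coords[v][1] >= half[1])
        groups[region_ids[r]] = _REGION_GROUPS[quad]
    return Atlas(
        region_ids=region_ids,
        region_names=region_names,
        grid_shape=grid_shape,
        voxel_coords=coords,
        voxel_region=assignment,
        region_group=groups,
    )


def generate_signatures(
    n_genes: int,
    n_types: int,
    markers_per_type: int = 10,
    class_labels: list[str] | None = None,
    rng_seed: int = 0,
    fold_up: float = 10.0,
) -> GeneSignatureMatrix:
    """Marker-structured consensus signature matrix (genes x cell types).

    Each gene has a shared log-normal baseline across types (mu=0, sigma=1)
    modulated by bounded multiplicative jitter; each type's marker genes are
    additionally scaled by ``fold_up`` (default 10x) in that type only.  The
    jitter is clipped so that at the default fold-up a marker's maximum is
    forced to lie in its own type.
    """
    if n_genes < 1 or n_types < 1 or markers_per_type < 0:
        raise ValueError("n_genes, n_types positive; markers_per_type nonnegative")
    if n_types * markers_per_type > n_genes:
        raise ValueError("marker budget exceeds gene count")
    if class_labels is None:
        class_labels = [CELL_CLASSES[t % len(CELL_CLASSES)] for t in range(n_types)]
    if len(class_labels) != n_types:
        raise ValueError("class_labels must have length n_types")
    if not set(class_labels) <= set(CELL_CLASSES):
        raise ValueError(f"class labels must be drawn from {CELL_CLASSES}")

    rng = np.random.default_rng(rng_seed)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    type_ids = [f"T{t:02d}" for t in range(n_types)]

    base = np.exp(rng.normal(0.0, 1.0, size=n_genes))[:, None]
    jitter = np.exp(np.clip(rng.normal(0.0, 0.25, size=(n_genes, n_types)), -1.0, 1.0))
    values = base * jitter

    perm = rng.permutation(n_genes)
    marker_genes: dict[str, list[str]] = {}
    for t, tid in enumerate(type_ids):
        block = perm[t * markers_per_type: (t + 1) * markers_per_type]
        marker_genes[tid] = sorted(gene_ids[g] for g in block)
        values[block, t] *= fold_up

    df = pd.DataFrame(values, index=gene_ids, columns=type_ids)
    return GeneSignatureMatrix(
        values=df,
        class_label=dict(zip(type_ids, class_labels)),
        marker_genes=marker_genes,
    )


def _smoothed_field(atlas: Atlas, smoothness: float, rng: np.random.Generator,
                    mean: float = 0.0) -> np.ndarray:
    """Gaussian-kernel-smoothed white noise evaluated at atlas voxels."""
    field = rng.normal(mean, 1.0, size=atlas.grid_shape)
    if smoothness > 0:
        field = gaussian_filter(field, sigma=smoothness, mode="reflect")
    return field.reshape(-1)  # C order matches atlas voxel order


def generate_density_truth(atlas: Atlas, n_types: int, smoothness: float = 1.5,
                           rng_seed: int = 0,
                           type_ids: list[str] | None = None) -> CellDensityMap:
    """Spatially autocorrelated nonnegative true densities, one field per type.

    Each type is an independent Gaussian random field (white noise of mean 1,
    unit variance, smoothed with an isotropic Gaussian kernel of width
    ``smoothness`` voxels) rectified at zero.  Smoothing is applied without
    re-standardization, so large ``smoothness`` yields near-constant maps.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if n_types < 1:
        raise ValueError("n_types must be positive")
    rng = np.random.default_rng(rng_seed)
    if type_ids is None:
        type_ids = [f"T{t:02d}" for t in range(n_types)]
    rows = [np.clip(_smoothed_field(atlas, smoothness, rng, mean=1.0), 0.0, None)
            for _ in range(n_types)]
    df = pd.DataFrame(np.vstack(rows), index=type_ids,
                      columns=np.arange(atlas.n_voxels))
    return CellDensityMap(values=df, axis="voxel")


def synthesize_expression(C: GeneSignatureMatrix, D_true: CellDensityMap,
                          atlas: Atlas, noise_sd: float = 0.0,
                          rng_seed: int = 0) -> VoxelExpressionMap:
    """Forward model ``E = C @ D_true + eps`` with Gaussian noise rectified at 0."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if list(C.values.columns) != list(D_true.values.index):
        raise ValueError("signature types and density types must match")
    if D_true.axis != "voxel":
        raise ValueError("expression synthesis requires voxel-level densities")
    rng = np.random.default_rng(rng_seed)
    E = C.values.to_numpy() @ D_true.values.to_numpy()
    if noise_sd > 0:
        E = E + rng.normal(0.0, noise_sd, size=E.shape)
    E = np.clip(E, 0.0, None)
    df = pd.DataFrame(E, index=C.values.index, columns=D_true.values.columns)
    return VoxelExpressionMap(values=df, atlas=atlas)


def synthesize_tauopathy(
    atlas: Atlas,
    D_true_regional: CellDensityMap,
    effects: dict[str, float],
    n_datasets: int = 12,
    n_timepoints: int = 3,
    seed_regions: list[list[str]] | None = None,
    tau_noise_params: tuple[float, float] = (1.5, 0.0),
    rng_seed: int = 0,
    baseline: float | str = "auto",
    seed_boost: float = 1.5,
) -> list[TauopathyDataset]:
    """Regional tau burden tables: rectified noisy combinations of densities.

    Per dataset and time point ``k`` (1-based)::

        tau_k = rectify( (k / n_timepoints) * (signal + baseline) + noise_k )

    where ``signal = sum_t effects[t] * density_t`` on regions, and ``noise_k``
    is a regional aggregate of a Gaussian-smoothed voxel noise field (same
    kernel scheme as the density truth, so autocorrelation-preserving nulls
    are meaningfully calibrated) scaled to sd ``tau_noise_params[1] * k / n``.
    ``baseline="auto"`` shifts the signal so its minimum is zero, keeping
    rectification from erasing planted negative effects.  Seed regions are
    recorded and given an elevated burden (``seed_boost`` times the map max).
    """
    if not any(w != 0 for w in effects.values()):
        raise ValueError("at least one nonzero effect weight required")
    if D_true_regional.axis != "region":
        raise ValueError("tau synthesis requires region-level densities")
    unknown = set(effects) - set(D_true_regional.type_ids)
    if unknown:
        raise ValueError(f"unknown effect types: {sorted(unknown)}")
    corr_len, tau_sd = tau_noise_params
    if tau_sd < 0:
        raise ValueError("tau noise sd must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    regions = list(D_true_regional.values.columns)
    if seed_regions is None:
        seed_regions = [[] for _ in range(n_datasets)]
    if len(seed_regions) != n_datasets:
        raise ValueError("seed_regions must have one entry per dataset")
    for lst in seed_regions:
        bad = set(lst) - set(regions)
        if bad:
            raise ValueError(f"unknown seed regions: {sorted(bad)}")

    signal = np.zeros(len(regions))
    for t, w in effects.items():
        signal = signal + w * D_true_regional.values.loc[t].to_numpy()
    if baseline == "auto":
        offset = -float(signal.min())
    else:
        offset = float(baseline)
    signal = signal + offset

    vol = atlas.region_volume.to_numpy().astype(float)
    datasets = []
    for d in range(n_datasets):
        cols = {}
        for k in range(1, n_timepoints + 1):
            scale = k / n_timepoints
            noise = np.zeros(len(regions))
            if tau_sd > 0:
                vox_noise = _smoothed_field(atlas, corr_len, rng)
                reg_noise = np.bincount(
                    atlas.voxel_region, weights=vox_noise,
                    minlength=atlas.n_regions) / vol
                sd = reg_noise.std()
                if sd > 0:
                    noise = reg_noise / sd * (tau_sd * scale)
            cols[f"t{k}"] = np.clip(scale * signal + noise, 0.0, None)
        tau = pd.DataFrame(cols, index=regions)
        for s in seed_regions[d]:
            tau.loc[s] = tau.to_numpy().max() * seed_boost
        datasets.append(TauopathyDataset(
            dataset_id=f"DS{d + 1:02d}",
            tau=tau,
            seed_region_ids=list(seed_regions[d]),
            mapping_table={r: [r] for r in regions},
        ))
    return datasets


def generate_world(
    n_regions: int = 60,
    grid_shape: tuple[int, int, int] = (12, 12, 10),
    n_genes: int = 300,
    n_types: int = 12,
    markers_per_type: int = 10,
    smoothness: float = 1.5,
    expression_noise: float = 0.1,
    n_datasets: int = 12,
    n_timepoints: int = 3,
    n_unseeded: int = 2,
    snr: float = 2.0,
    n_vulnerable: int = 2,
    n_resilient: int = 1,
    rng_seed: int = 0,
) -> SyntheticWorld:
    """Build a complete synthetic study with planted vulnerability structure.

    ``expression_noise`` is relative: the additive expression noise sd is
    ``expression_noise * mean(C @ D_true)``.  ``snr`` is the ratio of the
    regional tau signal sd to the regional tau noise sd.  Two datasets are
    unseeded by default; the rest get one random seed region each.
    """
    from .miss import aggregate_regions  # local import to avoid cycle

    rng = np.random.default_rng(rng_seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=5)]

    atlas = generate_atlas(n_regions, grid_shape, rng_seed=sub[0])
    C = generate_signatures(n_genes, n_types, markers_per_type, rng_seed=sub[1])
    D_true = generate_density_truth(atlas, n_types, smoothness, rng_seed=sub[2],
                                    type_ids=C.type_ids)

    clean = C.values.to_numpy() @ D_true.values.to_numpy()
    noise_sd = expression_noise * float(clean.mean())
    expression = synthesize_expression(C, D_true, atlas, noise_sd=noise_sd,
                                       rng_seed=sub[3])

    D_reg = aggregate_regions(D_true, atlas)

    types = list(C.type_ids)
    chosen = rng.choice(len(types), size=n_vulnerable + n_resilient, replace=False)
    vulnerable = {types[i]: 1.0 - 0.3 * k for k, i in enumerate(chosen[:n_vulnerable])}
    resilient = {types[i]: -0.7 for i in chosen[n_vulnerable:]}
    effects = {**vulnerable, **resilient}

    signal = np.zeros(atlas.n_regions)
    for t, w in effects.items():
        signal += w * D_reg.values.loc[t].to_numpy()
    tau_sd = float(signal.std()) / snr if snr > 0 else 0.0

    seed_lists: list[list[str]] = []
    for d in range(n_datasets):
        if d >= n_datasets - n_unseeded:
            seed_lists.append([])
        else:
            seed_lists.append([atlas.region_ids[int(rng.integers(n_regions))]])

    tau_datasets = synthesize_tauopathy(
        atlas, D_reg, effects,
        n_datasets=n_datasets, n_timepoints=n_timepoints,
        seed_regions=seed_lists,
        tau_noise_params=(smoothness, tau_sd),
        rng_seed=sub[4],
    )

    truth = GroundTruth(
        true_density=D_true,
        marker_assignment=dict(C.marker_genes),
        vulnerable_types=vulnerable,
        resilient_types=resilient,
        expression_noise_sd=noise_sd,
        tau_noise_params=(smoothness, tau_sd),
        rng_seed=rng_seed,
    )
    return SyntheticWorld(
        atlas=atlas,
        signatures=C,
        expression=expression,
        tau_datasets=tau_datasets,
        truth=truth,
    )
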