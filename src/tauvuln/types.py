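"""Core data containers shared across the pipeline.

All matrices are stored as labeled :class:`pandas.DataFrame` objects so that
gene, cell-type, voxel and region identifiers travel with the numbers.  The
thin dataclass wrappers below add the invariants and metadata that a bare
DataFrame cannot express (parcellation structure, normalization provenance,
planted ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four coarse cell-type classes used throughout the analysis.
CELL_CLASSES = (
    "cortical glutamatergic",
    "hippocampal glutamatergic",
    "GABAergic",
    "non-neuronal",
)


@dataclass
class Atlas:
    """A 3-D voxel grid partitioned into contiguous named regions.

    Voxels live on an integer grid (semantically 200 um spacing).  Every voxel
    belongs to exactly one region and every region has volume >= 1.
    """

    region_ids: list[str]
    region_names: list[str]
    grid_shape: tuple[int, int, int]
    voxel_coords: np.ndarray  # (n_voxels, 3) int
    voxel_region: np.ndarray  # (n_voxels,) index into region_ids
    region_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region_ids must be unique")
        if self.voxel_coords.shape[0] != self.voxel_region.shape[0]:
            raise ValueError("voxel_coords and voxel_region must align")
        counts = np.bincount(self.voxel_region, minlength=len(self.region_ids))
        if (counts < 1).any():
            raise ValueError("every region must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        return self.voxel_coords.shape[0]

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def region_volume(self) -> pd.Series:
        counts = np.bincount(self.voxel_region, minlength=self.n_regions)
        return pd.Series(counts, index=self.region_ids, name="volume")

    def region_centroids(self) -> pd.DataFrame:
        """Mean voxel coordinate per region (used for variogram distances)."""
        df = pd.DataFrame(self.voxel_coords, columns=["x", "y", "z"])
        df["region"] = np.asarray(self.region_ids)[self.voxel_region]
        cent = df.groupby("region").mean()
        return cent.loc[self.region_ids]

    def membership_table(self) -> pd.DataFrame:
        """Tab-delimited-ready table of voxel x,y,z -> region id."""
        out = pd.DataFrame(self.voxel_coords, columns=["x", "y", "z"])
        out["region_id"] = np.asarray(self.region_ids)[self.voxel_region]
        return out


@dataclass
class GeneSignatureMatrix:
    """Consensus (trimmed-mean style) expression: genes x cell types.

    ``values`` is an ``n_genes x n_types`` nonnegative DataFrame; ``class_label``
    maps each type to one of :data:`CELL_CLASSES`.  ``normalization`` records
    how (if at all) columns were rescaled.
    """

    values: pd.DataFrame
    class_label: dict[str, str]
    normalization: str = "none"
    marker_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signature matrix must be nonnegative")
        missing = set(self.values.columns) - set(self.class_label)
        if missing:
            raise ValueError(f"missing class labels for types: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def type_ids(self) -> list[str]:
        return list(self.values.columns)

    def restrict(self, genes: list[str]) -> "GeneSignatureMatrix":
        return GeneSignatureMatrix(
            self.values.loc[genes], dict(self.class_label),
            normalization=self.normalization, marker_genes=dict(self.marker_genes),
        )


@dataclass
class VoxelExpressionMap:
    """Spatial gene expression: genes x voxels, tied to an :class:`Atlas`.

    ``gene_scale`` records the per-gene multiplier applied during
    normalization (``E_norm = diag(gene_scale) @ E_raw``); reconstruction
    steps weight the signature design rows by the same factors so the
    deconvolution stays scale-consistent.
    """

    values: pd.DataFrame  # genes x voxels (columns = voxel index as str or int)
    atlas: Atlas
    normalization: str = "none"
    gene_scale: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression map must be nonnegative")
        if self.values.shape[1] != self.atlas.n_voxels:
            raise ValueError("expression columns must match atlas voxels")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def restrict(self, genes: list[str]) -> "VoxelExpressionMap":
        scale = None if self.gene_scale is None else self.gene_scale.loc[genes]
        return VoxelExpressionMap(self.values.loc[genes], self.atlas,
                                  normalization=self.normalization,
                                  gene_scale=scale)


@dataclass
class CellDensityMap:
    """Cell-type densities: types x (voxels | regions), nonnegative.

    ``residual`` optionally stores the per-voxel (or per-region) squared
    reconstruction error from the deconvolution that produced the map.
    """

    values: pd.DataFrame
    axis: str  # "voxel" or "region"
    residual: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.axis not in ("voxel", "region"):
            raise ValueError("axis must be 'voxel' or 'region'")
        if (self.values.to_numpy() < -1e-12).any():
            raise ValueError("densities must be nonnegative")

    @property
    def type_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class TauopathyDataset:
    """Regional tau burden for one experimental condition.

    ``tau`` is regions x time points (nonnegative); ``seed_region_ids`` are the
    injection sites (empty for unseeded models); ``mapping_table`` maps each
    dataset region onto one or more atlas regions.
    """

    dataset_id: str
    tau: pd.DataFrame
    seed_region_ids: list[str] = field(default_factory=list)
    mapping_table: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.tau.to_numpy() < 0).any():
            raise ValueError("tau burden must be nonnegative")
        unknown = set(self.seed_region_ids) - set(self.tau.index)
        if unknown:
            raise ValueError(f"seed regions not in dataset regions: {sorted(unknown)}")

    @property
    def region_ids(self) -> list[str]:
        return list(self.tau.index)

    @property
    def end_timepoint(self) -> pd.Series:
        return self.tau.iloc[:, -1]


@dataclass
class GroundTruth:
    """Planted truth of a synthetic world (unobservable in the real study)."""

    true_density: CellDensityMap
    marker_assignment: dict[str, list[str]]
    vulnerable_types: dict[str, float]
    resilient_types: dict[str, float]
    expression_noise_sd: float
    tau_noise_params: tuple[float, float]
    rng_seed: int

    def __post_init__(self) -> None:
        overlap = set(self.vulnerable_types) & set(self.resilient_types)
        if overlap:
            raise ValueError(f"types cannot be both vulnerable and resilient: {sorted(overlap)}")
        if self.expression_noise_sd < 0 or self.tau_noise_params[1] < 0:
            raise ValueError("noise sds must be nonnegative")
        for w in (*self.vulnerable_types.values(), *self.resilient_types.values()):
            if not np.isfinite(w):
                raise ValueError("effect weights must be finite")


@dataclass
class SyntheticWorld:
    """One fully specified synthetic study: atlas, signatures, expression, tau."""

    atlas: Atlas
    signatures: GeneSignatureMatrix
    expression: VoxelExpressionMap
    tau_datasets: list[TauopathyDataset]
    truth: GroundTruth
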