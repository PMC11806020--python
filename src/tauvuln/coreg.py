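"""Region correspondence and seed removal.

Tauopathy experiments quantify tau on their own (often coarser) parcellation.
This module carries regional feature tables (cell-type densities or gene
expression) into each dataset's region space via an explicit mapping table —
1:1 regions are copied, one-to-many regions are volume-weight averaged, and
unmappable regions are dropped with a logged list — and removes injection
seed regions from both the features and the tau table before any association
analysis.  Purely tabular; no image registration.
"""

from __future__ import annotations

import logging
import warnings

import pandas as pd

from .types import Atlas, TauopathyDataset

logger = logging.getLogger(__name__)


def match_regions(regional_features: pd.DataFrame, dataset: TauopathyDataset,
                  atlas: Atlas) -> pd.DataFrame:
    """Project an atlas-space feature table (regions x features) into dataset space.

    Dataset regions mapping to a single atlas region copy that region's row;
    regions mapping to several atlas subregions take the subregion-volume-
    weighted mean.  Dataset regions with no mapping entry (or whose mapped
    atlas regions are absent from the feature table) are dropped and logged.
    """
    if not dataset.mapping_table:
        raise ValueError(f"dataset {dataset.dataset_id} has no mapping table")
    volume = atlas.region_volume
    rows: dict[str, pd.Series] = {}
    dropped: list[str] = []
    for region in dataset.region_ids:
        members = dataset.mapping_table.get(region, [])
        members = [m for m in members if m in regional_features.index]
        if not members:
            dropped.append(region)
            continue
        if len(members) == 1:
            rows[region] = regional_features.loc[members[0]]
        else:
            w = volume.loc[members].to_numpy().astype(float)
            sub = regional_features.loc[members]
            rows[region] = pd.Series(
                (sub.to_numpy() * w[:, None]).sum(axis=0) / w.sum(),
                index=regional_features.columns,
            )
    if dropped:
        logger.info("dataset %s: dropped %d unmapped regions: %s",
                    dataset.dataset_id, len(dropped), dropped)
    if not rows:
        raise ValueError(f"dataset {dataset.dataset_id}: no regions could be matched")
    out = pd.DataFrame(rows).T
    out.index.name = "region"
    return out


def remove_seed_regions(table: pd.DataFrame, dataset: TauopathyDataset,
                        tau: pd.DataFrame | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop injection seed regions from the feature table and the tau table.

    Unseeded datasets pass through unchanged.  A seed id absent from the
    table triggers a warning, not an error (it may already have been
    unmappable).  The returned tables share an identical, ordered region
    index.
    """
    if tau is None:
        tau = dataset.tau
    seeds = set(dataset.seed_region_ids)
    missing = seeds - set(table.index)
    if missing:
        warnings.warn(
            f"dataset {dataset.dataset_id}: seed regions absent from table: "
            f"{sorted(missing)}")
    keep = [r for r in table.index if r not in seeds and r in tau.index]
    return table.loc[keep], tau.loc[keep]


def align_dataset(regional_features: pd.DataFrame, dataset: TauopathyDataset,
                  atlas: Atlas) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match regions then remove seeds; returns (features, tau) on a shared index."""
    matched = match_regions(regional_features, dataset, atlas)
    return remove_seed_regions(matched, dataset)
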