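"""Reading and writing the pipeline's tabular formats.

All tables are tab-delimited text with a header row and a first label column.
Atlases are stored as voxel membership tables (x, y, z, region_id) with a
region-group sidecar; tauopathy datasets as a tau table plus a seed-region
sidecar and a mapping table (dataset region -> comma-separated atlas
regions).  A whole synthetic world can optionally be bundled into a single
HDF5 container.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import (
    Atlas,
    CellDensityMap,
    GeneSignatureMatrix,
    SyntheticWorld,
    TauopathyDataset,
    VoxelExpressionMap,
)


def write_matrix(df: pd.DataFrame, path: str | Path, label: str = "id") -> None:
    df = df.copy()
    df.index.name = label
    df.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_atlas(atlas: Atlas, path: str | Path) -> None:
    """Membership table (x, y, z, region_id) plus a region-group sidecar."""
    path = Path(path)
    atlas.membership_table().to_csv(path, sep="\t", index=False)
    groups = pd.DataFrame({
        "region_id": atlas.region_ids,
        "region_name": atlas.region_names,
        "group": [atlas.region_group.get(r, "") for r in atlas.region_ids],
    })
    groups.to_csv(path.with_suffix(".groups.tsv"), sep="\t", index=False)


def read_atlas(path: str | Path) -> Atlas:
    path = Path(path)
    mem = pd.read_csv(path, sep="\t")
    groups = pd.read_csv(path.with_suffix(".groups.tsv"), sep="\t")
    region_ids = list(groups["region_id"])
    pos = {r: k for k, r in enumerate(region_ids)}
    coords = mem[["x", "y", "z"]].to_numpy(dtype=np.int64)
    grid_shape = tuple(int(c) + 1 for c in coords.max(axis=0))
    return Atlas(
        region_ids=region_ids,
        region_names=list(groups["region_name"]),
        grid_shape=grid_shape,
        voxel_coords=coords,
        voxel_region=np.array([pos[r] for r in mem["region_id"]], dtype=np.int64),
        region_group=dict(zip(groups["region_id"], groups["group"].fillna(""))),
    )


def write_tau_dataset(ds: TauopathyDataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix(ds.tau, directory / f"{ds.dataset_id}.tau.tsv", label="region")
    (directory / f"{ds.dataset_id}.seeds.txt").write_text(
        "\n".join(ds.seed_region_ids) + ("\n" if ds.seed_region_ids else ""))
    with open(directory / f"{ds.dataset_id}.mapping.tsv", "w") as fh:
        fh.write("dataset_region\tatlas_regions\n")
        for region, members in ds.mapping_table.items():
            fh.write(f"{region}\t{','.join(members)}\n")


def read_tau_dataset(dataset_id: str, directory: str | Path) -> TauopathyDataset:
    directory = Path(directory)
    tau = read_matrix(directory / f"{dataset_id}.tau.tsv")
    seeds = [s for s in
             (directory / f"{dataset_id}.seeds.txt").read_text().splitlines() if s]
    mapping = {}
    lines = (directory / f"{dataset_id}.mapping.tsv").read_text().splitlines()[1:]
    for line in lines:
        region, members = line.split("\t")
        mapping[region] = members.split(",")
    return TauopathyDataset(dataset_id=dataset_id, tau=tau,
                            seed_region_ids=seeds, mapping_table=mapping)


def write_gene_list(genes: list[str], path: str | Path) -> None:
    """One gene id per line (plain text, for external enrichment tools)."""
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""))


def read_gene_list(path: str | Path) -> list[str]:
    return [g for g in Path(path).read_text().splitlines() if g]


# ---------------------------------------------------------------------------
# HDF5 world bundle


def write_world_h5(world: SyntheticWorld, path: str | Path) -> None:
    """Bundle one synthetic world (atlas, C, E, truth, tau) into a single file."""
    with h5py.File(path, "w") as f:
        a = f.create_group("atlas")
        a.create_dataset("voxel_coords", data=world.atlas.voxel_coords)
        a.create_dataset("voxel_region", data=world.atlas.voxel_region)
        a.attrs["grid_shape"] = world.atlas.grid_shape
        a.attrs["region_ids"] = json.dumps(world.atlas.region_ids)
        a.attrs["region_names"] = json.dumps(world.atlas.region_names)
        a.attrs["region_group"] = json.dumps(world.atlas.region_group)

        c = f.create_group("signatures")
        c.create_dataset("values", data=world.signatures.values.to_numpy())
        c.attrs["gene_ids"] = json.dumps(world.signatures.gene_ids)
        c.attrs["type_ids"] = json.dumps(world.signatures.type_ids)
        c.attrs["class_label"] = json.dumps(world.signatures.class_label)
        c.attrs["marker_genes"] = json.dumps(world.signatures.marker_genes)

        e = f.create_group("expression")
        e.create_dataset("values", data=world.expression.values.to_numpy())

        t = f.create_group("truth")
        t.create_dataset("true_density", data=world.truth.true_density.values.to_numpy())
        t.attrs["vulnerable_types"] = json.dumps(world.truth.vulnerable_types)
        t.attrs["resilient_types"] = json.dumps(world.truth.resilient_types)
        t.attrs["expression_noise_sd"] = world.truth.expression_noise_sd
        t.attrs["tau_noise_params"] = world.truth.tau_noise_params
        t.attrs["rng_seed"] = world.truth.rng_seed

        g = f.create_group("tau")
        for ds in world.tau_datasets:
            gd = g.create_group(ds.dataset_id)
            gd.create_dataset("values", data=ds.tau.to_numpy())
            gd.attrs["regions"] = json.dumps(list(ds.tau.index))
            gd.attrs["timepoints"] = json.dumps(list(ds.tau.columns))
            gd.attrs["seeds"] = json.dumps(ds.seed_region_ids)
            gd.attrs["mapping"] = json.dumps(ds.mapping_table)


def read_world_h5(path: str | Path) -> SyntheticWorld:
    from .types import GroundTruth

    with h5py.File(path, "r") as f:
        a = f["atlas"]
        atlas = Atlas(
            region_ids=json.loads(a.attrs["region_ids"]),
            region_names=json.loads(a.attrs["region_names"]),
            grid_shape=tuple(int(x) for x in a.attrs["grid_shape"]),
            voxel_coords=a["voxel_coords"][()],
            voxel_region=a["voxel_region"][()],
            region_group=json.loads(a.attrs["region_group"]),
        )
        c = f["signatures"]
        gene_ids = json.loads(c.attrs["gene_ids"])
        type_ids = json.loads(c.attrs["type_ids"])
        C = GeneSignatureMatrix(
            values=pd.DataFrame(c["values"][()], index=gene_ids, columns=type_ids),
            class_label=json.loads(c.attrs["class_label"]),
            marker_genes=json.loads(c.attrs["marker_genes"]),
        )
        E = VoxelExpressionMap(
            values=pd.DataFrame(f["expression/values"][()], index=gene_ids,
                                columns=np.arange(atlas.n_voxels)),
            atlas=atlas,
        )
        t = f["truth"]
        truth = GroundTruth(
            true_density=CellDensityMap(
                values=pd.DataFrame(t["true_density"][()], index=type_ids,
                                    columns=np.arange(atlas.n_voxels)),
                axis="voxel"),
            marker_assignment=json.loads(c.attrs["marker_genes"]),
            vulnerable_types=json.loads(t.attrs["vulnerable_types"]),
            resilient_types=json.loads(t.attrs["resilient_types"]),
            expression_noise_sd=float(t.attrs["expression_noise_sd"]),
            tau_noise_params=tuple(float(x) for x in t.attrs["tau_noise_params"]),
            rng_seed=int(t.attrs["rng_seed"]),
        )
        datasets = []
        for name in sorted(f["tau"]):
            gd = f["tau"][name]
            datasets.append(TauopathyDataset(
                dataset_id=name,
                tau=pd.DataFrame(gd["values"][()],
                                 index=json.loads(gd.attrs["regions"]),
                                 columns=json.loads(gd.attrs["timepoints"])),
                seed_region_ids=json.loads(gd.attrs["seeds"]),
                mapping_table=json.loads(gd.attrs["mapping"]),
            ))
    return SyntheticWorld(atlas=atlas, signatures=C, expression=E,
                          tau_datasets=datasets, truth=truth)
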