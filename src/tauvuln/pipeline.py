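"""End-to-end pipeline driver.

Runs, in order: synthetic-world generation (or HDF5 load), MISS deconvolution,
per-dataset coregistration and univariate association with surrogate nulls,
spectral embedding, multivariate BIC/top-k model selection (optionally per
time point), and gene-set construction.  Every stage writes tab-delimited
outputs under the run directory and a JSON manifest records the config, the
seeds, and a checksum per written file, so a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, coreg, genesets, io, miss, models, spectral, synth
from .types import SyntheticWorld

logger = logging.getLogger(__name__)

STAGES = ("synth", "miss", "assoc", "spectral", "models", "genesets")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; round-trips losslessly through YAML."""

    outdir: str = "results"
    rng_seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    world_h5: str | None = None  # load instead of generating

    # synthetic world recipe
    n_regions: int = 60
    grid_shape: list[int] = field(default_factory=lambda: [12, 12, 10])
    n_genes: int = 300
    n_types: int = 12
    markers_per_type: int = 10
    smoothness: float = 1.5
    expression_noise: float = 0.1
    n_datasets: int = 12
    n_timepoints: int = 3
    snr: float = 2.0

    # miss
    prune_fraction: float = 0.10
    n_selected_genes: int | None = 120
    candidate_sizes: list[int] | None = None
    nnls_tolerance: float = 1e-8

    # association
    method: str = "pearson"
    n_surrogates: int = 1000
    alpha: float = 0.05

    # models
    folds: int = 10
    top_k: int = 5
    per_timepoint: bool = False

    # gene sets
    geneset_fraction: float = 0.10
    n_risk_genes: int = 24

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class PipelineResult:
    config: PipelineConfig
    world: SyntheticWorld | None = None
    density_voxel: object = None
    density_region: object = None
    mrx3_state: object = None
    association: pd.DataFrame | None = None
    significance: pd.DataFrame | None = None
    class_tests: tuple | None = None
    risk_genes: list[str] | None = None
    eigengene_scores: pd.Series | None = None
    embedding_gene: object = None
    embedding_spatial: object = None
    fits: dict | None = None
    gene_fits: dict | None = None
    gene_sets: object = None
    manifest: dict | None = None


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages and write outputs plus a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    result = PipelineResult(config=config)
    stages = list(config.stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    def _require(attr: str, needed_by: str) -> None:
        if getattr(result, attr) is None:
            raise RuntimeError(
                f"stage '{needed_by}' needs outputs missing because an earlier "
                f"stage was toggled off ({attr} unavailable)")

    def _write(df: pd.DataFrame, name: str, label: str = "id") -> None:
        path = outdir / name
        io.write_matrix(df, path, label=label)
        written.append(path)

    # ---------------------------------------------------------------- synth
    if "synth" in stages:
        logger.info("stage synth")
        if config.world_h5:
            result.world = io.read_world_h5(config.world_h5)
        else:
            result.world = synth.generate_world(
                n_regions=config.n_regions,
                grid_shape=tuple(config.grid_shape),
                n_genes=config.n_genes,
                n_types=config.n_types,
                markers_per_type=config.markers_per_type,
                smoothness=config.smoothness,
                expression_noise=config.expression_noise,
                n_datasets=config.n_datasets,
                n_timepoints=config.n_timepoints,
                snr=config.snr,
                rng_seed=config.rng_seed,
            )
        world = result.world
        io.write_atlas(world.atlas, outdir / "atlas.tsv")
        written += [outdir / "atlas.tsv", outdir / "atlas.groups.tsv"]
        _write(world.signatures.values, "signatures.tsv", label="gene")
        io.write_world_h5(world, outdir / "world.h5")
        truth_meta = {
            "vulnerable_types": world.truth.vulnerable_types,
            "resilient_types": world.truth.resilient_types,
            "expression_noise_sd": world.truth.expression_noise_sd,
            "tau_noise_params": list(world.truth.tau_noise_params),
            "rng_seed": world.truth.rng_seed,
        }
        (outdir / "ground_truth.json").write_text(
            json.dumps(truth_meta, indent=2, sort_keys=True))
        written.append(outdir / "ground_truth.json")
        for ds in world.tau_datasets:
            io.write_tau_dataset(ds, outdir / "tau")
            written += [outdir / "tau" / f"{ds.dataset_id}.tau.tsv",
                        outdir / "tau" / f"{ds.dataset_id}.seeds.txt",
                        outdir / "tau" / f"{ds.dataset_id}.mapping.tsv"]

    world = result.world

    # ----------------------------------------------------------------- miss
    if "miss" in stages:
        _require("world", "miss")
        logger.info("stage miss")
        D_vox, D_reg, state = miss.run_miss(
            world.signatures, world.expression,
            n_genes=config.n_selected_genes,
            candidate_sizes=config.candidate_sizes,
            prune_fraction=config.prune_fraction,
        )
        result.density_voxel, result.density_region = D_vox, D_reg
        result.mrx3_state = state
        _write(D_reg.values, "density_regional.tsv", label="type")
        sel = pd.DataFrame({"gene": state.selected,
                            "order": np.arange(len(state.selected))})
        sel.to_csv(outdir / "selected_genes.tsv", sep="\t", index=False)
        written.append(outdir / "selected_genes.tsv")
        if state.residual_curve is not None:
            state.residual_curve.to_csv(outdir / "residual_curve.tsv",
                                        sep="\t", index=False)
            written.append(outdir / "residual_curve.tsv")

    # ---------------------------------------------------------------- assoc
    if "assoc" in stages:
        _require("density_region", "assoc")
        logger.info("stage assoc")
        feats = result.density_region.values  # types x regions
        result.association = assoc.association_table(
            feats, world.tau_datasets, world.atlas, method=config.method)
        result.significance = assoc.surrogate_significance(
            feats, world.tau_datasets, world.atlas,
            n_surrogates=config.n_surrogates, rng_seed=config.rng_seed)
        result.class_tests = assoc.class_level_tests(
            result.association, world.signatures.class_label)
        result.association.to_csv(outdir / "association.tsv", sep="\t",
                                  index=False)
        written.append(outdir / "association.tsv")
        _write(result.significance, "significance.tsv", label="type")

        # risk-gene panel: planted-type markers plus random fillers, used for
        # the eigengene summary and the gene-pool models
        rng = np.random.default_rng(config.rng_seed + 1)
        markers = [g for t in world.truth.vulnerable_types
                   for g in world.signatures.marker_genes.get(t, [])]
        n_fill = max(0, config.n_risk_genes - len(markers))
        others = sorted(set(world.signatures.gene_ids) - set(markers))
        fillers = list(rng.choice(others, size=min(n_fill, len(others)),
                                  replace=False))
        result.risk_genes = sorted(markers[:config.n_risk_genes] + fillers)
        io.write_gene_list(result.risk_genes, outdir / "risk_genes.txt")
        written.append(outdir / "risk_genes.txt")
        gene_regional = miss.regional_mean_expression(world.expression,
                                                      world.atlas)
        scores, explained, _ = assoc.eigengene(
            gene_regional.loc[result.risk_genes].T)
        result.eigengene_scores = scores
        eg = scores.to_frame()
        eg["explained_variance"] = explained
        _write(eg, "eigengene.tsv", label="region")

    # ------------------------------------------------------------- spectral
    if "spectral" in stages:
        _require("density_region", "spectral")
        logger.info("stage spectral")
        C_norm, _ = miss.normalize(world.signatures, world.expression)
        subset = result.mrx3_state.selected[: result.mrx3_state.chosen_size] \
            if result.mrx3_state is not None else C_norm.gene_ids
        gene_profiles = C_norm.values.loc[subset].T  # types x genes
        result.embedding_gene = spectral.embed_profiles(gene_profiles)
        result.embedding_spatial = spectral.embed_profiles(
            result.density_region.values)
        _write(result.embedding_gene.loadings, "embedding_gene.tsv",
               label="type")
        _write(result.embedding_spatial.loadings, "embedding_spatial.tsv",
               label="type")

    # --------------------------------------------------------------- models
    if "models" in stages:
        _require("density_region", "models")
        logger.info("stage models")
        feats = result.density_region.values
        timepoints = (range(config.n_timepoints) if config.per_timepoint
                      else [-1])
        result.fits = {}
        for tp in timepoints:
            result.fits[tp] = models.fit_dataset_models(
                feats, world.tau_datasets, world.atlas, pool="types",
                k=config.top_k, folds=config.folds,
                rng_seed=config.rng_seed, timepoint=tp)
            table = models.summary_table(result.fits[tp])
            _write(table, f"models_tp{tp}.tsv", label="dataset")
        if result.risk_genes is not None:
            gene_regional = miss.regional_mean_expression(world.expression,
                                                          world.atlas)
            result.gene_fits = models.fit_dataset_models(
                gene_regional.loc[result.risk_genes], world.tau_datasets,
                world.atlas, pool="genes", k=config.top_k,
                folds=config.folds, rng_seed=config.rng_seed)
            _write(models.summary_table(result.gene_fits),
                   "models_genes.tsv", label="dataset")

    # ------------------------------------------------------------- genesets
    if "genesets" in stages:
        _require("fits", "genesets")
        logger.info("stage genesets")
        gene_regional = miss.regional_mean_expression(world.expression,
                                                      world.atlas)
        gene_assoc = assoc.association_table(
            gene_regional, world.tau_datasets, world.atlas,
            method=config.method)
        mean_r_genes = assoc.mean_correlation(gene_assoc)
        mean_r_types = assoc.mean_correlation(result.association)
        end_fits = [pair["bic"] for pair in
                    result.fits[list(result.fits)[-1]].values()]
        sel_counts = pd.Series(0, index=result.density_region.type_ids,
                               dtype=float)
        for f in end_fits:
            for t in f.selected:
                sel_counts[t] += 1
        C_norm, _ = miss.normalize(world.signatures, world.expression)
        collection = genesets.build_gene_sets(
            mean_r_genes, mean_r_types, sel_counts, C_norm.values,
            fraction=config.geneset_fraction)
        result.gene_sets = collection
        for name, members in collection.as_dict().items():
            path = outdir / f"{name}.txt"
            io.write_gene_list(members, path)
            written.append(path)
        overlaps = genesets.overlap_counts(collection)
        overlaps.to_csv(outdir / "overlaps.tsv", sep="\t", index=False)
        written.append(outdir / "overlaps.tsv")

    # ------------------------------------------------------------- manifest
    manifest = {
        "config": dataclasses.asdict(config),
        "stages_run": stages,
        "checksums": {str(p.relative_to(outdir)): _checksum(p)
                      for p in sorted(set(written))},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    result.manifest = manifest
    return result
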