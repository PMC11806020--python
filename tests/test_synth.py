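"""Synthetic-world generator: tiling, marker structure, forward model, tau."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tauvuln import miss, synth


class TestGenerateAtlas:
    def test_single_region_absorbs_all_voxels(self):
        atlas = synth.generate_atlas(1, (2, 2, 2), rng_seed=0)
        assert atlas.n_regions == 1
        assert atlas.region_volume.iloc[0] == 8

    def test_pigeonhole_one_voxel_per_region(self):
        atlas = synth.generate_atlas(8, (2, 2, 2), rng_seed=0)
        assert (atlas.region_volume == 1).all()

    def test_volumes_conserve_and_seed_reproduces(self):
        a1 = synth.generate_atlas(60, (12, 12, 10), rng_seed=7)
        a2 = synth.generate_atlas(60, (12, 12, 10), rng_seed=7)
        assert a1.region_volume.sum() == 1440
        assert (a1.voxel_region == a2.voxel_region).all()

    def test_regions_are_contiguous(self, atlas60):
        # every region's voxel set must be connected under 6-neighborhood
        coords = {tuple(c): r for c, r in
                  zip(atlas60.voxel_coords, atlas60.voxel_region)}
        for r in range(atlas60.n_regions):
            voxels = {tuple(c) for c, reg in
                      zip(atlas60.voxel_coords, atlas60.voxel_region) if reg == r}
            start = next(iter(voxels))
            seen, stack = {start}, [start]
            while stack:
                x, y, z = stack.pop()
                for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    nb = (x + dx, y + dy, z + dz)
                    if nb in voxels and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            assert seen == voxels

    def test_infeasible_tiling_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_atlas(9, (2, 2, 2), rng_seed=0)


class TestGenerateSignatures:
    def test_no_markers_means_no_planted_structure(self):
        C = synth.generate_signatures(20, 4, markers_per_type=0, rng_seed=0)
        assert C.marker_genes == {t: [] for t in C.type_ids}
        assert (C.values.to_numpy() > 0).all()

    def test_marker_max_forced_into_own_type(self):
        C = synth.generate_signatures(4, 2, markers_per_type=1, rng_seed=3)
        for t in C.type_ids:
            for g in C.marker_genes[t]:
                assert C.values.loc[g].idxmax() == t

    def test_markers_correlate_with_own_type_across_seeds(self):
        # a type's column-normalized profile should resemble its own markers'
        # indicator more than other types' markers in nearly every draw
        wins = 0
        for seed in range(100):
            C = synth.generate_signatures(60, 4, markers_per_type=5,
                                          rng_seed=seed)
            V = C.values.div(C.values.sum(axis=0), axis=1)
            ok = True
            for t in C.type_ids:
                own = V.loc[C.marker_genes[t], t].mean()
                others = [V.loc[C.marker_genes[u], t].mean()
                          for u in C.type_ids if u != t]
                ok &= own > max(others)
            wins += ok
        assert wins >= 95

    def test_marker_budget_exceeding_genes_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_signatures(5, 3, markers_per_type=2, rng_seed=0)


class TestGenerateDensityTruth:
    def test_vanishing_smoothness_gives_uncorrelated_neighbors(self, atlas60):
        D = synth.generate_density_truth(atlas60, 1, smoothness=1e-6, rng_seed=1)
        vals = D.values.iloc[0].to_numpy().reshape(atlas60.grid_shape)
        r = np.corrcoef(vals[:-1].ravel(), vals[1:].ravel())[0, 1]
        assert abs(r) < 0.1

    def test_large_smoothness_gives_nearly_constant_map(self, atlas60):
        D = synth.generate_density_truth(atlas60, 1, smoothness=12.0, rng_seed=1)
        v = D.values.iloc[0]
        assert v.std() / v.mean() < 0.2

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_densities_nonnegative(self, atlas60, seed):
        D = synth.generate_density_truth(atlas60, 3, smoothness=1.5, rng_seed=seed)
        assert (D.values.to_numpy() >= 0).all()


class TestSynthesizeExpression:
    def test_zero_noise_reproduces_forward_model(self, atlas60):
        C = synth.generate_signatures(30, 4, 3, rng_seed=0)
        D = synth.generate_density_truth(atlas60, 4, 1.5, rng_seed=1,
                                         type_ids=C.type_ids)
        E = synth.synthesize_expression(C, D, atlas60, noise_sd=0.0)
        expected = C.values.to_numpy() @ D.values.to_numpy()
        np.testing.assert_allclose(E.values.to_numpy(), expected)

    def test_identity_signature_recovers_density(self, atlas60):
        D = synth.generate_density_truth(atlas60, 4, 1.5, rng_seed=1)
        eye = pd.DataFrame(np.eye(4), index=[f"g{i}" for i in range(4)],
                           columns=D.values.index)
        from tauvuln.types import GeneSignatureMatrix
        C = GeneSignatureMatrix(eye, {t: "GABAergic" for t in D.values.index})
        E = synth.synthesize_expression(C, D, atlas60, noise_sd=0.0)
        np.testing.assert_allclose(E.values.to_numpy(), D.values.to_numpy())

    def test_noise_sd_close_to_nominal(self, atlas60):
        C = synth.generate_signatures(30, 4, 3, rng_seed=0)
        D = synth.generate_density_truth(atlas60, 4, 1.5, rng_seed=1,
                                         type_ids=C.type_ids)
        clean = C.values.to_numpy() @ D.values.to_numpy()
        sd = 0.1 * clean.mean()
        E = synth.synthesize_expression(C, D, atlas60, noise_sd=sd, rng_seed=2)
        resid = E.values.to_numpy() - np.clip(clean, 0, None)
        per_gene_sd = resid.std(axis=1)
        # genes expressed well above the noise floor are unaffected by the
        # nonnegativity truncation; their residual sd should track nominal
        strong = clean.min(axis=1) > 2 * sd
        assert strong.sum() >= 10
        assert (np.abs(per_gene_sd[strong] - sd) / sd < 0.2).all()


class TestSynthesizeTauopathy:
    def test_single_vulnerable_type_zero_noise_is_proportional(self, atlas60):
        D = synth.generate_density_truth(atlas60, 3, 1.5, rng_seed=4)
        Dr = miss.aggregate_regions(D, atlas60)
        t0 = Dr.type_ids[0]
        seeds = [[atlas60.region_ids[5]]]
        (ds,) = synth.synthesize_tauopathy(
            atlas60, Dr, {t0: 1.0}, n_datasets=1, n_timepoints=2,
            seed_regions=seeds, tau_noise_params=(1.5, 0.0), rng_seed=0)
        keep = [r for r in ds.region_ids if r not in ds.seed_region_ids]
        r = stats.pearsonr(ds.tau.loc[keep, "t2"],
                           Dr.values.loc[t0, keep]).statistic
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_negative_weight_zero_noise_anticorrelates(self, atlas60):
        D = synth.generate_density_truth(atlas60, 3, 1.5, rng_seed=4)
        Dr = miss.aggregate_regions(D, atlas60)
        t0 = Dr.type_ids[0]
        # auto baseline keeps the construction strictly nonnegative, so
        # rectification never acts and the sign survives intact
        (ds,) = synth.synthesize_tauopathy(
            atlas60, Dr, {t0: -1.0}, n_datasets=1, n_timepoints=1,
            tau_noise_params=(1.5, 0.0), rng_seed=0)
        r = stats.pearsonr(ds.tau["t1"], Dr.values.loc[t0]).statistic
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_unknown_seed_region_rejected(self, atlas60):
        D = synth.generate_density_truth(atlas60, 2, 1.5, rng_seed=4)
        Dr = miss.aggregate_regions(D, atlas60)
        with pytest.raises(ValueError, match="seed"):
            synth.synthesize_tauopathy(
                atlas60, Dr, {Dr.type_ids[0]: 1.0}, n_datasets=1,
                n_timepoints=1, seed_regions=[["nonexistent"]],
                tau_noise_params=(1.5, 0.0), rng_seed=0)

    def test_seed_regions_receive_elevated_burden(self, atlas60):
        D = synth.generate_density_truth(atlas60, 2, 1.5, rng_seed=4)
        Dr = miss.aggregate_regions(D, atlas60)
        seed_region = atlas60.region_ids[3]
        (ds,) = synth.synthesize_tauopathy(
            atlas60, Dr, {Dr.type_ids[0]: 1.0}, n_datasets=1, n_timepoints=1,
            seed_regions=[[seed_region]], tau_noise_params=(1.5, 0.0),
            rng_seed=0)
        others = ds.tau.drop(index=seed_region)["t1"]
        assert ds.tau.loc[seed_region, "t1"] > others.max()


class TestGenerateWorld:
    def test_world_is_seed_deterministic(self):
        w1 = synth.generate_world(n_genes=60, n_types=4, markers_per_type=4,
                                  n_datasets=2, rng_seed=5)
        w2 = synth.generate_world(n_genes=60, n_types=4, markers_per_type=4,
                                  n_datasets=2, rng_seed=5)
        pd.testing.assert_frame_equal(w1.expression.values, w2.expression.values)
        pd.testing.assert_frame_equal(w1.tau_datasets[0].tau,
                                      w2.tau_datasets[0].tau)

    def test_planted_effect_sets_are_disjoint_and_recorded(self, small_world):
        truth = small_world.truth
        assert set(truth.vulnerable_types).isdisjoint(truth.resilient_types)
        assert truth.tau_noise_params[1] > 0
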