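"""MISS: normalization, MRx3 selection, NNLS deconvolution, aggregation."""

import numpy as np
import pandas as pd
import pytest

from tauvuln import miss, synth
from tauvuln.types import CellDensityMap, GeneSignatureMatrix, VoxelExpressionMap

from .oracles import (
    mrmr_stepwise,
    nnls_by_enumeration,
    noise_scores_full_resolve,
)


def _toy_pair(C_vals, E_vals, atlas):
    genes = [f"g{i}" for i in range(C_vals.shape[0])]
    types = [f"T{i:02d}" for i in range(C_vals.shape[1])]
    C = GeneSignatureMatrix(pd.DataFrame(C_vals, index=genes, columns=types),
                            {t: "GABAergic" for t in types})
    E = VoxelExpressionMap(
        pd.DataFrame(E_vals, index=genes, columns=range(E_vals.shape[1])),
        atlas)
    return C, E


@pytest.fixture(scope="module")
def atlas8():
    return synth.generate_atlas(2, (2, 2, 2), rng_seed=0)


class TestNormalize:
    def test_column_sum_and_row_max_conventions(self, atlas8):
        C, E = _toy_pair(np.array([[2.0], [2.0]]),
                         np.array([[0, 5, 10, 1, 1, 1, 1, 1],
                                   [1, 1, 1, 1, 1, 1, 1, 2]], dtype=float),
                         atlas8)
        C_n, E_n = miss.normalize(C, E)
        np.testing.assert_allclose(C_n.values.to_numpy().ravel(), [0.5, 0.5])
        np.testing.assert_allclose(E_n.values.iloc[0, :3], [0, 0.5, 1.0])

    def test_all_zero_gene_row_left_unchanged_with_warning(self, atlas8):
        C, E = _toy_pair(np.ones((2, 1)),
                         np.vstack([np.zeros(8), np.ones(8)]), atlas8)
        with pytest.warns(UserWarning, match="all-zero"):
            _, E_n = miss.normalize(C, E)
        assert (E_n.values.iloc[0] == 0).all()

    def test_empty_gene_intersection_rejected(self, atlas8):
        C, E = _toy_pair(np.ones((2, 1)), np.ones((2, 8)), atlas8)
        C.values.index = ["a", "b"]
        with pytest.raises(ValueError, match="shared"):
            miss.normalize(C, E)


class TestScoreGeneNoise:
    def test_consistent_gene_adds_zero_residual(self):
        # gene 2's row in both C and E is a copy of gene 0 and gene 1's sum,
        # so it is exactly consistent with the running least-squares fit
        rng = np.random.default_rng(1)
        C = rng.uniform(0.5, 2.0, size=(3, 2))
        C[2] = C[0] + C[1]
        D = rng.uniform(0.5, 2.0, size=(2, 5))
        E = C @ D
        scores = noise_scores_full_resolve(C, E)
        assert scores[2] == pytest.approx(0.0, abs=1e-8)

    def test_identical_rows_at_identical_state_score_identically(self):
        rng = np.random.default_rng(2)
        C = rng.uniform(0.1, 1.0, (4, 3))
        E = rng.uniform(0.1, 1.0, (4, 6))
        A = np.zeros((3, 3))
        B = np.zeros((3, 6))
        prev = float((E ** 2).sum())
        s1, *_ = miss.incremental_mse(A, B, C, E, prev, C[1], E[1])
        s2, *_ = miss.incremental_mse(A, B, C, E, prev, C[1].copy(), E[1].copy())
        assert s1 == s2

    def test_rank_one_updates_match_full_resolve_oracle(self, atlas8):
        rng = np.random.default_rng(3)
        Cv = rng.uniform(0.1, 1.0, (6, 2))
        Ev = rng.uniform(0.1, 1.0, (6, 8))
        C, E = _toy_pair(Cv, Ev, atlas8)
        scores = miss.score_gene_noise(E, C)
        expected = noise_scores_full_resolve(Cv, Ev)
        np.testing.assert_allclose(scores.to_numpy(), expected, atol=1e-8)


class TestPruneNoisyGenes:
    def test_ten_percent_of_ten_removes_one(self):
        scores = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        assert len(miss.prune_noisy_genes(scores, 0.10)) == 9

    def test_equal_scores_remove_lexicographically_last(self):
        scores = pd.Series(1.0, index=[f"g{i}" for i in range(10)])
        kept = miss.prune_noisy_genes(scores, 0.10)
        assert "g9" not in kept and len(kept) == 9

    def test_quantile_arithmetic_on_ranked_scores(self):
        scores = pd.Series(np.arange(1.0, 101.0),
                           index=[f"g{i:03d}" for i in range(100)])
        kept = miss.prune_noisy_genes(scores, 0.10)
        removed = set(scores.index) - set(kept)
        assert removed == {f"g{i:03d}" for i in range(90, 100)}

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 2.0])
    def test_fraction_out_of_range_rejected(self, fraction):
        with pytest.raises(ValueError):
            miss.prune_noisy_genes(pd.Series([1.0, 2.0]), fraction)


class TestMrmrSelect:
    def _sig(self, rows, ids=None):
        ids = ids or [f"g{i}" for i in range(len(rows))]
        types = [f"T{i:02d}" for i in range(len(rows[0]))]
        return GeneSignatureMatrix(
            pd.DataFrame(np.asarray(rows, dtype=float), index=ids,
                         columns=types),
            {t: "non-neuronal" for t in types})

    def test_constant_row_never_beats_varying_row(self):
        C = self._sig([[1, 1, 1], [0, 1, 2]])
        assert miss.mrmr_select(C, 2) == ["g1", "g0"]

    def test_fewer_than_three_types_refused(self):
        C = self._sig([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="3 cell types"):
            miss.mrmr_select(C, 1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_greedy_matches_stepwise_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.uniform(0.0, 1.0, size=(5, 4))
        C = self._sig(rows)
        got = miss.mrmr_select(C, 3)
        expected = mrmr_stepwise(rows, list(C.gene_ids), 3)
        assert got == expected


class TestChooseSubsetSize:
    def test_elbow_of_convex_curve_matches_closed_form(self):
        sizes = np.arange(10.0, 101.0, 10.0)
        resid = 1.0 / sizes  # strictly convex decreasing
        idx = miss._elbow(sizes, resid)
        # closed form: max distance to the chord of the min-max normalized curve
        xn = (sizes - sizes[0]) / (sizes[-1] - sizes[0])
        yn = (resid - resid[0]) / (resid[-1] - resid[0])
        expected = int(np.argmax(np.abs(xn - yn)))
        assert idx == expected

    def test_flat_curve_returns_smallest_size(self):
        assert miss._elbow(np.array([10.0, 20, 30]), np.ones(3)) == 0

    def test_increasing_curve_falls_back_to_argmin(self):
        with pytest.warns(UserWarning, match="non-monotone"):
            idx = miss._elbow(np.array([10.0, 20, 30]),
                              np.array([1.0, 0.5, 2.0]))
        assert idx == 1

    def test_marker_recovery_picks_compact_subset(self, atlas60):
        # 20 informative marker genes + 80 genes whose expression rows are
        # pure noise: the elbow should land near the number of useful genes
        hits = 0
        for seed in range(10):
            C = synth.generate_signatures(100, 4, markers_per_type=5,
                                          rng_seed=seed)
            D = synth.generate_density_truth(atlas60, 4, 1.5, rng_seed=seed + 50,
                                             type_ids=C.type_ids)
            E = synth.synthesize_expression(C, D, atlas60, noise_sd=0.0)
            markers = {g for t in C.type_ids for g in C.marker_genes[t]}
            noise_genes = [g for g in C.gene_ids if g not in markers]
            rng_local = np.random.default_rng(seed + 99)
            vals = E.values.copy()
            scale = vals.to_numpy().mean()
            vals.loc[noise_genes] = rng_local.uniform(
                0, 2 * scale, size=(len(noise_genes), vals.shape[1]))
            E_noisy = VoxelExpressionMap(vals, atlas60)
            n_G, curve, state = miss.choose_subset_size(
                E_noisy, C, candidate_sizes=list(range(5, 91, 5)))
            hits += 15 <= n_G <= 40
        assert hits >= 8


class TestDeconvolve:
    def test_identity_signature_returns_expression(self, atlas8):
        C, E = _toy_pair(np.eye(2), np.array([[2.0] * 8, [3.0] * 8]), atlas8)
        D = miss.deconvolve(E, C)
        np.testing.assert_allclose(D.values.to_numpy()[:, 0], [2.0, 3.0])

    def test_one_dimensional_least_squares_solution(self, atlas8):
        C, E = _toy_pair(np.array([[1.0], [1.0]]),
                         np.column_stack([[1.0, 3.0]] * 8), atlas8)
        D = miss.deconvolve(E, C)
        assert D.values.iloc[0, 0] == pytest.approx(2.0)
        assert D.residual.iloc[0] == pytest.approx(2.0)

    def test_all_zero_voxel_gives_zero_density_and_residual(self, atlas8):
        Ev = np.ones((3, 8))
        Ev[:, 2] = 0.0
        C, E = _toy_pair(np.abs(np.random.default_rng(0).normal(1, 0.2, (3, 2))),
                         Ev, atlas8)
        D = miss.deconvolve(E, C)
        assert (D.values.iloc[:, 2] == 0).all()
        assert D.residual.iloc[2] == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_active_set_enumeration_oracle(self, atlas8, seed):
        rng = np.random.default_rng(seed)
        Cv = rng.uniform(0.0, 1.0, (8, 3))
        Ev = rng.uniform(0.0, 1.0, (8, 8))
        C, E = _toy_pair(Cv, Ev, atlas8)
        D = miss.deconvolve(E, C)
        for k in range(8):
            expected = nnls_by_enumeration(Cv, Ev[:, k])
            np.testing.assert_allclose(D.values.to_numpy()[:, k], expected,
                                       atol=1e-8)

    def test_voxel_order_has_no_cross_voxel_state(self, atlas8):
        rng = np.random.default_rng(4)
        Cv = rng.uniform(0.1, 1.0, (5, 2))
        Ev = rng.uniform(0.1, 1.0, (5, 8))
        C, E = _toy_pair(Cv, Ev, atlas8)
        perm = rng.permutation(8)
        E_shuf = VoxelExpressionMap(
            E.values.iloc[:, perm].set_axis(range(8), axis=1), atlas8)
        D = miss.deconvolve(E, C)
        D_shuf = miss.deconvolve(E_shuf, C)
        np.testing.assert_allclose(D_shuf.values.to_numpy(),
                                   D.values.to_numpy()[:, perm])


class TestAggregateRegions:
    def test_region_mean_of_member_voxels(self, atlas8):
        vals = pd.DataFrame(np.zeros((1, 8)), index=["T00"], columns=range(8))
        members0 = np.flatnonzero(atlas8.voxel_region == 0)
        vals.iloc[0, members0[:1]] = 1.0
        vals.iloc[0, members0[1:2]] = 3.0
        D = CellDensityMap(vals, axis="voxel")
        reg = miss.aggregate_regions(D, atlas8)
        vol0 = atlas8.region_volume.iloc[0]
        assert reg.values.iloc[0, 0] == pytest.approx(4.0 / vol0)

    def test_grouping_is_volume_weighted(self, atlas60):
        r0, r1 = atlas60.region_ids[:2]
        vol = atlas60.region_volume
        vals = np.zeros((1, atlas60.n_voxels))
        vals[0, atlas60.voxel_region == 0] = 4.0
        D = CellDensityMap(pd.DataFrame(vals, index=["T00"],
                                        columns=range(atlas60.n_voxels)),
                           axis="voxel")
        grouped = miss.aggregate_regions(D, atlas60, grouping={"G": [r0, r1]})
        expected = 4.0 * vol[r0] / (vol[r0] + vol[r1])
        assert grouped.values.loc["T00", "G"] == pytest.approx(expected)

    def test_volume_weighted_totals_conserved(self, atlas60, rng):
        vals = rng.uniform(0, 1, (3, atlas60.n_voxels))
        D = CellDensityMap(pd.DataFrame(vals, index=["a", "b", "c"],
                                        columns=range(atlas60.n_voxels)),
                           axis="voxel")
        reg = miss.aggregate_regions(D, atlas60)
        vol = atlas60.region_volume.to_numpy()
        np.testing.assert_allclose(
            (reg.values.to_numpy() * vol).sum(axis=1), vals.sum(axis=1))


class TestValidateAgainstReference:
    def test_self_reference_gives_unit_correlation(self, small_world_densities):
        _, D_reg, _ = small_world_densities
        ref = D_reg.values
        out = miss.validate_against_reference(D_reg, ref)
        np.testing.assert_allclose(out["R"], 1.0, atol=1e-12)

    def test_merging_identical_subtypes_preserves_correlation(
            self, small_world_densities):
        _, D_reg, _ = small_world_densities
        t = D_reg.type_ids[0]
        ref = D_reg.values.loc[[t]]
        merged = miss.validate_against_reference(
            D_reg, ref, type_merge_rules={t: [t, t]})
        assert merged.loc[t, "R"] == pytest.approx(1.0, abs=1e-12)

    def test_inferred_maps_track_truth_at_moderate_noise(self, small_world,
                                                         small_world_densities):
        _, D_reg, _ = small_world_densities
        truth_reg = miss.aggregate_regions(small_world.truth.true_density,
                                           small_world.atlas)
        out = miss.validate_against_reference(D_reg, truth_reg.values)
        assert out["R"].median() >= 0.8

    def test_too_few_shared_regions_refused(self, small_world_densities):
        _, D_reg, _ = small_world_densities
        ref = D_reg.values.iloc[:, :2]
        with pytest.raises(ValueError, match="3 shared"):
            miss.validate_against_reference(D_reg, ref)


class TestMissInvariants:
    def test_densities_nonnegative(self, small_world_densities):
        D_vox, D_reg, _ = small_world_densities
        assert (D_vox.values.to_numpy() >= 0).all()
        assert (D_reg.values.to_numpy() >= 0).all()

    def test_residual_nonincreasing_on_nested_prefixes(self, atlas60):
        C = synth.generate_signatures(80, 4, markers_per_type=5, rng_seed=2)
        D = synth.generate_density_truth(atlas60, 4, 1.5, rng_seed=3,
                                         type_ids=C.type_ids)
        E = synth.synthesize_expression(C, D, atlas60, noise_sd=0.5, rng_seed=4)
        n_G, curve, state = miss.choose_subset_size(
            E, C, candidate_sizes=[10, 20, 30, 40, 50, 60])
        resid = curve["residual"].to_numpy()
        assert (resid[1:] <= resid[:-1] + 1e-9).all()
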