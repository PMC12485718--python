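"""Reciprocal NNLS correspondence: pseudobulking, gene selection, the NNLS
solver against an exhaustive active-set oracle, the combined statistic and
planted-correspondence recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from gastrumatch import SimSpec, generate_paired_datasets
from gastrumatch import correspondence as corr
from gastrumatch.preprocess import lognormalize


def nnls_oracle(design: np.ndarray, target: np.ndarray):
    """Exhaustive active-set NNLS with free intercept.

    For every support (subset of columns allowed to be nonzero), solve the
    unconstrained least squares with intercept on that support; keep feasible
    solutions (all coefficients >= 0) and return the one with the smallest
    residual norm. Valid because the NNLS optimum's support is one of the
    enumerated subsets.
    """
    n, p = design.shape
    best = None
    for r in range(p + 1):
        for support in itertools.combinations(range(p), r):
            cols = np.column_stack([np.ones(n)] + [design[:, j] for j in support])
            sol, *_ = np.linalg.lstsq(cols, target, rcond=None)
            if np.any(sol[1:] < -1e-12):
                continue
            beta = np.zeros(p)
            beta[list(support)] = np.clip(sol[1:], 0.0, None)
            resid = np.linalg.norm(target - (sol[0] + design @ beta))
            if best is None or resid < best[2] - 1e-12:
                best = (sol[0], beta, resid)
    return best


class TestPseudobulk:
    def test_single_cell_cluster_profile_is_that_cell(self, small_norm):
        labels = ["solo"] + ["rest"] * (small_norm.n_obs - 1)
        prof = corr.pseudobulk_profiles(small_norm, labels)
        row = np.asarray(small_norm.X[0].todense()).ravel()
        np.testing.assert_allclose(prof.profiles.loc["solo"], row, atol=1e-12)
        assert prof.n_cells["solo"] == 1

    def test_large_downsample_limit_changes_nothing(self, small_norm, small_dataset):
        _, truth = small_dataset
        labels = truth.cells["cell_type"]
        full = corr.pseudobulk_profiles(small_norm, labels)
        capped = corr.pseudobulk_profiles(small_norm, labels, downsample_n=10**6)
        pd.testing.assert_frame_equal(full.profiles, capped.profiles)

    def test_identical_cells_downsample_to_the_same_mean(self):
        X = np.tile(np.arange(5, dtype=float), (50, 1))
        ad = AnnData(
            X=X,
            obs=pd.DataFrame(index=[f"c{i}" for i in range(50)]),
            var=pd.DataFrame(index=[f"g{i}" for i in range(5)]),
        )
        prof = corr.pseudobulk_profiles(ad, ["k"] * 50, downsample_n=10, seed=1)
        np.testing.assert_allclose(prof.profiles.loc["k"], np.arange(5))


class TestGeneSelection:
    def test_union_saturates_when_n_exceeds_genes(self, rng):
        profs = pd.DataFrame(rng.random((3, 20)),
                             columns=[f"g{i}" for i in range(20)])
        sel = corr.select_genes_for_target(profs.iloc[0], profs,
                                           n_expr=50, n_spec=50)
        assert set(sel) == set(profs.columns)

    def test_exclusive_gene_always_in_specific_set(self, rng):
        profs = pd.DataFrame(rng.random((4, 100)) + 0.5,
                             columns=[f"g{i}" for i in range(100)])
        profs.iloc[1:, 7] = 0.0  # expressed only in the target cluster
        sel = corr.select_genes_for_target(profs.iloc[0], profs,
                                           n_expr=5, n_spec=5)
        assert "g7" in set(sel)

    def test_matches_brute_force_two_ranking_oracle(self, rng):
        n_genes, n_expr, n_spec = 5000, 1500, 1500
        profs = pd.DataFrame(
            rng.random((10, n_genes)) * (rng.random((10, n_genes)) > 0.2),
            columns=[f"g{i:05d}" for i in range(n_genes)],
        )
        target = profs.iloc[0]
        sel = set(corr.select_genes_for_target(target, profs,
                                               n_expr=n_expr, n_spec=n_spec))
        # oracle: two independent stable sorts
        t = target.to_numpy()
        by_expr = sorted(range(n_genes), key=lambda i: (-t[i], i))[:n_expr]
        spec_score = t / (profs.to_numpy().mean(axis=0) + 1e-8)
        eligible = [i for i in range(n_genes) if t[i] > 0]
        by_spec = sorted(eligible, key=lambda i: (-spec_score[i], i))[:n_spec]
        expected = {profs.columns[i] for i in set(by_expr) | set(by_spec)}
        assert sel == expected
        assert n_expr <= len(sel) <= n_expr + n_spec


class TestNNLS:
    def test_orthogonal_indicator_design_recovers_exact_coefficients(self):
        design = np.array([[1.0, 0.0]] * 3 + [[0.0, 1.0]] * 3)
        target = 3.0 * design[:, 0]
        fit = corr.nnls_fit(target, design)
        np.testing.assert_allclose(fit.beta, [3.0, 0.0], atol=1e-10)
        assert fit.beta0 == pytest.approx(0.0, abs=1e-10)
        assert fit.residual_norm == pytest.approx(0.0, abs=1e-10)

    def test_negative_constant_target_absorbed_by_intercept(self, rng):
        design = rng.random((10, 3))
        fit = corr.nnls_fit(-np.ones(10), design)
        np.testing.assert_allclose(fit.beta, 0.0, atol=1e-8)
        assert fit.beta0 == pytest.approx(-1.0, abs=1e-8)

    def test_matches_active_set_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            p = int(rng.integers(1, 9))
            # overdetermined systems, as in the cluster-profile use case;
            # underdetermined fits have non-unique optima
            n = int(rng.integers(p + 5, 51))
            design = rng.normal(size=(n, p))
            target = rng.normal(size=n)
            fit = corr.nnls_fit(target, design)
            b0, beta, resid = nnls_oracle(design, target)
            assert np.abs(fit.beta - beta).max() < 1e-6
            assert fit.beta0 == pytest.approx(b0, abs=1e-6)
            assert fit.residual_norm == pytest.approx(resid, abs=1e-6)

    def test_residual_never_worse_than_intercept_only(self, rng):
        for _ in range(20):
            design = rng.normal(size=(30, 4))
            target = rng.normal(size=30)
            fit = corr.nnls_fit(target, design)
            assert fit.residual_norm <= np.linalg.norm(target - target.mean()) + 1e-10

    def test_adding_a_column_never_increases_residual(self, rng):
        design = rng.normal(size=(40, 6))
        target = rng.normal(size=40)
        prev = np.inf
        for p in range(1, 7):
            fit = corr.nnls_fit(target, design[:, :p])
            assert fit.residual_norm <= prev + 1e-10
            prev = fit.residual_norm

    def test_non_finite_inputs_error(self):
        with pytest.raises(ValueError):
            corr.nnls_fit(np.array([1.0, np.nan]), np.ones((2, 1)))


class TestCombineBetas:
    def test_zero_pair_gives_exact_floor_value(self):
        assert corr.combine_betas(0.0, 0.0) == pytest.approx(2e-4, abs=1e-18)

    def test_unit_pair(self):
        assert corr.combine_betas(0.99, 0.99) == pytest.approx(2.0, abs=1e-12)

    def test_symmetry_over_random_pairs(self, rng):
        a = rng.random(1000)
        b = rng.random(1000)
        for x, y in zip(a, b):
            assert corr.combine_betas(x, y) == corr.combine_betas(y, x)

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            corr.combine_betas(-0.1, 0.2)


@pytest.fixture(scope="module")
def paired_profiles():
    spec = SimSpec(
        n_genes=1500, n_types=6, cells_per_type=120, type_effect=2.0,
        n_markers_per_type=40, doublet_rate=0.0, seed=21,
    )
    a, b, truth = generate_paired_datasets(spec, shared_types=6)
    pa = corr.pseudobulk_profiles(lognormalize(a), a.obs["cell_type"],
                                  downsample_n=200, seed=0)
    pb = corr.pseudobulk_profiles(lognormalize(b), b.obs["cell_type"],
                                  downsample_n=500, seed=0)
    return pa, pb, truth


class TestCorrespondenceMatrix:
    def test_combined_entries_all_positive(self, paired_profiles):
        pa, pb, _ = paired_profiles
        res = corr.correspondence_matrix(pa, pb, n_expr=300, n_spec=300)
        assert (res.combined.to_numpy() > 0).all()
        np.testing.assert_allclose(res.row_scaled.max(axis=1), 1.0)
        assert (res.row_scaled.to_numpy() > 0).all()
        assert (res.row_scaled.to_numpy() <= 1.0).all()

    def test_row_argmax_recovers_planted_correspondence(self, paired_profiles):
        pa, pb, truth = paired_profiles
        res = corr.correspondence_matrix(pa, pb, n_expr=300, n_spec=300)
        argmax = res.combined.idxmax(axis=1)
        hits = sum(argmax[a] == b for a, b in truth.correspondence.items())
        assert hits == len(truth.correspondence)

    def test_permuting_b_clusters_permutes_columns(self, paired_profiles):
        pa, pb, _ = paired_profiles
        res = corr.correspondence_matrix(pa, pb, n_expr=300, n_spec=300)
        perm = list(pb.profiles.index[::-1])
        pb_perm = corr.ClusterProfile(
            profiles=pb.profiles.loc[perm], n_cells=pb.n_cells.loc[perm]
        )
        res_perm = corr.correspondence_matrix(pa, pb_perm,
                                              n_expr=300, n_spec=300)
        pd.testing.assert_frame_equal(
            res.combined[perm], res_perm.combined, atol=1e-10, rtol=1e-8
        )

    def test_duplicated_dataset_matches_itself(self, rng):
        profs = pd.DataFrame(
            rng.random((4, 400)) * 3.0,
            index=[f"K{i}" for i in range(4)],
            columns=[f"g{i}" for i in range(400)],
        )
        cp = corr.ClusterProfile(profiles=profs,
                                 n_cells=pd.Series(10, index=profs.index))
        res = corr.correspondence_matrix(cp, cp, n_expr=100, n_spec=100)
        argmax = res.combined.idxmax(axis=1)
        assert all(argmax[k] == k for k in profs.index)

    def test_single_cluster_inputs_error(self, rng):
        one = corr.ClusterProfile(
            profiles=pd.DataFrame(rng.random((1, 10))),
            n_cells=pd.Series([5]),
        )
        with pytest.raises(ValueError):
            corr.correspondence_matrix(one, one)


class TestMapHomologs:
    def _counts(self, X, genes):
        return AnnData(
            X=np.asarray(X, dtype=float),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(len(X))]),
            var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
        )

    def test_one_to_one_mapping_preserves_values(self):
        ad = self._counts([[3, 5], [2, 0]], ["s1", "s2"])
        table = pd.DataFrame({"source": ["s1", "s2"], "target": ["t1", "t2"]})
        out = corr.map_homologs(ad, table)
        expected = lognormalize(self._counts([[3, 5], [2, 0]], ["t1", "t2"]))
        np.testing.assert_allclose(
            np.asarray(out.X.todense()), np.asarray(expected.X), atol=1e-12
        )

    def test_two_sources_collapse_by_summing_counts(self):
        ad = self._counts([[3, 5, 2]], ["s1", "s2", "s3"])
        table = pd.DataFrame(
            {"source": ["s1", "s2", "s3"], "target": ["t1", "t1", "t2"]}
        )
        out = corr.map_homologs(ad, table)
        counts = np.asarray(out.layers["counts"].todense()).ravel()
        assert dict(zip(out.var_names, counts)) == {"t1": 8.0, "t2": 2.0}

    def test_many_to_many_hand_oracle(self):
        # 3 source genes, 2 targets, 4 edges: s1->t1, s1->t2, s2->t1, s3->t2
        ad = self._counts([[4, 6, 10]], ["s1", "s2", "s3"])
        table = pd.DataFrame(
            {"source": ["s1", "s1", "s2", "s3"],
             "target": ["t1", "t2", "t1", "t2"]}
        )
        out = corr.map_homologs(ad, table)
        counts = np.asarray(out.layers["counts"].todense()).ravel()
        # hand collapse: t1 = s1 + s2 = 10, t2 = s1 + s3 = 14
        assert dict(zip(out.var_names, counts)) == {"t1": 10.0, "t2": 14.0}
        total = counts.sum()
        np.testing.assert_allclose(
            np.asarray(out.X.todense()).ravel(),
            np.log1p(10_000 * counts / total),
        )

    def test_empty_mapping_errors(self):
        ad = self._counts([[1]], ["s1"])
        with pytest.raises(ValueError):
            corr.map_homologs(ad, pd.DataFrame(columns=["source", "target"]))
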