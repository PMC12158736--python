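import numpy as np
import pandas as pd
import pytest

import reversig as rv
from reversig.deconvolution import cpm
from reversig.formats import CountsMatrix, OrthologMap


def sc_matrix(values, labels):
    values = np.asarray(values)
    samples = list(labels)
    genes = [f"g{i}" for i in range(values.shape[0])]
    return CountsMatrix(pd.DataFrame(values, index=genes, columns=samples), dict(labels))


class TestBuildReference:
    def test_identical_cells_give_profile_column(self):
        m = sc_matrix(
            [[10, 10, 1, 1], [30, 30, 3, 3]],
            {"c1": "A", "c2": "A", "c3": "B", "c4": "B"},
        )
        ref = rv.build_reference(m)
        # both types have the same relative profile 1:3 → CPM column 25%/75%
        assert np.allclose(ref.signatures["A"], [250_000, 750_000])
        assert np.allclose(ref.signatures["B"], [250_000, 750_000])

    def test_depth_invariance(self):
        base = sc_matrix(
            [[10, 5, 1, 2], [30, 15, 3, 6]],
            {"c1": "A", "c2": "A", "c3": "B", "c4": "B"},
        )
        doubled_values = base.counts.copy()
        doubled_values["c1"] *= 2  # deeper sequencing of one cell
        doubled = CountsMatrix(doubled_values, dict(base.groups))
        a = rv.build_reference(base)
        b = rv.build_reference(doubled)
        assert np.allclose(a.signatures, b.signatures)

    def test_reference_recovers_generating_profiles(self):
        sc, profiles = rv.simulate_reference(K=3, G=800, cells_per_type=60, seed=24)
        ref = rv.build_reference(sc)
        for k, t in enumerate(profiles.cell_types):
            r = np.corrcoef(ref.signatures[t], profiles.profiles.iloc[:, k])[0, 1]
            assert r > 0.95

    def test_small_cell_type_rejected(self):
        m = sc_matrix([[1, 2, 3]], {"c1": "A", "c2": "A", "c3": "B"})
        with pytest.raises(ValueError, match="fewer than 2"):
            rv.build_reference(m)


class TestMatchGenes:
    def make_ref(self, genes):
        sig = pd.DataFrame(
            np.ones((len(genes), 2)), index=genes, columns=["A", "B"]
        )
        return rv.ReferenceMatrix(sig)

    def test_identity_full_intersection(self):
        genes = [f"g{i}" for i in range(60)]
        ref = self.make_ref(genes)
        bulk = sc_matrix(np.ones((60, 2)), {"s1": "x", "s2": "x"})
        aref, abulk = rv.match_genes(ref, bulk)
        assert aref.gene_ids == abulk.gene_ids == genes

    def test_disjoint_universes_rejected(self):
        ref = self.make_ref([f"m{i}" for i in range(60)])
        bulk = sc_matrix(np.ones((60, 2)), {"s1": "x", "s2": "x"})
        with pytest.raises(ValueError, match="shared"):
            rv.match_genes(ref, bulk)

    def test_partial_ortholog_map_keeps_exactly_mapped(self):
        ref = self.make_ref([f"m{i}" for i in range(60)])
        bulk = sc_matrix(np.ones((60, 2)), {"s1": "x", "s2": "x"})
        omap = OrthologMap({f"m{i}": f"g{i}" for i in range(55)})
        aref, abulk = rv.match_genes(ref, bulk, omap)
        assert aref.gene_ids == [f"g{i}" for i in range(55)]
        assert abulk.n_genes == 55


class TestRidge:
    def test_identity_design_closed_form(self):
        beta = rv.ridge_fit(np.array([1.0, 0.0]), np.eye(2), lam=1.0, standardize=False)
        assert np.allclose(beta, [0.5, 0.0], atol=1e-12)

    def test_lambda_zero_matches_least_squares_oracle(self):
        rng = np.random.default_rng(25)
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.5, -2.0, 0.3]) + rng.normal(0, 0.1, 40)
        beta = rv.ridge_fit(y, X, lam=0.0, standardize=False)
        oracle = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(beta, oracle, atol=1e-8)

    def test_huge_lambda_shrinks_to_zero(self):
        rng = np.random.default_rng(26)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        beta = rv.ridge_fit(y, X, lam=1e8)
        assert np.all(np.abs(beta) < 1e-4)

    def test_monotone_shrinkage(self):
        rng = np.random.default_rng(27)
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        norms = [
            np.linalg.norm(rv.ridge_fit(y, X, lam) * X.std(axis=0))
            for lam in (0.0, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_matches_sklearn_ridge(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(28)
        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        lam = 2.5
        beta = rv.ridge_fit(y, X, lam, standardize=False)
        model = sklearn.Ridge(alpha=lam, fit_intercept=False).fit(X, y)
        assert np.allclose(beta, model.coef_, atol=1e-8)

    def test_collinear_columns_at_zero_lambda_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(np.linalg.LinAlgError):
            rv.ridge_fit(np.ones(10), X, lam=0.0, standardize=False)


class TestSelectLambda:
    def test_noiseless_mixture_prefers_grid_minimum(self):
        rng = np.random.default_rng(29)
        X = rng.lognormal(5, 1, size=(500, 3))  # CPM-like magnitudes
        y = X @ np.array([0.5, 0.3, 0.2])
        # ridge bias on the standardised problem is ~λ/n, so the smallest
        # grid point must sit well below n·1e-6 for exact recovery
        grid = [1e-5, 1e-1, 10.0]
        lam, table = rv.select_lambda(y, X, grid=grid, seed=30)
        assert lam == grid[0]
        beta = rv.ridge_fit(y, X, lam)
        assert np.max(np.abs(beta - [0.5, 0.3, 0.2])) < 1e-6

    def test_deterministic_under_seed_and_single_grid(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(50, 2))
        y = rng.normal(size=50)
        a, _ = rv.select_lambda(y, X, grid=[0.1, 1.0], seed=5)
        b, _ = rv.select_lambda(y, X, grid=[0.1, 1.0], seed=5)
        assert a == b
        only, _ = rv.select_lambda(y, X, grid=[0.7], seed=5)
        assert only == 0.7

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            rv.select_lambda(np.ones(5), np.ones((5, 1)), grid=[])


class TestProportions:
    @pytest.mark.parametrize(
        "beta,expected",
        [([2.0, -1.0, 2.0], [0.5, 0.0, 0.5]), ([1.0, 0.0, 3.0], [0.25, 0.0, 0.75])],
    )
    def test_negative_zeroing_and_renormalisation(self, beta, expected):
        props, defined = rv.to_proportions(np.array(beta))
        assert defined
        assert np.allclose(props, expected)

    def test_all_nonpositive_flagged_undefined(self):
        props, defined = rv.to_proportions(np.array([-1.0, -2.0]))
        assert not defined
        assert np.isnan(props).all()


@pytest.fixture(scope="module")
def reference():
    sc, profiles = rv.simulate_reference(K=4, G=1500, cells_per_type=40, seed=32)
    return rv.build_reference(sc), profiles


class TestDeconvolveCohort:
    def test_single_type_bulk_assigns_that_type(self, reference):
        ref, profiles = reference
        bulk, _ = rv.simulate_bulk(
            profiles, {"g": [0.0, 1.0, 0.0, 0.0]}, 3, 400_000, 0.0, seed=33
        )
        res = rv.deconvolve_cohort(bulk, ref, lam=1e-3)
        top = res.set_index("cell_type")["proportion"]
        assert top["type1"] > 0.95

    def test_proportions_invariant_under_library_scaling(self, reference):
        ref, profiles = reference
        bulk, _ = rv.simulate_bulk(
            profiles, {"g": [0.4, 0.3, 0.2, 0.1]}, 2, 200_000, 0.0, seed=34
        )
        scaled = CountsMatrix(bulk.counts * 10, dict(bulk.groups))
        a = rv.deconvolve_cohort(bulk, ref, lam=0.01)["proportion"]
        b = rv.deconvolve_cohort(scaled, ref, lam=0.01)["proportion"]
        assert np.allclose(a, b, atol=1e-6)

    def test_per_sample_mode_reports_group_mean(self, reference):
        ref, profiles = reference
        bulk, _ = rv.simulate_bulk(
            profiles, {"g": [0.25, 0.25, 0.25, 0.25]}, 3, 200_000, 0.05, seed=35
        )
        res = rv.deconvolve_cohort(bulk, ref, lam=0.1, mode="per-sample")
        mean_rows = res[res["sample"] == "<group mean>"]
        assert len(mean_rows) == 4
        assert mean_rows["proportion"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_unknown_mode_rejected(self, reference):
        ref, _ = reference
        with pytest.raises(ValueError, match="mode"):
            rv.deconvolve_cohort(None, ref, mode="bogus")


class TestCPM:
    def test_columns_sum_to_scale(self):
        df = pd.DataFrame({"a": [1, 3], "b": [2, 2]})
        out = cpm(df)
        assert np.allclose(out.sum(axis=0), 1e6)
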