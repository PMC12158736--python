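import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import reversig as rv
from reversig.formats import CountsMatrix

from conftest import make_two_group_counts

GROUPS2 = {"s1": "control", "s2": "disease"}


def cm(values, groups=None, genes=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = list(groups or GROUPS2)
    return CountsMatrix(pd.DataFrame(values, index=genes, columns=samples), dict(groups or GROUPS2))


class TestFilterUnexpressed:
    def test_zero_row_removed_order_preserved(self):
        out = rv.filter_unexpressed(cm([[1, 2], [0, 0], [3, 0]]))
        assert out.gene_ids == ["g0", "g2"]

    def test_no_zero_rows_unchanged(self):
        m = cm([[1, 2], [3, 4]])
        assert rv.filter_unexpressed(m).counts.equals(m.counts)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="no expressed genes"):
            rv.filter_unexpressed(cm([[0, 0]]))


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        sf = rv.estimate_size_factors(cm([[5, 5], [9, 9]]))
        assert np.allclose(sf, [1.0, 1.0])

    def test_median_of_ratios_hand_example(self):
        """[[1,2],[2,4],[3,6]]: every ratio to the geometric mean is 1/√2, √2."""
        sf = rv.estimate_size_factors(cm([[1, 2], [2, 4], [3, 6]]))
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_scale_equivariance(self):
        base = make_two_group_counts(0, G=200, n=3)
        doubled = CountsMatrix(
            base.counts.assign(**{base.sample_ids[0]: base.counts.iloc[:, 0] * 2}),
            dict(base.groups),
        )
        sf0 = rv.estimate_size_factors(base)
        sf1 = rv.estimate_size_factors(doubled)
        # factors are defined up to a common rescaling, so compare ratios
        assert sf1.iloc[0] / sf1.iloc[1] == pytest.approx(
            2 * sf0.iloc[0] / sf0.iloc[1], rel=1e-9
        )

    def test_gene_reordering_invariance(self):
        base = make_two_group_counts(1, G=100, n=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(base.n_genes)
        shuffled = CountsMatrix(base.counts.iloc[perm], dict(base.groups))
        assert np.allclose(rv.estimate_size_factors(base), rv.estimate_size_factors(shuffled))

    def test_no_common_gene_needs_pseudo_reference(self):
        m = cm([[0, 2], [3, 0]])
        with pytest.raises(ValueError, match="pseudo_reference"):
            rv.estimate_size_factors(m)
        sf = rv.estimate_size_factors(m, pseudo_reference=True)
        assert (sf > 0).all()


class TestDispersions:
    def test_poisson_counts_give_small_estimates(self):
        m = make_two_group_counts(2, G=800, n=20, dispersion=0.0)
        sf = rv.estimate_size_factors(m)
        disp = rv.estimate_dispersions(m, sf, ["disease", "control"])
        assert disp.median() < 0.05

    def test_planted_dispersion_recovered(self):
        m = make_two_group_counts(3, G=800, n=50, dispersion=0.5, mean=100)
        sf = rv.estimate_size_factors(m)
        disp = rv.estimate_dispersions(m, sf, ["disease", "control"])
        assert 0.35 < disp.median() < 0.65

    def test_constant_matrix_hits_floor(self):
        m = cm(np.full((5, 4), 7), groups={f"s{i}": ("a" if i < 2 else "b") for i in range(4)})
        sf = pd.Series(1.0, index=m.sample_ids)
        disp = rv.estimate_dispersions(m, sf, ["a", "b"])
        assert (disp == 1e-8).all()

    def test_single_sample_group_rejected(self):
        m = cm([[1, 2], [3, 4]])
        sf = rv.estimate_size_factors(m)
        with pytest.raises(ValueError, match="fewer than 2"):
            rv.estimate_dispersions(m, sf, ["control", "disease"])


class TestNBWald:
    def test_poisson_limit_matches_closed_form_glm(self):
        """At α→0 the NB GLM equals the Poisson GLM, whose two-group MLE is
        log of the ratio of offset-weighted group means."""
        m = make_two_group_counts(4, G=20, n=6, dispersion=0.0, mean=200,
                                  lfc_idx=np.arange(10), lfc=1.0)
        sf = rv.estimate_size_factors(m)
        disp = pd.Series(1e-8, index=m.gene_ids)
        table = rv.fit_nb_wald(m, sf, disp, ("disease", "control"))
        lab = np.array([m.groups[s] for s in m.sample_ids])
        s = sf.to_numpy()
        y = m.counts.to_numpy(dtype=float)
        oracle = np.log2(
            (y[:, lab == "disease"].sum(1) / s[lab == "disease"].sum())
            / (y[:, lab == "control"].sum(1) / s[lab == "control"].sum())
        )
        oracle = pd.Series(oracle, index=m.gene_ids).loc[table.index]
        assert np.allclose(table["log2fc"], oracle, atol=1e-3)

    def test_planted_lfc_recovered(self):
        idx = np.arange(50)
        m = make_two_group_counts(5, G=500, n=10, dispersion=0.1, mean=100,
                                  lfc_idx=idx, lfc=2.0)
        sf = rv.estimate_size_factors(m)
        disp = rv.estimate_dispersions(m, sf, ["disease", "control"])
        table = rv.fit_nb_wald(m, sf, disp, ("disease", "control"))
        planted = table.iloc[idx]["log2fc"]
        assert 1.8 < planted.median() < 2.2

    def test_padj_never_below_pvalue_and_monotone(self):
        m = make_two_group_counts(6, G=300, n=5)
        sf = rv.estimate_size_factors(m)
        disp = rv.estimate_dispersions(m, sf, ["disease", "control"])
        table = rv.fit_nb_wald(m, sf, disp, ("disease", "control"))
        assert (table["padj"] >= table["pvalue"] - 1e-12).all()
        ordered = table.sort_values("pvalue")
        assert (np.diff(ordered["padj"]) >= -1e-12).all()

    def test_missing_contrast_group_rejected(self):
        m = make_two_group_counts(7, G=20, n=3)
        sf = rv.estimate_size_factors(m)
        disp = pd.Series(0.1, index=m.gene_ids)
        with pytest.raises(ValueError):
            rv.fit_nb_wald(m, sf, disp, ("treated", "control"))


class TestBH:
    def test_step_up_hand_example(self):
        assert np.allclose(rv.adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_edge_cases(self):
        assert rv.adjust_bh(np.array([0.2])) == pytest.approx([0.2])
        assert np.allclose(rv.adjust_bh(np.ones(5)), 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, pvals):
        """BH equals sort → p·m/rank → cumulative min from the tail → unsort."""
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        scaled = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        assert np.allclose(rv.adjust_bh(p), expected, atol=1e-12)


class TestCallDegs:
    @pytest.mark.parametrize(
        "log2fc,padj,where",
        [(1.5, 0.01, "up"), (0.8, 0.001, None), (-2.0, 0.2, None), (-1.2, 0.04, "down"),
         (1.0, 0.01, None)],  # strict inequality at the threshold
    )
    def test_threshold_logic(self, log2fc, padj, where):
        table = pd.DataFrame({"log2fc": [log2fc], "padj": [padj]}, index=["g"])
        degs = rv.call_degs(table)
        member = "g" in degs.up and "up" or ("g" in degs.down and "down" or None)
        assert member == where

    def test_sets_disjoint_and_reproducible(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, 200), "padj": rng.uniform(0, 1, 200)},
            index=[f"g{i}" for i in range(200)],
        )
        a = rv.call_degs(table)
        b = rv.call_degs(table)
        assert not (a.up & a.down)
        assert a.up == b.up and a.down == b.down


class TestVST:
    def test_rows_standardised_and_constant_rows_zero(self):
        m = cm([[10, 20], [5, 5]])
        sf = pd.Series(1.0, index=m.sample_ids)
        scaled = rv.vst_scale(m, sf)
        assert np.allclose(scaled.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(scaled.loc["g1"], 0.0)
        assert np.allclose(scaled.loc["g0"].std(ddof=0), 1.0)

    def test_monotone_within_sample(self):
        m = cm([[1, 9], [5, 2], [40, 3]])
        sf = pd.Series([1.0, 2.0], index=m.sample_ids)
        scaled = rv.vst_scale(m, sf)
        col = m.counts.iloc[:, 0] / sf.iloc[0]
        assert (scaled.iloc[:, 0].to_numpy()[np.argsort(col)] == np.sort(scaled.iloc[:, 0])).all()


class TestDDCT:
    @pytest.mark.parametrize(
        "cts,expected",
        [((20, 18, 20, 18), 1.0), ((20, 18, 21, 18), 2.0), ((20, 18, 22, 18), 4.0)],
    )
    def test_fold_change_arithmetic(self, cts, expected):
        assert rv.ddct_fold_change(*cts) == pytest.approx(expected)
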