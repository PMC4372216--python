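"""Probe collapsing, KNN imputation, and alteration discretization."""

import numpy as np
import pandas as pd
import pytest

from ican.omics import (
    OmicsProfiles,
    collapse_probes,
    discretize,
    knn_impute,
)


def make_profiles(expr, cn, meth, calls=None, genes=None, samples=None):
    expr = np.asarray(expr, dtype=float)
    genes = genes or [f"g{i}" for i in range(expr.shape[0])]
    samples = samples or [f"s{j}" for j in range(expr.shape[1])]
    return OmicsProfiles(
        genes=genes,
        samples=samples,
        expression=expr,
        copy_number=np.asarray(cn, dtype=float),
        methylation=np.asarray(meth, dtype=float),
        cn_calls=None if calls is None else np.asarray(calls),
    )


class TestCollapseProbes:
    def test_mean_of_two_probes(self):
        m = pd.DataFrame({"s1": [0.2, 0.4]}, index=["p1", "p2"])
        out = collapse_probes(m, {"p1": "TP53", "p2": "TP53"})
        assert out.loc["TP53", "s1"] == pytest.approx(0.3)

    def test_single_probe_identity(self):
        m = pd.DataFrame({"s1": [0.7]}, index=["p1"])
        out = collapse_probes(m, {"p1": "BRCA1"})
        assert out.loc["BRCA1", "s1"] == 0.7

    def test_unmapped_and_all_missing_probes_dropped(self):
        m = pd.DataFrame(
            {"s1": [0.2, np.nan, 0.9]}, index=["p1", "p2", "p3"]
        )
        out = collapse_probes(m, {"p1": "A", "p2": "A"})  # p3 unmapped
        assert list(out.index) == ["A"]
        assert out.loc["A", "s1"] == pytest.approx(0.2)

    def test_random_map_matches_groupby_oracle(self, rng):
        probes = [f"p{i}" for i in range(50)]
        m = pd.DataFrame(
            rng.random((50, 8)), index=probes,
            columns=[f"s{j}" for j in range(8)],
        )
        mapping = {p: f"g{rng.integers(10)}" for p in probes}
        out = collapse_probes(m, mapping)
        # loop oracle
        for gene in out.index:
            members = [p for p in probes if mapping[p] == gene]
            expected = m.loc[members].mean(axis=0)
            assert np.allclose(out.loc[gene], expected)


class TestKnnImpute:
    def test_complete_matrix_unchanged(self, rng):
        x = rng.random((10, 5))
        assert np.array_equal(knn_impute(x, k=3), x)

    def test_single_nearest_neighbor_value(self):
        x = np.array(
            [
                [1.0, 2.0, 3.0],
                [10.0, 10.0, 10.0],
                [1.1, 2.1, np.nan],
            ]
        )
        out = knn_impute(x, k=1, min_overlap=2)
        assert out[2, 2] == pytest.approx(3.0)  # row0 is the nearest

    def test_observed_entries_untouched_all_finite(self, rng):
        x = rng.random((100, 20))
        mask = rng.random((100, 20)) < 0.05
        xm = x.copy()
        xm[mask] = np.nan
        # guard: keep at least one observed per row
        xm[np.isnan(xm).all(axis=1), 0] = 0.5
        out = knn_impute(xm, k=5)
        assert np.isfinite(out).all()
        obs = ~np.isnan(xm)
        assert np.array_equal(out[obs], xm[obs])

    def test_k_equals_all_others_on_equidistant_fixture(self):
        # three rows pairwise equidistant over observed columns
        x = np.array(
            [
                [0.0, 1.0, 4.0],
                [1.0, 0.0, 6.0],
                [0.0, 0.0, np.nan],
            ]
        )
        # distances row2->row0 and row2->row1 are both 1 over shared cols
        out = knn_impute(x, k=2, min_overlap=2)
        assert out[2, 2] == pytest.approx((4.0 + 6.0) / 2)

    def test_entirely_missing_errors(self):
        with pytest.raises(ValueError):
            knn_impute(np.full((3, 3), np.nan), k=1)


class TestDiscretize:
    def test_beta_thresholds(self):
        prof = make_profiles(
            expr=[[1, 1, 1, 2]],
            cn=[[0, 0, 0, 0]],
            meth=[[0.1, 0.85, 0.2, 0.8]],
            calls=[[0, 0, 0, 0]],
        )
        calls = discretize(prof)
        assert calls.feature("hypomethylated")[0].tolist() == [True, False, False, False]
        assert calls.feature("hypermethylated")[0].tolist() == [False, True, False, False]

    def test_cn_call_mapping(self):
        prof = make_profiles(
            expr=[[1, 2, 3, 4, 5]],
            cn=[[0] * 5],
            meth=[[0.5] * 5],
            calls=[[-2, -1, 0, 1, 2]],
        )
        calls = discretize(prof)
        assert calls.feature("homdel")[0].tolist() == [True, False, False, False, False]
        assert calls.feature("amplified")[0].tolist() == [False, False, False, True, True]

    def test_expression_boundary_is_strict(self):
        # stats come from the tumor subset; the remaining entries sit exactly
        # at mean +/- SD and just beyond it
        tumor = [0.0, 0.0, 2.0, 2.0]
        mu = np.mean(tumor)
        sd = np.std(tumor, ddof=1)
        row = tumor + [mu + sd, mu - sd, mu + sd + 0.01, mu - sd - 0.01]
        n = len(row)
        prof = make_profiles(
            expr=[row], cn=[[0] * n], meth=[[0.5] * n], calls=[[0] * n]
        )
        calls = discretize(prof, tumor_samples=prof.samples[:4])
        over = calls.feature("overexpressed")[0]
        under = calls.feature("underexpressed")[0]
        assert not over[4] and not under[5]  # exactly at the boundary: unaltered
        assert over[6] and under[7]  # strictly beyond: called

    def test_zero_variance_gene_gets_no_expression_calls(self):
        prof = make_profiles(
            expr=[[5, 5, 5, 5]], cn=[[0] * 4], meth=[[0.5] * 4], calls=[[0] * 4]
        )
        calls = discretize(prof)
        assert not calls.feature("overexpressed").any()
        assert not calls.feature("underexpressed").any()

    def test_sample_order_invariance_and_exclusivity(self, rng):
        n_g, n_s = 20, 30
        expr = rng.normal(size=(n_g, n_s))
        meth = rng.random((n_g, n_s))
        calls_mat = rng.integers(-2, 3, size=(n_g, n_s))
        prof = make_profiles(expr, np.zeros((n_g, n_s)), meth, calls_mat)
        calls = discretize(prof)
        # exclusivity invariants
        assert not (
            calls.feature("hypomethylated") & calls.feature("hypermethylated")
        ).any()
        assert not (
            calls.feature("overexpressed") & calls.feature("underexpressed")
        ).any()
        # permute samples: per-entry calls must follow the permutation
        perm = rng.permutation(n_s)
        prof_p = make_profiles(
            expr[:, perm], np.zeros((n_g, n_s)), meth[:, perm], calls_mat[:, perm],
            samples=[f"s{j}" for j in perm],
        )
        calls_p = discretize(prof_p)
        for name in calls.features:
            assert np.array_equal(calls.feature(name)[:, perm], calls_p.feature(name))

    def test_brute_force_per_entry_check(self, rng):
        n_g, n_s = 10, 15
        expr = rng.normal(size=(n_g, n_s))
        meth = rng.random((n_g, n_s))
        cmat = rng.integers(-2, 3, size=(n_g, n_s))
        prof = make_profiles(expr, np.zeros((n_g, n_s)), meth, cmat)
        calls = discretize(prof)
        for g in range(n_g):
            mu = expr[g].mean()
            sd = expr[g].std(ddof=1)
            for s in range(n_s):
                assert calls.feature("overexpressed")[g, s] == (expr[g, s] > mu + sd)
                assert calls.feature("underexpressed")[g, s] == (expr[g, s] < mu - sd)
                assert calls.feature("hypomethylated")[g, s] == (meth[g, s] < 0.2)
                assert calls.feature("amplified")[g, s] == (cmat[g, s] in (1, 2))


class TestOmicsProfilesInvariants:
    def test_beta_range_enforced(self):
        with pytest.raises(ValueError, match="beta"):
            make_profiles([[1.0]] * 1, [[0.0]], [[1.5]])

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            make_profiles([[np.nan]], [[0.0]], [[0.5]])

    def test_layer_accessor_and_unknown_layer(self):
        prof = make_profiles([[1.0, 2.0]], [[0.0, 0.1]], [[0.5, 0.6]])
        assert prof.layer("copy_number")[0, 1] == pytest.approx(0.1)
        with pytest.raises(ValueError, match="unknown layer"):
            prof.layer("proteome")

    def test_roundtrip_dir(self, tmp_path, rng):
        prof = make_profiles(
            rng.normal(size=(4, 3)), rng.normal(size=(4, 3)), rng.random((4, 3)),
            calls=rng.integers(-2, 3, size=(4, 3)),
        )
        prof.to_dir(tmp_path / "bundle")
        back = OmicsProfiles.from_dir(tmp_path / "bundle")
        assert back.genes == prof.genes and back.samples == prof.samples
        assert np.allclose(back.expression, prof.expression)
        assert np.array_equal(back.cn_calls, prof.cn_calls)
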