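import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

import mutcell as mc
from mutcell.association import binarize, zscore_rows
from mutcell.errors import ValidationError
from mutcell.mutation import MutationMatrix


def fisher_enumeration_oracle(a, b, c, d):
    """Exhaustive margin-fixed two-sided p: sum of hypergeometric
    probabilities no larger than the observed one (with relative slack)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, c1, r1)
    obs = hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= obs * (1 + 1e-7)].sum())


class TestZscoreRows:
    def test_hand_row(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]], index=["c"])
        z = zscore_rows(df)
        np.testing.assert_allclose(
            z.loc["c"], [-1.2649, -0.6325, 0.0, 0.6325, 1.2649], atol=1e-4
        )

    def test_constant_row_zeroed_and_flagged(self):
        df = pd.DataFrame([[7.0, 7.0, 7.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        z = zscore_rows(df)
        assert (z.loc["flat"] == 0).all()
        assert z.attrs["constant_rows"] == ["flat"]

    def test_rows_standardized(self, rng):
        df = pd.DataFrame(rng.standard_normal((5, 30)))
        z = zscore_rows(df)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)


class TestBinarize:
    def test_outlier_ten_in_zeros(self):
        # z of the lone 10 is 9/sqrt(10) = 2.846 > 2
        df = pd.DataFrame([[0.0] * 9 + [10.0]], index=["c"])
        out = binarize(zscore_rows(df))
        assert out.up.loc["c"].sum() == 1
        assert out.up.loc["c"].iloc[-1] == 1
        assert out.down.loc["c"].sum() == 0

    def test_boundary_strict_up_inclusive_down(self):
        z = pd.DataFrame([[2.0, -2.0, 1.9, -1.9]], index=["c"])
        out = binarize(z)
        assert list(out.up.loc["c"]) == [0, 0, 0, 0]  # strict >
        assert list(out.down.loc["c"]) == [0, 1, 0, 0]  # inclusive <=

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=12))
    def test_negating_z_swaps_up_and_down_and_matrices_disjoint(self, row):
        z = pd.DataFrame([row], index=["c"])
        fwd = binarize(z)
        rev = binarize(-z)
        # strict/inclusive boundary: negation maps z > 2 onto -z <= -2
        assert (fwd.up.to_numpy() <= rev.down.to_numpy()).all()
        assert not (fwd.up.to_numpy() & fwd.down.to_numpy()).any()


class TestFisherExact:
    def test_perfect_independence(self):
        odds, p = mc.fisher_exact_2x2([[5, 5], [5, 5]])
        assert odds == 1.0
        assert p == 1.0

    def test_matches_enumeration_oracle_spot(self):
        odds, p = mc.fisher_exact_2x2([[8, 2], [1, 9]])
        assert p == pytest.approx(fisher_enumeration_oracle(8, 2, 1, 9), abs=1e-12)
        assert odds == pytest.approx(36.0)

    def test_degenerate_margin(self):
        odds, p = mc.fisher_exact_2x2([[0, 10], [0, 10]])
        assert p == 1.0
        assert np.isnan(odds)

    def test_infinite_odds_ratio(self):
        odds, _ = mc.fisher_exact_2x2([[5, 0], [0, 5]])
        assert odds == np.inf

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            mc.fisher_exact_2x2([[1, -1], [0, 2]])


class TestBhAdjust:
    def test_single_p_identity(self):
        np.testing.assert_array_equal(mc.bh_adjust([0.05]), [0.05])

    def test_hand_stepup(self):
        np.testing.assert_allclose(
            mc.bh_adjust([0.01, 0.04, 0.03, 0.005]), [0.02, 0.04, 0.04, 0.02], atol=1e-12
        )

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(mc.bh_adjust([0.3] * 7), [0.3] * 7, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            mc.bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms(use_true_random=False))
    def test_permutation_equivariance_and_max_bound(self, ps, rnd):
        ps = np.asarray(ps)
        perm = np.array(rnd.sample(range(len(ps)), len(ps)))
        direct = mc.bh_adjust(ps)[perm]
        permuted = mc.bh_adjust(ps[perm])
        np.testing.assert_allclose(direct, permuted, atol=1e-12)
        assert mc.bh_adjust(ps).max() >= ps.max() - 1e-12  # q(m) = p(m) for the largest p


class TestAssociate:
    def test_planted_pair_recovered(self, planted_cohort):
        res = mc.associate(planted_cohort.abundance, planted_cohort.mutations,
                           n_perm=500, seed=3)
        pairs = {
            (g, row["cell"], row["direction"])
            for g, r in res.items()
            for _, row in r.driven.iterrows()
        }
        assert planted_cohort.truth.planted_pairs <= pairs

    def test_equivariant_under_joint_relabeling(self, planted_cohort, rng):
        ab, mut = planted_cohort.abundance, planted_cohort.mutations
        perm = rng.permutation(ab.shape[1])
        ab2 = ab.iloc[:, perm]
        mut2 = MutationMatrix(data=mut.data.iloc[:, perm])
        a = mc.associate(ab, mut, n_perm=300, seed=3)
        b = mc.associate(ab2, mut2, n_perm=300, seed=3)
        for gene in a:
            pd.testing.assert_frame_equal(a[gene].table, b[gene].table)

    def test_no_shared_samples_rejected(self, planted_cohort):
        ab = planted_cohort.abundance.rename(columns=lambda s: "X" + s)
        with pytest.raises(ValidationError, match="shared samples"):
            mc.associate(ab, planted_cohort.mutations, n_perm=300, seed=0)

    def test_gene_without_sam_hits_yields_empty_result(self, rng):
        ab = pd.DataFrame(rng.standard_normal((5, 60)),
                          index=[f"C{i}" for i in range(5)],
                          columns=[f"S{i}" for i in range(60)])
        mut = MutationMatrix(data=pd.DataFrame(
            [(rng.random(60) < 0.3).astype(int)], index=["G1"], columns=ab.columns))
        res = mc.associate(ab, mut, n_perm=300, seed=1)
        assert res["G1"].table.empty
        assert res["G1"].driven_cells == []

    def test_low_frequency_gene_skipped_with_warning(self, rng):
        ab = pd.DataFrame(rng.standard_normal((5, 60)),
                          index=[f"C{i}" for i in range(5)],
                          columns=[f"S{i}" for i in range(60)])
        vec = np.zeros(60, dtype=int)
        vec[0] = 1
        mut = MutationMatrix(data=pd.DataFrame([vec], index=["G1"], columns=ab.columns))
        with pytest.warns(UserWarning, match="skipped"):
            res = mc.associate(ab, mut, n_perm=300, seed=1)
        assert res["G1"].note.startswith("skipped")

    def test_global_fdr_is_valid_bh_of_pooled_pvalues(self, planted_cohort):
        res = mc.associate(planted_cohort.abundance, planted_cohort.mutations,
                           n_perm=300, seed=3, global_fdr=True)
        ps, qs = [], []
        for r in res.values():
            ps.extend(r.table["p"])
            qs.extend(r.table["fdr"])
        np.testing.assert_allclose(np.sort(qs), np.sort(mc.bh_adjust(ps)), atol=1e-12)


class TestCoocMutex:
    def _matrix(self, rows, genes):
        n = len(rows[0])
        return MutationMatrix(data=pd.DataFrame(
            rows, index=genes, columns=[f"S{i}" for i in range(n)]))

    def test_self_copy_cooccurring(self, rng):
        vec = (rng.random(100) < 0.4).astype(int)
        mut = self._matrix([vec, vec.copy()], ["A", "A_copy"])
        out = mc.cooc_mutex(mut)
        row = out.iloc[0]
        assert row["odds_ratio"] == np.inf
        assert row["label"] == "co-occurring"

    def test_disjoint_vectors_mutually_exclusive(self):
        a = np.array([1] * 30 + [0] * 70)
        b = np.array([0] * 30 + [1] * 30 + [0] * 40)
        mut = self._matrix([a, b], ["A", "B"])
        row = mc.cooc_mutex(mut).iloc[0]
        assert row["odds_ratio"] == 0.0
        assert row["label"] == "mutually exclusive"

    def test_null_pairs_rarely_labeled(self, rng):
        rows = (rng.random((8, 300)) < 0.3).astype(int)
        mut = self._matrix(list(rows), [f"G{i}" for i in range(8)])
        out = mc.cooc_mutex(mut, alpha=0.05)
        assert len(out) == 28
        assert (out["label"] != "none").mean() <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 28)

    def test_single_gene_rejected(self, rng):
        mut = self._matrix([(rng.random(30) < 0.5).astype(int)], ["A"])
        with pytest.raises(ValidationError):
            mc.cooc_mutex(mut)
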