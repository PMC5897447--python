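"""Rank matrices, paired rank products with pfp, and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

import serumgp as sg


class TestIntensityRanks:
    def test_descending_ranks(self):
        m = pd.DataFrame({"S1": [10.0, 5.0, 1.0]}, index=list("abc"))
        out = sg.intensity_ranks(m)
        np.testing.assert_allclose(out["S1"], [1, 2, 3])

    def test_tie_averaging(self):
        m = pd.DataFrame({"S1": [10.0, 10.0, 1.0]}, index=list("abc"))
        np.testing.assert_allclose(sg.intensity_ranks(m)["S1"],
                                   [1.5, 1.5, 3])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.uniform(1, 1e6, (20, 4)))
        pd.testing.assert_frame_equal(sg.intensity_ranks(m),
                                      sg.intensity_ranks(np.log2(m)))

    def test_missing_stays_missing(self):
        m = pd.DataFrame({"S1": [3.0, np.nan, 1.0]}, index=list("abc"))
        out = sg.intensity_ranks(m)
        assert np.isnan(out.loc["b", "S1"])
        np.testing.assert_allclose(out.loc[["a", "c"], "S1"], [1, 2])


def _paired_matrices(rng, m, k, offset=None):
    cols = [f"C{i}" for i in range(k)]
    idx = [f"P{i}" for i in range(m)]
    cord = pd.DataFrame(rng.standard_normal((m, k)), index=idx, columns=cols)
    fu = pd.DataFrame(rng.standard_normal((m, k)), index=idx, columns=cols)
    if offset is not None:
        cord.iloc[0] += offset
    return cord, fu


class TestRankProduct:
    def test_consistent_top_protein_gets_minimum_rp(self):
        rng = np.random.default_rng(1)
        cord, fu = _paired_matrices(rng, 4, 2, offset=50.0)
        res = sg.rank_product_test(cord, fu, exact=True)
        # protein P0 leads both pairs: normalized RP = (1/m) exactly
        assert res.table.loc["P0", "rp_up"] == pytest.approx(1 / 4)
        assert res.table["rp_up"].min() == res.table.loc["P0", "rp_up"]

    @pytest.mark.parametrize("m,k,seed", [(3, 2, 0), (4, 2, 1), (4, 1, 2)])
    def test_permutation_pfp_matches_exact_enumeration(self, m, k, seed):
        """B = 10,000 permutations reproduce the exhaustive null."""
        rng = np.random.default_rng(seed)
        cord, fu = _paired_matrices(rng, m, k)
        exact = sg.rank_product_test(cord, fu, exact=True)
        perm = sg.rank_product_test(cord, fu, exact=False, B=10_000,
                                    seed=123)
        for col in ("pfp_up", "pfp_down"):
            # Monte-Carlo tolerance: 4 binomial sds of the expected-FP
            # count at B = 10,000, propagated through the pfp ratio
            for prot in exact.table.index:
                e = exact.table.loc[prot, col]
                p = perm.table.loc[prot, col]
                r = np.searchsorted(
                    np.sort(exact.table[col.replace("pfp", "rp")]),
                    exact.table.loc[prot, col.replace("pfp", "rp")],
                    side="right")
                count = e * r  # expected false positives at this protein
                mc_sd = 4 * np.sqrt(max(count * m, 1) / 10_000) / r
                assert p == pytest.approx(e, abs=max(mc_sd, 0.02))

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        cord, fu = _paired_matrices(rng, 6, 2)
        res = sg.rank_product_test(cord, fu, exact=True)
        order = ["P3", "P0", "P5", "P1", "P4", "P2"]
        res2 = sg.rank_product_test(cord.loc[order], fu.loc[order],
                                    exact=True)
        pd.testing.assert_frame_equal(res.table.loc[order], res2.table)

    def test_unpaired_subject_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        cord, fu = _paired_matrices(rng, 5, 3)
        with pytest.warns(UserWarning, match="unpaired"):
            res = sg.rank_product_test(cord, fu, pairs=["C0", "C1", "XX"],
                                       exact=True)
        assert res.n_pairs == 2

    def test_low_permutation_count_warns(self):
        rng = np.random.default_rng(5)
        cord, fu = _paired_matrices(rng, 30, 3)
        with pytest.warns(UserWarning, match="low"):
            sg.rank_product_test(cord, fu, B=100, exact=False)

    def test_null_call_rate_controlled(self):
        """Exchangeable null: mean pfp<0.05 call rate stays near nominal."""
        rates = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            cord, fu = _paired_matrices(rng, 40, 5)
            res = sg.rank_product_test(cord, fu, B=1000, seed=seed,
                                       exact=False)
            rates.append(res.table["significant"].mean())
        assert np.mean(rates) <= 0.07

    def test_pfp_monotone_in_rp_order(self):
        rng = np.random.default_rng(6)
        cord, fu = _paired_matrices(rng, 12, 4, offset=5.0)
        res = sg.rank_product_test(cord, fu, B=2000, seed=0, exact=False)
        t = res.table.sort_values("rp_up")
        assert (np.diff(t["pfp_up"]) >= -1e-12).all()


class TestSpearmanCorrelation:
    def _cord_fu(self, cord_vals, fu_vals):
        subjects = [f"C{i}" for i in range(len(cord_vals))]
        cord = pd.DataFrame([cord_vals], index=["P1"], columns=subjects)
        fu = pd.DataFrame([fu_vals], index=["P1"], columns=subjects)
        return cord, {"3m": fu}

    def test_perfect_monotone_gives_rho_one(self):
        cord, fu = self._cord_fu([1, 2, 3, 4, 5, 6],
                                 [10, 20, 25, 30, 42, 50])
        res = sg.cord_followup_correlation(cord, fu)
        assert res.table.iloc[0]["rho"] == pytest.approx(1.0)

    def test_reversed_gives_rho_minus_one(self):
        cord, fu = self._cord_fu([6, 5, 4, 3, 2, 1],
                                 [10, 20, 25, 30, 42, 50])
        res = sg.cord_followup_correlation(cord, fu)
        assert res.table.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_matches_rank_covariance_definition(self):
        rng = np.random.default_rng(7)
        a, b = rng.standard_normal(5), rng.standard_normal(5)
        cord, fu = self._cord_fu(a, b)
        res = sg.cord_followup_correlation(cord, fu)
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        oracle = (np.cov(ra, rb)[0, 1]
                  / np.sqrt(np.var(ra, ddof=1) * np.var(rb, ddof=1)))
        assert res.table.iloc[0]["rho"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_reported_missing(self):
        cord, fu = self._cord_fu([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        res = sg.cord_followup_correlation(cord, fu)
        assert np.isnan(res.table.iloc[0]["rho"])

    def test_too_few_subjects_not_tested(self):
        cord, fu = self._cord_fu([1, 2, 3, 4], [1, 2, 3, 4])
        res = sg.cord_followup_correlation(cord, fu)
        assert len(res.table) == 0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        a, b = rng.uniform(1, 10, 8), rng.uniform(1, 10, 8)
        r1 = sg.cord_followup_correlation(
            *self._cord_fu(a, b)).table.iloc[0]["rho"]
        r2 = sg.cord_followup_correlation(
            *self._cord_fu(np.exp(a), b**3)).table.iloc[0]["rho"]
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(sg.bh_adjust([0.04]), [0.04])

    def test_step_up_arithmetic(self):
        q = sg.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(sg.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=25)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(sg.bh_adjust(p), expected, atol=1e-12)

    def test_missing_excluded_from_family(self):
        q = sg.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]],
                                   multipletests([0.01, 0.04],
                                                 method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sg.bh_adjust([0.5, 1.5])

    def test_tail_removal_never_increases_survivors(self):
        # dropping the largest p scales each step-up term by (m-1)/m,
        # so the surviving adjusted values can only shrink
        rng = np.random.default_rng(10)
        for _ in range(20):
            p = np.sort(rng.uniform(size=12))
            q_full = sg.bh_adjust(p)
            q_trim = sg.bh_adjust(p[:-1])
            assert (q_trim <= q_full[:-1] + 1e-12).all()

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=30)
        q = sg.bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
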