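import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mooneyrsa import stats_core
from mooneyrsa.rdm_core import fisher_z


class TestPairedT:
    def test_hand_computed_example(self):
        # differences {1,2,3}: mean 2, sd 1 -> t = 2/(1/sqrt(3)), d = 2
        res = stats_core.paired_t([2, 4, 6], [1, 2, 3])
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-6)
        assert res.effect_size == pytest.approx(2.0, abs=1e-12)
        assert res.df == (1, 2)

    def test_zero_variance_differences_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            stats_core.paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_cohens_d_equals_mean_over_sd(self, rng):
        x = rng.normal(size=12)
        res = stats_core.one_sample_t(x)
        assert res.effect_size == pytest.approx(x.mean() / x.std(ddof=1), abs=1e-12)
        assert res.effect_size == pytest.approx(
            stats_core.cohens_d_from_t(res.statistic, len(x)), abs=1e-12)


class TestWilcoxon:
    def test_exact_all_positive_n5(self):
        res = stats_core.wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.p == pytest.approx(2 / 32)

    def test_symmetric_null_p_one(self):
        res = stats_core.wilcoxon_signed_rank([-1, 1, -2, 2, -3, 3])
        assert res.p == pytest.approx(1.0, abs=0.05)

    def test_exact_matches_brute_force_enumeration(self, rng):
        # enumerate all 2^n sign assignments of the rank sums
        x = rng.normal(size=10)
        while np.unique(np.abs(x)).size < 10 or (x == 0).any():
            x = rng.normal(size=10)
        ranks = sps.rankdata(np.abs(x))
        w_obs = ranks[x > 0].sum()
        n = len(x)
        mu = n * (n + 1) / 4
        count = 0
        for signs in itertools.product([0, 1], repeat=n):
            w = ranks[np.array(signs, dtype=bool)].sum()
            if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
                count += 1
        expected = count / 2 ** n
        res = stats_core.wilcoxon_signed_rank(x)
        assert res.p == pytest.approx(expected, abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        for _ in range(5):
            x = rng.normal(size=20)
            exact = sps.wilcoxon(x, method="exact").pvalue
            res = sps.wilcoxon(x, method="approx", correction=True)
            assert res.pvalue == pytest.approx(exact, abs=1e-2)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError, match="zero"):
            stats_core.wilcoxon_signed_rank([0.0, 0.0, 0.0])


def _two_way_ss_oracle(wide):
    """From-scratch sums-of-squares for a two-way within design.

    ``wide``: array (n_subjects, a, b).  Returns dict of (F, df) per effect.
    """
    n, a, b = wide.shape
    grand = wide.mean()
    m_a = wide.mean(axis=(0, 2))
    m_b = wide.mean(axis=(0, 1))
    m_s = wide.mean(axis=(1, 2))
    m_ab = wide.mean(axis=0)
    m_sa = wide.mean(axis=2)
    m_sb = wide.mean(axis=1)
    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_sa = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_tot = ((wide - grand) ** 2).sum()
    ss_s = a * b * ((m_s - grand) ** 2).sum()
    ss_sab = ss_tot - ss_s - ss_a - ss_b - ss_ab - ss_sa - ss_sb
    out = {}
    for name, ss_eff, df_eff, ss_err, df_err in (
        ("A", ss_a, a - 1, ss_sa, (a - 1) * (n - 1)),
        ("B", ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
        ("A*B", ss_ab, (a - 1) * (b - 1), ss_sab, (a - 1) * (b - 1) * (n - 1)),
    ):
        F = (ss_eff / df_eff) / (ss_err / df_err)
        out[name] = (F, (df_eff, df_err), ss_eff / (ss_eff + ss_err))
    return out


class TestRmAnova:
    def test_constant_data_gives_zero_F(self):
        rows = [
            {"subject": s, "cond": c, "y": 3.0}
            for s in range(4) for c in "abc"
        ]
        res = stats_core.rm_anova(pd.DataFrame(rows), dv="y", within="cond",
                                  subject="subject")
        assert all(r.statistic == 0 and r.effect_size == 0 for r in res)

    def test_two_way_matches_ss_decomposition(self, rng):
        n, a, b = 5, 2, 3
        wide = rng.normal(size=(n, a, b)) + np.arange(a)[None, :, None]
        rows = [
            {"subject": s, "A": f"a{i}", "B": f"b{j}", "y": wide[s, i, j]}
            for s in range(n) for i in range(a) for j in range(b)
        ]
        res = stats_core.rm_anova(pd.DataFrame(rows), dv="y",
                                  within=["A", "B"], subject="subject")
        oracle = _two_way_ss_oracle(wide)
        by_label = {r.label.replace(" ", ""): r for r in res}
        for name, (F, df, eta) in oracle.items():
            got = by_label[name]
            assert got.statistic == pytest.approx(F, rel=1e-8)
            assert got.df == df
            assert got.effect_size == pytest.approx(eta, rel=1e-8)

    def test_unbalanced_design_rejected(self):
        rows = [{"subject": s, "cond": c, "y": 1.0}
                for s in range(3) for c in "ab"]
        rows.pop()
        with pytest.raises(ValueError, match="cell|incomplete|unbalanced"):
            stats_core.rm_anova(pd.DataFrame(rows), dv="y", within="cond",
                                subject="subject")


class TestEffectSizeIdentities:
    def test_zero_F(self):
        assert stats_core.partial_eta_sq_from_F(0.0, 1, 18) == 0.0

    def test_identity_matches_ss_based_eta(self, rng):
        n, a = 6, 4
        wide = rng.normal(size=(n, a, 1))
        rows = [{"subject": s, "A": f"a{i}", "y": wide[s, i, 0]}
                for s in range(n) for i in range(a)]
        res = stats_core.rm_anova(pd.DataFrame(rows), dv="y", within="A",
                                  subject="subject")[0]
        eta = stats_core.partial_eta_sq_from_F(res.statistic, *res.df)
        assert eta == pytest.approx(res.effect_size, abs=1e-10)


class TestCorrections:
    def test_fdr_step_up_by_hand(self):
        adjusted = stats_core.fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, 0.04)

    def test_fdr_single_and_degenerate(self):
        assert stats_core.fdr_bh([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(stats_core.fdr_bh([1.0, 1.0, 1.0]), 1.0)

    def test_fdr_never_decreases_and_is_rank_monotone(self, rng):
        p = rng.uniform(size=20)
        q = stats_core.fdr_bh(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_fdr_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            stats_core.fdr_bh([0.5, 1.5])

    @pytest.mark.parametrize("p,m,expected", [
        (0.01, 5, 0.05), (0.5, 3, 1.0), (0.7, 1, 0.7),
    ])
    def test_bonferroni(self, p, m, expected):
        assert stats_core.bonferroni(p, m) == pytest.approx(expected)


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_fdr_adjustment_properties(pvals):
    q = stats_core.fdr_bh(pvals)
    p = np.asarray(pvals)
    assert ((q >= p - 1e-15) & (q <= 1.0 + 1e-15)).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()


@given(st.floats(-0.999, 0.999))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_fisher_z_is_odd_and_increasing(r):
    assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)
    assert fisher_z(min(r + 1e-4, 0.9995)) >= fisher_z(r)
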