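import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from admixps import popstats, scores
from admixps.containers import AncestryMask

from conftest import make_genos, random_cohort


def enumeration_signed_rank_p(d, side):
    """Oracle: exact one-sided signed-rank p by enumerating all sign vectors."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array(
        [sum(r for r, b in zip(ranks, bits) if b)
         for bits in itertools.product((0, 1), repeat=n)]
    )
    if side == "toward0":
        return float((ws <= w_obs + 1e-9).mean())
    return float((ws >= w_obs - 1e-9).mean())


class TestWilcoxonSignedRank:
    def test_all_negative_n5_exact(self):
        """Five pairs all shifted toward zero: one-sided exact p = 1/32."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a + 1.0
        res = popstats.wilcoxon_signed_rank(a, b, "toward0")
        assert res.pvalue == pytest.approx(1 / 32)
        assert res.n == 5

    def test_symmetric_differences_not_significant(self):
        a = np.array([2.0, 0.0, 3.0, 1.0])
        b = np.array([1.0, 1.0, 2.0, 2.0])  # d = +1, -1, +1, -1
        for side in ("toward0", "awayfrom0"):
            assert popstats.wilcoxon_signed_rank(a, b, side).pvalue >= 0.5

    def test_matches_enumeration_oracle(self):
        """Exact p agrees with full 2^n sign enumeration, ties included."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(3, 13)
            # half-integer differences: exactly representable, with ties
            d = rng.integers(-4, 5, n) * 0.5
            d = d[d != 0]
            if len(d) == 0:
                continue
            a = np.abs(d) + 1.0
            b = a - d
            d_eff = np.abs(a) - np.abs(b)  # what the implementation sees
            for side in ("toward0", "awayfrom0"):
                got = popstats.wilcoxon_signed_rank(a, b, side).pvalue
                want = enumeration_signed_rank_p(d_eff, side)
                assert got == pytest.approx(want, abs=1e-12)

    def test_two_sides_cover_distribution(self):
        rng = np.random.default_rng(7)
        d = rng.standard_normal(15)
        a = np.abs(d) + 2.0
        b = a - d
        p1 = popstats.wilcoxon_signed_rank(a, b, "toward0").pvalue
        p2 = popstats.wilcoxon_signed_rank(a, b, "awayfrom0").pvalue
        assert p1 + p2 >= 1.0  # both tails include the observed atom

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal(25) + 0.3
        a = np.abs(d) + 2.0
        b = a - d
        exact = popstats.wilcoxon_signed_rank(a, b, "awayfrom0").pvalue
        big = popstats.wilcoxon_signed_rank(
            np.concatenate([a, [5.0]]), np.concatenate([b, [4.3]]), "awayfrom0"
        )
        assert big.n == 26  # exercises the normal branch
        assert abs(big.pvalue - exact) < 0.05  # same data plus one pair

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            popstats.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0], "toward0")


def wc84_scalar_oracle(groups):
    """Independently coded per-site Weir-Cockerham (1984) variance components."""
    a_sum = d_sum = 0.0
    per_site = []
    n_sites = groups[0].shape[1] // 1
    r = len(groups)
    for s in range(groups[0][0::2].shape[1]):
        ns, ps, hs = [], [], []
        for g in groups:
            h0, h1 = g[0::2, s], g[1::2, s]
            ok = (h0 >= 0) & (h1 >= 0)
            n = ok.sum()
            ns.append(n)
            ps.append((h0[ok].sum() + h1[ok].sum()) / (2 * n))
            hs.append((h0[ok] != h1[ok]).sum() / n)
        nbar = sum(ns) / r
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        per_site.append(a / denom if denom != 0 else np.nan)
        if denom != 0 and np.isfinite(denom):
            a_sum += a
            d_sum += denom
    return np.array(per_site), a_sum / d_sum


class TestWeirCockerhamFst:
    def test_matches_scalar_oracle_random(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n1, n2 = rng.integers(5, 20, 2)
            g1 = rng.integers(0, 2, (2 * n1, 8)).astype(np.int8)
            g2 = rng.integers(0, 2, (2 * n2, 8)).astype(np.int8)
            site, w = popstats.weir_cockerham_fst([g1, g2])
            o_site, o_w = wc84_scalar_oracle([g1, g2])
            np.testing.assert_allclose(site, o_site, atol=1e-10)
            assert w == pytest.approx(o_w, abs=1e-10)

    def test_fixed_difference_limit(self):
        g1 = np.ones((1000, 5), dtype=np.int8)
        g2 = np.zeros((1000, 5), dtype=np.int8)
        _, w = popstats.weir_cockerham_fst([g1, g2])
        assert w > 0.99

    def test_identical_populations_near_zero(self, rng):
        g = (rng.random((4000, 50)) < 0.4).astype(np.int8)
        _, w = popstats.weir_cockerham_fst([g[:2000], g[2000:]])
        assert abs(w) < 0.01

    def test_documented_two_group_case(self):
        """20 haplotypes per group, alt counts 10/20 vs 2/20."""
        g1 = np.array([[1] * 10 + [0] * 10]).T.astype(np.int8)
        g2 = np.array([[1] * 2 + [0] * 18]).T.astype(np.int8)
        _, w = popstats.weir_cockerham_fst([g1, g2])
        _, o = wc84_scalar_oracle([g1, g2])
        assert w == pytest.approx(o, abs=1e-12)
        assert 0 < w < 1

    def test_invariant_to_allele_swap_and_group_order(self, rng):
        g1 = rng.integers(0, 2, (30, 12)).astype(np.int8)
        g2 = rng.integers(0, 2, (40, 12)).astype(np.int8)
        _, w = popstats.weir_cockerham_fst([g1, g2])
        _, w_swap = popstats.weir_cockerham_fst([1 - g1, 1 - g2])
        _, w_ord = popstats.weir_cockerham_fst([g2, g1])
        assert w == pytest.approx(w_swap, abs=1e-12)
        assert w == pytest.approx(w_ord, abs=1e-12)

    def test_too_few_groups_error(self, rng):
        with pytest.raises(ValueError):
            popstats.weir_cockerham_fst([rng.integers(0, 2, (10, 5))])


class TestPsBias:
    def test_reference_against_itself_zero(self, rng):
        ps = rng.standard_normal(500)
        tr = rng.standard_normal(500)
        est = popstats.ps_bias(ps, tr, ps, tr)
        assert est.bias == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_ps_shift(self, rng):
        ref_ps = rng.standard_normal(100_000)
        ref_tr = rng.standard_normal(100_000)
        est = popstats.ps_bias(
            ref_ps[:1000] + ref_ps.std(ddof=1), ref_tr[:1000], ref_ps, ref_tr
        )
        assert est.bias == pytest.approx(1.0, abs=0.15)

    def test_matches_analytic_frequency_shift(self):
        """An engineered allele-frequency shift with no trait shift produces
        bias ~ (sum beta*dfreq / N) / sigma_ref (closed form)."""
        rng = np.random.default_rng(5)
        n_sites, n_ind = 300, 3000
        beta = rng.standard_normal(n_sites)
        f = rng.uniform(0.2, 0.8, n_sites)
        delta = 0.05 * np.sign(beta)
        ref_states = (rng.random((2 * n_ind, n_sites)) < f).astype(float)
        grp_states = (rng.random((2 * n_ind, n_sites)) < f + delta).astype(float)
        ref_ps = (ref_states[0::2] + ref_states[1::2]) @ beta / (2 * n_sites)
        grp_ps = (grp_states[0::2] + grp_states[1::2]) @ beta / (2 * n_sites)
        trait = rng.standard_normal(n_ind)
        est = popstats.ps_bias(grp_ps, trait, ref_ps, trait)
        sigma = np.sqrt((beta**2 * 2 * f * (1 - f)).sum()) / (2 * n_sites)
        analytic = (beta * delta).sum() / n_sites / sigma
        assert est.bias == pytest.approx(analytic, rel=0.12)

    def test_degenerate_reference_error(self):
        with pytest.raises(ValueError):
            popstats.ps_bias([1.0], [1.0], [2.0, 2.0], [0.0, 1.0])


class TestValidityFilter:
    def test_strict_threshold(self):
        tab = pd.DataFrame(
            {
                "sample": ["a", "b", "c", "d"],
                "ancestry": ["EUR", "EUR", "EUR", "TOTAL:EUR"],
                "N_S": [5, 10, 100, 100],
                "p": [0.09, 0.10, 1.0, 1.0],
                "raw": [0.1] * 4,
                "pps": [1.0, 2.0, 3.0, 4.0],
                "flag": ["ok"] * 4,
            }
        )
        out = popstats.validity_filter(tab)
        assert np.isnan(out.loc[0, "pps"])          # p = 0.09 removed
        assert out.loc[1, "pps"] == 2.0             # p = 0.10 retained (strict <)
        assert out.loc[2, "pps"] == 3.0             # p = 1 retained
        assert out.loc[3, "pps"] == 4.0             # total PS untouched


class TestNullAspps:
    def test_identical_individuals_degenerate(self, rng):
        states = np.tile(rng.integers(0, 2, 60).astype(np.int8), (12, 1))
        genos = make_genos(states)
        ref, wt, _ = random_cohort(rng, 30, 60)
        labels = np.tile(
            (rng.random(60) < 0.5).astype(np.int8), (12, 1)
        )
        mask = AncestryMask(ancestries=["A", "B"], hap_ids=genos.hap_ids, labels=labels)
        true_tab = scores.score_cohort(genos, {"A": wt}, mask, {"A": ref})
        null_tab = popstats.null_aspps(genos, {"A": wt}, mask, {"A": ref}, seed=0)
        with pytest.raises(ValueError):  # all paired differences are zero
            popstats.shift_tests(true_tab, null_tab, "A")

    def test_strong_bias_detected_away_from_zero(self, rng):
        """With a systematic B-ancestry frequency shift aligned to the effect
        signs, the non-GWAS component must shift away from zero relative to
        the deranged-mask null."""
        from conftest import shifted_cohort

        genos, wt, mask, ref = shifted_cohort(rng, n_ind=100, n_sites=800)
        w = {"A": wt}
        rp = {"A": ref}
        true_tab = scores.score_cohort(genos, w, mask, rp)
        null_tab = popstats.null_aspps(genos, w, mask, rp, seed=21)
        res = popstats.shift_tests(true_tab, null_tab, "A")
        p_away = res.loc[res["ancestry"] == "B", "p"].iloc[0]
        assert p_away < 0.05


def test_significance_stars():
    assert popstats.significance_stars(0.04) == "*"
    assert popstats.significance_stars(0.004) == "**"
    assert popstats.significance_stars(5e-6) == "***"
    assert popstats.significance_stars(0.2) == ""
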