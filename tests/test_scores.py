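import numpy as np
import pandas as pd
import pytest

from admixps import scores
from admixps.containers import MISSING, UNKNOWN, AncestryMask

from conftest import make_genos, make_weights, random_cohort


class TestRawPs:
    def test_sum_and_mean_forms(self):
        beta = np.array([0.1, -0.3, 0.2])
        x = np.array([1, 0, 1])
        assert scores.raw_ps(beta, x, "sum") == pytest.approx(0.3)
        assert scores.raw_ps(beta, x, "mean") == pytest.approx(0.1)

    def test_zero_effects(self):
        assert scores.raw_ps(np.zeros(4), np.ones(4), "sum") == 0.0

    def test_single_site(self):
        assert scores.raw_ps([0.5], [1], "sum") == scores.raw_ps([0.5], [1], "mean") == 0.5

    def test_missing_excluded_from_mean(self):
        beta = np.array([0.1, 0.2, 0.4])
        x = np.array([1, MISSING, 1])
        assert scores.raw_ps(beta, x, "mean") == pytest.approx(0.25)

    def test_all_missing_error(self):
        with pytest.raises(ValueError):
            scores.raw_ps([0.1], [MISSING])


class TestRawPps:
    def test_subset_mean(self):
        beta = np.array([0.1, -0.3, 0.2])
        x = np.array([1, 0, 1])
        val, n = scores.raw_pps(beta, x, [True, False, True])
        assert val == pytest.approx(0.15) and n == 2

    def test_full_subset_equals_raw_mean(self):
        beta = np.array([0.1, -0.3, 0.2])
        x = np.array([1, 0, 1])
        val, n = scores.raw_pps(beta, x, np.ones(3, bool))
        assert val == pytest.approx(scores.raw_ps(beta, x, "mean")) and n == 3

    def test_empty_subset_absent(self):
        val, n = scores.raw_pps([0.1], [1], [False])
        assert val is None and n == 0


class TestReferenceStats:
    def test_identical_individuals_degenerate(self):
        states = np.ones((6, 4), dtype=np.int8)
        with pytest.raises(ValueError, match="sigma"):
            scores.reference_stats(make_genos(states), np.ones(4))

    def test_explicit_values(self):
        # individuals engineered to have raw pPS 0, 1, 2 -> mu=1, sigma=1
        beta = np.array([2.0])
        states = np.array([[0], [0], [0], [1], [1], [1]], dtype=np.int8)
        ref = scores.reference_stats(make_genos(states), beta)
        assert ref.mu == pytest.approx(1.0) and ref.sigma == pytest.approx(1.0)


class TestStandardize:
    def test_zero_and_unit(self):
        ref = scores.ReferenceStats(mu=0.3, sigma=0.2, n_individuals=10)
        assert scores.standardize_pps(0.3, ref) == pytest.approx(0.0)
        assert scores.standardize_pps(0.5, ref) == pytest.approx(1.0)

    def test_self_standardization_mean0_sd1(self, rng):
        genos, wt, _ = random_cohort(rng, 40, 100)
        ref = scores.reference_stats(genos, wt)
        bb = np.concatenate([wt.beta, wt.beta])
        raws = []
        for j in range(genos.n_samples):
            v, _ = scores.raw_pps(
                bb,
                np.concatenate([genos.states[2 * j], genos.states[2 * j + 1]]),
                np.ones(200, bool),
            )
            raws.append(v)
        z = scores.standardize_pps(np.array(raws), ref)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)


class TestSqrtPCorrection:
    def test_examples(self):
        assert scores.correct_sqrt_p(0.5, 0.25) == pytest.approx(1.0)
        assert scores.correct_sqrt_p(0.7, 1.0) == pytest.approx(0.7)

    def test_p_zero_error(self):
        with pytest.raises(ValueError):
            scores.correct_sqrt_p(0.5, 0.0)


class TestCasps:
    @pytest.mark.parametrize(
        "aspps,fracs,expected",
        [
            ((1.0, -1.0), (0.5, 0.5), 0.0),
            ((2.5, np.nan), (1.0, 0.0), 2.5),
            ((1.0, 0.5), (0.6, 0.4), 0.8),
        ],
    )
    def test_weighted_combination(self, aspps, fracs, expected):
        out = scores.compute_casps(np.array([aspps]), np.array([fracs]))
        assert out[0] == pytest.approx(expected)

    def test_absent_component_renormalizes(self):
        out = scores.compute_casps(
            np.array([[1.0, np.nan, 3.0]]), np.array([[0.2, 0.5, 0.2]])
        )
        assert out[0] == pytest.approx((0.2 * 1.0 + 0.2 * 3.0) / 0.4)

    def test_no_contributing_ancestry_absent(self):
        out = scores.compute_casps(np.array([[np.nan, np.nan]]), np.array([[0.5, 0.5]]))
        assert np.isnan(out[0])

    def test_identical_components_invariant_to_fractions(self, rng):
        vals = rng.standard_normal((30, 1)) * np.ones((1, 3))
        fracs = rng.dirichlet((2, 2, 2), size=30)
        np.testing.assert_allclose(scores.compute_casps(vals, fracs), vals[:, 0])


class TestFullGenomeLimit:
    def test_pps_equals_classical_ps_machine_precision(self, rng):
        """Full-genome pPS must reproduce the classical z-scored PS exactly."""
        genos, wt, _ = random_cohort(rng, 30, 80)
        ref_genos, _, _ = random_cohort(rng, 50, 80)
        ref = scores.reference_stats(ref_genos, wt)
        classical = []
        partial = []
        for j in range(genos.n_samples):
            both = np.concatenate([genos.states[2 * j], genos.states[2 * j + 1]])
            bb = np.concatenate([wt.beta, wt.beta])
            classical.append((scores.raw_ps(bb, both, "mean") - ref.mu) / ref.sigma)
            v, _ = scores.raw_pps(bb, both, np.ones(160, bool))
            partial.append(scores.standardize_pps(v, ref))
        np.testing.assert_array_equal(classical, partial)


class TestInvariances:
    def test_site_reordering(self, rng):
        genos, wt, _ = random_cohort(rng, 10, 60)
        perm = rng.permutation(60)
        ref_genos, _, _ = random_cohort(rng, 30, 60)
        ref_a = scores.reference_stats(ref_genos, wt.beta)
        ref_b = scores.reference_stats(ref_genos.subset_sites(perm), wt.beta[perm])
        assert ref_a.mu == pytest.approx(ref_b.mu, rel=1e-12)
        assert ref_a.sigma == pytest.approx(ref_b.sigma, rel=1e-12)

    def test_haplotype_merge_equals_pooled_mean(self, rng):
        """With no missing data, the SNP-count-weighted haplotype merge equals
        a direct mean over both haplotypes' sites."""
        beta = rng.standard_normal(50)
        h1 = rng.integers(0, 2, 50).astype(np.int8)
        h2 = rng.integers(0, 2, 50).astype(np.int8)
        sel = rng.random(50) < 0.6
        v1, n1 = scores.raw_pps(beta, h1, sel)
        v2, n2 = scores.raw_pps(beta, h2, sel)
        merged = (n1 * v1 + n2 * v2) / (n1 + n2)
        pooled, _ = scores.raw_pps(
            np.concatenate([beta, beta]),
            np.concatenate([h1, h2]),
            np.concatenate([sel, sel]),
        )
        assert merged == pytest.approx(pooled, rel=1e-12)


class TestScoreCohort:
    def test_all_unknown_mask_gives_absent_aspps(self, rng):
        genos, wt, _ = random_cohort(rng, 10, 50)
        ref, _, _ = random_cohort(rng, 30, 50)
        mask = AncestryMask(
            ancestries=["A", "B"],
            hap_ids=genos.hap_ids,
            labels=np.full((20, 50), UNKNOWN, dtype=np.int8),
        )
        tab = scores.score_cohort(genos, {"A": wt}, mask, {"A": ref})
        total = tab[tab["ancestry"] == "TOTAL:A"]
        asp = tab[tab["ancestry"] == "A"]
        assert total["pps"].notna().all()
        assert asp["pps"].isna().all()
        assert (asp["flag"] == "empty_subset").all()

    def test_reference_scored_against_itself(self, rng):
        genos, wt, _ = random_cohort(rng, 40, 60)
        tab = scores.score_cohort(genos, {"A": wt}, None, {"A": genos})
        z = tab["pps"].values
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-10)

    def test_aspps_of_gwas_ancestry_less_shifted_than_total(self, default_sim_cohort):
        """On an admixed cohort scored with one GWAS, the aspPS of the GWAS's
        own ancestry should sit closer to the reference (|median| smaller)
        than the ancestry-contaminated total PS."""
        c = default_sim_cohort
        anc0 = c.config.ancestries[0]
        tab = scores.score_cohort(
            c.genos,
            {anc0: c.weights[anc0]},
            c.true_mask,
            {anc0: c.ref_panels[anc0]},
        )
        med_total = tab.loc[tab["ancestry"] == f"TOTAL:{anc0}", "pps"].median()
        med_asp = tab.loc[tab["ancestry"] == anc0, "pps"].median()
        assert abs(med_asp) < abs(med_total)

    def test_validity_filter_consulted(self, rng):
        genos, wt, _ = random_cohort(rng, 8, 100)
        ref, _, _ = random_cohort(rng, 30, 100)
        labels = np.full((16, 100), 1, dtype=np.int8)
        labels[:, :5] = 0  # ancestry A on 5% of sites only
        mask = AncestryMask(ancestries=["A", "B"], hap_ids=genos.hap_ids, labels=labels)
        tab = scores.score_cohort(genos, {"A": wt}, mask, {"A": ref})
        asp = tab[tab["ancestry"] == "A"]
        assert (asp["flag"] == "below_min_fraction").all()
        assert asp["pps"].isna().all()

    def test_missing_genotypes_shrink_denominator(self, rng):
        genos, wt, _ = random_cohort(rng, 6, 40)
        genos.states[0, :10] = MISSING
        ref, _, _ = random_cohort(rng, 30, 40)
        tab = scores.score_cohort(genos, {"A": wt}, None, {"A": ref})
        assert tab.loc[0, "N_S"] == 70  # 40 + 40 - 10 observed alleles
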