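"""Reusable simulation experiments validating the pPS/aspPS/casPS method.

Each function here drives a complete in-silico study: generate data under
stated conditions, run the scoring/testing/prediction machinery, and
return summary numbers.  They are used by the test suite and by the
reproduction script, and are deliberately deterministic given a seed.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import ancestry_masks, popstats, predictivity, scores
from . import synthetic_data as synth
from .containers import AncestryMask, HaplotypeMatrix

__all__ = [
    "sqrt_p_bias_experiment",
    "null_calibration_experiment",
    "reference_self_bias",
    "transferability_comparison",
    "casps_predictivity_experiment",
    "mask_resampling_summary",
    "parameter_recovery",
]


def _iid_population(rng, n_ind, freqs):
    states = (rng.random((2 * n_ind, len(freqs))) < freqs).astype(np.int8)
    return states


def sqrt_p_bias_experiment(
    seed,
    n_snps: int = 2000,
    n_ref: int = 400,
    n_target: int = 300,
    n_subsets: int = 25,
    delta: float = 0.05,
    p_grid=(0.05, 0.1, 0.25, 0.5, 1.0),
) -> dict:
    """Mean and sd of pPS across genomic fractions in a shifted population.

    Sites are iid; the target population's allele frequencies are shifted
    by ``delta`` in the direction of each effect sign, giving a constant
    raw-score mean shift.  Because the reference sd of the raw pPS scales
    as 1/sqrt(N_S), the standardized mean shift follows a*sqrt(p) while
    the 1/sqrt(p)-corrected score has a p-independent mean and an sd
    growing as 1/sqrt(p).  Returns the per-p means/sds, the R^2 of the
    sqrt-law fit and the log-log slope of the corrected sd.
    """
    rng = np.random.default_rng(seed)
    beta = rng.standard_normal(n_snps)
    f = rng.uniform(0.2, 0.8, n_snps)
    f_t = np.clip(f + delta * np.sign(beta), 0.05, 0.95)
    ref = _iid_population(rng, n_ref, f)
    tgt = _iid_population(rng, n_target, f_t)
    ref_ind = (ref[0::2] + ref[1::2]).astype(float)
    tgt_ind = (tgt[0::2] + tgt[1::2]).astype(float)

    mean_pps, mean_corr, sd_corr = [], [], []
    for p in p_grid:
        n_s = max(1, int(round(p * n_snps)))
        zs = []
        reps = 1 if n_s == n_snps else n_subsets
        for _ in range(reps):
            sel = rng.choice(n_snps, size=n_s, replace=False)
            rv = ref_ind[:, sel] @ beta[sel] / (2 * n_s)
            tv = tgt_ind[:, sel] @ beta[sel] / (2 * n_s)
            zs.append((tv - rv.mean()) / rv.std(ddof=1))
        zs = np.concatenate(zs)
        mean_pps.append(zs.mean())
        corr = zs / np.sqrt(p)
        mean_corr.append(corr.mean())
        sd_corr.append(corr.std(ddof=1))

    p_arr = np.asarray(p_grid, float)
    m = np.asarray(mean_pps)
    root = np.sqrt(p_arr)
    a = (root @ m) / (root @ root)  # through-origin least squares
    ss_res = ((m - a * root) ** 2).sum()
    ss_tot = ((m - m.mean()) ** 2).sum()
    fit_r2 = 1.0 - ss_res / ss_tot
    slope_sd = np.polyfit(np.log(p_arr), np.log(sd_corr), 1)[0]
    return {
        "p_grid": list(p_arr),
        "mean_pps": mean_pps,
        "mean_corrected": mean_corr,
        "sd_corrected": sd_corr,
        "sqrt_fit_r2": float(fit_r2),
        "sqrt_fit_a": float(a),
        "sd_loglog_slope": float(slope_sd),
    }


def null_calibration_experiment(
    seed, n_cohorts: int = 200, n_ind: int = 24, n_snps: int = 400, n_ref: int = 50
) -> dict:
    """Shuffled-mask Wilcoxon p-values under the null of no ancestry effect.

    Genotypes are iid across the two nominal ancestries (identical allele
    frequencies), so the deranged-mask null holds exactly and the
    toward-0 test p-values should be uniform.  Returns the p-values and a
    Kolmogorov-Smirnov test of uniformity.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_cohorts)
    pvals = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        freqs = rng.uniform(0.2, 0.8, n_snps)
        beta = rng.standard_normal(n_snps)
        sites = pd.DataFrame(
            {"chrom": "1", "pos": 100 + 10 * np.arange(n_snps), "ref": "A", "alt": "G"}
        )
        genos = HaplotypeMatrix(
            samples=[f"S{i}" for i in range(n_ind)],
            sites=sites,
            states=_iid_population(rng, n_ind, freqs),
        )
        ref = HaplotypeMatrix(
            samples=[f"R{i}" for i in range(n_ref)],
            sites=sites,
            states=_iid_population(rng, n_ref, freqs),
        )
        labels = (rng.random((2 * n_ind, n_snps)) < 0.5).astype(np.int8)
        mask = AncestryMask(
            ancestries=["A", "B"], hap_ids=genos.hap_ids, labels=labels
        )
        tab = scores.score_cohort(genos, {"A": beta}, mask, {"A": ref})
        null_tab = popstats.null_aspps(
            genos, {"A": beta}, mask, {"A": ref}, seed=int(s) + 1
        )
        res = popstats.shift_tests(tab, null_tab, "A")
        pvals.append(float(res.loc[res["ancestry"] == "A", "p"].iloc[0]))
    ks = stats.kstest(pvals, "uniform")
    return {"pvalues": pvals, "ks_p": float(ks.pvalue)}


def reference_self_bias(seed, n_ind: int = 2000, n_snps: int = 1000) -> dict:
    """PS bias of a fresh sample from the reference population (expect ~0)."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.2, 0.8, n_snps)
    beta = rng.standard_normal(n_snps)
    ref = _iid_population(rng, n_ind, freqs)
    grp = _iid_population(rng, n_ind, freqs)
    sel = rng.random(n_snps) < 0.5  # arbitrary mask; bias must still be ~0
    ref_ps = (ref[0::2] + ref[1::2])[:, sel].astype(float) @ beta[sel]
    grp_ps = (grp[0::2] + grp[1::2])[:, sel].astype(float) @ beta[sel]
    trait_ref = rng.standard_normal(n_ind)
    trait_grp = rng.standard_normal(n_ind)
    est = popstats.ps_bias(grp_ps, trait_grp, ref_ps, trait_ref)
    # mean of a standardized quantity over n individuals has sd ~ 1/sqrt(n)
    mc_sd = np.sqrt(2.0 / n_ind)
    return {"bias": est.bias, "mc_sd": float(mc_sd)}


def transferability_comparison(
    seed,
    n_replicates: int = 50,
    n: int = 2000,
    transferability: float = 0.0,
    bias: float = 3.0,
    r_a: float = 0.5,
    p_dist=("beta", 6.0, 6.0),
) -> pd.DataFrame:
    """Model R^2 of the four PS configurations over replicate simulations."""
    rows = []
    for k in range(n_replicates):
        cfg = synth.TransferabilityConfig(
            n=n, p_dist=p_dist, r_a=r_a,
            transferability=transferability, bias=bias, seed=None,
        )
        df = synth.simulate_transferability(cfg, seed=np.random.SeedSequence([seed, k]).generate_state(1)[0])
        rows.append(synth.evaluate_transferability_models(df))
    return pd.DataFrame(rows)


def casps_predictivity_replicate(
    seed,
    n_individuals: int = 4000,
    n_snps: int = 20_000,
    fst: float = 0.1,
    rho: float = 0.6,
    h2: float = 0.5,
    gwas_n=None,
    n_reference: int = 150,
) -> dict:
    """One replicate of the admixed-cohort predictivity comparison.

    Simulates an admixed cohort with ancestry-specific effects, scores it
    with both GWAS weight sets under the true local-ancestry masks and
    under a deranged-mask control, fits each PS configuration on half the
    cohort and reports added R^2 on the held-out half.
    """
    gwas_n = gwas_n or {"EUR": 100_000, "EAS": 20_000}
    cfg = synth.CohortConfig(
        n_individuals=n_individuals, n_snps=n_snps, fst=fst, rho=rho, h2=h2,
        gwas_n=gwas_n, n_reference=n_reference, seed=None,
    )
    c = synth.simulate_admixed_cohort(cfg, seed=seed)
    anc0, anc1 = cfg.ancestries

    tab = scores.score_cohort(
        c.genos, c.weights, c.true_mask, c.ref_panels, dtype=np.float32
    )
    deranged, _ = ancestry_masks.shuffle_masks(c.true_mask, seed + 1)
    tab_der = scores.score_cohort(
        c.genos, c.weights, deranged, c.ref_panels, dtype=np.float32
    )

    wide = tab.pivot_table(index="sample", columns="ancestry", values="pps")
    frac = tab[tab["ancestry"] == anc0].set_index("sample")["p"]
    data = c.phenotypes.set_index("sample").join(wide)
    data["frac0"] = frac
    data["casps_deranged"] = tab_der.pivot_table(
        index="sample", columns="ancestry", values="pps"
    )["CASPS"]
    data = data.reset_index()

    n_fit = n_individuals // 2
    fit_set = data.iloc[:n_fit]
    pred_set = data.iloc[n_fit:]
    base_cols = ["sex", "age", "frac0"]
    out = {}
    for label, cols in {
        "total_a": [f"TOTAL:{anc0}"],
        "total_b": [f"TOTAL:{anc1}"],
        "aspps_a": [anc0],
        "casps": ["CASPS"],
        "casps_deranged": ["casps_deranged"],
    }.items():
        pair = predictivity.fit_models(fit_set, "trait", base_cols, cols)
        out[label] = predictivity.added_r2(pair, pred_set, "trait")
    return out


def casps_predictivity_experiment(seed, n_replicates: int = 20, **kw) -> pd.DataFrame:
    """Replicated admixed-cohort predictivity comparison (one row each)."""
    rows = []
    for k in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        rows.append(casps_predictivity_replicate(rep_seed, **kw))
    return pd.DataFrame(rows)


def mask_resampling_summary(
    seed,
    n_individuals: int = 1500,
    n_snps: int = 4000,
    n_masks: int = 200,
    n_reference: int = 200,
    h2: float = 0.5,
) -> dict:
    """Predictivity of pPS from random genomic subsets on a uniform cohort.

    An unadmixed cohort is scored with masks of varying genomic fraction;
    the summary reports the Spearman correlation between fraction and
    added R^2, plus the full-genome mask's added R^2 against the total
    PS's (these must coincide).
    """
    rng = np.random.default_rng(seed)
    cfg = synth.CohortConfig(
        n_individuals=n_individuals, n_snps=n_snps, h2=h2,
        admixture_dist=("fixed", 1.0),  # uniform single-ancestry cohort
        n_reference=n_reference, seed=None,
    )
    c = synth.simulate_admixed_cohort(cfg, seed=seed)
    anc0 = cfg.ancestries[0]
    wt = c.weights[anc0]
    ref = c.ref_panels[anc0]

    lib = [np.ones(n_snps, dtype=bool)]
    for _ in range(n_masks - 1):
        frac = rng.uniform(0.05, 1.0)
        m = ancestry_masks.random_mask(
            n_snps, {"A": frac, "UNKNOWN": 1.0 - frac},
            int(rng.integers(2**31)), mode="blocky", mean_block=50,
        )
        lib.append(m.labels[0] == 0)

    res = predictivity.mask_resampling_experiment(
        c.genos, lib, wt, ref, c.phenotypes, "trait", ["sex", "age"]
    )
    # total-PS added R^2 through the cohort-scoring path
    tab = scores.score_cohort(c.genos, {anc0: wt}, None, {anc0: ref})
    data = c.phenotypes.merge(
        tab[["sample", "pps"]].rename(columns={"pps": "total_ps"}), on="sample"
    )
    pair = predictivity.fit_models(data, "trait", ["sex", "age"], ["total_ps"])
    total_added = predictivity.added_r2(pair, data, "trait")
    rho, pval = stats.spearmanr(res["fraction"], res["added_r2"])
    return {
        "table": res,
        "spearman_rho": float(rho),
        "spearman_p": float(pval),
        "full_genome_added_r2": float(res.loc[res["mask"] == 0, "added_r2"].iloc[0]),
        "total_ps_added_r2": float(total_added),
    }


def parameter_recovery(
    seed, n_individuals: int = 5000, n_snps: int = 3000, h2: float = 0.5,
    generations: float = 10.0, map_morgans: float = 35.0,
) -> dict:
    """Recovery of h^2, admixture proportions and tract lengths from one cohort."""
    cfg = synth.CohortConfig(
        n_individuals=n_individuals, n_snps=n_snps, h2=h2,
        generations=generations, map_morgans=map_morgans, seed=None,
    )
    c = synth.simulate_admixed_cohort(cfg, seed=seed)
    y = c.phenotypes["trait"].values
    gv = c.truth["genetic_value"]
    r = np.corrcoef(y, gv)[0, 1]
    r2 = r * r
    # delta-method sd of a squared correlation estimate
    r2_sd = 2 * abs(r) * (1 - r2) / np.sqrt(n_individuals)

    realized = c.truth["realized_fraction0"]
    prop_mean = float(np.mean(c.truth["admixture_proportion"]))
    prop_sd = realized.std(ddof=1) / np.sqrt(len(realized))

    per_hap_tract = map_morgans / (c.truth["n_switches"] + 1)
    tract_mean = float(per_hap_tract.mean())
    tract_sd = float(per_hap_tract.std(ddof=1) / np.sqrt(len(per_hap_tract)))
    return {
        "h2_estimate": float(r2),
        "h2_target": h2,
        "h2_mc_sd": float(r2_sd),
        "admixture_mean_realized": float(realized.mean()),
        "admixture_mean_target": prop_mean,
        "admixture_mc_sd": float(prop_sd),
        "tract_mean_realized": tract_mean,
        "tract_mean_target": 1.0 / generations,
        "tract_mc_sd": tract_sd,
    }
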