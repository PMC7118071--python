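"""Population-level analyses of (as)pPS distributions.

Covers the significance machinery for ancestry-specific score shifts
(true aspPS vs aspPS recomputed under an incorrect, deranged local-ancestry
pattern, one-sided Wilcoxon signed-rank on magnitudes), the directional
bias of a PS in a non-reference group, the Weir & Cockerham (1984) F_ST
estimator in its two-level (individuals within populations) form with the
weighted ratio-of-sums average, and the 10%-of-genome validity filter.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, AncestryMask, HaplotypeMatrix
from .scores import score_cohort

__all__ = [
    "ShiftTestResult",
    "BiasEstimate",
    "wilcoxon_signed_rank",
    "null_aspps",
    "shift_tests",
    "ps_bias",
    "weir_cockerham_fst",
    "validity_filter",
    "significance_stars",
]

EXACT_N_MAX = 25


@dataclass
class ShiftTestResult:
    ancestry: str | None
    side: str
    statistic: float  # W+ = sum of ranks of positive differences
    pvalue: float
    n: int  # pairs remaining after zero-difference removal


@dataclass
class BiasEstimate:
    group: str | None
    mean_z_ps: float
    mean_z_trait: float
    bias: float
    fst: float | None = None


def _exact_signed_rank_cdf(ranks: np.ndarray, w_obs: float, upper: bool) -> float:
    """Exact tail probability of W+ for the given rank multiset.

    Average ranks are half-integers; doubling makes them integers, so the
    null distribution of 2*W+ is the coefficient array of
    prod_i (1 + z^{2 r_i}) / 2^n — identical to enumerating all 2^n sign
    assignments.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r]
    counts /= 2 ** len(r2)
    w2 = int(np.rint(2 * w_obs))
    return float(counts[w2:].sum() if upper else counts[: w2 + 1].sum())


def wilcoxon_signed_rank(
    a: np.ndarray, b: np.ndarray, side: str, ancestry: str | None = None
) -> ShiftTestResult:
    """One-sided Wilcoxon signed-rank test on paired score magnitudes.

    Tests d = |a| - |b|; ``side="toward0"`` tests the alternative that the
    first scores are closer to zero (d < 0), ``"awayfrom0"`` the opposite.
    Zero differences are dropped, ties get average ranks; p is exact (by
    full sign enumeration, evaluated via convolution) for n <= 25 and a
    continuity-corrected normal approximation with tie-adjusted variance
    otherwise.
    """
    if side not in ("toward0", "awayfrom0"):
        raise ValueError(f"unknown side {side!r}")
    d = np.abs(np.asarray(a, dtype=float)) - np.abs(np.asarray(b, dtype=float))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    upper = side == "awayfrom0"
    if n <= EXACT_N_MAX:
        p = _exact_signed_rank_cdf(ranks, w_plus, upper)
    else:
        mean = n * (n + 1) / 4.0
        _, t = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((t**3 - t).sum()) / 48.0
        if upper:
            p = float(stats.norm.sf((w_plus - mean - 0.5) / np.sqrt(var)))
        else:
            p = float(stats.norm.cdf((w_plus - mean + 0.5) / np.sqrt(var)))
    return ShiftTestResult(
        ancestry=ancestry, side=side, statistic=w_plus, pvalue=min(p, 1.0), n=n
    )


def significance_stars(p: float) -> str:
    if p <= 1e-5:
        return "***"
    if p <= 0.005:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def null_aspps(
    genos: HaplotypeMatrix,
    weights,
    masks: AncestryMask,
    ref_panels,
    seed,
    n_shuffles: int = 1,
    **score_kw,
) -> pd.DataFrame:
    """aspPS recomputed under deranged (incorrect) local-ancestry patterns.

    Each shuffle reassigns observed mask pairs among individuals with no
    fixed point, then rescores the cohort; rows carry a ``shuffle`` column.
    """
    from .ancestry_masks import shuffle_masks

    seeds = np.random.SeedSequence(seed).spawn(n_shuffles)
    out = []
    for k in range(n_shuffles):
        shuffled, _ = shuffle_masks(masks, seeds[k])
        tab = score_cohort(genos, weights, shuffled, ref_panels, **score_kw)
        tab = tab[~tab["ancestry"].str.startswith("TOTAL:")].copy()
        tab["shuffle"] = k
        out.append(tab)
    return pd.concat(out, ignore_index=True)


def shift_tests(
    true_scores: pd.DataFrame,
    null_scores: pd.DataFrame,
    reference_ancestry: str,
) -> pd.DataFrame:
    """Wilcoxon shift tests of true vs deranged-mask aspPS, per ancestry.

    The test side is toward 0 for the reference (GWAS) ancestry and away
    from 0 otherwise.  Pairs where either score is absent are dropped.
    """
    rows = []
    ancestries = [
        a
        for a in true_scores["ancestry"].unique()
        if not a.startswith("TOTAL:") and a != "CASPS"
    ]
    for anc in ancestries:
        t = true_scores[true_scores["ancestry"] == anc].set_index("sample")["pps"]
        nl = null_scores[null_scores["ancestry"] == anc].set_index("sample")["pps"]
        nl = nl.groupby(level=0).mean()  # average over shuffles
        common = t.index.intersection(nl.index)
        tv, nv = t.loc[common].values, nl.loc[common].values
        ok = ~(np.isnan(tv) | np.isnan(nv))
        side = "toward0" if anc == reference_ancestry else "awayfrom0"
        res = wilcoxon_signed_rank(tv[ok], nv[ok], side, ancestry=anc)
        rows.append(
            {
                "ancestry": anc,
                "side": side,
                "W": res.statistic,
                "p": res.pvalue,
                "n": res.n,
                "stars": significance_stars(res.pvalue),
            }
        )
    return pd.DataFrame(rows)


def ps_bias(
    ps: np.ndarray,
    trait: np.ndarray,
    reference_ps: np.ndarray,
    reference_trait: np.ndarray,
    group: str | None = None,
    fst: float | None = None,
) -> BiasEstimate:
    """Directional PS bias: mean standardized PS minus mean standardized trait.

    Both quantities are z-scored against the reference population, so a
    group identical to the reference has bias ~ 0 and a PS shift not
    mirrored by a real trait shift shows up directly in units of reference
    standard deviations.
    """
    rp = np.asarray(reference_ps, dtype=float)
    rt = np.asarray(reference_trait, dtype=float)
    sp, st = rp.std(ddof=1), rt.std(ddof=1)
    if not (sp > 0 and st > 0):
        raise ValueError("degenerate reference standard deviation")
    z_ps = (np.asarray(ps, float) - rp.mean()) / sp
    z_tr = (np.asarray(trait, float) - rt.mean()) / st
    return BiasEstimate(
        group=group,
        mean_z_ps=float(z_ps.mean()),
        mean_z_trait=float(z_tr.mean()),
        bias=float(z_ps.mean() - z_tr.mean()),
        fst=fst,
    )


def _as_genotypes(group) -> np.ndarray:
    """Genotype dosage matrix (n_ind, n_sites) with het flag, from haplotypes."""
    if isinstance(group, HaplotypeMatrix):
        a0 = group.states[0::2]
        a1 = group.states[1::2]
    else:
        arr = np.asarray(group)
        if arr.ndim != 2 or arr.shape[0] % 2:
            raise ValueError("haplotype array must have an even number of rows")
        a0, a1 = arr[0::2], arr[1::2]
    miss = (a0 == MISSING) | (a1 == MISSING)
    g = np.where(miss, -1, a0 + a1)
    het = np.where(miss, False, a0 != a1)
    return g, het


def weir_cockerham_fst(groups) -> tuple[np.ndarray, float]:
    """Weir & Cockerham (1984) F_ST from phased groups.

    ``groups`` is a sequence of haplotype-state arrays (2 rows per
    individual) or :class:`HaplotypeMatrix`; the estimator uses the
    two-level variance components a (among populations), b (among
    individuals within populations) and c (within individuals, from
    observed heterozygosity).  Returns per-site a/(a+b+c) (NaN where the
    denominator is 0, e.g. sites monomorphic everywhere) and the weighted
    average sum(a)/sum(a+b+c); negative per-site components are retained
    in the sums.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    gs, hets = zip(*(_as_genotypes(g) for g in groups))
    for g in gs:
        if g.shape[0] < 1:
            raise ValueError("every group needs at least one individual (2 haplotypes)")
    r = len(gs)
    n_i = np.stack([(g >= 0).sum(axis=0).astype(float) for g in gs])  # (r, S)
    p_i = np.stack(
        [
            np.where(n >= 1, np.where(g >= 0, g, 0).sum(axis=0) / (2 * np.maximum(n, 1)), np.nan)
            for g, n in zip(gs, n_i)
        ]
    )
    h_i = np.stack(
        [h.sum(axis=0) / np.maximum(n, 1) for h, n in zip(hets, n_i)]
    )
    usable = (n_i >= 1).all(axis=0)

    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        denom = a + b + c
        per_site = np.where(usable & (denom != 0), a / denom, np.nan)
    ok = usable & np.isfinite(denom) & (denom != 0)
    if not ok.any():
        raise ValueError("no usable polymorphic sites")
    weighted = float(a[ok].sum() / denom[ok].sum())
    return per_site, weighted


def validity_filter(score_table: pd.DataFrame, min_fraction: float = 0.10) -> pd.DataFrame:
    """Mark aspPS computed from less than ``min_fraction`` of the genome absent.

    Applies only to ancestry-specific rows (total-PS rows always pass);
    the threshold is strict: p equal to the threshold is retained.
    """
    out = score_table.copy()
    asp = ~out["ancestry"].str.startswith("TOTAL:") & (out["ancestry"] != "CASPS")
    low = asp & (out["p"] < min_fraction)
    out.loc[low, "pps"] = np.nan
    out.loc[low, "flag"] = "below_min_fraction"
    return out
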