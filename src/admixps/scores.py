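"""Partial polygenic scores: raw PS, pPS, aspPS, the sqrt(p) correction, casPS.

The raw PS of individual j is the effect-size-weighted sum of its allele
counts, S_j = sum_i beta_i x_ij, or equivalently the mean over the N_V
scored variants.  A *partial* PS restricts the mean to a genomic subset of
size N_S (for an aspPS, the subset a local-ancestry mask assigns to one
ancestry, per haplotype), and is standardized into a Z-score against the
mean and standard deviation of the same subset-restricted statistic in a
reference population.  With the full genome as the subset this reproduces
the classical standardized PS exactly.

Because the reference moments shrink with the subset (sigma ~ 1/sqrt(N_S)
for weakly dependent sites), a population-level mean shift in raw scores
appears in the standardized pPS attenuated by sqrt(p), p = N_S/N_V; the
optional 1/sqrt(p) correction undoes this at the cost of inflating the
variance, and is off by default since it degrades trait prediction.

Haplotypes are scored independently and merged into individual scores as
the SNP-count-weighted mean of the two haplotype raw values (equal to a
direct individual-level mean over both haplotypes' observed subset sites),
then standardized.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, AncestryMask, HaplotypeMatrix, WeightTable

__all__ = [
    "ReferenceStats",
    "raw_ps",
    "raw_pps",
    "reference_stats",
    "standardize_pps",
    "correct_sqrt_p",
    "compute_casps",
    "score_cohort",
    "shared_mask_pps",
]

TOTAL_LABEL = "TOTAL"
CASPS_LABEL = "CASPS"


@dataclass
class ReferenceStats:
    """Mean/sd of the raw (partial) PS across a reference population."""

    mu: float
    sigma: float
    n_individuals: int

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("reference needs at least 2 individuals")
        if not self.sigma > 0:
            raise ValueError("degenerate reference: sigma must be > 0")


def raw_ps(beta: np.ndarray, states: np.ndarray, form: str = "mean") -> float:
    """Raw PS of one haplotype: weighted sum or mean over observed sites."""
    beta = np.asarray(beta, dtype=float)
    states = np.asarray(states)
    obs = states != MISSING
    n = int(obs.sum())
    if n == 0:
        raise ValueError("no observed sites")
    s = float(beta[obs] @ states[obs])
    if form == "sum":
        return s
    if form == "mean":
        return s / n
    raise ValueError(f"unknown form {form!r}")


def raw_pps(
    beta: np.ndarray, states: np.ndarray, select: np.ndarray
) -> tuple[float | None, int]:
    """Raw partial PS of one haplotype over a site selection.

    Returns ``(mean, N_S)`` over selected, observed sites; ``(None, 0)``
    when the selection is empty (score absent, not numeric).
    """
    beta = np.asarray(beta, dtype=float)
    states = np.asarray(states)
    sel = np.asarray(select, dtype=bool) & (states != MISSING)
    n = int(sel.sum())
    if n == 0:
        return None, 0
    return float(beta[sel] @ states[sel]) / n, n


def _individual_raw(
    beta: np.ndarray, states: np.ndarray, sel_pair: tuple[np.ndarray, np.ndarray]
) -> tuple[float | None, int]:
    """SNP-count-weighted merge of the two haplotype raw pPS values."""
    s = 0.0
    n = 0
    for hap_states, sel in zip(states, sel_pair):
        obs = np.asarray(sel, dtype=bool) & (hap_states != MISSING)
        s += float(beta[obs] @ hap_states[obs])
        n += int(obs.sum())
    if n == 0:
        return None, 0
    return s / n, n


def reference_stats(
    reference: HaplotypeMatrix,
    weights: WeightTable | np.ndarray,
    selection: np.ndarray | tuple[np.ndarray, np.ndarray] | None = None,
) -> ReferenceStats:
    """Mean/sd of the raw pPS across all reference individuals.

    ``selection`` is the genomic subset: None for the full genome, one
    boolean site vector applied to both haplotypes, or a pair of vectors
    applied to the first/second haplotype respectively (the mask-transplant
    used when standardizing an admixed individual's aspPS).
    """
    beta = weights.beta if isinstance(weights, WeightTable) else np.asarray(weights, float)
    if selection is None:
        selection = np.ones(reference.n_sites, dtype=bool)
    if isinstance(selection, tuple):
        sel1, sel2 = selection
    else:
        sel1 = sel2 = np.asarray(selection, dtype=bool)
    vals = []
    for j in range(reference.n_samples):
        v, _ = _individual_raw(
            beta, reference.states[2 * j : 2 * j + 2], (sel1, sel2)
        )
        if v is None:
            raise ValueError("empty subset on a reference individual")
        vals.append(v)
    vals = np.array(vals)
    return ReferenceStats(
        mu=float(vals.mean()),
        sigma=float(vals.std(ddof=1)),
        n_individuals=len(vals),
    )


def standardize_pps(raw: float | np.ndarray, ref: ReferenceStats) -> float | np.ndarray:
    """Z-score a raw (partial) PS against reference moments."""
    return (raw - ref.mu) / ref.sigma


def correct_sqrt_p(pps: float | np.ndarray, p: float | np.ndarray):
    """Divide a pPS by sqrt(p) to undo the sqrt(p) attenuation of its mean.

    Inflates the standard deviation by 1/sqrt(p); off by default in
    :func:`score_cohort` because it degrades trait predictivity.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p must be in (0, 1]")
    out = np.asarray(pps, dtype=float) / np.sqrt(p)
    return float(out) if out.ndim == 0 else out


def compute_casps(aspps: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Combine per-ancestry aspPS into a casPS, weighting by ancestry fraction.

    ``aspps`` and ``fractions`` are (n_individuals, n_ancestries); NaN marks
    an absent aspPS (empty subset or validity-filtered), which is excluded
    from the sum and from fraction renormalization.  Rows with no
    contributing ancestry yield NaN.
    """
    aspps = np.atleast_2d(np.asarray(aspps, dtype=float))
    fractions = np.atleast_2d(np.asarray(fractions, dtype=float))
    if aspps.shape != fractions.shape:
        raise ValueError("aspps and fractions must have matching shapes")
    present = ~np.isnan(aspps)
    w = np.where(present, fractions, 0.0)
    tot = w.sum(axis=1)
    out = np.full(aspps.shape[0], np.nan)
    ok = tot > 0
    out[ok] = (np.where(present, aspps, 0.0) * w).sum(axis=1)[ok] / tot[ok]
    return out


# ---------------------------------------------------------------------------
# vectorized cohort machinery


def _hap_masked_sums(
    states: np.ndarray,
    beta: np.ndarray,
    sel: np.ndarray | None,
    dtype=np.float64,
    chunk: int = 2048,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-haplotype sum(beta*x) and observed-site count over a selection."""
    H = states.shape[0]
    sums = np.empty(H, dtype=np.float64)
    counts = np.empty(H, dtype=np.int64)
    b = beta.astype(dtype)
    for lo in range(0, H, chunk):
        hi = min(lo + chunk, H)
        block = states[lo:hi]
        obs = block != MISSING
        use = obs if sel is None else (obs & sel[lo:hi])
        x = np.where(use, block, 0).astype(dtype)
        sums[lo:hi] = x @ b
        counts[lo:hi] = use.sum(axis=1)
    return sums, counts


def _reference_moments_batch(
    ref: HaplotypeMatrix,
    beta: np.ndarray,
    sel1: np.ndarray,
    sel2: np.ndarray,
    counts: np.ndarray,
    dtype=np.float64,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference mu/sigma for each query individual's transplanted mask pair.

    ``sel1``/``sel2`` are (n_query, n_sites) boolean selections for the two
    haplotypes; the reference panel must have no missing calls.  Query j's
    reference raw pPS for reference individual r is
    (x_rA . beta*sel1_j + x_rB . beta*sel2_j) / counts_j.
    """
    if np.any(ref.states == MISSING):
        raise ValueError("reference panel must be complete (no missing calls)")
    RA = ref.states[0::2].astype(dtype)
    RB = ref.states[1::2].astype(dtype)
    b = beta.astype(dtype)
    nq = sel1.shape[0]
    mu = np.empty(nq)
    sd = np.empty(nq)
    for lo in range(0, nq, chunk):
        hi = min(lo + chunk, nq)
        B1 = (sel1[lo:hi] * b).T.astype(dtype, copy=False)
        B2 = (sel2[lo:hi] * b).T.astype(dtype, copy=False)
        S = RA @ B1 + RB @ B2
        vals = S / counts[lo:hi]
        mu[lo:hi] = vals.mean(axis=0)
        sd[lo:hi] = vals.std(axis=0, ddof=1)
    return mu, sd


def shared_mask_pps(
    genos: HaplotypeMatrix,
    weights: WeightTable | np.ndarray,
    selection: np.ndarray,
    reference: HaplotypeMatrix,
    dtype=np.float64,
) -> pd.DataFrame:
    """Standardized pPS of every individual under one shared site selection.

    Fast path for experiments that apply a single mask to a whole cohort:
    the reference moments are computed once.  Returns a DataFrame with
    sample, N_S, p, raw, pps.
    """
    beta = weights.beta if isinstance(weights, WeightTable) else np.asarray(weights, float)
    selection = np.asarray(selection, dtype=bool)
    sums, counts = _hap_masked_sums(
        genos.states, beta, np.broadcast_to(selection, genos.states.shape), dtype=dtype
    )
    s_ind = sums[0::2] + sums[1::2]
    n_ind = counts[0::2] + counts[1::2]
    if np.any(n_ind == 0):
        raise ValueError("empty subset for at least one individual")
    raw = s_ind / n_ind
    ref = reference_stats(reference, beta, selection)
    return pd.DataFrame(
        {
            "sample": genos.samples,
            "N_S": n_ind,
            "p": selection.mean(),
            "raw": raw,
            "pps": standardize_pps(raw, ref),
        }
    )


def score_cohort(
    genos: HaplotypeMatrix,
    weights: dict[str, WeightTable] | dict[str, np.ndarray],
    masks: AncestryMask | None = None,
    ref_panels: dict[str, HaplotypeMatrix] | None = None,
    *,
    min_fraction: float = 0.10,
    sqrt_p_correction: bool = False,
    dtype=np.float64,
) -> pd.DataFrame:
    """Score a cohort: total PS per weight set, aspPS per ancestry, casPS.

    ``weights`` maps ancestry name -> weight table (or aligned beta vector)
    from the GWAS matched to that ancestry; ``ref_panels`` maps ancestry ->
    the reference panel used to standardize scores built from that weight
    set.  Each admixed individual's aspPS is standardized against reference
    moments obtained by transplanting that individual's own haplotype mask
    pair onto the reference panel.  aspPS from less than ``min_fraction``
    of the genome are marked absent (validity filter) and excluded from the
    casPS combination; casPS is emitted when at least two weight sets are
    available and is not re-standardized.

    Returns a long DataFrame with columns sample, ancestry, N_S, p, raw,
    pps, flag; total-PS rows carry ancestry ``"TOTAL:<weight set>"``.
    """
    if ref_panels is None:
        raise ValueError("reference panels are required for standardization")
    betas = {
        a: (w.beta if isinstance(w, WeightTable) else np.asarray(w, float))
        for a, w in weights.items()
    }
    for a, b in betas.items():
        if len(b) != genos.n_sites:
            raise ValueError(f"weight set {a!r} not aligned to genotypes")
    rows: list[pd.DataFrame] = []
    samples = np.asarray(genos.samples)

    # total PS per weight set, standardized against its matched panel
    for a, b in betas.items():
        sums, counts = _hap_masked_sums(genos.states, b, None, dtype=dtype)
        s_ind = sums[0::2] + sums[1::2]
        n_ind = counts[0::2] + counts[1::2]
        raw = np.where(n_ind > 0, s_ind / np.maximum(n_ind, 1), np.nan)
        ref = reference_stats(ref_panels[a], b, None)
        rows.append(
            pd.DataFrame(
                {
                    "sample": samples,
                    "ancestry": f"{TOTAL_LABEL}:{a}",
                    "N_S": n_ind,
                    "p": 1.0,
                    "raw": raw,
                    "pps": standardize_pps(raw, ref),
                    "flag": "ok",
                }
            )
        )

    if masks is not None:
        if masks.labels.shape != genos.states.shape:
            raise ValueError("mask not co-indexed with genotypes")
        # ancestry-matched weight set where available; with a single weight
        # set, every ancestry component is scored against that GWAS (the
        # population-level aspPS configuration)
        if len(betas) == 1:
            only = next(iter(betas))
            weight_for = {a: only for a in masks.ancestries}
        else:
            weight_for = {a: a for a in masks.ancestries if a in betas}
        scored = list(weight_for)
        asp_vals = np.full((genos.n_samples, len(scored)), np.nan)
        asp_fracs = np.zeros((genos.n_samples, len(scored)))
        for ai, a in enumerate(scored):
            b = betas[weight_for[a]]
            code = masks.code(a)
            sel = masks.labels == code
            sums, counts = _hap_masked_sums(genos.states, b, sel, dtype=dtype)
            s_ind = sums[0::2] + sums[1::2]
            n_ind = counts[0::2] + counts[1::2]
            frac = sel.mean(axis=1)
            p_ind = 0.5 * (frac[0::2] + frac[1::2])
            raw = np.where(n_ind > 0, s_ind / np.maximum(n_ind, 1), np.nan)

            pps = np.full(genos.n_samples, np.nan)
            flag = np.where(n_ind == 0, "empty_subset", "ok").astype(object)
            todo = n_ind > 0
            if todo.any():
                sel_obs = sel & (genos.states != MISSING)
                idx = np.where(todo)[0]
                mu, sd = _reference_moments_batch(
                    ref_panels[weight_for[a]],
                    b,
                    sel_obs[2 * idx],
                    sel_obs[2 * idx + 1],
                    n_ind[idx],
                    dtype=dtype,
                )
                good = sd > 0
                pps[idx[good]] = (raw[idx[good]] - mu[good]) / sd[good]
                flag[idx[~good]] = "degenerate_reference"
            if sqrt_p_correction:
                ok = (~np.isnan(pps)) & (p_ind > 0)
                pps[ok] = pps[ok] / np.sqrt(p_ind[ok])
            low = p_ind < min_fraction
            flag[low & (flag == "ok")] = "below_min_fraction"
            valid = ~low & ~np.isnan(pps)
            asp_vals[valid, ai] = pps[valid]
            asp_fracs[:, ai] = p_ind
            pps_out = np.where(low, np.nan, pps)
            rows.append(
                pd.DataFrame(
                    {
                        "sample": samples,
                        "ancestry": a,
                        "N_S": n_ind,
                        "p": p_ind,
                        "raw": raw,
                        "pps": pps_out,
                        "flag": flag,
                    }
                )
            )
        if len(scored) >= 2 and len(betas) >= 2:
            cas = compute_casps(asp_vals, asp_fracs)
            rows.append(
                pd.DataFrame(
                    {
                        "sample": samples,
                        "ancestry": CASPS_LABEL,
                        "N_S": 0,
                        "p": asp_fracs.sum(axis=1),
                        "raw": np.nan,
                        "pps": cas,
                        "flag": np.where(np.isnan(cas), "absent", "ok"),
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True)
    return out
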