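"""Synthetic cohorts for exercising and validating the scoring pipeline.

Two generators are provided.

``simulate_transferability`` is an abstract, genotype-free model of PS
portability: each individual carries a proportion p of ancestry A and
1 - p of ancestry B; the A-derived score component is unbiased and
correlates r_A with the trait, while the B component is directionally
biased (mean shift b) and attenuated (correlation t * r_A, with
transferability t in [0, 1]).  The observed total PS mixes the two with
weight p, so the four regression models of interest (PS_A alone, PS_A
plus p, aspPS_A alone, casPS) can be compared under controlled bias and
transferability.

``simulate_admixed_cohort`` is a genotype-level simulator: two ancestral
populations diverge under a Balding–Nichols model with drift parameter F;
admixed haplotypes are tiled with ancestry tracts from a Markov switch
process with g switch events per Morgan (g = generations since admixture,
expected tract length 1/g Morgans); alleles are drawn from tract-matched
ancestral frequencies; the trait is additive with *local-ancestry-specific*
effect sizes whose cross-ancestry correlation rho tunes effect
transferability, plus Gaussian noise set to reach heritability h^2.
Per-ancestry GWAS weight tables are noisy estimates of the true effects
with sampling error driven by an effective GWAS sample size, emulating
power differences between biobanks.  Everything downstream (true masks,
degraded dosages, reference panels, phenotypes, truth record) is returned
for recovery tests, and can be serialized to the package's file formats
for end-to-end CLI runs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import UNKNOWN, AncestryDosage, AncestryMask, HaplotypeMatrix, WeightTable
from .scores import compute_casps

__all__ = [
    "TransferabilityConfig",
    "simulate_transferability",
    "evaluate_transferability_models",
    "CohortConfig",
    "SimCohort",
    "simulate_admixed_cohort",
    "degrade_dosages",
    "write_cohort",
]

# non-palindromic ref/alt pairs used for simulated SNPs
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


def _draw_p(dist, n: int, rng: np.random.Generator) -> np.ndarray:
    kind, *args = dist
    if kind == "fixed":
        return np.full(n, float(args[0]))
    if kind == "uniform":
        return rng.uniform(args[0], args[1], n)
    if kind == "beta":
        return rng.beta(args[0], args[1], n)
    raise ValueError(f"unknown distribution {dist!r}")


@dataclass
class TransferabilityConfig:
    """Abstract PS-portability model parameters.

    r_a is the correlation of the unbiased A-ancestry score with the
    trait; transferability t scales the B component's correlation to
    t * r_a; bias b shifts the B component's mean; r_b is the correlation
    of the independent B-calibrated score (defaults to r_a).  p_dist is
    the individual-level distribution of the ancestry-A proportion.
    """

    n: int = 2000
    p_dist: tuple = ("beta", 6.0, 6.0)
    r_a: float = 0.5
    transferability: float = 0.5
    bias: float = 1.0
    r_b: float | None = None
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_a <= 1.0:
            raise ValueError("r_a must be in [0, 1]")
        if not 0.0 <= self.transferability <= 1.0:
            raise ValueError("transferability must be in [0, 1]")
        rb = self.r_a if self.r_b is None else self.r_b
        if not 0.0 <= rb <= 1.0:
            raise ValueError("r_b must be in [0, 1]")


def _correlated(y: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    return r * y + np.sqrt(1.0 - r * r) * rng.standard_normal(len(y))


def simulate_transferability(
    cfg: TransferabilityConfig, seed=None
) -> pd.DataFrame:
    """Simulate per-individual trait and score components.

    Returns columns: trait, p, ps_a (total PS from the A-ancestry GWAS,
    standardized against a pure-A reference), aspps_a, aspps_b, casps.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    y = rng.standard_normal(cfg.n)
    p = _draw_p(cfg.p_dist, cfg.n, rng)
    a_comp = _correlated(y, cfg.r_a, rng)
    b_comp = _correlated(y, cfg.transferability * cfg.r_a, rng) + cfg.bias
    r_b = cfg.r_a if cfg.r_b is None else cfg.r_b
    aspps_b = _correlated(y, r_b, rng)
    # a pure-A reference individual's total PS is the A component itself
    # (mean 0, sd 1), so standardization against that reference is identity
    ps_a = p * a_comp + (1.0 - p) * b_comp
    casps = compute_casps(
        np.column_stack([a_comp, aspps_b]), np.column_stack([p, 1.0 - p])
    )
    return pd.DataFrame(
        {
            "trait": y,
            "p": p,
            "ps_a": ps_a,
            "aspps_a": a_comp,
            "aspps_b": aspps_b,
            "casps": casps,
        }
    )


def evaluate_transferability_models(df: pd.DataFrame) -> dict[str, float]:
    """R^2 of the four trait-regression models on a simulated sample.

    Models: total PS alone; total PS plus ancestry proportion p; aspPS_A
    alone; casPS alone.
    """
    from .predictivity import fit_models, realized_r2

    out = {}
    for label, cols in {
        "ps_a": ["ps_a"],
        "ps_a_plus_p": ["ps_a", "p"],
        "aspps_a": ["aspps_a"],
        "casps": ["casps"],
    }.items():
        pair = fit_models(df, "trait", [], cols, family="gaussian")
        out[label] = realized_r2(pair.extended, df, "trait")
    return out


# ---------------------------------------------------------------------------
# genotype-level simulator


@dataclass
class CohortConfig:
    """Admixed-cohort simulator parameters.

    fst is the Balding–Nichols drift parameter F between the two ancestral
    populations; generations g sets the ancestry-switch rate (per Morgan)
    of the tract process; admixture_dist draws each individual's
    ancestry-0 proportion; rho is the cross-ancestry correlation of true
    per-SNP effects; gwas_n gives the effective GWAS sample size behind
    each ancestry's weight table (larger = less estimation noise).
    """

    n_individuals: int = 1000
    n_snps: int = 5000
    fst: float = 0.1
    generations: float = 10.0
    admixture_dist: tuple = ("beta", 2.0, 2.0)
    map_morgans: float = 35.0
    rho: float = 0.6
    h2: float = 0.5
    prevalence: float | None = None
    ancestries: tuple = ("EUR", "EAS")
    gwas_n: dict = field(default_factory=lambda: {"EUR": 100_000, "EAS": 20_000})
    n_reference: int = 200
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("infeasible h2: must be in (0, 1]")
        if len(self.ancestries) != 2:
            raise ValueError("the tuned simulator is two-way; provide 2 ancestries")


@dataclass
class SimCohort:
    config: CohortConfig
    genos: HaplotypeMatrix
    true_mask: AncestryMask
    weights: dict[str, WeightTable]
    ref_panels: dict[str, HaplotypeMatrix]
    phenotypes: pd.DataFrame
    truth: dict


def _balding_nichols_freqs(
    n_snps: int, fst: float, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    q = rng.uniform(0.05, 0.95, n_snps)
    a = q * (1.0 - fst) / fst
    b = (1.0 - q) * (1.0 - fst) / fst
    freqs = np.stack([rng.beta(a, b) for _ in range(n_pops)])
    return np.clip(freqs, 0.01, 0.99)


def _tract_labels(
    morgans: np.ndarray,
    length: float,
    prop0: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-haplotype ancestry labels at each site plus switch counts.

    Switch events follow a Poisson process with ``rate`` events per
    Morgan; each inter-event segment's ancestry is drawn independently
    from the haplotype's admixture proportions, so a "tract" is an
    inter-switch segment and its mean length is exactly 1/rate Morgans.
    """
    n_hap = len(prop0)
    labels = np.empty((n_hap, len(morgans)), dtype=np.int8)
    n_switch = rng.poisson(rate * length, n_hap)
    for h in range(n_hap):
        cuts = np.sort(rng.uniform(0.0, length, n_switch[h]))
        seg_anc = (rng.random(n_switch[h] + 1) >= prop0[h]).astype(np.int8)
        labels[h] = seg_anc[np.searchsorted(cuts, morgans, side="right")]
    return labels, n_switch


def simulate_admixed_cohort(cfg: CohortConfig, seed=None) -> SimCohort:
    """Generate a phased admixed cohort with truth for recovery tests."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n, S = cfg.n_individuals, cfg.n_snps
    L, g = cfg.map_morgans, cfg.generations
    anc_names = list(cfg.ancestries)

    step = L / S
    morgans = (np.arange(S) + 0.5) * step
    pos = np.asarray(np.round(morgans * 1e6), dtype=np.int64) + 1
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), S)
    ref_alleles = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    alt_alleles = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    sites = pd.DataFrame(
        {"chrom": "1", "pos": pos, "ref": ref_alleles, "alt": alt_alleles}
    )

    freqs = _balding_nichols_freqs(S, cfg.fst, 2, rng)

    props = _draw_p(cfg.admixture_dist, n, rng)
    hap_props = np.repeat(props, 2)
    labels, n_switch = _tract_labels(morgans, L, hap_props, g, rng)

    states = np.empty((2 * n, S), dtype=np.int8)
    chunk = max(1, int(2e7) // S)
    freqs32 = freqs.astype(np.float32)
    col = np.arange(S)[None, :]
    for lo in range(0, 2 * n, chunk):
        hi = min(lo + chunk, 2 * n)
        p_site = freqs32[labels[lo:hi], col]
        states[lo:hi] = rng.random((hi - lo, S), dtype=np.float32) < p_site

    samples = [f"S{j:05d}" for j in range(n)]
    genos = HaplotypeMatrix(samples=samples, sites=sites, states=states)
    hap_ids = genos.hap_ids
    true_mask = AncestryMask(ancestries=anc_names, hap_ids=hap_ids, labels=labels)

    # ancestry-specific true effects with cross-ancestry correlation rho
    z1 = rng.standard_normal(S)
    z2 = rng.standard_normal(S)
    scale = 1.0 / np.sqrt(S)
    beta = {
        anc_names[0]: z1 * scale,
        anc_names[1]: (cfg.rho * z1 + np.sqrt(1.0 - cfg.rho**2) * z2) * scale,
    }

    # genetic value: each allele copy weighted by its own ancestry's effect;
    # computed as X b_1 + (X o I_0)(b_0 - b_1) to save one masked product
    g_hap = np.zeros(2 * n)
    b1 = beta[anc_names[1]].astype(np.float32)
    bdiff = (beta[anc_names[0]] - beta[anc_names[1]]).astype(np.float32)
    for lo in range(0, 2 * n, chunk):
        hi = min(lo + chunk, 2 * n)
        x = states[lo:hi].astype(np.float32)
        g_hap[lo:hi] = x @ b1 + (x * (labels[lo:hi] == 0)) @ bdiff
    g_ind = g_hap[0::2] + g_hap[1::2]

    var_g = g_ind.var()
    if var_g == 0:
        raise ValueError("degenerate genetic values; increase n_snps")
    sigma_e = np.sqrt(var_g * (1.0 - cfg.h2) / cfg.h2) if cfg.h2 < 1 else 0.0
    y = g_ind + rng.normal(0.0, sigma_e, n)

    pheno = pd.DataFrame(
        {
            "sample": samples,
            "trait": y,
            "sex": rng.integers(0, 2, n),
            "age": rng.uniform(40.0, 70.0, n).round(1),
            "admixture_true": props,
        }
    )
    if cfg.prevalence is not None:
        cut = np.quantile(y, 1.0 - cfg.prevalence)
        pheno["case"] = (y > cut).astype(int)

    # noisy GWAS weight tables, one per ancestry
    weights = {}
    sd_y = y.std()
    for ai, anc in enumerate(anc_names):
        f = freqs[ai]
        se = sd_y / np.sqrt(2.0 * cfg.gwas_n[anc] * f * (1.0 - f))
        bhat = beta[anc] + rng.normal(0.0, se)
        weights[anc] = WeightTable(
            table=pd.DataFrame(
                {
                    "chrom": "1",
                    "pos": pos,
                    "effect_allele": alt_alleles,
                    "other_allele": ref_alleles,
                    "beta": bhat,
                }
            )
        )

    # unadmixed reference panels drawn from each ancestral frequency vector
    ref_panels = {}
    for ai, anc in enumerate(anc_names):
        rstates = (
            rng.random((2 * cfg.n_reference, S)) < freqs[ai][None, :]
        ).astype(np.int8)
        ref_panels[anc] = HaplotypeMatrix(
            samples=[f"R{anc}{j:04d}" for j in range(cfg.n_reference)],
            sites=sites,
            states=rstates,
        )

    truth = {
        "beta": beta,
        "genetic_value": g_ind,
        "admixture_proportion": props,
        "realized_fraction0": (labels == 0).mean(axis=1),
        "n_switches": n_switch,
        "mean_tract_morgans": float(np.mean(L / (n_switch + 1))),
        "freqs": freqs,
        "sigma_e": float(sigma_e),
        "var_g": float(var_g),
    }
    return SimCohort(
        config=cfg,
        genos=genos,
        true_mask=true_mask,
        weights=weights,
        ref_panels=ref_panels,
        phenotypes=pheno,
        truth=truth,
    )


def degrade_dosages(
    mask: AncestryMask, error_rate: float, softness: float, seed=None
) -> AncestryDosage:
    """Turn a true hard mask into noisy posterior dosages.

    The displayed label receives dosage 1 - softness (the rest spread
    evenly over other ancestries); a fraction ``error_rate`` of sites
    displays a wrong label instead.  Sites UNKNOWN in the input get a flat
    dosage.  With error 0 and softness 0, hard-calling recovers the truth
    exactly.
    """
    if not (0.0 <= error_rate <= 1.0 and 0.0 <= softness <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    K = len(mask.ancestries)
    shown = mask.labels.copy().astype(np.int64)
    flip = (rng.random(shown.shape) < error_rate) & (shown != UNKNOWN)
    offset = rng.integers(1, K, shown.shape)
    shown[flip] = (shown[flip] + offset[flip]) % K

    dos = np.full((*shown.shape, K), softness / max(K - 1, 1))
    known = shown != UNKNOWN
    hh, ss = np.nonzero(known)
    dos[hh, ss, shown[hh, ss]] = 1.0 - softness
    dos[~known] = 1.0 / K
    return AncestryDosage(
        ancestries=list(mask.ancestries), hap_ids=list(mask.hap_ids), dosages=dos
    )


def write_cohort(cohort: SimCohort, outdir) -> dict[str, str]:
    """Serialize a simulated cohort to the package's file formats."""
    from . import io_formats

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    vcf = out / "cohort.vcf"
    io_formats.write_phased_vcf(cohort.genos, vcf)
    paths["vcf"] = str(vcf)
    mask = out / "true_mask.tsv"
    io_formats.write_mask(cohort.true_mask, cohort.genos.sites, mask)
    paths["mask"] = str(mask)
    for anc, wt in cohort.weights.items():
        wp = out / f"weights_{anc}.tsv"
        io_formats.write_weights(wt, wp)
        paths[f"weights_{anc}"] = str(wp)
    for anc, panel in cohort.ref_panels.items():
        rp = out / f"reference_{anc}.vcf"
        io_formats.write_phased_vcf(panel, rp)
        paths[f"reference_{anc}"] = str(rp)
    ph = out / "phenotypes.tsv"
    cohort.phenotypes.to_csv(ph, sep="\t", index=False)
    paths["phenotypes"] = str(ph)
    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cohort.config).items()
        },
        "mean_tract_morgans": cohort.truth["mean_tract_morgans"],
        "var_g": cohort.truth["var_g"],
        "sigma_e": cohort.truth["sigma_e"],
        "mean_admixture": float(np.mean(cohort.truth["admixture_proportion"])),
    }
    ty = out / "truth.yaml"
    with open(ty, "w") as fh:
        yaml.safe_dump(truth, fh)
    paths["truth"] = str(ty)
    return paths
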