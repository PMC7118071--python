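"""Hard-calling, summarizing and permuting local-ancestry masks.

A haplotype's mask is the genomic subset of SNPs confidently assigned to
each ancestral population.  Dosages are hard-called by assigning each site
to the ancestry with the highest posterior dosage provided it reaches a
threshold (default 0.9), labelling it unknown otherwise; exact argmax ties
are also labelled unknown.  The module also provides the two null-mask
constructions used for significance testing: derangement shuffling of
observed masks among individuals, and synthetic masks with prescribed
ancestry fractions.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import UNKNOWN, UNKNOWN_LABEL, AncestryDosage, AncestryMask

__all__ = [
    "call_mask",
    "ancestry_fraction",
    "derangement",
    "shuffle_masks",
    "random_mask",
]


def call_mask(dosage: AncestryDosage, threshold: float = 0.9) -> AncestryMask:
    """Hard-call dosages into per-site ancestry labels.

    A site is assigned to the argmax ancestry when its dosage reaches
    ``threshold``, and to UNKNOWN otherwise or on an exact tie.
    """
    k = len(dosage.ancestries)
    if not (1.0 / k < threshold <= 1.0):
        raise ValueError(f"threshold must be in (1/{k}, 1]")
    d = dosage.dosages
    best = d.argmax(axis=2)
    top = np.take_along_axis(d, best[:, :, None], axis=2)[:, :, 0]
    tie = (d == top[:, :, None]).sum(axis=2) > 1
    labels = np.where((top >= threshold) & ~tie, best, UNKNOWN).astype(np.int8)
    return AncestryMask(
        ancestries=list(dosage.ancestries),
        hap_ids=list(dosage.hap_ids),
        labels=labels,
    )


def ancestry_fraction(mask: AncestryMask, level: str = "haplotype") -> pd.DataFrame:
    """Fraction of sites assigned to each ancestry (UNKNOWN included).

    ``level="haplotype"`` returns one row per haplotype; ``"individual"``
    averages the two haplotypes of each individual.  Fractions sum to 1
    across the ancestry columns plus UNKNOWN.
    """
    if mask.n_sites == 0:
        raise ValueError("mask has zero sites")
    counts = np.stack(
        [(mask.labels == i).mean(axis=1) for i in range(len(mask.ancestries))]
        + [(mask.labels == UNKNOWN).mean(axis=1)],
        axis=1,
    )
    df = pd.DataFrame(
        counts, columns=mask.ancestries + [UNKNOWN_LABEL], index=mask.hap_ids
    )
    if level == "haplotype":
        return df
    if level == "individual":
        samples = [h.rsplit(".", 1)[0] for h in mask.hap_ids]
        out = df.groupby(samples, sort=False).mean()
        out.index.name = "sample"
        return out
    raise ValueError(f"unknown level {level!r}")


def derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample a fixed-point-free permutation of ``range(n)`` uniformly.

    Rejection sampling from uniform permutations is exactly uniform over
    derangements (acceptance probability ~ 1/e).
    """
    if n < 2:
        raise ValueError("a derangement requires at least 2 individuals")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def shuffle_masks(mask: AncestryMask, seed) -> tuple[AncestryMask, np.ndarray]:
    """Reassign observed mask *pairs* among individuals without fixed points.

    Both haplotype masks of an individual move together.  Returns the
    permuted mask and the permutation (entry j = donor individual of the
    mask now held by individual j).
    """
    if len(mask.hap_ids) % 2:
        raise ValueError("mask must hold haplotype pairs (even row count)")
    n = len(mask.hap_ids) // 2
    rng = np.random.default_rng(seed)
    perm = derangement(n, rng)
    return mask.permuted(perm), perm


def random_mask(
    n_sites: int,
    fractions: dict[str, float],
    seed,
    mode: str = "iid",
    *,
    n_haplotypes: int = 1,
    mean_block: float = 100.0,
    hap_ids: list[str] | None = None,
) -> AncestryMask:
    """Generate masks with prescribed expected ancestry fractions.

    ``mode="iid"`` draws each site independently; ``mode="blocky"`` draws
    contiguous blocks with geometric lengths of mean ``mean_block`` sites,
    each block labelled independently from ``fractions``.  ``fractions``
    may include UNKNOWN.
    """
    names = list(fractions)
    probs = np.array([fractions[a] for a in names], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError("fractions must be nonnegative and sum to 1")
    ancestries = [a for a in names if a != UNKNOWN_LABEL]
    codes = np.array(
        [UNKNOWN if a == UNKNOWN_LABEL else ancestries.index(a) for a in names],
        dtype=np.int8,
    )
    rng = np.random.default_rng(seed)
    labels = np.empty((n_haplotypes, n_sites), dtype=np.int8)
    if mode == "iid":
        draw = rng.choice(len(names), size=(n_haplotypes, n_sites), p=probs)
        labels = codes[draw]
    elif mode == "blocky":
        if mean_block < 1:
            raise ValueError("mean_block must be >= 1 site")
        for h in range(n_haplotypes):
            filled = 0
            row = np.empty(n_sites, dtype=np.int8)
            while filled < n_sites:
                length = rng.geometric(1.0 / mean_block)
                row[filled : filled + length] = codes[rng.choice(len(names), p=probs)]
                filled += length
            labels[h] = row
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if hap_ids is None:
        hap_ids = [f"H{i // 2}.{i % 2}" for i in range(n_haplotypes)]
    return AncestryMask(ancestries=ancestries, hap_ids=hap_ids, labels=labels)
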