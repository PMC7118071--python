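"""Core in-memory containers shared across the package.

All genotype-level objects are indexed by *haplotype*: a phased individual
contributes two rows, ordered ``(sample, 0)`` then ``(sample, 1)``.  Sites
are 1-based (VCF convention) and identified by ``(chrom, pos)``; after
harmonization the allelic state counts copies of the weight table's
*effect* allele.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel state for a missing allele call
MISSING = -1
#: sentinel mask label for sites not confidently assigned to any ancestry
UNKNOWN = -1
#: name used for the unknown label in serialized masks and fraction tables
UNKNOWN_LABEL = "UNKNOWN"

WEIGHT_COLUMNS = ["chrom", "pos", "effect_allele", "other_allele", "beta"]
VALID_ALLELES = frozenset("ACGT")


@dataclass
class WeightTable:
    """Per-SNP GWAS effect sizes with effect-allele orientation.

    ``table`` has columns chrom, pos, effect_allele, other_allele, beta and
    optionally pvalue / freq; one row per SNP, unique on (chrom, pos,
    effect_allele, other_allele).  ``filter_log`` records how many input
    rows each loading filter removed.
    """

    table: pd.DataFrame
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in WEIGHT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"weight table missing columns: {missing}")
        keys = list(zip(self.table["chrom"], self.table["pos"]))
        if len(set(keys)) != len(keys):
            dup = pd.Series(keys).value_counts()
            bad = dup[dup > 1].index[0]
            raise ValueError(f"duplicate snp_key in weight table: {bad}")
        beta = np.asarray(self.table["beta"], dtype=float)
        if not np.all(np.isfinite(beta)):
            raise ValueError("non-finite beta in weight table")
        for col in ("effect_allele", "other_allele"):
            bad = ~self.table[col].isin(VALID_ALLELES)
            if bad.any():
                raise ValueError(
                    f"invalid {col} values: {sorted(self.table.loc[bad, col].unique())}"
                )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def beta(self) -> np.ndarray:
        return np.asarray(self.table["beta"], dtype=float)

    @property
    def snp_keys(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays(
            [self.table["chrom"], self.table["pos"]], names=["chrom", "pos"]
        )


@dataclass
class HaplotypeMatrix:
    """Phased allelic states, one row per haplotype, one column per site.

    ``sites`` has columns chrom, pos, ref, alt (one row per site, co-ordered
    with ``states`` columns).  ``states`` is an int8 array of shape
    ``(2 * n_samples, n_sites)`` with values {0, 1, MISSING}.
    """

    samples: list[str]
    sites: pd.DataFrame
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (2 * len(self.samples), len(self.sites)):
            raise ValueError(
                f"states shape {self.states.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        # int8 in [-1, 1] is exactly {MISSING, 0, 1}
        if self.states.size and not (
            self.states.min() >= MISSING and self.states.max() <= 1
        ):
            raise ValueError("allelic states must be 0, 1 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def hap_ids(self) -> list[str]:
        return [f"{s}.{h}" for s in self.samples for h in (0, 1)]

    @property
    def snp_keys(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays(
            [self.sites["chrom"], self.sites["pos"]], names=["chrom", "pos"]
        )

    def subset_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            states=self.states[:, idx],
        )

    def subset_samples(self, names: list[str]) -> "HaplotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = []
        for s in names:
            if s not in pos:
                raise KeyError(f"unknown sample {s!r}")
            rows.extend((2 * pos[s], 2 * pos[s] + 1))
        return HaplotypeMatrix(
            samples=list(names), sites=self.sites, states=self.states[rows]
        )


@dataclass
class AncestryDosage:
    """Per-haplotype, per-site posterior ancestry dosages.

    ``dosages`` has shape ``(n_haplotypes, n_sites, n_ancestries)``; rows
    sum to 1 over the last axis.
    """

    ancestries: list[str]
    hap_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 3 or self.dosages.shape[2] != len(self.ancestries):
            raise ValueError("dosages must be (n_hap, n_sites, n_ancestries)")
        if self.dosages.shape[0] != len(self.hap_ids):
            raise ValueError("dosage rows inconsistent with hap_ids")
        sums = self.dosages.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > 0.05):
            h, s = np.argwhere(np.abs(sums - 1.0) > 0.05)[0]
            raise ValueError(
                f"dosage sum {sums[h, s]:.3f} at haplotype {self.hap_ids[h]!r}, "
                f"site index {s} outside tolerance"
            )
        # renormalize small deviations so downstream argmax logic is exact
        self.dosages = self.dosages / sums[:, :, None]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]


@dataclass
class AncestryMask:
    """Hard per-haplotype per-site ancestry labels.

    ``labels`` is int8 of shape ``(n_haplotypes, n_sites)``; values index
    into ``ancestries`` or equal :data:`UNKNOWN`.
    """

    ancestries: list[str]
    hap_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 2 or self.labels.shape[0] != len(self.hap_ids):
            raise ValueError("labels must be (n_hap, n_sites)")
        if self.labels.size and (
            self.labels.max() >= len(self.ancestries) or self.labels.min() < UNKNOWN
        ):
            raise ValueError("mask labels out of range")

    @property
    def n_sites(self) -> int:
        return self.labels.shape[1]

    def code(self, ancestry: str) -> int:
        return self.ancestries.index(ancestry)

    def permuted(self, individual_order: np.ndarray) -> "AncestryMask":
        """Reassign mask *pairs* to individuals following ``individual_order``.

        ``individual_order[j]`` is the individual whose haplotype pair the
        j-th individual receives; haplotype pairing is preserved.
        """
        order = np.asarray(individual_order)
        rows = np.empty(2 * len(order), dtype=int)
        rows[0::2] = 2 * order
        rows[1::2] = 2 * order + 1
        return AncestryMask(
            ancestries=list(self.ancestries),
            hap_ids=list(self.hap_ids),
            labels=self.labels[rows],
        )
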