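"""Readers/writers for external formats and weight/genotype harmonization.

Formats handled here:

* GWAS weight tables — TSV with a configurable column map (default header
  ``CHR POS A1 A2 BETA P FREQ``, A1 = effect allele).  Loading applies the
  standard summary-statistics hygiene filters: palindromic (A/T, C/G) SNPs
  are removed, and SNPs with MAF < 0.01 are removed when a frequency column
  is present.  Input is assumed pre-clumped.
* Phased genotypes — VCF 4.x via cyvcf2; biallelic SNPs only.
* Local ancestry — either a per-haplotype ancestry *dosage* TSV (dialect
  documented at :func:`read_local_ancestry`) or RFMix2 ``.msp.tsv`` tract
  intervals.
* Hard ancestry masks and score tables — plain TSV, round-trip exact.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    UNKNOWN,
    UNKNOWN_LABEL,
    AncestryDosage,
    AncestryMask,
    HaplotypeMatrix,
    WeightTable,
)

__all__ = [
    "WeightTable",
    "HaplotypeMatrix",
    "AncestryDosage",
    "AncestryMask",
    "FormatError",
    "read_weights",
    "write_weights",
    "read_phased_vcf",
    "write_phased_vcf",
    "harmonize",
    "harmonize_multi",
    "read_local_ancestry",
    "mask_from_tracts",
    "write_mask",
    "read_mask",
    "write_dosages",
    "write_scores",
    "read_scores",
]

DEFAULT_WEIGHT_COLUMNS = {
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "A1",
    "other_allele": "A2",
    "beta": "BETA",
    "pvalue": "P",
    "freq": "FREQ",
}

PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    pair = a1 + a2
    return pair.isin(["AT", "TA", "CG", "GC"])


def read_weights(
    path,
    column_map: dict | None = None,
    *,
    maf_min: float = 0.01,
    drop_palindromic: bool = True,
) -> WeightTable:
    """Load a pre-clumped GWAS weight table from TSV.

    ``column_map`` maps canonical names (chrom, pos, effect_allele,
    other_allele, beta, and optionally pvalue, freq) to header names in the
    file.  Palindromic SNPs are dropped; the MAF filter applies only when a
    frequency column is present.  Per-filter drop counts are recorded in
    ``WeightTable.filter_log``.
    """
    cmap = dict(DEFAULT_WEIGHT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(
        path, sep="\t", dtype={cmap["chrom"]: str}, float_precision="round_trip"
    )
    for canon in ("chrom", "pos", "effect_allele", "other_allele", "beta"):
        if cmap[canon] not in df.columns:
            raise FormatError(
                f"weights file {path} missing mandatory column "
                f"{cmap[canon]!r} (for {canon})"
            )
    rename = {v: k for k, v in cmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    df["pos"] = df["pos"].astype(np.int64)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    log: dict[str, int] = {"input_rows": len(df)}
    if drop_palindromic:
        pal = _is_palindromic(df["effect_allele"], df["other_allele"])
        log["dropped_palindromic"] = int(pal.sum())
        df = df[~pal]
    else:
        log["dropped_palindromic"] = 0
    if "freq" in df.columns:
        maf = np.minimum(df["freq"].astype(float), 1.0 - df["freq"].astype(float))
        low = maf < maf_min
        log["dropped_maf"] = int(low.sum())
        df = df[~low]
    else:
        log["dropped_maf"] = 0
    log["retained_rows"] = len(df)

    keep = [c for c in ("chrom", "pos", "effect_allele", "other_allele", "beta", "pvalue", "freq") if c in df.columns]
    return WeightTable(table=df[keep].reset_index(drop=True), filter_log=log)


def write_weights(weights: WeightTable, path) -> None:
    """Write a weight table in the default external dialect (CHR POS A1 A2 ...)."""
    df = weights.table.rename(columns=DEFAULT_WEIGHT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_phased_vcf(
    path,
    sample_subset: list[str] | None = None,
    *,
    strict_phase: bool = True,
    multiallelic: str = "skip",
) -> HaplotypeMatrix:
    """Read phased biallelic SNPs from a VCF into a :class:`HaplotypeMatrix`.

    Multiallelic records are skipped (and counted) under the default policy;
    ``multiallelic="error"`` raises instead.  Under ``strict_phase`` an
    unphased *heterozygous* genotype is an error naming the first offending
    record; unphased homozygotes are accepted since their phase is
    unambiguous, and missing calls ``./.`` yield two missing states.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample_subset is not None:
        vcf.set_samples(sample_subset)
    samples = list(vcf.samples)
    rows: list[dict] = []
    states_cols: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0] not in "ACGT" or var.REF not in "ACGT":
            if multiallelic == "error":
                raise FormatError(
                    f"non-biallelic-SNP record at {var.CHROM}:{var.POS}"
                )
            n_multi += 1
            continue
        col = np.empty(2 * len(samples), dtype=np.int8)
        for j, (a0, a1, phased) in enumerate(var.genotypes):
            if a0 < 0 or a1 < 0:
                col[2 * j] = MISSING if a0 < 0 else a0
                col[2 * j + 1] = MISSING if a1 < 0 else a1
                continue
            if not phased and a0 != a1 and strict_phase:
                raise FormatError(
                    f"unphased heterozygote for sample {samples[j]!r} at "
                    f"{var.CHROM}:{var.POS}"
                )
            col[2 * j] = a0
            col[2 * j + 1] = a1
        rows.append(
            {"chrom": var.CHROM, "pos": var.POS, "ref": var.REF, "alt": var.ALT[0]}
        )
        states_cols.append(col)
    vcf.close()
    if not rows:
        raise FormatError(f"no usable biallelic SNP records in {path}")
    sites = pd.DataFrame(rows)
    states = np.stack(states_cols, axis=1)
    hm = HaplotypeMatrix(samples=samples, sites=sites, states=states)
    hm.n_multiallelic_skipped = n_multi
    return hm


def write_phased_vcf(genos: HaplotypeMatrix, path) -> None:
    """Write a minimal phased VCF 4.2 (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(genos.sites["chrom"]):
            last = int(genos.sites.loc[genos.sites["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={last + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genos.samples)
            + "\n"
        )
        st = genos.states
        for i, site in enumerate(genos.sites.itertuples()):
            gts = []
            for j in range(genos.n_samples):
                a0, a1 = st[2 * j, i], st[2 * j + 1, i]
                gts.append(
                    f"{'.' if a0 == MISSING else a0}|{'.' if a1 == MISSING else a1}"
                )
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def harmonize(
    weights: WeightTable, genos: HaplotypeMatrix
) -> tuple[WeightTable, HaplotypeMatrix]:
    """Align a weight table and genotype matrix on shared SNPs.

    Sites are intersected on (chrom, pos).  Where the weight table's
    effect/other alleles equal the VCF's alt/ref the states already count
    the effect allele; where they equal ref/alt the states are flipped
    (x -> 1 - x, missing preserved); any other allele combination is
    dropped and counted.  Returns co-ordered copies; harmonizing already
    aligned inputs is a no-op.
    """
    wk = weights.snp_keys
    gk = genos.snp_keys
    common = wk.intersection(gk)
    if len(common) == 0:
        raise FormatError("no overlapping SNPs between weights and genotypes")
    widx = wk.get_indexer(common)
    gidx = gk.get_indexer(common)
    wt = weights.table.iloc[widx].reset_index(drop=True)
    sites = genos.sites.iloc[gidx].reset_index(drop=True)
    states = genos.states[:, gidx].copy()

    direct = (wt["effect_allele"].values == sites["alt"].values) & (
        wt["other_allele"].values == sites["ref"].values
    )
    swapped = (wt["effect_allele"].values == sites["ref"].values) & (
        wt["other_allele"].values == sites["alt"].values
    )
    keep = direct | swapped
    n_mismatch = int((~keep).sum())

    flip = swapped & keep
    cols = np.where(flip)[0]
    sub = states[:, cols]
    obs = sub != MISSING
    sub[obs] = 1 - sub[obs]
    states[:, cols] = sub

    kidx = np.where(keep)[0]
    wt = wt.iloc[kidx].reset_index(drop=True)
    log = dict(weights.filter_log)
    log["dropped_allele_mismatch"] = n_mismatch
    log["flipped_to_effect_allele"] = int(flip.sum())
    out_w = WeightTable(table=wt, filter_log=log)
    out_g = HaplotypeMatrix(
        samples=list(genos.samples),
        sites=sites.iloc[kidx].reset_index(drop=True),
        states=states[:, kidx],
    )
    return out_w, out_g


def harmonize_multi(
    weights: dict[str, WeightTable], genos: HaplotypeMatrix
) -> tuple[dict[str, WeightTable], HaplotypeMatrix]:
    """Align several weight tables and one genotype matrix on shared SNPs.

    Because different weight tables may orient the same SNP differently,
    the genotype states are kept counting the VCF ALT allele and each
    table's beta is re-oriented to the ALT allele instead (sign flip when
    its effect allele is REF).  Standardized scores are unaffected by this
    orientation choice; raw scores are ALT-oriented.
    """
    gk = genos.snp_keys
    common = gk
    for w in weights.values():
        common = common.intersection(w.snp_keys)
    if len(common) == 0:
        raise FormatError("no SNPs shared by all weight tables and genotypes")
    gidx = gk.get_indexer(common)
    sites = genos.sites.iloc[gidx].reset_index(drop=True)

    keep = np.ones(len(common), dtype=bool)
    oriented: dict[str, pd.DataFrame] = {}
    for a, w in weights.items():
        wt = w.table.iloc[w.snp_keys.get_indexer(common)].reset_index(drop=True)
        direct = (wt["effect_allele"].values == sites["alt"].values) & (
            wt["other_allele"].values == sites["ref"].values
        )
        swapped = (wt["effect_allele"].values == sites["ref"].values) & (
            wt["other_allele"].values == sites["alt"].values
        )
        wt.loc[swapped, "beta"] = -wt.loc[swapped, "beta"]
        wt.loc[swapped, ["effect_allele", "other_allele"]] = wt.loc[
            swapped, ["other_allele", "effect_allele"]
        ].values
        keep &= direct | swapped
        oriented[a] = wt
    kidx = np.where(keep)[0]
    out_w = {
        a: WeightTable(
            table=wt.iloc[kidx].reset_index(drop=True),
            filter_log={**weights[a].filter_log, "dropped_allele_mismatch": int((~keep).sum())},
        )
        for a, wt in oriented.items()
    }
    out_g = HaplotypeMatrix(
        samples=list(genos.samples),
        sites=sites.iloc[kidx].reset_index(drop=True),
        states=genos.states[:, gidx][:, kidx],
    )
    return out_w, out_g


# ---------------------------------------------------------------------------
# local ancestry


def read_local_ancestry(
    path, format: str, sites: pd.DataFrame | None = None
) -> AncestryDosage | AncestryMask:
    """Read local-ancestry calls.

    ``format="elai_dosage"`` reads this package's dosage dialect: a TSV
    whose first two columns are ``chrom`` and ``pos`` (one row per site)
    followed by one column per haplotype x ancestry named
    ``<sample>.<hap>|<ancestry>`` holding the posterior dosage.  Row sums
    per haplotype must be within 1 +/- 0.05 (renormalized when within
    tolerance, error otherwise).

    ``format="msp_tracts"`` reads an RFMix2 ``.msp.tsv`` interval file and
    requires ``sites`` (DataFrame with chrom/pos) to rasterize intervals
    into a hard :class:`AncestryMask`; intervals are 1-based closed, and
    overlapping intervals within one haplotype are an error.
    """
    if format == "elai_dosage":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        dose_cols = [c for c in df.columns if c not in ("chrom", "pos")]
        parsed = []
        for c in dose_cols:
            m = re.fullmatch(r"(.+\.\d)\|(.+)", c)
            if not m:
                raise FormatError(f"bad dosage column name {c!r}")
            parsed.append(m.groups())
        hap_ids = list(dict.fromkeys(h for h, _ in parsed))
        ancestries = list(dict.fromkeys(a for _, a in parsed))
        arr = np.empty((len(hap_ids), len(df), len(ancestries)))
        for c, (h, a) in zip(dose_cols, parsed):
            arr[hap_ids.index(h), :, ancestries.index(a)] = df[c].values
        return AncestryDosage(ancestries=ancestries, hap_ids=hap_ids, dosages=arr)
    if format == "msp_tracts":
        if sites is None:
            raise ValueError("msp_tracts requires the target site table")
        return mask_from_tracts(_read_msp(path), sites)
    raise ValueError(f"unknown local-ancestry format {format!r}")


@dataclass
class _TractSet:
    ancestries: list[str]
    hap_ids: list[str]
    # per hap: list of (chrom, start, end, code); 1-based closed intervals
    tracts: list[list[tuple[str, int, int, int]]]


def _read_msp(path) -> _TractSet:
    with open(path) as fh:
        first = fh.readline().strip().replace("\t", " ")
        if not first.startswith("#Subpopulation order/codes:"):
            raise FormatError("missing MSP subpopulation header line")
        codes = {}
        for tok in first.split(":", 1)[1].replace(",", " ").split():
            name, _, num = tok.partition("=")
            codes[int(num)] = name
        ancestries = [codes[k] for k in sorted(codes)]
        header = fh.readline().lstrip("#").split()
        hap_cols = header[6:]
        tracts: list[list[tuple[str, int, int, int]]] = [[] for _ in hap_cols]
        for line in fh:
            f = line.split()
            chrom, spos, epos = f[0], int(f[1]), int(f[2])
            for k, v in enumerate(f[6:]):
                tracts[k].append((chrom, spos, epos, int(v)))
    return _TractSet(ancestries=ancestries, hap_ids=hap_cols, tracts=tracts)


def mask_from_tracts(ts: _TractSet, sites: pd.DataFrame) -> AncestryMask:
    labels = np.full((len(ts.hap_ids), len(sites)), UNKNOWN, dtype=np.int8)
    chrom = sites["chrom"].values
    pos = sites["pos"].values.astype(np.int64)
    for h, tlist in enumerate(ts.tracts):
        covered = np.zeros(len(sites), dtype=bool)
        for c, s, e, code in tlist:
            sel = (chrom == c) & (pos >= s) & (pos <= e)
            if (covered & sel).any():
                raise FormatError(
                    f"overlapping tracts within haplotype {ts.hap_ids[h]!r} "
                    f"on {c}:{s}-{e}"
                )
            covered |= sel
            labels[h, sel] = code
    return AncestryMask(ancestries=ts.ancestries, hap_ids=ts.hap_ids, labels=labels)


def write_dosages(dosage: AncestryDosage, sites: pd.DataFrame, path) -> None:
    cols = {"chrom": sites["chrom"], "pos": sites["pos"]}
    for hi, h in enumerate(dosage.hap_ids):
        for ai, a in enumerate(dosage.ancestries):
            cols[f"{h}|{a}"] = dosage.dosages[hi, :, ai]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_mask(mask: AncestryMask, sites: pd.DataFrame, path) -> None:
    """Serialize a hard mask: site rows, one label column per haplotype."""
    names = np.array(mask.ancestries + [UNKNOWN_LABEL])
    cols = {"chrom": sites["chrom"], "pos": sites["pos"]}
    for hi, h in enumerate(mask.hap_ids):
        cols[h] = names[mask.labels[hi]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_mask(path, ancestries: list[str] | None = None) -> AncestryMask:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    hap_ids = [c for c in df.columns if c not in ("chrom", "pos")]
    seen = pd.unique(df[hap_ids].values.ravel())
    if ancestries is None:
        ancestries = sorted(a for a in seen if a != UNKNOWN_LABEL)
    lut = {a: i for i, a in enumerate(ancestries)}
    lut[UNKNOWN_LABEL] = UNKNOWN
    labels = np.empty((len(hap_ids), len(df)), dtype=np.int8)
    for hi, h in enumerate(hap_ids):
        labels[hi] = df[h].map(lut).values
    return AncestryMask(ancestries=list(ancestries), hap_ids=hap_ids, labels=labels)


def write_scores(scores: pd.DataFrame, path) -> None:
    """Write a score table TSV with a deterministic column order."""
    order = [c for c in ("sample", "ancestry", "N_S", "p", "raw", "pps", "flag") if c in scores.columns]
    order += [c for c in scores.columns if c not in order]
    scores[order].to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
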