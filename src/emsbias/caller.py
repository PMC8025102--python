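"""EMS-induced SNP calling from multi-bulk variant tables.

A candidate site is accepted as EMS-induced when it is supported by at least
``min_alt_mq20`` mapping-quality-passing mutant reads in exactly one test
bulk, the mean mutant-read count over all other bulks is at most
``max_other_bulk_mean_alt``, and any alt evidence in another bulk stays
within the sequencing-error tolerance (alt fraction <= ``error_tolerance``).
Dense per-bulk SNP clusters — residual heterozygous fragments inherited from
breeding — are then masked out.  Accepted SNPs carry the SNP index (SI, the
alt-read fraction in the test bulk: ~1 at the causal site, ~0.5 at unlinked
heterozygous sites) and ED^6, the Euclidean distance between the test bulk's
and the other bulks' mean allele-frequency 4-vectors raised to the 6th power
to sharpen linkage peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BASES, VARIANT_COLUMNS

MUTATION_TYPES = [f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a]

REASON_LOW_SUPPORT = "low_support"
REASON_SHARED = "shared"
REASON_HIGH_BACKGROUND = "high_background"
REASON_RESIDUAL_FRAGMENT = "residual_fragment"


@dataclass
class CallerParams:
    """Filter thresholds for the cross-bulk caller."""

    min_alt_mq20: int = 3
    max_other_bulk_mean_alt: float = 1.0
    error_tolerance: float = 0.20
    fragment_mask_window: int = 100_000
    fragment_mask_min_snps: int = 20
    fragment_mask_step: int | None = None  # default: window // 2

    def validate(self) -> None:
        if min(self.min_alt_mq20, self.max_other_bulk_mean_alt,
               self.error_tolerance, self.fragment_mask_window,
               self.fragment_mask_min_snps) < 0:
            raise ValueError("thresholds must be >= 0")

    @property
    def mask_step(self) -> int:
        return self.fragment_mask_step or max(1, self.fragment_mask_window // 2)


@dataclass
class CallResult:
    """Accepted EMS SNPs plus machine-readable rejections and masks."""

    accepted: pd.DataFrame   # chrom,pos,ref,alt,bulk_id,si,ed6,mutation_type,...
    rejected: pd.DataFrame   # chrom,pos,ref,alt,bulk_id,reason
    masks: pd.DataFrame      # bulk_id,chrom,start,end
    n_bulks: int


def snp_index(alt_reads: int, total_reads: int) -> float:
    """SNP index: mutant-read fraction in the test bulk."""
    if total_reads <= 0:
        raise ValueError("SNP index undefined at zero depth")
    return alt_reads / total_reads


def euclidean_distance6(test_freqs, other_mean_freqs) -> float:
    """ED^6 between two allele-frequency 4-vectors over A/C/G/T."""
    t = np.asarray(test_freqs, dtype=float)
    o = np.asarray(other_mean_freqs, dtype=float)
    for v in (t, o):
        if v.shape != (4,) or np.any(v < -1e-9) or abs(v.sum() - 1) > 1e-6:
            raise ValueError("allele-frequency vector must be a 4-vector "
                             "summing to 1")
    ed = float(np.sqrt(np.sum((t - o) ** 2)))
    return ed ** 6


def filter_candidate(site: pd.DataFrame, params: CallerParams,
                     n_bulks: int) -> tuple[bool, str | None, str | None]:
    """Judge one site given its per-bulk evidence rows.

    ``site`` holds one row per bulk with any record at this (chrom, pos, ref,
    alt); bulks without a record contribute zero reads.  Returns
    (accepted, test_bulk_id, reason).
    """
    if n_bulks < 2:
        raise ValueError("cross-bulk comparison requires >= 2 bulks")
    passing = site[site["alt_mq20"] >= params.min_alt_mq20]
    if len(passing) == 0:
        return False, None, REASON_LOW_SUPPORT
    if len(passing) > 1:
        return False, None, REASON_SHARED
    test = passing.iloc[0]
    others = site[site["bulk_id"] != test["bulk_id"]]
    if len(others):
        frac = others["alt_reads"] / others["total_reads"]
        if (frac > params.error_tolerance).any():
            return False, test["bulk_id"], REASON_SHARED
    mean_other = others["alt_reads"].sum() / (n_bulks - 1)
    if mean_other > params.max_other_bulk_mean_alt:
        return False, test["bulk_id"], REASON_HIGH_BACKGROUND
    return True, test["bulk_id"], None


def mask_residual_fragments(bulk_variants: pd.DataFrame, params: CallerParams,
                            chrom_lengths: dict[str, int] | None = None
                            ) -> pd.DataFrame:
    """Windows with a dense per-bulk SNP load, merged into masked intervals.

    Sliding windows of ``fragment_mask_window`` bp (step ``mask_step``) that
    contain at least ``fragment_mask_min_snps`` candidate SNPs from one bulk
    qualify; overlapping or adjacent qualifying windows merge into maximal
    intervals.  Returns columns bulk_id, chrom, start, end.
    """
    rows = []
    w, step = params.fragment_mask_window, params.mask_step
    for (bulk, chrom), grp in bulk_variants.groupby(["bulk_id", "chrom"]):
        pos = np.sort(grp["pos"].to_numpy())
        L = (chrom_lengths or {}).get(chrom, int(pos[-1]) + 1 if len(pos) else 0)
        intervals = []
        for start in range(0, max(L, 1), step):
            end = min(start + w, L)
            count = np.searchsorted(pos, end) - np.searchsorted(pos, start)
            if count >= params.fragment_mask_min_snps:
                intervals.append((start, end))
            if end >= L:
                break
        for s, e in _merge_touching(intervals):
            rows.append((bulk, chrom, s, e))
    return pd.DataFrame(rows, columns=["bulk_id", "chrom", "start", "end"])


def _merge_touching(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _site_vectors(site: pd.DataFrame, test_bulk: str,
                  n_bulks: int) -> tuple[np.ndarray, np.ndarray]:
    """Allele-frequency 4-vectors: the test bulk's, and the other bulks' mean.

    Bulks without a record at the site count as pure reference.
    """
    ref_i = BASES.index(site.iloc[0]["ref"])
    alt_i = BASES.index(site.iloc[0]["alt"])
    test = site[site["bulk_id"] == test_bulk].iloc[0]
    tvec = np.zeros(4)
    tvec[alt_i] = test["alt_reads"] / test["total_reads"]
    tvec[ref_i] += 1 - tvec[alt_i]
    osum = np.zeros(4)
    n_seen = 0
    for row in site.itertuples(index=False):
        if row.bulk_id == test_bulk:
            continue
        f = row.alt_reads / row.total_reads
        v = np.zeros(4)
        v[alt_i] = f
        v[ref_i] += 1 - f
        osum += v
        n_seen += 1
    absent = (n_bulks - 1) - n_seen
    ref_unit = np.zeros(4)
    ref_unit[ref_i] = 1.0
    ovec = (osum + absent * ref_unit) / (n_bulks - 1)
    return tvec, ovec


def call_ems_snps(variants: pd.DataFrame, params: CallerParams | None = None,
                  n_bulks: int | None = None,
                  chrom_lengths: dict[str, int] | None = None) -> CallResult:
    """Run the full filter chain over the pooled multi-bulk variant table.

    ``variants`` uses the columns of ``io.VARIANT_COLUMNS``.  ``n_bulks``
    defaults to the number of distinct bulk ids present; pass it explicitly
    when some bulks contributed no records.
    """
    params = params or CallerParams()
    params.validate()
    variants = variants[VARIANT_COLUMNS].copy()
    bulk_ids = sorted(variants["bulk_id"].unique())
    if n_bulks is None:
        n_bulks = len(bulk_ids)
    if n_bulks < 2:
        raise ValueError("cross-bulk comparison requires >= 2 bulks")

    acc_rows, rej_rows = [], []
    for key, site in variants.groupby(["chrom", "pos", "ref", "alt"],
                                      sort=True):
        ok, test_bulk, reason = filter_candidate(site, params, n_bulks)
        if not ok:
            rej_rows.append((*key, test_bulk, reason))
            continue
        test = site[site["bulk_id"] == test_bulk].iloc[0]
        tvec, ovec = _site_vectors(site, test_bulk, n_bulks)
        acc_rows.append((*key, test_bulk,
                         snp_index(int(test["alt_reads"]),
                                   int(test["total_reads"])),
                         euclidean_distance6(tvec, ovec),
                         int(test["alt_reads"]), int(test["total_reads"]),
                         int(test["alt_mq20"])))
    accepted = pd.DataFrame(acc_rows, columns=[
        "chrom", "pos", "ref", "alt", "bulk_id", "si", "ed6",
        "alt_reads", "total_reads", "alt_mq20"])
    rejected = pd.DataFrame(rej_rows, columns=[
        "chrom", "pos", "ref", "alt", "bulk_id", "reason"])

    masks = mask_residual_fragments(accepted, params, chrom_lengths) \
        if len(accepted) else pd.DataFrame(
            columns=["bulk_id", "chrom", "start", "end"])
    if len(masks):
        drop = np.zeros(len(accepted), dtype=bool)
        for m in masks.itertuples(index=False):
            drop |= ((accepted["bulk_id"] == m.bulk_id)
                     & (accepted["chrom"] == m.chrom)
                     & (accepted["pos"] >= m.start)
                     & (accepted["pos"] < m.end)).to_numpy()
        masked = accepted[drop]
        rejected = pd.concat([rejected, pd.DataFrame({
            "chrom": masked["chrom"], "pos": masked["pos"],
            "ref": masked["ref"], "alt": masked["alt"],
            "bulk_id": masked["bulk_id"],
            "reason": REASON_RESIDUAL_FRAGMENT})], ignore_index=True)
        accepted = accepted[~drop]

    accepted = accepted.assign(
        mutation_type=accepted["ref"].str.cat(accepted["alt"], sep=">"))
    accepted = accepted.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return CallResult(accepted, rejected.reset_index(drop=True), masks, n_bulks)


# ---------------------------------------------------------------------------
# Natural-panel filtering
# ---------------------------------------------------------------------------

def panel_site_stats(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-site n_typed, MAF and missing rate from a genotype-dosage panel."""
    geno_cols = [c for c in panel.columns
                 if c not in ("chrom", "pos", "ref", "alt")]
    geno = panel[geno_cols].to_numpy(float)
    n_var = geno.shape[1]
    n_typed = np.sum(~np.isnan(geno), axis=1)
    with np.errstate(invalid="ignore"):
        af = np.nansum(geno, axis=1) / (2 * np.maximum(n_typed, 1))
    maf = np.minimum(af, 1 - af)
    out = panel[["chrom", "pos", "ref", "alt"]].copy()
    out["n_typed"] = n_typed.astype(int)
    out["maf"] = maf
    out["missing_rate"] = 1 - n_typed / n_var
    return out


def filter_natural_panel(sites: pd.DataFrame, min_typed: int = 30,
                         min_maf: float = 0.01,
                         max_missing: float = 0.8) -> pd.DataFrame:
    """Retain biallelic sites typed in >= ``min_typed`` varieties with
    MAF >= ``min_maf`` and missing rate < ``max_missing``."""
    keep = ((sites["n_typed"] >= min_typed)
            & (sites["maf"] >= min_maf)
            & (sites["missing_rate"] < max_missing))
    return sites[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_ems_tsv(accepted: pd.DataFrame, path: str | Path) -> None:
    """TSV with 1-based positions (column ``pos``), matching VCF convention."""
    out = accepted.copy()
    out["pos"] = out["pos"] + 1
    cols = ["chrom", "pos", "ref", "alt", "bulk_id", "si", "ed6",
            "mutation_type"]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_ems_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"] - 1
    return df


def write_ems_vcf(accepted: pd.DataFrame, chrom_lengths: dict[str, int],
                  path: str | Path) -> None:
    """Accepted EMS SNPs as a sites-only VCF with BULK/SI/ED6 INFO fields."""
    import pysam
    header = pysam.VariantHeader()
    header.add_line("##source=emsbias-caller")
    for name, length in chrom_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("BULK", 1, "String", "Test bulk carrying the mutation")
    header.info.add("SI", 1, "Float", "SNP index in the test bulk")
    header.info.add("ED6", 1, "Float", "Euclidean distance to other bulks ^6")
    rows = accepted.sort_values(["chrom", "pos"], kind="mergesort")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in rows.itertuples(index=False):
            rec = vcf.new_record(contig=row.chrom, start=int(row.pos),
                                 stop=int(row.pos) + 1,
                                 alleles=(row.ref, row.alt))
            rec.info["BULK"] = row.bulk_id
            rec.info["SI"] = float(row.si)
            rec.info["ED6"] = float(row.ed6)
            vcf.write(rec)
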