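"""Chromatin-structure overlays on EMS SNP density.

DH-site merging and per-bin counts, per-SNP epigenetic signal extraction
(max over experiments at the base, ±10 bp fallback), coverage-based track
retention, per-bin-class signal means, TE/non-TE gene ratios, and
expression-level grouping.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .binscan import CLASS_LABELS
from .io import GeneModel, read_bedgraph

SOURCE_AT_SITE = "at_site"
SOURCE_FLANK = "flank10"
SOURCE_MISSING = "missing"


def merge_dh_sites(intervals: pd.DataFrame, gap: int = 36) -> pd.DataFrame:
    """Merge same-chromosome intervals whose gap is <= ``gap`` bp, transitively.

    Output is sorted and disjoint; idempotent.
    """
    if len(intervals) and (intervals[["start", "end"]].to_numpy() < 0).any():
        raise ValueError("negative interval coordinates")
    rows = []
    for chrom, grp in intervals.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = int(s), int(e)
            elif s - cur_e <= gap:
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _midpoint_counts(items: pd.DataFrame, bins: pd.DataFrame) -> np.ndarray:
    counts = np.zeros(len(bins), dtype=int)
    if not len(items):
        return counts
    mids = (items["start"] + items["end"]) // 2
    for chrom, grp in items.assign(mid=mids).groupby("chrom"):
        mid = np.sort(grp["mid"].to_numpy(int))
        sel = (bins["chrom"] == chrom).to_numpy()
        counts[sel] = (np.searchsorted(mid, bins.loc[sel, "end"])
                       - np.searchsorted(mid, bins.loc[sel, "start"]))
    return counts


def dh_per_bin(merged: pd.DataFrame, bins: pd.DataFrame,
               threshold: int = 20) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin DH counts (midpoint membership) and the per-class fraction of
    bins holding more than ``threshold`` sites."""
    out = bins.copy()
    out["dh_count"] = _midpoint_counts(merged, bins)
    rows = []
    for label in CLASS_LABELS + ["all"]:
        sub = out if label == "all" else out[out["class_label"] == label]
        frac = float((sub["dh_count"] > threshold).mean()) if len(sub) \
            else float("nan")
        rows.append((label, len(sub), frac))
    summary = pd.DataFrame(rows, columns=["class_label", "n_bins",
                                          f"frac_gt_{threshold}"])
    return out, summary


class SignalTrack:
    """One experiment's BedGraph held as per-chromosome interval arrays."""

    def __init__(self, frame: pd.DataFrame, name: str = ""):
        self.name = name
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in frame.groupby("chrom"):
            grp = grp.sort_values("start")
            self._by_chrom[chrom] = (grp["start"].to_numpy(int),
                                     grp["end"].to_numpy(int),
                                     grp["value"].to_numpy(float))

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "SignalTrack":
        return cls(read_bedgraph(path), name=Path(path).name)

    def value_at(self, chrom: str, pos: int) -> float | None:
        if chrom not in self._by_chrom:
            return None
        starts, ends, vals = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(vals[i])
        return None

    def max_in(self, chrom: str, start: int, end: int) -> float | None:
        """Max value over intervals overlapping [start, end); None if none."""
        if chrom not in self._by_chrom or end <= start:
            return None
        starts, ends, vals = self._by_chrom[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return None
        return float(vals[lo:hi].max())


def load_track_manifest(manifest_path: str | Path,
                        tracks_dir: str | Path) -> dict[str, list[SignalTrack]]:
    """modification -> experiment tracks, from a (file, modification,
    experiment) manifest TSV."""
    manifest = pd.read_csv(manifest_path, sep="\t")
    tracks_dir = Path(tracks_dir)
    out: dict[str, list[SignalTrack]] = {}
    for row in manifest.itertuples(index=False):
        out.setdefault(row.modification, []).append(
            SignalTrack.from_bedgraph(tracks_dir / row.file))
    return out


def snp_signal(snps: pd.DataFrame, tracks: list[SignalTrack],
               flank: int = 10) -> pd.DataFrame:
    """Per-SNP signal: max over experiments at the base, else max over
    ±``flank`` bp, else missing."""
    values, sources = [], []
    for row in snps.itertuples(index=False):
        at = [v for t in tracks
              if (v := t.value_at(row.chrom, int(row.pos))) is not None]
        if at:
            values.append(max(at))
            sources.append(SOURCE_AT_SITE)
            continue
        near = [v for t in tracks
                if (v := t.max_in(row.chrom, int(row.pos) - flank,
                                  int(row.pos) + flank + 1)) is not None]
        if near:
            values.append(max(near))
            sources.append(SOURCE_FLANK)
        else:
            values.append(np.nan)
            sources.append(SOURCE_MISSING)
    out = snps[["chrom", "pos"]].copy()
    out["value"] = values
    out["source"] = sources
    return out


def coverage_filter(signals: pd.DataFrame, min_fraction: float = 0.5) -> bool:
    """Keep a modification iff it covers at least ``min_fraction`` of SNPs."""
    if not len(signals):
        return False
    return float((signals["source"] != SOURCE_MISSING).mean()) >= min_fraction


def assign_snp_class(snps: pd.DataFrame, bins: pd.DataFrame) -> pd.Series:
    """Bin-class label per SNP.

    A SNP inside overlapping bins inherits the class of the covering bin with
    the higher SNP count (the denser local context).
    """
    labels = []
    by_chrom = {c: g.reset_index(drop=True) for c, g in bins.groupby("chrom")}
    for row in snps.itertuples(index=False):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            labels.append(None)
            continue
        cover = grp[(grp["start"] <= row.pos) & (row.pos < grp["end"])]
        if not len(cover):
            labels.append(None)
            continue
        best = cover.loc[cover["snp_count"].idxmax()]
        labels.append(best["class_label"])
    return pd.Series(labels, index=snps.index, name="class_label")


def class_signal_summary(modification_signals: dict[str, pd.DataFrame],
                         snp_classes: pd.Series,
                         min_coverage: float = 0.5) -> pd.DataFrame:
    """Per-class mean of per-SNP max signals for each retained modification.

    Modifications covering fewer than ``min_coverage`` of the SNPs are
    dropped, mirroring the retention rule for sparse epigenetic tracks.
    """
    rows = []
    for mod, sig in modification_signals.items():
        if not coverage_filter(sig, min_coverage):
            continue
        for label in CLASS_LABELS:
            vals = sig.loc[(snp_classes == label).to_numpy(), "value"].dropna()
            rows.append((mod, label, len(vals),
                         float(vals.mean()) if len(vals) else float("nan")))
    return pd.DataFrame(rows, columns=["modification", "class_label",
                                       "n_snps", "mean_signal"])


def te_ratio_per_bin(genes: list[GeneModel],
                     bins: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TE / non-TE gene-count ratio per bin (midpoint membership).

    Bins with no genes get NaN ratio and ``no_genes`` flag; all-TE bins get
    inf coded as NaN with ``zero_nonte`` flag.  The class summary reports the
    fraction of gene-bearing bins with ratio > 0.5.
    """
    gdf = pd.DataFrame([(g.chrom, g.start, g.end, g.is_te) for g in genes],
                       columns=["chrom", "start", "end", "is_te"])
    te = _midpoint_counts(gdf[gdf["is_te"]], bins)
    nonte = _midpoint_counts(gdf[~gdf["is_te"]], bins)
    out = bins.copy()
    out["te_genes"] = te
    out["nonte_genes"] = nonte
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(nonte > 0, te / np.maximum(nonte, 1), np.nan)
    out["te_ratio"] = ratio
    out["te_flag"] = np.select([te + nonte == 0, nonte == 0],
                               ["no_genes", "zero_nonte"], default="ok")
    rows = []
    for label in CLASS_LABELS + ["all"]:
        sub = out if label == "all" else out[out["class_label"] == label]
        ok = sub[sub["te_flag"] != "no_genes"]
        enriched = (ok["te_ratio"] > 0.5) | (ok["te_flag"] == "zero_nonte")
        rows.append((label, len(sub),
                     float(enriched.mean()) if len(ok) else float("nan")))
    summary = pd.DataFrame(rows, columns=["class_label", "n_bins",
                                          "frac_te_enriched"])
    return out, summary


@dataclass
class ExpressionSummary:
    per_gene: pd.DataFrame
    per_class: pd.DataFrame
    n_missing_from_matrix: int


def expression_summary(expr: pd.DataFrame, genes: list[GeneModel],
                       ems_snps: pd.DataFrame, bins: pd.DataFrame,
                       flank: int = 3000,
                       low_fpkm: float = 1.0) -> ExpressionSummary:
    """Fraction of genes with mean FPKM < ``low_fpkm`` per bin class, split by
    whether the gene is EMS-targeted (>= 1 SNP in the body or ±3 kb flanks).

    ``expr`` is indexed by gene id with one column per dataset; genes absent
    from the matrix are excluded (not zero-filled).
    """
    mean_fpkm = expr.mean(axis=1)
    snp_pos = {c: np.sort(g["pos"].to_numpy(int))
               for c, g in ems_snps.groupby("chrom")}
    rows = []
    missing = 0
    for g in genes:
        if g.gene_id not in mean_fpkm.index:
            missing += 1
            continue
        pos = snp_pos.get(g.chrom, np.empty(0, dtype=int))
        lo, hi = g.start - flank, g.end + flank
        targeted = bool(np.searchsorted(pos, hi) - np.searchsorted(pos, lo))
        rows.append((g.gene_id, g.chrom, g.midpoint,
                     float(mean_fpkm[g.gene_id]), targeted))
    per_gene = pd.DataFrame(rows, columns=["gene_id", "chrom", "mid",
                                           "mean_fpkm", "targeted"])
    per_gene["low_expression"] = per_gene["mean_fpkm"] < low_fpkm
    pseudo = per_gene.rename(columns={"mid": "pos"})
    per_gene["class_label"] = assign_snp_class(pseudo, bins).to_numpy()

    rows = []
    for label in CLASS_LABELS:
        sub = per_gene[per_gene["class_label"] == label]
        for targeted in (True, False):
            tsub = sub[sub["targeted"] == targeted]
            rows.append((label, "targeted" if targeted else "non_targeted",
                         len(tsub),
                         float(tsub["low_expression"].mean()) if len(tsub)
                         else float("nan")))
    per_class = pd.DataFrame(rows, columns=["class_label", "group", "n_genes",
                                            "frac_low_fpkm"])
    return ExpressionSummary(per_gene, per_class, missing)
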