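"""Overlapping sliding-window scan of EMS SNP density.

The genome is divided into overlapping bins (default 100 kb, 50-kb step);
per-bin SNP counts are classified into coldspots (0 SNPs), 1-5, 5-10, and
hotspots (>= 10), with chi-square significance cuts around the genome-wide
mean reported as justification for the integer hotspot rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CLASS_LABELS = ["coldspot", "low", "mid", "hotspot"]


def make_bins(chrom_lengths: dict[str, int], window: int = 100_000,
              step: int = 50_000) -> pd.DataFrame:
    """Ordered overlapping bins per chromosome.

    Full windows start at 0, step, 2·step, ... while start + window <= L;
    if they leave an uncovered tail of >= 1 bp, one final clipped bin covers
    it from the next start.  A chromosome shorter than the window yields a
    single clipped bin.
    """
    if step <= 0 or step > window:
        raise ValueError("require 0 < step <= window")
    rows = []
    for chrom, L in chrom_lengths.items():
        start = 0
        last_end = 0
        while start + window <= L:
            rows.append((chrom, start, start + window, False))
            last_end = start + window
            start += step
        if last_end < L:
            rows.append((chrom, start, L, True))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "clipped"])


def count_snps_per_bin(bins: pd.DataFrame, snps: pd.DataFrame) -> pd.DataFrame:
    """Half-open membership (start <= pos < end); a SNP in an overlap region
    counts in every covering bin."""
    out = bins.copy()
    counts = np.zeros(len(bins), dtype=int)
    for chrom, grp in snps.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy(int))
        sel = (bins["chrom"] == chrom).to_numpy()
        starts = bins.loc[sel, "start"].to_numpy()
        ends = bins.loc[sel, "end"].to_numpy()
        counts[sel] = (np.searchsorted(pos, ends, side="left")
                       - np.searchsorted(pos, starts, side="left"))
    out["snp_count"] = counts
    return out


def chi_square_thresholds(mu: float, alpha: float = 0.05) -> tuple[float, float]:
    """Count cuts at which (n − μ)²/μ reaches the χ²₁(1−α) quantile.

    low = max(0, μ − sqrt(χ²·μ)), high = μ + sqrt(χ²·μ).
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    q = stats.chi2.ppf(1 - alpha, df=1)
    half = float(np.sqrt(q * mu))
    return max(0.0, mu - half), mu + half


def classify_bins(bins: pd.DataFrame, hotspot_min: int = 10) -> pd.DataFrame:
    """coldspot = 0; low = [1, 5); mid = [5, hotspot_min); hotspot >= hotspot_min."""
    c = bins["snp_count"].to_numpy()
    labels = np.select(
        [c == 0, c < 5, c < hotspot_min],
        ["coldspot", "low", "mid"], default="hotspot")
    out = bins.copy()
    out["class_label"] = labels
    return out


def class_counts(bins: pd.DataFrame) -> pd.Series:
    return bins["class_label"].value_counts().reindex(CLASS_LABELS,
                                                      fill_value=0)


def bin_ed6_profile(bins: pd.DataFrame, snps: pd.DataFrame) -> pd.DataFrame:
    """Per-bin max (and mean) ED^6 of member SNPs; empty bins report 0."""
    out = bins.copy()
    mx = np.zeros(len(bins))
    mn = np.zeros(len(bins))
    for chrom, grp in snps.groupby("chrom"):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy(int)
        ed6 = grp["ed6"].to_numpy(float)
        sel = np.nonzero((bins["chrom"] == chrom).to_numpy())[0]
        for i in sel:
            lo = np.searchsorted(pos, bins["start"].iat[i])
            hi = np.searchsorted(pos, bins["end"].iat[i])
            if hi > lo:
                mx[i] = ed6[lo:hi].max()
                mn[i] = ed6[lo:hi].mean()
    out["max_ed6"] = mx
    out["mean_ed6"] = mn
    return out


@dataclass
class BinScanResult:
    """Scan summary: bins with counts/classes, the mean, and the chi-square cuts."""

    bins: pd.DataFrame
    window: int
    step: int
    mu: float
    low_cut: float
    high_cut: float
    class_totals: pd.Series

    def summary(self) -> dict:
        return {
            "window": self.window, "step": self.step,
            "n_bins": int(len(self.bins)), "mean_snps_per_bin": self.mu,
            "low_cut": self.low_cut, "high_cut": self.high_cut,
            "class_totals": {k: int(v) for k, v in self.class_totals.items()},
        }


def scan(snps: pd.DataFrame, chrom_lengths: dict[str, int],
         window: int = 100_000, step: int = 50_000, hotspot_min: int = 10,
         alpha: float = 0.05, include_clipped_in_mean: bool = True,
         ) -> BinScanResult:
    """Full scan: bins, counts, classes, mean and chi-square cuts, ED^6 profile."""
    bins = make_bins(chrom_lengths, window, step)
    bins = count_snps_per_bin(bins, snps)
    if "ed6" in snps.columns:
        bins = bin_ed6_profile(bins, snps)
    bins = classify_bins(bins, hotspot_min)
    pool = bins if include_clipped_in_mean else bins[~bins["clipped"]]
    mu = float(pool["snp_count"].mean()) if len(pool) else float("nan")
    low, high = chi_square_thresholds(mu, alpha) if mu > 0 else (0.0, 0.0)
    return BinScanResult(bins, window, step, mu, low, high, class_counts(bins))
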