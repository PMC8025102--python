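"""Chromatin-track generation: DH sites, per-experiment signal BedGraphs, and
an FPKM expression matrix, all correlated with the domain layout.

DNase I hypersensitive (DH) sites and active marks (histone acetylation,
H2A.Z) concentrate in euchromatin; DNA methylation and MNase (nucleosome
occupancy) signal is high in heterochromatin; heterochromatin genes are
biased toward low expression (mean FPKM < 1)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..io import GeneModel, Genome, write_bed3, write_bedgraph
from .config import SimConfig


def generate_dh_sites(genome: Genome, config: SimConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Poisson-placed DH intervals with euchromatin-weighted density."""
    tc = config.tracks
    rows = []
    for chrom, codes in genome.chroms.items():
        het = genome.domain_kind_mask(chrom, "heterochromatin")
        L = len(codes)
        rate = np.where(het, tc.dh_rate_het, tc.dh_rate_eu)
        n = rng.poisson(rate.sum())
        if n == 0:
            continue
        p = rate / rate.sum()
        starts = np.sort(rng.choice(L, size=n, replace=False, p=p))
        lens = rng.integers(tc.dh_len_range[0], tc.dh_len_range[1], size=n)
        for s, ln in zip(starts, lens):
            rows.append((chrom, int(s), int(min(s + ln, L))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def generate_signal_tracks(genome: Genome, config: SimConfig,
                           rng: np.random.Generator,
                           outdir: str | Path) -> pd.DataFrame:
    """Write one BedGraph per experiment; returns the track manifest.

    Interval values are Gamma(2, mean/2) noise around a domain-dependent
    mean; a ``dropout`` fraction of intervals is omitted so the per-SNP
    extraction's ±10 bp fallback and missing handling get exercised.
    """
    tc = config.tracks
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for modification, n_exp in tc.experiments.items():
        high_in_het = modification not in tc.active
        for e in range(1, n_exp + 1):
            rows = []
            for chrom, codes in genome.chroms.items():
                L = len(codes)
                het = genome.domain_kind_mask(chrom, "heterochromatin")
                starts = np.arange(0, L, tc.interval)
                ends = np.minimum(starts + tc.interval, L)
                mids = (starts + ends) // 2
                in_het = het[np.minimum(mids, L - 1)]
                matched = in_het if high_in_het else ~in_het
                mean = np.where(matched, tc.high_mean, tc.high_mean / tc.contrast)
                vals = rng.gamma(2.0, mean / 2.0)
                keep = rng.random(len(starts)) >= tc.dropout
                for s, en, v in zip(starts[keep], ends[keep], vals[keep]):
                    rows.append((chrom, int(s), int(en), float(v)))
            fname = f"{modification}.exp{e}.bedgraph"
            write_bedgraph(pd.DataFrame(
                rows, columns=["chrom", "start", "end", "value"]),
                outdir / fname)
            manifest.append((fname, modification, f"exp{e}"))
    return pd.DataFrame(manifest, columns=["file", "modification", "experiment"])


def generate_expression(genome: Genome, genes: list[GeneModel],
                        config: SimConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """FPKM matrix (genes x datasets) with heterochromatin genes biased low.

    Low-expression genes draw dataset values around FPKM ~0.2; the rest
    around ~8, both lognormal.  TE genes are additionally pushed toward the
    low class, mirroring their transcriptional inertness.
    """
    cols = [f"ds{j + 1:03d}" for j in range(config.n_expr_datasets)]
    p_eu, p_het = config.low_expr_prob
    rows = {}
    for g in genes:
        het = bool(genome.domain_kind_mask(g.chrom, "heterochromatin")[
            min(g.midpoint, len(genome.chroms[g.chrom]) - 1)])
        p_low = p_het if het else p_eu
        if g.is_te:
            p_low = min(1.0, p_low + 0.10)
        low = rng.random() < p_low
        base = 0.2 if low else 8.0
        mean = base * rng.lognormal(0, 0.4)
        rows[g.gene_id] = mean * rng.lognormal(0, 0.5, size=config.n_expr_datasets)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "gene_id"
    return df


def generate_tracks(genome: Genome, genes: list[GeneModel], config: SimConfig,
                    outdir: str | Path,
                    rng: np.random.Generator | None = None,
                    expr_rng: np.random.Generator | None = None) -> dict:
    """Generate DH BED, signal BedGraphs + manifest, and the FPKM TSV."""
    streams = config.rng_streams()
    rng = rng or streams["tracks"]
    expr_rng = expr_rng or streams["expression"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dh = generate_dh_sites(genome, config, rng)
    write_bed3(dh, outdir / "dh_sites.bed")
    manifest = generate_signal_tracks(genome, config, rng, outdir / "tracks")
    manifest.to_csv(outdir / "tracks_manifest.tsv", sep="\t", index=False)
    expr = generate_expression(genome, genes, config, expr_rng)
    expr.to_csv(outdir / "fpkm.tsv", sep="\t", float_format="%.4f")
    return {"dh": dh, "manifest": manifest, "expression": expr,
            "dh_path": outdir / "dh_sites.bed",
            "manifest_path": outdir / "tracks_manifest.tsv",
            "tracks_dir": outdir / "tracks",
            "fpkm_path": outdir / "fpkm.tsv"}
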