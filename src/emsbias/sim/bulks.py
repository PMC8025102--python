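"""Per-bulk read-count simulation and VCF emission.

Each bulk's variant table is the union of: its own implanted EMS sites
(pooled alt fraction 0.5; 1.0 at the causal site), the shared natural
background sites (alt fraction 1.0 in every bulk — the mutagenized line is
homozygous for them against the reference), its residual heterozygous
fragment sites (0.5, unique to the bulk), and low-level sequencing-error
sites (1-2 stray alt reads).  Depth is Poisson around the configured mean;
alt reads are binomial at the pooled frequency; the mapping-quality-passing
alt count is binomially thinned at ``mq_pass_rate``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..io import BASES, Genome, write_bulk_vcf
from .config import SimConfig
from .mutations import TruthSet


def add_background_sites(genome: Genome, config: SimConfig, truth: TruthSet,
                         rng: np.random.Generator) -> TruthSet:
    """Draw shared natural sites and per-bulk residual fragments into ``truth``."""
    nat_rows = []
    taken = set(zip(truth.ems_sites["chrom"], truth.ems_sites["pos"]))
    for chrom, codes in genome.chroms.items():
        L = len(codes)
        n = rng.poisson(config.natural_site_rate * L)
        for pos in np.sort(rng.choice(L, size=min(n, L), replace=False)):
            pos = int(pos)
            if (chrom, pos) in taken or codes[pos] >= 4:
                continue
            taken.add((chrom, pos))
            ref = int(codes[pos])
            alt = int(rng.choice([b for b in range(4) if b != ref]))
            nat_rows.append((chrom, pos, BASES[ref], BASES[alt]))
    natural = pd.DataFrame(nat_rows, columns=["chrom", "pos", "ref", "alt"])

    frag_rows, frag_site_rows = [], []
    chrom_names = list(genome.chroms)
    for b in range(config.n_bulks):
        bulk_id = f"bulk{b + 1:02d}"
        if rng.random() >= config.residual_fragment_prob:
            continue
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        L = len(genome.chroms[chrom])
        flen = min(config.residual_fragment_len, L)
        start = int(rng.integers(0, max(1, L - flen)))
        end = start + flen
        frag_rows.append((bulk_id, chrom, start, end))
        n = rng.poisson(config.residual_fragment_snp_rate * flen)
        codes = genome.chroms[chrom]
        for pos in np.sort(start + rng.choice(flen, size=min(n, flen),
                                              replace=False)):
            pos = int(pos)
            if (chrom, pos) in taken or codes[pos] >= 4:
                continue
            taken.add((chrom, pos))
            ref = int(codes[pos])
            alt = int(rng.choice([b for b in range(4) if b != ref]))
            frag_site_rows.append((bulk_id, chrom, pos, BASES[ref], BASES[alt]))
    truth.natural_sites = natural
    truth.residual_fragments = pd.DataFrame(
        frag_rows, columns=["bulk_id", "chrom", "start", "end"])
    truth.fragment_sites = pd.DataFrame(
        frag_site_rows, columns=["bulk_id", "chrom", "pos", "ref", "alt"])
    return truth


def _freq_records(sites: pd.DataFrame, freqs: np.ndarray, config: SimConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Simulate read counts for sites with pooled alt frequencies ``freqs``."""
    n = len(sites)
    dp = np.maximum(1, rng.poisson(config.depth, size=n))
    alt = rng.binomial(dp, freqs)
    mq = rng.binomial(alt, config.mq_pass_rate)
    out = sites[["chrom", "pos", "ref", "alt"]].copy() if n else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt"])
    out["alt_reads"] = alt
    out["total_reads"] = dp
    out["alt_mq20"] = mq
    return out[out["alt_reads"] > 0]


def _error_records(genome: Genome, config: SimConfig,
                   rng: np.random.Generator,
                   exclude: set[tuple[str, int]]) -> pd.DataFrame:
    """Sequencing-error sites: 1-2 alt reads, at most half of them MQ-passing.

    At ~39x with per-base error around 0.3%, three identical high-quality
    alt reads at one position are vanishingly unlikely, so error sites never
    reach the caller's minimum-support threshold; they exist to exercise the
    cross-bulk error-tolerance rule.
    """
    rows = []
    for chrom, codes in genome.chroms.items():
        L = len(codes)
        n = rng.poisson(config.error_site_rate * L)
        for pos in np.sort(rng.choice(L, size=min(n, L), replace=False)):
            pos = int(pos)
            if (chrom, pos) in exclude or codes[pos] >= 4:
                continue
            ref = int(codes[pos])
            alt = int(rng.choice([b for b in range(4) if b != ref]))
            alt_reads = 1 + int(rng.random() < 0.25)
            dp = max(int(rng.poisson(config.depth)),
                     int(np.ceil(alt_reads / config.seq_error_rate)))
            mq = int(rng.binomial(alt_reads, 0.5))
            rows.append((chrom, pos, BASES[ref], BASES[alt],
                         alt_reads, dp, mq))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "alt_reads", "total_reads", "alt_mq20"])


def simulate_bulk_vcfs(genome: Genome, truth: TruthSet, config: SimConfig,
                       outdir: str | Path,
                       rng: np.random.Generator | None = None) -> list[Path]:
    """Write one VCF per bulk; returns the file paths in bulk order."""
    if rng is None:
        rng = config.rng_streams()["bulks"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lengths = genome.chrom_lengths
    paths = []
    for b in range(config.n_bulks):
        bulk_id = f"bulk{b + 1:02d}"
        parts = []
        ems = truth.ems_sites[truth.ems_sites["bulk_id"] == bulk_id]
        parts.append(_freq_records(ems, ems["zygosity"].to_numpy(float),
                                   config, rng))
        nat = truth.natural_sites
        if len(nat):
            parts.append(_freq_records(nat, np.ones(len(nat)), config, rng))
        frag = truth.fragment_sites[truth.fragment_sites["bulk_id"] == bulk_id]
        if len(frag):
            parts.append(_freq_records(frag, np.full(len(frag), 0.5),
                                       config, rng))
        if config.seq_error_rate > 0 and config.error_site_rate > 0:
            exclude = set(zip(ems["chrom"], ems["pos"])) \
                | set(zip(nat["chrom"], nat["pos"])) \
                | set(zip(frag["chrom"], frag["pos"]))
            parts.append(_error_records(genome, config, rng, exclude))
        records = pd.concat([p for p in parts if len(p)], ignore_index=True) \
            if any(len(p) for p in parts) else parts[0]
        path = outdir / f"{bulk_id}.vcf"
        write_bulk_vcf(records, lengths, path, sample=bulk_id)
        paths.append(path)
    return paths
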