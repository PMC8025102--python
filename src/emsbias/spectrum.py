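"""Mutation spectrum, flanking base composition, k-mer context enrichment,
and codon/amino-acid usage of EMS-induced SNPs.

All context extraction is on the reference plus strand with the SNP site at
position 0; G>A and C>T are tallied separately, so reverse-complementing the
genome and the SNP set maps each type onto its complement exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .io import BASES, GeneModel, Genome, codes_to_seq

MUTATION_TYPES = [f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a]

#: the five position sets used for di/trinucleotide context tables
POSITION_SETS: dict[str, tuple[int, ...]] = {
    "-1/0": (-1, 0),
    "0/+1": (0, 1),
    "-2/-1/0": (-2, -1, 0),
    "-1/0/+1": (-1, 0, 1),
    "0/+1/+2": (0, 1, 2),
}


class RefMismatchError(ValueError):
    """A SNP's stated reference allele disagrees with the genome."""


def _check_ref(snps: pd.DataFrame, genome: Genome) -> None:
    for chrom, grp in snps.groupby("chrom"):
        codes = genome.chroms[chrom]
        pos = grp["pos"].to_numpy(int)
        ref = np.array([BASES.index(r) for r in grp["ref"]])
        bad = np.nonzero(codes[pos] != ref)[0]
        if len(bad):
            i = bad[0]
            raise RefMismatchError(
                f"ref allele mismatch at {chrom}:{pos[i]} "
                f"(genome {BASES[codes[pos[i]]]}, snp {grp['ref'].iloc[i]})")


@dataclass
class SpectrumTable:
    """Counts and fractions of the 12 ref>alt mutation types."""

    counts: pd.Series
    fractions: pd.Series
    gc_site_fraction: float
    n: int

    @property
    def defined(self) -> bool:
        return self.n > 0


def mutation_spectrum(snps: pd.DataFrame, genome: Genome | None = None
                      ) -> SpectrumTable:
    """Tally the 12 plus-strand mutation types and the G/C-site fraction."""
    if genome is not None and len(snps):
        _check_ref(snps, genome)
    types = snps["ref"].str.cat(snps["alt"], sep=">") if len(snps) \
        else pd.Series(dtype=str)
    counts = types.value_counts().reindex(MUTATION_TYPES, fill_value=0)
    n = int(counts.sum())
    fractions = counts / n if n else counts.astype(float) * np.nan
    gc = counts[[t for t in MUTATION_TYPES if t[0] in "GC"]].sum() / n \
        if n else float("nan")
    return SpectrumTable(counts, fractions, float(gc), n)


@dataclass
class FlankGC:
    mean_gc: float
    per_snp_gc: np.ndarray
    n_used: int
    n_skipped: int
    gc_adjacent_fraction: float | None = None  # flank=1 only


def flank_gc(snps: pd.DataFrame, genome: Genome, flank_bp: int = 50) -> FlankGC:
    """GC fraction of the 2×``flank_bp`` bases around each SNP.

    The SNP base itself is excluded.  SNPs whose flanks run off the
    chromosome are skipped (counted).  For ``flank_bp == 1`` the fraction of
    SNPs with a G or C at either immediate neighbour is reported too.
    """
    vals, adjacent = [], []
    skipped = 0
    for chrom, grp in snps.groupby("chrom"):
        codes = genome.chroms[chrom]
        L = len(codes)
        for pos in grp["pos"].to_numpy(int):
            if pos - flank_bp < 0 or pos + flank_bp >= L:
                skipped += 1
                continue
            window = np.concatenate([codes[pos - flank_bp:pos],
                                     codes[pos + 1:pos + flank_bp + 1]])
            acgt = window < 4
            if not acgt.any():
                skipped += 1
                continue
            is_gc = (window == 1) | (window == 2)
            vals.append(is_gc.sum() / acgt.sum())
            if flank_bp == 1:
                adjacent.append(bool(is_gc.any()))
    arr = np.asarray(vals)
    return FlankGC(
        mean_gc=float(arr.mean()) if len(arr) else float("nan"),
        per_snp_gc=arr, n_used=len(arr), n_skipped=skipped,
        gc_adjacent_fraction=(float(np.mean(adjacent)) if adjacent else None)
        if flank_bp == 1 else None)


def kmer_context_freqs(snps: pd.DataFrame, genome: Genome,
                       position_set: str) -> tuple[pd.Series, int]:
    """Per-k-mer fractions at the given offsets around each SNP site.

    Returns (fractions indexed by all 4^k k-mers, number of SNPs skipped for
    running off a chromosome end or containing N).
    """
    offsets = POSITION_SETS[position_set]
    k = len(offsets)
    kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    counts = dict.fromkeys(kmers, 0)
    skipped = 0
    for chrom, grp in snps.groupby("chrom"):
        codes = genome.chroms[chrom]
        L = len(codes)
        for pos in grp["pos"].to_numpy(int):
            idx = [pos + o for o in offsets]
            if idx[0] < 0 or idx[-1] >= L:
                skipped += 1
                continue
            sub = codes[idx]
            if (sub >= 4).any():
                skipped += 1
                continue
            counts[codes_to_seq(sub)] += 1
    total = sum(counts.values())
    fr = pd.Series(counts, dtype=float)
    return (fr / total if total else fr * np.nan), skipped


def genome_kmer_freqs(genome: Genome, k: int) -> pd.Series:
    """Genome-wide k-mer composition (plus strand, N-free windows)."""
    kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    counts = np.zeros(4 ** k, dtype=np.int64)
    for codes in genome.chroms.values():
        if len(codes) < k:
            continue
        idx = np.zeros(len(codes) - k + 1, dtype=np.int64)
        valid = np.ones(len(codes) - k + 1, dtype=bool)
        for j in range(k):
            sub = codes[j:len(codes) - k + 1 + j]
            idx = idx * 4 + sub
            valid &= sub < 4
        counts += np.bincount(idx[valid], minlength=4 ** k)
    fr = pd.Series(counts, index=kmers, dtype=float)
    return fr / fr.sum()


@dataclass
class RandomSiteBaseline:
    """Random-site context baseline: per-k-mer mean ± SD over replicates."""

    n: int
    reps: int
    kmer_mean: dict[str, pd.Series]
    kmer_sd: dict[str, pd.Series]
    flank_gc_mean: float
    flank_gc_sd: float


def random_site_baseline(genome: Genome, n: int = 10_000, reps: int = 10,
                         seed: int = 0, flank_bp: int = 50,
                         position_sets: tuple[str, ...] = tuple(POSITION_SETS),
                         ) -> RandomSiteBaseline:
    """Context tables at uniformly drawn sites (without replacement within a
    replicate; N bases excluded)."""
    total = len(genome)
    if n > total:
        raise ValueError(f"cannot draw {n} sites from a {total}-bp genome")
    rng = np.random.default_rng(seed)
    chrom_names = list(genome.chroms)
    offsets = np.cumsum([0] + [len(genome.chroms[c]) for c in chrom_names])
    tables: dict[str, list[pd.Series]] = {ps: [] for ps in position_sets}
    gcs = []
    for _ in range(reps):
        flat = rng.choice(total, size=n, replace=False)
        rows = []
        for f in np.sort(flat):
            ci = int(np.searchsorted(offsets, f, side="right") - 1)
            chrom = chrom_names[ci]
            pos = int(f - offsets[ci])
            if genome.chroms[chrom][pos] >= 4:
                continue
            rows.append((chrom, pos))
        sites = pd.DataFrame(rows, columns=["chrom", "pos"])
        for ps in position_sets:
            fr, _ = kmer_context_freqs(sites, genome, ps)
            tables[ps].append(fr)
        gcs.append(flank_gc(sites, genome, flank_bp).mean_gc)
    return RandomSiteBaseline(
        n=n, reps=reps,
        kmer_mean={ps: pd.concat(v, axis=1).mean(axis=1)
                   for ps, v in tables.items()},
        kmer_sd={ps: pd.concat(v, axis=1).std(axis=1, ddof=1)
                 for ps, v in tables.items()},
        flank_gc_mean=float(np.mean(gcs)), flank_gc_sd=float(np.std(gcs, ddof=1)))


def context_enrichment_test(obs_count: int, obs_total: int, base_count: float,
                            base_total: float,
                            yates: bool = False) -> tuple[float, float]:
    """2×2 chi-square (k-mer vs not, observed vs baseline), 1 df.

    Returns (statistic, p).  A zero-margin table is degenerate: (0.0, 1.0).
    """
    if obs_total <= 0 or base_total <= 0:
        raise ValueError("totals must be positive")
    table = np.array([[obs_count, obs_total - obs_count],
                      [base_count, base_total - base_count]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(stat), float(p)


def kmer_enrichment_table(obs: pd.Series, obs_total: int, base: pd.Series,
                          base_total: float, yates: bool = False
                          ) -> pd.DataFrame:
    """Per-k-mer enrichment tests with Benjamini-Hochberg adjusted p-values.

    The raw p < 0.05 rule remains the default decision criterion; adjusted
    values are reported alongside.
    """
    from statsmodels.stats.multitest import multipletests
    rows = []
    for kmer in obs.index:
        oc = float(obs[kmer]) * obs_total
        bc = float(base.get(kmer, 0.0)) * base_total
        stat, p = context_enrichment_test(oc, obs_total, bc, base_total,
                                          yates=yates)
        rows.append((kmer, obs[kmer], base.get(kmer, np.nan), stat, p))
    df = pd.DataFrame(rows, columns=["kmer", "obs_fraction", "base_fraction",
                                     "chi2", "p"])
    df["p_bh"] = multipletests(df["p"].fillna(1.0), method="fdr_bh")[1]
    return df.set_index("kmer")


# ---------------------------------------------------------------------------
# Codon / amino-acid usage
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    """Codon composition of the longest-isoform CDS space versus EMS hits."""

    genome_codon_freq: pd.Series
    ems_codon_counts: pd.Series
    aa_before: pd.Series        # fractions over NS mutations, original aa
    aa_after: pd.Series         # fractions over NS mutations, substituted aa
    n_ns: int
    n_skipped_models: int = 0


def longest_isoforms(genes: list[GeneModel]) -> list[GeneModel]:
    """One model per gene locus: the longest CDS wins.

    Gene ids of the form ``<locus>.<n>`` are treated as isoforms of
    ``<locus>``; plain ids are their own locus.
    """
    best: dict[str, GeneModel] = {}
    for g in genes:
        locus = g.gene_id.rsplit(".", 1)[0] if "." in g.gene_id else g.gene_id
        if locus not in best or g.cds_length() > best[locus].cds_length():
            best[locus] = g
    return sorted(best.values(), key=lambda g: (g.chrom, g.start))


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """Offset of genome position ``pos`` within the spliced coding-strand CDS."""
    segs = sorted(gene.cds)
    off = 0
    hit = None
    for s, e in segs:
        if s <= pos < e:
            hit = off + (pos - s)
            break
        off += e - s
    if hit is None:
        return None
    if gene.strand == "-":
        return gene.cds_length() - 1 - hit
    return hit


def codon_usage(ns_candidates: pd.DataFrame, genes: list[GeneModel],
                genome: Genome) -> CodonUsageTable:
    """Codon and amino-acid usage of EMS-hit codons (standard genetic code).

    ``ns_candidates`` are exonic SNPs (chrom, pos, ref, alt); synonymous hits
    are excluded from the amino-acid tables, stop gains/losses are tracked as
    '*'.  CDS models whose length is not a multiple of 3 are skipped.
    """
    from Bio.Seq import Seq

    genes = longest_isoforms(genes)
    skipped = 0
    usable = []
    for g in genes:
        if g.cds_length() % 3 != 0 or g.cds_length() == 0:
            skipped += 1
            continue
        usable.append(g)
    codons = ["".join(p) for p in product("ACGT", repeat=3)]
    genome_counts = pd.Series(0, index=codons, dtype=float)
    for g in usable:
        seq = g.cds_sequence(genome)
        for i in range(0, len(seq) - 2, 3):
            c = seq[i:i + 3]
            if c in genome_counts.index:
                genome_counts[c] += 1

    ems_counts = pd.Series(0, index=codons, dtype=int)
    before, after = [], []
    by_chrom = {}
    for g in usable:
        by_chrom.setdefault(g.chrom, []).append(g)
    for row in ns_candidates.itertuples(index=False):
        for g in by_chrom.get(row.chrom, []):
            off = _cds_offset(g, int(row.pos))
            if off is None:
                continue
            cds = g.cds_sequence(genome)
            ci = off // 3
            codon = cds[ci * 3:ci * 3 + 3]
            alt = row.alt if g.strand == "+" else \
                str(Seq(row.alt).complement())
            mutated = list(codon)
            mutated[off % 3] = alt
            mutated = "".join(mutated)
            aa0 = str(Seq(codon).translate())
            aa1 = str(Seq(mutated).translate())
            if aa0 == aa1:
                break  # synonymous: excluded from NS tables
            ems_counts[codon] += 1
            before.append(aa0)
            after.append(aa1)
            break
    n_ns = len(before)
    aa_before = pd.Series(before).value_counts() / n_ns if n_ns \
        else pd.Series(dtype=float)
    aa_after = pd.Series(after).value_counts() / n_ns if n_ns \
        else pd.Series(dtype=float)
    return CodonUsageTable(
        genome_codon_freq=genome_counts / genome_counts.sum()
        if genome_counts.sum() else genome_counts,
        ems_codon_counts=ems_counts, aa_before=aa_before, aa_after=aa_after,
        n_ns=n_ns, n_skipped_models=skipped)
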