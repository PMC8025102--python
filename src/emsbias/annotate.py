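"""Genic-context classification of SNPs and cross-reference with the natural
panel.

Categories, in precedence order: exon (split non-synonymous / synonymous /
non-coding) > intron > upstream3k > downstream3k > intergenic.  Upstream and
downstream are strand-aware relative to the gene; a SNP upstream of one gene
and downstream of another is classed upstream.  "Gene body" is the transcript
span of the longest isoform, consistent with the codon-usage analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BASES, GeneModel, Genome
from .spectrum import RefMismatchError, _cds_offset, longest_isoforms

CATEGORIES = ["exon_nonsynonymous", "exon_synonymous", "exon_noncoding",
              "intron", "upstream3k", "downstream3k", "intergenic"]

_PRECEDENCE = {"exon": 0, "intron": 1, "upstream3k": 2, "downstream3k": 3}


def _classify_vs_gene(g: GeneModel, pos: int, flank: int) -> str | None:
    if g.start <= pos < g.end:
        if any(s <= pos < e for s, e in g.exons):
            return "exon"
        return "intron"
    if g.strand == "+":
        upstream = g.start - flank <= pos < g.start
        downstream = g.end <= pos < g.end + flank
    else:
        upstream = g.end <= pos < g.end + flank
        downstream = g.start - flank <= pos < g.start
    if upstream:
        return "upstream3k"
    if downstream:
        return "downstream3k"
    return None


def _exon_effect(g: GeneModel, pos: int, ref: str, alt: str,
                 genome: Genome) -> tuple[str, str | None]:
    """(category, amino-acid change) for an exonic SNP."""
    from Bio.Seq import Seq
    off = _cds_offset(g, pos)
    if off is None:
        return "exon_noncoding", None
    cds = g.cds_sequence(genome)
    ci = off // 3
    codon = cds[ci * 3:ci * 3 + 3]
    if len(codon) < 3:
        return "exon_noncoding", None
    alt_cs = alt if g.strand == "+" else str(Seq(alt).complement())
    mutated = codon[:off % 3] + alt_cs + codon[off % 3 + 1:]
    aa0 = str(Seq(codon).translate())
    aa1 = str(Seq(mutated).translate())
    if aa0 == aa1:
        return "exon_synonymous", None
    return "exon_nonsynonymous", f"{aa0}{ci + 1}{aa1}"


def annotate_snps(snps: pd.DataFrame, genes: list[GeneModel], genome: Genome,
                  flank: int = 3000) -> pd.DataFrame:
    """One annotation row per SNP.

    Overlapping genes: the gene giving the highest-precedence category wins;
    ties break to the lexicographically smaller gene id.
    """
    models = longest_isoforms(genes)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in models:
        by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    for row in snps.itertuples(index=False):
        pos = int(row.pos)
        if genome.chroms[row.chrom][pos] != BASES.index(row.ref):
            raise RefMismatchError(
                f"ref allele mismatch at {row.chrom}:{pos}")
        best: tuple[int, str, GeneModel] | None = None
        for g in by_chrom.get(row.chrom, []):
            if pos < g.start - flank or pos >= g.end + flank:
                continue
            cat = _classify_vs_gene(g, pos, flank)
            if cat is None:
                continue
            key = (_PRECEDENCE[cat], g.gene_id)
            if best is None or key < (best[0], best[2].gene_id):
                best = (_PRECEDENCE[cat], cat, g)
        if best is None:
            rows.append((row.chrom, pos, row.ref, row.alt, "intergenic",
                         None, None))
            continue
        _, cat, g = best
        aa = None
        if cat == "exon":
            cat, aa = _exon_effect(g, pos, row.ref, row.alt, genome)
        rows.append((row.chrom, pos, row.ref, row.alt, cat, g.gene_id, aa))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "category", "gene_id", "aa_change"])


def category_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Category fractions; exon subcategories also folded into an exon total."""
    counts = annotated["category"].value_counts().reindex(CATEGORIES,
                                                          fill_value=0)
    n = len(annotated)
    df = pd.DataFrame({"count": counts,
                       "fraction": counts / n if n else np.nan})
    exon = counts[["exon_nonsynonymous", "exon_synonymous",
                   "exon_noncoding"]].sum()
    df.loc["exon_total"] = [exon, exon / n if n else np.nan]
    genic = exon + counts["intron"]
    df.loc["gene_body_total"] = [genic, genic / n if n else np.nan]
    return df


@dataclass
class PanelSharing:
    per_snp: pd.DataFrame
    shared_fraction: float
    shared_maf_lt: float        # among shared, fraction with MAF < maf_cut
    maf_cut: float


def shared_with_panel(ems_snps: pd.DataFrame, panel_sites: pd.DataFrame,
                      maf_cut: float = 0.10) -> PanelSharing:
    """Flag EMS SNPs present in the (filtered) natural panel.

    Shared means same chromosome, position, and alt allele.  Reports the
    shared fraction of all EMS SNPs and, among shared, the fraction with
    panel MAF below ``maf_cut``.
    """
    key = panel_sites.set_index(["chrom", "pos", "alt"])["maf"]
    out = ems_snps[["chrom", "pos", "ref", "alt"]].copy()
    idx = pd.MultiIndex.from_frame(out[["chrom", "pos", "alt"]])
    maf = key.reindex(idx)
    out["panel_shared"] = (~maf.isna()).to_numpy()
    out["panel_maf"] = maf.to_numpy()
    n = len(out)
    shared = out[out["panel_shared"]]
    return PanelSharing(
        per_snp=out,
        shared_fraction=len(shared) / n if n else float("nan"),
        shared_maf_lt=float((shared["panel_maf"] < maf_cut).mean())
        if len(shared) else float("nan"),
        maf_cut=maf_cut)
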