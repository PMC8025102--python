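"""Shared containers and file-format glue.

Internal coordinates are 0-based, half-open throughout the package; VCF and
GFF3 files are read and written 1-based per their standards.  Sequences are
held as ``numpy.uint8`` code arrays (A=0, C=1, G=2, T=3, N=4) so that the
context and island scans can run vectorised over megabase chromosomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGTN"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string into the package's uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return codes_to_seq(revcomp_codes(seq_to_codes(seq)))


@dataclass(frozen=True)
class Domain:
    """A chromatin domain annotation (euchromatin or heterochromatin)."""

    chrom: str
    start: int
    end: int
    kind: str  # "euchromatin" | "heterochromatin"


class Genome:
    """In-memory genome: chromosome name -> uint8 code array.

    Optionally carries the chromatin-domain layout used by the simulator and
    the overlay analyses.
    """

    def __init__(self, chroms: Mapping[str, np.ndarray],
                 domains: Sequence[Domain] | None = None):
        self.chroms: dict[str, np.ndarray] = {
            name: np.asarray(arr, dtype=np.uint8) for name, arr in chroms.items()
        }
        self.domains: list[Domain] = list(domains or [])

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(arr) for name, arr in self.chroms.items()}

    def __len__(self) -> int:
        return sum(len(a) for a in self.chroms.values())

    def codes(self, chrom: str) -> np.ndarray:
        return self.chroms[chrom]

    def sequence(self, chrom: str, start: int | None = None,
                 end: int | None = None) -> str:
        return codes_to_seq(self.chroms[chrom][start:end])

    def base(self, chrom: str, pos: int) -> str:
        return BASES[self.chroms[chrom][pos]]

    def gc_fraction(self, chrom: str | None = None,
                    start: int | None = None, end: int | None = None) -> float:
        """GC fraction over ACGT bases (N excluded from the denominator)."""
        if chrom is None:
            arrays = list(self.chroms.values())
        else:
            arrays = [self.chroms[chrom][start:end]]
        gc = acgt = 0
        for arr in arrays:
            gc += int(np.count_nonzero((arr == 1) | (arr == 2)))
            acgt += int(np.count_nonzero(arr < 4))
        return gc / acgt if acgt else float("nan")

    def domain_kind_mask(self, chrom: str, kind: str = "heterochromatin") -> np.ndarray:
        """Boolean per-base mask of domains of the given kind on one chromosome."""
        mask = np.zeros(len(self.chroms[chrom]), dtype=bool)
        for d in self.domains:
            if d.chrom == chrom and d.kind == kind:
                mask[d.start:d.end] = True
        return mask

    def revcomp(self) -> "Genome":
        """Reverse-complement every chromosome (domains are mirrored too)."""
        out = {name: revcomp_codes(arr) for name, arr in self.chroms.items()}
        doms = [Domain(d.chrom, len(self.chroms[d.chrom]) - d.end,
                       len(self.chroms[d.chrom]) - d.start, d.kind)
                for d in self.domains]
        return Genome(out, doms)

    # ---- FASTA ----
    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, arr in self.chroms.items():
                fh.write(f">{name}\n")
                seq = codes_to_seq(arr)
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    @classmethod
    def read_fasta(cls, path: str | Path,
                   domains: Sequence[Domain] | None = None) -> "Genome":
        import pyfaidx
        fa = pyfaidx.Fasta(str(path))
        chroms = {name: seq_to_codes(str(fa[name][:])) for name in fa.keys()}
        return cls(chroms, domains)


def write_domains_bed(domains: Iterable[Domain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.kind}\n")


def read_domains_bed(path: str | Path) -> list[Domain]:
    out = []
    with open(path) as fh:
        for line in fh:
            c, s, e, k = line.rstrip("\n").split("\t")[:4]
            out.append(Domain(c, int(s), int(e), k))
    return out


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A single-isoform gene model (0-based half-open coordinates).

    ``exons`` and ``cds`` are sorted lists of (start, end) intervals in genome
    coordinates regardless of strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" | "-"
    is_te: bool
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def cds_codes(self, genome: Genome) -> np.ndarray:
        """Spliced CDS on the coding strand."""
        parts = [genome.chroms[self.chrom][s:e] for s, e in sorted(self.cds)]
        arr = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        if self.strand == "-":
            arr = revcomp_codes(arr)
        return arr

    def cds_sequence(self, genome: Genome) -> str:
        return codes_to_seq(self.cds_codes(genome))


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS features with a ``gene_biotype=TE|non-TE`` tag."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            biotype = "TE" if g.is_te else "non-TE"
            fh.write(f"{g.chrom}\temsbias\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};gene_biotype={biotype}\n")
            mrna = f"{g.gene_id}.1"
            fh.write(f"{g.chrom}\temsbias\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n")
            for s, e in sorted(g.exons):
                fh.write(f"{g.chrom}\temsbias\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tParent={mrna}\n")
            for s, e in sorted(g.cds):
                fh.write(f"{g.chrom}\temsbias\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t0\tParent={mrna}\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        biotype = (g.attributes.get("gene_biotype") or ["non-TE"])[0]
        exons, cds = [], []
        for child in db.children(g, featuretype="exon"):
            exons.append((child.start - 1, child.end))
        for child in db.children(g, featuretype="CDS"):
            cds.append((child.start - 1, child.end))
        genes.append(GeneModel(g.id, g.seqid, g.start - 1, g.end, g.strand,
                               biotype == "TE", sorted(exons), sorted(cds)))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# ---------------------------------------------------------------------------
# Bulk variant VCFs
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ["bulk_id", "chrom", "pos", "ref", "alt",
                   "alt_reads", "total_reads", "alt_mq20"]


def write_bulk_vcf(records: pd.DataFrame, chrom_lengths: Mapping[str, int],
                   path: str | Path, sample: str) -> None:
    """Write one bulk's variant records as VCF v4.2.

    ``records`` needs columns chrom, pos (0-based), ref, alt, alt_reads,
    total_reads, alt_mq20.  AD/DP go in FORMAT; the mapping-quality-passing
    alt-read count goes in the custom INFO field MQAD.
    """
    import pysam
    header = pysam.VariantHeader()
    header.add_line('##source=emsbias-simulator')
    for name, length in chrom_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("MQAD", 1, "Integer",
                    "Alt read count with mapping quality >= 20")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.add_sample(sample)
    records = records.sort_values(["chrom", "pos"], kind="mergesort")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in records.itertuples(index=False):
            rec = vcf.new_record(contig=row.chrom, start=int(row.pos),
                                 stop=int(row.pos) + 1,
                                 alleles=(row.ref, row.alt))
            rec.info["MQAD"] = int(row.alt_mq20)
            alt, dp = int(row.alt_reads), int(row.total_reads)
            rec.samples[sample]["GT"] = (0, 1) if alt < dp else (1, 1)
            rec.samples[sample]["AD"] = (dp - alt, alt)
            rec.samples[sample]["DP"] = dp
            vcf.write(rec)


def read_bulk_vcf(path: str | Path, bulk_id: str | None = None,
                  mq_field: str = "MQAD") -> pd.DataFrame:
    """Read one bulk VCF into the caller's variant-table layout.

    For VCFs lacking the simulator's MQAD INFO field, ``mq_field=None`` falls
    back to using the raw alt-read count as the MQ-passing count.
    """
    import pysam
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        if bulk_id is None:
            bulk_id = sample
        for rec in vcf:
            ad = rec.samples[sample]["AD"]
            dp = rec.samples[sample]["DP"]
            alt = int(ad[1])
            if mq_field and mq_field in rec.info:
                mq = int(rec.info[mq_field])
            else:
                mq = alt
            rows.append((bulk_id, rec.contig, rec.start, rec.ref,
                         rec.alts[0], alt, int(dp), mq))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def read_bulk_vcf_dir(vcf_dir: str | Path, mq_field: str = "MQAD") -> pd.DataFrame:
    """Read every ``*.vcf`` in a directory; bulk id = file stem."""
    frames = []
    for path in sorted(Path(vcf_dir).glob("*.vcf")):
        frames.append(read_bulk_vcf(path, bulk_id=path.stem, mq_field=mq_field))
    if not frames:
        raise FileNotFoundError(f"no .vcf files under {vcf_dir}")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Simple track formats
# ---------------------------------------------------------------------------

def write_bed3(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed3(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.4f")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"])


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
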