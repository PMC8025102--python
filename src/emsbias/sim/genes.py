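"""Synthetic gene models (TE and non-TE) written into the genome.

Gene placement is weighted so TE genes concentrate in heterochromatin.  CDS
sequence is rewritten in place (start codon, sense codons, stop codon) so
every model translates cleanly; this happens before mutations are implanted.
"""

from __future__ import annotations

import numpy as np

from ..io import GeneModel, Genome, revcomp_codes, seq_to_codes
from .config import SimConfig

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE = [c for c in _CODONS if c not in _STOPS]
_SENSE_CODES = np.array([seq_to_codes(c) for c in _SENSE])
_STOP_CODES = np.array([seq_to_codes(c) for c in sorted(_STOPS)])
_START = seq_to_codes("ATG")


def _sample_structure(rng: np.random.Generator) -> tuple[int, list[int]]:
    """Pick a CDS length (multiple of 3) and intron lengths."""
    n_codons = int(rng.integers(100, 500))
    n_exons = int(rng.integers(1, 4))
    introns = [int(rng.integers(80, 400)) for _ in range(n_exons - 1)]
    return n_codons * 3, introns


def generate_gene_models(genome: Genome, config: SimConfig,
                         rng: np.random.Generator | None = None) -> list[GeneModel]:
    """Place ``config.n_genes`` gene models and rewrite their CDS in place.

    TE genes are placed with ``te_het_weight``-fold preference for
    heterochromatin; non-TE genes with the inverse preference.  Genes never
    overlap.  Exons coincide with CDS segments (no UTRs are modelled).
    """
    if rng is None:
        rng = config.rng_streams()["genes"]
    n_te = int(round(config.n_genes * config.te_gene_fraction))
    is_te_flags = np.array([True] * n_te + [False] * (config.n_genes - n_te))
    rng.shuffle(is_te_flags)

    chrom_names = list(genome.chroms)
    lengths = np.array([len(genome.chroms[c]) for c in chrom_names], dtype=float)
    het_masks = {c: genome.domain_kind_mask(c, "heterochromatin")
                 for c in chrom_names}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    genes: list[GeneModel] = []
    for i, is_te in enumerate(is_te_flags):
        cds_len, introns = _sample_structure(rng)
        span = cds_len + sum(introns)
        for _attempt in range(200):
            chrom = chrom_names[rng.choice(len(chrom_names), p=lengths / lengths.sum())]
            L = len(genome.chroms[chrom])
            if span + 2 >= L:
                continue
            start = int(rng.integers(0, L - span))
            in_het = bool(het_masks[chrom][min(start + span // 2, L - 1)])
            w = config.te_het_weight
            keep_p = (w / (w + 1)) if (is_te == in_het) else (1 / (w + 1))
            if rng.random() > keep_p:
                continue
            end = start + span
            if any(s < end and start < e for s, e in occupied[chrom]):
                continue
            break
        else:
            raise RuntimeError("could not place gene; genome too crowded")
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"

        # genome-coordinate CDS segments
        segs: list[tuple[int, int]] = []
        pos = start
        exon_lens = _split_lengths(cds_len, len(introns) + 1, rng)
        for j, el in enumerate(exon_lens):
            segs.append((pos, pos + el))
            pos += el
            if j < len(introns):
                pos += introns[j]

        _write_cds(genome, chrom, segs, strand, rng)
        genes.append(GeneModel(f"gene{i + 1:04d}", chrom, start, end, strand,
                               bool(is_te), exons=list(segs), cds=list(segs)))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _split_lengths(total: int, parts: int, rng: np.random.Generator) -> list[int]:
    """Split ``total`` (multiple of 3) into ``parts`` positive multiples of 3."""
    codons = total // 3
    cuts = sorted(rng.choice(codons - 1, size=parts - 1, replace=False) + 1) \
        if parts > 1 else []
    bounds = [0] + list(cuts) + [codons]
    return [(bounds[k + 1] - bounds[k]) * 3 for k in range(parts)]


def _write_cds(genome: Genome, chrom: str, segs: list[tuple[int, int]],
               strand: str, rng: np.random.Generator) -> None:
    total = sum(e - s for s, e in segs)
    n_codons = total // 3
    body = _SENSE_CODES[rng.integers(0, len(_SENSE), size=n_codons - 2)].ravel()
    stop = _STOP_CODES[rng.integers(0, len(_STOP_CODES))]
    cds = np.concatenate([_START, body, stop]).astype(np.uint8)
    if strand == "-":
        cds = revcomp_codes(cds)
    off = 0
    for s, e in segs:
        genome.chroms[chrom][s:e] = cds[off:off + (e - s)]
        off += e - s
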