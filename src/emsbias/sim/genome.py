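"""Synthetic genome generation with domain-structured base composition."""

from __future__ import annotations

import numpy as np

from ..io import Domain, Genome
from .config import SimConfig


def domain_layout(config: SimConfig) -> list[Domain]:
    """Expand the fractional per-chromosome layout into base-pair domains."""
    domains = []
    for chrom in config.chrom_names():
        L = config.chrom_len
        for fs, fe, kind in config.domain_fractions:
            start, end = int(round(fs * L)), int(round(fe * L))
            if end > start:
                domains.append(Domain(chrom, start, end, kind))
    return domains


def generate_genome(config: SimConfig,
                    rng: np.random.Generator | None = None) -> Genome:
    """Generate the genome described by ``config``.

    Bases are drawn i.i.d. within each domain at the domain's GC target
    (euchromatin ``eu_gc``, heterochromatin ``het_gc``); heterochromatin
    additionally receives implanted CG dinucleotides at rate
    ``het_cpg_boost`` so that CpG-island density is elevated there, as it is
    around rice centromeres.
    """
    config.validate()
    if rng is None:
        rng = config.rng_streams()["genome"]
    domains = domain_layout(config)
    chroms: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names():
        arr = np.empty(config.chrom_len, dtype=np.uint8)
        for d in domains:
            if d.chrom != chrom:
                continue
            gc = config.het_gc if d.kind == "heterochromatin" else config.eu_gc
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            n = d.end - d.start
            arr[d.start:d.end] = rng.choice(4, size=n, p=p).astype(np.uint8)
            if d.kind == "heterochromatin" and config.het_cpg_boost > 0:
                k = rng.binomial(n - 1, config.het_cpg_boost)
                if k:
                    starts = d.start + rng.choice(n - 1, size=k, replace=False)
                    arr[starts] = 1      # C
                    arr[starts + 1] = 2  # G
        chroms[chrom] = arr
    return Genome(chroms, domains)
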