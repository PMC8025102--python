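"""Simulation configuration.

The simulator emulates a bulked-segregant resequencing experiment: a panel of
recessive mutants, each backcrossed and selfed, with 30 phenotype-selected F2
individuals pooled and sequenced per mutant.  Mutations are implanted under a
context-dependent hazard model (G/C preference, trinucleotide multipliers,
heterochromatin enrichment) so that the downstream analyses can recover the
biases from the generated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass
class ContextRateModel:
    """Per-site EMS mutation hazard model.

    hazard(site) = base_rate × gc_multiplier[site is G/C]
                 × kmer_multipliers[trinucleotide ending at site]
                 × heterochromatin_multiplier[site in heterochromatin]

    ``base_rate`` is mutations per bp per bulk.  ``kmer_multipliers`` is keyed
    by the upstream trinucleotide context (positions −2/−1/0, the site last),
    the orientation in which the AAG preference upstream of mutated G was
    reported.  The identity model (all multipliers 1) places mutations
    uniformly.  ``gc_transition_fraction`` is the conditional probability of a
    transition (G→A, C→T) given a mutation at a G/C site; the remaining mass
    splits evenly over the two transversions.  At A/T sites the conditional
    alt distribution follows the observed EMS spectrum: transition 0.47,
    A→T/T→A 0.36, A→C/T→G 0.17.
    """

    base_rate: float = 9e-7
    gc_multiplier: float = 3.0
    kmer_multipliers: dict[str, float] = field(default_factory=dict)
    heterochromatin_multiplier: float = 3.0
    gc_transition_fraction: float = 0.85
    at_alt_fractions: tuple[float, float, float] = (0.47, 0.36, 0.17)

    def validate(self) -> None:
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if self.gc_multiplier <= 0 or self.heterochromatin_multiplier <= 0:
            raise ValueError("multipliers must be > 0")
        for k, v in self.kmer_multipliers.items():
            if len(k) != 3 or any(b not in "ACGT" for b in k):
                raise ValueError(f"bad trinucleotide key {k!r}")
            if v <= 0:
                raise ValueError("multipliers must be > 0")
        if not 0 <= self.gc_transition_fraction <= 1:
            raise ValueError("gc_transition_fraction must be in [0,1]")

    @classmethod
    def identity(cls, base_rate: float) -> "ContextRateModel":
        return cls(base_rate=base_rate, gc_multiplier=1.0,
                   kmer_multipliers={}, heterochromatin_multiplier=1.0)


#: default per-chromosome domain layout as length fractions: a pericentromeric
#: heterochromatin block spanning the middle 30% of each chromosome.
DEFAULT_DOMAIN_FRACTIONS: tuple[tuple[float, float, str], ...] = (
    (0.00, 0.35, "euchromatin"),
    (0.35, 0.65, "heterochromatin"),
    (0.65, 1.00, "euchromatin"),
)


@dataclass
class TrackConfig:
    """Chromatin-track generator settings.

    ``experiments`` maps modification name -> number of replicate experiment
    tracks.  ``active`` marks modifications whose signal is high in
    euchromatin (acetylation, H2A.Z); the others (DNA methylation, MNase) are
    high in heterochromatin.  ``contrast`` is the high:low mean signal ratio
    between matched and unmatched domains.
    """

    experiments: dict[str, int] = field(default_factory=lambda: {
        "DNA-methylation": 3, "MNase": 2, "H3K9ac": 2, "H3K23ac": 2,
        "H2A.Z": 2,
    })
    active: tuple[str, ...] = ("H3K9ac", "H3K23ac", "H3K27ac", "H4K12ac",
                               "H4K16ac", "H3K4ac", "H2A.Z")
    contrast: float = 3.0
    high_mean: float = 3.0
    interval: int = 500
    dropout: float = 0.05  # fraction of intervals left uncovered
    dh_rate_eu: float = 4e-4   # DH sites per bp in euchromatin
    dh_rate_het: float = 8e-5
    dh_len_range: tuple[int, int] = (50, 300)


@dataclass
class SimConfig:
    """Full study-design configuration.

    Defaults mirror the emulated experiment: 52 bulks of 30 pooled F2
    individuals at ~39× mean depth, on a two-chromosome 5-Mb genome with a
    pericentromeric heterochromatin block per chromosome.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 2_500_000
    n_bulks: int = 52
    pool_size: int = 30
    depth: float = 39.0
    seq_error_rate: float = 0.05
    error_site_rate: float = 2e-5        # observed error sites per bp per bulk
    natural_site_rate: float = 2e-4      # shared HHZ-vs-reference background
    residual_fragment_prob: float = 0.5  # per-bulk chance of one fragment
    residual_fragment_len: int = 150_000
    residual_fragment_snp_rate: float = 1e-3
    mq_pass_rate: float = 0.95
    domain_fractions: tuple[tuple[float, float, str], ...] = DEFAULT_DOMAIN_FRACTIONS
    ems_rate_model: ContextRateModel = field(default_factory=ContextRateModel)
    eu_gc: float = 0.40
    het_gc: float = 0.55
    het_cpg_boost: float = 0.02
    n_genes: int = 400
    te_gene_fraction: float = 0.4
    te_het_weight: float = 5.0
    n_varieties: int = 100
    panel_site_rate: float = 4e-4
    panel_truth_overlap: float = 0.22
    n_expr_datasets: int = 284
    low_expr_prob: tuple[float, float] = (0.35, 0.85)  # (euchromatin, heterochromatin)
    tracks: TrackConfig = field(default_factory=TrackConfig)

    def validate(self) -> None:
        if self.n_chrom <= 0 or self.chrom_len <= 0:
            raise ValueError("n_chrom and chrom_len must be positive")
        if self.n_bulks <= 0 or self.pool_size <= 0 or self.depth <= 0:
            raise ValueError("bulk design parameters must be positive")
        for r in (self.seq_error_rate, self.natural_site_rate,
                  self.residual_fragment_prob, self.mq_pass_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0,1]")
        cover = 0.0
        prev_end = 0.0
        for s, e, kind in self.domain_fractions:
            if kind not in ("euchromatin", "heterochromatin"):
                raise ValueError(f"unknown domain kind {kind!r}")
            if abs(s - prev_end) > 1e-9 or e <= s:
                raise ValueError("domains must tile each chromosome without "
                                 "overlap or gaps")
            prev_end = e
            cover += e - s
        if abs(cover - 1.0) > 1e-9:
            raise ValueError("domain fractions must cover [0, 1]")
        self.ems_rate_model.validate()

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def rng_streams(self) -> dict[str, np.random.Generator]:
        """Named child RNG streams so stages stay independent and reproducible."""
        names = ["genome", "genes", "mutations", "bulks", "panel", "tracks",
                 "expression"]
        seqs = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}

    def to_dict(self) -> dict:
        return asdict(self)
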