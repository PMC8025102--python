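"""EMS mutation implanting under the context-dependent hazard model."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..io import BASES, Genome, read_json, write_json
from .config import ContextRateModel, SimConfig

TRUTH_EMS_COLUMNS = ["bulk_id", "chrom", "pos", "ref", "alt", "zygosity", "causal"]

_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T (codes)


@dataclass
class TruthSet:
    """Simulator ground truth for recovery tests.

    ``ems_sites``: one row per implanted mutation (bulk_id, chrom, pos, ref,
    alt, zygosity, causal).  Zygosity is the pooled alt-allele frequency: 1.0
    at each bulk's causal site, 0.5 at unlinked heterozygous sites.
    ``natural_sites``: background SNPs shared by every bulk.
    ``residual_fragments``: per-bulk dense heterozygous fragments (with their
    own SNP lists in ``fragment_sites``) that the caller must mask out.
    """

    ems_sites: pd.DataFrame
    natural_sites: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt"]))
    residual_fragments: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["bulk_id", "chrom", "start", "end"]))
    fragment_sites: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["bulk_id", "chrom", "pos", "ref", "alt"]))

    def causal_sites(self) -> pd.DataFrame:
        return self.ems_sites[self.ems_sites["causal"]]

    def to_json(self, path: str | Path) -> None:
        write_json({
            "ems_sites": self.ems_sites.to_dict(orient="list"),
            "natural_sites": self.natural_sites.to_dict(orient="list"),
            "residual_fragments": self.residual_fragments.to_dict(orient="list"),
            "fragment_sites": self.fragment_sites.to_dict(orient="list"),
        }, path)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        raw = read_json(path)
        return cls(
            ems_sites=pd.DataFrame(raw["ems_sites"], columns=TRUTH_EMS_COLUMNS),
            natural_sites=pd.DataFrame(raw["natural_sites"],
                                       columns=["chrom", "pos", "ref", "alt"]),
            residual_fragments=pd.DataFrame(
                raw["residual_fragments"],
                columns=["bulk_id", "chrom", "start", "end"]),
            fragment_sites=pd.DataFrame(
                raw["fragment_sites"],
                columns=["bulk_id", "chrom", "pos", "ref", "alt"]),
        )


def context_hazard(genome: Genome, model: ContextRateModel,
                   chrom: str) -> np.ndarray:
    """Per-base mutation hazard for one chromosome.

    The trinucleotide multiplier keys on positions −2/−1/0 (the mutated site
    last); the first two bases of a chromosome only see the G/C and domain
    multipliers.  N bases get hazard 0.
    """
    codes = genome.chroms[chrom]
    L = len(codes)
    hazard = np.full(L, model.base_rate, dtype=np.float64)
    is_gc = (codes == 1) | (codes == 2)
    hazard[is_gc] *= model.gc_multiplier
    if model.kmer_multipliers:
        mult = np.ones(64, dtype=np.float64)
        for kmer, m in model.kmer_multipliers.items():
            idx = 0
            for b in kmer:
                idx = idx * 4 + BASES.index(b)
            mult[idx] = m
        valid = (codes[:-2] < 4) & (codes[1:-1] < 4) & (codes[2:] < 4)
        tri = (codes[:-2].astype(np.int32) * 16
               + codes[1:-1].astype(np.int32) * 4 + codes[2:])
        hazard[2:][valid] *= mult[tri[valid]]
    if model.heterochromatin_multiplier != 1.0:
        het = genome.domain_kind_mask(chrom, "heterochromatin")
        hazard[het] *= model.heterochromatin_multiplier
    hazard[codes >= 4] = 0.0
    return hazard


def calibrated_base_rate(genome: Genome, model: ContextRateModel,
                         n_bulks: int, target_total: float) -> float:
    """Base rate at which the model's expected total implant count over all
    bulks equals ``target_total``.

    Used to pin the simulated genome-wide SNP density (e.g. a mean of 4.65
    SNPs per 100-kb bin) regardless of the multipliers in force.
    """
    probe = ContextRateModel(base_rate=1.0,
                             gc_multiplier=model.gc_multiplier,
                             kmer_multipliers=dict(model.kmer_multipliers),
                             heterochromatin_multiplier=model.heterochromatin_multiplier)
    total_weight = sum(float(context_hazard(genome, probe, c).sum())
                       for c in genome.chroms)
    return target_total / (n_bulks * total_weight)


def _draw_alt(ref_code: int, model: ContextRateModel,
              rng: np.random.Generator) -> int:
    others = [b for b in range(4) if b != ref_code]
    ti = _TRANSITION[ref_code]
    if ref_code in (1, 2):  # C or G
        p = model.gc_transition_fraction
        probs = [(p if b == ti else (1 - p) / 2) for b in others]
    else:
        t, tv_wc, tv_other = model.at_alt_fractions
        # transversion to the Watson-Crick partner (A->T / T->A) vs the other
        wc = 3 - ref_code if ref_code in (0, 3) else None
        probs = []
        for b in others:
            if b == ti:
                probs.append(t)
            elif b == wc:
                probs.append(tv_wc)
            else:
                probs.append(tv_other)
    probs = np.asarray(probs) / np.sum(probs)
    return int(others[rng.choice(3, p=probs)])


def implant_ems_mutations(genome: Genome, model: ContextRateModel,
                          n_bulks: int,
                          rng: np.random.Generator | int) -> TruthSet:
    """Implant per-bulk EMS mutations; returns the (EMS part of the) truth set.

    Sites are drawn independently per base with probability equal to the
    context hazard, so per-bulk counts are Poisson-distributed under the
    identity model.  Each site is unique to one bulk (cross-bulk collisions,
    which are vanishingly rare at realistic rates, are dropped from the later
    bulk).  One implanted site per bulk is designated causal (zygosity 1.0).
    """
    model.validate()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    hazards = {c: context_hazard(genome, model, c) for c in genome.chroms}
    expected = n_bulks * sum(float(h.sum()) for h in hazards.values())
    if expected > 0.1 * len(genome):
        raise ValueError(
            f"expected mutation count {expected:.0f} exceeds 10% of the "
            "genome; rate model is unrealistically dense")
    taken: set[tuple[str, int]] = set()
    rows = []
    for b in range(n_bulks):
        bulk_id = f"bulk{b + 1:02d}"
        bulk_rows = []
        for chrom, hazard in hazards.items():
            if not hazard.any():
                continue
            hits = np.nonzero(rng.random(len(hazard)) < hazard)[0]
            for pos in hits:
                key = (chrom, int(pos))
                if key in taken:
                    continue
                taken.add(key)
                ref_code = int(genome.chroms[chrom][pos])
                alt_code = _draw_alt(ref_code, model, rng)
                bulk_rows.append([bulk_id, chrom, int(pos), BASES[ref_code],
                                  BASES[alt_code], 0.5, False])
        if bulk_rows:
            causal_idx = int(rng.integers(0, len(bulk_rows)))
            bulk_rows[causal_idx][5] = 1.0
            bulk_rows[causal_idx][6] = True
        rows.extend(bulk_rows)
    ems = pd.DataFrame(rows, columns=TRUTH_EMS_COLUMNS)
    if len(ems):
        ems = ems.sort_values(["bulk_id", "chrom", "pos"]).reset_index(drop=True)
    return TruthSet(ems_sites=ems)
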