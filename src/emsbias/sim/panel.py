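"""Natural-diversity SNP panel: a scaled stand-in for a germplasm resequencing
panel with per-variety genotypes, realistic allele-frequency and missingness
structure, and a configurable overlap with the implanted EMS truth sites."""

from __future__ import annotations

from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ..io import BASES, Genome
from .config import SimConfig
from .mutations import TruthSet


def default_maf_dist(rng: np.random.Generator, n: int) -> np.ndarray:
    """Skewed minor-allele-frequency distribution on (0, 0.5].

    Beta(0.7, 1.8) scaled to [0, 0.5]: most variants rare, matching the
    shape of diversity panels where roughly half the shared variants sit
    below MAF 0.10.
    """
    return 0.5 * rng.beta(0.7, 1.8, size=n)


def default_missing_dist(rng: np.random.Generator, n: int) -> np.ndarray:
    """Missing-call rate per site, mostly well below the 0.8 filter."""
    return np.clip(rng.beta(1.0, 6.0, size=n), 0, 1)


def generate_natural_panel(genome: Genome, truth: TruthSet, config: SimConfig,
                           rng: np.random.Generator | None = None,
                           maf_dist: Callable | None = None,
                           missing_dist: Callable | None = None) -> pd.DataFrame:
    """Biallelic panel sites with per-variety genotype dosages.

    Returns a DataFrame with columns chrom, pos, ref, alt followed by one
    column per variety holding minor-allele dosage 0/1/2 (NaN = missing).  A
    fraction ``panel_truth_overlap`` of the implanted EMS truth sites is
    included in the panel (same position and alt allele), so the downstream
    shared-with-panel fraction recovers that setting.
    """
    if config.n_varieties < 2:
        raise ValueError("n_varieties must be >= 2")
    if rng is None:
        rng = config.rng_streams()["panel"]
    maf_dist = maf_dist or default_maf_dist
    missing_dist = missing_dist or default_missing_dist

    n_sites = int(rng.poisson(config.panel_site_rate * len(genome)))
    ems = truth.ems_sites
    n_overlap = int(round(len(ems) * config.panel_truth_overlap))
    rows = []
    if n_overlap and len(ems):
        pick = rng.choice(len(ems), size=min(n_overlap, len(ems)), replace=False)
        for i in pick:
            r = ems.iloc[int(i)]
            rows.append((r["chrom"], int(r["pos"]), r["ref"], r["alt"]))
    n_sites = max(n_sites, len(rows))
    taken = {(c, p) for c, p, _, _ in rows}
    chrom_names = list(genome.chroms)
    lengths = np.array([len(genome.chroms[c]) for c in chrom_names], float)
    while len(rows) < n_sites:
        chrom = chrom_names[rng.choice(len(chrom_names), p=lengths / lengths.sum())]
        pos = int(rng.integers(0, len(genome.chroms[chrom])))
        if (chrom, pos) in taken or genome.chroms[chrom][pos] >= 4:
            continue
        taken.add((chrom, pos))
        ref = int(genome.chroms[chrom][pos])
        alt = int(rng.choice([b for b in range(4) if b != ref]))
        rows.append((chrom, pos, BASES[ref], BASES[alt]))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    n = len(df)
    mafs = maf_dist(rng, n)
    miss = missing_dist(rng, n)
    geno = rng.binomial(2, mafs[:, None],
                        size=(n, config.n_varieties)).astype(float)
    missing_mask = rng.random((n, config.n_varieties)) < miss[:, None]
    geno[missing_mask] = np.nan
    geno_df = pd.DataFrame(
        geno, columns=[f"var{v + 1:03d}" for v in range(config.n_varieties)])
    df = pd.concat([df, geno_df], axis=1)
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.0f")


def read_panel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df
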