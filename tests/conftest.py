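from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from emsbias.io import Genome, seq_to_codes
from emsbias.sim import (ContextRateModel, SimConfig, TruthSet,
                         acceptance_sim_config, simulate_all)


def genome_from_seqs(seqs: dict[str, str], domains=None) -> Genome:
    return Genome({c: seq_to_codes(s) for c, s in seqs.items()}, domains)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A compact but complete simulated study (1 chromosome, 4 bulks)."""
    cfg = SimConfig(
        seed=7, n_chrom=1, chrom_len=600_000, n_bulks=4,
        ems_rate_model=ContextRateModel(base_rate=4e-6, gc_multiplier=3.0,
                                        kmer_multipliers={"AAG": 2.0}),
        residual_fragment_len=60_000, n_genes=60, n_varieties=40,
        n_expr_datasets=12)
    outdir = tmp_path_factory.mktemp("small_sim")
    return simulate_all(cfg, outdir)


@pytest.fixture(scope="session")
def recovery_sim(tmp_path_factory):
    """The scaled bias-recovery study: 5-Mb genome, 10 bulks, fixed seed,
    gc_multiplier 4, AAG multiplier 3, heterochromatin multiplier 3."""
    cfg = acceptance_sim_config(seed=1)
    outdir = tmp_path_factory.mktemp("recovery_sim")
    return simulate_all(cfg, outdir)


@pytest.fixture(scope="session")
def recovery_call(recovery_sim):
    from emsbias.caller import CallerParams, call_ems_snps
    from emsbias.io import read_bulk_vcf_dir
    variants = read_bulk_vcf_dir(recovery_sim.vcf_dir)
    return call_ems_snps(variants, CallerParams(),
                         chrom_lengths=recovery_sim.genome.chrom_lengths)
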