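"""End-to-end simulation driver: genome -> genes -> mutations -> bulk VCFs ->
panel -> tracks, all written to an output directory with a truth manifest."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ..io import Genome, write_domains_bed, write_gff3, write_json
from .bulks import add_background_sites, simulate_bulk_vcfs
from .config import ContextRateModel, SimConfig
from .genes import generate_gene_models
from .genome import generate_genome
from .mutations import TruthSet, calibrated_base_rate, implant_ems_mutations
from .panel import generate_natural_panel, write_panel


@dataclass
class SimOutput:
    """Handles to everything one simulation produced."""

    config: SimConfig
    outdir: Path
    genome: Genome
    genes: list
    truth: TruthSet
    panel: pd.DataFrame
    tracks: dict
    vcf_dir: Path

    @property
    def paths(self) -> dict[str, str]:
        return {
            "genome": str(self.outdir / "genome.fa"),
            "genes": str(self.outdir / "genes.gff3"),
            "domains": str(self.outdir / "domains.bed"),
            "vcf_dir": str(self.vcf_dir),
            "panel": str(self.outdir / "panel.tsv"),
            "truth": str(self.outdir / "truth.json"),
            "dh": str(self.tracks["dh_path"]),
            "tracks_manifest": str(self.tracks["manifest_path"]),
            "tracks_dir": str(self.tracks["tracks_dir"]),
            "fpkm": str(self.tracks["fpkm_path"]),
        }


def simulate_all(config: SimConfig, outdir: str | Path) -> SimOutput:
    """Run the full generator and write every artifact under ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = config.rng_streams()

    genome = generate_genome(config, streams["genome"])
    genes = generate_gene_models(genome, config, streams["genes"])
    truth = implant_ems_mutations(genome, config.ems_rate_model,
                                  config.n_bulks, streams["mutations"])
    truth = add_background_sites(genome, config, truth, streams["bulks"])

    genome.write_fasta(outdir / "genome.fa")
    write_domains_bed(genome.domains, outdir / "domains.bed")
    write_gff3(genes, outdir / "genes.gff3")
    truth.to_json(outdir / "truth.json")

    vcf_dir = outdir / "bulks"
    simulate_bulk_vcfs(genome, truth, config, vcf_dir, streams["bulks"])

    panel = generate_natural_panel(genome, truth, config, streams["panel"])
    write_panel(panel, outdir / "panel.tsv")

    tracks = generate_tracks_stage(genome, genes, config, outdir, streams)
    write_json({"seed": config.seed, "n_bulks": config.n_bulks,
                "genome_bp": len(genome),
                "n_ems_sites": int(len(truth.ems_sites))},
               outdir / "sim_manifest.json")
    return SimOutput(config, outdir, genome, genes, truth, panel, tracks,
                     vcf_dir)


def generate_tracks_stage(genome, genes, config, outdir, streams):
    from .tracks import generate_tracks
    return generate_tracks(genome, genes, config, outdir,
                           rng=streams["tracks"], expr_rng=streams["expression"])


def acceptance_sim_config(seed: int = 0) -> SimConfig:
    """The scaled study design used for bias-recovery checks.

    Two 2.5-Mb chromosomes, 10 bulks, depth 39, pericentromeric
    heterochromatin; hazard model gc_multiplier 4, AAG trinucleotide
    multiplier 3, heterochromatin multiplier 3.  The base rate is calibrated
    so the expected genome-wide mean is 4.65 EMS SNPs per 100-kb bin, the
    density the full-scale experiment showed.
    """
    model = ContextRateModel(base_rate=1.0, gc_multiplier=4.0,
                             kmer_multipliers={"AAG": 3.0},
                             heterochromatin_multiplier=3.0)
    config = SimConfig(seed=seed, n_chrom=2, chrom_len=2_500_000, n_bulks=10,
                       ems_rate_model=model)
    probe = generate_genome(SimConfig(seed=seed, n_chrom=2,
                                      chrom_len=2_500_000))
    target_total = 4.65 * (config.n_chrom * config.chrom_len / 100_000)
    model.base_rate = calibrated_base_rate(probe, model, config.n_bulks,
                                           target_total)
    return config
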