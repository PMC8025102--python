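"""Pipeline orchestration: simulate -> call -> analyze with one config.

Every stage reads its inputs from and writes its outputs under one run
directory; all randomness flows from the global seed; reruns with an
identical config are byte-identical (no timestamps are written).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import binscan, caller, chromatin, cpg, spectrum
from .io import (Genome, read_bed3, read_bulk_vcf_dir, read_domains_bed,
                 read_gff3, read_json, write_json)
from .sim import SimConfig, ContextRateModel, simulate_all
from .sim.panel import read_panel


class DependencyError(RuntimeError):
    """A stage's upstream output is missing."""


STAGES = ["simulate", "call", "context", "bins", "cpg", "chromatin",
          "annotate"]


@dataclass
class RunConfig:
    """One run's full parameterization."""

    outdir: str = "emsbias_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sim: dict = field(default_factory=dict)          # SimConfig overrides
    rate_model: dict = field(default_factory=dict)   # ContextRateModel overrides
    caller: dict = field(default_factory=dict)       # CallerParams overrides
    window: int = 100_000
    step: int = 50_000
    hotspot_min: int = 10
    cpg_min_islands: int = 40
    dh_threshold: int = 20
    random_baseline_n: int = 10_000
    random_baseline_reps: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        model = ContextRateModel(**self.rate_model)
        cfg = SimConfig(seed=self.seed, ems_rate_model=model, **self.sim)
        return cfg

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir, "seed": self.seed, "stages": self.stages,
            "sim": self.sim, "rate_model": self.rate_model,
            "caller": self.caller, "window": self.window, "step": self.step,
            "hotspot_min": self.hotspot_min,
            "cpg_min_islands": self.cpg_min_islands,
            "dh_threshold": self.dh_threshold,
            "random_baseline_n": self.random_baseline_n,
            "random_baseline_reps": self.random_baseline_reps,
        }


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage '{stage}' requires missing upstream output {path}")
    return path


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in dependency order; returns the run dir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_json({"config": config.to_dict()}, out / "run_config.json")
    simdir = out / "sim"

    if "simulate" in config.stages:
        simulate_all(config.sim_config(), simdir)

    genome = None

    def get_genome() -> Genome:
        nonlocal genome
        if genome is None:
            fa = _require(simdir / "genome.fa", "analysis")
            domains = read_domains_bed(simdir / "domains.bed") \
                if (simdir / "domains.bed").exists() else None
            genome = Genome.read_fasta(fa, domains)
        return genome

    if "call" in config.stages:
        vcf_dir = _require(simdir / "bulks", "call")
        variants = read_bulk_vcf_dir(vcf_dir)
        params = caller.CallerParams(**config.caller)
        result = caller.call_ems_snps(variants, params,
                                      chrom_lengths=get_genome().chrom_lengths)
        caller.write_ems_tsv(result.accepted, out / "ems_snps.tsv")
        caller.write_ems_vcf(result.accepted, get_genome().chrom_lengths,
                             out / "ems_snps.vcf")
        result.rejected.to_csv(out / "rejected.tsv", sep="\t", index=False)
        result.masks.to_csv(out / "masks.tsv", sep="\t", index=False)

    def get_snps() -> pd.DataFrame:
        return caller.read_ems_tsv(_require(out / "ems_snps.tsv", "analysis"))

    if "context" in config.stages:
        snps = get_snps()
        g = get_genome()
        spec = spectrum.mutation_spectrum(snps, g)
        spec.counts.rename("count").to_frame().assign(
            fraction=spec.fractions).to_csv(out / "spectrum.tsv", sep="\t")
        fg = spectrum.flank_gc(snps, g, 50)
        fg1 = spectrum.flank_gc(snps, g, 1)
        baseline = spectrum.random_site_baseline(
            g, n=min(config.random_baseline_n, len(g) // 2),
            reps=config.random_baseline_reps, seed=config.seed)
        tables = {}
        for ps in spectrum.POSITION_SETS:
            fr, _ = spectrum.kmer_context_freqs(snps, g, ps)
            k = len(spectrum.POSITION_SETS[ps])
            enr = spectrum.kmer_enrichment_table(
                fr, spec.n, spectrum.genome_kmer_freqs(g, k), len(g))
            safe = ps.replace("/", "_")
            enr.to_csv(out / f"context_{safe}.tsv", sep="\t")
            tables[ps] = enr
        write_json({
            "n_snps": spec.n, "gc_site_fraction": spec.gc_site_fraction,
            "flank50_gc": fg.mean_gc, "flank1_gc": fg1.mean_gc,
            "gc_adjacent_fraction": fg1.gc_adjacent_fraction,
            "random_flank50_gc_mean": baseline.flank_gc_mean,
            "random_flank50_gc_sd": baseline.flank_gc_sd,
        }, out / "context_summary.json")

    if "bins" in config.stages:
        snps = get_snps()
        scan = binscan.scan(snps, get_genome().chrom_lengths,
                            window=config.window, step=config.step,
                            hotspot_min=config.hotspot_min)
        scan.bins.to_csv(out / "bins.tsv", sep="\t", index=False)
        write_json(scan.summary(), out / "bins_summary.json")

    def get_bins() -> pd.DataFrame:
        return pd.read_csv(_require(out / "bins.tsv", "analysis"), sep="\t")

    if "cpg" in config.stages:
        g = get_genome()
        islands = cpg.find_islands_genome(g)
        islands.to_csv(out / "cpg_islands.tsv", sep="\t", index=False)
        per_bin, summary = cpg.islands_per_bin(islands, get_bins(),
                                               config.cpg_min_islands)
        per_bin.to_csv(out / "cpg_per_bin.tsv", sep="\t", index=False)
        summary.to_csv(out / "cpg_class_summary.tsv", sep="\t", index=False)

    if "chromatin" in config.stages:
        g = get_genome()
        snps = get_snps()
        bins = get_bins()
        dh_raw = read_bed3(_require(simdir / "dh_sites.bed", "chromatin"))
        merged = chromatin.merge_dh_sites(dh_raw)
        per_bin, dh_summary = chromatin.dh_per_bin(merged, bins,
                                                   config.dh_threshold)
        dh_summary.to_csv(out / "dh_class_summary.tsv", sep="\t", index=False)
        tracks = chromatin.load_track_manifest(
            _require(simdir / "tracks_manifest.tsv", "chromatin"),
            simdir / "tracks")
        signals = {mod: chromatin.snp_signal(snps, tlist)
                   for mod, tlist in tracks.items()}
        classes = chromatin.assign_snp_class(snps, bins)
        sig_summary = chromatin.class_signal_summary(signals, classes)
        sig_summary.to_csv(out / "signal_class_summary.tsv", sep="\t",
                           index=False)
        genes = read_gff3(_require(simdir / "genes.gff3", "chromatin"))
        _, te_summary = chromatin.te_ratio_per_bin(genes, bins)
        te_summary.to_csv(out / "te_class_summary.tsv", sep="\t", index=False)
        expr = pd.read_csv(_require(simdir / "fpkm.tsv", "chromatin"),
                           sep="\t", index_col=0)
        es = chromatin.expression_summary(expr, genes, snps, bins)
        es.per_class.to_csv(out / "expression_class_summary.tsv", sep="\t",
                            index=False)

    if "annotate" in config.stages:
        g = get_genome()
        snps = get_snps()
        genes = read_gff3(_require(simdir / "genes.gff3", "annotate"))
        ann = annotate_mod.annotate_snps(snps, genes, g)
        ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
        annotate_mod.category_summary(ann).to_csv(
            out / "annotation_summary.tsv", sep="\t")
        panel = read_panel(_require(simdir / "panel.tsv", "annotate"))
        stats = caller.panel_site_stats(panel)
        filtered = caller.filter_natural_panel(stats)
        sharing = annotate_mod.shared_with_panel(snps, filtered)
        write_json({"shared_fraction": sharing.shared_fraction,
                    "shared_maf_lt_0.10": sharing.shared_maf_lt},
                   out / "panel_sharing.json")
    return out


def output_checksums(run_dir: str | Path) -> dict[str, str]:
    """SHA-256 of every file in a run directory (relative path keyed)."""
    run_dir = Path(run_dir)
    out = {}
    for path in sorted(run_dir.rglob("*")):
        if path.is_file():
            out[str(path.relative_to(run_dir))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    return out


def acceptance_report(run_dir: str | Path) -> pd.DataFrame:
    """Built-in sanity checks over a completed run: a pass/fail table."""
    run_dir = Path(run_dir)
    checks = []

    def add(name, ok, value):
        checks.append((name, bool(ok), value))

    bs = read_json(_require(run_dir / "bins_summary.json", "report"))
    low, high = binscan.chi_square_thresholds(4.65)
    add("chi2_cuts_at_mu_4.65", abs(low - 0.4235) < 5e-4
        and abs(high - 8.8765) < 5e-4, f"{low:.4f}/{high:.4f}")
    add("class_counts_sum", sum(bs["class_totals"].values()) == bs["n_bins"],
        bs["n_bins"])

    spec = pd.read_csv(run_dir / "spectrum.tsv", sep="\t", index_col=0)
    frac_sum = float(spec["fraction"].sum())
    add("spectrum_fractions_sum_to_1", abs(frac_sum - 1) < 1e-9, frac_sum)

    truth_path = run_dir / "sim" / "truth.json"
    if truth_path.exists():
        from .sim import TruthSet
        truth = TruthSet.from_json(truth_path)
        snps = caller.read_ems_tsv(run_dir / "ems_snps.tsv")
        called = set(zip(snps["chrom"], snps["pos"], snps["alt"]))
        true = set(zip(truth.ems_sites["chrom"], truth.ems_sites["pos"],
                       truth.ems_sites["alt"]))
        tp = len(called & true)
        precision = tp / len(called) if called else float("nan")
        recall = tp / len(true) if true else float("nan")
        add("caller_precision_ge_0.95", precision >= 0.95, round(precision, 4))
        add("caller_recall_ge_0.95", recall >= 0.95, round(recall, 4))
    df = pd.DataFrame(checks, columns=["check", "passed", "value"])
    df.to_csv(run_dir / "acceptance_report.tsv", sep="\t", index=False)
    return df
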