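"""Synthetic-data generator: determinism, composition targets, implant model."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emsbias.io import Genome, read_bulk_vcf
from emsbias.sim import (ContextRateModel, SimConfig, TruthSet,
                         generate_gene_models, generate_genome,
                         implant_ems_mutations, simulate_all)
from emsbias.sim.bulks import add_background_sites, simulate_bulk_vcfs
from emsbias.sim.panel import generate_natural_panel


def _flat_config(**kw) -> SimConfig:
    base = dict(seed=3, n_chrom=1, chrom_len=300_000,
                domain_fractions=((0.0, 1.0, "euchromatin"),),
                ems_rate_model=ContextRateModel.identity(1e-5))
    base.update(kw)
    return SimConfig(**base)


class TestGenome:
    def test_realized_gc_matches_target(self):
        cfg = _flat_config(eu_gc=0.435)
        g = generate_genome(cfg)
        assert abs(g.gc_fraction() - 0.435) < 0.01

    def test_same_seed_identical_fasta(self, tmp_path):
        for name in ("a", "b"):
            generate_genome(_flat_config()).write_fasta(tmp_path / f"{name}.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_domain_gc_contrast(self):
        cfg = SimConfig(seed=4, n_chrom=1, chrom_len=300_000,
                        eu_gc=0.40, het_gc=0.55)
        g = generate_genome(cfg)
        het = [d for d in g.domains if d.kind == "heterochromatin"][0]
        eu = [d for d in g.domains if d.kind == "euchromatin"][0]
        gc_het = g.gc_fraction(het.chrom, het.start, het.end)
        gc_eu = g.gc_fraction(eu.chrom, eu.start, eu.end)
        assert gc_het - gc_eu >= 0.10

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(_flat_config(chrom_len=0))


class TestGenes:
    def test_all_cds_translate_cleanly(self, small_sim):
        from Bio.Seq import Seq
        genes = small_sim.genes
        assert len(genes) == small_sim.config.n_genes
        for g in genes:
            cds = g.cds_sequence(small_sim.genome)
            assert len(cds) % 3 == 0 and cds.startswith("ATG")
            prot = str(Seq(cds).translate())
            assert prot.endswith("*") and "*" not in prot[:-1]

    def test_te_genes_concentrate_in_heterochromatin(self, small_sim):
        g = small_sim.genome
        rows = []
        for gene in small_sim.genes:
            het = bool(g.domain_kind_mask(gene.chrom, "heterochromatin")[
                gene.midpoint])
            rows.append((gene.is_te, het))
        df = pd.DataFrame(rows, columns=["is_te", "het"])
        te_frac_het = df[df.het].is_te.mean()
        te_frac_eu = df[~df.het].is_te.mean()
        assert te_frac_het > te_frac_eu


class TestImplant:
    def test_identity_model_count_poisson(self):
        cfg = _flat_config()
        g = generate_genome(cfg)
        rate, n_bulks = 1e-5, 10
        truth = implant_ems_mutations(g, ContextRateModel.identity(rate),
                                      n_bulks, rng=11)
        mean = n_bulks * rate * len(g)
        assert abs(len(truth.ems_sites) - mean) < 3 * np.sqrt(mean)

    def test_gc_multiplier_biases_sites(self):
        cfg = _flat_config()
        g = generate_genome(cfg)
        model = ContextRateModel(base_rate=1e-5, gc_multiplier=4.0,
                                 heterochromatin_multiplier=1.0)
        truth = implant_ems_mutations(g, model, 10, rng=12)
        k = truth.ems_sites.ref.isin(["G", "C"]).sum()
        p = stats.binomtest(int(k), len(truth.ems_sites), g.gc_fraction(),
                            alternative="greater").pvalue
        assert p < 1e-6

    def test_identity_model_per_bin_dispersion(self):
        """Uniform hazard: per-bin implant counts are Poisson-dispersed."""
        from emsbias.binscan import count_snps_per_bin, make_bins
        cfg = _flat_config(chrom_len=1_000_000)
        g = generate_genome(cfg)
        truth = implant_ems_mutations(g, ContextRateModel.identity(5e-5), 4,
                                      rng=21)
        bins = make_bins({"chr1": 1_000_000}, window=50_000, step=50_000)
        counts = count_snps_per_bin(bins, truth.ems_sites).snp_count
        n = len(counts)
        disp = (n - 1) * counts.var(ddof=1) / counts.mean()
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=n - 1)
        assert lo < disp < hi

    def test_zero_rate_empty(self):
        g = generate_genome(_flat_config())
        truth = implant_ems_mutations(g, ContextRateModel.identity(0.0), 5,
                                      rng=1)
        assert len(truth.ems_sites) == 0

    def test_overdense_model_refused(self):
        g = generate_genome(_flat_config())
        with pytest.raises(ValueError, match="dense"):
            implant_ems_mutations(g, ContextRateModel.identity(0.05), 10,
                                  rng=1)

    def test_sites_unique_to_one_bulk(self, small_sim):
        sites = small_sim.truth.ems_sites
        assert not sites.duplicated(["chrom", "pos"]).any()

    def test_one_causal_per_bulk(self, small_sim):
        causal = small_sim.truth.causal_sites()
        assert (causal.groupby("bulk_id").size() == 1).all()
        assert (causal.zygosity == 1.0).all()


class TestBulkVcfs:
    def test_causal_site_si_one(self, small_sim):
        truth, cfg = small_sim.truth, small_sim.config
        causal = truth.causal_sites().iloc[0]
        df = read_bulk_vcf(small_sim.vcf_dir / f"{causal.bulk_id}.vcf")
        rec = df[df.pos == causal.pos].iloc[0]
        assert rec.alt_reads == rec.total_reads  # SI exactly 1

    def test_het_sites_si_near_half(self, small_sim):
        truth = small_sim.truth
        sis = []
        for bulk_id, grp in truth.ems_sites.groupby("bulk_id"):
            df = read_bulk_vcf(small_sim.vcf_dir / f"{bulk_id}.vcf")
            m = df.merge(grp[~grp.causal], on=["chrom", "pos", "ref", "alt"])
            sis.extend(m.alt_reads / m.total_reads)
        assert 0.45 <= np.mean(sis) <= 0.55

    def test_no_error_sites_when_rate_zero(self, tmp_path):
        cfg = _flat_config(seq_error_rate=0.0, natural_site_rate=0.0,
                           residual_fragment_prob=0.0, n_bulks=3)
        g = generate_genome(cfg)
        truth = implant_ems_mutations(g, cfg.ems_rate_model, cfg.n_bulks,
                                      rng=5)
        truth = add_background_sites(g, cfg, truth, np.random.default_rng(6))
        paths = simulate_bulk_vcfs(g, truth, cfg, tmp_path / "bulks",
                                   np.random.default_rng(7))
        truth_keys = set(zip(truth.ems_sites.chrom, truth.ems_sites.pos))
        for p in paths:
            df = read_bulk_vcf(p)
            assert set(zip(df.chrom, df.pos)) <= truth_keys

    def test_natural_sites_in_every_bulk(self, small_sim):
        nat = small_sim.truth.natural_sites
        for b in range(small_sim.config.n_bulks):
            df = read_bulk_vcf(small_sim.vcf_dir / f"bulk{b + 1:02d}.vcf")
            present = set(zip(df.chrom, df.pos))
            assert set(zip(nat.chrom, nat.pos)) <= present


class TestPanel:
    def test_point_mass_maf_no_missing(self):
        cfg = _flat_config(n_varieties=50, panel_truth_overlap=0.0)
        g = generate_genome(cfg)
        truth = implant_ems_mutations(g, cfg.ems_rate_model, 2, rng=3)
        panel = generate_natural_panel(
            g, truth, cfg, np.random.default_rng(4),
            maf_dist=lambda rng, n: np.full(n, 0.5),
            missing_dist=lambda rng, n: np.zeros(n))
        from emsbias.caller import panel_site_stats
        st = panel_site_stats(panel)
        assert (st.missing_rate == 0).all()
        assert (st.n_typed == 50).all()

    def test_all_missing_fails_downstream_filter(self):
        cfg = _flat_config(n_varieties=20)
        g = generate_genome(cfg)
        truth = implant_ems_mutations(g, cfg.ems_rate_model, 2, rng=3)
        panel = generate_natural_panel(
            g, truth, cfg, np.random.default_rng(4),
            missing_dist=lambda rng, n: np.full(n, 0.9))
        from emsbias.caller import filter_natural_panel, panel_site_stats
        kept = filter_natural_panel(panel_site_stats(panel))
        assert len(kept) == 0

    def test_truth_overlap_fraction(self, small_sim):
        panel = small_sim.panel
        truth_keys = set(zip(small_sim.truth.ems_sites.chrom,
                             small_sim.truth.ems_sites.pos))
        n_shared = sum((c, p) in truth_keys
                       for c, p in zip(panel.chrom, panel.pos))
        expected = round(len(truth_keys)
                         * small_sim.config.panel_truth_overlap)
        assert n_shared == expected


class TestTracksAndOutputs:
    def test_methylation_contrast_across_domains(self, small_sim):
        from emsbias.chromatin import SignalTrack
        import pandas as pd
        g = small_sim.genome
        track = SignalTrack.from_bedgraph(
            small_sim.tracks["tracks_dir"] / "DNA-methylation.exp1.bedgraph")
        het = g.domain_kind_mask("chr1", "heterochromatin")
        starts, ends, vals = track._by_chrom["chr1"]
        mids = (starts + ends) // 2
        in_het = het[np.minimum(mids, len(het) - 1)]
        assert vals[in_het].mean() >= 2 * vals[~in_het].mean()

    def test_fpkm_matrix_shape(self, small_sim):
        expr = small_sim.tracks["expression"]
        assert expr.shape == (small_sim.config.n_genes,
                              small_sim.config.n_expr_datasets)

    def test_dh_counts_poisson_on_flat_genome(self):
        from emsbias.binscan import count_snps_per_bin, make_bins
        from emsbias.sim.tracks import generate_dh_sites
        cfg = _flat_config(chrom_len=1_000_000)
        g = generate_genome(cfg)
        dh = generate_dh_sites(g, cfg, np.random.default_rng(31))
        mids = pd.DataFrame({"chrom": dh.chrom,
                             "pos": (dh.start + dh.end) // 2})
        bins = make_bins({"chr1": 1_000_000}, window=50_000, step=50_000)
        counts = count_snps_per_bin(bins, mids).snp_count
        n = len(counts)
        disp = (n - 1) * counts.var(ddof=1) / counts.mean()
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=n - 1)
        assert lo < disp < hi

    def test_dh_density_higher_in_euchromatin(self, small_sim):
        dh = small_sim.tracks["dh"]
        g = small_sim.genome
        het = g.domain_kind_mask("chr1", "heterochromatin")
        mids = ((dh.start + dh.end) // 2).to_numpy()
        in_het = het[np.minimum(mids, len(het) - 1)]
        het_bp = het.sum()
        eu_bp = len(het) - het_bp
        assert (~in_het).sum() / eu_bp > in_het.sum() / het_bp

    def test_truth_manifest_roundtrip(self, small_sim, tmp_path):
        truth = small_sim.truth
        truth.to_json(tmp_path / "t.json")
        back = TruthSet.from_json(tmp_path / "t.json")
        pd.testing.assert_frame_equal(truth.ems_sites, back.ems_sites)
        pd.testing.assert_frame_equal(truth.residual_fragments,
                                      back.residual_fragments)

    def test_full_rerun_byte_identical(self, tmp_path):
        cfg = _flat_config(n_bulks=2, n_genes=10, n_varieties=10,
                           n_expr_datasets=3)
        outs = []
        for name in ("r1", "r2"):
            simulate_all(cfg, tmp_path / name)
            outs.append({p.relative_to(tmp_path / name): p.read_bytes()
                         for p in sorted((tmp_path / name).rglob("*"))
                         if p.is_file()})
        assert outs[0].keys() == outs[1].keys()
        for k in outs[0]:
            assert outs[0][k] == outs[1][k], k
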