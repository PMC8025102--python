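"""Cross-bulk EMS SNP caller: SI/ED^6 arithmetic, filter chain, masking."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from emsbias.caller import (CallerParams, call_ems_snps, euclidean_distance6,
                            filter_candidate, filter_natural_panel,
                            mask_residual_fragments, panel_site_stats,
                            read_ems_tsv, snp_index, write_ems_tsv)
from emsbias.io import VARIANT_COLUMNS

from _oracles import brute_filter_chain


def V(*rows) -> pd.DataFrame:
    """(bulk, chrom, pos, ref, alt, alt_reads, total_reads, alt_mq20) rows."""
    return pd.DataFrame(list(rows), columns=VARIANT_COLUMNS)


class TestSnpIndex:
    @pytest.mark.parametrize("alt,total,expected",
                             [(15, 30, 0.5), (40, 40, 1.0), (0, 25, 0.0)])
    def test_values(self, alt, total, expected):
        assert snp_index(alt, total) == expected

    def test_zero_depth_error(self):
        with pytest.raises(ValueError):
            snp_index(0, 0)


class TestEd6:
    def test_identical_vectors_zero(self):
        assert euclidean_distance6([0.25] * 4, [0.25] * 4) == 0.0

    def test_half_contrast(self):
        # ED = sqrt(0.5^2 + 0.5^2) = 0.70711; ED^6 = 0.5^3 = 0.125
        ed6 = euclidean_distance6((0, 0, 0, 1), (0, 0, 0.5, 0.5))
        assert ed6 == pytest.approx(0.125, abs=1e-12)

    def test_opposite_unit_vectors(self):
        ed6 = euclidean_distance6((0, 0, 0, 1), (0, 0, 1, 0))
        assert ed6 == pytest.approx(8.0, abs=1e-9)

    def test_malformed_vector_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance6((0.5, 0.5, 0.5, 0.5), (0.25,) * 4)


class TestFilterCandidate:
    def test_accept_clean_unique_site(self):
        site = V(("b1", "chr1", 10, "G", "A", 12, 30, 12),
                 ("b2", "chr1", 10, "G", "A", 1, 30, 1))
        ok, bulk, reason = filter_candidate(site, CallerParams(), n_bulks=5)
        assert ok and bulk == "b1" and reason is None

    def test_low_support(self):
        site = V(("b1", "chr1", 10, "G", "A", 2, 30, 2))
        ok, _, reason = filter_candidate(site, CallerParams(), n_bulks=5)
        assert not ok and reason == "low_support"

    def test_shared_by_fraction(self):
        # alt fraction 0.45 in a second bulk exceeds the 20% error tolerance
        site = V(("b1", "chr1", 10, "G", "A", 15, 30, 15),
                 ("b2", "chr1", 10, "G", "A", 2, 30, 2),
                 ("b3", "chr1", 10, "G", "A", 9, 20, 2))
        ok, _, reason = filter_candidate(site, CallerParams(), n_bulks=52)
        assert not ok and reason == "shared"

    def test_two_passing_bulks_shared(self):
        site = V(("b1", "chr1", 10, "G", "A", 15, 30, 15),
                 ("b2", "chr1", 10, "G", "A", 14, 30, 14))
        ok, _, reason = filter_candidate(site, CallerParams(), n_bulks=5)
        assert not ok and reason == "shared"

    def test_high_background_mean(self):
        site = V(("b1", "chr1", 10, "G", "A", 15, 30, 15),
                 ("b2", "chr1", 10, "G", "A", 2, 30, 2),
                 ("b3", "chr1", 10, "G", "A", 2, 30, 2))
        ok, _, reason = filter_candidate(site, CallerParams(), n_bulks=3)
        assert not ok and reason == "high_background"

    def test_single_bulk_refused(self):
        site = V(("b1", "chr1", 10, "G", "A", 15, 30, 15))
        with pytest.raises(ValueError):
            filter_candidate(site, CallerParams(), n_bulks=1)


class TestMask:
    def test_dense_window_masked(self):
        rows = [("b1", "chr1", 1000 + 4000 * i, "G", "A", 15, 30, 15)
                for i in range(25)]
        masks = mask_residual_fragments(V(*rows), CallerParams(),
                                        {"chr1": 200_000})
        assert len(masks) == 1
        m = masks.iloc[0]
        assert m.start == 0 and m.end >= 100_000

    def test_sparse_no_masks(self):
        rows = [("b1", "chr1", 20_000 * i, "G", "A", 15, 30, 15)
                for i in range(10)]
        masks = mask_residual_fragments(V(*rows), CallerParams(),
                                        {"chr1": 200_000})
        assert len(masks) == 0

    def test_adjacent_windows_merge(self):
        rows = [("b1", "chr1", int(p), "G", "A", 15, 30, 15)
                for p in np.linspace(0, 199_999, 60)]
        masks = mask_residual_fragments(V(*rows), CallerParams(),
                                        {"chr1": 200_000})
        assert len(masks) == 1 and masks.iloc[0].end == 200_000


class TestCallEmsSnps:
    def test_single_clean_snp(self):
        variants = V(("b1", "chr1", 500, "G", "A", 14, 30, 14),
                     ("b1", "chr1", 900, "C", "T", 30, 30, 30),
                     ("b2", "chr1", 900, "C", "T", 28, 28, 28),
                     ("b3", "chr1", 900, "C", "T", 30, 31, 29))
        res = call_ems_snps(variants, n_bulks=3)
        assert len(res.accepted) == 1
        snp = res.accepted.iloc[0]
        assert (snp.pos, snp.bulk_id, snp.mutation_type) == (500, "b1", "G>A")
        assert snp.si == pytest.approx(14 / 30)

    def test_all_bulks_identical_empty(self):
        rows = [(f"b{i}", "chr1", 100, "G", "A", 20, 40, 20)
                for i in range(1, 5)]
        res = call_ems_snps(V(*rows))
        assert len(res.accepted) == 0

    def test_monotone_in_min_support(self, small_sim):
        from emsbias.io import read_bulk_vcf_dir
        variants = read_bulk_vcf_dir(small_sim.vcf_dir)
        prev = None
        for thr in (3, 5, 8, 12):
            res = call_ems_snps(variants, CallerParams(min_alt_mq20=thr),
                                chrom_lengths=small_sim.genome.chrom_lengths)
            keys = set(zip(res.accepted.chrom, res.accepted.pos,
                           res.accepted.bulk_id))
            if prev is not None:
                assert keys <= prev
            prev = keys

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        n_bulks, n_sites = 5, 400
        rows = []
        for s in range(n_sites):
            pos = int(rng.integers(0, 300_000))
            ref, alt = "G", "A"
            for b in range(n_bulks):
                if rng.random() < 0.5:
                    continue
                dp = int(rng.integers(5, 60))
                ar = int(rng.integers(0, dp + 1)) if rng.random() < 0.5 \
                    else int(rng.integers(0, 4))
                mq = int(rng.integers(0, ar + 1))
                rows.append((f"b{b}", "chr1", pos, ref, alt, ar, dp, mq))
        variants = V(*rows)
        lengths = {"chr1": 300_000}
        res = call_ems_snps(variants, CallerParams(fragment_mask_window=50_000,
                                                   fragment_mask_min_snps=10),
                            n_bulks=n_bulks, chrom_lengths=lengths)
        got = set(zip(res.accepted.chrom, res.accepted.pos, res.accepted.ref,
                      res.accepted.alt, res.accepted.bulk_id))
        expected = brute_filter_chain(variants, n_bulks, mask_window=50_000,
                                      mask_min=10, chrom_lengths=lengths)
        assert got == expected

    def test_accepted_unique_to_bulk_invariant(self, recovery_call):
        acc = recovery_call.accepted
        assert not acc.duplicated(["chrom", "pos"]).any()

    def test_causal_sites_have_max_ed6(self, recovery_sim, recovery_call):
        acc = recovery_call.accepted
        causal = recovery_sim.truth.causal_sites()
        called_causal = acc.merge(causal, on=["chrom", "pos"])
        if len(called_causal):
            assert called_causal.ed6.min() > acc.ed6.median()

    def test_tsv_roundtrip(self, tmp_path):
        variants = V(("b1", "chr1", 500, "G", "A", 14, 30, 14),
                     ("b2", "chr1", 77, "C", "T", 1, 30, 1))
        res = call_ems_snps(variants, n_bulks=2)
        write_ems_tsv(res.accepted, tmp_path / "ems.tsv")
        back = read_ems_tsv(tmp_path / "ems.tsv")
        assert list(back.pos) == list(res.accepted.pos)

    def test_vcf_output(self, tmp_path):
        import pysam
        from emsbias.caller import write_ems_vcf
        variants = V(("b1", "chr1", 500, "G", "A", 14, 30, 14),
                     ("b2", "chr1", 77, "C", "T", 1, 30, 1))
        res = call_ems_snps(variants, n_bulks=2)
        write_ems_vcf(res.accepted, {"chr1": 1000}, tmp_path / "ems.vcf")
        with pysam.VariantFile(str(tmp_path / "ems.vcf")) as vcf:
            recs = list(vcf)
        assert len(recs) == 1
        assert recs[0].start == 500 and recs[0].info["BULK"] == "b1"
        assert recs[0].info["SI"] == pytest.approx(14 / 30, abs=1e-6)


class TestPanelFilter:
    def _sites(self, n_typed, maf, missing):
        return pd.DataFrame({"chrom": ["chr1"], "pos": [10], "ref": ["A"],
                             "alt": ["G"], "n_typed": [n_typed], "maf": [maf],
                             "missing_rate": [missing]})

    @pytest.mark.parametrize("n_typed,maf,missing,kept", [
        (29, 0.3, 0.1, False),    # below the 30-variety support floor
        (100, 0.005, 0.1, False),  # MAF below 0.01
        (100, 0.3, 0.8, False),    # missing rate not < 0.8
        (100, 0.3, 0.1, True),
        (30, 0.01, 0.79, True),    # all three boundaries inclusive-correct
    ])
    def test_boundaries(self, n_typed, maf, missing, kept):
        out = filter_natural_panel(self._sites(n_typed, maf, missing))
        assert (len(out) == 1) == kept

    def test_stats_from_genotypes(self):
        panel = pd.DataFrame({
            "chrom": ["chr1"], "pos": [5], "ref": ["A"], "alt": ["G"],
            "v1": [0.0], "v2": [1.0], "v3": [2.0], "v4": [np.nan]})
        st = panel_site_stats(panel)
        assert st.n_typed.iloc[0] == 3
        assert st.maf.iloc[0] == pytest.approx(0.5)
        assert st.missing_rate.iloc[0] == pytest.approx(0.25)
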