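"""VCF filtering, diagnostic SNPs, window ancestry, novel mutations.

Boundary-condition fixtures are written directly through the synthetic
writer so pass/fail labels are known by construction.
"""

import numpy as np
import pandas as pd
import pytest

from wormsweep.genome import FOUNDER_LABELS, GenomeLayout
from wormsweep.poolseq import (
    VCFFormatError,
    detect_novel_mutations,
    find_diagnostic_snps,
    load_snps,
    window_ancestry,
)
from wormsweep.synth import (
    SynthSpec,
    make_founder_panel,
    make_mosaic_pool,
    mutation_alleles,
    write_vcf,
)


@pytest.fixture
def two_chrom_layout():
    return GenomeLayout((("I", 5), ("II", 4)), window_size_bp=200_000)


def pool_record(chrom, pos, dp, ad, qual=60.0, ref="A", alt="T"):
    return (chrom, pos, ref, alt, qual, [(dp, ad)])


class TestLoadSnps:
    def test_quality_and_depth_boundaries(self, two_chrom_layout, tmp_path):
        path = str(tmp_path / "f.vcf")
        write_vcf(path, two_chrom_layout, ["pool"], [
            pool_record("I", 100, 50, 10, qual=29.9),   # fails quality
            pool_record("I", 200, 101, 10, qual=60.0),  # fails depth > 100
            pool_record("I", 300, 100, 10, qual=30.0),  # passes both at bound
        ])
        table = load_snps(path)
        assert len(table) == 1
        assert table.df["pos"].tolist() == [300]

    def test_multiallelic_and_indels_dropped(self, two_chrom_layout, tmp_path):
        path = str(tmp_path / "f.vcf")
        write_vcf(path, two_chrom_layout, ["pool"], [
            ("I", 100, "A", "AT", 60.0, [(20, 5)]),  # indel
            pool_record("I", 200, 20, 5),
        ])
        table = load_snps(path)
        assert table.df["pos"].tolist() == [200]

    def test_filters_are_idempotent(self, two_chrom_layout, tmp_path):
        spec = SynthSpec(layout=two_chrom_layout, seed=8)
        path = str(tmp_path / "panel.vcf")
        make_founder_panel(spec, path)
        t1 = load_snps(path)
        dp, ad = t1.depths(), t1.alt_counts()
        keep = (t1.df["qual"] >= 30) & (dp <= 100).all(axis=1)
        assert keep.all()  # re-applying the same filters changes nothing

    def test_missing_format_fields_error_names_field(
        self, two_chrom_layout, tmp_path
    ):
        import pysam

        header = pysam.VariantHeader()
        header.contigs.add("I", length=1_000_000)
        header.formats.add("GT", 1, "String", "Genotype")
        header.add_sample("pool")
        path = str(tmp_path / "nodp.vcf")
        with pysam.VariantFile(path, "w", header=header) as out:
            rec = out.new_record(contig="I", start=99, alleles=("A", "T"), qual=60)
            rec.samples["pool"]["GT"] = (0, 1)
            out.write(rec)
        with pytest.raises(VCFFormatError, match="DP"):
            load_snps(path)

    def test_record_view(self, two_chrom_layout, tmp_path):
        path = str(tmp_path / "f.vcf")
        write_vcf(path, two_chrom_layout, ["pool"], [pool_record("II", 70, 30, 12)])
        rec = load_snps(path).record(0)
        assert (rec.chrom, rec.pos) == ("II", 70)
        assert rec.depth["pool"] == 30 and rec.alt_count["pool"] == 12


def founder_record(pos, freqs, dp=30, chrom="I", ref="A", alt="T"):
    """Panel record with given alt frequencies per founder sample."""
    per_sample = [(dp, int(round(dp * f))) for f in freqs]
    return (chrom, pos, ref, alt, 60.0, per_sample)


class TestFindDiagnosticSnps:
    def write_panel(self, layout, tmp_path, records):
        path = str(tmp_path / "panel.vcf")
        write_vcf(path, layout, list(FOUNDER_LABELS), records)
        return load_snps(path)

    def test_unique_allele_is_diagnostic(self, two_chrom_layout, tmp_path):
        panel = self.write_panel(two_chrom_layout, tmp_path, [
            founder_record(100, [0, 1.0, 0, 0, 0]),
        ])
        diag = find_diagnostic_snps(panel)
        assert len(diag) == 1
        assert diag.iloc[0]["diagnostic_background"] == "CB4856"
        assert diag.iloc[0]["diagnostic_allele"] == "alt"

    def test_allele_in_two_backgrounds_is_not_diagnostic(
        self, two_chrom_layout, tmp_path
    ):
        panel = self.write_panel(two_chrom_layout, tmp_path, [
            founder_record(100, [0, 1.0, 1.0, 0, 0]),
        ])
        assert len(find_diagnostic_snps(panel)) == 0

    def test_low_coverage_site_skipped(self, two_chrom_layout, tmp_path):
        rec = ("I", 100, "A", "T", 60.0,
               [(9, 0), (30, 30), (30, 0), (30, 0), (30, 0)])
        panel = self.write_panel(two_chrom_layout, tmp_path, [rec])
        assert len(find_diagnostic_snps(panel, min_depth=10)) == 0

    def test_reference_allele_can_be_diagnostic(self, two_chrom_layout, tmp_path):
        # four backgrounds carry the alt; N2 alone retains the reference
        panel = self.write_panel(two_chrom_layout, tmp_path, [
            founder_record(100, [0.0, 1.0, 1.0, 1.0, 1.0]),
        ])
        diag = find_diagnostic_snps(panel)
        assert len(diag) == 1
        assert diag.iloc[0]["diagnostic_background"] == "N2"
        assert diag.iloc[0]["diagnostic_allele"] == "ref"

    def test_synthetic_panel_recovery_within_five_percent(self, tmp_path):
        layout = GenomeLayout((("I", 10), ("II", 10)), window_size_bp=200_000)
        spec = SynthSpec(layout=layout, diagnostic_density=750, depth=30,
                         error_rate=0.002, seed=21)
        path = str(tmp_path / "panel.vcf")
        truth = make_founder_panel(spec, path)
        diag = find_diagnostic_snps(load_snps(path))
        merged = truth.merge(diag, on=["chrom", "pos", "ref", "alt"])
        assert len(merged) >= 0.95 * len(truth)
        assert (merged["background"] == merged["diagnostic_background"]).all()


class TestWindowAncestry:
    @pytest.fixture
    def painted(self, two_chrom_layout, tmp_path):
        spec = SynthSpec(layout=two_chrom_layout, diagnostic_density=750,
                         depth=30, error_rate=0.002, seed=33)
        panel_path = str(tmp_path / "panel.vcf")
        make_founder_panel(spec, panel_path)
        diag = find_diagnostic_snps(load_snps(panel_path))
        # chromosome I pure CB4856; II switches MY2 -> JU258 at window 2
        mosaic = {"I": np.full(5, 1), "II": np.array([3, 3, 4, 4])}
        pool_path = str(tmp_path / "pool.vcf")
        make_mosaic_pool(spec, mosaic, pool_path)
        wa = window_ancestry(load_snps(pool_path), diag)
        return wa, mosaic

    def test_pure_block_near_one(self, painted):
        wa, _ = painted
        chrom_i = wa[wa["chrom"] == "I"]
        assert (chrom_i["freq_CB4856"] > 0.97).all()
        assert (chrom_i[["freq_N2", "freq_AB1", "freq_MY2", "freq_JU258"]]
                .max().max() < 0.03)

    def test_argmax_switches_exactly_at_breakpoint(self, painted):
        wa, mosaic = painted
        freq_cols = [f"freq_{b}" for b in FOUNDER_LABELS]
        for chrom, truth_bgs in mosaic.items():
            sub = wa[wa["chrom"] == chrom].sort_values("window_start")
            pred = np.nanargmax(sub[freq_cols].to_numpy(), axis=1)
            np.testing.assert_array_equal(pred, truth_bgs)

    def test_missing_background_is_nan_not_zero(self, two_chrom_layout, tmp_path):
        # a single diagnostic SNP for CB4856 only: other backgrounds have no
        # informative site in the window and must come out missing
        panel_path = str(tmp_path / "p.vcf")
        write_vcf(panel_path, two_chrom_layout, list(FOUNDER_LABELS),
                  [founder_record(100, [0, 1.0, 0, 0, 0])])
        diag = find_diagnostic_snps(load_snps(panel_path))
        pool_path = str(tmp_path / "s.vcf")
        write_vcf(pool_path, two_chrom_layout, ["pool"],
                  [pool_record(chrom="I", pos=100, dp=25, ad=25)])
        wa = window_ancestry(load_snps(pool_path), diag)
        row = wa.iloc[0]
        assert row["freq_CB4856"] == 1.0
        assert np.isnan(row["freq_MY2"]) and row["n_MY2"] == 0

    def test_depth_weighted_estimator(self, two_chrom_layout, tmp_path):
        panel_path = str(tmp_path / "p.vcf")
        write_vcf(panel_path, two_chrom_layout, list(FOUNDER_LABELS), [
            founder_record(100, [0, 1.0, 0, 0, 0]),
            founder_record(200, [0, 1.0, 0, 0, 0]),
        ])
        diag = find_diagnostic_snps(load_snps(panel_path))
        pool_path = str(tmp_path / "s.vcf")
        write_vcf(pool_path, two_chrom_layout, ["pool"], [
            pool_record(chrom="I", pos=100, dp=10, ad=10),
            pool_record(chrom="I", pos=200, dp=90, ad=0),
        ])
        pool = load_snps(pool_path)
        unweighted = window_ancestry(pool, diag)
        weighted = window_ancestry(pool, diag, depth_weighted=True)
        assert unweighted.iloc[0]["freq_CB4856"] == pytest.approx(0.5)
        assert weighted.iloc[0]["freq_CB4856"] == pytest.approx(0.1)


class TestDetectNovelMutations:
    def build_case(self, layout, tmp_path, evolved_freq, anc_depth=30):
        """One planted mutation; returns the call table."""
        chrom, pos = "I", 123_457
        ref, alt = mutation_alleles(chrom, pos)
        spec = SynthSpec(layout=layout, diagnostic_density=5000, depth=30,
                         error_rate=0.0, seed=9)
        monitors = [(chrom, pos, ref, alt)]
        panel_path = str(tmp_path / "panel.vcf")
        make_founder_panel(spec, panel_path, monitor_positions=monitors)
        anc_path = str(tmp_path / "anc.vcf")
        write_vcf(anc_path, layout, ["ancestor"],
                  [(chrom, pos, ref, alt, 60.0, [(anc_depth, 0)])])
        ev_path = str(tmp_path / "ev.vcf")
        dp = 30
        write_vcf(ev_path, layout, ["EE1"],
                  [(chrom, pos, ref, alt, 60.0, [(dp, int(round(dp * evolved_freq)))])])
        return detect_novel_mutations(
            {"EE1": load_snps(ev_path)}, load_snps(anc_path),
            load_snps(panel_path),
        )

    def test_fixed_mutation_called(self, two_chrom_layout, tmp_path):
        calls = self.build_case(two_chrom_layout, tmp_path, evolved_freq=1.0)
        assert len(calls) == 1
        assert calls.iloc[0]["line"] == "EE1"
        assert calls.iloc[0]["position"] == 123_457

    def test_threshold_is_strict(self, two_chrom_layout, tmp_path):
        # exactly 90% frequency does not qualify ("nearly fixed" is > 90%)
        calls = self.build_case(two_chrom_layout, tmp_path, evolved_freq=0.9)
        assert len(calls) == 0

    def test_shallow_ancestor_blocks_call(self, two_chrom_layout, tmp_path):
        calls = self.build_case(
            two_chrom_layout, tmp_path, evolved_freq=1.0, anc_depth=9
        )
        assert len(calls) == 0

    def test_site_absent_from_ancestor_not_called(self, two_chrom_layout, tmp_path):
        chrom, pos = "I", 123_457
        ref, alt = mutation_alleles(chrom, pos)
        spec = SynthSpec(layout=two_chrom_layout, diagnostic_density=5000,
                         depth=30, error_rate=0.0, seed=9)
        panel_path = str(tmp_path / "panel.vcf")
        make_founder_panel(spec, panel_path,
                          monitor_positions=[(chrom, pos, ref, alt)])
        anc_path = str(tmp_path / "anc.vcf")
        write_vcf(anc_path, two_chrom_layout, ["ancestor"], [])
        ev_path = str(tmp_path / "ev.vcf")
        write_vcf(ev_path, two_chrom_layout, ["EE1"],
                  [(chrom, pos, ref, alt, 60.0, [(30, 30)])])
        calls = detect_novel_mutations(
            {"EE1": load_snps(ev_path)}, load_snps(anc_path), load_snps(panel_path)
        )
        assert len(calls) == 0
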