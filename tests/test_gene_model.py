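import numpy as np
import pandas as pd
import pytest

from gwasea.gene_model import (
    BoundaryConfig,
    GeneRecord,
    InputError,
    assign_snps,
    extend_boundaries,
    load_refflat,
    read_snp_table,
)


def _refflat_line(symbol, chrom, strand, tx_start0, tx_end, name=None):
    name = name or f"{symbol}.tx"
    return "\t".join(
        [symbol, name, chrom, strand, str(tx_start0), str(tx_end),
         str(tx_start0), str(tx_end), "1", f"{tx_start0},", f"{tx_end},"]
    )


def write_refflat(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadRefflat:
    def test_single_transcript_and_coordinate_conversion(self, tmp_path):
        f = write_refflat(tmp_path / "a.refFlat", [_refflat_line("A", "chr1", "+", 99, 200)])
        (rec,) = load_refflat(f)
        # refFlat txStart is 0-based: 99 -> 1-based 100
        assert rec == GeneRecord("A", "1", "+", 100, 200)

    def test_transcripts_collapse_to_extreme_boundaries(self, tmp_path):
        f = write_refflat(
            tmp_path / "a.refFlat",
            [
                _refflat_line("A", "chr2", "+", 1000, 5000, "A.1"),
                _refflat_line("A", "chr2", "+", 3000, 9000, "A.2"),
            ],
        )
        (rec,) = load_refflat(f)
        assert (rec.tx_start, rec.tx_end) == (1001, 9000)

    def test_multi_chromosome_gene_excluded(self, tmp_path):
        f = write_refflat(
            tmp_path / "a.refFlat",
            [
                _refflat_line("A", "chr1", "+", 100, 200, "A.1"),
                _refflat_line("A", "chr2", "+", 100, 200, "A.2"),
                _refflat_line("B", "chr1", "+", 100, 200),
            ],
        )
        recs = load_refflat(f)
        assert [r.gene_symbol for r in recs] == ["B"]

    def test_distant_transcripts_excluded_but_single_long_transcript_kept(self, tmp_path):
        f = write_refflat(
            tmp_path / "a.refFlat",
            [
                _refflat_line("FAR", "chr1", "+", 1_000, 2_000, "FAR.1"),
                _refflat_line("FAR", "chr1", "+", 1_200_000, 1_201_000, "FAR.2"),
                _refflat_line("LONG", "chr1", "+", 1_000, 1_500_000),
            ],
        )
        recs = load_refflat(f)
        # collapsed span 1.2 Mb > 1 Mb with >=2 transcripts -> excluded;
        # a single transcript of any length is kept
        assert [r.gene_symbol for r in recs] == ["LONG"]

    def test_strand_conflict_excluded_with_warning(self, tmp_path, caplog):
        f = write_refflat(
            tmp_path / "a.refFlat",
            [
                _refflat_line("A", "chr1", "+", 100, 200, "A.1"),
                _refflat_line("A", "chr1", "-", 150, 250, "A.2"),
            ],
        )
        with caplog.at_level("WARNING"):
            recs = load_refflat(f)
        assert recs == []
        assert any("strand" in r.message for r in caplog.records)

    def test_malformed_line_rejected_with_line_number(self, tmp_path):
        f = tmp_path / "bad.refFlat"
        f.write_text(_refflat_line("A", "chr1", "+", 100, 200) + "\nB\tonly\ttwo\n")
        with pytest.raises(InputError, match="line 2"):
            load_refflat(f)

    def test_collapsing_is_idempotent(self, tmp_path, tiny_genome):
        paths = tiny_genome.to_files(tmp_path / "fx")
        first = load_refflat(paths["refflat"])
        # re-serialise the collapsed records (one transcript per gene) and re-load
        lines = [
            _refflat_line(g.gene_symbol, f"chr{g.chrom}", g.strand, g.tx_start - 1, g.tx_end)
            for g in first
        ]
        second = load_refflat(write_refflat(tmp_path / "re.refFlat", lines))
        assert sorted(first, key=lambda g: g.gene_symbol) == sorted(
            second, key=lambda g: g.gene_symbol
        )


class TestExtendBoundaries:
    G_PLUS = GeneRecord("A", "1", "+", 1_000_000, 1_050_000)
    G_MINUS = GeneRecord("A", "1", "-", 1_000_000, 1_050_000)
    CFG = BoundaryConfig(upstream_bp=110_000, downstream_bp=40_000)

    def test_plus_strand_asymmetric(self):
        (r,) = extend_boundaries([self.G_PLUS], self.CFG)
        assert (r.region_start, r.region_end) == (890_000, 1_090_000)

    def test_minus_strand_mirrored(self):
        (r,) = extend_boundaries([self.G_MINUS], self.CFG)
        assert (r.region_start, r.region_end) == (960_000, 1_160_000)

    def test_strand_ignored_when_not_strand_aware(self):
        cfg = BoundaryConfig(110_000, 40_000, strand_aware=False)
        (r,) = extend_boundaries([self.G_MINUS], cfg)
        assert (r.region_start, r.region_end) == (890_000, 1_090_000)

    def test_region_start_clipped_to_one(self):
        g = GeneRecord("A", "1", "+", 50_000, 60_000)
        (r,) = extend_boundaries([g], self.CFG)
        assert r.region_start == 1

    def test_symmetric_boundaries_are_strand_invariant(self):
        cfg = BoundaryConfig.symmetric_50kb()
        (rp,) = extend_boundaries([self.G_PLUS], cfg)
        (rm,) = extend_boundaries([self.G_MINUS], cfg)
        assert (rp.region_start, rp.region_end) == (rm.region_start, rm.region_end)

    def test_negative_extension_rejected(self):
        with pytest.raises(ValueError):
            BoundaryConfig(upstream_bp=-1)


class TestAssignSnps:
    def _snps(self, rows):
        return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "p"])

    def test_boundaries_inclusive(self):
        g = GeneRecord("A", "1", "+", 1_000_000, 1_050_000)
        regions = extend_boundaries([g], BoundaryConfig(110_000, 40_000))
        snps = self._snps(
            [("rs1", "1", 890_000, 0.5), ("rs2", "1", 889_999, 0.5), ("rs3", "1", 1_090_000, 0.5)]
        )
        (r,) = assign_snps(regions, snps)
        assert sorted(snps.loc[r.snp_indices, "snp"]) == ["rs1", "rs3"]

    def test_unmatched_chromosome_counted(self, caplog):
        g = GeneRecord("A", "1", "+", 1000, 2000)
        regions = extend_boundaries([g], BoundaryConfig(100, 100))
        snps = self._snps([("rsX", "X", 1500, 0.5)])
        with caplog.at_level("WARNING"):
            (r,) = assign_snps(regions, snps)
        assert r.n_snps == 0
        assert any("absent" in rec.message for rec in caplog.records)

    def test_counts_inside_vs_outside(self):
        g = GeneRecord("A", "1", "+", 10_000, 20_000)
        regions = extend_boundaries([g], BoundaryConfig(1_000, 1_000))
        snps = self._snps(
            [("rs%d" % i, "1", pos, 0.5)
             for i, pos in enumerate([9_500, 15_000, 20_500, 8_000, 25_000])]
        )
        (r,) = assign_snps(regions, snps)
        assert r.n_snps == 3

    def test_every_assigned_snp_satisfies_interval_predicate(self, tiny_genome):
        pos = tiny_genome.snps["pos"].to_numpy()
        chrom = tiny_genome.snps["chrom"].to_numpy()
        for r in tiny_genome.regions:
            if r.n_snps == 0:
                continue
            assert np.all(pos[r.snp_indices] >= r.region_start)
            assert np.all(pos[r.snp_indices] <= r.region_end)
            assert np.all(chrom[r.snp_indices] == r.gene.chrom)


class TestReadSnpTable:
    def test_case_insensitive_columns_and_chr_prefix(self, tmp_path):
        f = tmp_path / "assoc.tsv"
        f.write_text("Snp\tChr\tPos\tP\textra\nrs1\tchr1\t100\t0.5\tx\n")
        df = read_snp_table(f)
        assert list(df.columns) == ["snp", "chrom", "pos", "p"]
        assert df.loc[0, "chrom"] == "1"

    def test_invalid_rows_dropped_and_zero_p_clamped(self, tmp_path):
        f = tmp_path / "assoc.tsv"
        f.write_text(
            "SNP CHR POS P\nrs1 1 100 0.0\nrs2 1 200 1.5\nrs3 1 300 NA\nrs4 1 400 0.25\n"
        )
        df = read_snp_table(f)
        assert set(df["snp"]) == {"rs1", "rs4"}
        assert 0 < df.set_index("snp").loc["rs1", "p"] < 1e-250

    def test_duplicate_snp_ids_rejected(self, tmp_path):
        f = tmp_path / "assoc.tsv"
        f.write_text("SNP CHR POS P\nrs1 1 100 0.5\nrs1 1 200 0.2\n")
        with pytest.raises(InputError, match="duplicate"):
            read_snp_table(f)

    def test_missing_column_rejected(self, tmp_path):
        f = tmp_path / "assoc.tsv"
        f.write_text("SNP CHR POS\nrs1 1 100\n")
        with pytest.raises(InputError, match="missing"):
            read_snp_table(f)
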