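import gzip

import numpy as np
import pandas as pd
import pytest

import octomethyl as om
from octomethyl import formats_io as fio

from conftest import make_cpg_table, make_features, make_repeats


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestCgmap:
    def test_single_row_conversion(self, tmp_path):
        """One CGmap line maps to (0-based pos, strand from nucleotide, percent)."""
        p = write(tmp_path, "a.cgmap", "s1\tC\t101\tCG\tCG\t0.5\t5\t10\n")
        t = fio.read_cgmap(p, min_total=1)
        row = t.iloc[0]
        assert (row.scaffold, row.pos, row.strand) == ("s1", 100, "+")
        assert row.meth_pct == 50.0 and row.n_meth == 5 and row.n_total == 10

    def test_strand_law(self, tmp_path):
        """Strand is + iff the Watson nucleotide column is C."""
        p = write(
            tmp_path,
            "b.cgmap",
            "s1\tC\t10\tCG\tCG\t0.1\t1\t10\ns1\tG\t11\tCG\tCG\t0.2\t2\t10\n",
        )
        t = fio.read_cgmap(p)
        assert list(t["strand"]) == ["+", "-"]

    def test_non_cpg_context_dropped(self, tmp_path):
        p = write(
            tmp_path,
            "c.cgmap",
            "s1\tC\t10\tCHH\tCA\t0.1\t1\t10\ns1\tC\t12\tCHG\tCC\t0.2\t2\t10\n",
        )
        assert len(fio.read_cgmap(p)) == 0

    def test_empty_file(self, tmp_path):
        assert len(fio.read_cgmap(write(tmp_path, "d.cgmap", ""))) == 0

    def test_min_total_filter(self, tmp_path):
        p = write(
            tmp_path,
            "e.cgmap",
            "s1\tC\t10\tCG\tCG\t0.5\t2\t4\ns1\tC\t20\tCG\tCG\t0.5\t5\t10\n",
        )
        t = fio.read_cgmap(p, min_total=10)
        assert list(t["pos"]) == [19]

    def test_bad_level_rejected(self, tmp_path):
        p = write(tmp_path, "f.cgmap", "s1\tC\t10\tCG\tCG\t1.5\t3\t2\n")
        with pytest.raises(fio.FormatError):
            fio.read_cgmap(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = write(tmp_path, "g.cgmap", "s1\tC\t10\tCG\n")
        with pytest.raises(fio.FormatError, match=":1:"):
            fio.read_cgmap(p)

    def test_gzip_supported(self, tmp_path):
        p = tmp_path / "h.cgmap.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("s1\tC\t101\tCG\tCG\t0.5\t5\t10\n")
        assert len(fio.read_cgmap(p)) == 1

    def test_round_trip(self, tmp_path):
        table = make_cpg_table(
            [
                ("s1", 5, "+", 100 * 3 / 7, 3, 7),
                ("s1", 6, "-", 0.0, 0, 12),
                ("s2", 0, "+", 100.0, 9, 9),
            ],
            sample="x",
        )
        path = tmp_path / "rt.cgmap"
        fio.write_cgmap(table, path)
        back = fio.read_cgmap(path, sample="x")
        pd.testing.assert_frame_equal(
            back[["scaffold", "pos", "strand", "n_meth", "n_total"]],
            table[["scaffold", "pos", "strand", "n_meth", "n_total"]],
        )
        assert np.allclose(back["meth_pct"], table["meth_pct"], atol=0.01)


class TestBismarkCoverage:
    def test_depth_filter_drops_nine_reads(self, tmp_path):
        p = write(tmp_path, "a.cov", "s1\t5\t5\t44.44\t4\t5\n")
        assert len(fio.read_bismark_coverage(p, min_total=10)) == 0

    def test_fully_methylated_site(self, tmp_path):
        p = write(tmp_path, "b.cov", "s1\t11\t11\t100.0\t12\t0\n")
        t = fio.read_bismark_coverage(p)
        assert t.iloc[0].meth_pct == 100.0 and t.iloc[0].n_total == 12
        assert t.iloc[0].pos == 10

    def test_interval_rows_rejected(self, tmp_path):
        p = write(tmp_path, "c.cov", "s1\t11\t12\t100.0\t12\t0\n")
        with pytest.raises(fio.FormatError):
            fio.read_bismark_coverage(p)

    def test_percent_consistent_with_counts(self, tmp_path, tiny_dataset):
        rrbs = om.simulate_methylome(tiny_dataset, "RRBS", "r1", seed=2)
        path = tmp_path / "r1.cov"
        fio.write_bismark_coverage(rrbs, path)
        back = fio.read_bismark_coverage(path, min_total=1)
        recomputed = 100.0 * back["n_meth"] / back["n_total"]
        assert np.allclose(back["meth_pct"], recomputed, atol=0.01)

    def test_strand_resolution_with_genome(self, tmp_path):
        p = write(tmp_path, "d.cov", "s1\t2\t2\t50.0\t5\t5\ns1\t3\t3\t50.0\t5\t5\n")
        t = fio.read_bismark_coverage(p, min_total=1, genome={"s1": "ACGT"})
        assert list(t["strand"]) == ["+", "-"]
        assert t.attrs["strand_resolved"]
        t2 = fio.read_bismark_coverage(p, min_total=1)
        assert list(t2["strand"]) == ["+", "+"] and not t2.attrs["strand_resolved"]


class TestGeneModels:
    GFF = (
        "##gff-version 3\n"
        "s1\t.\tmRNA\t101\t200\t.\t+\t.\tID=tA\n"
        "s1\t.\texon\t101\t140\t.\t+\t.\tID=tA.e1;Parent=tA\n"
        "s1\t.\texon\t161\t200\t.\t+\t.\tID=tA.e2;Parent=tA\n"
        "s1\t.\tmRNA\t301\t400\t.\t-\t.\tID=tB\n"
        "s1\t.\texon\t301\t400\t.\t-\t.\tID=tB.e1;Parent=tB\n"
    )

    def test_coordinate_conversion_and_tss(self, tmp_path):
        feats = fio.read_gene_models(write(tmp_path, "a.gff3", self.GFF))
        a = feats[feats.transcript_id == "tA"].iloc[0]
        assert (a.start, a.end) == (100, 200)
        assert fio.feature_tss(a) == 100 and fio.feature_tts(a) == 199
        assert a.exons == [(100, 140), (160, 200)]

    def test_minus_strand_tss_flip(self, tmp_path):
        feats = fio.read_gene_models(write(tmp_path, "b.gff3", self.GFF))
        b = feats[feats.transcript_id == "tB"].iloc[0]
        assert fio.feature_tss(b) == 399 and fio.feature_tts(b) == 300

    def test_empty_annotation(self, tmp_path):
        feats = fio.read_gene_models(write(tmp_path, "c.gff3", "##gff-version 3\n"))
        assert len(feats) == 0

    def test_orphan_exon_warns(self, tmp_path):
        gff = self.GFF + "s1\t.\texon\t501\t600\t.\t+\t.\tID=x;Parent=missing\n"
        with pytest.warns(UserWarning, match="no parent"):
            feats = fio.read_gene_models(write(tmp_path, "d.gff3", gff))
        assert len(feats) == 2

    def test_gff_round_trip_identity(self, tmp_path, tiny_dataset):
        """GFF -> internal -> GFF -> internal is the identity on features."""
        p1 = tmp_path / "x.gff3"
        tiny_dataset.write_gff3(p1)
        feats = fio.read_gene_models(p1)
        p2 = tmp_path / "y.gff3"
        fio.write_gff3(feats, p2)
        again = fio.read_gene_models(p2)
        orig = tiny_dataset.features.sort_values("transcript_id").reset_index(drop=True)
        again = again.sort_values("transcript_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(
            again[["transcript_id", "scaffold", "start", "end", "strand"]],
            orig[["transcript_id", "scaffold", "start", "end", "strand"]],
        )
        assert [list(map(tuple, e)) for e in again.exons] == [
            list(map(tuple, e)) for e in orig.exons
        ]


class TestRepeatMasker:
    def test_grouping_rules(self):
        assert fio.classify_repeat("LINE/L2") == "LINE"
        assert fio.classify_repeat("rRNA") == "OtherRE"
        assert fio.classify_repeat("Simple_repeat") == "SimpleRepeat"
        assert fio.classify_repeat("Satellite/acro") == "Satellite"
        for cls in ("DNA/hAT", "LTR/Gypsy", "SINE/tRNA"):
            assert fio.classify_repeat(cls) in fio.TE_GROUPS

    def test_header_only_file(self, tmp_path):
        p = write(
            tmp_path,
            "a.out",
            "   SW  perc ...\nscore  div. ...\n\n",
        )
        assert len(fio.read_repeatmasker(p)) == 0

    def test_round_trip(self, tmp_path, tiny_dataset):
        p = tmp_path / "r.out"
        tiny_dataset.write_repeatmasker(p)
        back = fio.read_repeatmasker(p)
        orig = tiny_dataset.repeats
        pd.testing.assert_frame_equal(
            back[["scaffold", "start", "end", "raw_class", "group"]].reset_index(drop=True),
            orig[["scaffold", "start", "end", "raw_class", "group"]].reset_index(drop=True),
        )


class TestTpmMatrix:
    def test_round_trip(self, tmp_path):
        tpm = pd.DataFrame(
            {"a": [0.0, 1.5], "b": [2.0, 3.25]},
            index=pd.Index(["t1", "t2"], name="transcript_id"),
        )
        p = tmp_path / "tpm.tsv"
        fio.write_tpm_matrix(tpm, p)
        pd.testing.assert_frame_equal(fio.read_tpm_matrix(p), tpm)

    def test_negative_rejected(self, tmp_path):
        p = write(tmp_path, "neg.tsv", "transcript_id\ta\nt1\t-1\n")
        with pytest.raises(fio.FormatError):
            fio.read_tpm_matrix(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = write(tmp_path, "dup.tsv", "transcript_id\ta\nt1\t1\nt1\t2\n")
        with pytest.raises(fio.FormatError, match="t1"):
            fio.read_tpm_matrix(p)

    def test_generator_output_round_trips(self, tmp_path, tiny_dataset):
        tpm = om.simulate_expression(tiny_dataset, seed=5)
        p = tmp_path / "g.tsv"
        fio.write_tpm_matrix(tpm, p)
        back = fio.read_tpm_matrix(p)
        assert np.allclose(back.to_numpy(), tpm.to_numpy(), atol=1e-9)
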