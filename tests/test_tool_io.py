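"""Readers/writers for tool dialects, GTF and the harmonized table."""

from __future__ import annotations

import pytest

from spliceharmony import tool_io
from spliceharmony.model import (
    EmptyAnnotationError,
    EventType,
    Family,
    MethodStats,
    RowError,
    SchemaError,
    SplicingEvent,
)


class TestReadGtf:
    def test_toy_transcript(self, toy_gtf_path):
        model = tool_io.read_gtf(toy_gtf_path)
        tx = model.genes["G1"].transcripts["T1"]
        assert tx.exons == [(101, 200), (301, 400), (501, 600)]
        assert "G1" in model.boundary_index[("chr1", "+", 200, "R")]
        assert "G1" in model.boundary_index[("chr1", "+", 301, "L")]
        assert ("chr1", "+", 201, 300) in model.introns

    def test_single_exon_transcript_retained(self, tmp_path):
        path = tmp_path / "single.gtf"
        path.write_text(
            'chr1\tx\texon\t10\t50\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        )
        model = tool_io.read_gtf(path)
        assert model.genes["G"].transcripts["T"].exons == [(10, 50)]

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.gtf"
        path.write_text("")
        with pytest.raises(EmptyAnnotationError):
            tool_io.read_gtf(path)

    def test_gene_only_lines_rejected(self, tmp_path):
        path = tmp_path / "genes.gtf"
        path.write_text('chr1\tx\tgene\t1\t100\t.\t+\t.\tgene_id "G";\n')
        with pytest.raises(EmptyAnnotationError):
            tool_io.read_gtf(path)

    def test_malformed_exon_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(
            'chr1\tx\texon\t10\t50\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            "chr1\tx\texon\t60\t90\t.\t+\t.\tno_attributes_here\n"
        )
        with pytest.raises(RowError, match="line 2"):
            tool_io.read_gtf(path)


RMATS_SE_HEADER = (
    "ID\tGeneID\tgeneSymbol\tchr\tstrand\texonStart_0base\texonEnd\t"
    "upstreamES\tupstreamEE\tdownstreamES\tdownstreamEE\tPValue\tFDR\t"
    "IncLevel1\tIncLevel2\tIncLevelDifference\n"
)


def _write_se(tmp_path, rows):
    path = tmp_path / "SE.MATS.JC.txt"
    path.write_text(RMATS_SE_HEADER + "".join(rows))
    return path


class TestReadRmats:
    def test_row_parsed_with_dpsi_passthrough(self, tmp_path):
        path = _write_se(tmp_path, [
            '1\t"G1"\t"G1"\tchr1\t+\t300\t400\t100\t200\t500\t600\t0.001\t0.01\t'
            "0.2,0.2\t0.5,0.5\t-0.3\n"
        ])
        (rec,) = tool_io.read_rmats(path)
        assert rec.event_kind == "SE"
        assert rec.inc_level_difference == pytest.approx(-0.3)
        assert rec.fdr == pytest.approx(0.01)
        assert rec.coords["upstreamEE"] == 200

    def test_replicate_mean_ignores_na(self, tmp_path):
        path = _write_se(tmp_path, [
            '1\t"G1"\t"G1"\tchr1\t+\t300\t400\t100\t200\t500\t600\t0.5\t0.9\t'
            "0.8,NA,0.6\t0.5,0.5\t0.2\n"
        ])
        (rec,) = tool_io.read_rmats(path)
        assert rec.inc_level_alt == pytest.approx(0.7)  # group 1 = treated

    def test_all_na_row_dropped(self, tmp_path):
        path = _write_se(tmp_path, [
            '1\t"G1"\t"G1"\tchr1\t+\t300\t400\t100\t200\t500\t600\t0.5\t0.9\t'
            "NA,NA\t0.5,0.5\t0.0\n"
        ])
        assert tool_io.read_rmats(path) == []

    def test_header_only_gives_empty_list(self, tmp_path):
        path = _write_se(tmp_path, [])
        assert tool_io.read_rmats(path) == []

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "SE.MATS.JC.txt"
        path.write_text("ID\tGeneID\tchr\tstrand\n")
        with pytest.raises(SchemaError, match="exonStart_0base"):
            tool_io.read_rmats(path)

    def test_non_numeric_fdr_is_row_error(self, tmp_path):
        path = _write_se(tmp_path, [
            '1\t"G1"\t"G1"\tchr1\t+\t300\t400\t100\t200\t500\t600\t0.5\toops\t'
            "0.5\t0.5\t0.0\n"
        ])
        with pytest.raises(RowError, match="FDR"):
            tool_io.read_rmats(path)

    def test_swap_groups_flips_sign(self, tmp_path):
        path = _write_se(tmp_path, [
            '1\t"G1"\t"G1"\tchr1\t+\t300\t400\t100\t200\t500\t600\t0.001\t0.01\t'
            "0.2,0.2\t0.5,0.5\t-0.3\n"
        ])
        (rec,) = tool_io.read_rmats(path, swap_groups=True)
        assert rec.inc_level_difference == pytest.approx(0.3)
        assert rec.inc_level_alt == pytest.approx(0.5)


LC_ES_HEADER = "intron\tlogef\tctrl\tcase\tdeltapsi\n"
LC_SIG_HEADER = "cluster\tstatus\tloglr\tdf\tp\tp.adjust\n"


def _write_leafcutter(tmp_path, es_rows, sig_rows):
    es = tmp_path / "x_effect_sizes.txt"
    sig = tmp_path / "x_cluster_significance.txt"
    es.write_text(LC_ES_HEADER + "".join(es_rows))
    sig.write_text(LC_SIG_HEADER + "".join(sig_rows))
    return es, sig


class TestReadLeafcutter:
    def test_junction_joined_to_cluster_fdr(self, tmp_path):
        es, sig = _write_leafcutter(
            tmp_path,
            ["chr1:200:501:clu_1_+\t1.2\t0.1\t0.5\t0.4\n"],
            ["chr1:clu_1_+\tSuccess\t5.0\t1\t0.001\t0.02\n"],
        )
        (rec,) = tool_io.read_leafcutter(es, sig)
        assert rec.dpsi == pytest.approx(0.4)
        assert rec.fdr == pytest.approx(0.02)
        assert rec.strand == "+"

    def test_failed_cluster_junctions_excluded(self, tmp_path):
        es, sig = _write_leafcutter(
            tmp_path,
            ["chr1:200:501:clu_1_+\t1.2\t0.1\t0.5\t0.4\n"],
            ["chr1:clu_1_+\tNoSuccess\t5.0\t1\t0.5\t0.9\n"],
        )
        assert tool_io.read_leafcutter(es, sig) == []

    def test_cluster_fdr_shared_by_members(self, tmp_path):
        es, sig = _write_leafcutter(
            tmp_path,
            [
                "chr1:200:501:clu_1_+\t1.2\t0.1\t0.5\t0.4\n",
                "chr1:600:901:clu_1_+\t-1.2\t0.9\t0.5\t-0.4\n",
            ],
            ["chr1:clu_1_+\tSuccess\t5.0\t1\t0.001\t0.02\n"],
        )
        recs = tool_io.read_leafcutter(es, sig)
        assert [r.fdr for r in recs] == [pytest.approx(0.02)] * 2

    def test_orphan_cluster_dropped(self, tmp_path):
        es, sig = _write_leafcutter(
            tmp_path,
            ["chr1:200:501:clu_9_+\t1.2\t0.1\t0.5\t0.4\n"],
            ["chr1:clu_1_+\tSuccess\t5.0\t1\t0.001\t0.02\n"],
        )
        assert tool_io.read_leafcutter(es, sig) == []

    def test_bad_intron_key_is_row_error(self, tmp_path):
        es, sig = _write_leafcutter(
            tmp_path,
            ["chr1-200-501\t1.2\t0.1\t0.5\t0.4\n"],
            ["chr1:clu_1_+\tSuccess\t5.0\t1\t0.001\t0.02\n"],
        )
        with pytest.raises(RowError):
            tool_io.read_leafcutter(es, sig)


MAJIQ_HEADER = (
    "gene_id\tlsv_id\tmean_dpsi_per_lsv_junction\tprobability_changing\t"
    "ref_mean_psi\talt_mean_psi\tjunctions_coords\tir_coords\tchr\tstrand\n"
)


class TestReadMajiq:
    def test_lsv_exploded_per_junction(self, tmp_path):
        path = tmp_path / "voila.tsv"
        path.write_text(
            MAJIQ_HEADER
            + "G1\tG1:s:1\t0.35;-0.35\t0.97;0.97\t0.1;0.9\t0.45;0.55\t"
            "201-500;401-500\t\tchr1\t+\n"
        )
        recs = tool_io.read_majiq(path)
        assert len(recs) == 2
        assert recs[0].dpsi == pytest.approx(0.35)
        assert recs[1].dpsi == pytest.approx(-0.35)
        assert not any(r.is_intron_retention for r in recs)

    def test_ir_coordinates_flag_matching_junction(self, tmp_path):
        path = tmp_path / "voila.tsv"
        path.write_text(
            MAJIQ_HEADER
            + "G1\tG1:s:2\t0.2;0.3\t0.9;0.9\t0.1;0.1\t0.3;0.4\t"
            "201-500;601-700\t601-700\tchr1\t+\n"
        )
        recs = tool_io.read_majiq(path)
        flags = [r.is_intron_retention for r in recs]
        assert flags == [False, True]

    def test_empty_tsv_gives_empty_list(self, tmp_path):
        path = tmp_path / "voila.tsv"
        path.write_text(MAJIQ_HEADER)
        assert tool_io.read_majiq(path) == []

    def test_ragged_fields_are_row_error(self, tmp_path):
        path = tmp_path / "voila.tsv"
        path.write_text(
            MAJIQ_HEADER
            + "G1\tG1:s:1\t0.35\t0.97;0.97\t0.1\t0.45\t201-500;401-500\t\tchr1\t+\n"
        )
        with pytest.raises(RowError, match="ragged"):
            tool_io.read_majiq(path)


def _example_events():
    es = SplicingEvent(
        label="chr1:200-301-400-501:+",
        family=Family.ES,
        event_type=EventType.ESIN,
        chrom="chr1",
        strand="+",
        gene_id="G1",
        annotated=True,
        method_stats={
            "rmats": MethodStats(dpsi=0.5, confidence=0.99, psi_ref=0.1, psi_alt=0.6),
            "majiq": MethodStats(dpsi=0.3, confidence=0.9, psi_ref=0.2, psi_alt=0.5),
        },
        psi_ref=0.15, psi_alt=0.55, dpsi=0.4, confidence=0.99,
    )
    ir = SplicingEvent(
        label="chr2:99-151:-",
        family=Family.IR,
        event_type=EventType.IROUT,
        chrom="chr2",
        strand="-",
        gene_id="G2",
        method_stats={"leafcutter": MethodStats(dpsi=-0.25, confidence=0.97)},
        dpsi=-0.25, confidence=0.97,
    )
    return [es, ir]


class TestHarmonizedTable:
    def test_round_trip_preserves_all_fields(self, tmp_path):
        events = _example_events()
        path = tmp_path / "harmonized.tsv"
        tool_io.write_harmonized(events, path)
        back = tool_io.read_harmonized(path)
        assert len(back) == 2
        for orig, rt in zip(sorted(events, key=lambda e: e.label),
                            sorted(back, key=lambda e: e.label)):
            assert rt.label == orig.label
            assert rt.event_type == orig.event_type
            assert rt.gene_id == orig.gene_id
            assert rt.annotated == orig.annotated
            assert rt.n_methods == orig.n_methods
            assert rt.dpsi == pytest.approx(orig.dpsi, abs=1e-6)
            for m, st in orig.method_stats.items():
                assert rt.method_stats[m].dpsi == pytest.approx(st.dpsi, abs=1e-6)
                assert rt.method_stats[m].confidence == pytest.approx(
                    st.confidence, abs=1e-6
                )

    def test_zero_events_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        tool_io.write_harmonized([], path)
        assert path.read_text().strip() == "\t".join(tool_io.harmonized_columns())
        assert tool_io.read_harmonized(path) == []

    def test_n_methods_column(self, tmp_path):
        path = tmp_path / "harmonized.tsv"
        tool_io.write_harmonized(_example_events(), path)
        lines = path.read_text().strip().split("\n")
        header = lines[0].split("\t")
        row = dict(zip(header, lines[1].split("\t")))
        assert row["n_methods"] == "2"


class TestTruthTable:
    def test_round_trip(self, tmp_path, truth_default):
        path = tmp_path / "TrueEvent.csv"
        tool_io.write_truth(truth_default, [1.0, 0.8, 0.5, 0.2], path)
        back = tool_io.read_truth(path)
        assert len(back) == len(truth_default)
        for orig, rt in zip(truth_default, back):
            assert rt.label == orig.label
            assert rt.event_type == orig.event_type
            assert rt.cryptic == orig.cryptic
            assert rt.junctions == orig.junctions
            assert rt.control_exons == orig.control_exons
            assert rt.alt_exons == orig.alt_exons
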