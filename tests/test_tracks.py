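import pytest
from hypothesis import given, settings, strategies as st

from trackprov import annotate_build, read_track, write_track
from trackprov.errors import (
    AnnotationConflictError,
    MalformedFileError,
    TrackFormatError,
)
from trackprov.scanner import audit_file
from trackprov.tracks import GenomicInterval, detect_format


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestParsing:
    def test_bed_is_zero_based_half_open(self, tmp_path):
        track = read_track(_write(tmp_path, "a.bed", "chr1\t100\t200\n"))
        (rec,) = track.records
        assert (rec.chrom, rec.start, rec.end) == ("chr1", 100, 200)
        assert rec.source_line == 1

    def test_gff_converts_one_based_inclusive(self, tmp_path):
        line = "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n"
        track = read_track(_write(tmp_path, "a.gff", line))
        (rec,) = track.records
        assert (rec.start, rec.end, rec.strand) == (100, 200, "+")

    def test_wig_fixedstep_start_step_span(self, tmp_path):
        text = "fixedStep chrom=chr2 start=11 step=10 span=5\n1.0\n2.0\n"
        track = read_track(_write(tmp_path, "a.wig", text))
        spans = [(r.chrom, r.start, r.end) for r in track.records]
        assert spans == [("chr2", 10, 15), ("chr2", 20, 25)]

    def test_wig_variablestep(self, tmp_path):
        text = "variableStep chrom=chr3 span=3\n21\t0.5\n101\t0.7\n"
        track = read_track(_write(tmp_path, "a.wig", text))
        spans = [(r.start, r.end, r.score) for r in track.records]
        assert spans == [(20, 23, 0.5), (100, 103, 0.7)]

    def test_narrowpeak_field_count_enforced(self, tmp_path):
        good = "chr1\t10\t50\tp1\t100\t.\t5.5\t-1\t-1\t20"
        short = "chr1\t10\t50\tp2\t100\t."
        track = read_track(
            _write(tmp_path, "a.narrowPeak", good + "\n" + short + "\n"),
            max_malformed_fraction=0.5,
        )
        assert len(track.records) == 1
        assert len(track.malformed) == 1
        assert track.records[0].extra == ("5.5", "-1", "-1", "20")

    def test_header_lines_captured(self, tmp_path):
        text = "# a comment\ntrack name=peaks\nbrowser position chr1\nchr1\t0\t10\n"
        track = read_track(_write(tmp_path, "a.bed", text))
        assert len(track.header_lines) == 3
        assert len(track.records) == 1

    def test_inverted_coordinates_go_to_malformed(self, tmp_path):
        track = read_track(
            _write(tmp_path, "a.bed", "chr1\t0\t10\nchr1\t500\t100\n"),
            max_malformed_fraction=0.5,
        )
        assert len(track.records) == 1
        assert track.malformed[0].line_no == 2

    def test_strictness_threshold(self, tmp_path):
        path = _write(tmp_path, "a.bed", "chr1\t0\t10\nchr1\t500\t100\n")
        with pytest.raises(MalformedFileError):
            read_track(path, max_malformed_fraction=0.05)
        read_track(path, max_malformed_fraction=0.5)  # tolerant mode passes

    def test_format_detection_failure(self, tmp_path):
        path = _write(tmp_path, "mystery.xyz", "completely unstructured\ntext\n")
        with pytest.raises(TrackFormatError):
            read_track(path)

    @pytest.mark.parametrize(
        "name,content,expected",
        [
            ("x.bed", "", "BED"),
            ("x.gtf", "", "GFF"),
            ("x.txt", "fixedStep chrom=chr1 start=1 step=1\n1\n", "WIG"),
            ("x.txt", "chr1\tsrc\tgene\t1\t10\t.\t+\t.\tID=1\n", "GFF"),
            ("x.txt", "chr1\t0\t10\n", "BED"),
        ],
    )
    def test_format_detection(self, tmp_path, name, content, expected):
        path = _write(tmp_path, name, content)
        assert detect_format(path) == expected


class TestRoundTrip:
    @pytest.mark.parametrize(
        "name,text",
        [
            ("t.bed", "# h\nchr1\t0\t10\nchr2\t5\t9\tpk\t3\t-\n"),
            ("t.gff", "chr1\tsrc\tgene\t101\t200\t5\t-\t0\tID=g\n"),
            ("t.narrowPeak", "chr1\t10\t50\tp\t0\t.\t1\t-1\t-1\t7\n"),
            ("t.broadPeak", "chr1\t10\t50\tp\t0\t+\t1\t-1\t-1\n"),
            ("t.wig", "fixedStep chrom=chr1 start=5 step=2 span=2\n1.5\n2.5\n"),
        ],
    )
    def test_read_write_read_identity(self, tmp_path, name, text):
        original = read_track(_write(tmp_path, name, text))
        out = tmp_path / ("rt_" + name)
        write_track(original, out)
        again = read_track(out)
        key = lambda t: [(r.chrom, r.start, r.end, r.strand) for r in t.records]
        assert key(again) == key(original)
        assert again.header_lines == original.header_lines

    def test_gff_writeback_restores_one_based(self, tmp_path):
        path = _write(tmp_path, "t.gff", "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tx\n")
        out = tmp_path / "back.gff"
        write_track(read_track(path), out)
        assert out.read_text().split("\t")[3:5] == ["101", "200"]

    def test_empty_records_writes_header_only(self, tmp_path):
        path = _write(tmp_path, "t.bed", "# only a header\n")
        out = tmp_path / "empty.bed"
        write_track(read_track(path), out)
        assert out.read_text() == "# only a header\n"

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2", "chrX"]),
                st.integers(0, 10_000),
                st.integers(1, 500),
                st.sampled_from(["+", "-", "."]),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_bed_round_trip_property(self, tmp_path_factory, rows):
        tmp = tmp_path_factory.mktemp("rt")
        text = "".join(
            f"{c}\t{s}\t{s + l}\tn\t0\t{strand}\n" for c, s, l, strand in rows
        )
        path = tmp / "p.bed"
        path.write_text(text)
        track = read_track(path)
        out = tmp / "q.bed"
        write_track(track, out)
        again = read_track(out)
        assert [(r.chrom, r.start, r.end, r.strand) for r in again.records] == [
            (c, s, s + l, strand) for c, s, l, strand in rows
        ]


class TestAnnotation:
    def test_comment_mechanism(self, tmp_path, registry):
        path = _write(tmp_path, "t.bed", "chr1\t0\t10\n")
        track = annotate_build(read_track(path), "hg38", "comment", registry)
        assert track.header_lines[0] == "# genome=hg38"

    def test_trackline_created_and_extended(self, tmp_path, registry):
        bare = read_track(_write(tmp_path, "a.bed", "chr1\t0\t10\n"))
        assert annotate_build(bare, "mm10", "trackline", registry).header_lines[0] == \
            "track genome=mm10"
        existing = read_track(_write(tmp_path, "b.bed", "track name=x\nchr1\t0\t10\n"))
        annotated = annotate_build(existing, "mm10", "trackline", registry)
        assert annotated.header_lines[0] == "track name=x genome=mm10"

    def test_filename_mechanism_inserts_before_extension(self, tmp_path, registry):
        path = _write(tmp_path, "peaks.bed", "chr1\t0\t10\n")
        annotated = annotate_build(read_track(path), "dm6", "filename", registry)
        assert annotated.path.endswith("peaks.dm6.bed")

    @pytest.mark.parametrize("mechanism", ["comment", "trackline", "filename"])
    def test_idempotent(self, tmp_path, registry, mechanism):
        path = _write(tmp_path, "t.bed", "chr1\t0\t10\n")
        once = annotate_build(read_track(path), "hg38", mechanism, registry)
        twice = annotate_build(once, "hg38", mechanism, registry)
        assert twice.header_lines == once.header_lines
        assert twice.path == once.path

    def test_conflicting_annotation_refused(self, tmp_path, registry):
        path = _write(tmp_path, "t.bed", "# genome=hg38\nchr1\t0\t10\n")
        with pytest.raises(AnnotationConflictError):
            annotate_build(read_track(path), "hg19", "comment", registry)

    def test_conflict_detected_across_mechanisms(self, tmp_path, registry):
        path = _write(tmp_path, "t.bed", "track genome=mm9\nchr1\t0\t10\n")
        with pytest.raises(AnnotationConflictError):
            annotate_build(read_track(path), "mm10", "comment", registry)

    def test_filename_conflict(self, tmp_path, registry):
        path = _write(tmp_path, "peaks.hg38.bed", "chr1\t0\t10\n")
        with pytest.raises(AnnotationConflictError):
            annotate_build(read_track(path), "hg19", "filename", registry)

    def test_alias_conflict_resolves_to_same_build(self, tmp_path, registry):
        # grch38 is hg38: annotating hg38 over "# genome=GRCh38" is idempotent
        path = _write(tmp_path, "t.bed", "# genome=GRCh38\nchr1\t0\t10\n")
        annotated = annotate_build(read_track(path), "hg38", "comment", registry)
        assert annotated.header_lines == ["# genome=GRCh38"]

    def test_annotate_then_scan_detects_build(self, tmp_path, registry):
        path = _write(tmp_path, "t.bed", "chr1\t0\t10\n")
        annotated = annotate_build(read_track(path), "hg19", "comment", registry)
        out = tmp_path / "annotated.bed"
        write_track(annotated, out)
        record = audit_file(out)
        assert record.classification == "header_only"
        assert "hg19" in record.tokens


def test_interval_invariants():
    with pytest.raises(ValueError):
        GenomicInterval(chrom="chr1", start=10, end=10)
    with pytest.raises(ValueError):
        GenomicInterval(chrom="chr1", start=-1, end=10)
    with pytest.raises(ValueError):
        GenomicInterval(chrom="chr1", start=0, end=10, source_line=0)
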