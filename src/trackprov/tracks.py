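"""Readers, writers and build annotation for genomic track formats.

Supported formats: BED, GFF (GFF3/GTF dialects), WIG (fixedStep and
variableStep), narrowPeak and broadPeak.  All records are normalized into
one in-memory representation, :class:`GenomicInterval`, with 0-based
half-open coordinates:

* BED / narrowPeak / broadPeak are already 0-based half-open;
* GFF/GTF are 1-based inclusive and converted on read (start-1, end
  unchanged) and back on write;
* WIG declaration starts are 1-based; each value covers ``span`` bases.

Malformed data lines are never silently dropped: they are collected with
line numbers on the :class:`TrackFile` and re-emitted in place on write.
A file whose malformed fraction exceeds the strictness threshold raises
:class:`~trackprov.errors.MalformedFileError` — track tools commonly fail
outright on files that do not strictly follow their format specification,
and this makes that failure mode explicit and configurable.

Build annotation implements the three recommended ways of making the
genome build travel with the file: a leading ``# genome=<id>`` comment,
a ``genome=<id>`` attribute on a browser ``track`` line, or a ``.<id>``
tag in the filename.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .errors import (
    AnnotationConflictError,
    MalformedFileError,
    TrackFormatError,
)
from .registry import BuildRegistry, load_registry

__all__ = [
    "GenomicInterval",
    "MalformedLine",
    "TrackFile",
    "read_track",
    "write_track",
    "annotate_build",
    "detect_format",
    "FORMATS",
]

FORMATS = ("BED", "GFF", "WIG", "narrowPeak", "broadPeak")

Mechanism = Literal["comment", "trackline", "filename"]

_EXTENSION_FORMATS = {
    ".bed": "BED",
    ".gff": "GFF",
    ".gff3": "GFF",
    ".gtf": "GFF",
    ".wig": "WIG",
    ".narrowpeak": "narrowPeak",
    ".broadpeak": "broadPeak",
}


@dataclass(frozen=True)
class GenomicInterval:
    """One track record in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None
    source_line: int = 1
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.source_line < 1:
            raise ValueError("source_line must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class MalformedLine:
    line_no: int
    text: str
    reason: str


@dataclass
class TrackFile:
    """A parsed track file: header lines, records and malformed lines."""

    path: str
    format: str
    header_lines: list[str] = field(default_factory=list)
    records: list[GenomicInterval] = field(default_factory=list)
    malformed: list[MalformedLine] = field(default_factory=list)
    #: extra per-format state needed for faithful re-serialization
    wig_declarations: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def malformed_fraction(self) -> float:
        n_data = len(self.records) + len(self.malformed)
        return len(self.malformed) / n_data if n_data else 0.0


def detect_format(path: str | Path, peek_lines: Sequence[str] | None = None) -> str:
    """Infer the track format from the file extension, else from content."""
    suffix = Path(path).suffix.lower()
    if suffix in _EXTENSION_FORMATS:
        return _EXTENSION_FORMATS[suffix]
    if peek_lines is None:
        with open(path) as fh:
            peek_lines = [fh.readline() for _ in range(50)]
    for line in peek_lines:
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "track", "browser")):
            continue
        if stripped.startswith(("fixedStep", "variableStep")):
            return "WIG"
        fields = stripped.split("\t")
        if len(fields) >= 8 and fields[6] in "+-." and _is_int(fields[3]) and _is_int(fields[4]):
            return "GFF"
        if len(fields) >= 3 and _is_int(fields[1]) and _is_int(fields[2]):
            if len(fields) == 10:
                return "narrowPeak"
            if len(fields) == 9:
                return "broadPeak"
            return "BED"
        if len(fields) == 2 and _is_int(fields[0]):
            return "WIG"  # variableStep data line
    raise TrackFormatError(f"{path}: cannot detect track format")


def _is_int(text: str) -> bool:
    try:
        int(text)
    except ValueError:
        return False
    return True


def _is_header(line: str) -> bool:
    return line.startswith("#") or line.startswith("track") or line.startswith("browser")


def read_track(
    path: str | Path,
    format: str | None = None,
    max_malformed_fraction: float = 0.05,
) -> TrackFile:
    """Read a track file into normalized intervals.

    Parameters
    ----------
    path
        Text track file.
    format
        Explicit format override; auto-detected when omitted.
    max_malformed_fraction
        Strictness threshold: raise :class:`MalformedFileError` when the
        fraction of malformed data lines exceeds it.  Pass ``0.0`` for
        strict mode.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if format is None:
        format = detect_format(path, peek_lines=lines[:50])
    if format not in FORMATS:
        raise TrackFormatError(f"unsupported format {format!r}")

    track = TrackFile(path=str(path), format=format)
    in_header = True
    parser = _PARSERS[format]
    state: dict = {}
    for line_no, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if in_header and _is_header(line):
            track.header_lines.append(line)
            continue
        in_header = False
        if line.startswith("#"):
            # mid-file comments tolerated (bedtools-style) but not header
            continue
        parser(track, line_no, line, state)

    if track.malformed_fraction() > max_malformed_fraction:
        raise MalformedFileError(
            f"{path}: {len(track.malformed)}/{track.n_records + len(track.malformed)}"
            f" data lines malformed (threshold {max_malformed_fraction:.0%});"
            " first offence at line "
            f"{track.malformed[0].line_no}: {track.malformed[0].reason}"
        )
    return track


# ---------------------------------------------------------------------------
# per-format parsing


def _parse_bed_like(track: TrackFile, line_no: int, line: str, state: dict,
                    min_fields: int = 3) -> None:
    fields = line.rstrip().split("\t")
    if len(fields) == 1:
        fields = line.split()
    if len(fields) < min_fields:
        track.malformed.append(MalformedLine(line_no, line, f"fewer than {min_fields} fields"))
        return
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        track.malformed.append(MalformedLine(line_no, line, "non-integer coordinates"))
        return
    if not (0 <= start < end):
        track.malformed.append(
            MalformedLine(line_no, line, f"invalid half-open interval [{start},{end})")
        )
        return
    name = fields[3] if len(fields) > 3 else None
    score = None
    if len(fields) > 4:
        try:
            score = float(fields[4])
        except ValueError:
            score = None
    strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
    track.records.append(
        GenomicInterval(
            chrom=chrom, start=start, end=end, strand=strand, score=score,
            name=name, source_line=line_no, extra=tuple(fields[6:]),
        )
    )


def _parse_bed(track: TrackFile, line_no: int, line: str, state: dict) -> None:
    _parse_bed_like(track, line_no, line, state, min_fields=3)


def _parse_peak(expected: int):
    def parse(track: TrackFile, line_no: int, line: str, state: dict) -> None:
        n = len(line.rstrip().split("\t"))
        if n != expected:
            track.malformed.append(
                MalformedLine(line_no, line, f"expected {expected} fields, found {n}")
            )
            return
        _parse_bed_like(track, line_no, line, state, min_fields=6)
    return parse


def _parse_gff(track: TrackFile, line_no: int, line: str, state: dict) -> None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 8:
        track.malformed.append(MalformedLine(line_no, line, "fewer than 8 GFF fields"))
        return
    chrom, source, feature = fields[0], fields[1], fields[2]
    try:
        start1, end1 = int(fields[3]), int(fields[4])
    except ValueError:
        track.malformed.append(MalformedLine(line_no, line, "non-integer coordinates"))
        return
    if not (1 <= start1 <= end1):
        track.malformed.append(
            MalformedLine(line_no, line, f"invalid 1-based inclusive span {start1}..{end1}")
        )
        return
    score: float | None
    try:
        score = float(fields[5])
    except ValueError:
        score = None
    strand = fields[6] if fields[6] in "+-." else "."
    attrs = fields[8] if len(fields) > 8 else ""
    track.records.append(
        GenomicInterval(
            chrom=chrom, start=start1 - 1, end=end1, strand=strand, score=score,
            name=feature, source_line=line_no,
            extra=(source, fields[7], attrs),
        )
    )


_FIXEDSTEP_RE = re.compile(r"fixedStep\s+(.*)")
_VARIABLESTEP_RE = re.compile(r"variableStep\s+(.*)")


def _wig_attrs(text: str) -> dict[str, str]:
    return dict(
        (m.group(1), m.group(2))
        for m in re.finditer(r"(\w+)=(\S+)", text)
    )


def _parse_wig(track: TrackFile, line_no: int, line: str, state: dict) -> None:
    stripped = line.strip()
    if stripped.startswith(("fixedStep", "variableStep")):
        attrs = _wig_attrs(stripped)
        if "chrom" not in attrs:
            track.malformed.append(MalformedLine(line_no, line, "declaration without chrom"))
            state.pop("mode", None)
            return
        state["mode"] = "fixed" if stripped.startswith("fixedStep") else "variable"
        state["chrom"] = attrs["chrom"]
        state["span"] = int(attrs.get("span", 1))
        if state["mode"] == "fixed":
            try:
                state["pos"] = int(attrs["start"]) - 1  # 1-based declaration
                state["step"] = int(attrs.get("step", 1))
            except (KeyError, ValueError):
                track.malformed.append(
                    MalformedLine(line_no, line, "fixedStep needs integer start/step")
                )
                state.pop("mode", None)
                return
        track.wig_declarations.append((line_no, stripped))
        return
    mode = state.get("mode")
    if mode is None:
        track.malformed.append(MalformedLine(line_no, line, "data before step declaration"))
        return
    fields = stripped.split()
    try:
        if mode == "fixed":
            value = float(fields[0])
            start = state["pos"]
            state["pos"] += state["step"]
        else:
            start = int(fields[0]) - 1
            value = float(fields[1])
    except (ValueError, IndexError):
        track.malformed.append(MalformedLine(line_no, line, "bad WIG data line"))
        return
    track.records.append(
        GenomicInterval(
            chrom=state["chrom"], start=start, end=start + state["span"],
            score=value, source_line=line_no,
        )
    )


_PARSERS = {
    "BED": _parse_bed,
    "narrowPeak": _parse_peak(10),
    "broadPeak": _parse_peak(9),
    "GFF": _parse_gff,
    "WIG": _parse_wig,
}


# ---------------------------------------------------------------------------
# serialization


def _format_score(score: float | None, default: str = "0") -> str:
    if score is None:
        return default
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def _serialize_record(rec: GenomicInterval, format: str) -> str:
    if format in ("BED", "narrowPeak", "broadPeak"):
        fields = [rec.chrom, str(rec.start), str(rec.end)]
        if rec.name is not None or rec.score is not None or rec.strand != "." or rec.extra:
            fields.append(rec.name if rec.name is not None else ".")
        if rec.score is not None or rec.strand != "." or rec.extra:
            fields.append(_format_score(rec.score))
        if rec.strand != "." or rec.extra:
            fields.append(rec.strand)
        fields.extend(rec.extra)
        return "\t".join(fields)
    if format == "GFF":
        source, frame, attrs = (rec.extra + (".", ".", ""))[:3]
        return "\t".join([
            rec.chrom, source, rec.name or "feature",
            str(rec.start + 1), str(rec.end),
            _format_score(rec.score, default="."), rec.strand, frame, attrs,
        ])
    raise TrackFormatError(f"cannot serialize records of format {format!r}")


def write_track(track: TrackFile, path: str | Path) -> None:
    """Serialize *track* back to its source dialect.

    Header lines come first, then records (and any malformed lines) in
    source order.  Reading the result back reproduces chrom/start/end/strand
    of every record.
    """
    path = Path(path)
    lines: list[tuple[int, str]] = []
    if track.format == "WIG":
        lines.extend(track.wig_declarations)
        decls = sorted(track.wig_declarations)
        decl_text_by_line = dict(decls)
        for rec in track.records:
            # each value is emitted under its governing declaration line
            decl_line = max((ln for ln, _ in decls if ln < rec.source_line), default=None)
            if decl_line is None:
                raise TrackFormatError("WIG record without a declaration line")
            if decl_text_by_line[decl_line].startswith("fixedStep"):
                lines.append((rec.source_line, _format_score(rec.score, "0")))
            else:
                lines.append((rec.source_line, f"{rec.start + 1}\t{_format_score(rec.score, '0')}"))
    else:
        for rec in track.records:
            lines.append((rec.source_line, _serialize_record(rec, track.format)))
    for bad in track.malformed:
        lines.append((bad.line_no, bad.text))
    lines.sort(key=lambda item: item[0])
    with open(path, "w") as fh:
        for header in track.header_lines:
            fh.write(header + "\n")
        for _, text in lines:
            fh.write(text + "\n")


# ---------------------------------------------------------------------------
# build annotation

_COMMENT_GENOME_RE = re.compile(r"^#\s*genome\s*=\s*(\S+)\s*$", re.IGNORECASE)
_TRACKLINE_GENOME_RE = re.compile(r"\bgenome\s*=\s*\"?([\w.]+)\"?", re.IGNORECASE)


def _existing_annotations(track: TrackFile, registry: BuildRegistry) -> set[str]:
    """Build ids already annotated via comment or track line."""
    found: set[str] = set()
    for line in track.header_lines:
        if line.startswith("#"):
            m = _COMMENT_GENOME_RE.match(line)
        elif line.startswith("track"):
            m = _TRACKLINE_GENOME_RE.search(line)
        else:
            m = None
        if m:
            resolved = registry.resolve_token(m.group(1))
            found.add(resolved if resolved is not None else m.group(1).lower())
    return found


def annotate_build(
    track: TrackFile,
    build_id: str,
    mechanism: Mechanism = "comment",
    registry: BuildRegistry | None = None,
) -> TrackFile:
    """Attach the genome build to a track file.

    ``comment`` prepends ``# genome=<id>`` as the first header line;
    ``trackline`` adds ``genome=<id>`` to the browser track line (creating
    one if absent); ``filename`` inserts ``.<id>`` before the extension.
    Annotation is idempotent, and an existing annotation naming a
    *different* build raises :class:`AnnotationConflictError` rather than
    being silently overwritten.

    Returns a new :class:`TrackFile`; the input is not modified.
    """
    if registry is None:
        registry = load_registry()
    build = registry.lookup(build_id)  # raises UnknownBuildError if absent

    existing = _existing_annotations(track, registry)
    conflicting = existing - {build.id}
    if conflicting:
        raise AnnotationConflictError(
            f"{track.path}: already annotated as {sorted(conflicting)},"
            f" refusing to overwrite with {build.id!r}"
        )

    header = list(track.header_lines)
    new_path = track.path
    if mechanism == "comment":
        if not any(_COMMENT_GENOME_RE.match(h) for h in header):
            header.insert(0, f"# genome={build.id}")
    elif mechanism == "trackline":
        track_idx = next(
            (i for i, h in enumerate(header) if h.startswith("track")), None
        )
        if track_idx is None:
            header.insert(0, f"track genome={build.id}")
        elif not _TRACKLINE_GENOME_RE.search(header[track_idx]):
            header[track_idx] = header[track_idx].rstrip() + f" genome={build.id}"
    elif mechanism == "filename":
        p = Path(track.path)
        stem_parts = p.name.split(".")
        from .scanner import scan_tokens  # deferred: scanner imports nothing from here

        filename_builds = {
            registry.resolve_token(hit.token)
            for hit in scan_tokens(p.name, where="filename")
        } - {None}
        if filename_builds - {build.id}:
            raise AnnotationConflictError(
                f"{p.name}: filename already names build(s)"
                f" {sorted(filename_builds - {build.id})}"
            )
        if build.id not in filename_builds:
            if len(stem_parts) > 1:
                stem_parts.insert(-1, build.id)
                new_name = ".".join(stem_parts)
            else:
                new_name = f"{p.name}.{build.id}"
            new_path = str(p.with_name(new_name))
    else:
        raise ValueError(f"unknown annotation mechanism {mechanism!r}")

    annotated = replace_track(track, header_lines=header, path=new_path)
    return annotated


def replace_track(track: TrackFile, **changes) -> TrackFile:
    fields_ = dict(
        path=track.path,
        format=track.format,
        header_lines=list(track.header_lines),
        records=list(track.records),
        malformed=list(track.malformed),
        wig_declarations=list(track.wig_declarations),
    )
    fields_.update(changes)
    return TrackFile(**fields_)
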