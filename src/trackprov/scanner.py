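"""Detection of genome-build tokens in filenames and header lines.

Audits whether a track file carries its genome build along with it, the
way repository surveys do: scan the basename and the first 50 lines of the
file, case-insensitively, for a fixed vocabulary of build names covering
human, mouse and Drosophila assemblies.  Matching is longest-token-first,
so ``bdgp5.25`` wins over ``bdgp5`` and ``build5.41`` over ``build5``;
there are no word-boundary requirements, so the low-specificity bare
``ncbi`` token matches inside longer words unless a more specific token
starts at the same position.

Files are classified into four mutually exclusive classes — build token
only in the filename, only in the file (header lines), in both, or in
neither — and directory audits aggregate per-format counts and
percentages.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .tracks import _EXTENSION_FORMATS

__all__ = [
    "BUILD_TOKENS",
    "LOW_SPECIFICITY_TOKENS",
    "HEADER_SCAN_LINES",
    "TokenHit",
    "AuditRecord",
    "AuditReport",
    "scan_tokens",
    "audit_file",
    "audit_directory",
]

#: The build-name vocabulary, as used in repository metadata surveys.
BUILD_TOKENS = (
    "hg17", "hg18", "hg19", "hg38",
    "grch36", "grch37", "grch38",
    "build37.2", "build37.1", "build36.3",
    "ncbi35", "ncbi36", "ncbi37",
    "mm8", "mm9", "mm10", "grcm38",
    "bdgp6", "bdgp5", "bdgp5.25",
    "build5.41", "build5.3", "build5", "build4.1",
    "dm6", "dm3", "ncbi",
)

#: Tokens that name no specific build; reported but flagged.
LOW_SPECIFICITY_TOKENS = frozenset({"ncbi"})

#: Header scanning depth, in lines.
HEADER_SCAN_LINES = 50

# Longest alternative first so that at equal start positions the most
# specific token wins (regex alternation is first-match, not longest-match).
_TOKEN_RE = re.compile(
    "|".join(re.escape(t) for t in sorted(BUILD_TOKENS, key=len, reverse=True)),
    re.IGNORECASE,
)

Where = Literal["filename", "header"]

Classification = Literal["filename_only", "header_only", "both", "neither"]


@dataclass(frozen=True)
class TokenHit:
    """One build-token match."""

    token: str  # canonical lowercase form of the matched token
    where: Where
    span: tuple[int, int]
    line: int | None = None  # header line number; None for filename hits

    @property
    def low_specificity(self) -> bool:
        return self.token in LOW_SPECIFICITY_TOKENS


def scan_tokens(text: str, where: Where = "header", line: int | None = None) -> list[TokenHit]:
    """All non-overlapping build-token matches in *text*, left to right.

    Case-insensitive; at a given position the longest token takes
    precedence.  Dots in tokens match the literal dot only.
    """
    return [
        TokenHit(token=m.group(0).lower(), where=where, span=m.span(), line=line)
        for m in _TOKEN_RE.finditer(text)
    ]


@dataclass(frozen=True)
class AuditRecord:
    """Per-file classification of build-token presence."""

    path: str
    classification: Classification | None
    hits: tuple[TokenHit, ...] = ()
    error: str | None = None

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(h.token for h in self.hits))


def _classify(filename_hits: bool, header_hits: bool) -> Classification:
    if filename_hits and header_hits:
        return "both"
    if filename_hits:
        return "filename_only"
    if header_hits:
        return "header_only"
    return "neither"


def audit_file(path: str | Path, n_lines: int = HEADER_SCAN_LINES) -> AuditRecord:
    """Classify one file by where (if anywhere) it names a genome build.

    Scans the basename only — directory components are disrupted by almost
    any transfer and are deliberately ignored — plus the first *n_lines*
    lines of the file, whatever their kind (comment, track line or data).
    An unreadable file yields an error record, not a "neither" call.
    """
    path = Path(path)
    hits: list[TokenHit] = list(scan_tokens(path.name, where="filename"))
    filename_hit = bool(hits)
    try:
        with open(path, errors="replace") as fh:
            for line_no, line in enumerate(fh, start=1):
                if line_no > n_lines:
                    break
                hits.extend(scan_tokens(line.rstrip("\n"), where="header", line=line_no))
    except OSError as exc:
        return AuditRecord(path=str(path), classification=None, hits=(), error=str(exc))
    header_hit = any(h.where == "header" for h in hits)
    return AuditRecord(
        path=str(path),
        classification=_classify(filename_hit, header_hit),
        hits=tuple(hits),
    )


_CLASSES: tuple[str, ...] = ("filename_only", "header_only", "both", "neither")


@dataclass
class AuditReport:
    """Aggregate audit over a directory tree, one row per track format."""

    records: list[AuditRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Counts and percentages per format.

        Percentages are over the readable files of each format; unreadable
        files appear in the ``errors`` column and are excluded from the
        percentage base.
        """
        rows = []
        by_format: dict[str, list[AuditRecord]] = {}
        for rec in self.records:
            fmt = _EXTENSION_FORMATS.get(Path(rec.path).suffix.lower(), "other")
            by_format.setdefault(fmt, []).append(rec)
        for fmt in sorted(by_format):
            recs = by_format[fmt]
            errors = sum(1 for r in recs if r.error is not None)
            checked = len(recs) - errors
            row: dict[str, object] = {"format": fmt, "total": checked, "errors": errors}
            for cls in _CLASSES:
                n = sum(1 for r in recs if r.classification == cls)
                row[cls] = n
                row[f"{cls}_pct"] = round(100.0 * n / checked, 1) if checked else 0.0
            rows.append(row)
        columns = ["format", "total", "errors"]
        for cls in _CLASSES:
            columns += [cls, f"{cls}_pct"]
        return pd.DataFrame(rows, columns=columns)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)

    def to_json(self) -> str:
        frame = self.to_frame()
        payload = {
            "formats": frame.to_dict(orient="records"),
            "files": [
                {
                    "path": r.path,
                    "classification": r.classification,
                    "tokens": list(r.tokens),
                    "low_specificity_tokens": [
                        t for t in r.tokens if t in LOW_SPECIFICITY_TOKENS
                    ],
                    "error": r.error,
                }
                for r in self.records
            ],
        }
        return json.dumps(payload, indent=2)


def audit_directory(
    root: str | Path,
    glob: str = "**/*",
    extensions: Iterable[str] | None = None,
) -> AuditReport:
    """Audit every track file under *root* matching *glob*.

    Only files with a recognized track extension are audited unless
    *extensions* overrides the filter.  An empty match set yields an empty
    report (total 0, no division).
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"audit root {root} does not exist")
    allowed = (
        set(_EXTENSION_FORMATS) if extensions is None
        else {e.lower() for e in extensions}
    )
    report = AuditReport()
    for path in sorted(root.glob(glob)):
        if path.is_file() and path.suffix.lower() in allowed:
            report.records.append(audit_file(path))
    return report
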