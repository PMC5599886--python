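"""Prediction of the genome build of orphan track files.

A track file whose build was never recorded (an *orphan* file) can often
still be assigned one: its coordinates are compatible with some builds and
not others.  For every candidate build we score the fraction of records
whose chromosome resolves in that build and whose end coordinate fits
within the chromosome length.  A build wins when it attains the strictly
highest score above an acceptance threshold; exact score ties are broken
only by the number of *discriminative* records — records valid in that
build but out of bounds (or on an unknown chromosome) in at least one
other candidate.  If the tie survives, the call is ``ambiguous``: a file
whose coordinates are equally compatible with several builds cannot be
assigned one from coordinates alone, by construction.  If no candidate
reaches the threshold the file is ``incompatible`` with the whole set.

The score is a plain fraction rather than a likelihood, so the failure
mode of malformed or truncated files stays visible in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import ConfigurationError, EmptyTrackError
from .registry import BuildRegistry, GenomeBuild, load_registry, normalize_chrom
from .tracks import GenomicInterval, TrackFile

__all__ = [
    "DEFAULT_MIN_SCORE",
    "CompatibilityReport",
    "Prediction",
    "score_against_build",
    "predict_build",
]

#: Default acceptance threshold on the within-bounds fraction.  Tolerant of
#: the same ~5% malformed-record slack the readers allow, while wrong-species
#: or truncated-assembly files still fall well below it.
DEFAULT_MIN_SCORE = 0.95

#: Evidence intervals listed in a unique prediction.
MAX_EVIDENCE = 10


@dataclass(frozen=True)
class CompatibilityReport:
    """Per-candidate-build tallies for one track file.

    Invariant chain: ``n_discriminative <= n_within_bounds <=
    n_chrom_known <= n_records``.
    """

    build_id: str
    n_records: int
    n_chrom_known: int
    n_within_bounds: int
    n_discriminative: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_discriminative <= self.n_within_bounds
                <= self.n_chrom_known <= self.n_records):
            raise ValueError(f"inconsistent tallies in report for {self.build_id}")

    @property
    def score(self) -> float:
        return self.n_within_bounds / self.n_records


@dataclass(frozen=True)
class Prediction:
    """Outcome of build prediction for one track file."""

    status: str  # unique | ambiguous | incompatible
    best_builds: tuple[str, ...]
    reports: tuple[CompatibilityReport, ...]
    evidence: tuple[GenomicInterval, ...] = ()
    min_score: float = DEFAULT_MIN_SCORE

    @property
    def build_id(self) -> str | None:
        return self.best_builds[0] if self.status == "unique" else None

    def report_for(self, build_id: str) -> CompatibilityReport:
        for report in self.reports:
            if report.build_id == build_id:
                return report
        raise KeyError(build_id)

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "best_builds": list(self.best_builds),
            "min_score": self.min_score,
            "reports": [
                {
                    "build": r.build_id,
                    "n_records": r.n_records,
                    "n_chrom_known": r.n_chrom_known,
                    "n_within_bounds": r.n_within_bounds,
                    "n_discriminative": r.n_discriminative,
                    "score": round(r.score, 6),
                }
                for r in self.reports
            ],
            "evidence": [
                {
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "source_line": iv.source_line,
                }
                for iv in self.evidence
            ],
        }


def _within_bounds(iv: GenomicInterval, build: GenomeBuild) -> bool | None:
    """True/False for known chromosomes, None when the chromosome is unknown."""
    canonical = normalize_chrom(iv.chrom, build)
    if canonical is None:
        return None
    return iv.end <= build.chrom_sizes[canonical]


def score_against_build(
    track: TrackFile,
    build: GenomeBuild,
    others: Sequence[GenomeBuild] = (),
) -> CompatibilityReport:
    """Tally how compatible *track*'s coordinates are with *build*.

    Each record's chromosome is normalized against the build's table and,
    when known, its end is compared with the chromosome length.  When
    *others* is given, records within bounds for *build* but out of bounds
    (or on an unknown chromosome) in at least one of them are additionally
    counted as discriminative.
    """
    if not track.records:
        raise EmptyTrackError(f"{track.path}: no records to score")
    n_known = n_within = n_disc = 0
    for iv in track.records:
        fits = _within_bounds(iv, build)
        if fits is None:
            continue
        n_known += 1
        if not fits:
            continue
        n_within += 1
        if any(_within_bounds(iv, other) is not True for other in others):
            n_disc += 1
    return CompatibilityReport(
        build_id=build.id,
        n_records=len(track.records),
        n_chrom_known=n_known,
        n_within_bounds=n_within,
        n_discriminative=n_disc,
    )


def predict_build(
    track: TrackFile,
    candidates: Sequence[str] | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
    registry: BuildRegistry | None = None,
) -> Prediction:
    """Predict the genome build of *track* from coordinate compatibility.

    Parameters
    ----------
    track
        The parsed orphan track file; must contain at least one record.
    candidates
        Build ids/aliases to consider; all registry builds by default.
    min_score
        Minimum within-bounds fraction for a build to be acceptable.
    registry
        Registry to resolve candidates in; the bundled one by default.

    Returns
    -------
    Prediction
        ``unique`` with one best build, ``ambiguous`` with the tied set,
        or ``incompatible`` when no candidate reaches *min_score*.  The
        result is independent of candidate order (reports are sorted by
        build id; ties are resolved by tallies only).
    """
    if registry is None:
        registry = load_registry()
    if candidates is None:
        builds = sorted(registry, key=lambda b: b.id)
    else:
        if not candidates:
            raise ConfigurationError("empty candidate set")
        builds = sorted(
            {registry.lookup(c).id: registry.lookup(c) for c in candidates}.values(),
            key=lambda b: b.id,
        )
    if not track.records:
        raise EmptyTrackError(f"{track.path}: no records to score")
    if not (0.0 <= min_score <= 1.0):
        raise ConfigurationError(f"min_score {min_score} outside [0, 1]")

    reports = tuple(
        score_against_build(track, b, others=[o for o in builds if o.id != b.id])
        for b in builds
    )
    eligible = [r for r in reports if r.score >= min_score]
    if not eligible:
        return Prediction(
            status="incompatible", best_builds=(), reports=reports, min_score=min_score
        )
    top_score = max(r.score for r in eligible)
    top = [r for r in eligible if r.score == top_score]
    if len(top) > 1:
        # score ties broken only by a strictly greater discriminative count;
        # surviving ties are genuine ambiguity
        max_disc = max(r.n_discriminative for r in top)
        top = [r for r in top if r.n_discriminative == max_disc]
    if len(top) == 1:
        winner = top[0]
        build = registry.lookup(winner.build_id)
        others = [registry.lookup(r.build_id) for r in reports if r.build_id != winner.build_id]
        evidence = tuple(
            iv for iv in track.records
            if _within_bounds(iv, build) is True
            and any(_within_bounds(iv, o) is not True for o in others)
        )[:MAX_EVIDENCE]
        return Prediction(
            status="unique",
            best_builds=(winner.build_id,),
            reports=reports,
            evidence=evidence,
            min_score=min_score,
        )
    return Prediction(
        status="ambiguous",
        best_builds=tuple(sorted(r.build_id for r in top)),
        reports=reports,
        min_score=min_score,
    )
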