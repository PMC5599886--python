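"""Deterministic generators for synthetic tracks, chains and toy builds.

Everything the test-suite and the acceptance checks need is generated
offline and reproducibly: given the same specification (including seed)
the generators emit byte-identical files.

Track generation draws intervals uniformly over a build's primary
chromosomes (weighted by length) and can guarantee *discriminative*
content: records placed so that every other candidate build is ruled out
by at least one record that is out of bounds, or on an unknown
chromosome, for it.  Where one chromosome exists on which the target
build strictly exceeds every candidate sharing that name, a single record
there rules out the whole field at once; otherwise a minimal greedy cover
places one record per remaining candidate.  If some candidate cannot be
ruled out at all (its chromosome set and lengths dominate the target's,
as with the bundled toyB against toyA), the fixture is infeasible and an
error says so.

Chain generation emits a valid chain per chromosome equal to the identity
map modified by user-stated indel edits, which makes per-base oracle
checking of the lift-over arithmetic trivial.

No attempt is made at biological realism (no peak shapes, no gene
models); these fixtures exercise coordinate logic only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import FixtureInfeasibleError, TrackProvError
from .registry import BuildRegistry, GenomeBuild, load_registry
from .tracks import GenomicInterval, MalformedLine, TrackFile

__all__ = [
    "FixtureSpec",
    "generate_track",
    "generate_ambiguous_track",
    "generate_chain",
    "identity_chain",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of one synthetic track file.

    Parameters
    ----------
    build_id
        The build the intervals are drawn from (the prediction target).
    n_intervals
        Total records, including discriminative ones.
    interval_length
        Fixed length in bp, or an inclusive (lo, hi) range sampled
        uniformly per record.
    discriminative_count
        Minimum number of records dedicated to ruling out the other
        candidates; raised automatically if the candidate set needs more.
    candidates
        Build ids the discriminative guarantee is made against; all
        registry builds when None.
    malformed_fraction
        Share of deliberately broken data lines, rounded to a whole
        number of lines, appended after the valid records.
    seed
        Seed for the single pseudo-random generator; identical specs give
        byte-identical files.
    """

    build_id: str
    n_intervals: int = 200
    interval_length: int | tuple[int, int] = (100, 1000)
    discriminative_count: int = 1
    candidates: tuple[str, ...] | None = None
    malformed_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_intervals < 1:
            raise TrackProvError("n_intervals must be >= 1")
        if not (0.0 <= self.malformed_fraction < 1.0):
            raise TrackProvError("malformed_fraction must be in [0, 1)")
        if self.discriminative_count > self.n_intervals:
            raise TrackProvError("discriminative_count cannot exceed n_intervals")


def _length_sampler(spec: FixtureSpec, rng: np.random.Generator):
    if isinstance(spec.interval_length, int):
        fixed = spec.interval_length
        return lambda: fixed
    lo, hi = spec.interval_length
    return lambda: int(rng.integers(lo, hi + 1))


def _shared_length(build_id: str, chrom: str, others: Sequence[GenomeBuild]) -> int:
    """Longest extent of *chrom* compatible with any other candidate (0 if
    nobody else has the chromosome)."""
    return max((o.chrom_sizes.get(chrom, 0) for o in others), default=0)


def discriminative_windows(
    build: GenomeBuild,
    others: Sequence[GenomeBuild],
) -> dict[str, tuple[int, int]]:
    """Per-chromosome windows (lo, hi] unique to *build* against *others*.

    A record ending inside such a window is incompatible with every other
    candidate that shares the chromosome; candidates lacking the
    chromosome are ruled out by any record on it.
    """
    windows: dict[str, tuple[int, int]] = {}
    for chrom in build.primary_set:
        limit = _shared_length(build.id, chrom, others)
        length = build.chrom_sizes[chrom]
        if length > limit:
            windows[chrom] = (limit, length)
    return windows


def _cover_placements(
    build: GenomeBuild, others: Sequence[GenomeBuild]
) -> list[tuple[str, int, int]]:
    """Minimal greedy list of (chrom, lo, hi] windows ruling out every
    other candidate; raises when some candidate is uncoverable."""
    remaining = list(others)
    placements: list[tuple[str, int, int]] = []
    # universal window first: one that every sharing candidate falls short of
    for chrom in build.primary_set:
        limit = _shared_length(build.id, chrom, remaining)
        if build.chrom_sizes[chrom] > limit:
            placements.append((chrom, limit, build.chrom_sizes[chrom]))
            return placements
    while remaining:
        best: tuple[int, str, int, int] | None = None
        for chrom in build.primary_set:
            length = build.chrom_sizes[chrom]
            # candidates this chromosome can rule out with end in (lo, length]
            excludable = [o for o in remaining if o.chrom_sizes.get(chrom, 0) < length]
            if not excludable:
                continue
            lo = max(o.chrom_sizes.get(chrom, 0) for o in excludable)
            if best is None or len(excludable) > best[0]:
                best = (len(excludable), chrom, lo, length)
        if best is None:
            raise FixtureInfeasibleError(
                f"{build.id}: cannot construct records incompatible with "
                f"{[o.id for o in remaining]} — their chromosome lengths dominate"
            )
        _, chrom, lo, hi = best
        placements.append((chrom, lo, hi))
        remaining = [o for o in remaining if o.chrom_sizes.get(chrom, 0) > lo]
    return placements


def generate_track(
    spec: FixtureSpec,
    format: str = "BED",
    registry: BuildRegistry | None = None,
) -> TrackFile:
    """Generate a synthetic track file per *spec*.

    The returned :class:`TrackFile` scores 1.0 against its own build
    (malformed lines aside) and, via the discriminative records, is
    incompatible with every other candidate by at least one record.
    """
    if registry is None:
        registry = load_registry()
    build = registry.lookup(spec.build_id)
    candidate_ids = spec.candidates
    if candidate_ids is None:
        candidate_ids = registry.ids
    others = [
        registry.lookup(c) for c in candidate_ids
        if registry.lookup(c).id != build.id
    ]
    rng = np.random.default_rng(spec.seed)
    sample_length = _length_sampler(spec, rng)

    placements: list[tuple[str, int, int]] = []
    if spec.discriminative_count > 0 and others:
        placements = _cover_placements(build, others)
        while len(placements) < spec.discriminative_count:
            placements.append(placements[0])

    n_uniform = spec.n_intervals - len(placements)
    if n_uniform < 0:
        raise FixtureInfeasibleError(
            f"{build.id}: needs {len(placements)} discriminative records to rule out"
            f" all candidates but n_intervals is only {spec.n_intervals}"
        )

    chroms = list(build.primary_set)
    weights = np.array([build.chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    records: list[GenomicInterval] = []
    for i in range(n_uniform):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = min(sample_length(), build.chrom_sizes[chrom])
        start = int(rng.integers(0, build.chrom_sizes[chrom] - length + 1))
        records.append(
            GenomicInterval(chrom=chrom, start=start, end=start + length,
                            name=f"iv{i}", source_line=1)
        )
    for j, (chrom, lo, hi) in enumerate(placements):
        end = int(rng.integers(lo + 1, hi + 1))
        length = min(sample_length(), end)
        records.append(
            GenomicInterval(chrom=chrom, start=end - length, end=end,
                            name=f"disc{j}", source_line=1)
        )

    n_bad = round(spec.malformed_fraction * spec.n_intervals)
    track = _assemble(spec, format, records, n_bad, rng)
    return track


def generate_ambiguous_track(
    candidates: Sequence[str],
    n_intervals: int = 200,
    interval_length: int | tuple[int, int] = (100, 1000),
    seed: int = 0,
    registry: BuildRegistry | None = None,
) -> TrackFile:
    """A track confined to coordinates shared by *all* candidate builds.

    Every record lies on a chromosome present in every candidate's primary
    set, within the minimum length across candidates, so all candidates
    score 1.0 with no discriminative records: prediction must come back
    ambiguous by construction.
    """
    if registry is None:
        registry = load_registry()
    builds = [registry.lookup(c) for c in candidates]
    if len(builds) < 2:
        raise TrackProvError("ambiguous fixtures need at least two candidates")
    shared = set(builds[0].primary_set)
    for b in builds[1:]:
        shared &= set(b.primary_set)
    limits = {
        c: min(b.chrom_sizes[c] for b in builds) for c in sorted(shared)
    }
    limits = {c: l for c, l in limits.items() if l > 1}
    if not limits:
        raise FixtureInfeasibleError(
            f"no chromosome is shared by all of {[b.id for b in builds]}"
        )
    rng = np.random.default_rng(seed)
    chroms = sorted(limits)
    weights = np.array([limits[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    if isinstance(interval_length, int):
        sample_length = lambda: interval_length  # noqa: E731
    else:
        lo, hi = interval_length
        sample_length = lambda: int(rng.integers(lo, hi + 1))  # noqa: E731
    records = []
    for i in range(n_intervals):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = min(sample_length(), limits[chrom] - 1)
        start = int(rng.integers(0, limits[chrom] - length + 1))
        records.append(
            GenomicInterval(chrom=chrom, start=start, end=start + length,
                            name=f"iv{i}", source_line=1)
        )
    spec = FixtureSpec(build_id=builds[0].id, n_intervals=n_intervals, seed=seed)
    return _assemble(spec, "BED", records, n_bad=0, rng=rng)


_FORMAT_SUFFIX = {
    "BED": "bed", "GFF": "gff", "WIG": "wig",
    "narrowPeak": "narrowPeak", "broadPeak": "broadPeak",
}

#: columns 7+ per peak dialect (signalValue, pValue, qValue[, peak])
_PEAK_EXTRAS = {"narrowPeak": ("0", "-1", "-1", "-1"), "broadPeak": ("0", "-1", "-1")}


def _assemble(
    spec: FixtureSpec,
    format: str,
    records: list[GenomicInterval],
    n_bad: int,
    rng: np.random.Generator,
) -> TrackFile:
    """Assign source lines, format-specific fields and malformed lines."""
    if format not in _FORMAT_SUFFIX:
        raise TrackProvError(f"cannot generate format {format!r}")
    fixed: list[GenomicInterval] = []
    declarations: list[tuple[int, str]] = []
    line = 1
    for rec in records:
        extra = rec.extra
        score = rec.score
        strand = rec.strand
        if format in _PEAK_EXTRAS:
            extra = _PEAK_EXTRAS[format]
            score = score if score is not None else 0.0
            strand = strand if strand != "." else "."
        elif format == "WIG":
            # one variableStep declaration per record so lengths may vary
            declarations.append(
                (line, f"variableStep chrom={rec.chrom} span={rec.end - rec.start}")
            )
            line += 1
            score = score if score is not None else 1.0
        fixed.append(
            GenomicInterval(
                chrom=rec.chrom, start=rec.start, end=rec.end, strand=strand,
                score=score, name=rec.name, source_line=line, extra=extra,
            )
        )
        line += 1
    malformed = []
    for k in range(n_bad):
        # inverted coordinates: unambiguously broken in every format
        pos = int(rng.integers(1000, 100000))
        malformed.append(
            MalformedLine(line, f"chr1\t{pos}\t{pos - 500}\tbad{k}", "injected")
        )
        line += 1
    return TrackFile(
        path=f"synthetic_{spec.build_id}_seed{spec.seed}.{_FORMAT_SUFFIX[format]}",
        format=format,
        header_lines=[],
        records=fixed,
        malformed=malformed,
        wig_declarations=declarations,
    )


# ---------------------------------------------------------------------------
# chain generation

Edit = tuple[int, int, int]  # (target position, dt, dq)


def generate_chain(
    t_sizes: Mapping[str, int],
    q_sizes: Mapping[str, int] | None = None,
    edits: Mapping[str, Sequence[Edit]] | None = None,
    score: float = 1000.0,
    q_suffix: str = "",
) -> str:
    """Emit chain-file text equal to the identity map modified by indels.

    Parameters
    ----------
    t_sizes
        Target chromosome lengths; one chain is emitted per chromosome.
    q_sizes
        Query chromosome lengths; computed as target length - sum(dt) +
        sum(dq) when omitted.
    edits
        Per chromosome, ordered non-overlapping (position, dt, dq)
        triples: at *position* on the target, skip *dt* target bases
        (unmapped) and insert *dq* query bases (shifting everything
        downstream by dq - dt).
    q_suffix
        Appended to query sequence names (useful for cross-name tests).
    """
    edits = dict(edits or {})
    lines: list[str] = []
    chain_id = 1
    for chrom in t_sizes:
        t_size = t_sizes[chrom]
        chrom_edits = sorted(edits.get(chrom, ()))
        prev_end = None
        for pos, dt, dq in chrom_edits:
            if dt < 0 or dq < 0 or pos < 0 or pos + dt > t_size:
                raise TrackProvError(f"{chrom}: bad edit ({pos}, {dt}, {dq})")
            if prev_end is not None and pos < prev_end:
                raise TrackProvError(f"{chrom}: overlapping edits at {pos}")
            prev_end = pos + dt
        q_name = chrom + q_suffix
        net = sum(dq - dt for _, dt, dq in chrom_edits)
        q_size = q_sizes[q_name] if q_sizes is not None else t_size + net
        t_start, q_start = 0, 0
        # leading edit at position 0 folds into the header offsets
        if chrom_edits and chrom_edits[0][0] == 0:
            _, dt0, dq0 = chrom_edits[0]
            t_start, q_start = dt0, dq0
            chrom_edits = chrom_edits[1:]
        blocks: list[tuple[int, int, int]] = []
        t_cursor = t_start
        for pos, dt, dq in chrom_edits:
            size = pos - t_cursor
            if size <= 0:
                raise TrackProvError(f"{chrom}: edit at {pos} leaves an empty block")
            blocks.append((size, dt, dq))
            t_cursor = pos + dt
        final = t_size - t_cursor
        if final <= 0:
            raise TrackProvError(f"{chrom}: edits leave no terminal block")
        blocks.append((final, 0, 0))
        q_end = q_start + sum(size + dq for size, _, dq in blocks)
        lines.append(
            f"chain {score:g} {chrom} {t_size} + {t_start} {t_size} "
            f"{q_name} {q_size} + {q_start} {q_end} {chain_id}"
        )
        for size, dt, dq in blocks[:-1]:
            lines.append(f"{size} {dt} {dq}")
        lines.append(str(blocks[-1][0]))
        lines.append("")
        chain_id += 1
    return "\n".join(lines) + "\n"


def identity_chain(build: GenomeBuild, primary_only: bool = True) -> str:
    """An identity chain over a build's chromosomes (lift is a no-op)."""
    names = build.primary_set if primary_only else tuple(build.chrom_sizes)
    return generate_chain({c: build.chrom_sizes[c] for c in names})
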