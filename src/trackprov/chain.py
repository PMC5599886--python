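"""UCSC chain parsing and interval lift-over by block arithmetic.

A chain file describes a pairwise genome alignment as a list of chains.
Each chain header names a target and a query sequence with aligned spans::

    chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id

followed by alignment lines ``size dt dq`` — *size* aligned bases, then a
*dt*-base gap on the target and a *dq*-base gap on the query — with the
final line carrying only a size.  Block sums must reproduce the header
spans exactly; a chain violating that is rejected.

Lift-over maps an interval through the best-scoring chain overlapping it.
Bases falling in target gaps do not map; the *matched fraction* (mapped
bases / interval length) must reach a minimum-match threshold, defaulting
to 0.95 as in same-species liftOver practice, for the lift to count as
successful.  An interval whose mapped bases land on discontiguous query
runs is reported as ``split``; one overlapping no chain as ``unmapped``.
Negative-strand query coordinates are reflected so results are always
plus-strand intervals.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .errors import ChainIntegrityError, ChainParseError, ConfigurationError
from .tracks import GenomicInterval

__all__ = [
    "DEFAULT_MIN_MATCH",
    "ChainAlignment",
    "ChainIndex",
    "LiftResult",
    "read_chain",
    "lift_interval",
]

DEFAULT_MIN_MATCH = 0.95


@dataclass(frozen=True)
class ChainAlignment:
    """One chain: a piecewise map from target to query coordinates."""

    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    #: (size, dt, dq) per block; the final block has dt = dq = 0
    blocks: tuple[tuple[int, int, int], ...]

    def validate(self) -> None:
        t_span = sum(size + dt for size, dt, _ in self.blocks)
        q_span = sum(size + dq for size, _, dq in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ChainIntegrityError(
                self.chain_id,
                f"target block sum {t_span} != header span {self.t_end - self.t_start}",
            )
        if q_span != self.q_end - self.q_start:
            raise ChainIntegrityError(
                self.chain_id,
                f"query block sum {q_span} != header span {self.q_end - self.q_start}",
            )
        for size, dt, dq in self.blocks:
            if size <= 0 or dt < 0 or dq < 0:
                raise ChainIntegrityError(
                    self.chain_id, f"bad block (size={size}, dt={dt}, dq={dq})"
                )

    def block_starts(self) -> tuple[list[int], list[int], list[int]]:
        """Per-block (target start, query-strand-space start, size)."""
        t_starts: list[int] = []
        q_starts: list[int] = []
        sizes: list[int] = []
        t, q = self.t_start, self.q_start
        for size, dt, dq in self.blocks:
            t_starts.append(t)
            q_starts.append(q)
            sizes.append(size)
            t += size + dt
            q += size + dq
        return t_starts, q_starts, sizes

    def q_to_plus(self, start: int, end: int) -> tuple[int, int]:
        """Reflect a query-strand-space run onto the plus strand."""
        if self.q_strand == "-":
            return self.q_size - end, self.q_size - start
        return start, end


@dataclass(frozen=True)
class LiftResult:
    """Outcome of lifting one interval."""

    status: str  # mapped | unmapped | partial_below_threshold | split
    mapped_interval: GenomicInterval | None = None
    matched_fraction: float = 0.0
    chain_id: int | None = None

    @property
    def is_mapped(self) -> bool:
        return self.status == "mapped"


def read_chain(path: str | Path) -> list[ChainAlignment]:
    """Parse a UCSC chain file, verifying block sums against header spans."""
    path = Path(path)
    chains: list[ChainAlignment] = []
    header: list[str] | None = None
    header_line = 0
    blocks: list[tuple[int, int, int]] = []
    closed = True

    def finish(line_no: int) -> None:
        nonlocal header, blocks, closed
        if header is None:
            return
        if not closed:
            raise ChainParseError(
                str(path), line_no, "chain ended without a terminal size-only line"
            )
        try:
            chain = ChainAlignment(
                score=float(header[1]),
                t_name=header[2], t_size=int(header[3]), t_strand=header[4],
                t_start=int(header[5]), t_end=int(header[6]),
                q_name=header[7], q_size=int(header[8]), q_strand=header[9],
                q_start=int(header[10]), q_end=int(header[11]),
                chain_id=int(header[12]) if len(header) > 12 else len(chains) + 1,
                blocks=tuple(blocks),
            )
        except ValueError as exc:
            raise ChainParseError(str(path), header_line, f"bad chain header: {exc}") from None
        chain.validate()
        chains.append(chain)
        header, blocks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                finish(line_no)
                header = line.split()
                header_line = line_no
                if len(header) < 12:
                    raise ChainParseError(
                        str(path), line_no, f"chain header has {len(header)} fields, needs >= 12"
                    )
                closed = False
                continue
            if header is None:
                raise ChainParseError(str(path), line_no, "alignment line outside any chain")
            fields = line.split()
            try:
                if len(fields) == 3:
                    blocks.append((int(fields[0]), int(fields[1]), int(fields[2])))
                elif len(fields) == 1:
                    blocks.append((int(fields[0]), 0, 0))
                    closed = True
                else:
                    raise ValueError(f"{len(fields)} fields")
            except ValueError:
                raise ChainParseError(
                    str(path), line_no, f"bad alignment line {line!r}"
                ) from None
    finish(line_no=0)
    return chains


class ChainIndex:
    """Chains indexed by target sequence for overlap queries."""

    def __init__(self, chains: Iterable[ChainAlignment]) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self.chains = tuple(chains)
        for chain in self.chains:
            self._trees.setdefault(chain.t_name, IntervalTree()).addi(
                chain.t_start, chain.t_end, chain
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "ChainIndex":
        return cls(read_chain(path))

    def overlapping(self, chrom: str, start: int, end: int) -> list[ChainAlignment]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]

    def best_chain(self, chrom: str, start: int, end: int) -> ChainAlignment | None:
        """Best-scoring chain overlapping the span.

        Ties go to the longest target overlap, then the lowest chain id,
        so the choice is deterministic.
        """
        hits = self.overlapping(chrom, start, end)
        if not hits:
            return None
        def key(chain: ChainAlignment) -> tuple:
            overlap = min(end, chain.t_end) - max(start, chain.t_start)
            return (-chain.score, -overlap, chain.chain_id)
        return min(hits, key=key)


def _mapped_runs(
    chain: ChainAlignment, start: int, end: int
) -> list[tuple[int, int]]:
    """Plus-strand query runs the target span [start, end) maps onto.

    Runs contiguous in query space are merged even when a target gap
    separates the contributing blocks (the intervening target bases simply
    do not map).
    """
    t_starts, q_starts, sizes = chain.block_starts()
    runs: list[tuple[int, int]] = []
    # only blocks that can overlap [start, end)
    first = max(0, bisect_right(t_starts, start) - 1)
    for i in range(first, len(sizes)):
        bt, bq, size = t_starts[i], q_starts[i], sizes[i]
        if bt >= end:
            break
        lo = max(start, bt)
        hi = min(end, bt + size)
        if lo >= hi:
            continue
        q_lo = bq + (lo - bt)
        q_hi = bq + (hi - bt)
        if runs and runs[-1][1] == q_lo:
            runs[-1] = (runs[-1][0], q_hi)
        else:
            runs.append((q_lo, q_hi))
    return [chain.q_to_plus(a, b) for a, b in runs]


def lift_interval(
    iv: GenomicInterval,
    chains: ChainIndex,
    min_match: float = DEFAULT_MIN_MATCH,
) -> LiftResult:
    """Map one interval to the query build through its best chain.

    ``mapped`` requires all mapped bases to fall on one contiguous query
    run covering at least *min_match* of the interval; otherwise the result
    is ``split`` (discontiguous runs), ``partial_below_threshold`` (single
    run, too little of the interval aligned) or ``unmapped`` (no aligned
    base / no overlapping chain).
    """
    if not (0.0 < min_match <= 1.0):
        raise ConfigurationError(f"min_match {min_match} outside (0, 1]")
    chain = chains.best_chain(iv.chrom, iv.start, iv.end)
    if chain is None:
        return LiftResult(status="unmapped")
    runs = _mapped_runs(chain, iv.start, iv.end)
    if not runs:
        return LiftResult(status="unmapped", chain_id=chain.chain_id)
    mapped_bases = sum(b - a for a, b in runs)
    fraction = mapped_bases / iv.length
    if len(runs) > 1:
        return LiftResult(
            status="split", matched_fraction=fraction, chain_id=chain.chain_id
        )
    if fraction < min_match:
        return LiftResult(
            status="partial_below_threshold",
            matched_fraction=fraction,
            chain_id=chain.chain_id,
        )
    a, b = runs[0]
    mapped = GenomicInterval(
        chrom=chain.q_name, start=a, end=b, strand=iv.strand,
        score=iv.score, name=iv.name, source_line=iv.source_line,
    )
    return LiftResult(
        status="mapped",
        mapped_interval=mapped,
        matched_fraction=fraction,
        chain_id=chain.chain_id,
    )
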