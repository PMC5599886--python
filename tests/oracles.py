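"""Brute-force per-base lift-over oracle.

Independent of the block-arithmetic implementation: every target base of
every chain is enumerated into an explicit base -> base map, and interval
lifting is re-derived from that map by grouping consecutive query
positions.  Only feasible for toy-sized chains, which is the point.
"""

from __future__ import annotations

from trackprov.chain import ChainAlignment, DEFAULT_MIN_MATCH
from trackprov.tracks import GenomicInterval


def per_base_map(chain: ChainAlignment) -> dict[int, tuple[str, int]]:
    """target position -> (query name, plus-strand query position)."""
    mapping: dict[int, tuple[str, int]] = {}
    t, q = chain.t_start, chain.q_start
    for size, dt, dq in chain.blocks:
        for offset in range(size):
            q_pos = q + offset
            if chain.q_strand == "-":
                q_pos = chain.q_size - 1 - q_pos
            mapping[t + offset] = (chain.q_name, q_pos)
        t += size + dt
        q += size + dq
    return mapping


def brute_force_lift(
    iv: GenomicInterval,
    chains: list[ChainAlignment],
    min_match: float = DEFAULT_MIN_MATCH,
) -> tuple[str, tuple[str, int, int] | None, float]:
    """(status, mapped (chrom, start, end) or None, matched fraction)."""
    overlapping = [
        c for c in chains
        if c.t_name == iv.chrom and c.t_start < iv.end and c.t_end > iv.start
    ]
    if not overlapping:
        return "unmapped", None, 0.0
    best = min(
        overlapping,
        key=lambda c: (
            -c.score,
            -(min(iv.end, c.t_end) - max(iv.start, c.t_start)),
            c.chain_id,
        ),
    )
    mapping = per_base_map(best)
    images = sorted(
        mapping[pos][1] for pos in range(iv.start, iv.end) if pos in mapping
    )
    if not images:
        return "unmapped", None, 0.0
    runs = 1
    for a, b in zip(images, images[1:]):
        if b != a + 1:
            runs += 1
    fraction = len(images) / iv.length
    if runs > 1:
        return "split", None, fraction
    if fraction < min_match:
        return "partial_below_threshold", None, fraction
    q_name = mapping[next(p for p in range(iv.start, iv.end) if p in mapping)][0]
    return "mapped", (q_name, images[0], images[-1] + 1), fraction
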