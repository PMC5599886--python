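# Methods

This note documents the models, conventions and design choices behind
`trackprov`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under what assumptions, with which
defaults, and what the synthetic tests do and do not demonstrate.

## Coordinate conventions

All records are normalized to 0-based half-open intervals `[start, end)`.

* **BED / narrowPeak / broadPeak** are natively 0-based half-open and pass
  through unchanged. narrowPeak and broadPeak are treated as BED6+4 and
  BED6+3; the extra columns are preserved verbatim so round-trips are
  faithful, and lines with the wrong column count are malformed.
* **GFF/GTF** is 1-based inclusive; on read `start := start − 1`, on write
  the inverse. Both GFF3 and GTF attribute dialects are accepted because
  the attribute column is carried opaquely.
* **WIG** declaration `start` values are 1-based; each value covers
  `span` bases and `fixedStep` advances by `step`. So
  `fixedStep chrom=chr2 start=11 step=10 span=5` with two values yields
  `chr2:[10,15)` and `chr2:[20,25)`.

Records violating `0 ≤ start < end` (or the per-format field contract)
are never silently dropped: they are collected with their line numbers and
re-emitted on write. A file whose malformed fraction exceeds a strictness
threshold fails outright; the default threshold is 5% (`0.0` gives a
strict mode), making the common tool behaviour of refusing
non-spec-conforming files explicit and tunable.

## Chromosome-name normalization

Only three auditable rules: case-insensitive exact match, adding/stripping
the `chr` prefix, and the mitochondrial synonym `MT ↔ chrM`. Anything
else — scaffolds, alt/haplotype names, Ensembl-style contig accessions —
must match the registry table exactly or is *unknown* (a value, not an
error; unknown chromosomes simply do not count as compatible evidence).
More aggressive fuzzy matching was deliberately rejected: false merges of
sequence names are precisely the class of silent error the package exists
to surface.

## The build registry

Eight builds are bundled as frozen two-column `chrom.sizes` tables
(human hg18/hg19/hg38, mouse mm9/mm10, fruit fly dm3/dm6, and the toy pair
below), with aliases (`grch37 → hg19`, `grcm38 → mm10`, `bdgp5.25 → dm3`,
…) resolved case-insensitively. Each table carries the primary
chromosomes — autosomes plus sex chromosomes — and chrM; the primary set
defines the binning universe, while chrM stays available for compatibility
scoring. Unlocalized/alt/patch contigs are not bundled; users needing them
can extend the registry with their own tables (YAML config or ad-hoc
`extra_tables`), which is also the route for any additional species.
Duplicate ids/aliases across the registry are a hard error.

The toy pair exists for fast exact tests: `toyA` has chr1/chr2/chr3 of
10 kb/5 kb/2 kb; `toyB` is identical except chr1 = 9 kb. Because toyB's
extents are a strict subset of toyA's, toyB can never be uniquely
distinguished from toyA — the registry's built-in example of the
infeasibility condition.

## Build prediction

For build $B$, the compatibility score of a track is the fraction of its
records whose chromosome resolves in $B$ and whose end fits the
chromosome length. Records compatible with $B$ but incompatible with at
least one other candidate are counted as *discriminative*.

Decision rule: among candidates with score ≥ `min_score` (default 0.95),
the strictly highest score wins; exact score ties are broken only by a
strictly greater discriminative count; surviving ties are `ambiguous`;
an empty eligible set is `incompatible`. The result is invariant to
candidate order (reports are sorted by build id and ties are resolved by
tallies alone).

Notes and caveats:

* The score is a plain fraction, not a likelihood. This keeps the
  malformed/truncated-file failure mode visible in the report and makes
  the threshold interpretable: `min_score = 0.95` tolerates the same ~5%
  slack as the reader's strictness default, while a wrong-species file or
  a file from a very different assembly falls far below it.
* A useful identity: at an exact score tie the discriminative tie-break is
  provably inert. If builds $A$ and $B$ tie, their within-bounds record
  counts are equal, and each build's discriminative count equals that
  count minus the number of records valid in *every* candidate — the same
  quantity for both. The tie-break is retained as documented behaviour
  (it is cheap and makes the contract explicit), but score ties always
  surface as genuine ambiguity, which is the scientifically honest
  outcome: builds with identical chromosome-length vectors over the
  observed chromosomes are indistinguishable from coordinates alone.
* `min_score` outside degenerate cases should stay above 0.5; the default
  0.95 was chosen with the strictness default, before any benchmark runs,
  and is configurable per call.
* Species is not pre-filtered: all registry builds compete unless a
  candidate list is given. Chromosome-name evidence (a name present in
  only one candidate's table) is discriminative by the same rule as
  out-of-bounds evidence.
* WIG values are ignored for prediction; only coordinates matter.

## Chain lift-over

Chain files are parsed with full validation: per chain,
$\sum (\text{size} + dt) = t_\text{end} - t_\text{start}$ and
$\sum (\text{size} + dq) = q_\text{end} - q_\text{start}$ must hold
exactly, block sizes must be positive and gaps non-negative; violations
are integrity errors naming the chain id.

An interval is lifted through the *best* overlapping chain — highest
score, ties by longest target overlap, then lowest chain id, so the
choice is deterministic. Within that chain the interval's bases map
block-by-block; query runs that abut (a target gap with `dq = 0`) are
merged. Outcomes:

* `mapped` — one contiguous query run covering ≥ `min_match` of the
  interval (default 0.95, the conventional same-species lift-over
  minimum); coordinates are reflected to the plus strand for
  negative-strand chains.
* `partial_below_threshold` — one run, but too little of the interval
  aligned.
* `split` — mapped bases land on discontiguous query runs.
* `unmapped` — no overlapping chain, or the interval lies wholly in a
  target gap.

Spanning multiple chains is not attempted (no multi-hop lift either);
cross-chromosome images are legal `mapped` results and classified
downstream. The block arithmetic is verified in the tests against an
independent brute-force oracle that enumerates every target base's image.

## Binned incompatibility analysis

`make_bins` tiles each primary chromosome with consecutive bins of
`bin_size` (default 1,000 bp; the final bin may be short — hg19 yields
exactly 3,095,689 bins). Each bin is lifted and classified:

* **failed** — any non-`mapped` outcome (split and below-threshold
  mappings are conservatively counted as failures);
* **cross-chromosome** — mapped onto a different chromosome name;
* **identical** — same chromosome, same start, same end;
* **beyond threshold** — same-chromosome midpoint displacement
  > 30,000 bp (midpoint = floor of the coordinate mean).

Because "share of bins moved beyond 30 kb" admits two denominators, the
report carries both `pct_beyond_threshold` (over all bins) and
`pct_beyond_threshold_of_mapped`. The headline `pct_erroneous` is
$100 (n_\text{total} - n_\text{identical}) / n_\text{total}$.
Percentages are reported to one decimal. Final short bins use their true
length as the matched-fraction denominator.

Running the full hg19→hg38 analysis requires the public UCSC chain file
(~1 MB download, not bundled); all shipped tests instead exercise the
identical pipeline on synthetic chains where every expected number is
exact by construction.

## Synthetic fixtures

The generators are deterministic: one seeded NumPy generator per spec,
identical specs give byte-identical files.

* **Tracks** draw intervals uniformly over the build's primary
  chromosomes, weighted by length, with lengths uniform in 100–1,000 bp
  by default — small intervals at genome-scale positions, the regime
  where build prediction is actually hard because most records fit every
  related build.
* **Discriminative placement** guarantees that each non-target candidate
  is ruled out by at least one record. Where one chromosome exists on
  which the target strictly exceeds every candidate sharing the name
  (hg19 chr1 against hg38, mouse chrX for mm10), a single record with its
  end in the unique window suffices; otherwise a greedy cover places one
  record per remaining candidate (dm3 needs two: any chr2L record rules
  out human and mouse, and a chr4 record beyond dm6's shorter chr4 rules
  out dm6). If some candidate cannot be ruled out at all the fixture is
  infeasible and says so (toyB vs toyA).
* **Ambiguous tracks** are confined to chromosomes present in every
  candidate, within the minimum length — the constructive form of the
  infeasibility condition.
* **Malformed lines** are injected as inverted-coordinate records,
  exactly `round(fraction × n)` of them.
* **Chains** are identity maps modified by ordered, non-overlapping
  `(position, dt, dq)` indel edits, with an edit at position 0 folded
  into the header offsets; every emitted chain passes the parser's
  integrity checks, and its per-base semantics are what the brute-force
  oracle enumerates.

What passing these tests shows — and does not. The synthetic tracks have
uniform positions and no biological structure (no peak shapes, clustering
or chromatin bias); perfect recovery on them demonstrates the correctness
of the scoring/decision machinery and the fixtures' guarantees, not an
accuracy figure for real repository files, whose discriminative content
varies and whose format violations are more creative. The audit
percentages likewise depend entirely on the file population scanned;
the package reports them, it does not predict them.

## Token scanning

The vocabulary is a fixed alternation of human/mouse/fly build names.
Matching is case-insensitive, longest-token-first at each position
(`bdgp5.25` beats `bdgp5`, `build5.41` beats `build5`), with literal
dots and deliberately *no* word boundaries — the cost is that the bare
`ncbi` token can match inside unrelated words, so it is retained but
flagged low-specificity in reports. Filename scanning uses the basename
only: directory components do not survive transfers. Header scanning
covers the first 50 lines of the file, of any kind, since build mentions
occur on track lines and even data lines, not only comments.

## CLI contract

Exit codes: 0 success/unique, 2 usage, 3 ambiguous, 4 incompatible,
5 I/O or parse failure — so pipelines can branch on the
prediction-infeasible case without parsing text. Machine output (`--json`)
is stable and deterministic for a given input and seed.

## Problem sizes used in the shipped checks

The acceptance script and test-suite run everything at the sizes stated
in their docstrings: 100 tracks × 200 records per build for recovery,
100 shared-coordinate tracks for ambiguity, 1,000 random intervals over
20+ seeded chains (plus hand-written negative-strand chains) for oracle
agreement, all 5 formats × 7 builds × 3 mechanisms for annotation
closure, and the 17-bin toy genome for the exact degenerate liftchecks.
The only full-genome computation is hg19 binning, which is exact and runs
in about a second.
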