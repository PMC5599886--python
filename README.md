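# trackprov

Genome-build provenance for genomic track files.

Interval-based track formats — BED, GFF/GTF, WIG, narrowPeak, broadPeak —
record coordinates on a reference genome but, in most real files, not
*which* reference. A BED interval `chr1 248960000 249000000` is a valid
location on hg19 (GRCh37) and nonsense on hg38 (GRCh38), whose chr1 is
294 kb shorter; integrating files from mismatched builds silently produces
wrong intersections, wrong distances, wrong everything. `trackprov` is for
anyone who curates, audits or reuses such files:

* **audit** — scan filenames and the first 50 lines of each file for a
  fixed vocabulary of build names (`hg19`, `grch38`, `mm10`, `bdgp5.25`, …)
  and tabulate, per format, how many files carry the build only in the
  filename, only in the file, in both, or nowhere;
* **annotate** — attach the build the recommended ways: a leading
  `# genome=<id>` comment, a `genome=<id>` attribute on a browser `track`
  line, or a `.<id>` tag in the filename (idempotent, and refusing to
  overwrite a conflicting annotation);
* **predict** — infer the build of an *orphan* file from coordinate
  compatibility against a registry of chromosome-size tables;
* **liftcheck** — quantify how incompatible two builds are by cutting one
  into fixed-size bins, lifting every bin through a UCSC chain file, and
  measuring how far each bin moved;
* **simulate** — deterministic synthetic tracks and chain files, so all of
  the above is testable offline.

## The method

**Prediction.** For a candidate build $B$ with chromosome lengths
$L_B(c)$, each record $(c, s, e)$ is *compatible* when its (normalized)
chromosome resolves in $B$ and $e \le L_B(c)$. The score of $B$ is the
compatible fraction of records; a build is called **unique** when it
attains the strictly highest score at or above a threshold (default 0.95).
Records compatible with $B$ but not with some other candidate are
*discriminative* evidence; exact score ties fall back to discriminative
counts and, if still tied, the call is **ambiguous** — a file whose
coordinates fit several builds equally cannot be assigned one from
coordinates alone. If no candidate reaches the threshold the file is
**incompatible**. The bundled registry covers hg18/hg19/hg38, mm9/mm10 and
dm3/dm6 (plus aliases such as GRCh37 and BDGP6) and is user-extensible
from two-column `chrom.sizes` tables.

**Incompatibility measurement.** Chromosomes of the source build are
segmented into consecutive bins $[k s, \min((k{+}1)s, L))$ with $s = 1000$
bp by default — for hg19's autosomes and sex chromosomes exactly
3,095,689 bins. Each bin is lifted through the best-scoring overlapping
chain, requiring a minimum matched fraction (default 0.95). For a mapped
bin the displacement is $|m(\text{src}) - m(\text{image})|$ with
$m = \lfloor (s{+}e)/2 \rfloor$ the midpoint; the report tallies failed,
cross-chromosome, identical, and beyond-threshold (30 kb) bins, and the
**erroneous fraction** $(n_\text{total} - n_\text{identical}) /
n_\text{total}$ — the share of bins naive cross-build integration would
get wrong.

## Worked example

Generate a synthetic orphan file drawn from hg19 and predict its build:

```
$ trackprov simulate track --build hg19 --n 200 --seed 42 --out orphan.bed
$ trackprov predict orphan.bed
orphan.bed: unique
best: hg19
  dm3        score=0.0150 within=3/200 discriminative=3
  dm6        score=0.0150 within=3/200 discriminative=3
  hg18       score=0.9850 within=197/200 discriminative=197
  hg19       score=1.0000 within=200/200 discriminative=200
  hg38       score=0.9900 within=198/200 discriminative=198
  mm10       score=0.8500 within=170/200 discriminative=170
  mm9        score=0.8450 within=169/200 discriminative=169
  toyA       score=0.0000 within=0/200 discriminative=0
  toyB       score=0.0000 within=0/200 discriminative=0
```

Every record fits hg19 (score 1.0000); three records exceed hg18/hg38
chromosome ends (scores 0.9850/0.9900), so hg19 wins uniquely and the
process exits 0 (3 = ambiguous, 4 = incompatible, for shell pipelines).
The fly builds share almost no chromosome names with human files, hence
scores near zero. Attach the call to the file and verify it now audits as
carrying its build:

```
$ trackprov annotate orphan.bed hg19 --out annotated.bed
$ head -1 annotated.bed
# genome=hg19
```

Measure what a systematic 40-kb coordinate shift between two builds does
to 1-kb bins (on the bundled 17-kb toy genome):

```
$ trackprov simulate chain --build toyA --edit chr1:0:0:40000 \
      --edit chr2:0:0:40000 --edit chr3:0:0:40000 --out shift.chain
$ trackprov liftcheck --from-build toyA --chain shift.chain --json
{
  "n_total": 17,
  "n_identical": 0,
  "n_beyond_threshold": 17,
  "pct_beyond_threshold": 100.0,
  "pct_erroneous": 100.0,
  ...
}
```

All 17 bins lift, none keeps its coordinates, and all land beyond the
30-kb threshold: any genome arithmetic mixing the two coordinate systems
would be 100% wrong. The same pipeline pointed at the public hg19→hg38
UCSC chain file (`liftcheck --from-build hg19 --chain
hg19ToHg38.over.chain`) measures the real extent of incompatibility
between the two human builds.

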