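# Methods

This note records the procedures `ampliprep` implements, the defaults it
ships, and the design choices made where more than one reasonable convention
exists. Nothing here claims an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Barcode-orientation detection

Reads are compared against the metadata barcode set in both orientations by
exact, 5′-anchored prefix match: a read with first *L* bases equal to a
barcode counts toward `n_same`, equal to a reverse-complemented barcode
toward `n_revcomp`. Both counts are taken over the same read set. Matching
is deliberately exact — no mismatch tolerance, no 5′ insertion scan — so a
sequencing error in the barcode simply makes that read non-informative
rather than mis-informative. Reads shorter than the barcode count as
non-matching.

The decision rule is a strict dominance test with ratio 10: the orientation
is `same` iff `n_same > 10 · n_revcomp`, `reverse_complement` iff
`n_revcomp > 10 · n_same`, and otherwise `ambiguous`. Ambiguity is a
first-class outcome: downstream stages refuse to run on it and the CLI
exits non-zero naming the stage, because silently guessing an orientation
corrupts every later count. The ratio and the number of inspected reads
(default: all) are configurable; capping inspection takes the *first* N
records so the subsample is deterministic.

Two exact symmetries are tested: replacing every metadata barcode by its
reverse complement swaps the two counts (and hence flips any non-ambiguous
decision) for arbitrary reads; reverse-complementing every *read* does the
same when reads are exactly barcode-length. For longer reads the read-level
flip moves the barcode to the 3′ end, out of reach of prefix matching, so
the metadata-level formulation is the one that generalizes.

## Demultiplexing

A read is assigned to the unique sample whose oriented barcode equals its
5′ prefix; the prefix and its quality values are removed from the assigned
record. Unassigned reads are kept verbatim (written to `unassigned.fastq`
by the CLI) and counted; assigned + unassigned always equals the input
count, and the `auto` report records this conservation check per run. For
the barcode-outside layout, the barcode-read file is matched against the
metadata and the biological reads are split by the per-record assignment,
pairing the two files by record order (the common convention for
index-read FASTQs; id-based pairing is not attempted). Biological reads are
not trimmed in that layout.

## High-quality-region selection

The per-position profile is the *median* Phred score at each position,
computed over every read long enough to cover that position; the median of
an even-sized set is the mean of the two central values. Internally the
profile is accumulated as one histogram per position over the 0–93 Phred
range, so memory is independent of read count. By default all reads
contribute; `--sample-n` restricts to the first N for very deep runs.

The medians are smoothed with a moving average of window 5. The window is
*centered* with edge truncation: position *p* averages the positions within
radius 2 that exist, so the ends use windows of 3 and 4 and the output has
the input's length. Centering treats both read ends symmetrically and is
standard signal-processing practice; it is a documented, configurable choice
(`--window`, odd values only) rather than a claim about any particular
upstream tool's convention.

Selection scans the smoothed profile for maximal runs of positions strictly
above the cutoff (default Q30), returns the longest run as 1-based inclusive
coordinates, breaks length ties toward the earliest start, and requires the
winner to span strictly more than `min_span_frac` (default 0.5) of the
profile length. Both inequalities are strict. When nothing qualifies the
error names the best run found, which is usually enough to diagnose a
failed run or a too-aggressive cutoff. Correctness of the run scan is
checked against an exhaustive O(L²) interval oracle on random profiles.

## Rarefaction-depth optimization

Given per-sample totals, the candidate depths are the distinct positive
totals at or below the median total (even-sized median = mean of the two
central values). Including a sample sitting exactly at the median matters
only for odd sample counts and guarantees the "at least half the samples
retained" property either way. For each candidate *d* the objective is
*d · N(d)* with *N(d)* the number of samples with total ≥ *d*; the maximizer
wins, ties broken toward the larger depth (equal total retained reads, but
more reads per retained sample). One degenerate case falls outside the rule:
if every positive total lies above the median (possible only when most
samples are empty), the candidate set as defined is empty and the smallest
positive total is used. The optimizer is validated against a brute-force
scan of the full candidate set on random count vectors.

## Rarefaction

Samples below the depth are dropped; each remaining sample's column is
replaced by a uniform subsample without replacement of exactly `depth`
reads, drawn as a multivariate hypergeometric variate over its feature
counts (numpy's generator). Column sums therefore equal the depth exactly,
a sample whose total equals the depth is returned unchanged, and a fixed
seed reproduces the table bit for bit. The mean rarefied count of a feature
is `depth · count / total` (the hypergeometric mean), which the suite
checks by Monte-Carlo over seeds.

## Merging runs

ASVs are exact sequences, so feature identity across runs is exact
(case-insensitive) sequence equality; matching features' counts are summed
per sample and the merged feature keeps the lexicographically first
contributing id. When any input table lacks representative sequences, all
tables are merged by feature id instead. The same sample id in two tables
is an error (it almost always indicates a metadata mistake), as is one
feature id bound to two different sequences. Output rows are ordered by
descending total then id, columns by sample id, making output files
deterministic; total counts are conserved exactly, and merging is
commutative and associative up to that ordering.

## Synthetic data generator

`simulate_run` emulates the structure the detectors assume: unique
equal-length 5′ barcodes (as written or reverse-complemented), uniform
random template bases, and per-base qualities drawn from a Gaussian around
a deterministic mean curve — a plateau, an optional linear 3′ decay, and
optional isolated one-position dips — clamped to [2, 41] and rounded,
mimicking binned Illumina scores. Defaults describe a small modern 16S run:
40 samples, 12-nt barcodes, 150-bp reads, per-sample totals log-uniform in
[200, 1000] (a right-skewed spread whose shallow half exercises the depth
optimizer), 98% intact barcodes, plateau Q38 with noise sd 2 and a decay of
0.4 Phred/position from position 110 (crossing Q30 near position 129).

Barcodes are drawn so that no barcode is its own reverse complement and no
two are mutual reverse complements. Real barcode sets are designed this
way; without the constraint a palindromic barcode makes its sample's reads
count in both orientations and the dominance test correctly reports
ambiguity — a property of bad barcode design, not of the detector.

With probability `1 − barcode_intact_frac` a read's barcode is corrupted by
a point substitution re-drawn until the prefix matches no barcode in either
orientation, so ground-truth labels are unambiguous: corrupted reads must
end up unassigned. The generator does not emulate primers, chimeras, PhiX,
instrument-specific error profiles, or quality/base correlation; passing
tests therefore demonstrate the detectors' correctness on the structural
features they read (prefixes, quality profiles, count totals), not
robustness to every artefact of real sequencing.

`simulate_feature_table` draws heavy-tailed feature weights (log-normal,
shape 2) and per-sample multinomial counts at totals from the same
log-uniform rule, which yields realistic many-rare/few-dominant ASV tables.

## Numerical and interface choices

- FASTQ is Phred+33 only; a request for Phred+64 is refused explicitly.
  Gzip is detected from magic bytes, not the filename.
- Quality profiles are exact medians (histogram-based), not subsampled
  estimates, unless `--sample-n` is given.
- All randomness (rarefaction, simulation) flows through a single integer
  seed; the CLI exposes it globally and logs it, and `auto` reports are
  timestamp-free so reruns are byte-identical.
- Problem sizes in the test suite and acceptance script (hundreds of reads
  per simulated run, 40-sample tables, 100–1000 replicate draws) were chosen
  as the smallest sizes at which the checked properties are
  non-trivial — exact conservation laws hold at any size, and the
  stochastic checks (orientation recovery, hypergeometric means) are
  already far from their error floors at these sizes.

## Known limitations

- No error-tolerant barcode matching (by design: exactness is what makes
  the orientation counts trustworthy), so heavily degraded barcode regions
  reduce assignment rates rather than being rescued.
- Mixed-orientation libraries (both orientations truly present) are
  reported ambiguous rather than split.
- Paired-end mates are treated as independent files; there is no mate
  synchronization beyond equal record counts in the barcode-outside layout.
- Rarefaction discards data by construction; variance-stabilizing
  alternatives are out of scope.
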