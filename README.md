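# ampliprep

Automatic parameter detection for 16S/amplicon sequencing preprocessing.

Three decisions in a standard amplicon workflow are usually made by a human
staring at files and charts: whether the metadata barcodes appear in the
reads as written or reverse-complemented, where to trim reads before
denoising, and what depth to rarefy the feature table to. Those manual
choices are slow and, worse, inconsistent between analysts. `ampliprep`
makes all three automatically and reproducibly, and provides the
demultiplexing, rarefaction and multi-run feature-table merging stages the
detected parameters feed. Its intended users are microbiome bioinformaticians
who want deterministic, auditable preprocessing in front of a denoiser such
as DADA2.

## The three detectors

**Barcode orientation.** For barcode set *B* and barcode length *L*, count
reads whose first *L* bases exactly equal some *b ∈ B* (`n_same`) or some
reverse complement *rc(b)* (`n_revcomp`) — no mismatches, no 5′ offset.
Declare an orientation only when one count strictly exceeds 10× the other;
otherwise the result is *ambiguous* and the pipeline stops with a diagnostic
instead of guessing.

**High-quality region.** Build the per-position median Phred profile
*m₁ … m_L* over all reads, smooth it with a centered 5-position moving
average (edge-truncated), and take the longest run of consecutive positions
with smoothed quality strictly above the cutoff (default Q30). The run must
span strictly more than half the profile; the result is a pair of 1-based
inclusive trim coordinates. Smoothing is the point: a single aberrant
position (median 27, say) inside a clean Q38 stretch has a window mean well
above 30 and no longer truncates the region prematurely.

**Rarefaction depth.** Let *Rᵢ* be per-sample read totals. Candidate depths
are the distinct totals at or below the median (so at least half the samples
survive); for each candidate *d*, *N(d)* is the number of samples with at
least *d* reads. The chosen depth maximizes the total retained reads
*d · N(d)*, ties going to the larger depth, and the full candidate trace is
reported so the choice can be audited.

Rarefaction itself is uniform subsampling without replacement (a
multivariate hypergeometric draw per sample), and merging collapses features
with identical representative sequences across runs, summing counts.

## Worked example

Simulate a multiplexed run whose barcodes are reverse-complemented in the
reads, plus a 40-sample feature table, then run the full auto-detect
workflow:

```
$ ampliprep --seed 11 simulate run --samples 6 --reads 200,600 \
      --read-length 150 --barcode-length 12 --orientation revcomp --outdir sim
reads	1917
orientation	reverse_complement
true_hq_end	129

$ ampliprep --seed 11 simulate table --features 200 --samples 40 \
      --depths 200,1000 --out table.tsv
...
$ ampliprep --seed 11 auto --reads sim/reads.fastq \
      --metadata sim/metadata.tsv --table table.tsv --outdir out
orientation	reverse_complement
hq_region	1 117
depth	358
report	out/report.json
```

The detector recovered the reverse-complement orientation from the read
prefixes alone. The high-quality region (1, 117) is reported in
barcode-trimmed coordinates: the simulated quality plateau (Q38) decays from
position 110 of the raw read and crosses Q30 at position 129, i.e. position
117 after the 12-base barcode is cut — the detector recovered the true
boundary exactly. The depth subcommand shows the candidate trace behind the
chosen depth:

```
$ ampliprep depth --table table.tsv
depth	358
retained_samples	25
total_retained	8950
candidate_depth	n_samples	total
392	21	8232
389	22	8558
384	23	8832
372	24	8928
...
```

Rarefying at 358 keeps 25 of 40 samples and 8950 reads in total — more than
any other candidate depth. `out/report.json` records every detected
parameter, the per-stage read conservation and the candidate trace; rerunning
with the same inputs and seed reproduces it byte for byte.

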