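# Methods

## Problem and model

Replicative DNA polymerases mis-insert ribonucleoside monophosphates
(rNMPs) into genomic DNA at appreciable rates, and several sequencing
chemistries exist to capture those embedded ribonucleotides: ribose-seq
(tRNA-ligase capture after alkaline cleavage 3′ of the rNMP), HydEn-seq and
Pu-seq (alkaline hydrolysis 3′ of the rNMP) and emRiboSeq (RNase H2
incision 5′ of the rNMP). All four share one structural property: the
embedded ribonucleotide sits at a fixed offset and strand relative to the
5′-most base of sequencing read 1 (the *tagged nucleotide*). Mapping rNMPs
to single-nucleotide resolution is therefore pure interval arithmetic on
aligned read-1 coordinates — no base-calling or sequence correction is
involved.

All genomic intervals in this package are zero-based half-open (BED
convention). SAM's 1-based inclusive positions are converted exactly once,
at ingestion. Writing `start`/`end` for a read's interval, the site of the
rNMP implied by one aligned read is:

| technique          | `+` read → site            | `-` read → site           |
|--------------------|----------------------------|---------------------------|
| ribose-seq         | `[start, start+1)` on `-`  | `[end-1, end)` on `+`     |
| HydEn-seq / Pu-seq | `[start-1, start)` on `+`  | `[end, end+1)` on `-`     |
| emRiboSeq          | `[start-1, start)` on `-`  | `[end, end+1)` on `+`     |

HydEn-seq and Pu-seq share one code path; their chemistries are
positionally identical.

### Biological-relevance screen

For the three techniques that place the rNMP *outside* the read's
footprint, a read aligned at a chromosome's 5′-most end implies a
coordinate off the chromosome (start −1, or end one past the chromosome
length). Such coordinates are biologically meaningless and would break any
per-position downstream analysis, so every computed site is screened
(`0 ≤ start` and `end ≤ chromosome length`) before export. Rejected sites
are written to an audit log with their originating read names, never
silently dropped. A consequence worth noting: ribose-seq sites lie inside
the read footprint, so an in-range alignment can never produce a rejected
site; only HydEn-seq/Pu-seq/emRiboSeq can.

### De-duplication

Libraries built with PCR are de-duplicated before counting. The group key
is `(chromosome, strand, 5′ position, UMI)` — the 5′ position, not the
full interval, because reads of different lengths from the same molecule
share their tagged base. UMI matching is exact string equality; directional
or edit-distance UMI clustering is deliberately out of scope, since the
validation surface uses error-free reads where exact matching is both
correct and deterministic. The retained representative per group is the
lexicographically smallest read name, a deterministic tie-break. With
empty UMIs grouping degrades to positional-only and a warning is emitted,
because distinct molecules at one position would then be wrongly merged.
Barcode matching likewise allows zero mismatches, keeping read retention
auditable. Read-1-only, MAPQ-thresholded, primary-alignment filtering is
applied at SAM ingestion.

## Synthetic data generator

The simulator exists so that every stage is testable with no external
data. It inverts the table above: for each planted site it places the one
read-1 alignment whose arithmetic maps back to that site, making
coordinate recovery an identity round trip by construction. What it
emulates:

* i.i.d. random genomes with controllable per-chromosome GC content and an
  organelle label per chromosome;
* planted sites sampled without replacement over (chromosome, position,
  strand), optionally rejection-filtered to a requested rNMP identity bias;
* the 5′ `UMI + barcode + insert` read structure, Phred+33 FASTQ with
  constant quality `I`;
* PCR duplication as verbatim re-emission of a record with probability
  `duplication_rate` (a copy keeps its UMI and position — exactly the
  signal de-duplication keys on).

What it does **not** emulate, and what passing tests therefore do not
show: sequencing errors, adapter contamination, paired-end reads, genome
repeats at realistic scale (random sequence has essentially no repeat
structure), chromatin- or replication-coupled site clustering, and the
behaviour of a real aligner (multi-mapping, clipping). Tests that
"preprocess and map" simulated FASTQ resolve read placements through a
perfect-placement lookup of the simulator's own records; alignment
software is out of scope throughout.

Sites whose technique-specific read would overhang a chromosome end are
skipped and removed from the truth set (and logged): they cannot be
simulated at that read length. End-aligned reads — the pathological case
the screen exists for — are constructed separately by
`end_aligned_alignments()`, since no valid planted site corresponds to
them.

## Sequence-context profiles

Windows around each screened site are read 5′→3′ on the rNMP-bearing
strand (reverse-complemented for `-` sites), so relative position 0 is the
ribonucleotide and negative positions are upstream on its own strand. Two
default half-widths are produced, 100 nt (broad context) and 15 nt
(zoomed), both configurable.

Per-position base frequencies are normalized by the background
mononucleotide composition of the *matching organelle compartment*, pooled
over both strands (so background is complement-symmetric by construction;
`N` bases are excluded from numerator and denominator). Organelle-specific
background is a design choice — nuclear and mitochondrial composition can
differ by tens of percentage points, and a whole-genome background would
leak that difference into every mitochondrial profile. The thymine column
is reported as `T/U`: at position 0 it is rUMP, elsewhere flanking DNA
thymine.

Sites are weighted by their raw count by default (each count is one
observed incorporation event); `unique_site_weighting` switches to
one-vote-per-site. Per-position denominators count only sites whose window
covers that position — a window truncated at a chromosome end contributes
*absent*, not zero, which keeps edge positions unbiased. Per-rNMP-type
profiles (rA/rC/rG/rU) partition the sites, so their count-weighted tallies
sum exactly to the unfiltered tally; profiles over uniformly sampled sites
are flat at 1.0 up to sampling noise. Sites whose position-0 base is `N`
match no type filter; on real genomes with `N` runs the per-type matrices
then recombine to the unfiltered matrix minus those sites.

## Coverage tracks

Per-nucleotide coverage is the summed raw count at each position under a
strand scope (`+`, `-`, or pooled). Normalized coverage is *reads per
hundred*: value / whole-library total × 100, chosen so that tracks from
libraries of different depth are directly comparable and the global sum is
exactly 100. Per-chromosome normalization is available behind a flag and
labelled `perchrom` in filenames, because it destroys cross-library
comparability. Tracks are sparse (zero runs omitted) with adjacent
equal-valued runs merged — standard BedGraph conventions, directly
loadable in a genome browser. Plots pool strands by default; stranded
tracks are always exported alongside.

## Numerical and formatting choices

* Counts are exact integers; normalized quantities are IEEE doubles, with
  invariant checks at 1e-6 (sums of percentages) and 1e-9 (frequency
  sums).
* BedGraph values print with at most 6 decimals, trailing zeros trimmed.
* Empty inputs are valid everywhere downstream of screening: an empty site
  list yields an empty table, empty tracks, and an all-absent profile (a
  warning-level situation, not an error).
* Determinism: every random draw flows from an explicit integer seed
  through `numpy.random.default_rng`; reruns with one config and seed are
  byte-identical across BED/TSV/FASTQ outputs.

## Validation problem sizes

The test and validation suites run at desk scale, chosen to keep the
binomial/sampling noise of each check far below its tolerance: ~100 kb
genomes with 1,000–2,000 planted sites for round-trip and normalization
checks (these are exact identities, so size only affects coverage of edge
cases), and ≥10,000 uniformly sampled sites for the sequence-context null,
where the ±0.1 band sits >5 standard errors from the mean at that n.

## Known limitations

* Alignment itself is delegated: the package consumes SAM/BAM/BED and
  never calls an aligner.
* Exact-match UMI grouping over-splits real data with UMI sequencing
  errors; on error-free validation data it is exact.
* The simulator's uniform genomes cannot probe mappability artifacts.
* Windowed (per-bin) site counting and hotspot statistics are out of
  scope; coverage is strictly per-nucleotide.
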