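# rnmpmap

Map ribonucleoside monophosphates (rNMPs) embedded in genomic DNA to
single-nucleotide resolution, from reads produced by any of the four rNMP
sequencing techniques — **ribose-seq**, **HydEn-seq**, **Pu-seq** and
**emRiboSeq** — and characterize the sequence context and genome-wide
distribution of the mapped sites. It is aimed at researchers studying
ribonucleotide incorporation, RNase H2 biology and genome instability who
need a technique-agnostic path from aligned reads to site tables, context
profiles and browser-ready coverage tracks.

## The method

Each technique tags the embedded rNMP at a fixed offset and strand
relative to the 5′ base of read 1, so mapping is strand-aware interval
arithmetic on zero-based half-open (BED) coordinates. For an aligned
read-1 interval `[start, end)`:

| technique          | `+` strand read → rNMP site | `-` strand read → rNMP site |
|--------------------|-----------------------------|-----------------------------|
| ribose-seq         | `[start, start+1)` on `-`   | `[end-1, end)` on `+`       |
| HydEn-seq / Pu-seq | `[start-1, start)` on `+`   | `[end, end+1)` on `-`       |
| emRiboSeq          | `[start-1, start)` on `-`   | `[end, end+1)` on `+`       |

Because three of the four rules step outside the read, a read aligned to a
chromosome's 5′-most end implies a coordinate off the chromosome (e.g.
start −1); every computed site is therefore screened for biological
relevance (`0 ≤ start`, `end ≤ chromosome length`) before export, with
rejects logged for audit. Upstream, reads are demultiplexed on an exact 5′
molecular barcode, UMIs are moved into read names, and aligned reads are
de-duplicated on `(chromosome, strand, 5′ position, UMI)`. Downstream,
per-site counts are normalized to reads per hundred; nucleotide
frequencies around sites are normalized to the organelle-matched genome
background.

A built-in simulator inverts the arithmetic above — it plants rNMPs and
places the exact read each technique would produce, including barcode/UMI
structure and PCR duplicates — so the whole pipeline is testable with no
external data, and recovery of planted sites is exact by construction.

## Worked example

One YAML config drives all stages. Save as `config.yaml`:

```yaml
technique: emriboseq
sample: demo
output_dir: out
barcode: TCA
umi_length: 6
windows: [15]
seed: 7
organelles:
  chrN: nuclear
  chrM: mitochondrial
simulate:
  chromosomes:
    - {name: chrN, length: 100000, organelle: nuclear, gc: 0.40}
    - {name: chrM, length: 10000, organelle: mitochondrial, gc: 0.20}
  n_sites: 2000
  read_length: 50
  duplication_rate: 0.3
```

then run the stages (each is independently invocable; `alignment` is an
accepted alias for `preprocess`):

```sh
rnmpmap simulate config.yaml
rnmpmap preprocess config.yaml
rnmpmap coordinate config.yaml
rnmpmap sequence config.yaml
rnmpmap distribution config.yaml
```

The log lines tell the story of the run:

```
stage simulate complete: {'sites_planted': 2000, 'sites_kept': 1998,
  'sites_skipped_at_ends': 2, 'alignments_written': 2599, 'fastq_records': 3411}
stage preprocess complete: {'fastq': {'retained': 3411, 'discarded': 0, ...},
  'dedup': {'reads_in': 2599, 'reads_out': 1998, 'groups': 1998, 'umi_missing': 0}}
stage coordinate complete: {'alignments_in': 1998, 'sites_accepted': 1998,
  'sites_rejected': 0, 'unique_sites': 1998, ...}
```

2,000 planted sites lose 2 whose reads would overhang a chromosome end;
PCR duplication inflates 2,599 alignments into 3,411 FASTQ records;
de-duplication collapses them back to exactly 1,998; and the coordinate
stage recovers one screened site per planted rNMP. `out/demo.counts.tsv`
holds the site table:

```
chrom	start	end	strand	raw	normalized
chrN	30	31	-	1	0.050050
chrN	61	62	-	1	0.050050
```

`normalized` is the site's percent of the library (1/1998 × 100); the
column sums to 100. The sequence stage writes one profile per organelle ×
window × rNMP type, e.g. `out/demo.nuclear.w15.all.tsv`:

```
position  A_raw     C_raw     G_raw     T/U_raw   A_normalized  ...
-15       0.295328  0.192436  0.207453  0.304783  0.984165      ...
```

with position 0 the rNMP itself (`T/U` is rUMP there). Normalized values
are observed frequency / organelle background frequency; here all hover
near 1.0 (position 0 row: A 0.956, C 0.985, G 1.040, T/U 1.027) because
the simulated sites are uniform — real libraries show incorporation biases
as departures from 1. The distribution stage exports raw and
reads-per-hundred BedGraphs per strand scope
(`out/demo.coverage.both.percent.bedgraph`: `chrN  30  31  0.05005`, global
sum 100) plus per-chromosome coverage plots.

All of this also works on real data: point `alignments` at a SAM/BAM/BED
of read-1 alignments (and/or `fastq` at raw reads), drop the `simulate`
block, and start from `preprocess` or `coordinate`.

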