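# circkit

Annotation and quantification of **alternative back-splicing** and
**alternative splicing within circular RNAs** from junction-level RNA-seq
evidence, plus a seeded synthetic-data generator with ground truth.

circRNAs arise when a downstream 5' splice (donor) site is joined to an
upstream 3' splice (acceptor) site. `circkit` takes back-splice junction
calls (STAR-style chimeric text or a BED6 junction dialect), realigns
("snaps") both sites to exon boundaries of the supplied gene models, and
builds exon-resolved circRNA records. Downstream stages cluster records
into alternative back-splicing events (quantified by PCU, Percent
Circularized-site Usage), detect the four basic alternative-splicing
types inside circRNA spans (PSI / PIR / PSU), contrast circular against
linear evidence to call circRNA-predominant events, discover unannotated
exons, and search flanking introns for orientation-opposite complementary
sequence pairs whose competition correlates with back-splice-site choice.

## Modules

| module | role |
| --- | --- |
| `circkit.genome_annotation` | genome FASTA access, genePred/refFlat and GTF parsing, splice-site indices, flanking-intron lookup |
| `circkit.junction_io` | back-splice/linear junction parsing (STAR chimeric text, BED6 dialect), RPM normalization, sample sheets |
| `circkit.circ_annotate` | junction snapping and exon-resolved circRNA records (BED12+6 I/O) |
| `circkit.alt_backsplice` | clustering by shared back-splice sites, PCU, RPM >= 0.1 high-confidence filter, cross-sample PCU spread |
| `circkit.alt_splicing` | cassette exon / intron retention / alt 5'SS / alt 3'SS detection, PSI/PIR/PSU, circRNA-predominance calls |
| `circkit.novel_discovery` | unannotated-exon discovery, PWM splice-strength scoring, GC/ESE characterization |
| `circkit.rna_pairing` | seed-and-extend complementary-pair search, proximal/distal competition classification |
| `circkit.simulate` | seeded generator of genome + annotation + junction evidence with a ground-truth manifest |
| `circkit.cli` | `circkit` subcommand interface |

Coordinates are 0-based half-open throughout; GTF (1-based inclusive) is
converted at the parsing boundary. A back-splice junction is stored as
`start` = first base of the genomically most upstream circRNA exon and
`end` = one past the last base of the most downstream exon.

## CLI walkthrough

```sh
# 1. synthetic fixture set with ground truth
circkit simulate --seed 7 --outdir sim --withhold-fraction 0.1

# 2. back-splice junctions -> exon-resolved circRNA records
circkit annotate \
    --genepred sim/reference.genepred --genome sim/genome.fa \
    --junctions sim/LIB_PAM.backsplice.bed --library LIB_PAM \
    --samples sim/samples.yaml --tolerance 2 -o circ.bed

# 3. alternative back-splicing events + PCU
circkit altbacksplice --circ circ.bed -o events.tsv

# 4. alternative splicing within circRNAs, circ vs linear
circkit altsplice --circ circ.bed \
    --circ-junctions sim/LIB_PAM.linear.bed --circ-library LIB_PAM \
    --linear-junctions sim/LIB_PAP.linear.bed --linear-library LIB_PAP \
    --boundary-counts sim/boundary_counts.tsv --samples sim/samples.yaml \
    --genepred sim/reference.genepred -o calls.tsv

# 5. unannotated exons inside circRNA spans
circkit novel --circ circ.bed --linear-junctions sim/LIB_PAM.linear.bed \
    --genepred sim/reference.genepred --genome sim/genome.fa \
    --samples sim/samples.yaml -o novel.bed

# 6. complementary-pair competition at alternative back-splice sites
circkit pairing --circ circ.bed --genepred sim/truth.genepred \
    --genome sim/genome.fa -o pairing.tsv

# 7. compare against the simulation's ground truth
circkit evaluate --manifest sim/manifest.json --circ circ.bed -o report.json
```

`circkit report --events a.tsv --events b.tsv -o merged.tsv` merges
per-library event tables into one flat cross-library export.

Library types follow the experimental design: `pA_minus` and
`pA_minus_RNaseR` libraries carry circRNA evidence; the parallel
`pA_plus` library of the same cell line supplies the linear contrast;
`ribo_minus` libraries are rejected on the circRNA side of splicing
comparisons because they contain polyadenylated transcripts too.

## File formats

- **genePred/refFlat** — tab-separated, 0-based half-open
  (`geneName name chrom strand txStart txEnd cdsStart cdsEnd exonCount
  exonStarts exonEnds`).
- **STAR chimeric junction text** — columns
  `chrA coordA strandA chrB coordB strandB junction_type repeatL repeatR
  read_name ...`; the first segment is the donor side, coordinates are
  1-based intron breakpoint bases; `junction_type < 0` lines are dropped
  unless `keep_noncanonical` is set.
- **junction BED6** — `chrom start end name read_count strand`; for
  back-splice junctions start/end follow the circRNA span convention,
  for linear junctions they are the intron interval.
- **circRNA BED12+6** — BED12 plus `readCount RPM circType geneName
  isoformName siteStatus`; the BED name column carries the library id.
- **boundary counts TSV** — `library_id chrom intron_start intron_end
  strand e5 e3` (exon-intron boundary reads for intron retention).
- **samples.yaml** — `libraries:` list of
  `{library_id, rna_fraction, total_mapped_reads, cell_line}`.
- **BEDPE** — complementary pairs, one arm per block, plus alignment
  length and identity columns.

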