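# strandloop

R-loop detection from strand-specific ssDNA fragment coverage.

An R-loop leaves one DNA strand single-stranded, so a strand-specific ssDNA
readout shows an excess of signal on the displaced strand over the strand
sequestered in the RNA-DNA hybrid, while a transcription bubble exposes both
strands equally. `strandloop` turns this into a caller:

1. split aligned fragments by strand and compute per-bin coverage on sliding
   windows (500 bp / 250 bp step by default);
2. drop blacklist-overlapping bins and keep bins with >= 250 bp overlap with
   broad ssDNA peaks (peaks are an input, e.g. MACS2 broad calls);
3. test each candidate bin's plus/minus fragment counts against a 50/50
   binomial (two-sided exact test), adjust with Benjamini-Hochberg across
   the candidate universe;
4. keep bins with mean strand density > 20 reads-per-base,
   |log2((plus+1)/(minus+1))| >= 1 and q <= 0.05;
5. merge overlapping significant bins of the same imbalance direction into
   R-loop calls; per-call density is the mean |plus - minus| coverage.

On top of the caller there are cross-condition tools (RNase H-style
dose-response summaries; type I/II/III classification under transcription
inhibitors), annotation metrics (genomic-category assignment, metagene
profiles, overlap fractions, 5-kb-bin Pearson correlations), and a simulator
that plants R-loops and bubbles with machine-readable truth sets so the whole
pipeline is testable without sequencing data.

## CLI

All analyses are exposed as subcommands of the `strandloop` entry point
(exit codes: 0 ok, 2 usage/input error, 3 runtime failure):

```sh
# synthetic fixture with planted truth
strandloop simulate --config sim.yaml --out fx/ --seed 7 \
    --conditions control,drb,trp,rnase_h:50

# call R-loops (replicate BEDs are pooled; flags > config file > defaults)
strandloop call --frags fx/frags_control.bed --peaks fx/peaks.bed \
    --blacklist blacklist.bed --chrom-sizes fx/chrom.sizes --out out/ \
    --paired --min-density 20 --min-log2fc 1 --max-q 0.05

# three-type classification under DRB / triptolide
strandloop classify --control-calls out/rloops.bed --drb-calls drb/rloops.bed \
    --trp-calls trp/rloops.bed --control-frags fx/frags_control.bed \
    --drb-frags fx/frags_drb.bed --trp-frags fx/frags_trp.bed \
    --chrom-sizes fx/chrom.sizes --out classified/

# dose-response table over an ordered manifest (label, calls_path, frags_path, dose)
strandloop dose --manifest manifest.tsv --genes fx/genes.bed \
    --chrom-sizes fx/chrom.sizes --out dose/

# category assignment + length/density summaries
strandloop annotate --calls out/rloops.bed --genes fx/genes.bed \
    --chrom-sizes fx/chrom.sizes --out annotated/

# binned Pearson correlation between two BedGraph tracks
strandloop correlate --track-a a.bedgraph --track-b b.bedgraph \
    --chrom-sizes fx/chrom.sizes --bin-size 5000 --out cor/

# genome-wide imbalanced-bin census on fixed 2-kb bins
strandloop census --frags fx/frags_control.bed --chrom-sizes fx/chrom.sizes \
    --out census/
```

Fragment inputs are BED6. `--paired` treats each record as a complete
fragment; `--single-end` extends reads to `--extend-to` bp (150 by default)
from their 5' end. Calls are written as BED6+3 (name, score = density x 10,
displaced strand, then density, n_bins, min_q); every output table carries a
comment header echoing the version and parameters, and reruns are
byte-identical given the same inputs and seed.

## Library use

```python
import strandloop as sl

asm = sl.read_chrom_sizes("chrom.sizes")
reads = sl.read_bed("frags.bed", asm)
frags = sl.reads_to_fragments(reads, asm, mode="paired_fragments")
peaks = sl.read_bed("peaks.bed", asm)
blacklist = sl.read_bed("blacklist.bed", asm)

result = sl.call_pipeline(frags, peaks, blacklist, asm, sl.CallerConfig())
result.calls          # DataFrame: chrom, start, end, name, displaced_strand,
                      #            density, n_bins, min_q
result.bin_stats      # per-candidate-bin densities, counts, log2 ratio, p, q
```

Coordinates are 0-based half-open (BED) throughout.
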