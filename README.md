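# demuxfdr

FDR-controlled detection and demultiplexing of barcoded reads in noisy
long-read sequencing data.

## The problem

In multiplexed long-read experiments (e.g. PacBio CLR), short DNA
barcodes — here 7-nt tags synthesized onto the PCR primers — identify
which sample each molecule came from.  Two things make decoding them
hard: reads frequently start *inside* the insert, so many reads carry
no barcode at all ("orphaned" reads), and per-base error rates above
10% corrupt the barcodes that are present.  Naively decoding the start
of every read misassigns orphaned reads wholesale, because short
barcodes coincide with genomic sequence by chance.

`demuxfdr` treats the decision "does this read start with a barcode?"
as a large-scale testing problem.  The test statistic is the minimal
**Sequence-Levenshtein (SL) distance** δ of a read to the reference
set: the minimal number of insertions, deletions and substitutions
turning a reference into a prefix of the read (or vice versa), i.e.
the minimum over the last row and column of the Levenshtein DP matrix
— the right metric for a barcode followed by unknown DNA context.  The
observed histogram f(δ) is modeled as a mixture of a barcoded
component f₁ and an orphaned component f₀, both estimated by
simulation; the mixture parameters (barcoded fraction π₁, per-base
error rate μ ± σ, indel/substitution ratios R) are fitted to the
empirical histogram with an evolutionary search.  From the fitted
components the **tail-area false discovery rate**

    Fdr(δt) = F̂₀(δt) / (F̂₀(δt) + F̂₁(δt)),   precision = 1 − Fdr

is computed for every threshold δt, and the largest threshold with
precision above a target (default 95%) is used to call, decode and
trim barcodes at both read ends, with ties across samples left
unassigned.

The package also contains the supporting tooling: an [l,d] barcode-set
designer (pairwise SL distance ≥ d with GC/homopolymer/
self-complementarity filters), a PacBio-CLR-like read simulator used
both for fitting and as the synthetic test-data generator, and
distance-profile utilities.

## Worked example

Design a barcode set, simulate a labeled read mixture at the fitted
error model of the validation experiment, and run the full pipeline:

```
$ demuxfdr design --length 7 --dmin 3 --seed 1 --iterations 100 --out bc.fasta
[demuxfdr] designed 78 [7,3] barcodes (min pairwise 3, d_mean 3.72) in 19.8s -> bc.fasta
$ head -40 bc.fasta > bc20.fasta    # the validation design used 20 barcodes

$ demuxfdr simulate --m 2000 --pi1 0.34 --barcodes bc20.fasta \
      --extend-primers --seed 7 --out-dir sim/
[demuxfdr] simulated 2000 reads (680 barcoded, 1320 orphaned) -> sim

$ demuxfdr pipeline --reads sim/reads.fastq --barcodes bc20.fasta \
      --target-fdr 0.05 --seed 7 --out-dir run/
[demuxfdr] ratios INS/DEL/SUB = 0.462/0.359/0.179
[demuxfdr] fit: pi1=0.167 mu=0.087 sigma=0.051 (11 generations, converged=True)
[demuxfdr] chosen threshold 8 (precision 0.990, sensitivity 1.000)
[demuxfdr] assigned 631, ambiguous 55, unassigned 1314 of 2000 reads -> run
```

Reading the output: the pipeline profiles each read in both
orientations, so its π₁ is the fraction of *orientation records* that
start with a barcode — the 680 barcoded reads contribute 680 of 4000
records, and the fit recovers 0.167 ≈ 680/4000.  The error-ratio
estimate comes from reads at distance exactly 1 to the 27-nt barcoded
primers (truth 0.55/0.362/0.088; at a 12% error rate some compensating
double errors are observed as substitutions, inflating that share).
With the 40 barcoded primer references, distance threshold 8 is the
largest whose estimated precision stays above 95%; applying it assigns
631 of the 680 barcoded reads (93%) to their samples, leaves the 1314
orphans unassigned, and drops 55 reads whose two ends tie between
different samples.  `run/` then contains the empirical profile, the
fit trace, the per-threshold Fdr table, per-sample trimmed FASTQ
files, an assignment table and a provenance record that reproduces
the run.

Orientation matters: each read is scored at its 5' end and at the 5'
end of its reverse complement, so barcodes at either end are found;
reads whose two ends decode to different samples are reported
AMBIGUOUS rather than guessed.

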