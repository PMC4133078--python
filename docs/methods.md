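# Methods

## Problem and model

In multiplexed long-read sequencing (the motivating case is PacBio
Continuous Long Read data), each sample's molecules are tagged with a
short DNA barcode, here 7 nt, synthesized onto the PCR primer.  Because
sequencing may start anywhere inside the amplicon and per-base error
rates are high, a read may or may not still carry a (possibly
corrupted) barcode at either end.  Deciding which reads are *barcoded*
and which are *orphaned* (start inside the insert, no recoverable tag)
is a large-scale multiple-testing problem: every read-versus-reference
comparison is one test, and coincidental similarity between barcodes
and genomic sequence produces false detections at scale.

The test statistic is the minimal Sequence-Levenshtein (SL) distance
delta between a read and the reference set.  The SL distance between
sequences A and B is the minimal number of insertions, deletions and
substitutions turning one sequence into *any prefix* of the other (or
vice versa); operationally, the minimum over the last row and last
column of the standard Levenshtein dynamic-programming matrix.  The
prefix semantics make trailing insert sequence free, which is exactly
what a barcode embedded in unknown context requires.  An [l,d] barcode
set (l-nt barcodes, pairwise SL distance >= d) with d >= 3 corrects
any single error even in DNA context.

The observed histogram f(delta) over a read set is modeled as a
two-component mixture

    f(delta) = f1(delta) + f0(delta)

of barcoded (alternative) and orphaned (null) components.  Both
components are estimated by simulation; with the fitted components,
calling reads barcoded at delta <= delta_t has tail-area false
discovery rate

    Fdr(delta_t) = F0(delta_t) / (F0(delta_t) + F1(delta_t)),

with F0, F1 cumulative counts; precision is 1 - Fdr and detection
sensitivity is F1(delta_t) / F1(max).  The chosen threshold is the
largest delta_t whose precision exceeds a user target (default 0.95,
i.e. Fdr 0.05).  Standard FDR machinery (Benjamini-Hochberg, Efron's
local fdr, Storey's q-values) does not apply here: the null statistic
is a small discrete irregular distribution, and the null fraction can
be far below 80%.

## Read simulation

Simulated barcoded reads are a uniformly drawn reference (barcode or
barcoded primer) followed by insert sequence, corrupted base by base.
The error model has four parameters:

| parameter | meaning | default |
|---|---|---|
| mu_error | mean per-base error probability | 0.122 |
| sigma_error | between-read SD of the error probability | 0.048 |
| R = (R_INS, R_DEL, R_SUB) | operation-type ratios | 0.55 / 0.362 / 0.088 |
| pi1 | fraction of reads that start with a barcode | 0.34 |

The defaults are the operating point fitted to the validation data
set; they are also the conditions under which the acceptance checks
run.  Per read, an error rate p is drawn from Normal(mu, sigma)
truncated to [0, 1] (out-of-range draws are resampled) and held fixed
along the read.  At each template base, with probability p an
operation is drawn with relative probabilities R: an insertion emits
one uniform random base before the template base (at most one per
template position per pass), a deletion drops the base, and a
substitution replaces it with one of the three *other* bases uniformly
("altered" means visibly changed).  Error probability is uniform over
positions and operation types have no positional structure — the known
simplifications of this model are discussed under Limitations.

Orphaned reads are 50-nt windows that by construction carry no
barcode: in empirical mode, windows of real reads starting after
1-based position 40 (clear of any 5' barcode/primer); otherwise
windows of a supplied background sequence, or i.i.d. uniform ACGT.
A mixture of m reads contains round(pi1 * m) barcoded reads
(round-half-to-even; the source's nearest-integer bracket states no
tie rule) and the rest orphans.

Barcoded reads are simulated only to a window of reference + 50 nt of
insert.  This is exact for distance statistics: d_SL(b, s) <= |b|, so
no alignment of cost <= |b| ever consumes more than 2|b| read bases,
and 2|b| <= |b| + 50 for every shipped reference length.  The same
bound lets all distance computations truncate reads to a 2x(reference
length) prefix window, which is what makes the histogram scans cheap.

## Barcode design

Candidate l-mers are filtered for GC content in [40%, 60%], no perfect
self-complementarity, and no homopolymer run of 3+.  Construction is
greedy with restarts: draw a random 3-member seed at pairwise distance
>= d, scan eligible candidates in lexicographic order adding every
compatible one, and keep the largest set over the restart budget.
Between restarts the seed is either drawn fresh or derived from the
best seed so far by swapping one member for a random compatible
candidate (the alternation realizes "random and randomly modified"
seeds; the exact modification scheme was an open design choice).
Candidates are enumerated exhaustively for l <= 10; for longer
barcodes a random sample (default 200,000 distinct l-mers) is screened
instead, so very large designs (e.g. maximal [12,3] sets with tens of
thousands of members) are out of desk-scale scope.

## Fitting

The operation ratios R are estimated first, from reads at minimal
distance exactly 1 to the (primer-extended) reference set: such reads
are near-certainly barcoded, and the single edit is classified
directly by testing the three one-edit explanations (window mismatches
the reference at one position / reference minus one base is a window
prefix / window minus one base starts with the reference).  When one
edit admits several explanations the fixed precedence substitution >
deletion > insertion counts it once; with no distance-1 reads the
estimator raises and the uniform default (1/3, 1/3, 1/3) is the
documented fallback.

The remaining parameters (pi1, mu_error, sigma_error) are fitted by a
(mu + lambda) evolution strategy: population 20, offspring 40,
Gaussian mutation with initial steps (0.10, 0.03, 0.015) decaying by
0.95 per generation, box constraints pi1 in [0,1], mu in [0,0.5],
sigma in [0,0.2], at most 60 generations, elitist selection.  Fitness
is the RMS Euclidean distance between the simulated and empirical
histograms, on raw counts over the fixed support [0, reference
length] (simulated and empirical sets have equal size m, so counts
are directly comparable; explicit empty bins stabilize the RMS).

Fitness is stochastic, so common random numbers are used: a single
simulation seed is drawn at the start of the run and shared by every
candidate evaluation.  This makes the search surface deterministic
within a run — parent fitness can be cached, best fitness is
non-increasing, and the convergence rule (best parameter vector moves
less than 0.005 for 5 consecutive generations) is meaningful.
Re-drawing the seed each generation was tried first and rejected: the
re-ranking noise keeps the best vector wandering within the
Monte-Carlo band and the convergence rule essentially never fires.
The cost of the fixed seed is that the optimum targets one noise
realization of the simulation; the resulting parameter bias is on the
order of a single simulated set's sampling error (about 0.007 in pi1
at m = 5,000), well inside the recovery tolerances checked by the
tests (median over seeds: |pi1 error| <= 0.03, |mu error| <= 0.02).

## Demultiplexing

Each read is scored at both ends (read start, and start of the
reverse complement); the global minimum over both ends and all
references decides.  Forward and reverse barcoded primers of one
sample do not conflict: ties are evaluated at *sample* level, and a
read is AMBIGUOUS only when two different samples attain the minimal
distance (the typical case being different barcodes at the 5' and 3'
ends), UNASSIGNED when the minimum exceeds the threshold.  Assigned
reads are trimmed at the endpoint of the minimal SL alignment (the
longest read prefix attaining the minimum over alignment endpoints,
so a corrupted barcode of unequal length is removed cleanly); when
both ends match the same sample both are trimmed.  Whether primer
bases beyond the matched reference region should also be removed is
not specified by the protocol; trimming removes exactly the matched
region of whatever reference set is in use, so running with the
27-nt barcoded primers strips barcode + primer and running with the
plain barcodes strips the barcode only.

## Numerical and interface choices

* Alphabet is strict {A, C, G, T} (U maps to T, case-insensitive);
  N and other ambiguity codes are rejected rather than treated as
  wildcards, because no wildcard semantics is defined for the SL
  distance.  Background sampling skips windows containing invalid
  symbols instead of substituting.
* Orphan sampling coordinates: "after position 40" is read as 1-based,
  i.e. 0-based window starts >= 40; internal coordinates are 0-based
  half-open.
* Fdr table rows with no read at or below the threshold report missing
  (NaN) precision rather than 0 or 1.
* Assignment sensitivity divides by all reads by default (matching the
  stated definition "fraction of all reads"); a barcoded-only
  denominator is available for diagnostics.
* All randomness flows from numpy Generators seeded by a single master
  seed; identical seeds give byte-identical outputs.

## What the synthetic generator does and does not capture

The generator reproduces the features that drive the distance
statistic: per-read rate heterogeneity, unequal operation ratios, and
the mixture geometry (barcode context at the read start, featureless
insert elsewhere).  It does not model position-dependent error
hotspots, homopolymer-length-dependent indels, quality values, or
chimeric/adapter artifacts.  Passing tests therefore demonstrate the
statistical machinery (threshold selection, error-ratio recovery,
parameter fitting, demultiplexing bookkeeping) under the stated model,
not the fidelity of that model to any particular instrument run; on
real data the fit step exists precisely to absorb such differences
into the effective parameters.

Problem sizes used by the shipped checks were chosen for quick
desk-scale iteration: design runs use 100 restarts over the ~9,000
eligible 7-mers; histogram scans use 5,000 reads; operating-point
mixtures use 10,000-20,000 reads; recovery studies use 10 fits at
m = 5,000.  Relative Monte-Carlo error at these sizes is about 1-2%
on the reported fractions.

## Known limitations

* The mode of the barcoded-read distance histogram against the 27-nt
  references sits on a knife edge between 2 and 3 at the default
  operating point (the bulk mean is ~2.9 edits); seed-to-seed
  variation at n = 5,000 can move it.
* sigma_error is only weakly identified from plain 7-nt barcode
  profiles (support 0..7); pi1 is the robust parameter, as the
  orphan-peak shape depends on it alone.
* The greedy designer is not a maximum-clique solver; it matches
  exhaustive greedy baselines at small l but makes no optimality
  claim at l >= 10.
* Genome-scale background surveys (tens of millions of windows) are
  supported through the same API but not specially indexed or
  accelerated.
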