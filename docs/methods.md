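# Methods

This note records the models, conventions and design choices behind
`thx`, in the spirit of the methods documentation of statistical
genomics packages: what is computed, under which assumptions, which
defaults matter, and what the synthetic-data validation does and does not
demonstrate.

## Expression-matrix construction

The pipeline consumes one probe table per array with two processed
channels: a sample channel (cDNA from total, monosome- or
polysome-associated RNA) and a genomic-DNA reference channel.  Using
genomic DNA as the common reference makes log₂(signal/reference) a
per-gene abundance on a shared scale across arrays.

Order of operations is fixed: **log-ratios → per-array median centering →
between-array scale normalization in two batches → control filtering →
probe-to-gene averaging**.  Averaging after normalization keeps the
column statistics defined on the full probe population.

*Negative processed signals.*  Background subtraction in feature
extraction can push a processed intensity to or below zero, where the
log-ratio is undefined.  Rules, applied per array: if exactly one channel
of a probe is non-positive, that channel's value is replaced by the
lowest positive value of the same channel's distribution on that array
(the replacement is resolved per channel and per array because arrays
have independent intensity scales); if both channels are non-positive the
probe's log-ratio is set to 0.  Zeros are treated like negatives since
log₂(0) is equally undefined.  An ambiguity worth noting: "replace with
the lowest non-negative value" could also be read as replacing the
resulting *ratio* rather than the offending *channel value*; the
channel-level reading is implemented because it keeps the other channel's
information.

*Centering and scale normalization.*  Each array (column) has its median
subtracted, removing array-level intensity offsets.  Spread is then
equalized by the classical two-channel "scale" method: each column is
divided by its median absolute deviation and multiplied by the geometric
mean of its batch's column MADs, so columns of a batch share a common MAD
while the batch's overall spread is preserved.  The MAD is used without
the 1.4826 normal-consistency factor — only ratios of MADs enter.
Normalization runs independently in two batches, total-RNA arrays versus
monosome/polysome arrays, because the ribosomal fractions have a
genuinely different log-ratio distribution than total RNA; equalizing
them jointly would distort both.  A column with MAD 0 is degenerate data
and is reported as an error, by array name.

*Probe handling.*  Control probes are removed after normalization;
probes without a gene assignment are dropped (with a logged count — the
probe→gene map is an input artifact, the pipeline does not re-map probes
to the genome); each gene's value is the arithmetic mean of its probes'
log-ratios.  All arrays must share one probe set and one probe
annotation (a uniform platform); anything else is an error, not a merge.

## Rank products and pfp

For genes ranked within each replicate column (rank 1 = strongest change
in the tested direction; ties get average ranks), the rank product is
the geometric mean of a gene's ranks.  It is a nonparametric statistic
that rewards *consistency* across replicates and is robust to single
outlying replicates.

Significance is estimated by permutation.  Shuffling gene labels within
a replicate column simply redistributes the observed ranks, so the null
is generated by permuting the observed rank columns directly — no
re-ranking needed.  With B permutations, for each gene g:

* E(g) = (number of null rank products ≤ RP(g), over all B
  permutations and all genes) / B — the expected count of null genes as
  extreme as g;
* pfp(g) = E(g) / rank position of g in the observed RP ordering — an
  FDR-style proportion of false positives.

pfp is made non-decreasing along the RP-sorted gene list (cumulative
maximum) and capped at 1 for reporting.  Up- and down-direction tests
share the same permutation streams, which makes the sign symmetry exact:
negating every fold change swaps the up and down results bit for bit.
Defaults: B = 1000; a seed is always required.  The estimator was
validated against exhaustive enumeration of all within-column
permutations on small problems (max |Δpfp| < 0.004 at B = 50 000).

The heat-shock design is paired: five independent cultures sampled
immediately before and after the shift, so fold changes are formed
within replicate (42 °C minus 30 °C of the same culture) and never
across cultures.

## Translational efficiency and classification

TE is the log₂ ratio of a transcript's abundance in a ribosome-associated
fraction to its abundance in total RNA — on the GEM's log₂ scale, a
column subtraction.  TE is computed per replicate and temperature and
then contrasted (not contrast-of-means): rank products needs
per-replicate values and the pairing respects the culture structure.

Classification combines the TE call with the transcription (total-RNA)
call at the same pfp threshold into mutually exclusive classes:
potentiated (TE↑ and T↑), TE↑ with unchanged T, TE↑ despite T↓, TE↓,
T-only changes, none.  A gene called TE-up and TE-down simultaneously is
contradictory input and raises an error.

The monosome-partitioning contrast is formalized as a difference of
differences per replicate, [mono(42) − poly(42)] − [mono(30) − poly(30)]
— a deliberate interpretation of "changes in abundance in the monosome
relative to the polysome".  For the significant genes the report gives
the fraction with ORF < 1000 nt and their mean total-RNA abundance (mean
over replicates per temperature, from the total-RNA GEM) against the
genome mean, with one-tailed Wilcoxon rank-sum p-values.

## Composition battery

All set-level statistics are compared with a resampling null: 1000
random gene sets of the same size drawn uniformly without replacement
from all protein-coding genes excluding pseudogenes, and a statistic
more than 2 SD from the null mean is flagged (two-sided — departures in
either direction are reported).  Conventions:

* amino-acid frequencies and codon counts are **pooled over the set**
  (total counts per 100 residues), not per-gene means — "frequency of
  use per 100 residues" reads as a pooled rate;
* RSCU covers the 59 codons in synonymous families of size ≥ 2; ATG and
  TGG carry no synonymous choice and stop codons are tabulated
  separately as start/stop usage percentages; start codons are excluded
  from codon counts because their identity is constrained;
* G+C windows: 50 bp upstream of the start codon (genes with truncated
  upstream context are dropped from this window, with a warning), first
  50 coding bp, full CDS; set statistic is the unweighted mean of
  per-gene percentages, matching the accompanying per-gene Welch t-test;
* the positional profile uses coordinates with +1 = first base of the
  start codon and −1 = last upstream base (no position 0) and a ±12 nt
  smoothing window (the smoothing width is not standardized anywhere, so
  it is exposed as a parameter); a gene contributes at a position only
  if its sequence covers the whole window;
* alongside the per-statistic z flags, classical one-tailed tests are
  reported where a direction is expected: Wilcoxon rank-sum for protein
  lengths (alternative: shorter), Welch t for G+C (alternative: lower),
  plus a paired signed-rank p over the 20 amino-acid frequencies.

Calibration: applying the whole battery to a *random* set flags ≈5% of
statistics by construction; the acceptance checks assert ≤15% averaged
over 20 trials to leave room for correlation between statistics.

## Synthetic-data generator

The generator emulates the measurable structure of the experimental design — it
is a statistical emulator, not a physical model of sucrose-gradient
fractionation.

*Experiment.*  Design: 3 fractions × 2 temperatures × 5 replicates
(30 arrays), 3 probes per gene (the real platform has ~13; scaled down),
5% control probes.  Per-gene baseline log₂ abundance ~ N(8, 1);
heat adds the true transcriptional effect.  Ribosomal-fraction values
are built on the **realized** total-RNA value of the same culture plus a
gene-specific fraction offset, the true TE effect at 42 °C and their own
fraction-specific biological noise (sd `noise_sd` = 0.3 log₂ units per
value).  Building on the realized total is deliberate: the fractions are
aliquots of one lysate, so culture-level abundance fluctuations
propagate into the fraction measurements and cancel out of TE — exactly
the benefit of a paired design.  Arrays carry an offset (sd 0.3) and a
mild multiplicative scale artifact (sd 0.08 on the log-ratio scale) —
the artifacts centering and scale normalization exist to remove; probes
carry an affinity effect (sd 0.5) shared across arrays plus technical
noise (sd 0.1).  Channel intensities: reference = 2^(10 + probe effect +
noise), signal = reference × 2^(distorted log-ratio).

A `neg_signal_frac` share of entries per channel (default 1%) is negated
to exercise the negative-value rules.  Negation targets a random subset
of the channel's weakest tail (bottom 3·frac of the distribution) rather
than entries chosen uniformly: background-subtraction negatives occur
only near background, and because the pipeline's replacement rule maps
any negative entry to the channel minimum, negating strong features
would inject multi-log₂ outliers that no real feature-extraction output
contains.

Spiked groups mirror the scale of a genome-wide heat-shock screen: 74 TE-up genes
(15 potentiated with ΔT = +2, 40 with unchanged transcription, 19 with
ΔT = −2; all ΔTE = +1.5), 3 TE-down (ΔTE = −1.5), 30 transcription-up,
60 transcription-down, 15 monosome-shift genes (Δ(mono−poly) = +1.5 at
42 °C) drawn low-abundance (baseline N(6.5, 0.5)) and short
(< 1000 nt ORF) so the partitioning associations are real.  All effect
sizes are log₂ units, injected multiplicatively on intensities.

*Genome.*  Genes are drawn codon by codon: residues from a background
amino-acid distribution styled on a G+C-rich actinomycete proteome
(alanine/glycine/arginine-heavy), codons within each synonymous family
weighted by θ^(G+C of codon) with θ calibrated numerically so the
expected CDS G+C hits the target (72% background, 62% for the TE set —
matching a genome average of ~72%).  TE-set genes additionally use: a
length law 40% shorter (lognormal, background median 250 aa, σ = 0.45),
a 1.6×/0.65× boost/cut of the E/Q/M/V/K/I vs A/H/L/P/W/Y residue
frequencies, start-codon shares shifted from ATG/GTG/TTG ≈
61.7/35.1/0.3% to 65.7/30.1/4.1% and stop shares from TAA/TAG/TGA ≈
4.4/17.4/78.1% to 8.2/15.0/76.7%, and (by default) a G+C-maximized
codon block covering nt +55..+72 — a G+C-rich island centred near +63
of the CDS.  Genes are placed on one contig with 100 bp intergenic
spacers (the 50 bp immediately upstream of a TE gene are drawn at the TE
G+C level), random strand, and ~5% of unspiked genes flagged
`pseudo=true`.  The codon model is a two-parameter family (G+C bias ×
residue targets), sufficient for composition contrasts; it is not a
mutation–selection model.

Everything is deterministic under the configuration seed (truth
assignment, genome and experiment derive child seeds from one
SeedSequence).

*What passing tests show — and do not.*  The generator reproduces the
statistical shape the methods assume: paired replicates, batch-specific
array distributions, probe-level nuisance, composition-shifted gene
sets with known membership.  It does not reproduce operon structure,
leaderless transcripts, 5′-UTR/RNA-structure effects, correlated
expression along the chromosome, intensity-dependent (loess-shaped)
dye bias, or spatial array artifacts.  Recovery results on synthetic
data therefore validate the estimators and their calibration, not the
biological findings obtainable from any particular real data set.

## Numerical choices and validation scales

* Ties in ranking → average ranks; pfp monotonicity by cumulative max,
  cap at 1; pfp threshold 0.1 everywhere by default.
* Exhaustive-oracle checks run at n ≤ 5 genes × 2 replicates where all
  (n!)² within-column permutations are enumerable.
* Validation problem sizes: 2000 genes × 5 replicates × 3 probes for
  recovery and null-calibration runs (B = 1000 and 250 respectively, 50
  null repetitions); 1000 random sets and 20 calibration trials for the
  composition battery.  These sizes give Monte-Carlo error comfortably
  below the asserted margins while keeping any single run in seconds.
* Serialization is deterministic: floats are written with `repr` (the
  shortest round-trip form) and parsed with correctly-rounded readers,
  so write→read is bit-exact and identical inputs produce byte-identical
  outputs.

## Known limitations

* Unpaired designs, >2 conditions and the gamma approximation to the
  rank-product null are out of scope; the pfp is Monte-Carlo only.
* The probe table is a simplified two-channel dialect, not the full
  Agilent Feature Extraction format; constructing it from FE exports is
  a documentation-level exercise (two columns plus the control flag).
* Multi-part CDS features are concatenated in genomic order per strand —
  correct for the bacterial annotations targeted, untested for
  spliced genes.
* RSCU of a synonymous family absent from a set is undefined (NaN) and
  excluded from flag counts.
* Functional-enrichment analysis (DAVID/STRING-style) is external; the
  package only writes plain gene lists those services ingest.
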