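# Methods

This note documents the models, conventions and design decisions behind
`mslseq`, in the spirit of a statistical software appendix. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted from memory.

## Sequence-word profiling

Words of length k = 2..6 are counted in sliding windows of step one. A word
and its reverse complement are one variable; the canonical key is the
lexicographically smaller of the pair. Windows containing N are skipped,
but the frequency denominator stays the full sequence length L (count/L),
so frequencies remain comparable across sequences with sparse Ns and the
published 5456-column layout (all literal 2–6-mers, complement columns
mirrored) is reproduced exactly; the canonical layout (2770
reverse-complement classes) is used for modeling. Pooled observations
(e.g. "all strong promoters of one arm") concatenate member sequences with
a single N so no junction words are counted.

AT normalization divides each frequency by its i.i.d. expectation under the
observation's own mononucleotide composition: E(w) = Π p(wᵢ), plus the
reverse-complement term unless w is self-complementary. Base probabilities
are floored at 1e-6 so degenerate compositions cannot produce infinities.
No (L−k+1)/L edge correction is applied, mirroring the count/L frequency
definition. AT-normalized matrices are center-scaled only; raw matrices
get unit-variance scaling (zero-variance columns are left at zero rather
than divided).

## PCA and OPLS-DA

PCA is a thin layer over scikit-learn's SVD implementation with one added
convention: each loading vector's largest-magnitude entry is made positive
so loading lists are stable across runs. R²cum is the cumulative
explained-variance fraction.

OPLS-DA is implemented from scratch in the O-PLS NIPALS formulation. The
binary response is coded +1/−1 and centered. For each orthogonal
component: w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/(tᵀt),
w_orth ∝ p − (wᵀp)w, and X is deflated by t_orth p_orthᵀ. A single
predictive component is then fit on the deflated matrix (binary response ⇒
one predictive dimension). Prediction applies the stored training column
statistics, removes the stored orthogonal components sequentially, and
projects on the predictive weights; positive scores indicate the positive
(strong) class, which holds automatically because w ∝ Xᵀy.

Q² = 1 − PRESS/SS over stratified K-fold cross-validation (default 7
folds, seeded, scikit-learn StratifiedKFold); scaling statistics and the
response mean are recomputed inside each training fold. The number of
orthogonal components is chosen (cap 5) as the value maximizing the
cross-validated Q², ties toward fewer components. These conventions are
fixed here because the originals (a commercial package's CV partitioning)
are not recoverable; all Q² values in this package are comparable to each
other, not necessarily to other software's.

The train/test protocol for the binding models is a stratified, seeded
2/3–1/3 split of the strong/weak expressed genes; held-out separation is
summarized by a one-sided Mann-Whitney U on Y-prediction scores.

## The word-to-PWM aligner

A PWM accumulates loadings: cell (i, b) holds the summed loadings of
aligned words placing base b at column i, and the column view renormalizes
each row to sum to one. Scoring multiplies column values along an offset
(N contributes 0 — no pseudocounts, so a zero cell is a hard mismatch),
takes the better strand per position, and sums the best
`best_scores_per_seq` positions (default 1) per sequence.

Alignment of a candidate word tests both orientations at every offset with
at least ⌈word length/2⌉ overlapping columns (overhangs extend the PWM).
The minimum-overlap rule prevents 1-column overlaps from growing unbounded
matrices. Candidates are ranked by alignment compatibility — the dot
product of the word's one-hot matrix with the current PWM columns over the
overlap — and a word may also be added at its best two distinct offsets
simultaneously, each contributing its full loading; the gate arbitrates.

The gate is logistic regression of class on motif score: an update is
accepted only if it lowers the deviance and the updated score is
significant against the intercept-only model (likelihood-ratio test,
α = 0.05). Degenerate (constant) scores are rejected outright; perfect
separation is treated as a saturated fit. Because gating every word with a
regression each round is quadratic in the word list, the builder aligns
all unconsumed words each round (cheap), then walks down the compatibility
ranking applying the gate to at most 25 candidates; in practice the
accepted extension is found within the first few.

Seeding and stopping: the top unconsumed word seeds a one-hot PWM, which
must itself pass the significance gate (a single-word input list is
returned as its one-hot PWM). Building stops at the first rejected seed:
every retried seed is another 5%-level test, and retries measurably
inflate the junk-motif rate on label-free data. Finished motifs are masked
— each sequence's best above-cutoff occurrence replaced by N — and never
share source words. Under the null the gate still passes a junk seed at
roughly its nominal rate; about 8/10 label-free runs return no motif, not
all of them.

Cutoff calibration selects the smallest observed best-score value at which
the fraction of negative (weakly bound) promoters at/above it is ≤5%
(order statistic; if even the maximum is too common, the cutoff resolves
just above it and presence is zero). Two properties of this rule on sharp
synthetic motifs are worth knowing:

* **Tie cliffs.** Planted instances sampled from a sharp PWM share the
  exact consensus product, so when more than 5% of the negative set carry
  the site the 5% target falls inside a tie block and presence collapses
  to ~0. This is the rule working as stated, not a bug; the presence
  analog for strong-vs-weak fractions is therefore also calibrated on
  motif-free (unexpressed-class) promoters, where the rule lands at a
  background quantile and yields the expected ≈35%/≈19% fractions.
* **Column softening.** The gate legitimately accepts one-mismatch variant
  words (they capture the ~40% of planted instances that deviate from
  consensus), so a couple of recovered columns are soft and the recovered
  information content is ~0.65× the planted window's. Recovery quality is
  measured as mean per-column Pearson correlation against the planted PWM
  at the best offset/orientation (~0.95 at defaults). Because a single
  spuriously discriminative word can hold the top loading and seed the
  first PWM, the recovery benchmark builds up to three motifs and assigns
  recovered to planted by column correlation — the same rule used when two
  motifs are planted.

## Tiling-signal analytics

Gene binding is the mean of the top ⌈n/2⌉ exon-probe log₂ ratios (the
ceiling convention covers odd counts). Peak calling: the genomic mean and
SD are computed over all probes of all chromosomes (a per-chromosome
option exists but is off by default); probes ≥ mean + 3 SD are chained
while consecutive qualifying probes are ≤360 bp apart (midpoint
distances); chains spanning <360 bp or containing <5 probes are dropped. A
region's value is the mean of its highest six consecutive probe values and
its center their mid-position (all five for 5-probe regions; ties resolve
to the leftmost window). Dual-antibody confirmation intersects the two
region lists, emitting the union span, the larger value, and the mean of
the centers. Co-localization profiles average probe values in 100-bp bins
of signed distance from anchor centers, mirroring anchors so the TSS is
always rightward; empty bins are missing, not zero.

## Gene classes and downstream tests

Strong = binding >1.0 (log₂) for all three proteins; weak = all <0.5; a
gene with any protein in between is intermediate and excluded from model
sets. Expression is the median over replicates; [6, 10] is expressed,
<6 unexpressed, >10 expressed-but-excluded (outside the window the RNAi
effect, hence the label, is not quantifiable). CDS thirds are as equal as
possible with remainder bases assigned 5′-first, preserving the 3′ third's
length parity for the bias test; the bias statistic is a paired t of 3′ vs
5′ Y-prediction scores over held-out strong genes.

Codon usage: raw RSCU differences sum to exactly zero across codons
(family normalization), which makes a paired t on RSCU identically null —
verified numerically. The comparison therefore uses relative adaptiveness
w = RSCU / family max (the CAI weight) for the paired t across the 59
degenerate codons, and adds a within-family G-test on pooled counts, which
is the powered detector for shifts confined to one amino-acid family.

## The synthetic-data generator

The generator emulates the study's statistical structure, not fly
sequence. Defaults (chosen once; all randomness flows from one seed fanned
out into named sub-streams):

* 150 genes per class (strong / weak / unexpressed) across five
  chromosome arms; two exons and one intron per gene; feature length means
  200/1500/300/300 bp (5′ UTR/CDS/intron/3′ UTR), CDS a multiple of 3;
  inter-gene gaps of promoter+100..500 bp so promoters never truncate by
  default; background bases i.i.d. at A/C/G/T = 0.29/0.21/0.21/0.29.
* A 10-column planted promoter PWM (consensus TATCGATAGC, dominant base
  probability 0.95 — a sharp insulator-like site) inserted at a uniform
  promoter position in 44% of strong and 18% of weak genes. Softer planted
  motifs (e.g. 0.85) leave the word loadings dominated by sampling noise
  at this sample size, which is informative about the method's limits but
  makes a poor recovery benchmark.
* Class-dependent word-composition biases: 10 fixed promoter words at
  Poisson rate 0.25/word (3× in strong genes) and 10 fixed CDS words at
  rate 0.8/word/third, multiplied 1/2/3 across the 5′/mid/3′ thirds in
  strong genes only. Note the CDS insertion also shifts codon composition,
  so codon-usage tests fire on this synthetic data by construction.
* Probe tracks at 100-bp spacing: per-gene exon enrichment means of
  1.2/0.2/0.0 (strong/weak/unexpressed, per-gene SD 0.05) for three MSL
  proteins, Gaussian probe noise SD 0.1; insulator-like boxcar peaks
  (height 2.0, 7 probes) planted 100–400 bp upstream of the TSS in
  49%/13%/5% of genes, emitted as two antibody tracks with independent
  noise. 100-bp spacing is coarser than the real arrays but exercises the
  360-bp chaining rule at desk scale.
* Expression: uniform inside (6.2, 9.8) for expressed classes, (3.0, 5.5)
  for unexpressed, three replicates with SD 0.05 — medians stay inside the
  6–10 window by construction.

What the generator does **not** emulate: real base composition and its
chromosomal gradients, nucleosome/chromatin structure, alternative
splicing and overlapping gene models, probe-level array chemistry,
replicate variance structure, and any correlation between expression level
and sequence. Passing tests therefore demonstrate that the pipeline
recovers the structure it is told to look for at realistic sizes and noise
— not that the biological conclusions transfer to real data.

## Problem sizes and runtime

The default pipeline (450 genes, ~2 Mb genome, 5 proteins × ~23k probes,
canonical 2770-word matrices) runs in ~10 s on one CPU and is
bit-reproducible per seed. The benchmark experiments use the sizes named
in their docstrings — e.g. 150+150 genes for recovery, 500/class for
calibration, 7×100 sequences for the random-group null (reduced word set
k ≤ 4), 20 permutations/null seeds — keeping the full suite within a few
minutes.

## Known limitations

* The OPLS-DA CV partitioning and Q² convention are this package's own
  fixed choices; absolute Q² values are not comparable to other software.
* The aligner's "up to two simultaneous alignments" and the logistic gate
  statistic are documented interpretations of a description whose original
  implementation is unavailable.
* Loading-sum PWMs soften columns where discriminative variant words
  exist (see above); per-column correlation, not information content, is
  the recovery metric.
* The order-statistic cutoff has tie cliffs on synthetic sharp motifs.
* `read_fasta` loads chromosomes into memory; for large genomes use
  `pyfaidx.Fasta`, which `extract_sequences` accepts directly.
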