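# mslseq

Sequence-signature analysis of MSL-complex targeting on the *Drosophila*
X chromosome, rebuilt as a tested, reusable pipeline and exercised end to
end on synthetic data with known ground truth.

In *D. melanogaster* males, the Male-Specific Lethal (MSL) complex binds
hundreds of X-linked genes to double their expression (dosage
compensation). How the complex spreads from its high-affinity entry sites
to target genes is an open question; one hypothesis is that the DNA of
targeted genes itself carries discriminating sequence signatures. This
package implements the analysis chain for testing that hypothesis:

1. **Gene-feature k-mer profiling.** The genome is partitioned into six
   feature classes — promoter (≤500 bp upstream of the TSS), 5′ UTR, CDS,
   intron, 3′ UTR, intergenic — and every 2–6 bp word *w* is counted in
   sliding windows with forward and reverse complements merged. The
   frequency is *f_w = c_w / L*. In the published column layout the 2–6-mer
   matrix has 16+64+256+1024+4096 = 5456 variables; the canonical layout
   keeps one column per reverse-complement class (2770).
2. **AT normalization.** Each frequency is divided by its expectation under
   the observation's own mononucleotide composition,
   *E(w) = Π_i p(w_i)* (+ the reverse-complement term for non-palindromic
   words), removing the AT-content axis that otherwise dominates PC1.
   AT-normalized data are center-scaled; raw data are unit-variance scaled.
3. **PCA and OPLS-DA.** PCA summarizes composition differences between
   features and chromosome arms. Orthogonal partial least squares
   discriminant analysis (O-PLS NIPALS; binary response coded ±1, one
   predictive component, orthogonal components deflated first) seeks words
   *predictive* of strong vs weak MSL binding; predictive power is the
   cross-validated *Q²* = 1 − PRESS/SS over stratified folds. Held-out
   genes are classified by their Y-prediction score (projection on the
   predictive component after orthogonal removal).
4. **Word-to-PWM motif building.** Top-loaded words are iteratively aligned
   into position weight matrices: aligned words add their loading to
   matching base cells and columns renormalize to sum to one; a PWM scores
   a sequence as the product of column values at an offset (both strands,
   best position per sequence); every update must pass a logistic-
   regression gate (deviance decrease + likelihood-ratio significance).
   Finished motifs are masked with N and the next is seeded. Cutoffs are
   calibrated so the motif is present in ≤5% of weakly bound promoters.
5. **Tiling-signal analytics.** Gene binding values average the top 50% of
   exon probes. Insulator binding regions are probes ≥3 SD over the
   genomic average, chained within 360 bp, spanning ≥360 bp with ≥5 probes;
   a region's value/center come from its highest six consecutive probes,
   and regions must replicate across both antibodies. TSS–peak distances,
   chromosome coverage, and signal profiles in 100-bp bins around peak
   centers quantify co-localization.
6. **Class analytics.** Genes with binding >1.0 (log₂) for all three MSL
   proteins are "strong", <0.5 "weak"; expression (median of replicates)
   must lie in [6, 10], below 6 is unexpressed. CDS are split into three
   equal parts to test whether binding is better predicted from the 3′
   third (paired *t*); codon usage is compared by relative adaptiveness
   and a within-family G-test; random gene groups provide the null for
   model significance.

The real inputs (FlyBase genome, Affymetrix ChIP-chip/expression data) are
not required: `mslseq.synth` generates genomes, GFF3 annotation, probe
tracks and expression tables with planted, recoverable structure — a sharp
10-column promoter PWM inserted in 44%/18% of strong/weak genes,
class-dependent word-composition biases, 3′-graded CDS word enrichment,
MSL-like exon enrichment, and insulator-like promoter peaks.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate_dataset.py --seed 1   # genome, tracks, truth
python analysis/04_msl_models.py      --seed 1    # OPLS-DA models
python analysis/06_insulator_peaks.py --seed 1    # peak calling
```

`04_msl_models.py` prints:

```
promoter model: Q2 = 0.272 (1 orthogonal components), train n = 200, test n = 100, held-out Mann-Whitney p = 1.07e-06
cds model: Q2 = 0.482 (0 orthogonal components), train n = 200, test n = 100, held-out Mann-Whitney p = 1.51e-15
```

meaning: fit on two-thirds of the 150+150 strong/weak genes, the promoter
word model has cross-validated predictive power Q² = 0.27, and the
Y-prediction scores of the held-out third separate strong from weak genes
at p ≈ 10⁻⁶ (one-sided Mann-Whitney) — the planted promoter signal is
recovered from sequence alone. `06_insulator_peaks.py` prints:

```
regions per antibody: [88, 88], intersected: 88
TSS-distance Mann-Whitney (strong < weak): p = 4.68e-06
peak within 500 bp of TSS: strong 0.43, weak 0.11
```

i.e. the dual-antibody peak calls sit significantly closer to strong-gene
TSSs, and 43% / 11% of strong / weak genes have a peak within 500 bp of
the TSS (the generator plants them at 49% / 13%).

The same pipeline is scriptable as a whole:

```bash
mslseq --seed 1 --outdir results/run all     # or: synth / pca / oplsda / ...
```

Every artifact (class table, loadings, MEME motifs, BED peaks, report
JSON) lands in the output directory, and a rerun with the same seed
reproduces the report bit for bit.

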