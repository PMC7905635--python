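# Methods

## Model and assumptions

`orfrf` treats gene finding as binary classification of candidate ORFs.
The unit of analysis is the ORF — a start codon paired with its nearest
downstream in-frame stop — never a raw read or an alignment. The model
assumes the discriminating signal lives in sequence composition:
3-periodicity (positional GC, especially GC3), synonymous-codon usage
bias, k-mer spectrum skew, and length. It deliberately uses no context
outside the ORF (no ribosome-binding sites, no translation-initiation
context, no operon structure), which is what makes it applicable to
unoriented metagenomic fragments where flanking context is unreliable.

Stops are fixed at TAA/TAG/TGA; start codons default to ATG with GTG and
TTG available as options. The genetic code used for synonymous families
is the bacterial/archaeal translation table (11) throughout; alternate
codes are out of scope.

## ORF conventions

- Coordinates are 1-based inclusive on the forward strand everywhere
  (GFF3 convention); minus-strand ORFs are reported in forward
  coordinates with the sequence given on the coding strand.
- The ORF sequence **includes the stop codon**, and `length_nt` counts
  it. The choice is arbitrary; what matters is that training and
  prediction share it, so it is recorded in every model file.
- Every start sharing a stop is emitted (internal ORFs), not only the
  longest; a `longest_per_stop` reporting helper exists but is not used
  in training.
- ORF windows containing N are dropped (counted) — every feature assumes
  unambiguous bases. Starts with no in-frame stop before the sequence
  end are not ORFs and are only counted.
- Default minimum length: 60 nt. Spurious 2-3 codon ORFs carry no usable
  composition signal; 60 nt keeps them out while staying below gene
  lengths of interest.
- Both strands are scanned by default (metagenomic contigs are
  unoriented); single-strand mode exists for labeling experiments on
  oriented genomes.

## Features

Canonical order: `length_nt, gc, gc1, gc2, gc3, var2..var6, c_weight`.

- k-mer variance uses *frequencies* (counts divided by L−k+1, overlapping
  windows, step 1) so the statistic is length-comparable; length enters
  only through `length_nt`. The variance is the sample variance with
  denominator 4^k − 1 over the full 4^k-dimensional vector, zeros
  included. The convention tag is stored in model metadata.
- `c_weight` reduces per-codon relative preferences (count / family max)
  to one scalar by the arithmetic mean over *distinct observed* sense
  codons, excluding stops and the single-codon families (ATG/Met,
  TGG/Trp), which carry no bias information; an input with no eligible
  codons returns 1.0. Note the statistic is not monotone in bias
  strength: under strong bias, rarely used synonymous codons score near
  zero against the dominant one and pull the mean *down*, while perfectly
  uniform or perfectly single-codon usage both push it up. It remains
  discriminative because coding and random ORFs occupy different parts of
  that range. The reduction is an explicit policy choice; other
  reductions (e.g. RSCU-style) would be drop-in replacements.
- GC features are computed on the full ORF including the stop codon,
  consistent with the length convention.

## Labeling rule

Against a CDS annotation, an ORF is **coding** when it is contained in a
CDS interval on the same strand *and in the same reading frame*. An
in-frame ORF contained in a CDS necessarily shares its stop codon — the
definition of an internal ORF. It is **intergenic** when it overlaps no
CDS on either strand. Everything else — boundary straddlers, antisense
ORFs inside genes, and same-strand but frame-shifted ORFs inside genes —
is ambiguous: such intervals are neither internal ORFs nor between genes,
and including them in either class injects label noise (frame-shifted
contained ORFs in particular look compositionally random while sitting
inside genes). They are discarded and counted. Classes are then
near-balanced by seeded undersampling of the majority class, mirroring
the near-balanced corpus design the training protocol expects.

## Synthetic data

The generator emulates exactly the structure the features detect:

- **CDS**: ATG + i.i.d. sense codons from a sampled usage table + one
  stop. The usage table interpolates, per synonymous family, between
  uniform (`codon_bias_strength` 0) and a point mass on one preferred
  codon (1); a `gc3_target` (default 0.65) biases which codon is
  preferred toward G/C third positions. Family marginals are proportional
  to family size, so bias 0 is uniform over the 61 sense codons.
- **Intergenic spacers**: order-0 i.i.d. bases at a flat GC (default
  0.45). Real intergenic DNA has structure (promoters, terminators), but
  the features measure periodicity and bias, for which order-0 is the
  appropriate null. Chance ORFs arising in spacers are *kept* and labeled
  intergenic — they are the realistic hard negatives.
- **Layout**: alternating spacer/CDS, strands ±with equal probability,
  exact coordinates recorded as the annotation. Default gene length:
  gamma-distributed, mean 300 codons (900 nt), minimum 30; spacers mean
  120 nt, minimum 20 — genes long, spacers short, as in real prokaryotic
  genomes. Communities draw per-genome jitter (±10% on means) from a
  single root seed; presets low/medium/high = 5/15/40 genomes.
- All randomness flows from one `SeedSequence` per spec; every artifact
  is bit-reproducible.

The **null dataset** used as a negative control draws *both* classes from
the same bias-0 generator with one shared length distribution. This is
the exact matched-GC/matched-length null: an ORF extracted from i.i.d.
equal-frequency DNA, conditioned on its length, is distributionally a
uniform-sense-codon sequence, so generating both classes identically is
equivalent to (and far cheaper than) rejection-sampling 900 nt ORFs out
of random spacers. Any AUC departure from 0.5 on this data would indicate
leakage in the pipeline, not signal.

What the generator does **not** model: sequencing error, read
fragmentation and edge-truncated ORFs, operons and overlapping genes,
regulatory intergenic structure, horizontal heterogeneity of codon usage
within a genome. Passing tests on synthetic communities therefore
demonstrate that the pipeline recovers planted periodicity/bias/length
signal end to end; they do not certify field performance on real
assemblies, which depends on how closely real signal matches these
idealizations.

## Training protocol

Repeated stratified 5×5-fold CV scores each `mtry` in {2, 3, 6, 11} by
mean accuracy; ties go to the smaller (simpler) `mtry`; the final forest
is refit on all instances. Ensemble size is restricted to the canonical
grid {100, 200, 500, 700}; the default is 100 trees — on our data larger
ensembles move CV accuracy by fractions of a point at several times the
cost. `p_coding` is the fraction of trees voting coding, thresholded at
0.5 by default; both values are recorded in the model file. Permutation
importance (5 repeats, seeded) is computed on the training set at fit
time and reported scaled so the top feature reads 100; Gini importance is
available as an alternative. Model archives are versioned and embed the
ORF configuration, genetic code id and variance convention; prediction
refuses mismatched feature order or format version rather than silently
proceeding.

Desk-scale problem sizes: the package's own end-to-end experiments use a
16-genome × 400-gene training community (≈6.7 Mb, ≈5,000 balanced
instances after labeling) and an independent 8-genome × 200-gene test
community — large enough for stable rates while keeping a full train/test
cycle under two minutes on one core.

## Evaluation conventions

- Coding is the positive class; sensitivity = TP/(TP+FN) is the fraction
  of truly coding ORFs recovered, specificity = TN/(TN+FP) the fraction
  of intergenic ORFs rejected.
- Metrics with zero denominators return an explicit `None`, never 0.
- AUC is the Mann-Whitney rank form with ties worth ½ — identical to the
  trapezoidal area under the empirical ROC, which the test suite asserts
  to 1e-12.
- McNemar's test uses the continuity-corrected χ² statistic
  (|b−c|−1)²/(b+c) on 1 df when b+c ≥ 25 and the exact two-sided binomial
  test below that; the threshold and α (default 0.01) are arguments.
  b+c = 0 returns p = 1.
- Comparator predictions are ingested as per-ORF TSVs (coordinates +
  label, the dialect `predict` writes); truth labels are re-derived by
  the containment rule and predictors are paired on the intersection of
  their ORF references for McNemar. Tools that emit gene calls as FASTA
  can be scored by converting their coordinate lists to this dialect.

## Known limitations

- No model for edge-truncated ORFs on short reads; fragments whose genes
  lack an in-frame stop inside the fragment are invisible.
- Labels near annotation boundaries depend on annotation quality;
  discarded-ORF counts should be inspected when training on real
  annotations.
- The synthetic generator's idealizations above; in particular,
  specificity estimates on order-0 spacers are optimistic relative to
  real intergenic DNA containing conserved elements.
- Single genetic code (table 11); organisms using alternate codes will
  mis-measure `c_weight` and positional GC family structure.
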