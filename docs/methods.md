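# Methods

`mirhairpin` classifies candidate RNA hairpins — viral microRNA precursors
(pre-miRNAs) versus pseudo-hairpin genomic fragments — from a 54-dimensional
representation combining local structure-sequence composition, thermodynamic
stability, and base-pairing topology. This note records the models,
conventions, and design choices behind each stage, and what the synthetic
benchmark does and does not demonstrate.

## Problem setting

Viral pre-miRNAs are ~60–120-nt stem-loop RNAs. Discriminating them from the
vast background of genomic fragments that can also fold into hairpin-like
shapes is a binary classification problem traditionally attacked with
hand-crafted features over the predicted secondary structure. The package
implements the full pipeline: folding, feature extraction, Fisher F-score
filter selection, SVM/random-forest classification, and a stratified
cross-validation protocol with a six-metric report (SN, SP, PRE, ACC,
balanced ACC, MCC).

## Folding

### Built-in folder

The default folder is a maximum-pair-score dynamic program over nested
structures with Watson–Crick and G-U wobble pairs:

* pair scores G-C = 3, A-U = 2, G-U = 1 (dimensionless; the ordering mirrors
  relative thermodynamic stability),
* minimum hairpin-loop size `min_loop` = 3 nt (steric minimum),
* reported `mfe` is the negated optimal score, so lower = more stable,
  matching the sign convention of thermodynamic folders.

The recursion "first position unpaired, or paired with position k" generates
every nested structure exactly once, which makes the same decomposition
usable as an unambiguous partition function: Boltzmann-weighting each pair
with `exp(score/kT)` (default `kT` = 1) gives the exact ensemble probability
of the MFE structure (*Frequency*) and, through the matching outside
recursion, exact base-pair probabilities `P(i,j)`. *Diversity* is defined as
`Σ_{i<j} P(i,j)(1 − P(i,j))` (the variance form; the quantity has no single
standard definition, so this convention is fixed here and tested against
exhaustive enumeration). Both the optimum and the ensemble quantities are
verified against brute-force enumeration of all nested structures for
sequences up to 12 nt (agreement to 1e-9 or better).

Tie-breaking among co-optimal structures: the traceback prefers pairing the
first position over leaving it unpaired and, among co-optimal partners, the
*outermost* (largest) one. The outermost-partner rule matters: preferring the
nearest partner can split a perfect stem-loop into a branched co-optimal
structure, which would corrupt loop-count-dependent features on exactly the
cleanest inputs.

Floating-point note: partition-function weights are accumulated in linear
space; with the default scores this is safe for sequences up to a few hundred
nt (weights stay far below overflow), which covers the intended 50–200-nt
candidate range.

### External backend

A thermodynamic backend can be registered by name; the bundled adapter uses
the Vienna RNA package's Python bindings (structure and MFE in kcal/mol at a
configurable temperature, default 37 °C; ensemble frequency from the
ensemble free energy, diversity as mean base-pair distance). The built-in
folder remains the default so the package is fully functional and testable
without thermodynamic parameter tables; backends are swappable per record
via `FoldConfig(backend=...)`.

## Structure statistics

* A *stem run* is a maximal set of stacked pairs; any bulge or interior loop
  breaks the run. `n_stems` counts runs of **more than three** pairs (>= 4),
  the miPred-style stem definition; the cutoff is configurable
  (`min_stem_pairs`).
* `n_loops` counts hairpin (terminal) loops only — unpaired intervals closed
  by a pair with no pairs inside. A `count_all_loops` switch additionally
  counts interior/bulge and multibranch loops.
* *Hairpin length* is the nt span from the outermost pair enclosing the
  largest terminal loop to its partner; *loop length* is the size of that
  loop. Structures with no pairs report 0 for both.
* A structure is *hairpin-like* iff it has at least one pair and exactly one
  terminal loop (every branch of a multiloop ends in its own terminal loop,
  so this is equivalent to single-stem-loop topology).

## Features (canonical order)

1. **32 triplet elements** — for each interior position, the pairing states
   of the three residues centred on it ('(' for paired in either direction)
   keyed by the middle nucleotide: 4 x 2^3 categories. Counts are normalised
   by the number of windows (L−2) so the block sums to 1.
2. **4 sequential** — %G+C (0–100), sequence length, hairpin length, loop
   length.
3. **8 thermodynamic** — `dP = n_bp/L`, `dG = MFE/L`, z-scores `zP`, `zG`
   against dinucleotide-preserving shuffles, `MFEI_1 = dG/%G+C` (percentage
   scale), `MFEI_2 = dG/n_stems`, `MFEI_3 = dG/n_loops`,
   `MFEI_4 = MFE/n_bp`.
4. **8 base-pair** — `|X-Y|/L` for (A-U), (G-C), (G-U); `%(X-Y)/stems`
   where `%(X-Y) = 100·|X-Y|/L` (the percentage convention is fixed here —
   the quantity is only ever defined by its row label in the literature);
   `ConsecBP` (longest stacked run); `Avg_BP_Stem = n_bp/n_stems`.
5. **2 ensemble** — Frequency and Diversity as above.

**Shuffle null.** `zP`/`zG` standardise the observed `dP`/`dG` against
refolded dinucleotide-preserving shuffles (Altschul–Erickson Eulerian-path
sampling), which conserves the 16-entry dinucleotide table exactly — plain
permutation would destroy stacking-correlated composition and exaggerate
stability z-scores. Default 1000 shuffles per record (the convention for
this feature family); the test suite and synthetic benchmark use 100 to keep
runtimes proportionate, which widens the z-score noise by ~sqrt(10) but
leaves class separation intact. Shuffled folds reuse the record's
`FoldConfig`.

**Degenerate denominators.** Unpaired or stem-free records (common among
negatives) zero the affected features (`MFEI_2..4`, per-stem ratios,
`Avg_BP_Stem`, and z-scores when the shuffle spread is 0) and flag them
(`*_degenerate` columns on request) instead of dropping the record — the
classifier must see such records, because failing to fold is itself
informative.

**Determinism.** Per-record shuffle seeds are derived from
`sha256(seed:record_id)`, so batch extraction equals record-by-record
extraction and is independent of batch order.

## Feature selection

The Fisher F-score
`F = [(x̄⁺−x̄)² + (x̄⁻−x̄)²] / (s²₊ + s²₋)` (pooled mean; unbiased
within-class variances) ranks features; the compact model keeps those with
`F >= 0.60`. The threshold comparison is inclusive because the published
54-feature score table places a feature scoring exactly 0.60 inside its
40-feature compact model. Zero within-class variance yields `inf` (perfect
separation) or 0 (no separation). The published score table ships in
`mirhairpin.reference` so the compact model is reproducible without the
original miRBase-era datasets.

## Classification and evaluation

* Features are scaled to [−1, 1] by training-fold min/max; constant features
  map to 0.
* SVM (RBF): when `C`/`gamma` are unset, an inner 3-fold grid search over
  `C ∈ 2^-5..2^15`, `gamma ∈ 2^-15..2^3` (log2 steps of 2, balanced-accuracy
  scoring) picks them on the training data. Random forest: 500 trees, sqrt(d)
  features per split. Both use class weights inverse to class frequencies, so
  heavily imbalanced negative sets can be used verbatim.
* Cross-validation is stratified k-fold (default 5) with scaling and any
  grid search refitted inside each training fold; confusion counts are pooled
  across folds (integer counts, consistent with how the benchmark tables are
  reported). Fold assignment orders each class by `sha256(seed:id)` and deals
  round-robin — per-class fold sizes differ by at most one, assignment is
  independent of record order, and adding records leaves most existing
  assignments in place. (A pure hash-mod-k rule would be fully incremental
  but cannot guarantee balanced folds; balance was kept.)
* Reports round half-up to two decimals only at presentation time; the
  label-permutation null in the synthetic benchmark runs with fixed SVM
  hyperparameters (C = 1, gamma = 'scale') — the null's location does not
  depend on tuning, and per-permutation grid searches would dominate runtime.

## Synthetic data

The generator emulates the two ingredients of the original benchmark at
desk scale:

* **Positives**: arm + loop + reverse-complement(arm) hairpins (default stem
  12 bp, loop 6 nt) with i.i.d. per-base substitutions (default 5%)
  supplying the bulges and wobbles of real precursors. Each unmutated
  molecule is verified to fold into exactly the designed stem-loop and
  redrawn otherwise: roughly 0.5% of raw draws admit a strictly
  better-scoring branched structure (loop residues recruiting extra pairs),
  which would silently violate the generator's defining contract of emitting
  single hairpins.
* **Negatives**: either dinucleotide-preserving shuffles of the positives
  (composition-matched, structure-free) or 120-nt fragments sampled
  uniformly without replacement from a genome, rejecting fragments that
  overlap supplied positive intervals (1-based closed coordinates; bounded
  rejection sampling with an explicit error rather than a silent
  undershoot). Fragments come from the given strand only; callers supply the
  reverse complement explicitly.

What passing the synthetic benchmark shows: the pipeline separates designed
stem-loops from composition-matched nulls (balanced accuracy >= 90% in
five-fold CV at n = 200 + 200) and collapses to chance under label
permutation. What it does not show: performance on real viral pre-miRNAs,
whose stems are imperfect in structured (non-i.i.d.) ways, whose negative
space includes genuinely hairpin-like pseudo precursors, and whose
separability is far lower — published figures on the real benchmark are
balanced accuracies slightly above 83%, not the mid-90s the clean synthetic
task yields.

## Known limitations

* The built-in folder's score model is not a nearest-neighbour free-energy
  model; absolute `dG`-derived features are on a dimensionless scale (the
  external Vienna backend restores kcal/mol).
* No pseudoknots, no suboptimal-structure enumeration, no probability
  calibration of classifier scores.
* The published benchmark's exact cross-validation tables are not
  reproducible without the original miRBase v19-era positive set and the
  Pseudo-8494 negative set; the pipeline accepts such data as FASTA, and the
  shipped reference tables cover the published F-scores and independent-test
  confusion counts.
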