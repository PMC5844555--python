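# Methods

## The measurement and its normalization

A 3' UTR reporter screen probes one gene's 3' UTR against a library of ~470
miRNA mimics. Cells carry two luciferases: firefly (`luc2P`) downstream of
the cloned 3' UTR and renilla (`Rluc`) as an unregulated control. A screen
spans six 96-well plates per gene, one gene per plate, with four
non-targeting (NTC) and four vehicle control wells on every plate, and is
replicated in two or three independent experiments per gene.

Raw luminescence is converted in three steps:

1. **Normalized reporter activity.** `NRA = log2(luc2P / Rluc)`. The ratio
   removes well-to-well transfection efficiency; the log makes repression
   and de-repression symmetric around 0.
2. **Per-plate robust z.** `z = (NRA − median(NRA)_p) / MAD(NRA)_p`, with
   `MAD = median(|NRA − median|)` and deliberately *no* 1.4826
   normal-consistency factor — the raw MAD is the definition used
   throughout, so z units are "raw MADs from the plate median". This removes
   plate-level location and scale without being dragged by the few true
   hits. By default the median/MAD pool is every usable well including
   controls (configurable to treatment wells only; the source protocol does
   not pin this down).
3. **Interaction score.** `i = z − median(z)_m`, the per-miRNA
   median-centering. Some mimics depress or elevate reporter output across
   *every* gene (toxicity, off-target load, concentration artifacts). Under
   the assumption that no miRNA genuinely represses most of the screened
   genes, that miRNA-specific offset is exactly the per-miRNA median of z,
   and subtracting it removes the bias while leaving gene-specific
   repression intact. More negative = stronger evidence of interaction.
   The centering pool is all (gene, replicate) values of the miRNA;
   a per-replicate-stratified pool is available behind `center_pool`.

Replicate interaction scores are averaged arithmetically over whatever
replicates are usable; pairs with no usable replicate are reported, never
imputed.

Two comparison metrics are implemented for benchmarking only: the **B-score**
(residuals of a two-way Tukey median polish of the plate's z grid, removing
row/column positional bias; sweeps iterate to 1e-9 or 100 iterations,
medians average the two middle values on even counts) and the **knockdown
percentage** `100·(1 − 2^(NRA − mean NRA_NTC))` relative to the plate's
NTC wells.

## Cutoff calibration

Scores are oriented so negative means interaction, and a score is called
positive iff `s ≤ cutoff` (inclusive — a published cutoff should call a
score exactly at it). The ROC sweep uses every distinct observed score plus
±∞ as thresholds; AUC is the trapezoidal area, which equals the
tie-adjusted Mann–Whitney probability that a random positive scores below a
random negative. The proposed cutoff maximizes accuracy, with ties broken
toward the *lower* (more stringent) threshold, deliberately favoring false
negatives over false positives. AUC differences between metrics are tested
by paired bootstrap over control items (positives and negatives resampled
separately, both metrics evaluated on the same resample); a DeLong
asymptotic variant is available.

Positive controls are literature-validated interactions present in the
screen; negative controls are scores from screening the library on a
reporter with no 3' UTR insert, which shares the library's per-miRNA biases
but can contain no UTR-mediated interaction.

## Binding-site taxonomy

All sequence work is in RNA space (T→U on input), 5'→3', with 1-based
inclusive UTR coordinates. A register is the UTR position opposite miRNA
nt 1; nt k pairs UTR position `register − k + 1` (antiparallel, fixed
register, no bulges except where a class definition says so).

* **Canonical**: Watson–Crick match to the seed (nt 2–7), classified
  maximally 8mer > 7mer-m8 > 7mer-A1 > 6mer. The A1 position must be a
  target adenosine regardless of miRNA nt 1 — it is recognized as A, not by
  pairing. Site-level canonical classes are therefore exclusive and
  exhaustive over seed-matched loci: per-class counts sum to the total.
* **Offset 6mer**: match to nt 3–8 with nt 2 *not* pairing (otherwise the
  locus is canonical and excluded).
* **Seed-mismatch / G:U wobble**: exactly one of nt 2–7 non-WC; wobble if
  the offending pair is G:U in either orientation; the seed position of the
  mismatch is recorded. Registers overlapping canonical sites elsewhere are
  counted independently. Note an offset 6mer locus necessarily doubles as a
  single-mismatch window one register over; both are reported, as the
  combination-level statistics treat classes non-exclusively.
* **G-bulge**: a 7-nt locus equal to the perfect seed target with one extra
  G between the bases pairing nt 6 and nt 5; equivalent deletions inside a
  G run collapse to a single site keyed by window coordinates.
* **Centered**: ≥ 11 consecutive WC pairs fully covering nt 4–14 or 5–15;
  registers whose seed also matches are excluded (they are canonical);
  duplicates across the two windows merge. Reported coordinates span the
  maximal paired run.
* **3' supplementary pairing**: ≥ 3 contiguous WC pairs at nt 13–16 at the
  site's own register; **3' compensatory** (imperfect-seed sites only):
  ≥ 4 contiguous pairs at nt 12–17. Wobbles do not count as pairs, strict
  window containment is required, and truncation at the UTR 5' end means no
  pairing. All three choices (no loops, no wobbles, strict containment) are
  the deterministic defaults; the definitions in circulation are loose on
  these points.

Combination-level annotation counts sites per class per (miRNA, UTR) pair;
class membership at the combination level is non-exclusive (a pair can be
in the 8mer and the 6mer stratum at once), which is why combination counts
per class sum to more than the number of combinations with any canonical
site, while site-level class counts are additive.

## Enrichment statistics

Every stratified comparison asks whether a feature-bearing stratum of
combinations has *more negative* average scores than its complement:
one-sided two-sample Kolmogorov–Smirnov, `D⁺ = sup_x (F_a − F_b)`, with the
asymptotic p-value `exp(−2 D⁺² n_a n_b / (n_a + n_b))` capped at 1. Below 5
observations per group a seeded permutation test replaces the asymptotic
formula. Each invocation (one figure-equivalent batch of strata) is
Benjamini–Hochberg corrected as a family. Predictor precision is
`|predicted ∩ called| / |predicted|`; percentages round half away from zero.

## Clustering of miRNA activity profiles

Each miRNA's profile is its vector of average interaction scores over the
screened genes. Pairwise Pearson correlations use complete-case genes
(≥ 3 shared); zero-variance profiles are dropped and reported. The rows of
the correlation matrix are clustered agglomeratively under Euclidean
distance; the linkage (average by default; complete/single available) is a
free choice since hierarchical-clustering conventions differ, and rows are
pre-sorted lexicographically so ties break deterministically. Family
co-clustering reports, per miRNA family, the largest dendrogram subtree
containing only family members ("k of n").

## The synthetic screen

The generator's defaults are the study's conditions: 470 miRNAs × the 17
cancer genes (7990 combinations), six 96-well plates per gene with 4 NTC +
4 vehicle controls, duplicate screening with TP53 and PHF6 in triplicate,
and 4.9% interaction prevalence (≈ 390/7990). Well-level NRA is additive:

    NRA = gene baseline + plate offset + miRNA bias + effect·1[interaction]
          + edge field + N(0, noise_sd)

with effects drawn N(−3, 0.5) truncated at 0 (log2 units; the magnitudes
are the ones a clearly-scoring reporter hit shows), miRNA bias N(0, 0.5)
by default, plate offsets N(0, 0.25), noise sd 0.5, and an optional
additive edge-well term emulating evaporation gradients. Renilla is drawn
log-normally and firefly reconstructed from the NRA, so the ratio
normalization is genuinely exercised. miRNAs are plated round-robin,
mimicking a fixed library plating. The empty-screen generator forces
prevalence to 0 and can reuse another screen's miRNA biases — the same
physical library screened again — which is what makes the debiasing
property testable.

What the simulator does *not* emulate: transfection toxicity dose-response,
spatial bias beyond a step edge field, heavy-tailed luminescence noise,
and any coupling between a miRNA's bias and its true targets. Passing
tests therefore demonstrate the pipeline's algebraic and statistical
properties under the stated generative model, not performance on real
plates.

Sequence fixtures implant sites built directly from each class definition
into random-background UTRs, with guard bases preventing accidental
upgrades (an offset 6mer locus gets a guaranteed nt-2 mismatch; a 6mer gets
a non-A at A1 and a non-match at m8; a centered site's run is stopped at
exactly nt 4–14). Backgrounds are resampled until all implants are
recovered and no same-class site exists away from the implanted loci, so
the truth table is complete for the implanted classes up to sites the
implants themselves entail at overlapping registers.

Under unit miRNA bias the per-miRNA medians of z-scores spread with a
standard deviation of about 1.3 rather than 1.0 — the per-plate raw MAD of
(bias + noise) is about 0.75 of their standard deviation, and dividing by
it inflates the bias component correspondingly. The tests assert the
qualitative contrast (z medians spread on the order of the injected bias;
interaction-score medians identically zero) rather than a point value.

## Problem sizes and numerical choices

The acceptance script runs the full study scale (7990 pairs plus a
duplicate empty screen, ~22k wells) in seconds; the repeated-seed AUC
ordering check (interaction score vs z, 50 seeds) runs at a reduced scale
of 120 miRNAs × 5 genes × 2 plates per gene, which keeps the whole
recomputation under a minute while leaving dozens of true interactions per
run. Scanner/oracle equivalence is checked on 1000 random 22-nt × 200-nt
pairs. Tolerances: 1e-9 for formula oracles and median-polish convergence;
score TSVs are written with 17 significant digits and parsed with
round-trip float precision so read∘write is bit-exact.

## Known limitations

* The per-plate MAD is the raw, unscaled estimator by definition; z and
  interaction scores are therefore not directly comparable to
  normal-consistent robust z-scores from other pipelines (multiply by
  ~0.6745 to convert).
* The ROC cutoff search is over observed scores only; between-score cutoffs
  can never be optimal under the inclusive call rule, but reported cutoffs
  equal an observed score rather than a midpoint.
* Mismatch-site censuses count every qualifying register, including ones
  overlapping canonical sites at other registers; pipelines that exclude
  such overlaps will report fewer sites.
* The KS p-values are asymptotic unless a group falls below 5 values;
  at the screen's group sizes the approximation error is negligible
  relative to the BH-corrected decision thresholds used.
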